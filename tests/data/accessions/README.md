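# Accession regression inputs

The regression tests in `tests/test_acceptance.py` validate the
detector against known Ankyrin repeat structures.  Experimental
coordinate files are not redistributed with this package; to enable
those tests, place the files here as:

```
<pdbid>.pdb      # e.g. 1N0R.pdb, from https://files.rcsb.org/download/1N0R.pdb
<pdbid>.stride   # optional: STRIDE output for the same file
```

Accessions used: 1N0R, 3EHQ, 3EU9, 1D9S, 3SO8, 1OUV.  When a `.stride`
file is absent the built-in geometric assigner is used, which can
shift boundaries by a few residues relative to STRIDE-based runs.
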