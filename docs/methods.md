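# Methods

## Model

A protein chain is reduced to its Cα trace and represented as an
undirected graph: residues are nodes, and an edge joins residues *i*
and *j* whenever their Cα distance satisfies `d_ij ≤ R_c` with `i ≠ j`.
The default cutoff `R_c = 7 Å` is roughly twice the peptide-bond
length, chosen so that the non-covalent contacts that stabilize the
fold are represented while sequence-remote noise is not.  The cutoff
comparison is inclusive.

The per-residue profile used for detection is the principal eigenvector
of the adjacency matrix (eigenvector centrality): the component of
residue *i* is proportional to the sum of its neighbours' components,
so it rewards residues embedded in densely interconnected
neighbourhoods and, crucially, repeats with the period of a stacked
structural repeat.  For an ANK solenoid the profile shows one dominant
peak per inner (first) helix and a smaller peak per outer (second)
helix, decaying toward the termini.

Detection is rule-based on this profile plus a four-class secondary
structure labelling (helix / strand / turn / coil).  Candidate motifs
are consecutive helix pairs separated only by turn/coil; a candidate is
accepted when the helices are anti-parallel (`d(S1,E2) < d(E1,E2)`,
strict, on Cα coordinates of the segment endpoints), the first helix
dominates the profile (strict comparison of arithmetic means over the
assigned helix residues), the profile peak positions are 5–15 residues
apart (signed, inclusive bounds), and the helix-turn-helix core spans
at least 13 residues (inclusive).  Boundaries: start = first-helix
start − 4, clamped at the chain start (clamping flags the motif
terminal); end = the turn residue of minimum profile value in the
window of up to 15 residues after the second helix, truncated to stop
before the next motif.  Windows with no turn fall back to coil
residues; a window that is empty or runs past the chain ends the motif
at the last residue (terminal).  Finally, motifs chain into tandem
regions while consecutive gaps (residues strictly between one motif's
end and the next motif's start) stay ≤ 17; regions with fewer than two
motifs are discarded.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `r_c` | 7.0 | Å | contact-network cutoff |
| `peak_dist_min` / `peak_dist_max` | 5 / 15 | residues | profile-peak separation window |
| `min_core_len` | 13 | residues | minimum H1–T–H2 span |
| `start_offset` | 4 | residues | motif start before H1 |
| `turn_window` | 15 | residues | end-search window after H2 |
| `tandem_gap_max` | 17 | residues | half a typical ANK motif |
| `min_chain_len` | 50 | residues | batch-mode size filter only |

All thresholds are exposed on the CLI (`--param key=value`); the
defaults reflect the observed length statistics of known ANK motifs
(helices averaging ~8 and ~10 residues, ~2-residue inner turn, ~33
residue full motif).

## Secondary structure

STRIDE output is the reference labelling; DSSP is accepted with the
same pooling, and the two are never mixed within a run.  α (H), 3₁₀
(G) and π (I) codes all pool to helix because repeat helices can be
as short as 3–4 residues — well inside 3₁₀ territory — and a pure-α
reading would drop them.  T pools to turn, E/B to strand, everything
else to coil.  The operational reading of "β-turn" for the
end-boundary search is the turn class; when an assigner emits no turn
inside the search window the coil residues there are used instead.

The built-in fallback assigner is purely geometric (Cα only): residue
*i* is helix-compatible when `d(i,i+3) ∈ [4.5, 6.5] Å` and
`d(i,i+4) ∈ [5.0, 7.0] Å`, with runs of ≥ 4 becoming helices;
`d(i,i+2) ∈ [6.4, 7.4] Å` runs of ≥ 3 become strands; up to 4
non-helix residues directly after a helix are labelled turn.  These
windows bracket ideal α-helix geometry (d₁₃ ≈ 5.0 Å, d₁₄ ≈ 6.2 Å) and
extended-strand geometry (d₁₂ ≈ 6.9 Å).  The assigner is invariant
under rigid motion and needs no external binary, which keeps the whole
test suite self-contained.

## Synthetic fixtures

The fixture generator emulates the *architecture* the detector keys
on, not protein physics.  A copy is an ideal first helix (8 residues),
a 2-residue turn, an anti-parallel ideal second helix (10 residues,
axes 9 Å apart) and a 12-residue connecting loop — 32 residues, near
the canonical motif length.  Copies stack 10 Å apart along a gently
curved solenoid (curvature radius 25 Å measured at the inner helix
column), which compresses the inner-helix column into mutual contact
range while fanning the outer helices apart; that asymmetry is what
makes the first helix the eigenvector-dominant one, as in real ANK
stacks.  Loops leave the outer helix on a wide outward arc and
re-enter from below the next inner helix, mimicking how the real ANK
hairpin packs under the stack — and, numerically, keeping loop
residues out of contact range of the outer helices.  Coordinates get
seeded Gaussian jitter (σ = 0.05 Å) and a steric floor of 2.5 Å is
enforced.

What the fixtures do **not** reproduce: side chains, sequence
variation, irregular helix geometry, disordered loops, neighbouring
domains, and assigner noise.  Passing the recovery tests therefore
demonstrates that the rule set and its implementation are faithful and
deterministic, not that the method's published accuracy on real
structures is reproduced; the accession regression tests cover real
structures when their coordinate files are supplied.

## Numerical choices

* Eigen decomposition uses a dense symmetric solver; the contract is
  the residual bound `‖A·x − λ·x‖∞ ≤ 1e−8·max(1, λ)` and unit norm,
  not the algorithm.  The sign is fixed by a positive component sum
  (positive largest-magnitude entry in the zero-sum case, which can
  occur only on disconnected graphs).  Disconnected chains are
  processed as a single matrix — components off the dominant one get
  near-zero weight — and flagged in the report.
* Ties in profile maxima (peaks) and minima (ends) resolve to the
  lowest index.
* The greedy scan advances two helices past an accepted motif (motifs
  never share a helix) and one helix past a rejected candidate.
* End windows that contain neither turn nor coil residues (all
  helix/strand) close at the window's last residue, marked `clipped`.
* Superposition RMSD is closed-form least squares (SVD) with the
  determinant sign corrected so reflections are never used.  Unequal
  lengths are handled by sliding the shorter set over every contiguous
  window of the longer and reporting the minimum — a deliberate
  simplification relative to fragment-alignment engines, justified by
  the near-constant motif length; absolute values may differ slightly
  from fragment-aligned RMSDs.
* Structure reading keeps the first model of multi-model entries, the
  highest-occupancy altLoc conformer (ties: blank < 'A' < 'B'),
  treats amino-acid HETATM modifications such as MSE as their parent
  residue, and skips everything without a Cα.  Author numbering and
  insertion codes are preserved for reporting; all internal indices
  are sequential file-order positions.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
chains of 32–192 residues (2–6 copies), where the dense eigensolver
and the quadratic distance matrix are instantaneous; batch mode on
real structures scales to typical chain lengths (≤ ~1500 residues)
without sparse machinery.

## Known limitations

* Detection quality on real structures inherits the quality of the
  secondary-structure assignment; a missed helix merges or drops
  motifs.  The geometric fallback is cruder than STRIDE/DSSP near
  helix termini, so boundaries can shift by a few residues.
* Motifs separated by more than 17 residues are reported as separate
  regions and singletons are dropped, so genuinely isolated copies are
  invisible by design.
* The rule set is ANK-specific; profile extraction is generic, but no
  classification rules for TPR/ARM/LRR/Kelch are included.
* The anti-parallel test compares segment-endpoint distances only; it
  is a heuristic that can misjudge strongly bent helices.
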