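"""Read PDB/mmCIF coordinate files into ordered per-chain C-alpha records.

The detector works on a protein contact network whose nodes are the
C-alpha atoms of one chain, so all that is retained per residue is the
chain id, author numbering (number + insertion code, used only for
reporting), the residue name and the C-alpha coordinates.  Internal
indices are sequential 0-based positions in file order; they are the
node indices of the graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import EmptyStructureError, InputError, MissingChainError

__all__ = [
    "ResidueRecord",
    "ChainStructure",
    "read_structure",
    "select_chain",
    "write_chain_pdb",
]


@dataclass(frozen=True)
class ResidueRecord:
    """One residue reduced to its C-alpha atom.

    ``author_seq``/``icode`` reproduce the numbering printed in the
    source file; ``ca_xyz`` is the C-alpha position in Angstrom.
    """

    chain_id: str
    author_seq: int
    icode: str
    resname: str
    ca_xyz: tuple[float, float, float]

    def __post_init__(self):
        if len(self.ca_xyz) != 3 or not all(math.isfinite(c) for c in self.ca_xyz):
            raise ValueError("ca_xyz must have exactly 3 finite components")

    @property
    def author_label(self) -> str:
        """Author residue number with insertion code, e.g. ``'100A'``."""
        return f"{self.author_seq}{self.icode.strip()}"


# 3-letter -> 1-letter fallback for names gemmi does not tabulate
_UNKNOWN = "X"


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return _UNKNOWN
    code = info.one_letter_code.upper()
    return code if code.isalpha() else _UNKNOWN


@dataclass
class ChainStructure:
    """Ordered C-alpha records of one chain: the node set of the graph."""

    chain_id: str
    residues: list[ResidueRecord] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.residues)

    @property
    def seq(self) -> str:
        return "".join(_one_letter(r.resname) for r in self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) float array of C-alpha coordinates in file order."""
        return np.array([r.ca_xyz for r in self.residues], dtype=float)

    def author_label(self, i: int) -> str:
        return self.residues[i].author_label

    def __len__(self) -> int:
        return self.n


def _altloc_rank(altloc: str) -> tuple[float, str]:
    # blank conformer sorts before 'A' < 'B' ...
    return ("" if altloc in ("", "\x00") else altloc,)


def _pick_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Highest-occupancy C-alpha; occupancy ties broken by altloc label."""
    cas = [
        a
        for a in residue
        if a.name == "CA" and a.element.name == "C"
    ]
    if not cas:
        return None
    return min(cas, key=lambda a: (-a.occ, _altloc_rank(a.altloc)))


def read_structure(path: str | Path, model: int = 1) -> list[ChainStructure]:
    """Read one model of a PDB/mmCIF file as per-chain C-alpha chains.

    Parameters
    ----------
    path:
        Coordinate file (PDB format; mmCIF also accepted).
    model:
        1-based model ordinal; the default (first model) matches a
        single-snapshot analysis of NMR entries.

    Returns
    -------
    list of ChainStructure, one per chain with at least one C-alpha.
    Residues without a C-alpha atom (including all nucleic-acid and
    ligand residues) are skipped.  HETATM residues that are tabulated
    amino-acid modifications (e.g. MSE) are kept as their parent type.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise InputError(f"could not parse {path}: {exc}") from exc

    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no models")
    idx = model - 1
    if not 0 <= idx < len(st):
        raise InputError(f"model {model} not present ({len(st)} model(s))")
    mdl = st[idx]

    chains: list[ChainStructure] = []
    for ch in mdl:
        records: list[ResidueRecord] = []
        for res in ch:
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            if res.het_flag == "H" and not is_aa:
                continue  # ions, ligands, waters
            ca = _pick_ca(res)
            if ca is None:
                continue
            records.append(
                ResidueRecord(
                    chain_id=ch.name,
                    author_seq=res.seqid.num,
                    icode=(res.seqid.icode or " "),
                    resname=res.name,
                    ca_xyz=(ca.pos.x, ca.pos.y, ca.pos.z),
                )
            )
        if records:
            chains.append(ChainStructure(chain_id=ch.name, residues=records))

    if not chains:
        raise EmptyStructureError(f"{path}: no C-alpha atoms found")
    return chains


def select_chain(chains: list[ChainStructure], chain_id: str = "A") -> ChainStructure:
    """Return the chain with the given id (default ``'A'``)."""
    if not chains:
        raise MissingChainError(chain_id, [])
    for ch in chains:
        if ch.chain_id == chain_id:
            return ch
    raise MissingChainError(chain_id, [c.chain_id for c in chains])


_ATOM_FMT = (
    "ATOM  {serial:5d}  CA  {resname:>3s} {chain:1s}{num:4d}{icode:1s}   "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}"
)


def write_chain_pdb(chain: ChainStructure, path: str | Path) -> None:
    """Write minimal C-alpha-only PDB ATOM records for one chain.

    Round-trips through :func:`read_structure`: author numbering,
    insertion codes, residue names and coordinates (3 decimals) are
    preserved.
    """
    lines = []
    for i, r in enumerate(chain.residues, start=1):
        x, y, z = r.ca_xyz
        lines.append(
            _ATOM_FMT.format(
                serial=i,
                resname=r.resname,
                chain=chain.chain_id[:1] or "A",
                num=r.author_seq,
                icode=r.icode[:1] or " ",
                x=x,
                y=y,
                z=z,
                occ=1.0,
                b=0.0,
                el="C",
            )
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
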