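"""Per-residue secondary structure: STRIDE/DSSP parsers and a C-alpha fallback.

The detector only distinguishes four classes — HELIX, STRAND, TURN and
COIL — emitted as maximal runs (segments) that partition the chain.
STRIDE is the reference assigner; DSSP output is accepted with the same
class pooling; and a purely geometric C-alpha assigner is built in so
that synthetic fixtures and structures without an external assignment
can still be processed.

Class pooling: alpha (H), 3-10 (G) and pi (I) helices all count as
HELIX, because individual repeat helices can be as short as 3-4
residues, well inside 3-10 territory.  E/B strands pool to STRAND and
T to TURN; everything else is COIL.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import AssignmentMissingError, TooShortChainError
from .structure_io import ChainStructure

__all__ = [
    "SSClass",
    "SSESegment",
    "segments_from_classes",
    "classes_from_segments",
    "parse_stride",
    "parse_dssp",
    "assign_internal",
]


class SSClass(enum.Enum):
    HELIX = "H"
    STRAND = "E"
    TURN = "T"
    COIL = "C"


@dataclass(frozen=True)
class SSESegment:
    """One maximal run of a single secondary-structure class.

    ``start``/``end`` are inclusive internal chain indices.
    """

    ss_class: SSClass
    start: int
    end: int
    source: str = "internal"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def segments_from_classes(classes: list[SSClass], source: str) -> list[SSESegment]:
    """Collapse a per-residue class list into maximal-run segments."""
    if not classes:
        return []
    segs: list[SSESegment] = []
    start = 0
    for i in range(1, len(classes) + 1):
        if i == len(classes) or classes[i] is not classes[start]:
            segs.append(SSESegment(classes[start], start, i - 1, source))
            start = i
    return segs


def classes_from_segments(segments: list[SSESegment], n: int) -> list[SSClass]:
    """Inverse of :func:`segments_from_classes`; validates the partition."""
    classes: list[SSClass | None] = [None] * n
    for seg in segments:
        for i in range(seg.start, seg.end + 1):
            if classes[i] is not None:
                raise ValueError(f"overlapping segments at index {i}")
            classes[i] = seg.ss_class
    if any(c is None for c in classes):
        raise ValueError("segments do not cover the chain")
    return classes  # type: ignore[return-value]


_STRIDE_MAP = {"H": SSClass.HELIX, "G": SSClass.HELIX, "I": SSClass.HELIX,
               "E": SSClass.STRAND, "B": SSClass.STRAND, "b": SSClass.STRAND,
               "T": SSClass.TURN}
_DSSP_MAP = {"H": SSClass.HELIX, "G": SSClass.HELIX, "I": SSClass.HELIX,
             "E": SSClass.STRAND, "B": SSClass.STRAND,
             "T": SSClass.TURN}


def _split_author_label(token: str) -> tuple[int, str]:
    """Split '100' / '100A' / '-5' into (number, insertion code)."""
    icode = " "
    if token and token[-1].isalpha():
        icode = token[-1]
        token = token[:-1]
    return int(token), icode


def _apply_records(
    records: dict[tuple[int, str], SSClass],
    chain: ChainStructure,
    source: str,
) -> list[SSESegment]:
    """Match (author number, icode)-keyed codes onto the chain residues."""
    if not records:
        raise AssignmentMissingError(
            f"no {source} records found for chain {chain.chain_id!r}"
        )
    classes = [SSClass.COIL] * chain.n
    keys = {(r.author_seq, r.icode): i for i, r in enumerate(chain.residues)}
    matched = 0
    for key, cls in records.items():
        i = keys.get(key)
        if i is None:
            continue
        classes[i] = cls
        matched += 1
    unmatched = len(records) - matched
    if unmatched:
        warnings.warn(
            f"{source}: {unmatched} record(s) did not match any chain "
            f"{chain.chain_id!r} residue and were dropped",
            stacklevel=3,
        )
    if matched == 0:
        raise AssignmentMissingError(
            f"{source} records exist but none match chain {chain.chain_id!r}"
        )
    return segments_from_classes(classes, source)


def parse_stride(path: str | Path, chain: ChainStructure) -> list[SSESegment]:
    """Parse STRIDE ``ASG`` records for one chain.

    Records are matched to chain residues by author number + insertion
    code; residues without a record are COIL, records for residues not
    present in the chain are dropped with a warning.
    """
    records: dict[tuple[int, str], SSClass] = {}
    for line in Path(path).read_text().splitlines():
        if not line.startswith("ASG"):
            continue
        fields = line.split()
        # ASG resname chain pdb_num ordinal code full_name phi psi area
        if len(fields) < 6:
            continue
        if fields[2] != chain.chain_id:
            continue
        try:
            num, icode = _split_author_label(fields[3])
        except ValueError:
            continue
        code = fields[5]
        records[(num, icode)] = _STRIDE_MAP.get(code, SSClass.COIL)
    return _apply_records(records, chain, "stride")


def parse_dssp(path: str | Path, chain: ChainStructure) -> list[SSESegment]:
    """Parse a classic-format ``.dssp`` file for one chain."""
    records: dict[tuple[int, str], SSClass] = {}
    in_body = False
    for line in Path(path).read_text().splitlines():
        if line.lstrip().startswith("#  RESIDUE"):
            in_body = True
            continue
        if not in_body or len(line) < 17:
            continue
        if line[13] == "!":  # chain break marker
            continue
        if line[11] != chain.chain_id:
            continue
        try:
            num = int(line[5:10])
        except ValueError:
            continue
        icode = line[10] if line[10] != " " else " "
        code = line[16]
        records[(num, icode)] = _DSSP_MAP.get(code, SSClass.COIL)
    return _apply_records(records, chain, "dssp")


# C-alpha distance windows (Angstrom) characteristic of helical geometry:
# in an ideal alpha helix d(i,i+3) ~ 5.0 and d(i,i+4) ~ 6.2, while in an
# extended strand d(i,i+2) ~ 6.9.
HELIX_D13 = (4.5, 6.5)
HELIX_D14 = (5.0, 7.0)
STRAND_D12 = (6.4, 7.4)
MIN_HELIX_RUN = 4
MIN_STRAND_RUN = 3
TURN_AFTER_HELIX = 4


def _mark_runs(flags: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, f in enumerate(flags.tolist() + [False]):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start >= min_run:
                runs.append((start, i - 1))
            start = None
    return runs


def assign_internal(chain: ChainStructure) -> list[SSESegment]:
    """Geometric C-alpha-only secondary-structure assignment.

    Residue ``i`` is helix-compatible when d(i, i+3) lies in
    ``HELIX_D13`` and d(i, i+4) in ``HELIX_D14``; runs of at least 4
    such residues are HELIX.  Strand-compatible means d(i, i+2) in
    ``STRAND_D12`` for runs of at least 3.  Up to 4 non-helix residues
    immediately after a helix are TURN; everything else is COIL.
    """
    n = chain.n
    if n < 5:
        raise TooShortChainError(f"internal assigner needs n >= 5, got {n}")
    xyz = chain.coords

    def dist(off: int) -> np.ndarray:
        return np.linalg.norm(xyz[off:] - xyz[:-off], axis=1)

    d2, d3, d4 = dist(2), dist(3), dist(4)
    helix_ok = np.zeros(n, dtype=bool)
    helix_ok[: n - 4] = (
        (d3[: n - 4] >= HELIX_D13[0]) & (d3[: n - 4] <= HELIX_D13[1])
        & (d4 >= HELIX_D14[0]) & (d4 <= HELIX_D14[1])
    )
    strand_ok = np.zeros(n, dtype=bool)
    strand_ok[: n - 2] = (d2 >= STRAND_D12[0]) & (d2 <= STRAND_D12[1])

    classes = [SSClass.COIL] * n
    for s, e in _mark_runs(helix_ok, MIN_HELIX_RUN):
        for i in range(s, e + 1):
            classes[i] = SSClass.HELIX
    for s, e in _mark_runs(strand_ok, MIN_STRAND_RUN):
        for i in range(s, e + 1):
            if classes[i] is SSClass.COIL:
                classes[i] = SSClass.STRAND
    # short window after each helix becomes TURN
    i = 0
    while i < n:
        if classes[i] is SSClass.HELIX:
            while i < n and classes[i] is SSClass.HELIX:
                i += 1
            j = i
            while j < n and j - i < TURN_AFTER_HELIX and classes[j] is SSClass.COIL:
                classes[j] = SSClass.TURN
                j += 1
            i = j
        else:
            i += 1
    return segments_from_classes(classes, "internal")
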