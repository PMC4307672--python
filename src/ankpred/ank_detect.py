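"""Ankyrin-repeat detection rules over the eigenvector-centrality profile.

An ANK motif is a helix-turn-helix (H1-T-H2) core followed by a long
loop ending in a beta-turn.  A candidate pair of consecutive helices is
accepted as an ANK motif when

(i)   the helices are anti-parallel: d(S1, E2) < d(E1, E2), where S1 is
      the start of H1 and E1/E2 the ends of H1/H2 (C-alpha distances);
(ii)  H1 is buried: the mean A_levc over H1 strictly exceeds that over
      H2 (the inner helix of the stack is the more central one);
(iii) the two A_levc peak positions are 5-15 residues apart; and
(iv)  the H1-T-H2 core spans at least 13 residues.

Motif boundaries: the repeat starts 4 residues before H1 (clamped at
the chain start); the end is the lowest-A_levc turn residue within a
window after H2 (at most 15 residues, truncated at the next repeat),
falling back to coil residues, or the chain end for a terminal repeat.
At least two accepted motifs whose gaps are at most 17 residues (half a
typical ANK motif) form a reported tandem repeat region; isolated
single motifs are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .contact_graph import EigenProfile
from .ss_assign import SSClass, SSESegment, classes_from_segments
from .structure_io import ChainStructure

__all__ = [
    "DetectionParams",
    "HelixPair",
    "AnkRepeat",
    "RepeatRegion",
    "find_hth_candidates",
    "is_antiparallel",
    "eigen_dominance",
    "peak_distance_ok",
    "core_length_ok",
    "repeat_start",
    "repeat_end",
    "detect_ank",
    "verify_repeat",
    "chain_passes_batch_filter",
]


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the rule set (residue counts unless noted).

    Defaults follow the length statistics of known ANK motifs: helices
    average ~8 and ~10 residues with a ~2-residue inner turn, the core
    is at least 13 residues, profile peaks sit 5-15 residues apart, and
    a typical full motif is ~33 residues, giving the half-motif tandem
    gap threshold of 17.
    """

    r_c: float = 7.0  # contact cutoff, Angstrom
    peak_dist_min: int = 5
    peak_dist_max: int = 15
    min_core_len: int = 13
    start_offset: int = 4
    turn_window: int = 15
    tandem_gap_max: int = 17
    min_chain_len: int = 50  # batch-mode filter only

    def __post_init__(self):
        numeric = {
            k: getattr(self, k)
            for k in (
                "r_c", "peak_dist_min", "peak_dist_max", "min_core_len",
                "start_offset", "turn_window", "tandem_gap_max", "min_chain_len",
            )
        }
        for k, v in numeric.items():
            if v <= 0:
                raise ValueError(f"{k} must be positive, got {v}")
        if self.peak_dist_min > self.peak_dist_max:
            raise ValueError("peak_dist_min must be <= peak_dist_max")

    def replace(self, **kw) -> "DetectionParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class HelixPair:
    """Two consecutive helices with only turn/coil between them."""

    h1: SSESegment
    h2: SSESegment
    peak1: int  # index of the A_levc maximum inside h1
    peak2: int  # index of the A_levc maximum inside h2

    @property
    def s1(self) -> int:
        return self.h1.start

    @property
    def e1(self) -> int:
        return self.h1.end

    @property
    def e2(self) -> int:
        return self.h2.end


@dataclass(frozen=True)
class AnkRepeat:
    """One predicted ANK motif with assigned boundaries."""

    start: int
    end: int
    pair: HelixPair
    terminal: bool = False
    end_rule: str = "turn_min"  # turn_min | chain_end | clipped


@dataclass
class RepeatRegion:
    """A tandem group of two or more ANK motifs."""

    repeats: list[AnkRepeat] = field(default_factory=list)

    @property
    def region_start(self) -> int:
        return self.repeats[0].start

    @property
    def region_end(self) -> int:
        return self.repeats[-1].end

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


def _peak_index(profile: EigenProfile, seg: SSESegment) -> int:
    """Index of the maximum A_levc inside a segment (ties: lowest index)."""
    window = profile.levc[seg.start : seg.end + 1]
    return seg.start + int(np.argmax(window))


def find_hth_candidates(
    segments: list[SSESegment], profile: EigenProfile
) -> list[HelixPair]:
    """All consecutive helix pairs separated only by TURN/COIL segments."""
    pairs: list[HelixPair] = []
    helices = [s for s in segments if s.ss_class is SSClass.HELIX]
    for h1, h2 in zip(helices, helices[1:]):
        if _only_turn_coil_between(segments, h1, h2):
            pairs.append(
                HelixPair(h1, h2, _peak_index(profile, h1), _peak_index(profile, h2))
            )
    return pairs


def _only_turn_coil_between(
    segments: list[SSESegment], h1: SSESegment, h2: SSESegment
) -> bool:
    for seg in segments:
        if h1.end < seg.start and seg.end < h2.start:
            if seg.ss_class not in (SSClass.TURN, SSClass.COIL):
                return False
    return True


def is_antiparallel(chain: ChainStructure, pair: HelixPair) -> bool:
    """Criterion (i): d(S1, E2) < d(E1, E2), strict (C-alpha distances)."""
    xyz = chain.coords
    d_s1e2 = float(np.linalg.norm(xyz[pair.s1] - xyz[pair.e2]))
    d_e1e2 = float(np.linalg.norm(xyz[pair.e1] - xyz[pair.e2]))
    return d_s1e2 < d_e1e2


def eigen_dominance(profile: EigenProfile, pair: HelixPair) -> bool:
    """Criterion (ii): mean A_levc over H1 strictly exceeds that over H2."""
    m1 = float(profile.levc[pair.h1.start : pair.h1.end + 1].mean())
    m2 = float(profile.levc[pair.h2.start : pair.h2.end + 1].mean())
    return m1 > m2


def peak_distance_ok(pair: HelixPair, params: DetectionParams) -> bool:
    """Criterion (iii): peak separation within [peak_dist_min, peak_dist_max]."""
    d = pair.peak2 - pair.peak1
    return params.peak_dist_min <= d <= params.peak_dist_max


def core_length_ok(pair: HelixPair, params: DetectionParams) -> bool:
    """Criterion (iv): H1-T-H2 core (S1..E2) spans >= min_core_len residues."""
    return (pair.e2 - pair.s1 + 1) >= params.min_core_len


def repeat_start(pair: HelixPair, params: DetectionParams) -> tuple[int, bool]:
    """Motif start = S1 - start_offset, clamped at 0.

    Returns ``(start, terminal)`` where ``terminal`` is True when the
    clamp was applied (incomplete N-terminal copy).
    """
    raw = pair.s1 - params.start_offset
    return max(0, raw), raw < 0


def repeat_end(
    profile: EigenProfile,
    segments: list[SSESegment],
    pair: HelixPair,
    next_start: int | None,
    params: DetectionParams,
) -> tuple[int, str]:
    """Motif end: lowest-A_levc turn residue in the window after H2.

    The window runs from E2+1 for ``turn_window`` residues, truncated
    so it stops before the next repeat's start.  TURN residues are
    preferred; if the window has none, COIL residues are used.  A
    window that is empty or runs past the chain end marks a terminal
    repeat ending at the last residue; an end that would collide with
    the next repeat is clipped to just before it.
    """
    n = profile.n
    e2 = pair.e2
    limit = params.turn_window
    if next_start is not None:
        limit = min(limit, next_start - e2 - 1)

    if limit <= 0 or e2 + limit > n - 1:
        end, rule = n - 1, "chain_end"
    else:
        window = list(range(e2 + 1, e2 + limit + 1))
        classes = classes_from_segments(segments, n)
        for wanted in (SSClass.TURN, SSClass.COIL):
            idxs = [i for i in window if classes[i] is wanted]
            if idxs:
                vals = profile.levc[idxs]
                end, rule = idxs[int(np.argmin(vals))], "turn_min"
                break
        else:  # window entirely helix/strand: fall back to its last residue
            end, rule = window[-1], "clipped"

    if next_start is not None and end >= next_start:
        end, rule = next_start - 1, "clipped"
    return end, rule


def detect_ank(
    chain: ChainStructure,
    segments: list[SSESegment],
    profile: EigenProfile,
    params: DetectionParams = DetectionParams(),
) -> list[RepeatRegion]:
    """Run the full rule set and group motifs into tandem regions.

    Greedy left-to-right scan over helices: a pair passing all four
    criteria is accepted and the scan resumes after its H2 (motifs
    never share a helix); a failing pair advances by one helix.
    Accepted motifs get boundaries in a second pass (so each end knows
    the next motif's start), then motifs with gaps of at most
    ``tandem_gap_max`` residues chain into regions; regions with fewer
    than two motifs are discarded.
    """
    if not (chain.n == profile.n):
        raise ValueError("chain and profile disagree on residue count")
    classes = classes_from_segments(segments, chain.n)  # validates the partition
    del classes

    helices = [s for s in segments if s.ss_class is SSClass.HELIX]
    accepted: list[HelixPair] = []
    i = 0
    while i + 1 < len(helices):
        h1, h2 = helices[i], helices[i + 1]
        if _only_turn_coil_between(segments, h1, h2):
            pair = HelixPair(h1, h2, _peak_index(profile, h1), _peak_index(profile, h2))
            if (
                is_antiparallel(chain, pair)
                and eigen_dominance(profile, pair)
                and peak_distance_ok(pair, params)
                and core_length_ok(pair, params)
            ):
                accepted.append(pair)
                i += 2
                continue
        i += 1

    starts = [repeat_start(p, params) for p in accepted]
    repeats: list[AnkRepeat] = []
    for j, pair in enumerate(accepted):
        start, clamped = starts[j]
        next_start = starts[j + 1][0] if j + 1 < len(accepted) else None
        end, rule = repeat_end(profile, segments, pair, next_start, params)
        repeats.append(
            AnkRepeat(
                start=start,
                end=end,
                pair=pair,
                terminal=clamped or rule == "chain_end",
                end_rule=rule,
            )
        )

    regions: list[RepeatRegion] = []
    group: list[AnkRepeat] = []
    for rep in repeats:
        if group and (rep.start - group[-1].end - 1) > params.tandem_gap_max:
            if len(group) >= 2:
                regions.append(RepeatRegion(repeats=group))
            group = []
        group.append(rep)
    if len(group) >= 2:
        regions.append(RepeatRegion(repeats=group))
    return regions


def verify_repeat(
    chain: ChainStructure,
    profile: EigenProfile,
    repeat: AnkRepeat,
    params: DetectionParams = DetectionParams(),
) -> bool:
    """Independent post-hoc re-check that a reported motif satisfies
    all four acceptance criteria and its boundary invariants."""
    p = repeat.pair
    return (
        is_antiparallel(chain, p)
        and eigen_dominance(profile, p)
        and peak_distance_ok(p, params)
        and core_length_ok(p, params)
        and repeat.start <= p.s1 < p.e2 <= repeat.end
        and 0 <= repeat.start
        and repeat.end < chain.n
    )


def chain_passes_batch_filter(
    chain: ChainStructure, params: DetectionParams = DetectionParams()
) -> bool:
    """Batch-mode size filter: short fragments cannot hold two motifs."""
    return chain.n >= params.min_chain_len
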