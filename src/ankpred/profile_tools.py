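"""Per-repeat profile overlays and rigid-body superposition RMSD.

Two validation tools: (1) slicing the A_levc profile per predicted
repeat and normalizing each slice by its largest peak, so copies of the
same motif overlay almost perfectly; (2) optimal rigid-body
least-squares superposition (Kabsch) of two C-alpha coordinate sets,
used to compare predicted motifs against a reference ANK motif.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ank_detect import AnkRepeat
from .contact_graph import EigenProfile
from .errors import DegenerateProfileError, TooFewPointsError

__all__ = [
    "RepeatProfile",
    "extract_profile",
    "normalize_profile",
    "profile_correlation",
    "kabsch_rotation",
    "superpose_rmsd",
]


@dataclass(frozen=True)
class RepeatProfile:
    """A_levc slice over one repeat's [start, end] span."""

    start: int
    end: int
    values: np.ndarray
    normalized: bool = False


def extract_profile(profile: EigenProfile, repeat: AnkRepeat) -> RepeatProfile:
    """Slice the chain profile over one predicted repeat."""
    return RepeatProfile(
        start=repeat.start,
        end=repeat.end,
        values=profile.levc[repeat.start : repeat.end + 1].copy(),
    )


def normalize_profile(p: RepeatProfile) -> RepeatProfile:
    """Divide by the largest peak so the copies overlay on one scale."""
    if p.values.size == 0:
        raise DegenerateProfileError("empty profile slice")
    peak = float(np.max(p.values))
    if peak <= 0:
        raise DegenerateProfileError("all-zero profile slice cannot be normalized")
    return RepeatProfile(p.start, p.end, p.values / peak, normalized=True)


def profile_correlation(a: RepeatProfile, b: RepeatProfile) -> float:
    """Pearson correlation of two repeat profiles over their common length.

    Copies of a structural repeat differ slightly in length; the
    overlay aligns them at their starts and compares the shared span.
    """
    m = min(a.values.size, b.values.size)
    if m < 3:
        raise TooFewPointsError("need at least 3 shared positions")
    x, y = a.values[:m], b.values[:m]
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateProfileError("constant profile has no correlation")
    return float(np.corrcoef(x, y)[0, 1])


def kabsch_rotation(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal proper rotation of centred ``a`` onto centred ``b``.

    Returns ``(R, rmsd)`` minimizing ||R a_c - b_c|| over rotations
    (reflections disallowed: the determinant sign is corrected).
    """
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.array([1.0, 1.0, d])
    r = vt.T @ np.diag(diag) @ u.T
    # explicit residual: the closed-form trace expression loses precision
    # to cancellation when the fit is near-exact
    msd = float(np.mean(np.sum((ac @ r.T - bc) ** 2, axis=1)))
    return r, float(np.sqrt(msd))


def superpose_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimal rigid-body RMSD between two ordered C-alpha sets.

    Correspondence is positional (i <-> i).  When lengths differ, the
    shorter set is aligned against every contiguous window of the
    longer and the minimum RMSD is returned (ANK motifs are
    near-constant length, so a sliding window replaces fragment
    alignment).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 3 or b.shape[1] != 3:
        raise ValueError("expected (n, 3) coordinate arrays")
    if min(a.shape[0], b.shape[0]) < 3:
        raise TooFewPointsError("superposition needs at least 3 points")
    if a.shape[0] > b.shape[0]:
        a, b = b, a
    m, n = a.shape[0], b.shape[0]
    best = np.inf
    for off in range(n - m + 1):
        _, rmsd = kabsch_rotation(a, b[off : off + m])
        best = min(best, rmsd)
    return float(best)
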