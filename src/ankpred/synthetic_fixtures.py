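"""Parametric synthetic C-alpha geometries for testing the detector.

Three generators: ideal alpha helices (standard C-alpha helix geometry:
1.5 A rise, 2.3 A radius, 100 degrees twist per residue), fully
extended chains, and ANK-like multi-copy folds.  The ANK fixture stacks
helix-turn-helix units on a gently curved solenoid so that, by
construction, every detection criterion holds: the two helices of a
copy are anti-parallel and packed within contact range; the first-helix
column lies on the concave (inner) side of the solenoid where adjacent
copies touch, making H1 the buried, eigenvector-dominant helix; and the
connecting loop bulges outward on a wide arc so it adds no spurious
contacts.  Fixtures are poly-alanine: the rules never look at sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import pdist

from .errors import FixtureConstructionError
from .structure_io import ChainStructure, ResidueRecord, write_chain_pdb

__all__ = [
    "HelixSpec",
    "AnkFixtureSpec",
    "build_helix",
    "build_extended_chain",
    "build_parallel_bundle",
    "build_ank_fixture",
    "write_fixture_pdb",
    "coords_to_chain",
]

CA_STEP = 3.8  # consecutive C-alpha distance, Angstrom
MIN_SEPARATION = 2.5  # steric floor for any C-alpha pair


@dataclass(frozen=True)
class HelixSpec:
    """Ideal C-alpha helix: points on a circular helix around an axis."""

    n_res: int
    rise: float = 1.5  # A per residue along the axis
    radius: float = 2.3  # A, C-alpha distance from the axis
    twist: float = 100.0  # degrees per residue
    axis_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_direction: tuple[float, float, float] = (0.0, 1.0, 0.0)
    phase: float = 0.0  # radians

    def __post_init__(self):
        if self.n_res < 1:
            raise ValueError("n_res must be >= 1")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if not np.isclose(np.linalg.norm(self.axis_direction), 1.0, atol=1e-6):
            raise ValueError("axis_direction must be a unit vector")


def _frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair perpendicular to ``direction``."""
    d = direction / np.linalg.norm(direction)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    u = ref - (ref @ d) * d
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def build_helix(spec: HelixSpec) -> np.ndarray:
    """(n_res, 3) C-alpha coordinates of the parametric helix."""
    d = np.asarray(spec.axis_direction, dtype=float)
    origin = np.asarray(spec.axis_origin, dtype=float)
    u, v = _frame(d)
    i = np.arange(spec.n_res)
    ang = np.deg2rad(spec.twist) * i + spec.phase
    return (
        origin[None, :]
        + np.outer(i * spec.rise, d)
        + spec.radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    )


def build_extended_chain(n_res: int, step: float = CA_STEP) -> np.ndarray:
    """Fully extended chain: collinear points ``step`` apart along x."""
    pts = np.zeros((n_res, 3))
    pts[:, 0] = np.arange(n_res) * step
    return pts


def _arc_points(
    p0: np.ndarray, p1: np.ndarray, n_mid: int, bulge: np.ndarray, step: float = CA_STEP
) -> np.ndarray:
    """``n_mid`` points on a circular arc from p0 to p1 bulging along ``bulge``.

    The arc's wrap angle is chosen so successive points sit ~``step``
    apart, letting a long chain segment span a short straight-line gap
    without self-clashes (unlike a zigzag, arc points never fold back).
    """
    chord_vec = p1 - p0
    c = float(np.linalg.norm(chord_vec))
    if c < 1e-9:
        raise FixtureConstructionError("arc endpoints coincide")
    arclen = (n_mid + 1) * step
    ratio = arclen / c
    if ratio <= 1.0:  # nearly straight: linear interpolation suffices
        ts = np.linspace(0.0, 1.0, n_mid + 2)[1:-1]
        return p0[None, :] + np.outer(ts, chord_vec)
    # wrap angle theta solves theta / (2 sin(theta/2)) = arclen / chord
    f = lambda t: t / (2.0 * np.sin(t / 2.0)) - ratio
    theta = brentq(f, 1e-9, 2.0 * np.pi - 1e-6)
    r = c / (2.0 * np.sin(theta / 2.0))
    chord_hat = chord_vec / c
    m = bulge - (bulge @ chord_hat) * chord_hat
    if np.linalg.norm(m) < 1e-9:
        raise FixtureConstructionError("bulge direction parallel to chord")
    m /= np.linalg.norm(m)
    axis = np.cross(chord_hat, m)
    axis /= np.linalg.norm(axis)
    mid = (p0 + p1) / 2.0
    half = abs(r * np.cos(theta / 2.0))
    ts = theta * np.arange(1, n_mid + 1) / (n_mid + 1)
    # two candidate centers (either side of the chord) x two rotation
    # senses; keep the combination that closes on p1 with its apex on
    # the bulge side
    for center in (mid - m * half, mid + m * half):
        v0 = p0 - center
        for sense in (1.0, -1.0):
            end = _rotate_about(v0, axis, np.array([sense * theta]))[0] + center
            if np.linalg.norm(end - p1) > 1e-6:
                continue
            apex = (
                _rotate_about(v0, axis, np.array([sense * theta / 2.0]))[0] + center
            )
            if (apex - mid) @ m > 0:
                return _rotate_about(v0, axis, sense * ts) + center
    raise FixtureConstructionError("arc does not close on its endpoint")


def _rotate_about(v: np.ndarray, axis: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of vector ``v`` about ``axis`` by each angle."""
    cos = np.cos(angles)[:, None]
    sin = np.sin(angles)[:, None]
    return (
        v[None, :] * cos
        + np.cross(axis, v)[None, :] * sin
        + axis[None, :] * ((axis @ v) * (1.0 - cos))
    )


@dataclass(frozen=True)
class AnkFixtureSpec:
    """Parameters of the synthetic multi-copy ANK-like fold.

    Segment lengths follow the mean architecture of real ANK motifs
    (first helix ~8, inner turn ~2, second helix ~10, loop ~12 residues,
    copy length ~32); ``stack_offset`` is the spacing between the inner
    helix columns of adjacent copies, sized so the 7 A contact network
    links them.
    """

    n_copies: int = 4
    h1_len: int = 8
    h2_len: int = 10
    inner_turn_len: int = 2
    loop_len: int = 12
    stack_offset: float = 10.0
    seed: int = 0
    jitter_sd: float = 0.05

    # geometry of one copy (not usually varied)
    pair_sep: float = 9.0  # distance between the two helix axes, A
    solenoid_radius: float = 25.0  # curvature center distance from H1 column

    def __post_init__(self):
        for name in ("n_copies", "h1_len", "h2_len", "inner_turn_len", "loop_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.stack_offset <= 0 or self.pair_sep <= 0:
            raise ValueError("offsets must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    @property
    def copy_len(self) -> int:
        return self.h1_len + self.inner_turn_len + self.h2_len + self.loop_len


def _copy_template(spec: AnkFixtureSpec) -> dict[str, np.ndarray]:
    """One copy in its local frame: H1 up (+y) at x=0, H2 down at x=pair_sep.

    H2 starts 2.5 A below the top of H1 so that the end of the assigned
    part of H2 sits near H1's start: this makes the anti-parallel test
    d(S1,E2) < d(E1,E2) hold with a wide margin.
    """
    h1_top_y = (spec.h1_len - 1) * 1.5
    h1 = build_helix(HelixSpec(n_res=spec.h1_len))
    h2 = build_helix(
        HelixSpec(
            n_res=spec.h2_len,
            axis_origin=(spec.pair_sep, h1_top_y - 2.5, 0.0),
            axis_direction=(0.0, -1.0, 0.0),
            phase=np.pi,
        )
    )
    # inner turn: short arc from the last H1 point to the first H2 point,
    # bulging up and slightly outward so it never reads as helix geometry
    turn = _arc_points(
        h1[-1], h2[0], spec.inner_turn_len, bulge=np.array([0.3, 1.0, 0.6])
    )
    return {"h1": h1, "turn": turn, "h2": h2}


def build_ank_fixture(spec: AnkFixtureSpec) -> ChainStructure:
    """Stacked ANK-like fold as a single poly-alanine chain.

    Copies are rotated about a y-parallel solenoid axis placed
    ``solenoid_radius`` A behind the H1 column, by an angle giving the
    requested ``stack_offset`` between adjacent H1 columns.  The outer
    (H2) columns end up farther apart than the cutoff, so only the
    inner helices touch their neighbours: that asymmetry is what makes
    H1 the eigenvector-dominant helix.  Loops run on outward-bulging
    arcs from the end of each H2 to the start of the next copy's H1.
    """
    tmpl = _copy_template(spec)
    r0 = spec.solenoid_radius
    alpha = spec.stack_offset / r0  # radians between adjacent copies
    pivot = np.array([-r0, 0.0, 0.0])
    yaxis = np.array([0.0, 1.0, 0.0])

    def place(points: np.ndarray, k: int) -> np.ndarray:
        return _rotate_many(points - pivot, yaxis, k * alpha) + pivot

    parts: list[np.ndarray] = []
    for k in range(spec.n_copies):
        h1k = place(tmpl["h1"], k)
        turnk = place(tmpl["turn"], k)
        h2k = place(tmpl["h2"], k)
        parts += [h1k, turnk, h2k]
        # loop: from the end of this copy's H2 to the next copy's H1 start
        # (or a free outward tail for the last copy); the target point
        # itself belongs to the next copy, so only the loop_len
        # intermediate residues are appended here
        if k + 1 < spec.n_copies:
            # dogleg: swing outward-and-down from H2, then rise to the
            # next H1 start from below, packing under the inner helix
            # the way the real ANK hairpin does (and staying clear of
            # the outer helix column)
            target = place(tmpl["h1"], k + 1)[0]
            waypoint = place(np.array([[1.2, -8.0, 0.5]]), k + 1)[0]
            n2 = min(3, spec.loop_len - 2)
            n1 = spec.loop_len - 1 - n2
            down = np.array([0.0, -1.0, 0.0])
            bulge1 = _radial_out((h2k[-1] + waypoint) / 2.0, pivot) + down
            parts.append(_arc_points(h2k[-1], waypoint, n1, bulge1))
            parts.append(waypoint[None, :])
            bulge2 = -_radial_out((waypoint + target) / 2.0, pivot) + 0.5 * down
            parts.append(_arc_points(waypoint, target, n2, bulge2))
        else:
            # terminal tail: stretch the chord so the arc stays gentle
            # and clear of the last copy's helices
            outward = _radial_out(h2k[-1], pivot)
            span = max(6.0, (spec.loop_len - 1) * CA_STEP * 0.8)
            target = h2k[-1] + outward * span * 0.83 - np.array([0.0, span * 0.55, 0.0])
            bulge = _radial_out((h2k[-1] + target) / 2.0, pivot)
            parts.append(_arc_points(h2k[-1], target, spec.loop_len - 1, bulge))
            parts.append(target[None, :])
    coords = np.vstack(parts)

    rng = np.random.default_rng(spec.seed)
    if spec.jitter_sd > 0:
        coords = coords + rng.normal(0.0, spec.jitter_sd, coords.shape)

    if coords.shape[0] >= 2 and float(pdist(coords).min()) < MIN_SEPARATION:
        raise FixtureConstructionError(
            f"fixture self-clash: minimum C-alpha separation below {MIN_SEPARATION} A"
        )
    return coords_to_chain(coords)


def _rotate_many(points: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    cos, sin = np.cos(angle), np.sin(angle)
    return (
        points * cos
        + np.cross(axis, points) * sin
        + np.outer(points @ axis, axis) * (1.0 - cos)
    )


def _radial_out(point: np.ndarray, pivot: np.ndarray) -> np.ndarray:
    """Unit vector from the solenoid axis through ``point`` (in the xz plane)."""
    v = point - pivot
    v[1] = 0.0
    return v / np.linalg.norm(v)


def build_parallel_bundle(
    helix_len: int = 12, linker_len: int = 8, sep: float = 9.0
) -> ChainStructure:
    """Negative control: two helices running the same direction.

    The anti-parallel test fails for every candidate pair, so the
    detector must report nothing.
    """
    h1 = build_helix(HelixSpec(n_res=helix_len))
    h2 = build_helix(
        HelixSpec(n_res=helix_len, axis_origin=(sep, 0.0, 0.0), phase=np.pi)
    )
    bulge = np.array([0.3, 1.0, 0.0])
    linker = _arc_points(h1[-1], h2[0], linker_len, bulge)
    return coords_to_chain(np.vstack([h1, linker, h2]))


def coords_to_chain(
    coords: np.ndarray, chain_id: str = "A", first_author_seq: int = 1
) -> ChainStructure:
    """Wrap raw coordinates as a poly-alanine ChainStructure."""
    residues = [
        ResidueRecord(
            chain_id=chain_id,
            author_seq=first_author_seq + i,
            icode=" ",
            resname="ALA",
            ca_xyz=tuple(float(c) for c in xyz),
        )
        for i, xyz in enumerate(np.asarray(coords, dtype=float))
    ]
    return ChainStructure(chain_id=chain_id, residues=residues)


def write_fixture_pdb(chain: ChainStructure, path: str | Path) -> None:
    """Write the fixture as minimal C-alpha-only PDB ATOM records."""
    write_chain_pdb(chain, path)
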