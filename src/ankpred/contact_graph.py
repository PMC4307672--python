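"""Protein contact network and its principal-eigenvector profile.

Nodes are the C-alpha atoms of one chain; an undirected edge joins every
pair of residues whose C-alpha distance is at most the cutoff R_c
(default 7 A, roughly twice the peptide-bond length so that all
non-covalent contacts relevant to the fold are included).  The
per-residue components of the principal eigenvector of the adjacency
matrix (the eigenvector-centrality profile, "A_levc") peak inside
densely packed helices and repeat with the structural repeat period,
which is what the detector exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ComputationError, DegenerateStructureError
from .structure_io import ChainStructure

__all__ = [
    "ContactNetwork",
    "EigenProfile",
    "build_contact_network",
    "degree",
    "principal_eigenvector",
    "n_components",
    "export_edge_list",
    "export_profile_tsv",
]

DEFAULT_CUTOFF = 7.0  # Angstrom


@dataclass
class ContactNetwork:
    """Symmetric binary adjacency at cutoff ``r_c`` for one chain."""

    adjacency: np.ndarray  # (n, n) uint8, zero diagonal
    r_c: float
    chain_id: str = ""

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class EigenProfile:
    """Principal eigenpair of the contact-network adjacency matrix.

    ``levc`` has unit Euclidean norm and is sign-fixed so that for a
    connected network every component is non-negative (Perron vector).
    """

    lam: float
    levc: np.ndarray

    @property
    def n(self) -> int:
        return self.levc.shape[0]


def build_contact_network(
    chain: ChainStructure, r_c: float = DEFAULT_CUTOFF
) -> ContactNetwork:
    """Build the C-alpha contact network of a chain.

    The cutoff comparison is inclusive: d_ij <= r_c puts an edge between
    i and j (i != j).
    """
    if chain.n < 2:
        raise DegenerateStructureError(
            f"need at least 2 residues to build a network, got {chain.n}"
        )
    if r_c <= 0:
        raise ValueError(f"cutoff must be positive, got {r_c}")
    dmat = squareform(pdist(chain.coords))
    adj = (dmat <= r_c).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return ContactNetwork(adjacency=adj, r_c=float(r_c), chain_id=chain.chain_id)


def degree(net: ContactNetwork, i: int) -> int:
    """Number of neighbours of node ``i`` (row sum of the adjacency)."""
    if not 0 <= i < net.n:
        raise IndexError(f"node index {i} out of range [0, {net.n})")
    return int(net.adjacency[i].sum())


def principal_eigenvector(net: ContactNetwork) -> EigenProfile:
    """Top eigenpair of the adjacency matrix (dense symmetric solve).

    The sign is fixed so the component sum is positive; if the sum is
    exactly zero (possible only on disconnected graphs) the entry of
    largest magnitude is made positive.  Deterministic for fixed input.
    """
    if net.n < 2:
        raise DegenerateStructureError("eigen profile needs n >= 2")
    a = net.adjacency.astype(float)
    w, v = np.linalg.eigh(a)
    lam = float(w[-1])
    vec = v[:, -1].copy()
    s = vec.sum()
    if s < 0:
        vec = -vec
    elif s == 0:
        j = int(np.argmax(np.abs(vec)))
        if vec[j] < 0:
            vec = -vec
    vec /= np.linalg.norm(vec)
    resid = np.max(np.abs(a @ vec - lam * vec))
    if resid > 1e-8 * max(1.0, lam):
        raise ComputationError(
            f"eigenpair residual {resid:.3e} exceeds tolerance (lambda={lam:.6g})"
        )
    return EigenProfile(lam=lam, levc=vec)


def n_components(net: ContactNetwork) -> int:
    """Number of connected components (used to flag fragmented chains)."""
    from scipy.sparse.csgraph import connected_components

    ncomp, _ = connected_components(net.adjacency, directed=False)
    return int(ncomp)


def export_edge_list(
    net: ContactNetwork, chain: ChainStructure, path: str | Path
) -> None:
    """Write the contact list as TSV: i, j, d_ij (internal 0-based indices)."""
    coords = chain.coords
    ii, jj = np.nonzero(np.triu(net.adjacency, k=1))
    with open(path, "w") as fh:
        fh.write("i\tj\tdistance\n")
        for i, j in zip(ii.tolist(), jj.tolist()):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            fh.write(f"{i}\t{j}\t{d:.3f}\n")


def export_profile_tsv(
    profile: EigenProfile, chain: ChainStructure, path: str | Path
) -> None:
    """Write the A_levc profile as TSV: index, author number, A_levc."""
    with open(path, "w") as fh:
        fh.write("index\tauthor\ta_levc\n")
        for i, x in enumerate(profile.levc.tolist()):
            fh.write(f"{i}\t{chain.author_label(i)}\t{x:.8f}\n")
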