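"""Modular decomposition of a metabolic network via the null space of S.

Every steady-state flux vector lives in ``null(S)``; reaction *i* is
represented by the *i*-th row of an orthonormal kernel basis ``K``.  Rows
that are proportional correspond to strictly coupled reactions (fixed flux
ratio), and the angle between two rows measures how independently the two
reactions can vary.  Hierarchical clustering on the angle matrix recovers
the pathway-level modules of the network without enumerating elementary
flux modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.linalg import svd
from scipy.spatial.distance import squareform

from .model_io import MetabolicModel

__all__ = [
    "KernelBasis",
    "ModuleDecomposition",
    "kernel_basis",
    "nullspace_of",
    "reaction_angles",
    "cluster_reactions",
    "coverage_report",
    "linkage_to_newick",
]

#: rows of K with norm below this are treated as fully determined reactions
DETERMINED_ROW_TOL = 1e-10


@dataclass
class KernelBasis:
    """Orthonormal basis of null(S) with the rank bookkeeping."""

    K: np.ndarray          # N x d, orthonormal columns
    d: int                 # kernel dimension, N - rank
    rank: int
    sv_tolerance: float
    reaction_ids: Optional[List[str]] = None


@dataclass
class ModuleDecomposition:
    """Angle matrix, dendrogram and module labels at a chosen cut.

    ``labels`` maps every reaction to a module id; fully determined
    reactions (zero kernel row) are reported under module id 0 and are
    never forced into a cluster.
    """

    angles: np.ndarray
    linkage: Optional[np.ndarray]
    labels: Dict[str, int]
    n_modules: int
    determined: List[str]
    reaction_ids: List[str]


def nullspace_of(S: np.ndarray, tol: float = 1e-10):
    """Return ``(K, rank)`` for the matrix ``S`` via SVD.

    ``rank`` counts singular values above ``tol * sigma_max``; ``K`` holds
    the trailing right-singular vectors (orthonormal columns spanning the
    null space).
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.size == 0 or S.shape[0] == 0:
        n = S.shape[1]
        return np.eye(n), 0
    _, sv, Vh = svd(S, full_matrices=True)
    cutoff = tol * (sv[0] if sv.size else 0.0)
    rank = int(np.sum(sv > cutoff))
    return Vh[rank:].T.copy(), rank


def kernel_basis(model: MetabolicModel, tol: float = 1e-10) -> KernelBasis:
    """Compute the kernel basis of the model's stoichiometric matrix."""
    K, rank = nullspace_of(model.S, tol)
    return KernelBasis(K=K, d=K.shape[1], rank=rank, sv_tolerance=tol,
                       reaction_ids=list(model.reaction_ids))


def reaction_angles(basis: KernelBasis) -> np.ndarray:
    """Pairwise angles (degrees) between reaction row-vectors of K.

    Acute-angle convention: the cosine is taken in absolute value so that
    reactions coupled with opposite signs coincide at 0 degrees.  Rows
    with negligible norm (reactions fully determined by the constraints)
    are set 90 degrees away from everything, 0 on the diagonal.
    """
    if basis.d < 1:
        raise ValueError("model has no degrees of freedom (kernel dimension 0)")
    K = basis.K
    norms = np.linalg.norm(K, axis=1)
    live = norms > DETERMINED_ROW_TOL
    n = K.shape[0]
    cos = np.zeros((n, n))
    if live.any():
        Kn = K[live] / norms[live, None]
        cos_live = np.abs(Kn @ Kn.T)
        cos[np.ix_(live, live)] = np.clip(cos_live, 0.0, 1.0)
    ang = np.degrees(np.arccos(np.clip(cos, 0.0, 1.0)))
    np.fill_diagonal(ang, 0.0)
    return ang


def cluster_reactions(
    angles: np.ndarray,
    linkage: str = "average",
    n_modules: int = 2,
    reaction_ids: Optional[List[str]] = None,
    determined_mask: Optional[np.ndarray] = None,
) -> ModuleDecomposition:
    """Agglomerative clustering of reactions on the angle metric.

    ``determined_mask`` flags reactions with zero kernel rows; they are
    excluded from the clustering and labelled with module id 0.
    """
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    angles = np.asarray(angles, dtype=float)
    n = angles.shape[0]
    if angles.shape != (n, n):
        raise ValueError("angle matrix must be square")
    if reaction_ids is None:
        reaction_ids = [f"r{i}" for i in range(n)]
    if determined_mask is None:
        determined_mask = np.zeros(n, dtype=bool)
    determined_mask = np.asarray(determined_mask, dtype=bool)
    live_idx = np.flatnonzero(~determined_mask)
    n_live = live_idx.size
    if n_modules > n_live:
        raise ValueError(
            f"n_modules = {n_modules} exceeds the {n_live} clusterable reactions")

    labels: Dict[str, int] = {reaction_ids[i]: 0 for i in np.flatnonzero(determined_mask)}
    link = None
    if n_live == 1:
        labels[reaction_ids[live_idx[0]]] = 1
    elif n_live > 1:
        sub = angles[np.ix_(live_idx, live_idx)].copy()
        sub = 0.5 * (sub + sub.T)
        np.fill_diagonal(sub, 0.0)
        link = hierarchy.linkage(squareform(sub, checks=False), method=linkage)
        flat = hierarchy.fcluster(link, t=n_modules, criterion="maxclust")
        for pos, i in enumerate(live_idx):
            labels[reaction_ids[i]] = int(flat[pos])
    return ModuleDecomposition(
        angles=angles,
        linkage=link,
        labels=labels,
        n_modules=len(set(labels.values()) - {0}),
        determined=[reaction_ids[i] for i in np.flatnonzero(determined_mask)],
        reaction_ids=list(reaction_ids),
    )


def coverage_report(decomp: ModuleDecomposition, observed: Iterable[str]) -> pd.DataFrame:
    """Per-module counts of reactions matched by proteomic observations.

    Returns a table with columns ``module, n_reactions, n_observed,
    fraction, uncovered`` where ``uncovered`` flags modules with no
    observed reaction at all.
    """
    observed = set(observed)
    unknown = observed - set(decomp.reaction_ids)
    if unknown:
        raise KeyError(f"observed set contains unknown reactions: {sorted(unknown)}")
    rows = []
    for module in sorted(set(decomp.labels.values())):
        members = [r for r, lab in decomp.labels.items() if lab == module]
        n_obs = sum(1 for r in members if r in observed)
        rows.append({
            "module": module,
            "n_reactions": len(members),
            "n_observed": n_obs,
            "fraction": n_obs / len(members),
            "uncovered": n_obs == 0,
        })
    return pd.DataFrame(rows)


def linkage_to_newick(link: np.ndarray, leaf_names: List[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(link)

    def build(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"
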