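"""Beta diversity: Bray-Curtis, weighted UniFrac, PCoA, ANOSIM.

Distance matrices are :class:`skbio.DistanceMatrix` objects (symmetric,
hollow, labeled).  PCoA is classical scaling with negative eigenvalues
dropped (their mass is reported, no Lingoes/Cailliez correction).  ANOSIM
p-values use the (1 + count) / (1 + n_permutations) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _perms

import numpy as np
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

from .io import ZotuTable

__all__ = [
    "PcoaResult",
    "AnosimResult",
    "bray_curtis",
    "weighted_unifrac",
    "pcoa",
    "anosim",
]


@dataclass
class PcoaResult:
    coordinates: np.ndarray          # samples x retained axes
    eigenvalues: np.ndarray          # positive, descending
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float  # sum |negative eigenvalues|
    sample_ids: list[str]


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    permuted_R: np.ndarray | None = None


def bray_curtis(table: ZotuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x, y) = sum|x-y| / sum(x+y) on counts."""
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = table.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    x = table.counts.astype(float)
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = totals[:, None] + totals[None, :]
    d = num / den
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, ids=table.sample_ids)


def _branch_table(tree, zotu_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Indicator matrix (branches x ZOTUs) and branch lengths.

    One row per non-root node; entry 1 where the ZOTU's leaf descends
    through that node's parent branch.
    """
    idx = {z: j for j, z in enumerate(zotu_ids)}
    rows, lengths = [], []
    for node in tree.postorder(include_self=False):
        row = np.zeros(len(zotu_ids))
        for tip in node.tips(include_self=True):
            j = idx.get(tip.name)
            if j is not None:
                row[j] = 1.0
        rows.append(row)
        lengths.append(float(node.length or 0.0))
    return np.array(rows), np.array(lengths)


def weighted_unifrac(
    table: ZotuTable, tree, normalized: bool = False
) -> DistanceMatrix:
    """Weighted UniFrac on a rooted tree.

    Raw form: ``sum_b l_b |p_A(b) - p_B(b)|`` where ``p_X(b)`` is the
    fraction of sample X's reads descending branch ``b``.  The normalized
    form divides by ``sum_b l_b (p_A(b) + p_B(b))``.  Every ZOTU with a
    nonzero count must be a leaf of the tree.
    """
    leaf_names = {t.name for t in tree.tips()}
    nonzero = {
        table.zotu_ids[j]
        for j in np.flatnonzero(table.counts.sum(axis=0) > 0)
    }
    missing = sorted(nonzero - leaf_names)
    if missing:
        raise ValueError(f"ZOTUs missing from tree: {missing}")
    B, lengths = _branch_table(tree, table.zotu_ids)
    P = table.relative_abundance() @ B.T  # samples x branches
    diff = np.abs(P[:, None, :] - P[None, :, :])
    d = (diff * lengths).sum(axis=2)
    if normalized:
        den = ((P[:, None, :] + P[None, :, :]) * lengths).sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(den > 0, d / den, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, ids=table.sample_ids)


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-10) -> PcoaResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers ``-D^2/2``, eigendecomposes, and keeps the axes with
    positive eigenvalues sorted descending.  Coordinates are eigenvectors
    scaled by sqrt(eigenvalue); each axis is flipped so its first nonzero
    loading is positive.  ``proportion_explained`` is relative to the sum
    of positive eigenvalues; negative-eigenvalue mass is reported.
    """
    D = np.asarray(dm.data, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(abs(vals[0]), 1.0) if n else 1.0
    pos = vals > eig_tol * scale
    neg_mass = float(np.abs(vals[vals < 0]).sum())
    vals_p = vals[pos]
    coords = vecs[:, pos] * np.sqrt(vals_p)
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    total = vals_p.sum()
    props = vals_p / total if total > 0 else np.zeros_like(vals_p)
    return PcoaResult(
        coordinates=coords,
        eigenvalues=vals_p,
        proportion_explained=props,
        negative_eigenvalue_mass=neg_mass,
        sample_ids=list(dm.ids),
    )


def _anosim_r(ranks_sq: np.ndarray, labels: np.ndarray, denom: float) -> float:
    within = labels[:, None] == labels[None, :]
    iu = np.triu_indices(labels.size, k=1)
    w = within[iu]
    r_within = ranks_sq[iu][w].mean()
    r_between = ranks_sq[iu][~w].mean()
    return float((r_between - r_within) / denom)


def anosim(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
    keep_permuted: bool = False,
) -> AnosimResult:
    """Analysis of similarities: are between-group ranks larger than within?

    Ranks all n(n-1)/2 distances with average ranks on ties and computes
    ``R = (mean between-rank - mean within-rank) / (n(n-1)/4)``.
    Significance is the seeded label-permutation tail probability
    ``(1 + #{R_perm >= R_obs}) / (1 + n_permutations)``.

    ``n_permutations="exact"`` enumerates every distinct relabeling
    (feasible for small n only).
    """
    labels = np.asarray(list(groups))
    n = labels.size
    if n != dm.shape[0]:
        raise ValueError("group labels do not match distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    condensed = squareform(np.asarray(dm.data), checks=False)
    ranks = rankdata(condensed)
    ranks_sq = squareform(ranks, checks=False)
    denom = n * (n - 1) / 4.0
    r_obs = _anosim_r(ranks_sq, labels, denom)

    iu = np.triu_indices(n, k=1)
    rv = ranks_sq[iu]
    grand = rv.mean()
    n_pairs = rv.size

    def r_of(perm_labels: np.ndarray) -> float:
        w = (perm_labels[:, None] == perm_labels[None, :])[iu]
        nw = w.sum()
        r_within = rv[w].mean()
        # between mean from the grand total, avoids a second masked mean
        r_between = (grand * n_pairs - r_within * nw) / (n_pairs - nw)
        return float((r_between - r_within) / denom)

    if n_permutations == "exact":
        perms = {tuple(p) for p in _perms(labels.tolist())}
        permuted = np.array([r_of(np.asarray(p)) for p in sorted(perms)])
        n_used = permuted.size
        p = float((permuted >= r_obs - 1e-12).sum()) / n_used
    else:
        rng = np.random.default_rng(seed)
        permuted = np.empty(int(n_permutations))
        for k in range(int(n_permutations)):
            permuted[k] = r_of(rng.permutation(labels))
        n_used = int(n_permutations)
        p = (1.0 + (permuted >= r_obs - 1e-12).sum()) / (1.0 + n_used)
    return AnosimResult(
        R=r_obs,
        p_value=float(p),
        n_permutations=n_used,
        permuted_R=permuted if keep_permuted else None,
    )
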