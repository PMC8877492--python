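"""Attribute community dissimilarity to environmental variables.

Three routes, mirroring common practice in community ecology:

* Mantel tests of the community distance matrix against per-variable
  Euclidean distances on standardized covariates (and great-circle
  geographic distance);
* a multiple linear regression of unfolded community dissimilarities on
  the predictor distances, with the LMG decomposition allocating the
  model R^2 to predictors by averaging sequential R^2 gains over predictor
  orderings (exhaustive for <= 8 predictors);
* a Spearman screen of taxon relative abundances against covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations as _perms

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .io import ZotuTable
from .network import bh_adjust

__all__ = [
    "MantelResult",
    "VarianceDecomposition",
    "EnvDistanceSet",
    "env_distances",
    "haversine_km",
    "mantel",
    "distance_mlr_lmg",
    "taxa_env_spearman",
    "aggregate_taxa",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_permutations: int


@dataclass
class VarianceDecomposition:
    total_r_squared: float
    contribution: dict[str, float]          # shares, sum = total_r_squared
    cumulative_percent: dict[str, float]    # shares on a 0-100 scale
    n_pairs: int


@dataclass
class EnvDistanceSet:
    matrices: dict[str, DistanceMatrix]
    not_computed: list[str] = field(default_factory=list)

    def __getitem__(self, key: str) -> DistanceMatrix:
        return self.matrices[key]


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km on a 6371-km sphere."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def env_distances(
    metadata: pd.DataFrame,
    variables: list[str],
    include_geographic: bool = True,
) -> EnvDistanceSet:
    """Per-variable |z_i - z_j| distances plus geographic distance.

    Each variable is z-scored over its non-missing samples (ddof=1); pairs
    with a missing member get NaN entries.  A constant variable (sd = 0)
    is flagged not-computed and excluded.  Geographic distance is the
    haversine on latitude/longitude.
    """
    ids = list(metadata.index)
    n = len(ids)
    if n < 2:
        raise ValueError("need >= 2 samples")
    mats: dict[str, DistanceMatrix] = {}
    skipped: list[str] = []
    for var in variables:
        if var not in metadata.columns:
            raise ValueError(f"variable {var!r} not in metadata")
        v = metadata[var].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if ok.sum() < 2:
            skipped.append(var)
            continue
        sd = v[ok].std(ddof=1)
        if sd == 0:
            skipped.append(var)
            continue
        z = (v - v[ok].mean()) / sd
        d = np.abs(z[:, None] - z[None, :])
        np.fill_diagonal(d, 0.0)
        mats[var] = _nan_tolerant_dm(d, ids)
    if include_geographic:
        lat = metadata["latitude"].to_numpy(dtype=float)
        lon = metadata["longitude"].to_numpy(dtype=float)
        g = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                g[i, j] = g[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
        mats["geographic"] = _nan_tolerant_dm(g, ids)
    return EnvDistanceSet(matrices=mats, not_computed=skipped)


def _nan_tolerant_dm(d: np.ndarray, ids) -> DistanceMatrix:
    # skbio validates hollowness/symmetry but rejects NaN; distances with
    # missing members keep NaN via a non-validated construction
    if np.isnan(d).any():
        dm = DistanceMatrix(np.zeros_like(d), ids=ids)
        dm.data[:] = (d + d.T) / 2.0
        np.fill_diagonal(dm.data, 0.0)
        return dm
    return DistanceMatrix(d, ids=ids)


def _lower_triangle(dm: DistanceMatrix) -> np.ndarray:
    a = np.asarray(dm.data)
    iu = np.triu_indices(a.shape[0], k=1)
    return a[iu]


def mantel(
    d_community: DistanceMatrix,
    d_env: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test: Pearson correlation of two unfolded distance matrices.

    Permutes the rows/columns of the second matrix jointly.  The default
    alternative is one-sided for positive association; the p-value is
    ``(1 + #{r_perm >= r_obs}) / (1 + n_permutations)``.
    ``n_permutations="exact"`` enumerates all n! relabelings.
    Pairs with a missing (NaN) environmental entry are dropped from both
    vectors.
    """
    if list(d_community.ids) != list(d_env.ids):
        raise ValueError("distance matrices must share labels in the same order")
    n = d_community.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs >= 4 samples")
    A = np.asarray(d_community.data)
    Bm = np.asarray(d_env.data)
    iu = np.triu_indices(n, k=1)
    mask = ~np.isnan(Bm[iu])

    x0 = A[iu][mask]
    xc = x0 - x0.mean()
    xnorm = math.sqrt((xc ** 2).sum())

    def corr(B: np.ndarray) -> float:
        y = B[iu][mask]
        yc = y - y.mean()
        ynorm = math.sqrt((yc ** 2).sum())
        if xnorm == 0 or ynorm == 0:
            return 0.0
        return float((xc * yc).sum() / (xnorm * ynorm))

    r_obs = corr(Bm)
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")

    def tail(rp: float) -> bool:
        if alternative == "greater":
            return rp >= r_obs - 1e-12
        return abs(rp) >= abs(r_obs) - 1e-12

    if n_permutations == "exact":
        count = total = 0
        for perm in _perms(range(n)):
            p = np.asarray(perm)
            total += 1
            if tail(corr(Bm[np.ix_(p, p)])):
                count += 1
        pval = count / total
        n_used = total - 1
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(int(n_permutations)):
            p = rng.permutation(n)
            if tail(corr(Bm[np.ix_(p, p)])):
                count += 1
        pval = (1.0 + count) / (1.0 + int(n_permutations))
        n_used = int(n_permutations)
    return MantelResult(
        r=r_obs, r_squared=r_obs ** 2, p_value=float(pval), n_permutations=n_used
    )


# ---------------------------------------------------------------------------
# LMG variance decomposition
# ---------------------------------------------------------------------------

def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """OLS R^2 with intercept."""
    n = y.size
    Z = np.column_stack([np.ones(n), X]) if X.shape[1] else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return 0.0
    return float(1.0 - (resid ** 2).sum() / tss)


def distance_mlr_lmg(
    d_community: DistanceMatrix,
    env: EnvDistanceSet,
    predictors: list[str] | None = None,
    max_exact: int = 8,
    n_sampled_orderings: int = 5000,
    seed: int = 0,
) -> VarianceDecomposition:
    """Regress unfolded community dissimilarities on predictor distances.

    The LMG share of predictor k is the average, over all predictor
    orderings, of the R^2 increase when k enters; shares always sum to the
    full-model R^2.  Orderings are enumerated exhaustively for up to
    ``max_exact`` predictors and sampled (seeded) beyond that.  Pairs with
    any missing predictor are dropped listwise.  A rank-deficient design
    raises, naming the most collinear predictor pair.
    """
    names = predictors if predictors is not None else list(env.matrices)
    if len(names) < 2:
        raise ValueError("need >= 2 predictors")
    y_full = _lower_triangle(d_community)
    cols = [_lower_triangle(env[name]) for name in names]
    X_full = np.column_stack(cols)
    ok = ~np.isnan(X_full).any(axis=1) & ~np.isnan(y_full)
    y, X = y_full[ok], X_full[ok]
    p = len(names)
    if np.linalg.matrix_rank(np.column_stack([np.ones(y.size), X])) < p + 1:
        cc = np.corrcoef(X.T)
        np.fill_diagonal(cc, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(cc)), cc.shape)
        raise ValueError(
            f"collinear predictors: {names[i]!r} and {names[j]!r} "
            f"(|r| = {abs(cc[i, j]):.4f})"
        )

    r2_cache: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, p + 1):
        for S in combinations(range(p), size):
            r2_cache[frozenset(S)] = _r2(y, X[:, S])
    full_r2 = r2_cache[frozenset(range(p))]

    shares = np.zeros(p)
    if p <= max_exact:
        fact = [math.factorial(k) for k in range(p + 1)]
        for k in range(p):
            others = [i for i in range(p) if i != k]
            for size in range(p):
                w = fact[size] * fact[p - 1 - size] / fact[p]
                for S in combinations(others, size):
                    gain = r2_cache[frozenset(S) | {k}] - r2_cache[frozenset(S)]
                    shares[k] += w * gain
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_sampled_orderings):
            order = rng.permutation(p)
            prev: frozenset = frozenset()
            for k in order:
                cur = prev | {k}
                shares[k] += r2_cache[cur] - r2_cache[prev]
                prev = cur
        shares /= n_sampled_orderings
        shares *= full_r2 / shares.sum() if shares.sum() else 1.0
    return VarianceDecomposition(
        total_r_squared=full_r2,
        contribution={n_: float(s) for n_, s in zip(names, shares)},
        cumulative_percent={n_: float(100 * s) for n_, s in zip(names, shares)},
        n_pairs=int(y.size),
    )


# ---------------------------------------------------------------------------
# Taxon-environment screen
# ---------------------------------------------------------------------------

def aggregate_taxa(table: ZotuTable, rank: int) -> pd.DataFrame:
    """Sum member-ZOTU relative abundances at a taxonomy rank.

    ``rank`` indexes the semicolon-delimited path (0 = highest).  Raises
    if any ZOTU's path is too short to have that rank.
    """
    rel = table.relative_abundance()
    groups: dict[str, np.ndarray] = {}
    for j, tax in enumerate(table.taxonomy):
        parts = [t.strip() for t in tax.split(";")] if tax else []
        if rank >= len(parts):
            raise ValueError(
                f"rank {rank} absent from taxonomy of {table.zotu_ids[j]!r}: {tax!r}"
            )
        name = parts[rank]
        groups[name] = groups.get(name, 0) + rel[:, j]
    return pd.DataFrame(groups, index=pd.Index(table.sample_ids, name="sample_id"))


def taxa_env_spearman(
    table: ZotuTable,
    rank: int,
    metadata: pd.DataFrame,
    variables: list[str],
    fdr: bool = True,
) -> pd.DataFrame:
    """Spearman rho/p (and BH q) per (taxon, covariate).

    Taxa are relative-abundance sums at the given rank; missing covariate
    values are dropped pairwise; constant series are flagged
    ``not-computed`` rather than reported as rho = 0.
    """
    taxa = aggregate_taxa(table, rank)
    meta = metadata.loc[taxa.index]
    rows = []
    for taxon in taxa.columns:
        t = taxa[taxon].to_numpy(dtype=float)
        for var in variables:
            v = meta[var].to_numpy(dtype=float)
            okm = ~np.isnan(v) & ~np.isnan(t)
            if okm.sum() < 4 or np.all(t[okm] == t[okm][0]) or np.all(
                v[okm] == v[okm][0]
            ):
                rows.append((taxon, var, np.nan, np.nan, int(okm.sum()), "not-computed"))
                continue
            rho, pv = stats.spearmanr(t[okm], v[okm])
            rows.append((taxon, var, float(rho), float(pv), int(okm.sum()), "ok"))
    out = pd.DataFrame(rows, columns=["taxon", "variable", "rho", "p", "n", "status"])
    if fdr:
        pvals = out["p"].to_numpy()
        q = np.full_like(pvals, np.nan)
        mask = ~np.isnan(pvals)
        if mask.any():
            q[mask] = bh_adjust(pvals[mask])
        out["q"] = q
    return out
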