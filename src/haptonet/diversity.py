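"""Rarefaction and alpha diversity: richness, Shannon, Faith's PD.

Shannon entropy is reported in nats by default (``base`` rescales it);
Faith's phylogenetic diversity sums the branch lengths of the minimal
subtree connecting the sample's present leaves to the root of the provided
rooted tree, stem included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ZotuTable

__all__ = [
    "AlphaDiversityRecord",
    "GroupComparison",
    "rarefy",
    "alpha_diversity",
    "compare_alpha",
    "alpha_env_spearman",
    "faith_pd",
    "shannon",
]

ALPHA_METRICS = ("richness", "shannon", "pd")


@dataclass
class AlphaDiversityRecord:
    sample_id: str
    richness: int
    shannon: float
    pd: float | None = None


@dataclass
class GroupComparison:
    metric: str
    statistic: float
    p_value: float
    group_medians: dict[str, float]
    test: str = "rank-sum"


def rarefy(table: ZotuTable, depth: int, seed: int) -> ZotuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Equivalent to drawing ``depth`` reads from the sample's read pool
    (multivariate hypergeometric).  ZOTU columns that end up all-zero are
    retained so ids stay aligned across tables.  Raises ``ValueError``
    naming the first sample whose total is below ``depth``.
    """
    totals = table.sample_totals()
    short = totals < depth
    if short.any():
        bad = table.sample_ids[int(np.argmax(short))]
        raise ValueError(
            f"sample {bad!r} has only {int(totals[short][0])} reads, "
            f"cannot rarefy to {depth}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return ZotuTable(out, list(table.sample_ids), list(table.zotu_ids),
                     list(table.taxonomy))


def shannon(counts: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i of one sample's counts."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample has no reads")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def faith_pd(present_leaves: set[str], tree) -> float:
    """Faith's PD: branch lengths of the minimal rooted subtree.

    Sums the length of every branch with at least one present leaf below
    it, i.e. the union of root-to-leaf paths (the stem to the root is
    included).  Raises ``ValueError`` listing leaves absent from the tree.
    """
    by_name = {t.name: t for t in tree.tips()}
    missing = sorted(present_leaves - by_name.keys())
    if missing:
        raise ValueError(f"ZOTUs missing from tree: {missing}")
    counted = set()
    total = 0.0
    for name in present_leaves:
        node = by_name[name]
        while node.parent is not None and id(node) not in counted:
            counted.add(id(node))
            total += float(node.length or 0.0)
            node = node.parent
    return total


def alpha_diversity(
    table: ZotuTable, tree=None, base: float | None = None
) -> pd.DataFrame:
    """Per-sample richness, Shannon (nats by default) and optional PD.

    Returns a DataFrame indexed by sample id with columns ``richness``,
    ``shannon`` and — when a tree is given — ``pd``.
    """
    records = []
    for i, sid in enumerate(table.sample_ids):
        row = table.counts[i]
        rec = {
            "richness": int((row > 0).sum()),
            "shannon": shannon(row, base=base),
        }
        if tree is not None:
            present = {table.zotu_ids[j] for j in np.flatnonzero(row > 0)}
            rec["pd"] = faith_pd(present, tree)
        records.append(rec)
    return pd.DataFrame(records, index=pd.Index(table.sample_ids, name="sample_id"))


def compare_alpha(
    alpha: pd.DataFrame,
    habitats: pd.Series,
    paired: bool = False,
    stations: pd.Series | None = None,
) -> list[GroupComparison]:
    """Two-sided rank-based habitat comparison for each alpha metric.

    Unpaired uses the Mann-Whitney rank-sum test (exact when both groups
    have n <= 8 and no ties, normal approximation with tie correction
    otherwise).  ``paired=True`` uses the Wilcoxon signed-rank test with
    samples paired by station.
    """
    habitats = habitats.loc[alpha.index]
    groups = sorted(habitats.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    g0, g1 = groups
    if (habitats == g0).sum() < 2 or (habitats == g1).sum() < 2:
        raise ValueError("each group needs >= 2 samples")
    out = []
    for metric in alpha.columns:
        x = alpha.loc[habitats == g0, metric].to_numpy(dtype=float)
        y = alpha.loc[habitats == g1, metric].to_numpy(dtype=float)
        if paired:
            if stations is None:
                raise ValueError("paired comparison requires station labels")
            st = stations.loc[alpha.index]
            sx = st[habitats == g0]
            pairs = {s: v for s, v in zip(sx, x)}
            ordered = [
                (pairs[s], v)
                for s, v in zip(st[habitats == g1], y)
                if s in pairs
            ]
            a = np.array([p[0] for p in ordered])
            b = np.array([p[1] for p in ordered])
            res = stats.wilcoxon(a, b, alternative="two-sided")
            test = "signed-rank"
        else:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
            test = "rank-sum"
        out.append(
            GroupComparison(
                metric=metric,
                statistic=float(res.statistic),
                p_value=float(res.pvalue),
                group_medians={g0: float(np.median(x)), g1: float(np.median(y))},
                test=test,
            )
        )
    return out


def alpha_env_spearman(
    alpha: pd.DataFrame, metadata: pd.DataFrame, variables: list[str]
) -> pd.DataFrame:
    """Spearman correlation of each alpha metric with each covariate.

    Missing covariate values are dropped pairwise; a (metric, covariate)
    pair with fewer than 4 complete observations is flagged
    ``not-computed`` (rho and p NaN) rather than reported as zero.
    """
    rows = []
    meta = metadata.loc[alpha.index]
    for metric in alpha.columns:
        m = alpha[metric].to_numpy(dtype=float)
        for var in variables:
            v = meta[var].to_numpy(dtype=float)
            ok = ~np.isnan(v) & ~np.isnan(m)
            if ok.sum() < 4:
                rows.append((metric, var, np.nan, np.nan, int(ok.sum()), "not-computed"))
                continue
            rho, p = stats.spearmanr(m[ok], v[ok])
            rows.append((metric, var, float(rho), float(p), int(ok.sum()), "ok"))
    return pd.DataFrame(
        rows, columns=["metric", "variable", "rho", "p", "n", "status"]
    )
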