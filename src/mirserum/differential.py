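"""Fold-change analysis, rank tests, correlation screens, clustering and
longitudinal concordance for deltaCt-normalized panel data.

Fold change between matched conditions is ``2**(dCt_case - dCt_control)``
with deltaCt = reference Ct - assay Ct, so FC > 1 means higher abundance in
the case sample.  The significance cutoff for fold-change calls is not fixed
a priori but calibrated from a technical replicate pair: the chosen cutoff is
the smallest fold threshold whose technical false-call fraction stays within
a configured budget (default 10%, which selects 3-fold under the measured
replicate noise of a serum panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fold_change",
    "CutoffCalibrationResults",
    "calibrate_cutoff",
    "GroupComparison",
    "GroupComparisonResults",
    "mann_whitney_bh",
    "CorrelationScreen",
    "CorrelationScreenResults",
    "covariate_correlation_screen",
    "ClusterResults",
    "cluster_samples",
    "LongitudinalResults",
    "longitudinal_concordance",
]


def fold_change(delta_case, delta_control):
    """Linear-scale fold change ``2**(dCt_case - dCt_control)``.

    Accepts scalars, arrays or Series; missing deltaCt on either side yields
    NaN (the pair is not evaluable and is excluded from denominators).
    Satisfies ``fold_change(a, b) * fold_change(b, a) == 1``.
    """
    return np.power(2.0, np.asarray(delta_case, dtype=float) - np.asarray(delta_control, dtype=float))


# ---------------------------------------------------------------------------
# fold-change cutoff calibration from a technical replicate pair
# ---------------------------------------------------------------------------

@dataclass
class CutoffCalibrationResults:
    n_codetected: int
    fractions: dict[float, float]  # threshold -> fraction of assays >= threshold-fold apart
    cutoff: float | None
    budget: float

    def summary(self) -> str:
        lines = [
            "Fold-change cutoff calibration (technical replicates)",
            f"  co-detected assays: {self.n_codetected}",
        ]
        for t, f in self.fractions.items():
            lines.append(f"  >= {t:g}-fold apart: {100 * f:.0f}%")
        chosen = "none within budget" if self.cutoff is None else f"{self.cutoff:g}"
        lines.append(f"  chosen cutoff (budget {100 * self.budget:.0f}%): {chosen}")
        return "\n".join(lines)


def calibrate_cutoff(
    replicate_a: pd.Series,
    replicate_b: pd.Series,
    thresholds: Sequence[float] = (2.0, 3.0, 4.0),
    budget: float = 0.10,
    min_codetected: int = 10,
) -> CutoffCalibrationResults:
    """Choose a fold-change cutoff from two same-serum replicate profiles.

    Both inputs are deltaCt profiles normalized to the same reference.  For
    each threshold the fraction of co-detected assays whose replicate fold
    difference reaches the threshold is reported; the chosen cutoff is the
    smallest threshold with fraction <= ``budget``, or None when no threshold
    qualifies.
    """
    a, b = replicate_a.align(replicate_b)
    ok = a.notna() & b.notna()
    n = int(ok.sum())
    if n < min_codetected:
        raise ValueError(f"only {n} co-detected assays; calibration unreliable")
    diff = np.abs(a[ok] - b[ok]).to_numpy()
    thresholds = sorted(float(t) for t in thresholds)
    fractions = {t: float(np.mean(diff >= np.log2(t))) for t in thresholds}
    cutoff = next((t for t in thresholds if fractions[t] <= budget), None)
    return CutoffCalibrationResults(n, fractions, cutoff, float(budget))


# ---------------------------------------------------------------------------
# Mann-Whitney group comparison with Benjamini-Hochberg control
# ---------------------------------------------------------------------------

def _mann_whitney(x: np.ndarray, y: np.ndarray, exact_max_n: int = 16) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact when small and tie-free.

    The exact null distribution is used for combined n <= ``exact_max_n``
    with no ties (the regime of 7-10 samples per group); otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return len(x) * len(y) / 2.0, 1.0
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= exact_max_n and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class GroupComparisonResults:
    table: pd.DataFrame
    group_names: tuple[str, str]
    alpha: float
    skipped: list[str] = field(default_factory=list)

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    def summary(self) -> str:
        t = self.table
        lines = [
            f"Mann-Whitney comparison: {self.group_names[0]} vs {self.group_names[1]}",
            f"  assays tested: {len(t)}; skipped (group all-missing): {len(self.skipped)}",
            f"  significant (BH-adjusted P < {self.alpha:g}): {len(self.significant)}",
        ]
        if len(t):
            best = t["p"].idxmin()
            lines.append(
                f"  lowest raw P: {best} "
                f"(P = {t.loc[best, 'p']:.3g}, adjusted P = {t.loc[best, 'p_adj']:.3g})"
            )
        return "\n".join(lines)


class GroupComparison:
    """Per-assay two-sided Mann-Whitney test between two sample groups.

    Operates on deltaCt values; missing values are dropped per assay.  Assays
    with all values missing in either group are skipped and listed.  P-values
    are Benjamini-Hochberg adjusted across all tested assays.
    """

    def __init__(
        self,
        normalized: pd.DataFrame,
        group_a: Sequence[str],
        group_b: Sequence[str],
        alpha: float = 0.05,
        group_names: tuple[str, str] = ("case", "control"),
        min_group_n: int = 3,
    ) -> None:
        a, b = list(group_a), list(group_b)
        if set(a) & set(b):
            raise ValueError("groups must be disjoint")
        if len(a) < min_group_n or len(b) < min_group_n:
            raise ValueError(f"each group needs >= {min_group_n} samples")
        self.normalized = normalized
        self.group_a = a
        self.group_b = b
        self.alpha = float(alpha)
        self.group_names = group_names

    def fit(self) -> GroupComparisonResults:
        rows, skipped = [], []
        va = self.normalized[self.group_a]
        vb = self.normalized[self.group_b]
        for assay in self.normalized.index:
            x = va.loc[assay].dropna().to_numpy(float)
            y = vb.loc[assay].dropna().to_numpy(float)
            if len(x) == 0 or len(y) == 0:
                skipped.append(assay)
                continue
            u, p = _mann_whitney(x, y)
            rows.append(
                (assay, u, p, np.median(x), np.median(y), len(x), len(y))
            )
        table = pd.DataFrame(
            rows,
            columns=[
                "assay_id",
                "u_statistic",
                "p",
                f"median_{self.group_names[0]}",
                f"median_{self.group_names[1]}",
                f"n_{self.group_names[0]}",
                f"n_{self.group_names[1]}",
            ],
        ).set_index("assay_id")
        if len(table):
            table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        else:
            table["p_adj"] = pd.Series(dtype=float)
        table["significant"] = table["p_adj"] < self.alpha
        return GroupComparisonResults(table, self.group_names, self.alpha, skipped)


def mann_whitney_bh(
    normalized: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    **kwargs,
) -> GroupComparisonResults:
    return GroupComparison(normalized, group_a, group_b, alpha=alpha, **kwargs).fit()


# ---------------------------------------------------------------------------
# Pearson covariate screen
# ---------------------------------------------------------------------------

@dataclass
class CorrelationScreenResults:
    """Per-assay Pearson correlations against a sample covariate."""

    table: pd.DataFrame
    covariate_name: str
    alpha: float
    adjusted: bool

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    def summary(self) -> str:
        sig = self.table.loc[self.table["significant"]]
        pos = int((sig["r"] > 0).sum())
        neg = int((sig["r"] < 0).sum())
        col = "adjusted P" if self.adjusted else "raw P"
        return (
            f"Correlation screen vs {self.covariate_name}\n"
            f"  assays tested: {len(self.table)}\n"
            f"  significant ({col} < {self.alpha:g}): {len(sig)} "
            f"({pos} directly, {neg} inversely correlated)"
        )


class CorrelationScreen:
    """Pearson screen of normalized assay levels against a per-sample covariate.

    P-values come from the t transform with n-2 degrees of freedom;
    ``adjust=True`` applies Benjamini-Hochberg across all tested assays.
    Missing values are dropped pairwise; assays with fewer than ``min_n``
    complete observations, or with zero variance, are skipped.
    """

    def __init__(
        self,
        normalized: pd.DataFrame,
        covariate: pd.Series,
        alpha: float = 0.05,
        adjust: bool = False,
        min_n: int = 4,
        covariate_name: str = "covariate",
    ) -> None:
        cov = covariate.reindex(normalized.columns).astype(float)
        if cov.notna().sum() < min_n:
            raise ValueError(f"need at least {min_n} samples with covariate values")
        if np.nanstd(cov.to_numpy()) == 0:
            raise ValueError("covariate has zero variance")
        self.normalized = normalized
        self.covariate = cov
        self.alpha = float(alpha)
        self.adjust = bool(adjust)
        self.min_n = int(min_n)
        self.covariate_name = covariate_name

    def fit(self) -> CorrelationScreenResults:
        rows = []
        x_all = self.covariate.to_numpy()
        for assay, row in self.normalized.iterrows():
            y = row.to_numpy(dtype=float)
            ok = np.isfinite(y) & np.isfinite(x_all)
            n = int(ok.sum())
            if n < self.min_n or np.std(y[ok]) == 0 or np.std(x_all[ok]) == 0:
                continue
            r, p = stats.pearsonr(x_all[ok], y[ok])
            rows.append((assay, float(r), float(p), n))
        table = pd.DataFrame(rows, columns=["assay_id", "r", "p", "n"]).set_index(
            "assay_id"
        )
        if self.adjust and len(table):
            table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
            table["significant"] = table["p_adj"] < self.alpha
        else:
            table["p_adj"] = np.nan
            table["significant"] = table["p"] < self.alpha
        table["direction"] = np.where(table["r"] >= 0, "direct", "inverse")
        return CorrelationScreenResults(
            table=table,
            covariate_name=self.covariate_name,
            alpha=self.alpha,
            adjusted=self.adjust,
        )


def covariate_correlation_screen(
    normalized: pd.DataFrame,
    covariate: pd.Series,
    alpha: float = 0.05,
    adjust: bool = False,
    covariate_name: str = "covariate",
) -> CorrelationScreenResults:
    """Pearson screen against an arbitrary covariate (triglyceride, etc.).

    Defaults to uncorrected two-sided P-values, matching how per-covariate
    correlation tables are conventionally reported for small panels; pass
    ``adjust=True`` for Benjamini-Hochberg control.
    """
    return CorrelationScreen(
        normalized, covariate, alpha=alpha, adjust=adjust, covariate_name=covariate_name
    ).fit()


# ---------------------------------------------------------------------------
# average-linkage Pearson clustering of samples
# ---------------------------------------------------------------------------

@dataclass
class ClusterResults:
    linkage: np.ndarray
    labels: list[str]
    order: list[str]  # deterministic leaf order
    distances: pd.DataFrame

    def newick(self) -> str:
        """Ultrametric dendrogram in Newick format."""
        root = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            kids = sorted(
                [node.left, node.right], key=lambda c: (c.dist, _min_leaf(c, self.labels))
            )
            parts = ",".join(
                f"{rec(k)}:{max(node.dist - k.dist, 0.0):.6g}" for k in kids
            )
            return f"({parts})"

        return rec(root) + ";"

    def top_split(self) -> tuple[list[str], list[str]]:
        """Sample labels of the two subtrees under the root merge."""
        root = hierarchy.to_tree(self.linkage)
        return (
            [self.labels[i] for i in root.left.pre_order()],
            [self.labels[i] for i in root.right.pre_order()],
        )

    def summary(self) -> str:
        left, right = self.top_split()
        return (
            f"Average-linkage Pearson clustering of {len(self.labels)} samples\n"
            f"  top split: {len(left)} vs {len(right)} samples\n"
            f"  leaf order: {', '.join(self.order)}"
        )


def _min_leaf(node, labels: list[str]) -> str:
    return min(labels[i] for i in node.pre_order())


def _ordered_leaves(node, labels: list[str]) -> list[str]:
    if node.is_leaf():
        return [labels[node.id]]
    kids = sorted([node.left, node.right], key=lambda c: (c.dist, _min_leaf(c, labels)))
    out: list[str] = []
    for k in kids:
        out.extend(_ordered_leaves(k, labels))
    return out


def cluster_samples(normalized: pd.DataFrame, min_shared: int = 3) -> ClusterResults:
    """UPGMA clustering of samples with 1 - Pearson r distances.

    Correlations between sample profiles use pairwise-complete assays
    (missing values are absence, never imputed); any sample pair sharing
    fewer than ``min_shared`` assays is an error.  Leaf order is
    deterministic: children of every merge are visited by (merge height,
    lexicographically smallest leaf).
    """
    if normalized.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    corr = normalized.corr(method="pearson", min_periods=min_shared)
    if corr.isna().any().any():
        i, j = np.argwhere(corr.isna().to_numpy())[0]
        raise ValueError(
            f"samples {corr.index[i]!r} and {corr.columns[j]!r} share fewer "
            f"than {min_shared} assays"
        )
    dist = 1.0 - corr
    np.fill_diagonal(dist.values, 0.0)
    z = hierarchy.linkage(squareform(dist.to_numpy(), checks=False), method="average")
    labels = list(normalized.columns)
    order = _ordered_leaves(hierarchy.to_tree(z), labels)
    return ClusterResults(linkage=z, labels=labels, order=order, distances=dist)


# ---------------------------------------------------------------------------
# longitudinal concordance of matched within-person profiles
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalResults:
    per_pair: pd.DataFrame  # index pair label; r, n_assays
    dropouts: pd.DataFrame  # assays differentially detected between timepoints
    n_qualifying: int

    @property
    def min_r(self) -> float:
        return float(self.per_pair["r"].min())

    def summary(self) -> str:
        return (
            f"Longitudinal concordance over {len(self.per_pair)} matched pairs\n"
            f"  qualifying assays (ubiquitously detected): {self.n_qualifying}\n"
            f"  per-pair Pearson R: min {self.min_r:.2f}, "
            f"median {self.per_pair['r'].median():.2f}, "
            f"max {self.per_pair['r'].max():.2f}\n"
            f"  differentially detected assays: {len(self.dropouts)}"
        )


def longitudinal_concordance(
    normalized: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    min_detect_frac: float = 19.0 / 24.0,
    detect_ct_mask: pd.DataFrame | None = None,
    hemolysis_flagged: Sequence[str] | None = None,
) -> LongitudinalResults:
    """Within-person agreement of serum profiles across two timepoints.

    Per-pair Pearson correlations are computed over assays detected in at
    least ``min_detect_frac`` of all samples (19 of 24 for the default
    12-pair design) and present in both members of the pair.  Separately,
    assays detected in at least half of the first (or second) samples under
    ``detect_ct_mask`` (a stricter presence-call mask, e.g. Ct < 34) but in
    no matched opposite sample are listed as differentially detected, with a
    cross-reference against a hemolysis flag list when one is supplied.
    """
    firsts = [a for a, _ in pairs]
    seconds = [b for _, b in pairs]
    samples = firsts + seconds
    sub = normalized[samples]
    n_needed = int(np.ceil(min_detect_frac * len(samples) - 1e-9))
    qualifying = sub.index[sub.notna().sum(axis=1) >= n_needed]

    rows = []
    for i, (a, b) in enumerate(pairs):
        x = normalized.loc[qualifying, a]
        y = normalized.loc[qualifying, b]
        ok = x.notna() & y.notna()
        if ok.sum() < 3:
            raise ValueError(f"pair ({a}, {b}) has fewer than 3 qualifying assays")
        r, _ = stats.pearsonr(x[ok], y[ok])
        rows.append((f"pair_{i + 1}", a, b, float(r), int(ok.sum())))
    per_pair = pd.DataFrame(
        rows, columns=["pair", "first", "second", "r", "n_assays"]
    ).set_index("pair")

    present = (
        detect_ct_mask[samples]
        if detect_ct_mask is not None
        else sub.notna()
    )
    any_first = normalized[firsts].notna().to_numpy().any(axis=1)
    any_second = normalized[seconds].notna().to_numpy().any(axis=1)
    half = 0.5 * len(pairs)
    first_only = (present[firsts].sum(axis=1) >= half) & ~any_second
    second_only = (present[seconds].sum(axis=1) >= half) & ~any_first
    drop = pd.DataFrame(
        {
            "n_first_detected": present[firsts].sum(axis=1),
            "n_second_detected": present[seconds].sum(axis=1),
            "direction": np.where(first_only, "first_only", "second_only"),
        }
    ).loc[first_only | second_only]
    if hemolysis_flagged is not None:
        drop["in_hemolysis_list"] = drop.index.isin(set(hemolysis_flagged))
    return LongitudinalResults(
        per_pair=per_pair, dropouts=drop, n_qualifying=len(qualifying)
    )
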