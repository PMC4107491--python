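"""Endogenous-control selection and deltaCt normalization.

Two complementary stability procedures are provided:

* ``pairwise_ratio_stability`` — for matched-pair designs: per assay and
  pair, the linear-scale ratio ``2**(Ct_first - Ct_second)``; assays whose
  ratio stays below 2 in every pair are candidate within-pair controls,
  ordered by the standard deviation of their ratios.
* ``sd_stability_ranking`` — for cross-cohort comparisons: per assay, the
  standard deviation of the linear quantity ``2**(-Ct)`` across all samples,
  restricted to assays detected in every sample, with a global-mean
  pseudo-assay appended for comparison.  Smaller SD ranks first.

Normalization produces deltaCt = reference Ct - assay Ct (higher deltaCt =
higher relative abundance), where the reference is a single assay, the
arithmetic mean Ct of an assay pair, or the per-sample global mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CtMatrix

__all__ = [
    "GLOBAL_MEAN",
    "PairwiseStabilityResults",
    "StabilityRankingResults",
    "pairwise_ratio_stability",
    "sd_stability_ranking",
    "normalize",
]

#: reference spec value selecting global-mean normalization
GLOBAL_MEAN = "global_mean"


@dataclass
class PairwiseStabilityResults:
    """Within-pair ratio stability of assays detected in all paired samples."""

    table: pd.DataFrame  # index assay; max_ratio, ratio_sd, all_below_2
    ratios: pd.DataFrame  # assay x pair
    ratio_cutoff: float

    @property
    def candidates(self) -> pd.Index:
        """Assays with every ratio below the cutoff, most stable first."""
        ok = self.table[self.table["all_below_cutoff"]]
        ok = ok.loc[sorted(ok.index)]  # deterministic tie-break
        return ok.sort_values("ratio_sd", kind="mergesort").index

    def summary(self) -> str:
        return (
            "Within-pair ratio stability\n"
            f"  assays detected in all paired samples: {len(self.table)}\n"
            f"  candidates (all ratios < {self.ratio_cutoff:g}): "
            f"{len(self.candidates)}\n"
            f"  top candidates: {', '.join(self.candidates[:4])}"
        )


def pairwise_ratio_stability(
    ct: CtMatrix,
    pairs: Sequence[tuple[str, str]],
    ratio_cutoff: float = 2.0,
) -> PairwiseStabilityResults:
    """Rank within-pair stability by linear-scale Ct ratios.

    Only assays detected in *all* paired samples enter; for an assay missing
    in any paired sample a ratio would be undefined.  The ratio for a pair is
    ``2**(Ct_first - Ct_second)`` (abundance of the second member relative to
    the first; for the hemolysis design, lysed relative to unlysed).
    """
    first = [a for a, _ in pairs]
    second = [b for _, b in pairs]
    sub = ct.values[first + second]
    present = sub.notna().all(axis=1)
    assays = ct.assay_ids[present]
    cf = ct.values.loc[assays, first].to_numpy()
    cs = ct.values.loc[assays, second].to_numpy()
    ratios = np.power(2.0, cf - cs)
    table = pd.DataFrame(
        {
            "max_ratio": ratios.max(axis=1),
            "mean_ratio": ratios.mean(axis=1),
            "ratio_sd": ratios.std(axis=1, ddof=1) if ratios.shape[1] > 1 else 0.0,
            "all_below_cutoff": (ratios < ratio_cutoff).all(axis=1),
        },
        index=assays,
    )
    return PairwiseStabilityResults(
        table=table,
        ratios=pd.DataFrame(
            ratios, index=assays, columns=[f"pair_{i}" for i in range(len(pairs))]
        ),
        ratio_cutoff=ratio_cutoff,
    )


@dataclass
class StabilityRankingResults:
    """Cross-cohort linear-scale SD ranking, global-mean row included."""

    table: pd.DataFrame  # index assay (+ "global_mean"); linear_sd, rank
    n_samples: int

    @property
    def ranking(self) -> pd.Index:
        return self.table.sort_values("rank").index

    def best(self, n: int = 2, exclude_global_mean: bool = True) -> list[str]:
        order = [
            a
            for a in self.ranking
            if not (exclude_global_mean and a == GLOBAL_MEAN)
        ]
        return order[:n]

    def summary(self) -> str:
        top = self.table.sort_values("rank").head(6)
        lines = [
            "Endogenous-control ranking "
            f"(SD of 2^-Ct across {self.n_samples} samples; "
            f"{len(self.table) - 1} assays detected in every sample)",
        ]
        for a, row in top.iterrows():
            lines.append(f"  {int(row['rank']):3d}. {a}  SD={row['linear_sd']:.2e}")
        return "\n".join(lines)


def sd_stability_ranking(
    cts: CtMatrix | Sequence[CtMatrix],
) -> StabilityRankingResults:
    """Rank ubiquitously detected assays by cross-sample linear-scale SD.

    One or more cohorts may be given; their samples are pooled.  Only assays
    detected in every pooled sample enter the table.  The global-mean
    pseudo-assay is the per-sample mean of ``2**(-Ct)`` over that same
    detected-everywhere set.  Ties rank lexicographically by assay id.
    """
    if isinstance(cts, CtMatrix):
        cts = [cts]
    merged = pd.concat([c.values for c in cts], axis=1, join="inner")
    if merged.columns.has_duplicates:
        raise ValueError("pooled cohorts share sample ids")
    if merged.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    everywhere = merged.notna().all(axis=1)
    if not everywhere.any():
        raise ValueError("no assay detected in every sample")
    linear = np.power(2.0, -merged.loc[everywhere])
    sd = linear.std(axis=1, ddof=1)
    sd[GLOBAL_MEAN] = linear.mean(axis=0).std(ddof=1)
    table = pd.DataFrame({"linear_sd": sd})
    # lexicographic pre-sort + stable sort on SD gives deterministic tie-breaks
    table = table.loc[sorted(table.index)]
    order = table.sort_values(by="linear_sd", kind="mergesort").index
    table["rank"] = pd.Series(range(1, len(order) + 1), index=order)
    return StabilityRankingResults(table=table, n_samples=merged.shape[1])


def normalize(
    ct: CtMatrix,
    reference: str | Sequence[str],
) -> pd.DataFrame:
    """deltaCt-normalize a Ct matrix.

    ``reference`` is one assay id, a sequence of assay ids (averaged on the
    Ct scale, i.e. geometric mean of linear quantities), or ``"global_mean"``
    (per-sample mean Ct over assays detected in all samples).  DeltaCt is
    defined only where the assay Ct is present; the reference must be
    detected in every sample.

    Returns a DataFrame of deltaCt values with the reference recorded in
    ``.attrs["reference"]``.
    """
    vals = ct.values
    if isinstance(reference, str) and reference == GLOBAL_MEAN:
        everywhere = vals.notna().all(axis=1)
        if not everywhere.any():
            raise ValueError("global mean undefined: no assay detected everywhere")
        ref_ct = vals.loc[everywhere].mean(axis=0)
        ref_label: object = GLOBAL_MEAN
    else:
        refs = [reference] if isinstance(reference, str) else list(reference)
        missing = set(refs) - set(vals.index)
        if missing:
            raise ValueError(f"reference assay(s) not in matrix: {sorted(missing)}")
        ref_rows = vals.loc[refs]
        if ref_rows.isna().any().any():
            bad = ref_rows.columns[ref_rows.isna().any(axis=0)].tolist()
            raise ValueError(f"reference undetected in sample(s): {bad}")
        ref_ct = ref_rows.mean(axis=0)
        ref_label = refs
    out = (-vals).add(ref_ct, axis=1)
    out.attrs["reference"] = ref_label
    return out
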