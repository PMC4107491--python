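"""Reaction- and assay-level QC filters and inter-plate calibration.

Two detection thresholds are deliberately distinct, both configurable:

* ``max_ct`` (default 35): reactions above this cycle are excluded outright,
  alongside assays with multiple melting-curve peaks and reactions within
  ``neg_ctrl_margin`` cycles of their negative control.
* ``detect_ct`` (default 34): the ceiling for presence/absence calls used by
  detection-fraction comparisons.

Boundary conventions are literal: Ct 35.0 is retained by the reaction filter
("> 35" excluded), Ct 34.0 is not a presence call ("below 34"), and a
detection fraction of exactly 80% passes the detection filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AssayQcFlags, CtMatrix

__all__ = [
    "FilterConfig",
    "filter_reactions",
    "interplate_calibrate",
    "detection_filter",
    "spike_in_check",
    "SpikeInResult",
]


@dataclass(frozen=True)
class FilterConfig:
    max_ct: float = 35.0
    neg_ctrl_margin: float = 5.0
    detect_ct: float = 34.0
    min_detect_frac: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.detect_ct <= self.max_ct <= 40):
            raise ValueError("need 0 < detect_ct <= max_ct <= 40")
        if not (0 < self.min_detect_frac <= 1):
            raise ValueError("min_detect_frac must be in (0, 1]")


def filter_reactions(
    ct: CtMatrix, flags: AssayQcFlags | None, cfg: FilterConfig = FilterConfig()
) -> CtMatrix:
    """Hide unreliable reactions; never un-hides anything.

    An entry becomes missing when (a) its assay shows more than one melting
    peak, (b) its Ct exceeds ``cfg.max_ct``, or (c) it lies within
    ``cfg.neg_ctrl_margin`` cycles of an amplifying negative control.
    """
    vals = ct.values.copy()
    if flags is not None:
        missing = ct.assay_ids.difference(flags.table.index)
        if len(missing):
            raise ValueError(f"assays without QC flags: {list(missing)[:5]}...")
        tm = flags.table["n_tm_peaks"].reindex(ct.assay_ids)
        vals.loc[tm > 1, :] = np.nan
        neg = flags.table["negative_control_ct"].reindex(ct.assay_ids)
        has_neg = neg.notna().to_numpy()
        close = vals.to_numpy() >= (neg.to_numpy()[:, None] - cfg.neg_ctrl_margin)
        vals = vals.mask(pd.DataFrame(close & has_neg[:, None], index=vals.index, columns=vals.columns))
    vals = vals.mask(vals > cfg.max_ct)
    return CtMatrix(vals, None if ct.plate_of is None else ct.plate_of.copy())


def interplate_calibrate(ct: CtMatrix, ipc: pd.DataFrame | pd.Series) -> CtMatrix:
    """Remove plate-to-plate Ct offsets using inter-plate calibrator wells.

    For each plate the mean calibrator Ct minus the grand mean (of plate
    means) is subtracted from every reaction on that plate, so within-plate
    Ct differences are preserved exactly and re-calibration is idempotent.

    ``ipc`` is either a DataFrame with columns ``plate`` and ``ct`` (one row
    per calibrator well) or a Series of per-plate mean calibrator Ct.
    """
    if ct.plate_of is None:
        raise ValueError("Ct matrix has no plate assignments")
    if isinstance(ipc, pd.DataFrame):
        plate_means = ipc.groupby("plate")["ct"].mean()
    else:
        plate_means = ipc.astype(float)
    plates = pd.Index(ct.plate_of.unique())
    missing = plates.difference(plate_means.index)
    if len(missing):
        raise ValueError(f"plates without calibrator values: {list(missing)}")
    offsets = plate_means.loc[plates] - plate_means.loc[plates].mean()
    per_sample = ct.plate_of.map(offsets).astype(float)
    vals = ct.values.sub(per_sample.reindex(ct.sample_ids), axis=1)
    # calibration can push a value fractionally above the storage ceiling
    vals = vals.clip(upper=40.0)
    return CtMatrix(vals, ct.plate_of.copy())


def detection_filter(
    ct: CtMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    cfg: FilterConfig = FilterConfig(),
) -> pd.Index:
    """Assays detected in >= ``min_detect_frac`` of either group's samples.

    "Detected" means a present Ct at or below ``cfg.detect_ct``.  Low-abundance
    assays detected in fewer than the required fraction of *both* groups are
    excluded from analyses.
    """
    a = list(group_a)
    b = list(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if set(a) & set(b):
        raise ValueError("groups must be disjoint")
    det = ct.detected(ceiling=cfg.detect_ct)
    frac_a = det[a].mean(axis=1)
    frac_b = det[b].mean(axis=1)
    keep = (frac_a >= cfg.min_detect_frac) | (frac_b >= cfg.min_detect_frac)
    return ct.assay_ids[keep]


@dataclass
class SpikeInResult:
    """Extraction-efficiency check on an exogenous spike-in assay."""

    group_a_ct: pd.Series
    group_b_ct: pd.Series
    statistic: float
    p_value: float
    median_difference: float
    passed: bool

    def summary(self) -> str:
        state = "PASS" if self.passed else "FAIL"
        return (
            f"Spike-in check: {state}\n"
            f"  Mann-Whitney two-sided P = {self.p_value:.3f}; "
            f"median Ct difference = {self.median_difference:+.2f} cycles\n"
            f"  group medians: {self.group_a_ct.median():.2f} vs "
            f"{self.group_b_ct.median():.2f} (n = {len(self.group_a_ct)}, "
            f"{len(self.group_b_ct)})"
        )


def spike_in_check(
    ct: CtMatrix,
    spike_assay: str,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    max_median_shift: float = 1.5,
) -> SpikeInResult:
    """Test that extraction efficiency does not differ between two groups.

    The spike-in is added at a fixed amount before extraction, so its raw Ct
    should not differ between groups.  The check fails when the two-sided
    Mann-Whitney P falls below ``alpha`` *or* the group median Ct difference
    exceeds ``max_median_shift`` cycles; the effect-size guard keeps the check
    meaningful at group sizes too small for a rank test to reach ``alpha``.
    """
    if spike_assay not in ct.assay_ids:
        raise ValueError(f"spike-in assay {spike_assay!r} not in matrix")
    row = ct.values.loc[spike_assay]
    a = row[list(group_a)].dropna()
    b = row[list(group_b)].dropna()
    if a.empty or b.empty:
        raise ValueError("spike-in assay undetected in one of the groups")
    if a.nunique() == 1 and b.nunique() == 1 and a.iloc[0] == b.iloc[0]:
        u, p = len(a) * len(b) / 2.0, 1.0
    else:
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    mdiff = float(a.median() - b.median())
    passed = (p >= alpha) and (abs(mdiff) <= max_median_shift)
    return SpikeInResult(a, b, float(u), float(p), mdiff, passed)
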