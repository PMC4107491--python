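"""Hemolysis quantification and hemolysis-sensitivity screening.

Free hemoglobin released by ruptured red cells absorbs strongly at 415 nm;
the Harboe method estimates its serum concentration from absorbances at
380/415/450 nm with a three-point background correction:

    Hb [g/l] = (167.2 * A415 - 83.6 * A380 - 83.6 * A450) / 1000

Samples at or above 0.1 g/l are classified as hemolysed.  Because red cells
also carry abundant miRNAs, hemolysis inflates blood-cell-derived assays in
serum; the screen flags assays that are >= ``fc_cutoff``-fold up-regulated in
at least half of matched lysed/unlysed pairs, or that appear in lysed samples
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .differential import CorrelationScreen, CorrelationScreenResults
from .io import CtMatrix

__all__ = [
    "harboe_hemoglobin",
    "classify_hemolysis",
    "HemolysisScreen",
    "HemolysisScreenResults",
    "CorrelationScreen",
    "CorrelationScreenResults",
]

#: hemoglobin at which a serum sample is called hemolysed (g/l)
HEMOLYSIS_THRESHOLD = 0.1
#: clean-serum hemoglobin baseline used by the simulator's effect model (g/l)
CLEAN_HB = 0.05


def harboe_hemoglobin(a380, a415, a450):
    """Serum hemoglobin concentration (g/l) by the Harboe method.

    Accepts scalars or arrays.  Small negative results (>= -0.005 g/l), which
    arise from background-correction noise in clean samples, clamp to zero
    with a warning; strongly negative results signal mis-ordered absorbances
    and raise ``ValueError``.
    """
    a380 = np.asarray(a380, dtype=float)
    a415 = np.asarray(a415, dtype=float)
    a450 = np.asarray(a450, dtype=float)
    if (a380 < 0).any() or (a415 < 0).any() or (a450 < 0).any():
        raise ValueError("absorbances must be non-negative")
    hb = (167.2 * a415 - 83.6 * a380 - 83.6 * a450) / 1000.0
    if (hb < -0.005).any():
        raise ValueError(
            "strongly negative hemoglobin estimate; check absorbance ordering"
        )
    if (hb < 0).any():
        warnings.warn("negative hemoglobin estimate clamped to 0", stacklevel=2)
        hb = np.maximum(hb, 0.0)
    if hb.ndim == 0:
        return float(hb)
    return hb


def classify_hemolysis(hb, threshold: float = HEMOLYSIS_THRESHOLD):
    """True when hemoglobin >= threshold (boundary counts as hemolysed)."""
    hb_arr = np.asarray(hb, dtype=float)
    if (hb_arr < 0).any():
        raise ValueError("hemoglobin must be non-negative")
    out = hb_arr >= threshold
    if out.ndim == 0:
        return bool(out)
    return out


# ---------------------------------------------------------------------------
# hemolysis screen
# ---------------------------------------------------------------------------

@dataclass
class HemolysisScreenResults:
    """Per-assay hemolysis-sensitivity flags.

    ``table`` has one row per assay with per-pair fold-change summaries and a
    ``reason`` in {fold_change, differential_detection, both, none}.  Counts
    are reported against both denominators (all pairs / evaluable pairs);
    flags use the denominator the screen was configured with.
    """

    table: pd.DataFrame
    fold_changes: pd.DataFrame  # assay x pair FC (NaN where not evaluable)
    n_pairs: int
    fc_cutoff: float
    n_up_in_all: int = 0
    n_up_in_any: int = 0
    n_down_in_any: int = 0

    @property
    def flagged(self) -> pd.Index:
        return self.table.index[self.table["flag"]]

    def summary(self) -> str:
        t = self.table
        lines = [
            "Hemolysis sensitivity screen",
            f"  pairs: {self.n_pairs}; assays screened: {len(t)}",
            f"  fold-change cutoff: {self.fc_cutoff:g}",
            f"  >= {self.fc_cutoff:g}-fold up in all pairs: {self.n_up_in_all}",
            f"  >= {self.fc_cutoff:g}-fold up in >= 1 pair: {self.n_up_in_any}",
            f"  >= {self.fc_cutoff:g}-fold down in >= 1 pair: {self.n_down_in_any}",
            f"  flagged: {int(t['flag'].sum())} "
            f"(fold change {int((t['reason'] == 'fold_change').sum())}, "
            f"lysed-only detection {int((t['reason'] == 'differential_detection').sum())}, "
            f"both {int((t['reason'] == 'both').sum())})",
        ]
        return "\n".join(lines)


class HemolysisScreen:
    """Flag assays whose serum level is driven by red-cell contamination.

    Parameters
    ----------
    ct : CtMatrix
        Raw (reaction-filtered) Ct values.
    pairs : sequence of (unlysed_id, lysed_id)
        Matched sample pairs from one blood draw each.
    reference : str
        Assay used to normalize within each pair before fold-change analysis;
        it must be detected in every paired sample.  A single within-pair
        stable assay is used here (rather than the cross-cohort reference
        pair) because only intra-individual comparisons are made.
    fc_cutoff : float
        Fold-change threshold for the up-regulation rule (default 3).
    min_pair_frac : float
        Fraction of pairs that must exceed the cutoff (default 0.5).
    detect_ct : float
        Presence-call ceiling for the differential-detection rule (default 34).
    denominator : {"pairs", "evaluable"}
        Whether ``min_pair_frac`` is taken of all pairs or only of pairs where
        the assay yields a fold change.  Both counts are always reported.
    """

    def __init__(
        self,
        ct: CtMatrix,
        pairs: Sequence[tuple[str, str]],
        reference: str,
        fc_cutoff: float = 3.0,
        min_pair_frac: float = 0.5,
        detect_ct: float = 34.0,
        denominator: str = "pairs",
    ) -> None:
        if len(pairs) < 1:
            raise ValueError("at least one matched pair is required")
        if denominator not in ("pairs", "evaluable"):
            raise ValueError("denominator must be 'pairs' or 'evaluable'")
        if reference not in ct.assay_ids:
            raise ValueError(f"reference assay {reference!r} not in matrix")
        self.ct = ct
        self.pairs = list(pairs)
        self.reference = reference
        self.fc_cutoff = float(fc_cutoff)
        self.min_pair_frac = float(min_pair_frac)
        self.detect_ct = float(detect_ct)
        self.denominator = denominator

    def fit(self) -> HemolysisScreenResults:
        vals = self.ct.values
        unlysed = [u for u, _ in self.pairs]
        lysed = [l for _, l in self.pairs]
        ref_u = vals.loc[self.reference, unlysed]
        ref_l = vals.loc[self.reference, lysed]
        if ref_u.isna().any() or ref_l.isna().any():
            bad = ref_u.index[ref_u.isna()].tolist() + ref_l.index[ref_l.isna()].tolist()
            raise ValueError(
                f"reference assay {self.reference!r} undetected in paired "
                f"sample(s) {bad}"
            )

        assays = vals.index
        cu = vals[unlysed].to_numpy()
        cl = vals[lysed].to_numpy()
        # deltaCt = ref Ct - assay Ct; FC(lysed vs unlysed) = 2**(dCt_l - dCt_u)
        d_u = ref_u.to_numpy()[None, :] - cu
        d_l = ref_l.to_numpy()[None, :] - cl
        fc = np.power(2.0, d_l - d_u)  # NaN where either member missing

        n_pairs = len(self.pairs)
        evaluable = np.isfinite(fc)
        n_eval = evaluable.sum(axis=1)
        n_up = np.nansum(fc >= self.fc_cutoff, axis=1).astype(int)
        n_down = np.nansum(fc <= 1.0 / self.fc_cutoff, axis=1).astype(int)

        denom = n_pairs if self.denominator == "pairs" else np.maximum(n_eval, 1)
        frac_up = n_up / denom
        flag_fc = (n_eval > 0) & (frac_up >= self.min_pair_frac)

        det_l = np.isfinite(cl) & (cl < self.detect_ct)
        det_u_any = np.isfinite(cu).any(axis=1)
        flag_dd = (det_l.sum(axis=1) >= 0.5 * n_pairs) & ~det_u_any

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            max_fc = np.nanmax(np.where(evaluable, fc, np.nan), axis=1)

        reason = np.where(
            flag_fc & flag_dd,
            "both",
            np.where(flag_fc, "fold_change", np.where(flag_dd, "differential_detection", "none")),
        )
        table = pd.DataFrame(
            {
                "n_pairs_evaluable": n_eval,
                "n_pairs_up": n_up,
                "n_pairs_down": n_down,
                "frac_up_all_pairs": n_up / n_pairs,
                "frac_up_evaluable": np.where(n_eval > 0, n_up / np.maximum(n_eval, 1), np.nan),
                "max_fold_change": max_fc,
                "n_lysed_detected": det_l.sum(axis=1),
                "detected_in_unlysed": det_u_any,
                "flag": flag_fc | flag_dd,
                "reason": reason,
            },
            index=assays,
        )
        return HemolysisScreenResults(
            table=table,
            fold_changes=pd.DataFrame(fc, index=assays, columns=[f"pair_{i}" for i in range(n_pairs)]),
            n_pairs=n_pairs,
            fc_cutoff=self.fc_cutoff,
            n_up_in_all=int(((fc >= self.fc_cutoff).all(axis=1) & evaluable.all(axis=1)).sum()),
            n_up_in_any=int((n_up >= 1).sum()),
            n_down_in_any=int((n_down >= 1).sum()),
        )


def hemoglobin_correlation_screen(
    normalized: pd.DataFrame,
    hemoglobin: pd.Series,
    alpha: float = 0.05,
) -> CorrelationScreenResults:
    """BH-adjusted Pearson screen of normalized levels against hemoglobin."""
    return CorrelationScreen(
        normalized,
        hemoglobin,
        alpha=alpha,
        adjust=True,
        covariate_name="hemoglobin",
    ).fit()
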