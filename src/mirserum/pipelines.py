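"""End-to-end analyses tying the pipeline stages into the five study designs.

Each ``run_*`` function executes filter -> calibrate -> normalize ->
screen/test for one experimental design and returns a mapping of result
names to DataFrames and summary strings, suitable for ``io.write_report``.
The entry points operate on in-memory containers; the CLI wraps them with
file loading and a run configuration.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from . import differential, hemolysis, qc
from .io import AssayQcFlags, CtMatrix, SampleSheet
from .normalize import normalize, pairwise_ratio_stability, sd_stability_ranking
from .qc import FilterConfig

__all__ = [
    "prepare_matrix",
    "run_hemolysis",
    "run_endogenous_controls",
    "run_fasting",
    "run_smoking",
    "run_longitudinal",
    "run_calibrate_cutoff",
]


def prepare_matrix(
    ct: CtMatrix,
    flags: AssayQcFlags | None = None,
    ipc: pd.DataFrame | None = None,
    cfg: FilterConfig = FilterConfig(),
    drop_assays: Sequence[str] = (),
) -> CtMatrix:
    """Reaction-filter and inter-plate-calibrate a raw Ct matrix.

    ``drop_assays`` removes non-biological rows (e.g. an exogenous spike-in)
    before analysis.
    """
    out = qc.filter_reactions(ct, flags, cfg)
    if ipc is not None and out.plate_of is not None:
        out = qc.interplate_calibrate(out, ipc)
    if drop_assays:
        out = CtMatrix(
            out.values.drop(index=list(drop_assays), errors="ignore"),
            out.plate_of,
        )
    return out


def _hemoglobin(samples: SampleSheet) -> pd.Series:
    hb = samples.hemoglobin()
    if hb.isna().all():
        raise ValueError("sample sheet has neither hemoglobin nor absorbances")
    return hb


def run_hemolysis(
    ct: CtMatrix,
    samples: SampleSheet,
    flags: AssayQcFlags | None = None,
    ipc: pd.DataFrame | None = None,
    cfg: FilterConfig = FilterConfig(),
    fc_cutoff: float = 3.0,
    pair_reference: str | None = None,
    cohort_reference: Sequence[str] | None = None,
    spike_assay: str | None = None,
    alpha: float = 0.05,
) -> dict[str, object]:
    """The hemolysis experiment: classification, screens and clustering.

    Steps: quantify hemoglobin (Harboe) and classify samples; QC-filter and
    calibrate the matrix; check the spike-in when one is named; select the
    within-pair normalizer by ratio stability (unless ``pair_reference`` is
    given) and run the fold-change/differential-detection screen; normalize
    to ``cohort_reference`` (default: the two most SD-stable assays of this
    cohort) and screen for hemoglobin correlation; cluster the samples.
    """
    results: dict[str, object] = {}
    hb = _hemoglobin(samples)
    lysed_mask = hemolysis.classify_hemolysis(hb.to_numpy())
    classification = pd.DataFrame(
        {"hemoglobin_g_l": hb, "hemolysed": lysed_mask}, index=hb.index
    )
    results["hemoglobin_classification"] = classification

    work = prepare_matrix(
        ct, flags, ipc, cfg, drop_assays=[spike_assay] if spike_assay else []
    )

    if spike_assay is not None:
        clean = hb.index[~lysed_mask].tolist()
        lysed = hb.index[lysed_mask].tolist()
        spike = qc.spike_in_check(ct, spike_assay, clean, lysed, alpha=alpha)
        results["spike_in_check"] = spike.summary()

    pairs = samples.pairs()
    # order each pair (unlysed, lysed) using the hemoglobin classification
    ordered = []
    for a, b in pairs:
        if classification.loc[a, "hemolysed"] and not classification.loc[b, "hemolysed"]:
            a, b = b, a
        ordered.append((a, b))

    stability = pairwise_ratio_stability(work, ordered)
    results["pairwise_stability"] = stability.table
    results["pairwise_stability_summary"] = stability.summary()

    if pair_reference is None:
        if not len(stability.candidates):
            raise ValueError("no within-pair stable candidate; name pair_reference")
        pair_reference = stability.candidates[0]
    screen = hemolysis.HemolysisScreen(
        work, ordered, reference=pair_reference, fc_cutoff=fc_cutoff,
        detect_ct=cfg.detect_ct,
    ).fit()
    results["hemolysis_screen"] = screen.table
    results["hemolysis_screen_summary"] = screen.summary()
    results["hemolysis_flagged"] = screen.table.loc[screen.table["flag"]]

    if cohort_reference is None:
        cohort_reference = sd_stability_ranking(work).best(2)
    normalized = normalize(work, cohort_reference)
    clean = hb.index[~lysed_mask].tolist()
    lysed = hb.index[lysed_mask].tolist()
    keep = qc.detection_filter(work, lysed, clean, cfg)
    keep = keep.difference(pd.Index(cohort_reference))
    corr = hemolysis.hemoglobin_correlation_screen(
        normalized.loc[keep], hb, alpha=alpha
    )
    results["hemoglobin_correlation"] = corr.table
    results["hemoglobin_correlation_summary"] = corr.summary()

    clust = differential.cluster_samples(normalized.loc[keep])
    results["cluster_newick"] = clust.newick()
    results["cluster_summary"] = clust.summary()
    return results


def run_endogenous_controls(
    cts: Sequence[CtMatrix],
) -> dict[str, object]:
    """Cross-cohort endogenous-control ranking (linear-scale SD + global mean)."""
    ranking = sd_stability_ranking(list(cts))
    return {
        "stability_ranking": ranking.table.sort_values("rank"),
        "stability_summary": ranking.summary(),
        "recommended_controls": pd.Series(ranking.best(2), name="assay_id"),
    }


def _paired_group_analysis(
    ct: CtMatrix,
    samples: SampleSheet,
    group_a: str,
    group_b: str,
    reference: Sequence[str],
    cfg: FilterConfig,
    alpha: float,
    fc_cutoff: float,
) -> tuple[dict[str, object], pd.DataFrame]:
    """Detection comparison + group test + per-pair fold changes."""
    results: dict[str, object] = {}
    a_ids = samples.group_samples(group_a)
    b_ids = samples.group_samples(group_b)
    det = ct.detected(ceiling=cfg.detect_ct)
    counts = pd.DataFrame(
        {
            "n_detected": det.sum(axis=0),
            "group": samples.table.loc[det.columns, "group"],
        }
    )
    results["detection_counts"] = counts
    u, p = differential._mann_whitney(
        counts.loc[a_ids, "n_detected"].to_numpy(float),
        counts.loc[b_ids, "n_detected"].to_numpy(float),
    )
    results["detection_count_test"] = (
        f"Total detected assays, {group_a} vs {group_b}: "
        f"medians {counts.loc[a_ids, 'n_detected'].median():.0f} vs "
        f"{counts.loc[b_ids, 'n_detected'].median():.0f}; "
        f"Mann-Whitney two-sided P = {p:.2f}"
    )

    keep = qc.detection_filter(ct, a_ids, b_ids, cfg)
    keep = keep.difference(pd.Index(list(reference)))
    normalized = normalize(ct, list(reference))
    test = differential.GroupComparison(
        normalized.loc[keep], a_ids, b_ids, alpha=alpha, group_names=(group_a, group_b)
    ).fit()
    results["group_test"] = test.table
    results["group_test_summary"] = test.summary()

    pairs = samples.pairs()
    fc_rows = {}
    for i, (x, y) in enumerate(pairs):
        fc_rows[f"pair_{i + 1}"] = differential.fold_change(
            normalized.loc[keep, x], normalized.loc[keep, y]
        )
    fc = pd.DataFrame(fc_rows, index=keep)
    n_up = (fc >= fc_cutoff).sum(axis=1)
    n_down = (fc <= 1 / fc_cutoff).sum(axis=1)
    half = 0.5 * len(pairs)
    results["fold_changes"] = pd.DataFrame(
        {
            "n_pairs_up": n_up,
            "n_pairs_down": n_down,
            "frequently_deregulated": (n_up >= half) | (n_down >= half),
        }
    )
    return results, normalized


def run_fasting(
    ct: CtMatrix,
    samples: SampleSheet,
    flags: AssayQcFlags | None = None,
    ipc: pd.DataFrame | None = None,
    cfg: FilterConfig = FilterConfig(),
    reference: Sequence[str] | None = None,
    hemolysis_flagged: Sequence[str] = (),
    spike_assay: str | None = None,
    alpha: float = 0.05,
    fc_cutoff: float = 3.0,
) -> dict[str, object]:
    """The fasting experiment: triglyceride correlation + paired comparison.

    Assays previously flagged as hemolysis-sensitive can be excluded via
    ``hemolysis_flagged`` before detection counting, as the study design
    prescribes.
    """
    drop = list(hemolysis_flagged) + ([spike_assay] if spike_assay else [])
    work = prepare_matrix(ct, flags, ipc, cfg, drop_assays=drop)
    if reference is None:
        reference = sd_stability_ranking(work).best(2)
    results, normalized = _paired_group_analysis(
        work, samples, "non_fasting", "fasting", reference, cfg, alpha, fc_cutoff
    )
    tg = samples.table["triglyceride"].astype(float)
    keep = results["group_test"].index
    screen = differential.covariate_correlation_screen(
        normalized.loc[keep], tg, alpha=alpha, adjust=False,
        covariate_name="triglyceride",
    )
    results["triglyceride_correlation"] = screen.table
    results["triglyceride_summary"] = screen.summary()
    return results


def run_smoking(
    ct: CtMatrix,
    samples: SampleSheet,
    flags: AssayQcFlags | None = None,
    ipc: pd.DataFrame | None = None,
    cfg: FilterConfig = FilterConfig(),
    reference: Sequence[str] | None = None,
    spike_assay: str | None = None,
    alpha: float = 0.05,
) -> dict[str, object]:
    """The smoking experiment: BH-controlled group comparison."""
    work = prepare_matrix(
        ct, flags, ipc, cfg, drop_assays=[spike_assay] if spike_assay else []
    )
    if reference is None:
        reference = sd_stability_ranking(work).best(2)
    smokers = samples.group_samples("smoker")
    non = samples.group_samples("non_smoker")
    keep = qc.detection_filter(work, smokers, non, cfg)
    keep = keep.difference(pd.Index(list(reference)))
    normalized = normalize(work, list(reference))
    test = differential.GroupComparison(
        normalized.loc[keep], smokers, non, alpha=alpha,
        group_names=("smoker", "non_smoker"),
    ).fit()
    only_one_group = {
        "smoker_only": work.values.loc[keep, smokers].notna().any(axis=1)
        & ~work.values.loc[keep, non].notna().any(axis=1),
        "non_smoker_only": work.values.loc[keep, non].notna().any(axis=1)
        & ~work.values.loc[keep, smokers].notna().any(axis=1),
    }
    return {
        "group_test": test.table,
        "group_test_summary": test.summary(),
        "exclusive_detection": pd.DataFrame(only_one_group),
    }


def run_longitudinal(
    ct: CtMatrix,
    samples: SampleSheet,
    flags: AssayQcFlags | None = None,
    ipc: pd.DataFrame | None = None,
    cfg: FilterConfig = FilterConfig(),
    reference: Sequence[str] | None = None,
    hemolysis_flagged: Sequence[str] | None = None,
    spike_assay: str | None = None,
    min_detect_frac: float = 19.0 / 24.0,
    fc_cutoff: float = 3.0,
) -> dict[str, object]:
    """The longitudinal experiment: per-pair concordance and dropouts."""
    work = prepare_matrix(
        ct, flags, ipc, cfg, drop_assays=[spike_assay] if spike_assay else []
    )
    if reference is None:
        reference = sd_stability_ranking(work).best(2)
    normalized = normalize(work, list(reference))
    pairs = samples.pairs()
    detect_mask = work.detected(ceiling=cfg.detect_ct)
    res = differential.longitudinal_concordance(
        normalized,
        pairs,
        min_detect_frac=min_detect_frac,
        detect_ct_mask=detect_mask,
        hemolysis_flagged=hemolysis_flagged,
    )
    firsts = [a for a, _ in pairs]
    seconds = [b for _, b in pairs]
    fc_rows = {
        f"pair_{i + 1}": differential.fold_change(
            normalized[a], normalized[b]
        )
        for i, (a, b) in enumerate(pairs)
    }
    fc = pd.DataFrame(fc_rows, index=normalized.index)
    half = 0.5 * len(pairs)
    frequent = ((fc >= fc_cutoff).sum(axis=1) >= half) | (
        (fc <= 1 / fc_cutoff).sum(axis=1) >= half
    )
    return {
        "per_pair_correlation": res.per_pair,
        "differential_detection": res.dropouts,
        "frequently_deregulated": fc.loc[frequent],
        "longitudinal_summary": res.summary(),
    }


def run_calibrate_cutoff(
    ct: CtMatrix,
    samples: SampleSheet,
    flags: AssayQcFlags | None = None,
    ipc: pd.DataFrame | None = None,
    cfg: FilterConfig = FilterConfig(),
    reference: Sequence[str] | None = None,
    spike_assay: str | None = None,
    budget: float = 0.10,
) -> dict[str, object]:
    """Fold-change cutoff calibration from a technical replicate pair.

    The matrix must contain exactly one matched pair (two replicate profiles
    of the same serum); with several pairs each is calibrated and the median
    fractions are reported.
    """
    work = prepare_matrix(
        ct, flags, ipc, cfg, drop_assays=[spike_assay] if spike_assay else []
    )
    if reference is None:
        reference = sd_stability_ranking(work).best(2)
    normalized = normalize(work, list(reference))
    pairs = samples.pairs()
    if not pairs:
        raise ValueError("no matched replicate pair in the sample sheet")
    cals = [
        differential.calibrate_cutoff(normalized[a], normalized[b], budget=budget)
        for a, b in pairs
    ]
    table = pd.DataFrame(
        {
            "n_codetected": [c.n_codetected for c in cals],
            **{
                f"frac_ge_{t:g}fold": [c.fractions[t] for c in cals]
                for t in cals[0].fractions
            },
            "cutoff": [c.cutoff for c in cals],
        },
        index=[f"pair_{i + 1}" for i in range(len(cals))],
    )
    # consensus: apply the budget rule to the median fraction per threshold,
    # which is robust to single-pair sampling noise
    med_frac = {t: float(table[f"frac_ge_{t:g}fold"].median()) for t in cals[0].fractions}
    consensus = next((t for t in sorted(med_frac) if med_frac[t] <= budget), None)
    return {
        "cutoff_calibration": table,
        "consensus_cutoff": pd.Series(
            {**{f"median_frac_ge_{t:g}fold": v for t, v in med_frac.items()},
             "median_codetected": float(table["n_codetected"].median()),
             "cutoff": consensus},
            name="value",
        ),
        "cutoff_summary": cals[0].summary() if len(cals) == 1 else (
            f"Median over {len(cals)} replicate pairs: "
            + ", ".join(f">={t:g}-fold {100 * v:.0f}%" for t, v in med_frac.items())
            + f"; median co-detected {table['n_codetected'].median():.0f}"
            + f"; chosen cutoff {consensus:g}"
        ),
    }
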