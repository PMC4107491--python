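"""Synthetic panel design and measurement-noise model.

The default design emulates a 742-assay serum miRNA qRT-PCR panel:

* two designated reference assays -- biologically stable, hemolysis-
  insensitive, unusually tight technically; the panel's endogenous controls;
* two within-pair stable assays -- hemolysis-insensitive and technically
  quiet, but strongly person-variable (liver-enriched miR-122-like
  behaviour), so they are good within-pair normalizers and poor cross-cohort
  controls;
* one exogenous spike-in whose Ct is independent of every covariate;
* 162 blood-cell-derived assays whose serum level rises with free
  hemoglobin: 126 are expressed in clean serum (flaggable through fold
  change) and 36 appear only in hemolysed samples (flaggable through
  lysed-only detection);
* serum-expressed background assays, a sporadically expressed tier, and a
  large never-expressed remainder, as expected when a genome-wide panel is
  applied to serum.

Replicate noise is Ct-dependent and has two components: a tight, bounded
base error whose SD rises above ``knee_ct``, and sporadic near-discrete
threshold-cycle jumps whose probability ramps up above the knee
(low-template reactions sample few molecules, so their crossing cycle can
slip by one or more cycles in either direction).  Reactions whose noisy Ct
exceeds ``detect_ct`` are censored to missing, never clipped.  The numeric
defaults are calibrated so that a simulated technical-replicate pair
reproduces the detection count (~157 co-detected assays) and the
fold-difference fractions (~31%/9%/3% at 2/3/4-fold) measured for this
class of serum panel; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = ["NoiseModel", "PanelDesign", "CohortSpec", "default_panel", "SCENARIOS"]

#: physical floor for a "true" Ct; amplification saturates below this
CT_TRUE_FLOOR = 8.0

#: scenarios understood by the cohort generator
SCENARIOS = (
    "technical_repeat",
    "hemolysis_pairs",
    "fasting_pairs",
    "smoker_cohort",
    "longitudinal_pairs",
)

#: allowed scenario parameters and their defaults (see generate_cohort)
SCENARIO_DEFAULTS: dict[str, dict[str, Any]] = {
    "technical_repeat": {"hb_clean": (0.035, 0.08)},
    "hemolysis_pairs": {"hb_clean": (0.035, 0.08), "hb_lysed": (0.15, 2.45)},
    "fasting_pairs": {
        "hb_clean": (0.035, 0.08),
        "tg_nonfasting": (50.0, 210.0),
        "tg_fasting_ratio": (0.35, 0.85),
        "n_tg_correlated": 0,
        "tg_ct_per_mgdl": 0.015,
    },
    "smoker_cohort": {"hb_clean": (0.035, 0.08)},
    "longitudinal_pairs": {
        "hb_clean": (0.035, 0.08),
        "drift_sd_range": (0.2, 0.75),
        "days_between": (60, 520),
    },
}


@dataclass(frozen=True)
class NoiseModel:
    """Ct-dependent replicate noise with detection censoring.

    Two error components, both growing above ``knee_ct``:

    * base error with SD
      ``sigma(ct) = min(sigma_low + sigma_slope * max(0, ct - knee_ct), sigma_max)``
      cycles, distributed as a variance-matched bounded uniform rather than
      a Gaussian -- melting-curve inspection removes gross outlier reactions
      from panel exports, so surviving base deviations are bounded;
    * threshold-cycle jumps: with probability
      ``jump_prob_max * clip((ct - knee_ct) / jump_ramp, 0, 1)`` a reaction's
      Ct slips by a near-discrete amount, uniform on ``[jump_lo, jump_hi]``
      cycles with random sign, reflecting Poisson sampling of the few
      template molecules present at high Ct.  Jumps, not the base error,
      carry the large replicate fold deviations; coincident opposite-sign
      jumps produce the rare >=4-fold excursions.

    A measured Ct above ``detect_ct`` is reported as undetected (censored to
    missing, never clipped).
    """

    sigma_low: float = 0.17
    sigma_slope: float = 2.0
    knee_ct: float = 28.0
    sigma_max: float = 0.175
    detect_ct: float = 35.0
    jump_prob_max: float = 0.32
    jump_ramp: float = 1.25
    jump_lo: float = 1.0
    jump_hi: float = 1.55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_low <= 0:
            raise ValueError("sigma_low must be > 0")
        if self.sigma_slope < 0:
            raise ValueError("sigma_slope must be >= 0")
        if not self.knee_ct < self.detect_ct:
            raise ValueError("knee_ct must be below detect_ct")
        if self.sigma_max < self.sigma_low:
            raise ValueError("sigma_max must be >= sigma_low")
        if not (0 <= self.jump_prob_max <= 1):
            raise ValueError("jump_prob_max must be in [0, 1]")
        if not (0 < self.jump_lo <= self.jump_hi):
            raise ValueError("need 0 < jump_lo <= jump_hi")
        if self.jump_ramp <= 0:
            raise ValueError("jump_ramp must be > 0")

    def sigma(self, ct) -> np.ndarray:
        ct = np.asarray(ct, dtype=float)
        return np.minimum(
            self.sigma_low + self.sigma_slope * np.maximum(0.0, ct - self.knee_ct),
            self.sigma_max,
        )

    def jump_prob(self, ct) -> np.ndarray:
        ct = np.asarray(ct, dtype=float)
        return self.jump_prob_max * np.clip(
            (ct - self.knee_ct) / self.jump_ramp, 0.0, 1.0
        )


@dataclass
class PanelDesign:
    """Per-assay ground truth of the synthetic panel.

    ``table`` columns:

    baseline_ct
        mean clean-serum Ct of the assay (cycles);
    detect_prob
        probability that a given subject expresses the assay above detection;
    blood_cell_flag / hemolysis_slope
        blood-cell-derived assays gain ``hemolysis_slope`` cycles of signal
        (Ct decrease) per doubling of hemoglobin above the 0.05 g/l clean
        baseline; the slope is 0 for all other assays;
    reference_flag / pair_stable_flag / spike_in_flag
        the designated cross-cohort reference pair, the within-pair stable
        normalizers, and the exogenous spike-in;
    subject_sd
        between-person biological SD of the expressed level (cycles);
    noise_scale / jump_scale
        per-assay multipliers on the noise model's sigma(ct) and jump
        probability; the designated controls are planted as robust
        amplifiers (jump_scale 0);
    role
        descriptive tier label (reference, pair_stable, spike_in, blood_fc,
        blood_lysed_only, serum_null, sporadic, absent).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if int(t["reference_flag"].sum()) != 2:
            raise ValueError("design must mark exactly 2 reference assays")
        if int(t["spike_in_flag"].sum()) != 1:
            raise ValueError("design must mark exactly 1 spike-in assay")
        if (t["hemolysis_slope"] < 0).any():
            raise ValueError("hemolysis_slope must be >= 0")
        if (t.loc[~t["blood_cell_flag"], "hemolysis_slope"] != 0).any():
            raise ValueError("hemolysis_slope must be 0 for non-blood assays")
        if t.index.has_duplicates:
            raise ValueError("assay ids must be unique")

    @property
    def assay_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_assays(self) -> int:
        return len(self.table)

    @property
    def reference_assays(self) -> list[str]:
        return self.table.index[self.table["reference_flag"]].tolist()

    @property
    def pair_stable_assays(self) -> list[str]:
        return self.table.index[self.table["pair_stable_flag"]].tolist()

    @property
    def spike_in_assay(self) -> str:
        return self.table.index[self.table["spike_in_flag"]][0]

    @property
    def blood_cell_assays(self) -> pd.Index:
        return self.table.index[self.table["blood_cell_flag"]]


def default_panel(
    n_assays: int = 742,
    n_blood_fc: int = 126,
    n_blood_lysed_only: int = 36,
    n_serum_null: int = 16,
    n_sporadic: int = 16,
    design_seed: int = 742,
) -> PanelDesign:
    """Build the default 742-assay serum panel design.

    The design is deterministic for a given ``design_seed``: the same panel
    is produced in every session.  By default 162 assays carry the
    blood-cell flag.
    """
    rng = np.random.default_rng(design_seed)
    rows: list[dict[str, Any]] = []

    def add(assay_id, role, baseline, detect_prob=1.0, slope=0.0, subject_sd=0.7,
            noise_scale=1.0, jump_scale=1.0, blood=False, ref=False, stable=False,
            spike=False):
        rows.append(
            {
                "assay_id": assay_id,
                "role": role,
                "baseline_ct": float(baseline),
                "detect_prob": float(detect_prob),
                "blood_cell_flag": bool(blood),
                "hemolysis_slope": float(slope),
                "reference_flag": bool(ref),
                "pair_stable_flag": bool(stable),
                "spike_in_flag": bool(spike),
                "subject_sd": float(subject_sd),
                "noise_scale": float(noise_scale),
                "jump_scale": float(jump_scale),
            }
        )

    add("miR-ref-A", "reference", 32.6, subject_sd=0.12, noise_scale=0.45,
        jump_scale=0.0, ref=True)
    add("miR-ref-B", "reference", 33.0, subject_sd=0.12, noise_scale=0.45,
        jump_scale=0.0, ref=True)
    add("miR-pairstable-A", "pair_stable", 25.9, subject_sd=1.4, noise_scale=0.15,
        jump_scale=0.0, stable=True)
    add("miR-pairstable-B", "pair_stable", 26.6, subject_sd=1.4, noise_scale=0.15,
        jump_scale=0.0, stable=True)
    add("cel-spike-39", "spike_in", 23.3, jump_scale=0.0, spike=True)

    n_fc_low = 18  # abundant blood-cell assays (miR-16/451a-like, low serum Ct)
    for i in range(n_blood_fc):
        if i < n_fc_low:
            base = rng.uniform(20.0, 27.5)
        else:
            base = rng.uniform(28.5, 32.4)
        add(
            f"miR-blood-{i:03d}",
            "blood_fc",
            base,
            slope=rng.uniform(3.0, 4.0),
            blood=True,
        )
    for i in range(n_blood_lysed_only):
        add(
            f"miR-bloodonly-{i:03d}",
            "blood_lysed_only",
            41.0,
            slope=rng.uniform(6.0, 7.5),
            blood=True,
        )
    n_null_low = 5
    for i in range(n_serum_null):
        base = rng.uniform(19.5, 27.5) if i < n_null_low else rng.uniform(28.5, 32.4)
        add(f"miR-serum-{i:03d}", "serum_null", base)
    for i in range(n_sporadic):
        add(
            f"miR-sporadic-{i:03d}",
            "sporadic",
            rng.uniform(29.0, 32.4),
            detect_prob=rng.uniform(0.3, 0.85),
        )
    n_absent = n_assays - len(rows)
    if n_absent < 0:
        raise ValueError("tier counts exceed n_assays")
    for i in range(n_absent):
        add(f"miR-absent-{i:03d}", "absent", 42.0, detect_prob=0.0)

    table = pd.DataFrame(rows).set_index("assay_id")
    return PanelDesign(table)


@dataclass
class CohortSpec:
    """Recipe for one simulated cohort.

    ``scenario_params`` may override the per-scenario defaults
    (see ``SCENARIO_DEFAULTS``); unknown keys are rejected.
    """

    design: PanelDesign
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_subjects: int = 10
    scenario: str = "hemolysis_pairs"
    scenario_params: dict[str, Any] = field(default_factory=dict)
    plate_offset_sd: float = 0.15

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        defaults = SCENARIO_DEFAULTS[self.scenario]
        unknown = set(self.scenario_params) - set(defaults)
        if unknown:
            raise ValueError(
                f"unknown scenario_params for {self.scenario}: {sorted(unknown)}"
            )
        merged = dict(defaults)
        merged.update(self.scenario_params)
        self.scenario_params = merged

    @classmethod
    def from_dict(cls, cfg: Mapping[str, Any], design: PanelDesign | None = None) -> "CohortSpec":
        """Build a spec from a plain (YAML/JSON-loadable) mapping."""
        design = design if design is not None else default_panel(**cfg.get("panel", {}))
        noise = NoiseModel(**cfg.get("noise", {}))
        return cls(
            design=design,
            noise=noise,
            n_subjects=int(cfg.get("n_subjects", 10)),
            scenario=cfg.get("scenario", "hemolysis_pairs"),
            scenario_params=dict(cfg.get("scenario_params", {})),
            plate_offset_sd=float(cfg.get("plate_offset_sd", 0.15)),
        )
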