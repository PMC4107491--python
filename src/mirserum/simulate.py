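"""Cohort simulation with the measurement structure the pipeline assumes.

Every scenario draws, per subject, a binary expression state and a
biological level per assay, then measures each sample with Ct-dependent
replicate noise and detection censoring.  Hemolysed samples shift
blood-cell-derived assays down in Ct by ``hemolysis_slope`` cycles per
doubling of hemoglobin above the 0.05 g/l clean baseline.  The generator
emits the same CSV-ready containers the readers produce, so every
downstream stage is testable without external data.

Scenarios
---------
technical_repeat
    two independent extractions/quantifications of the same serum per
    subject (no biological difference, measurement noise only);
hemolysis_pairs
    matched unlysed/lysed vials from one draw per subject;
fasting_pairs
    matched non-fasting/fasting samples with serum triglyceride values;
smoker_cohort
    matched smoker/non-smoker samples with no planted group effect;
longitudinal_pairs
    two samples per subject months apart, with a per-subject within-person
    drift SD drawn from a configured range.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
import numpy as np
import pandas as pd

from .hemolysis import CLEAN_HB, HEMOLYSIS_THRESHOLD
from .io import CtMatrix, SampleSheet
from .panel import CT_TRUE_FLOOR, CohortSpec, PanelDesign

__all__ = [
    "Cohort",
    "generate_cohort",
    "hemoglobin_to_absorbances",
    "construct_correlated_profiles",
]

#: spike-in raw Ct distribution (cycles): fixed input amount, so independent
#: of hemoglobin and of every biological covariate
SPIKE_CT_MEAN = 23.3
SPIKE_CT_SD = 0.6

#: inter-plate calibrator true Ct and well-to-well noise
IPC_CT = 20.0
IPC_WELL_SD = 0.02


@dataclass
class Cohort:
    """A simulated cohort: Ct matrix, sample sheet, calibrators and truth."""

    ct: CtMatrix
    samples: SampleSheet
    ipc: pd.DataFrame  # columns plate, well, ct
    design: PanelDesign
    true_ct: pd.DataFrame
    expressed: pd.DataFrame  # assay x subject

    def __iter__(self):
        # allow ``ct, samples = generate_cohort(spec)`` unpacking
        return iter((self.ct, self.samples))


def hemoglobin_to_absorbances(
    hb,
    rng: np.random.Generator | int | None = None,
    background: tuple[float, float] = (0.02, 0.12),
):
    """Absorbance triplet (A380, A415, A450) consistent with a hemoglobin level.

    Background absorbances at 380 and 450 nm are drawn uniformly from
    ``background``; A415 is solved so the Harboe formula returns ``hb``
    exactly.  With ``background=(0, 0)`` and ``hb=0`` the triplet is all
    zeros.
    """
    hb_arr = np.asarray(hb, dtype=float)
    if (hb_arr < 0).any():
        raise ValueError("hemoglobin must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    a380 = rng.uniform(*background, size=hb_arr.shape)
    a450 = rng.uniform(*background, size=hb_arr.shape)
    a415 = (1000.0 * hb_arr + 83.6 * (a380 + a450)) / 167.2
    if hb_arr.ndim == 0:
        return float(a380), float(a415), float(a450)
    return a380, a415, a450


def _hemolysis_shift(slope: np.ndarray, hb: float) -> np.ndarray:
    """Ct decrease of blood-cell assays at hemoglobin ``hb`` (cycles).

    The shift is log2-linear in hemoglobin above the 0.05 g/l clean baseline
    and applies to hemolysed samples only: below the 0.1 g/l hemolysis
    threshold the red-cell contribution is negligible against the serum
    background.
    """
    if hb < HEMOLYSIS_THRESHOLD:
        return np.zeros_like(slope)
    return slope * np.log2(hb / CLEAN_HB)


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Simulate one cohort under ``spec``.

    ``seed`` overrides ``spec.noise.seed``.  Identical spec + seed give
    bit-identical output.
    """
    rng = np.random.default_rng(spec.noise.seed if seed is None else seed)
    design = spec.design
    t = design.table
    n_assay = design.n_assays
    n_subj = spec.n_subjects
    p = spec.scenario_params

    baseline = t["baseline_ct"].to_numpy()
    detect_prob = t["detect_prob"].to_numpy()
    subject_sd = t["subject_sd"].to_numpy()
    noise_scale = t["noise_scale"].to_numpy()
    slope = t["hemolysis_slope"].to_numpy()
    spike_idx = int(np.flatnonzero(t["spike_in_flag"].to_numpy())[0])

    n_groups = 2 if spec.scenario == "smoker_cohort" else 1
    n_people = n_subj * n_groups

    expressed = rng.random((n_assay, n_people)) < detect_prob[:, None]
    subj_level = baseline[:, None] + rng.normal(size=(n_assay, n_people)) * subject_sd[:, None]

    # --- scenario layout -------------------------------------------------
    meta_rows: list[dict] = []
    col_subject: list[int] = []
    col_shift: list[np.ndarray] = []  # per-sample Ct decrease vector (n_assay,)

    def sample(sample_id, subject_ix, subject_label, group, pair_key, hb,
               tg=np.nan, when=None, extra_shift=None):
        shift = _hemolysis_shift(slope, hb)
        if extra_shift is not None:
            shift = shift + extra_shift
        col_subject.append(subject_ix)
        col_shift.append(shift)
        meta_rows.append(
            {
                "sample_id": sample_id,
                "subject_id": subject_label,
                "group": group,
                "pair_key": pair_key,
                "hemoglobin": hb,
                "triglyceride": tg,
                "collection_date": None if when is None else when.isoformat(),
            }
        )

    if spec.scenario == "technical_repeat":
        hb = rng.uniform(*p["hb_clean"], size=n_subj)
        for s in range(n_subj):
            for r in (1, 2):
                sample(f"S{s + 1:04d}R{r}", s, f"subj{s + 1:04d}",
                       f"replicate_{r}", f"K{s + 1:04d}", hb[s])

    elif spec.scenario == "hemolysis_pairs":
        hb_u = rng.uniform(*p["hb_clean"], size=n_subj)
        lo, hi = p["hb_lysed"]
        hb_l = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_subj))
        for s in range(n_subj):
            sample(f"S{s + 1:03d}U", s, f"subj{s + 1:03d}", "unlysed",
                   f"K{s + 1:03d}", hb_u[s])
            sample(f"S{s + 1:03d}L", s, f"subj{s + 1:03d}", "lysed",
                   f"K{s + 1:03d}", hb_l[s])

    elif spec.scenario == "fasting_pairs":
        hb = rng.uniform(*p["hb_clean"], size=(n_subj, 2))
        tg_nf = rng.uniform(*p["tg_nonfasting"], size=n_subj)
        tg_f = tg_nf * rng.uniform(*p["tg_fasting_ratio"], size=n_subj)
        n_corr = int(p["n_tg_correlated"])
        corr_ix = np.flatnonzero((t["role"] == "serum_null").to_numpy())[:n_corr]
        per_mgdl = float(p["tg_ct_per_mgdl"])

        def tg_shift(tg):
            out = np.zeros(n_assay)
            out[corr_ix] = per_mgdl * (tg - 120.0)
            return out

        for s in range(n_subj):
            sample(f"S{s + 1:03d}NF", s, f"subj{s + 1:03d}", "non_fasting",
                   f"K{s + 1:03d}", hb[s, 0], tg=tg_nf[s],
                   extra_shift=tg_shift(tg_nf[s]))
            sample(f"S{s + 1:03d}F", s, f"subj{s + 1:03d}", "fasting",
                   f"K{s + 1:03d}", hb[s, 1], tg=tg_f[s],
                   extra_shift=tg_shift(tg_f[s]))

    elif spec.scenario == "smoker_cohort":
        hb = rng.uniform(*p["hb_clean"], size=2 * n_subj)
        for s in range(n_subj):
            sample(f"SM{s + 1:03d}", s, f"smoker{s + 1:03d}", "smoker",
                   f"K{s + 1:03d}", hb[2 * s])
            sample(f"NS{s + 1:03d}", n_subj + s, f"nonsmoker{s + 1:03d}",
                   "non_smoker", f"K{s + 1:03d}", hb[2 * s + 1])

    elif spec.scenario == "longitudinal_pairs":
        hb = rng.uniform(*p["hb_clean"], size=(n_subj, 2))
        tau = rng.uniform(*p["drift_sd_range"], size=n_subj)
        # within-person drift is biological, so assays with low person-to-
        # person variability (the designated controls) also drift less
        lability = (subject_sd / 0.7)[:, None]
        drift = rng.normal(size=(n_assay, n_subj)) * tau[None, :] * lability
        days = rng.integers(int(p["days_between"][0]), int(p["days_between"][1]) + 1,
                            size=n_subj)
        for s in range(n_subj):
            t0 = date(2012, 1, 10) + timedelta(days=14 * s)
            sample(f"S{s + 1:03d}T1", s, f"subj{s + 1:03d}", "timepoint_1",
                   f"K{s + 1:03d}", hb[s, 0], when=t0)
            sample(f"S{s + 1:03d}T2", s, f"subj{s + 1:03d}", "timepoint_2",
                   f"K{s + 1:03d}", hb[s, 1], when=t0 + timedelta(days=int(days[s])),
                   extra_shift=-drift[:, s])

    n_samples = len(meta_rows)
    sample_ids = [m["sample_id"] for m in meta_rows]

    # --- measurement -----------------------------------------------------
    true_ct = subj_level[:, col_subject] - np.column_stack(col_shift)
    true_ct = np.maximum(true_ct, CT_TRUE_FLOOR)
    noise = spec.noise
    sigma = noise.sigma(true_ct) * noise_scale[:, None]
    # base replicate error is bounded (variance-matched uniform): melting-
    # curve inspection removes gross outlier reactions from panel exports
    half_width = np.sqrt(3.0)
    measured = true_ct + rng.uniform(-half_width, half_width, size=true_ct.shape) * sigma
    # at low template, Poisson sampling of the few template molecules shifts
    # the threshold-crossing cycle by a near-discrete amount in either
    # direction; these jumps, not the base error, carry the large fold
    # deviations seen between technical replicates of a serum panel
    jump_scale = t["jump_scale"].to_numpy() if "jump_scale" in t.columns else np.ones(n_assay)
    jumps = rng.random(size=true_ct.shape) < noise.jump_prob(true_ct) * jump_scale[:, None]
    jump_mag = rng.uniform(noise.jump_lo, noise.jump_hi, size=true_ct.shape)
    jump_sign = np.where(rng.random(size=true_ct.shape) < 0.5, -1.0, 1.0)
    measured = measured + jumps * jump_sign * jump_mag
    measured[spike_idx, :] = SPIKE_CT_MEAN + SPIKE_CT_SD * rng.normal(size=n_samples)

    plate_offsets = rng.normal(0.0, spec.plate_offset_sd or 1e-12, size=n_samples)
    measured = measured + plate_offsets[None, :]

    detected = expressed[:, col_subject] & (measured <= spec.noise.detect_ct)
    detected[spike_idx, :] = True
    values = np.where(detected, measured, np.nan)
    values = np.clip(values, CT_TRUE_FLOOR / 2, 40.0)

    plates = pd.Series([f"PL-{sid}" for sid in sample_ids], index=sample_ids)
    ct = CtMatrix(
        pd.DataFrame(values, index=design.assay_ids, columns=sample_ids),
        plate_of=plates,
    )

    ipc_noise = rng.normal(size=(n_samples, 3)) * IPC_WELL_SD
    ipc = pd.DataFrame(
        {
            "plate": np.repeat(plates.to_numpy(), 3),
            "well": np.tile([1, 2, 3], n_samples),
            "ct": (IPC_CT + plate_offsets[:, None] + ipc_noise).ravel(),
        }
    )

    meta = pd.DataFrame(meta_rows)
    a380, a415, a450 = hemoglobin_to_absorbances(meta["hemoglobin"].to_numpy(), rng)
    meta["a380"], meta["a415"], meta["a450"] = a380, a415, a450
    sheet = SampleSheet(meta)

    subjects = sorted(set(m["subject_id"] for m in meta_rows))
    subj_cols = {m["subject_id"]: c for m, c in zip(meta_rows, col_subject)}
    expressed_df = pd.DataFrame(
        expressed[:, [subj_cols[s] for s in subjects]],
        index=design.assay_ids,
        columns=subjects,
    )
    return Cohort(
        ct=ct,
        samples=sheet,
        ipc=ipc,
        design=design,
        true_ct=pd.DataFrame(true_ct, index=design.assay_ids, columns=sample_ids),
        expressed=expressed_df,
    )


# ---------------------------------------------------------------------------
# exact-correlation profile construction
# ---------------------------------------------------------------------------

def construct_correlated_profiles(
    covariate: pd.Series,
    target_r: pd.Series,
    n_null: int = 0,
    seed: int | None = None,
    level: float = -4.0,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Build assay profiles whose sample Pearson correlations with
    ``covariate`` equal ``target_r`` exactly.

    Each target profile is ``r * x_std + sqrt(1 - r^2) * e_std`` where
    ``x_std`` is the standardized covariate and ``e_std`` a standardized
    random vector orthogonalized against it, so the realized sample
    correlation equals ``r`` to machine precision.  ``n_null`` additional
    assays are built from pure orthogonal residuals (correlation exactly 0).
    Profiles are shifted/scaled to a deltaCt-like range; correlation is
    unaffected.
    """
    x = covariate.to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    xs = (x - x.mean()) / x.std()

    def orthonormal_residual() -> np.ndarray:
        for _ in range(100):
            z = rng.normal(size=n)
            z = z - z.mean() - (z @ xs) / (xs @ xs) * xs
            sd = z.std()
            if sd > 1e-12:
                return z / sd
        raise RuntimeError("could not draw a non-degenerate residual")

    rows, names = [], []
    for name, r in target_r.items():
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"target correlation {r} outside [-1, 1]")
        e = orthonormal_residual()
        y = r * xs + np.sqrt(1.0 - r * r) * e
        rows.append(level + scale * y)
        names.append(name)
    for i in range(n_null):
        rows.append(level + scale * orthonormal_residual())
        names.append(f"null-{i:04d}")
    return pd.DataFrame(rows, index=names, columns=covariate.index)
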