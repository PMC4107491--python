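"""Bundled worked-example measurements used in the documentation and tests.

These small tables are printed measurements from a matched-design serum
miRNA QC study: hemoglobin concentrations of ten matched unlysed/lysed serum
pairs, exogenous spike-in (cel-miR-39-3p) raw Ct values from seven of those
pairs, serum triglyceride concentrations of seven non-fasting/fasting pairs,
per-assay Pearson correlations of six triglyceride-associated miRNAs, and
within-person profile correlations of twelve sample pairs collected months
apart.  They serve as fixed inputs for the worked examples: the analysis
routines must reproduce the behaviour observed on them (classification,
test outcomes), not the tables themselves.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "hemoglobin_pairs",
    "spike_in_cts",
    "triglyceride_pairs",
    "triglyceride_correlations",
    "longitudinal_correlations",
]


def hemoglobin_pairs() -> pd.DataFrame:
    """Hemoglobin (g/l) of ten matched unlysed/lysed serum samples."""
    data = [
        ("11", 0.051, 0.552),
        ("12", 0.048, 1.217),
        ("14", 0.055, 0.620),
        ("15", 0.056, 0.220),
        ("16", 0.042, 0.154),
        ("17", 0.074, 1.091),
        ("18", 0.069, 1.048),
        ("19", 0.075, 2.428),
        ("20", 0.037, 1.235),
        ("21", 0.070, 2.249),
    ]
    return pd.DataFrame(data, columns=["subject", "unlysed", "lysed"]).set_index(
        "subject"
    )


def spike_in_cts() -> pd.DataFrame:
    """Raw spike-in Ct of seven matched unlysed/lysed samples."""
    data = [
        ("15", 22.70, 22.20),
        ("16", 22.33, 22.66),
        ("17", 23.79, 24.32),
        ("18", 24.01, 23.46),
        ("19", 23.71, 22.70),
        ("20", 22.88, 22.89),
        ("21", 23.75, 24.04),
    ]
    return pd.DataFrame(data, columns=["subject", "unlysed", "lysed"]).set_index(
        "subject"
    )


def triglyceride_pairs() -> pd.DataFrame:
    """Serum triglyceride (mg/dl) of seven matched non-fasting/fasting samples."""
    data = [
        ("1", 202.8, 120.6),
        ("2", 152.1, 96.2),
        ("3", 148.5, 52.1),
        ("4", 93.3, 30.4),
        ("5", 176.4, 102.4),
        ("6", 72.4, 57.8),
        ("7", 53.5, 45.7),
    ]
    return pd.DataFrame(
        data, columns=["subject", "non_fasting", "fasting"]
    ).set_index("subject")


def triglyceride_correlations() -> pd.Series:
    """Pearson R of the six triglyceride-associated assays (n = 14 samples)."""
    return pd.Series(
        {
            "hsa-miR-17-3p": 0.88,
            "hsa-miR-375": 0.70,
            "hsa-miR-328-3p": -0.64,
            "hsa-miR-223-3p": -0.57,
            "hsa-miR-593-3p": 0.57,
            "hsa-miR-130b-5p": 0.55,
        },
        name="r",
    )


def longitudinal_correlations() -> pd.Series:
    """Within-person profile Pearson R of twelve matched sample pairs."""
    return pd.Series(
        [0.88, 0.99, 0.99, 0.99, 0.98, 0.99, 0.99, 0.99, 0.95, 0.99, 0.99, 0.87],
        index=[str(i) for i in range(1, 13)],
        name="r",
    )
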