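"""Reading, writing and validation of Ct matrices, sample sheets and QC flag tables.

The canonical on-disk dialect is UTF-8 CSV with a ``.`` decimal separator.
In a Ct matrix the header row holds sample ids, the first column holds assay
ids, and an empty cell means the reaction was undetected.  Instrument exports
that encode "undetected" as a sentinel Ct (conventionally 40) are accepted on
read via the ``sentinel`` argument and normalised to missing values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "AssayQcFlags",
    "SampleSheet",
    "read_ct_matrix",
    "write_ct_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_assay_flags",
    "write_report",
    "SchemaError",
]

CT_MIN = 0.0
CT_MAX = 40.0

#: mandatory sample-sheet columns
_SHEET_REQUIRED = ("sample_id", "subject_id", "group")
_SHEET_OPTIONAL = (
    "pair_key",
    "a380",
    "a415",
    "a450",
    "hemoglobin",
    "triglyceride",
    "collection_date",
)


class SchemaError(ValueError):
    """Raised when an input table violates the expected schema."""


def _check_unique(labels: Iterable[str], what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate {what}: {dups}")


@dataclass
class CtMatrix:
    """Ct values (cycles) for a panel, assays as rows and samples as columns.

    Missing entries (NaN) mean the reaction did not amplify above threshold
    ("undetected"); they are treated as absence throughout the pipeline and
    never as a numeric Ct.
    """

    values: pd.DataFrame
    plate_of: pd.Series | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = "assay_id"
        self.values.columns.name = None
        _check_unique(self.values.index, "assay ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        bad = (~np.isnan(arr)) & ((arr <= CT_MIN) | (arr > CT_MAX))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SchemaError(
                f"Ct value {arr[i, j]} for assay {self.values.index[i]!r} / "
                f"sample {self.values.columns[j]!r} outside ({CT_MIN}, {CT_MAX}]"
            )
        if self.plate_of is not None:
            self.plate_of = pd.Series(self.plate_of)
            missing = self.values.columns.difference(self.plate_of.index)
            if len(missing):
                raise SchemaError(f"samples without a plate assignment: {list(missing)}")

    # -- convenience -------------------------------------------------------
    @property
    def assay_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def detected(self, ceiling: float | None = None) -> pd.DataFrame:
        """Boolean mask of detected reactions, optionally below a Ct ceiling."""
        mask = self.values.notna()
        if ceiling is not None:
            mask &= self.values <= ceiling
        return mask

    def copy(self) -> "CtMatrix":
        return CtMatrix(
            self.values.copy(),
            None if self.plate_of is None else self.plate_of.copy(),
        )


@dataclass
class AssayQcFlags:
    """Per-assay QC flags consumed (not computed) by the reaction filter.

    ``n_tm_peaks`` is the number of distinct melting-curve peaks observed for
    the assay; ``negative_control_ct`` is the Ct of the matched no-template
    control, NaN when the control did not amplify.
    """

    table: pd.DataFrame  # index: assay_id; columns: n_tm_peaks, negative_control_ct

    def __post_init__(self) -> None:
        need = {"n_tm_peaks", "negative_control_ct"}
        if not need.issubset(self.table.columns):
            raise SchemaError(f"assay flag table needs columns {sorted(need)}")
        _check_unique(self.table.index, "assay ids")
        if (self.table["n_tm_peaks"] < 0).any():
            raise SchemaError("n_tm_peaks must be >= 0")


@dataclass
class SampleSheet:
    """Per-sample metadata: subject, group, pairing key, absorbances, covariates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in _SHEET_REQUIRED:
            if col not in self.table.columns:
                raise SchemaError(f"sample sheet lacks mandatory column {col!r}")
        _check_unique(self.table["sample_id"], "sample ids")
        for col in _SHEET_OPTIONAL:
            if col not in self.table.columns:
                self.table[col] = np.nan
        if self.table["pair_key"].notna().any():
            counts = self.table["pair_key"].dropna().value_counts()
            bad = counts[counts > 2]
            if len(bad):
                raise SchemaError(
                    f"pair_key values occurring more than twice: {bad.index.tolist()}"
                )
        self.table = self.table.set_index(
            pd.Index(self.table["sample_id"], name="sample_id"), drop=False
        )

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def pairs(self) -> list[tuple[str, str]]:
        """Matched sample pairs as (first, second) sample-id tuples.

        Within each pair the sheet's row order is preserved, so for the
        hemolysis design the unlysed sample comes first when the sheet lists
        it first.
        """
        out: list[tuple[str, str]] = []
        keyed = self.table.dropna(subset=["pair_key"])
        for _, grp in keyed.groupby("pair_key", sort=True):
            if len(grp) == 2:
                out.append((grp["sample_id"].iloc[0], grp["sample_id"].iloc[1]))
        return out

    def group_samples(self, group: str) -> list[str]:
        return self.table.loc[self.table["group"] == group, "sample_id"].tolist()

    def hemoglobin(self) -> pd.Series:
        """Per-sample hemoglobin (g/l), computed from absorbances when absent."""
        from .hemolysis import harboe_hemoglobin

        hb = self.table["hemoglobin"].astype(float).copy()
        need = hb.isna() & self.table["a415"].notna()
        if need.any():
            sub = self.table.loc[need]
            hb[need] = harboe_hemoglobin(
                sub["a380"].to_numpy(float),
                sub["a415"].to_numpy(float),
                sub["a450"].to_numpy(float),
            )
        return hb


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_ct_matrix(
    path: str | Path,
    sentinel: float | None = 40.0,
    plates: Mapping[str, str] | str | Path | None = None,
) -> CtMatrix:
    """Read a wide-format Ct matrix CSV.

    Empty cells and ``sentinel`` values (instrument "undetected" code,
    default 40) become missing.  ``plates`` may be a mapping sample -> plate
    or a path to a two-column CSV ``sample_id,plate``.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:  # pragma: no cover - message passthrough
        raise SchemaError(f"non-numeric Ct entry in {path}: {exc}") from exc
    if sentinel is not None:
        df = df.mask(df == sentinel)
    plate_of = None
    if plates is not None:
        if isinstance(plates, (str, Path)):
            pl = pd.read_csv(plates)
            plate_of = pd.Series(
                pl["plate"].astype(str).to_numpy(), index=pl["sample_id"].astype(str)
            )
        else:
            plate_of = pd.Series(dict(plates))
    return CtMatrix(df, plate_of)


def write_ct_matrix(ct: CtMatrix, path: str | Path) -> None:
    ct.values.to_csv(path, index_label="assay_id", float_format="%.6g")
    if ct.plate_of is not None:
        side = Path(path).with_suffix(".plates.csv")
        ct.plate_of.rename("plate").rename_axis("sample_id").to_csv(side)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str})
    if "pair_key" in df.columns:
        df["pair_key"] = df["pair_key"].astype("string")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False, float_format="%.6g")


def read_assay_flags(path: str | Path) -> AssayQcFlags:
    df = pd.read_csv(path, index_col="assay_id")
    df.index = df.index.astype(str)
    return AssayQcFlags(df)


def write_report(results: Mapping[str, object], outdir: str | Path) -> list[Path]:
    """Write a deterministic report bundle.

    ``results`` maps a name to either a DataFrame (written as ``<name>.csv``)
    or a string (appended to ``report.txt``).  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    text_parts: list[str] = []
    for name in sorted(results):
        obj = results[name]
        if isinstance(obj, pd.DataFrame):
            p = outdir / f"{name}.csv"
            obj.to_csv(p, float_format="%.6g")
            written.append(p)
        elif isinstance(obj, pd.Series):
            p = outdir / f"{name}.csv"
            obj.to_csv(p, float_format="%.6g")
            written.append(p)
        else:
            text_parts.append(f"== {name} ==\n{obj}\n")
    if text_parts:
        p = outdir / "report.txt"
        p.write_text("\n".join(text_parts))
        written.append(p)
    return written
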