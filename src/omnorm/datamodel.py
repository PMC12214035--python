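"""Data model and I/O for wide omics feature tables.

An :class:`OmicsMatrix` is a dense features x samples intensity matrix (rows =
features, columns = samples; this orientation is fixed everywhere in the
package). Missing values are represented as NaN; on the raw-intensity scale all
observed values must be non-negative. A :class:`SampleSheet` carries per-sample
metadata (role, treatment, time, injection order, batch) and a
:class:`Dataset` pairs the two with matching sample order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("omnorm")

ROLE_BIOLOGICAL = "biological"
ROLE_QC = "pooled_qc"

SHEET_COLUMNS = ["sample_id", "role", "treatment", "time_minutes",
                 "injection_order", "batch"]


class ValidationError(ValueError):
    """Raised when a matrix, sheet or their pairing violates an invariant."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class OmicsMatrix:
    """Features x samples intensity matrix.

    Parameters
    ----------
    feature_ids : unique row labels.
    sample_ids : unique column labels.
    values : 2-D float array, shape (n_features, n_samples); NaN = missing.
    raw_scale : True while values are raw intensities (non-negativity is
        enforced); transformed matrices (log, glog) set this False.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    raw_scale: bool = True

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n_feat, n_samp = self.values.shape
        if len(self.feature_ids) != n_feat or len(self.sample_ids) != n_samp:
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} feature ids x "
                f"{len(self.sample_ids)} sample ids")
        if n_feat < 2 or n_samp < 2:
            raise ValidationError("need at least 2 features and 2 samples")
        dup_f = _duplicates(self.feature_ids)
        if dup_f:
            raise ValidationError(f"duplicate feature ids: {sorted(dup_f)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise ValidationError(f"duplicate sample ids: {sorted(dup_s)}")
        if self.raw_scale and np.nanmin(self.values, initial=0.0) < 0:
            raise ValidationError("negative intensities on the raw scale")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)

    def copy_with(self, values: np.ndarray, raw_scale: bool | None = None) -> "OmicsMatrix":
        """New matrix with the same ids and different values."""
        return OmicsMatrix(list(self.feature_ids), list(self.sample_ids),
                           np.asarray(values, dtype=float),
                           self.raw_scale if raw_scale is None else raw_scale)


@dataclass
class SampleSheet:
    """Per-sample metadata table.

    ``frame`` is indexed by sample_id with columns role, treatment,
    time_minutes, injection_order, batch. Pooled-QC rows may leave treatment
    and time empty; injection_order must be unique within each batch.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        missing_cols = [c for c in SHEET_COLUMNS[1:] if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"sample sheet missing columns: {missing_cols}")
        dup = _duplicates(list(df.index))
        if dup:
            raise ValidationError(f"duplicate sample ids in sheet: {sorted(dup)}")
        bad_roles = set(df["role"]) - {ROLE_BIOLOGICAL, ROLE_QC}
        if bad_roles:
            raise ValidationError(f"unknown sample roles: {sorted(bad_roles)}")
        df["time_minutes"] = pd.to_numeric(df["time_minutes"], errors="coerce")
        df["injection_order"] = pd.to_numeric(df["injection_order"],
                                              errors="raise").astype(int)
        if (df["injection_order"] <= 0).any():
            raise ValidationError("injection_order must be positive")
        bio = df[df["role"] == ROLE_BIOLOGICAL]
        if (bio["time_minutes"] < 0).any():
            raise ValidationError("negative time_minutes")
        for batch, grp in df.groupby("batch"):
            if grp["injection_order"].duplicated().any():
                raise ValidationError(
                    f"duplicate injection_order within batch {batch!r}")
        df["batch"] = df["batch"].astype(str)
        df["treatment"] = df["treatment"].astype(object)
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def roles(self) -> pd.Series:
        return self.frame["role"]

    def qc_mask(self) -> np.ndarray:
        return (self.frame["role"] == ROLE_QC).to_numpy()

    def biological_mask(self) -> np.ndarray:
        return (self.frame["role"] == ROLE_BIOLOGICAL).to_numpy()

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        return SampleSheet(self.frame.loc[list(sample_ids)].copy())


@dataclass
class Dataset:
    """A matched (matrix, sheet) pair; column order follows the sheet."""

    matrix: OmicsMatrix
    sheet: SampleSheet
    layer: str = ""

    def __post_init__(self) -> None:
        mat_ids = self.matrix.sample_ids
        sheet_ids = self.sheet.sample_ids
        if set(mat_ids) != set(sheet_ids):
            only_mat = sorted(set(mat_ids) - set(sheet_ids))
            only_sheet = sorted(set(sheet_ids) - set(mat_ids))
            raise ValidationError(
                "sample sets differ between table and sheet: "
                f"only in table {only_mat}, only in sheet {only_sheet}")
        if mat_ids != sheet_ids:
            # canonicalize column order to sheet row order
            order = [mat_ids.index(s) for s in sheet_ids]
            self.matrix = OmicsMatrix(self.matrix.feature_ids, sheet_ids,
                                      self.matrix.values[:, order],
                                      self.matrix.raw_scale)

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def values(self) -> np.ndarray:
        return self.matrix.values

    def with_values(self, values: np.ndarray, raw_scale: bool | None = None) -> "Dataset":
        return Dataset(self.matrix.copy_with(values, raw_scale), self.sheet,
                       self.layer)

    def qc_columns(self) -> np.ndarray:
        return np.flatnonzero(self.sheet.qc_mask())

    def biological_columns(self) -> np.ndarray:
        return np.flatnonzero(self.sheet.biological_mask())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _duplicates(items: Sequence) -> set:
    seen: set = set()
    dups: set = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


def _sep(dialect: str) -> str:
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be csv or tsv, got {dialect!r}")
    return "," if dialect == "csv" else "\t"


def read_dataset(table_path: str | Path, sheet_path: str | Path,
                 dialect: Literal["csv", "tsv"] = "csv",
                 layer: str = "") -> Dataset:
    """Read a wide feature table plus sample sheet into a validated Dataset.

    The table's first column holds feature ids, remaining columns are samples.
    Empty cells and "NA" become missing (NaN); zeros are kept as zeros.
    Negative or unparseable intensities raise :class:`ValidationError`.
    """
    sep = _sep(dialect)
    table = pd.read_csv(table_path, sep=sep, index_col=0,
                        na_values=["NA"], keep_default_na=False,
                        skip_blank_lines=True)
    try:
        values = table.apply(pd.to_numeric, errors="raise").to_numpy(float)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"unparseable cell in {table_path}: {exc}") from exc
    sheet_df = pd.read_csv(sheet_path, sep=sep, na_values=["NA", ""],
                           keep_default_na=False)
    if "sample_id" not in sheet_df.columns:
        raise ValidationError("sample sheet must have a sample_id column")
    sheet = SampleSheet(sheet_df)
    matrix = OmicsMatrix(list(table.index), [str(c) for c in table.columns],
                         values)
    return Dataset(matrix, sheet, layer=layer)


def write_dataset(ds: Dataset, table_path: str | Path,
                  sheet_path: str | Path,
                  dialect: Literal["csv", "tsv"] = "csv") -> None:
    """Write a Dataset as a wide table + sheet readable by read_dataset.

    Missing values are written as empty cells. Values are written with
    repr-level precision so a round trip preserves them.
    """
    sep = _sep(dialect)
    for p in (table_path, sheet_path):
        parent = Path(p).parent
        if not parent.is_dir():
            raise FileNotFoundError(f"directory does not exist: {parent}")
    frame = ds.matrix.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(table_path, sep=sep, na_rep="", float_format="%.17g")
    sheet_out = ds.sheet.frame.reset_index(names="sample_id")
    sheet_out.to_csv(sheet_path, sep=sep, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Missing values and transforms
# ---------------------------------------------------------------------------

def impute_missing(ds: Dataset,
                   strategy: Literal["half_min_feature", "min_global", "none"]
                   = "half_min_feature") -> Dataset:
    """Replace missing intensities.

    half_min_feature: half of the feature's minimum observed value (an MNAR
    convention — values are missing mostly because they fell below detection).
    min_global: smallest observed value in the whole matrix.
    Features with no observed value at all are dropped with a warning.
    Observed values are never altered.
    """
    if strategy == "none":
        return ds
    X = ds.values().copy()
    if np.all(np.isnan(X)):
        raise ValidationError("matrix is entirely missing; cannot impute")
    all_missing = np.all(np.isnan(X), axis=1)
    feature_ids = list(ds.matrix.feature_ids)
    if all_missing.any():
        dropped = [f for f, m in zip(feature_ids, all_missing) if m]
        logger.warning("impute_missing: dropping %d all-missing features: %s",
                       len(dropped), dropped[:5])
        X = X[~all_missing]
        feature_ids = [f for f, m in zip(feature_ids, all_missing) if not m]
    if strategy == "half_min_feature":
        with np.errstate(all="ignore"):
            fill = 0.5 * np.nanmin(X, axis=1)
        fill = np.where(fill <= 0, np.nanmin(X[X > 0]) * 0.5 if (X > 0).any()
                        else 1.0, fill)
        X = np.where(np.isnan(X), fill[:, None], X)
    elif strategy == "min_global":
        gmin = np.nanmin(X)
        if gmin <= 0:
            gmin = np.nanmin(X[X > 0]) if (X > 0).any() else 1.0
        X = np.where(np.isnan(X), gmin, X)
    else:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    matrix = OmicsMatrix(feature_ids, list(ds.matrix.sample_ids), X,
                         ds.matrix.raw_scale)
    return Dataset(matrix, ds.sheet, ds.layer)


def log_transform(ds: Dataset, base: float = 10.0,
                  pseudocount: float = 1.0) -> Dataset:
    """Element-wise log_base(x + pseudocount); invertible given parameters."""
    if base <= 1:
        raise ValueError(f"log base must be > 1, got {base}")
    X = ds.values()
    if np.nanmin(X) < 0:
        raise ValidationError("log transform requires non-negative values")
    if np.nanmin(X + pseudocount) <= 0:
        raise ValueError("pseudocount too small: x + pseudocount must be > 0")
    out = np.log(X + pseudocount) / np.log(base)
    return ds.with_values(out, raw_scale=False)


def inverse_log_transform(ds: Dataset, base: float = 10.0,
                          pseudocount: float = 1.0) -> Dataset:
    """Inverse of :func:`log_transform`."""
    if base <= 1:
        raise ValueError(f"log base must be > 1, got {base}")
    out = np.power(base, ds.values()) - pseudocount
    return ds.with_values(out, raw_scale=True)
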