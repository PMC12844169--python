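"""Reading, validating, filtering and writing feature tables and sample metadata.

A *feature table* is a samples × feature-ions intensity matrix as extracted
from per-cell regions of interest of a ToF-SIMS acquisition: each row is one
single-cell (or QC) sample, each column one feature ion identified by its
mass-to-charge ratio.  This module establishes the canonical in-memory
:class:`Dataset` that every downstream stage (normalization, drift
correction, evaluation) consumes.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("cell", "qc")

METADATA_COLUMNS = ("sample_id", "role", "batch", "region", "acq_order")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _sep(fmt: str) -> str:
    if fmt == "csv":
        return ","
    if fmt == "tsv":
        return "\t"
    raise ValidationError(f"unknown format {fmt!r}; expected 'csv' or 'tsv'")


_MZ_RE = re.compile(r"^(?:mz[_ ]?)?([0-9]+(?:\.[0-9]+)?)$", re.IGNORECASE)


def parse_mz(feature_id: str) -> float:
    """Extract the m/z value from a feature id like ``mz_184.07`` or ``184.07``.

    Returns NaN when the id carries no parseable mass.
    """
    m = _MZ_RE.match(str(feature_id).strip())
    return float(m.group(1)) if m else float("nan")


@dataclass
class FeatureTable:
    """Non-negative intensity matrix (samples × feature ions) plus feature annotations.

    ``intensities`` is indexed by sample id with feature ids as columns.
    ``features`` is indexed by feature id with columns ``mz``, ``polarity``,
    ``total_counts`` and ``snr``; when no side-car annotation file is given,
    ``total_counts`` defaults to the observed column sum and ``snr`` to +inf
    so that the peak filter passes vacuously (the count/SNR screen is often
    already applied upstream in vendor software).
    """

    intensities: pd.DataFrame
    features: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.features is None:
            self.features = default_feature_annotations(self.intensities)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        idx = self.intensities.index
        cols = self.intensities.columns
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise ValidationError(f"duplicate feature ids: {dupes}")
        values = self.intensities.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("feature table contains non-numeric cells")
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                "negative or non-finite intensity at sample "
                f"{idx[i]!r}, feature {cols[j]!r}: {values[i, j]}"
            )
        if not self.features.index.equals(cols):
            raise ValidationError("feature annotations do not match table columns")
        for col, lo in (("mz", 0.0), ("total_counts", 0.0), ("snr", 0.0)):
            v = self.features[col].to_numpy(dtype=float)
            if np.any(v[~np.isnan(v)] < lo):
                raise ValidationError(f"feature annotation {col!r} below {lo}")

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.intensities.copy(), self.features.copy())


def default_feature_annotations(intensities: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mz": [parse_mz(c) for c in intensities.columns],
            "polarity": "positive",
            "total_counts": intensities.sum(axis=0).to_numpy(dtype=float),
            "snr": math.inf,
        },
        index=intensities.columns,
    )


@dataclass
class Dataset:
    """A feature table joined with per-sample metadata, row-aligned."""

    table: FeatureTable
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.meta["sample_id"]) != self.table.sample_ids:
            raise ValidationError("metadata rows are not aligned with table rows")
        if not (self.meta["role"] == "qc").any():
            raise ValidationError("at least one QC sample required")

    @property
    def intensities(self) -> pd.DataFrame:
        return self.table.intensities

    def qc_mask(self) -> np.ndarray:
        return (self.meta["role"] == "qc").to_numpy()

    def cell_mask(self) -> np.ndarray:
        return (self.meta["role"] == "cell").to_numpy()

    def with_intensities(self, intensities: pd.DataFrame) -> "Dataset":
        """Return a new Dataset sharing metadata/annotations with new values."""
        table = FeatureTable(intensities, self.table.features.loc[intensities.columns].copy())
        return Dataset(table, self.meta.copy())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_feature_table(path, format: str = "csv", features_path=None) -> FeatureTable:
    """Read a samples × features intensity table.

    First column holds sample ids; the header row holds feature ids
    (``mz_<value>`` or plain numeric).  An optional side-car feature file
    provides per-ion annotations (``feature_id, mz, polarity, total_counts,
    snr``).
    """
    df = pd.read_csv(path, sep=_sep(format), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in feature table {path}: {exc}") from None
    features = read_feature_annotations(features_path, format) if features_path else None
    if features is not None:
        missing = [c for c in values.columns if c not in features.index]
        if missing:
            raise ValidationError(f"features file lacks annotations for: {missing}")
        features = features.loc[values.columns]
    return FeatureTable(values, features)


def read_feature_annotations(path, format: str = "csv") -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(format))
    df.columns = [c.strip().lower() for c in df.columns]
    if "feature_id" not in df.columns:
        raise ValidationError("features file missing column 'feature_id'")
    df["feature_id"] = df["feature_id"].astype(str)
    df = df.set_index("feature_id")
    if "mz" not in df.columns:
        df["mz"] = [parse_mz(c) for c in df.index]
    if "polarity" not in df.columns:
        df["polarity"] = "positive"
    if "total_counts" not in df.columns:
        raise ValidationError("features file missing column 'total_counts'")
    if "snr" not in df.columns:
        raise ValidationError("features file missing column 'snr'")
    return df[["mz", "polarity", "total_counts", "snr"]]


def write_feature_table(table: FeatureTable, path, format: str = "csv") -> None:
    out = table.intensities.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=_sep(format), float_format="%.12g")


def write_feature_annotations(table: FeatureTable, path, format: str = "csv") -> None:
    out = table.features.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep=_sep(format))


def read_metadata(path, format: str = "csv") -> pd.DataFrame:
    """Read sample metadata (sample_id, role, batch, region, acq_order).

    Column matching is case-insensitive; roles are normalized to
    ``{cell, qc}``; 1-based acquisition orders (min == 1 overall) are shifted
    to the canonical 0-based convention with a logged notice.
    """
    df = pd.read_csv(path, sep=_sep(format))
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing column(s): {missing}")
    df = df[list(METADATA_COLUMNS)].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["role"] = df["role"].astype(str).str.strip().str.lower()
    bad_roles = sorted(set(df["role"]) - set(ROLES))
    if bad_roles:
        raise ValidationError(f"unknown role value(s): {bad_roles}; expected cell/qc")
    df["batch"] = df["batch"].astype(str)
    df["region"] = df["region"].astype(str)
    try:
        df["acq_order"] = df["acq_order"].astype(int)
    except ValueError:
        raise ValidationError("acq_order must be integer") from None
    if len(df) and df["acq_order"].min() == 1:
        logger.info("metadata uses 1-based acq_order; shifting to 0-based")
        df["acq_order"] -= 1
    validate_metadata(df)
    return df


def validate_metadata(meta: pd.DataFrame) -> None:
    if meta["sample_id"].duplicated().any():
        dupes = sorted(set(meta.loc[meta["sample_id"].duplicated(), "sample_id"]))
        raise ValidationError(f"duplicate sample ids in metadata: {dupes}")
    if (meta["acq_order"] < 0).any():
        raise ValidationError("negative acq_order")
    dup = meta.duplicated(subset=["batch", "acq_order"])
    if dup.any():
        pairs = meta.loc[dup, ["batch", "acq_order"]].to_records(index=False).tolist()
        raise ValidationError(f"duplicate (batch, acq_order) pair(s): {pairs}")


def write_metadata(meta: pd.DataFrame, path, format: str = "csv") -> None:
    meta.to_csv(path, sep=_sep(format), index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def filter_peaks(
    table: FeatureTable,
    min_counts: float = 1000.0,
    min_snr: float = 3.0,
    mz_max: float = 824.0,
) -> FeatureTable:
    """Apply the standard peak screen: counts strictly above ``min_counts``,
    SNR at least ``min_snr``, m/z within [0, ``mz_max``].

    The count threshold is strict and the SNR threshold inclusive; both are
    configurable.  Features with unparseable m/z are kept (no mass evidence
    against them).
    """
    if min_counts < 0 or min_snr < 0 or mz_max < 0:
        raise ValidationError("filter thresholds must be non-negative")
    feats = table.features
    counts = feats["total_counts"].to_numpy(dtype=float)
    snr = feats["snr"].to_numpy(dtype=float)
    mz = feats["mz"].to_numpy(dtype=float)
    keep = (counts > min_counts) & (snr >= min_snr) & (np.isnan(mz) | ((mz >= 0) & (mz <= mz_max)))
    if not keep.any():
        raise ValidationError(
            "peak filter removed every feature; review the thresholds "
            "(min_counts/min_snr/mz_max)"
        )
    kept = [c for c, k in zip(table.feature_ids, keep) if k]
    logger.info("peak filter retained %d / %d features", len(kept), len(keep))
    return FeatureTable(table.intensities[kept].copy(), feats.loc[kept].copy())


def join_dataset(table: FeatureTable, meta: pd.DataFrame) -> Dataset:
    """Join a feature table with sample metadata, matching rows by sample id."""
    validate_metadata(meta)
    table_ids = set(table.sample_ids)
    meta_ids = set(meta["sample_id"])
    only_table = sorted(table_ids - meta_ids)
    only_meta = sorted(meta_ids - table_ids)
    if only_table or only_meta:
        parts = []
        if only_table:
            parts.append(f"samples missing from metadata: {only_table}")
        if only_meta:
            parts.append(f"metadata rows missing from table: {only_meta}")
        raise ValidationError("; ".join(parts))
    aligned = meta.set_index("sample_id").loc[table.sample_ids].reset_index()
    return Dataset(table, aligned)
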