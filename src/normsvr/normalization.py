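"""The Norm step: Z-score standardization against QC statistics, and the
total-area baseline normalization it is compared against.

Standardizing each feature ion by the mean and standard deviation of the QC
samples — rather than of all samples — keeps biological heterogeneity of the
experimental cells out of the normalization parameters: what is being put on
a common scale is the *technical* fluctuation of each ion, as witnessed by
repeated measurements of near-identical QC cells.  The z-scored table is the
input space of the SVR drift models; the inverse transform returns corrected
data to the raw intensity scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import Dataset, FeatureTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class QCStats:
    """Per-feature mean and sample standard deviation over QC rows."""

    mu: pd.Series
    sigma: pd.Series
    n_qc: int

    def __post_init__(self) -> None:
        if len(self.mu) != len(self.sigma):
            raise ValidationError("mu and sigma length mismatch")
        if (self.sigma < 0).any():
            raise ValidationError("negative sigma")
        if self.n_qc < 2:
            raise ValidationError("QC statistics need at least 2 QC samples")


@dataclass
class ZScoredTable:
    """Z-scored intensities plus the QC statistics that produced them."""

    z: pd.DataFrame
    stats: QCStats
    dropped_features: list = field(default_factory=list)


def compute_qc_stats(ds: Dataset, ddof: int = 1) -> QCStats:
    """Mean and standard deviation of each feature over the QC rows.

    The sample (n−1) denominator is the default for the small QC sets
    typical of single-cell acquisitions.
    """
    qc = ds.intensities.loc[ds.qc_mask()]
    if len(qc) < 2:
        raise ValidationError(f"need >= 2 QC samples to compute statistics, got {len(qc)}")
    return QCStats(mu=qc.mean(axis=0), sigma=qc.std(axis=0, ddof=ddof), n_qc=len(qc))


def zscore_transform(
    ds: Dataset, stats: QCStats, sigma_policy: str = "drop"
) -> ZScoredTable:
    """z = (x − μ) / σ per feature, with μ, σ from the QC samples.

    Features with σ = 0 carry no calibratable technical signal; by default
    they are dropped (and recorded), or with ``sigma_policy='epsilon'`` σ is
    floored at a machine-epsilon-scaled value.
    """
    x = ds.intensities
    if list(x.columns) != list(stats.mu.index):
        raise ValidationError("feature set of dataset and QC statistics differ")
    sigma = stats.sigma.copy()
    zero = sigma == 0
    dropped: list = []
    if zero.any():
        if sigma_policy == "drop":
            dropped = list(sigma.index[zero])
            logger.info("dropping %d zero-sigma feature(s): %s", len(dropped), dropped[:5])
            x = x.drop(columns=dropped)
            stats = QCStats(
                mu=stats.mu.drop(index=dropped),
                sigma=sigma.drop(index=dropped),
                n_qc=stats.n_qc,
            )
            sigma = stats.sigma
        elif sigma_policy == "epsilon":
            floor = np.finfo(float).eps * np.maximum(stats.mu.abs(), 1.0)
            sigma = sigma.where(~zero, floor)
            logger.warning("floored sigma for %d zero-sigma feature(s)", int(zero.sum()))
            stats = QCStats(mu=stats.mu, sigma=sigma, n_qc=stats.n_qc)
        else:
            raise ValidationError(f"unknown sigma_policy {sigma_policy!r}")
    z = (x - stats.mu) / sigma
    return ZScoredTable(z=z, stats=stats, dropped_features=dropped)


@dataclass
class InverseResult:
    """Raw-scale table recovered from z-scores, with the negative-clip count."""

    table: FeatureTable
    n_clipped: int


def inverse_zscore(z: ZScoredTable, features: pd.DataFrame | None = None) -> InverseResult:
    """x̂ = z·σ + μ; negative back-transformed intensities are clipped to 0.

    Drift correction can legitimately push a low signal below μ − kσ, so
    negatives are clipped (and counted) rather than treated as errors.
    """
    raw = z.z * z.stats.sigma + z.stats.mu
    neg = raw.to_numpy() < 0
    n_clipped = int(neg.sum())
    if n_clipped:
        logger.info("clipped %d negative back-transformed intensities to 0", n_clipped)
        raw = raw.clip(lower=0.0)
    if features is not None:
        features = features.loc[raw.columns].copy()
    return InverseResult(FeatureTable(raw, features), n_clipped)


def total_area_normalize(ds: Dataset) -> Dataset:
    """Divide each sample row by its own total signal (row sum).

    This is the conventional ToF-SIMS baseline ("total area / pixels"
    normalization): it removes per-sample global scale only, so per-feature
    offsets between regions or batches survive it.
    """
    x = ds.intensities
    sums = x.sum(axis=1)
    zero = sums == 0
    if zero.any():
        raise ValidationError(
            f"sample(s) with zero total intensity: {sorted(x.index[zero])}"
        )
    return ds.with_intensities(x.div(sums, axis=0))
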