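"""Generator for ToF-SIMS-like single-cell feature tables with known truth.

Real single-cell ToF-SIMS acquisitions suffer from several compounding
non-biological effects: cells measured at different positions on a wafer
(regions) or on different wafers (batches) carry multiplicative per-ion
offsets; signal drifts smoothly over the acquisition sequence as the ion
beam and surface state evolve; and every measurement carries counting
noise.  This module emulates exactly that structure on top of log-normally
heterogeneous cell profiles and a fixed QC reference profile, with QC
pseudo-cells interleaved at a configurable cell:QC ratio (default 4:1,
bracketing the sequence), so that correction quality can be measured
against stored ground truth.

The observation model, per sample i (batch b, region r, order t) and
feature j:

    x_ij = p_ij · B_bj · R_brj · (1 + A·s_j(t/t_max)) · ε_ij

with p the drift-free profile (the QC reference for QC rows), B and R
per-feature log-normal batch/region factors, s a smooth drift shape scaled
to [−1, 1] affecting a subset of features, A the drift amplitude, and ε
log-normal technical noise with the configured CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_tables import Dataset, FeatureTable, ValidationError

DRIFT_SHAPES = ("linear", "exponential-decay", "sinusoidal")


@dataclass
class SyntheticConfig:
    """Study-design parameters for the generator.

    Defaults reproduce the three-batch design (3 × 52 cells plus scheduled
    QC at 4:1, 457 feature ions, three acquisition regions per wafer) with
    10% QC technical CV and up to ±40% relative drift on 80% of features.
    """

    n_cells_per_batch: int = 52
    n_batches: int = 3
    n_regions_per_batch: int = 3
    n_features: int = 457
    qc_ratio: int = 4
    base_profile: tuple = (2.0, 5.0)  # log10 mean-intensity range
    bio_cv: float = 0.5
    tech_cv: float = 0.1
    batch_factor_sd: float = 0.6  # log-scale sd of per-feature batch offsets
    region_factor_sd: float = 0.4
    drift_amplitude: float = 0.4
    drift_shape: str = "exponential-decay"
    drift_feature_fraction: float = 0.8
    drift_homogeneous: bool = False
    per_feature_offsets: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells_per_batch", "n_batches", "n_regions_per_batch", "n_features"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.qc_ratio < 1:
            raise ValidationError("qc_ratio must be >= 1")
        for name in ("bio_cv", "tech_cv", "batch_factor_sd", "region_factor_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.drift_feature_fraction <= 1:
            raise ValidationError("drift_feature_fraction must be in [0, 1]")
        if not 0 <= self.drift_amplitude < 1:
            raise ValidationError("drift_amplitude must be in [0, 1) for positivity")
        if self.drift_shape not in DRIFT_SHAPES:
            raise ValidationError(f"drift_shape must be one of {DRIFT_SHAPES}")

    @classmethod
    def single_wafer(cls, **overrides) -> "SyntheticConfig":
        """Single-batch, three-region design (one wafer, 56 cells)."""
        base = dict(n_cells_per_batch=56, n_batches=1, n_regions_per_batch=3)
        base.update(overrides)
        return cls(**base)


def schedule_qc(n_cells: int, qc_ratio: int) -> list[str]:
    """Role sequence with one QC after every ``qc_ratio`` cells, bracketed.

    The sequence begins and ends with a QC, giving
    n_qc = ceil(n_cells / qc_ratio) + 1.
    """
    if n_cells < 1 or qc_ratio < 1:
        raise ValidationError("n_cells and qc_ratio must be >= 1")
    roles = ["qc"]
    remaining = n_cells
    while remaining > 0:
        take = min(qc_ratio, remaining)
        roles += ["cell"] * take + ["qc"]
        remaining -= take
    assert roles.count("qc") == math.ceil(n_cells / qc_ratio) + 1
    return roles


def drift_shape_values(shape: str, u: np.ndarray) -> np.ndarray:
    """Smooth drift shape on u ∈ [0, 1], scaled to span [−1, 1]."""
    u = np.asarray(u, dtype=float)
    if shape == "linear":
        return 2.0 * u - 1.0
    if shape == "exponential-decay":
        lo = math.exp(-3.0)
        return 2.0 * (np.exp(-3.0 * u) - lo) / (1.0 - lo) - 1.0
    if shape == "sinusoidal":
        return np.sin(2.0 * np.pi * u)
    raise ValidationError(f"unknown drift shape {shape!r}")


@dataclass
class GroundTruth:
    """All generative components, sufficient to rebuild the table exactly."""

    config: SyntheticConfig
    qc_reference_profile: pd.Series
    true_profiles: pd.DataFrame  # drift-free, offset-free, noise-free, all rows
    batch_factors: pd.DataFrame  # batches × features
    region_factors: pd.DataFrame  # (batch, region) × features
    drift: pd.DataFrame  # relative drift g (rows × features); observed factor 1+g
    noise: pd.DataFrame  # multiplicative technical noise draws
    drifted_features: list = field(default_factory=list)
    drift_signs: pd.Series | None = None

    def drift_free_table(self) -> pd.DataFrame:
        """Counterfactual table with drift curves zeroed (offsets/noise kept)."""
        return _compose(self, drift=self.drift * 0.0)


def _compose(gt: GroundTruth, drift: pd.DataFrame | None = None) -> pd.DataFrame:
    drift = gt.drift if drift is None else drift
    meta_key = gt.true_profiles.index
    bf = gt.batch_factors.loc[gt._row_batches].to_numpy()
    rf = gt.region_factors.loc[list(zip(gt._row_batches, gt._row_regions))].to_numpy()
    values = (
        gt.true_profiles.to_numpy()
        * bf
        * rf
        * (1.0 + drift.to_numpy())
        * gt.noise.to_numpy()
    )
    return pd.DataFrame(values, index=meta_key, columns=gt.true_profiles.columns)


def reconstruct_observed(gt: GroundTruth) -> FeatureTable:
    """Recombine the stored components; exact by construction."""
    for name in ("true_profiles", "batch_factors", "region_factors", "drift", "noise"):
        if getattr(gt, name) is None:
            raise ValidationError(f"ground truth missing component {name!r}")
    return FeatureTable(_compose(gt))


def generate_dataset(config: SyntheticConfig | None = None) -> tuple[Dataset, GroundTruth]:
    """Draw one complete synthetic study (table + metadata + ground truth)."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    # feature ions: m/z mostly in the low-mass metabolite range
    mz = np.sort(rng.uniform(50.0, 400.0, size=config.n_features))
    mz += np.arange(config.n_features) * 1e-6  # force uniqueness
    feature_ids = [f"mz_{v:.4f}" for v in mz]

    log10_base = rng.uniform(*config.base_profile, size=config.n_features)
    qc_ref = pd.Series(10.0**log10_base, index=feature_ids, name="qc_reference")

    # metadata + schedule
    meta_rows = []
    for bi in range(config.n_batches):
        batch = f"b{bi + 1}"
        roles = schedule_qc(config.n_cells_per_batch, config.qc_ratio)
        blocks = np.array_split(np.arange(len(roles)), config.n_regions_per_batch)
        region_of = np.empty(len(roles), dtype=object)
        for ri, block in enumerate(blocks):
            region_of[block] = f"{batch}_r{ri + 1}"
        for order, role in enumerate(roles):
            meta_rows.append(
                {
                    "sample_id": f"{batch}_s{order:03d}",
                    "role": role,
                    "batch": batch,
                    "region": region_of[order],
                    "acq_order": order,
                }
            )
    meta = pd.DataFrame(meta_rows)
    n_rows = len(meta)
    sample_ids = meta["sample_id"].to_list()
    is_cell = (meta["role"] == "cell").to_numpy()

    # drift-free profiles: biological log-normal heterogeneity for cells,
    # the shared reference profile for QC pseudo-cells
    s_bio = math.sqrt(math.log(1.0 + config.bio_cv**2))
    profiles = np.tile(qc_ref.to_numpy(), (n_rows, 1))
    if s_bio > 0:
        bio = np.exp(rng.normal(0.0, s_bio, size=(int(is_cell.sum()), config.n_features)))
        profiles[is_cell] *= bio
    true_profiles = pd.DataFrame(profiles, index=sample_ids, columns=feature_ids)

    # multiplicative offsets (between-level effects: identity when one level)
    batches = sorted(meta["batch"].unique())
    if config.n_batches > 1 and config.batch_factor_sd > 0:
        shape = (len(batches), config.n_features if config.per_feature_offsets else 1)
        bf = np.exp(rng.normal(0.0, config.batch_factor_sd, size=shape))
        bf = np.broadcast_to(bf, (len(batches), config.n_features)).copy()
    else:
        bf = np.ones((len(batches), config.n_features))
    batch_factors = pd.DataFrame(bf, index=batches, columns=feature_ids)

    regions = sorted(meta[["batch", "region"]].drop_duplicates().itertuples(index=False))
    if config.n_regions_per_batch > 1 and config.region_factor_sd > 0:
        shape = (len(regions), config.n_features if config.per_feature_offsets else 1)
        rf = np.exp(rng.normal(0.0, config.region_factor_sd, size=shape))
        rf = np.broadcast_to(rf, (len(regions), config.n_features)).copy()
    else:
        rf = np.ones((len(regions), config.n_features))
    region_factors = pd.DataFrame(
        rf, index=pd.MultiIndex.from_tuples([tuple(r) for r in regions]), columns=feature_ids
    )

    # drift: smooth shape over scaled order, per-feature sign, subset affected
    n_drifted = int(round(config.drift_feature_fraction * config.n_features))
    drifted_idx = np.sort(rng.choice(config.n_features, size=n_drifted, replace=False))
    if config.drift_homogeneous:
        signs = np.ones(config.n_features)
    else:
        signs = rng.choice([-1.0, 1.0], size=config.n_features)
    affected = np.zeros(config.n_features, dtype=bool)
    affected[drifted_idx] = True

    u = np.empty(n_rows)
    for b, g in meta.groupby("batch"):
        m = int(g["acq_order"].max())
        u[g.index] = g["acq_order"] / m if m > 0 else 0.0
    s = drift_shape_values(config.drift_shape, u)
    drift_matrix = np.where(
        affected[None, :], config.drift_amplitude * signs[None, :] * s[:, None], 0.0
    )
    drift = pd.DataFrame(drift_matrix, index=sample_ids, columns=feature_ids)

    # technical counting noise, all rows
    s_tech = math.sqrt(math.log(1.0 + config.tech_cv**2))
    if s_tech > 0:
        noise = np.exp(rng.normal(0.0, s_tech, size=(n_rows, config.n_features)))
    else:
        noise = np.ones((n_rows, config.n_features))
    noise = pd.DataFrame(noise, index=sample_ids, columns=feature_ids)

    gt = GroundTruth(
        config=config,
        qc_reference_profile=qc_ref,
        true_profiles=true_profiles,
        batch_factors=batch_factors,
        region_factors=region_factors,
        drift=drift,
        noise=noise,
        drifted_features=[feature_ids[k] for k in drifted_idx],
        drift_signs=pd.Series(signs, index=feature_ids),
    )
    gt._row_batches = meta["batch"].to_list()
    gt._row_regions = meta["region"].to_list()

    observed = _compose(gt)
    features = pd.DataFrame(
        {
            "mz": mz,
            "polarity": "negative",
            "total_counts": observed.sum(axis=0).to_numpy(),
            "snr": np.inf,
        },
        index=observed.columns,
    )
    table = FeatureTable(observed, features)
    return Dataset(table, meta), gt


def true_qc_drift_z(gt: GroundTruth, ds: Dataset, stats) -> pd.DataFrame:
    """Deterministic (noise-free) z-score of the QC profile at every sample's
    covariates — the target surface a drift model should recover.

    For sample i and feature j this is
    (qc_ref_j · B_bj · R_brj · (1 + g_j(t_i)) − μ_j) / σ_j, in the z units
    defined by ``stats``.
    """
    bf = gt.batch_factors.loc[gt._row_batches].to_numpy()
    rf = gt.region_factors.loc[list(zip(gt._row_batches, gt._row_regions))].to_numpy()
    expected = gt.qc_reference_profile.to_numpy()[None, :] * bf * rf * (
        1.0 + gt.drift.to_numpy()
    )
    expected = pd.DataFrame(expected, index=gt.true_profiles.index, columns=gt.drift.columns)
    cols = list(stats.mu.index)
    return (expected[cols] - stats.mu) / stats.sigma
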