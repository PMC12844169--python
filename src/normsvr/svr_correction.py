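"""The SVR step: QC-driven modeling and subtraction of technical drift.

For every feature ion an ε-insensitive support-vector regression is fitted
mapping acquisition covariates (scaled acquisition order, one-hot region and
batch indicators) to the QC samples' z-scores.  Because QC cells are
near-replicates, any structure in their z-scores over the sequence or across
positions is technical, not biological; the fitted surface d̂_j is therefore
an estimate of the systematic error, and subtracting it from every sample
(cells and QC alike) removes drift while leaving within-sample biology
untouched.  Only QC rows ever enter a fit — cell intensities cannot leak
into the error model.

Hyperparameters are tuned per feature by exhaustive grid search with
k-fold cross-validation (default 5 folds), ties broken toward the least
complex model (smallest C, then ε, then γ).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .io_tables import Dataset, FeatureTable, ValidationError
from .normalization import (
    QCStats,
    ZScoredTable,
    compute_qc_stats,
    inverse_zscore,
    zscore_transform,
)

logger = logging.getLogger(__name__)

KNOWN_COVARIATES = ("acq_order", "region", "batch")


@dataclass
class CorrectionConfig:
    """Settings for drift-model fitting.

    Grids follow common QC-SVR practice and are fully overridable; the
    fitting ``scope`` defaults to per-batch models whenever more than one
    batch is present (drift curves are batch-specific), pooled otherwise.
    """

    kernel: str = "rbf"
    c_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    epsilon_grid: tuple = (0.01, 0.05, 0.1)
    gamma_grid: tuple = ("scale", 0.1, 1.0, 10.0)
    cv_folds: int = 5
    covariates: tuple = ("acq_order", "region", "batch")
    scope: str = "auto"  # auto | pooled | per_batch
    stats_scope: str = "pooled"  # pooled | per_batch
    sigma_policy: str = "drop"
    blocked_folds: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValidationError(f"unknown kernel {self.kernel!r}")
        if not (self.c_grid and self.epsilon_grid and self.gamma_grid):
            raise ValidationError("hyperparameter grids must be non-empty")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        unknown = set(self.covariates) - set(KNOWN_COVARIATES)
        if unknown:
            raise ValidationError(f"unknown covariate(s): {sorted(unknown)}")
        if self.scope not in ("auto", "pooled", "per_batch"):
            raise ValidationError(f"unknown scope {self.scope!r}")
        if self.stats_scope not in ("pooled", "per_batch"):
            raise ValidationError(f"unknown stats_scope {self.stats_scope!r}")


class CovariateEncoder:
    """Deterministic design-matrix builder for acquisition covariates.

    Acquisition order is scaled to [0, 1] within each batch (order divided
    by the batch's maximum order); region and batch become one-hot columns.
    Column order: the order column first, then region levels sorted
    lexicographically, then batch levels sorted.  Categorical levels unseen
    at fit time raise at transform time — drift is never extrapolated across
    an unseen batch or region.
    """

    def __init__(self, covariates) -> None:
        if not covariates:
            raise ValidationError("at least one covariate required")
        unknown = set(covariates) - set(KNOWN_COVARIATES)
        if unknown:
            raise ValidationError(f"unknown covariate(s): {sorted(unknown)}")
        self.covariates = tuple(c for c in KNOWN_COVARIATES if c in covariates)
        self.region_levels: list = []
        self.batch_levels: list = []
        self.order_max: dict = {}

    def fit(self, meta: pd.DataFrame) -> "CovariateEncoder":
        if "region" in self.covariates:
            self.region_levels = sorted(meta["region"].unique())
        if "batch" in self.covariates:
            self.batch_levels = sorted(meta["batch"].unique())
        self.order_max = {
            b: int(g["acq_order"].max()) for b, g in meta.groupby("batch")
        }
        self.columns = []
        if "acq_order" in self.covariates:
            self.columns.append("acq_order_scaled")
        self.columns += [f"region={r}" for r in self.region_levels]
        self.columns += [f"batch={b}" for b in self.batch_levels]
        return self

    def transform(self, meta: pd.DataFrame) -> np.ndarray:
        cols = []
        if "acq_order" in self.covariates:
            scaled = np.empty(len(meta), dtype=float)
            for i, (b, o) in enumerate(zip(meta["batch"], meta["acq_order"])):
                m = self.order_max.get(b)
                if m is None:
                    raise ValidationError(f"batch {b!r} unseen during fitting")
                scaled[i] = 0.0 if m == 0 else o / m
            cols.append(scaled)
        if "region" in self.covariates:
            unseen = sorted(set(meta["region"]) - set(self.region_levels))
            if unseen:
                raise ValidationError(f"region level(s) unseen during fitting: {unseen}")
            for r in self.region_levels:
                cols.append((meta["region"] == r).to_numpy(dtype=float))
        if "batch" in self.covariates:
            unseen = sorted(set(meta["batch"]) - set(self.batch_levels))
            if unseen:
                raise ValidationError(f"batch level(s) unseen during fitting: {unseen}")
            for b in self.batch_levels:
                cols.append((meta["batch"] == b).to_numpy(dtype=float))
        return np.column_stack(cols)

    def fit_transform(self, meta: pd.DataFrame) -> np.ndarray:
        return self.fit(meta).transform(meta)


def encode_covariates(meta: pd.DataFrame, covariates) -> np.ndarray:
    """Convenience fit+transform on one metadata table."""
    return CovariateEncoder(covariates).fit_transform(meta)


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

def _resolve_gamma(gamma, X: np.ndarray) -> float:
    if gamma == "scale":
        v = X.var()
        return 1.0 / (X.shape[1] * v) if v > 0 else 1.0
    return float(gamma)


def _cv_splits(n: int, config: CorrectionConfig):
    """Seeded shuffled k-fold splits (or acquisition-contiguous blocks)."""
    if config.blocked_folds:
        idx = np.arange(n)
        return [
            (np.setdiff1d(idx, test), test)
            for test in np.array_split(idx, config.cv_folds)
        ]
    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed % (2**31))
    return list(kf.split(np.arange(n)))


def tune_hyperparameters(
    y: np.ndarray,
    X: np.ndarray,
    config: CorrectionConfig,
    splits=None,
) -> tuple[dict, float]:
    """Exhaustive grid search minimizing mean CV squared error.

    The grid is scanned with C ascending, then ε, then γ, and a candidate
    replaces the incumbent only on a strict improvement — so exact ties
    resolve to the smallest C, then smallest ε, then smallest γ.
    """
    n = len(y)
    if n < config.cv_folds:
        raise ValidationError(
            f"{n} QC samples but cv_folds={config.cv_folds}; lower cv_folds"
        )
    if splits is None:
        splits = _cv_splits(n, config)
    gamma_grid = config.gamma_grid if config.kernel == "rbf" else (config.gamma_grid[0],)
    gammas = sorted(gamma_grid, key=lambda g: _resolve_gamma(g, X))
    best_params, best_mse = None, np.inf
    for C in sorted(config.c_grid):
        for eps in sorted(config.epsilon_grid):
            for gamma in gammas:
                fold_mses = []
                for train, test in splits:
                    model = SVR(
                        kernel=config.kernel,
                        C=C,
                        epsilon=eps,
                        gamma=gamma if gamma == "scale" else float(gamma),
                    )
                    model.fit(X[train], y[train])
                    resid = y[test] - model.predict(X[test])
                    fold_mses.append(float(np.mean(resid**2)))
                mse = float(np.mean(fold_mses))
                if mse < best_mse:
                    best_mse = mse
                    best_params = {"C": C, "epsilon": eps, "gamma": gamma}
    assert best_params is not None
    return best_params, best_mse


# ---------------------------------------------------------------------------
# fitting and applying drift models
# ---------------------------------------------------------------------------

@dataclass
class DriftModelSet:
    """One fitted per-feature regressor per fitting unit (pooled or batch)."""

    scope: str  # "pooled" | "per_batch"
    units: list  # unit keys ("all" or batch ids)
    encoders: dict  # unit -> CovariateEncoder
    models: dict  # (unit, feature_id) -> fitted SVR
    params: pd.DataFrame  # rows (unit, feature): C, epsilon, gamma, cv_mse
    feature_ids: list

    def predict(self, meta: pd.DataFrame) -> pd.DataFrame:
        """Drift estimate d̂ (z units) for every row of ``meta``, all features."""
        dhat = pd.DataFrame(
            np.nan, index=meta["sample_id"], columns=self.feature_ids
        )
        for unit in self.units:
            rows = (
                np.ones(len(meta), dtype=bool)
                if self.scope == "pooled"
                else (meta["batch"] == unit).to_numpy()
            )
            if not rows.any():
                continue
            X = self.encoders[unit].transform(meta.loc[rows])
            ids = meta.loc[rows, "sample_id"]
            for j in self.feature_ids:
                dhat.loc[ids, j] = self.models[(unit, j)].predict(X)
        if self.scope == "per_batch":
            unseen = sorted(set(meta["batch"]) - set(self.units))
            if unseen:
                raise ValidationError(f"batch level(s) unseen during fitting: {unseen}")
        if dhat.isna().any().any():
            raise ValidationError("drift prediction incomplete (unseen samples)")
        return dhat


def _resolve_scope(config: CorrectionConfig, meta: pd.DataFrame) -> str:
    if config.scope != "auto":
        return config.scope
    return "per_batch" if meta["batch"].nunique() > 1 else "pooled"


def fit_drift_models(
    z: ZScoredTable, meta: pd.DataFrame, config: CorrectionConfig
) -> DriftModelSet:
    """Fit one tuned SVR per feature ion on QC rows only."""
    scope = _resolve_scope(config, meta)
    units = ["all"] if scope == "pooled" else sorted(meta["batch"].unique())
    features = list(z.z.columns)
    encoders: dict = {}
    models: dict = {}
    rows = []
    qc_all = (meta["role"] == "qc").to_numpy()
    for unit in units:
        in_unit = (
            np.ones(len(meta), dtype=bool)
            if scope == "pooled"
            else (meta["batch"] == unit).to_numpy()
        )
        qc = in_unit & qc_all
        n_qc = int(qc.sum())
        if n_qc < max(2, config.cv_folds):
            raise ValidationError(
                f"fitting unit {unit!r} has {n_qc} QC samples; need >= "
                f"max(2, cv_folds={config.cv_folds})"
            )
        enc = CovariateEncoder(config.covariates).fit(meta.loc[in_unit])
        encoders[unit] = enc
        X_qc = enc.transform(meta.loc[qc])
        Z_qc = z.z.loc[meta.loc[qc, "sample_id"]].to_numpy()
        splits = _cv_splits(n_qc, config)
        for k, j in enumerate(features):
            y = Z_qc[:, k]
            params, cv_mse = tune_hyperparameters(y, X_qc, config, splits=splits)
            model = SVR(kernel=config.kernel, **params)
            model.fit(X_qc, y)
            models[(unit, j)] = model
            rows.append(
                {
                    "unit": unit,
                    "feature_id": j,
                    "C": params["C"],
                    "epsilon": params["epsilon"],
                    "gamma": params["gamma"],
                    "cv_mse": cv_mse,
                }
            )
        logger.info("fitted %d drift models for unit %r (n_qc=%d)", len(features), unit, n_qc)
    return DriftModelSet(
        scope=scope,
        units=units,
        encoders=encoders,
        models=models,
        params=pd.DataFrame(rows),
        feature_ids=features,
    )


@dataclass
class CorrectionResult:
    """Corrected dataset plus the fitted models and QC diagnostics."""

    corrected: Dataset
    corrected_z: ZScoredTable
    drift: pd.DataFrame  # d̂ per sample × feature, z units
    models: DriftModelSet
    diagnostics: pd.DataFrame  # per-feature QC RSD before/after (%)
    n_clipped: int


def _qc_rsd(values: pd.DataFrame, qc_mask: np.ndarray) -> pd.Series:
    qc = values.loc[qc_mask]
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    return rsd.where(mean != 0, np.inf)


def apply_correction(
    z: ZScoredTable, models: DriftModelSet, ds: Dataset
) -> CorrectionResult:
    """Subtract the predicted drift surface from every sample.

    corrected_z = z − d̂; raw-scale output via the inverse z-transform
    (x̂ = x − σ·d̂ wherever no clipping occurs).
    """
    missing = [j for j in z.z.columns if j not in models.feature_ids]
    if missing:
        raise ValidationError(f"no drift model for feature(s): {missing[:5]}")
    dhat = models.predict(ds.meta)
    dhat = dhat.loc[z.z.index, z.z.columns]
    corrected_z = ZScoredTable(z=z.z - dhat, stats=z.stats, dropped_features=z.dropped_features)
    inv = inverse_zscore(corrected_z, features=ds.table.features)
    corrected = ds.with_intensities(inv.table.intensities)
    qc_mask = ds.qc_mask()
    diagnostics = pd.DataFrame(
        {
            "qc_rsd_before": _qc_rsd(ds.intensities[z.z.columns], qc_mask),
            "qc_rsd_after": _qc_rsd(corrected.intensities, qc_mask),
        }
    )
    return CorrectionResult(
        corrected=corrected,
        corrected_z=corrected_z,
        drift=dhat,
        models=models,
        diagnostics=diagnostics,
        n_clipped=inv.n_clipped,
    )


def run_norm_svr(ds: Dataset, config: CorrectionConfig | None = None) -> CorrectionResult:
    """Full two-stage correction: QC z-scoring, drift fitting, subtraction.

    Deterministic given ``config.seed``.  With ``stats_scope='per_batch'``
    the z-scoring (and fitting) is done independently within each batch and
    the corrected batches are re-assembled in the original row order.
    """
    config = config or CorrectionConfig()
    if config.stats_scope == "per_batch" and ds.meta["batch"].nunique() > 1:
        return _run_per_batch_stats(ds, config)
    stats = compute_qc_stats(ds)
    z = zscore_transform(ds, stats, sigma_policy=config.sigma_policy)
    models = fit_drift_models(z, ds.meta, config)
    return apply_correction(z, models, ds)


def _run_per_batch_stats(ds: Dataset, config: CorrectionConfig) -> CorrectionResult:
    sub_config = replace(config, stats_scope="pooled", scope="pooled")
    pieces, z_pieces, d_pieces, diag = [], [], [], []
    all_models: dict = {}
    params_frames, units, encoders = [], [], {}
    batches = sorted(ds.meta["batch"].unique())
    kept_features: set | None = None
    results = {}
    for b in batches:
        mask = (ds.meta["batch"] == b).to_numpy()
        sub = Dataset(
            FeatureTable(ds.intensities.loc[mask].copy(), ds.table.features.copy()),
            ds.meta.loc[mask].reset_index(drop=True),
        )
        res = run_norm_svr(sub, sub_config)
        results[b] = res
        cols = set(res.corrected.intensities.columns)
        kept_features = cols if kept_features is None else kept_features & cols
    feature_order = [j for j in ds.intensities.columns if j in (kept_features or set())]
    for b in batches:
        res = results[b]
        pieces.append(res.corrected.intensities[feature_order])
        z_pieces.append(res.corrected_z.z[feature_order])
        d_pieces.append(res.drift[feature_order])
        diag.append(res.diagnostics.loc[feature_order])
        for (unit, j), m in res.models.models.items():
            if j in feature_order:
                all_models[(b, j)] = m
        encoders[b] = res.models.encoders["all"]
        units.append(b)
        pf = res.models.params.copy()
        pf["unit"] = b
        params_frames.append(pf[pf["feature_id"].isin(feature_order)])
    corrected_int = pd.concat(pieces).loc[ds.intensities.index]
    corrected = ds.with_intensities(corrected_int)
    first = results[batches[0]]
    corrected_z = ZScoredTable(
        z=pd.concat(z_pieces).loc[ds.intensities.index],
        stats=first.corrected_z.stats,
        dropped_features=sorted(set(ds.intensities.columns) - set(feature_order)),
    )
    models = DriftModelSet(
        scope="per_batch",
        units=units,
        encoders=encoders,
        models=all_models,
        params=pd.concat(params_frames, ignore_index=True),
        feature_ids=feature_order,
    )
    qc_mask = ds.qc_mask()
    diagnostics = pd.DataFrame(
        {
            "qc_rsd_before": _qc_rsd(ds.intensities[feature_order], qc_mask),
            "qc_rsd_after": _qc_rsd(corrected.intensities, qc_mask),
        }
    )
    n_clipped = sum(r.n_clipped for r in results.values())
    return CorrectionResult(
        corrected=corrected,
        corrected_z=corrected_z,
        drift=pd.concat(d_pieces).loc[ds.intensities.index],
        models=models,
        diagnostics=diagnostics,
        n_clipped=n_clipped,
    )
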