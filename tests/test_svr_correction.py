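import numpy as np
import pandas as pd
import pytest

from normsvr import (
    CorrectionConfig,
    CovariateEncoder,
    Dataset,
    FeatureTable,
    ValidationError,
    apply_correction,
    compute_qc_stats,
    encode_covariates,
    fit_drift_models,
    join_dataset,
    run_norm_svr,
    tune_hyperparameters,
    zscore_transform,
)
from normsvr.normalization import QCStats, ZScoredTable
from tests.conftest import make_meta


def qc_meta(n, batch="b1", region="r1"):
    return make_meta([(f"q{i}", "qc", batch, region, i) for i in range(n)])


def z_table(meta, columns):
    stats = QCStats(
        mu=pd.Series(0.0, index=list(columns)),
        sigma=pd.Series(1.0, index=list(columns)),
        n_qc=int((meta["role"] == "qc").sum()),
    )
    z = pd.DataFrame(columns, index=meta["sample_id"])
    return ZScoredTable(z=z, stats=stats)


class TestEncodeCovariates:
    def test_order_scaled_per_batch(self):
        meta = qc_meta(5)
        X = encode_covariates(meta, ("acq_order",))
        assert np.allclose(X[:, 0], [0, 0.25, 0.5, 0.75, 1.0])

    def test_region_one_hot_sorted(self):
        meta = make_meta(
            [("a", "qc", "b1", "r2", 0), ("b", "qc", "b1", "r1", 1)]
        )
        X = encode_covariates(meta, ("region",))
        # columns: r1 then r2 (lexicographic)
        assert X.tolist() == [[0.0, 1.0], [1.0, 0.0]]

    def test_column_order_and_batch_levels(self):
        meta = make_meta(
            [("a", "qc", "b2", "r1", 0), ("b", "qc", "b1", "r1", 0)]
        )
        enc = CovariateEncoder(("acq_order", "region", "batch")).fit(meta)
        assert enc.columns == ["acq_order_scaled", "region=r1", "batch=b1", "batch=b2"]

    def test_empty_covariates_is_error(self):
        with pytest.raises(ValidationError):
            CovariateEncoder(())

    def test_unknown_covariate_is_error(self):
        with pytest.raises(ValidationError, match="unknown covariate"):
            encode_covariates(qc_meta(3), ("acq_order", "bogus"))

    def test_unseen_level_raises_at_transform(self):
        enc = CovariateEncoder(("region",)).fit(qc_meta(3, region="r1"))
        with pytest.raises(ValidationError, match="unseen"):
            enc.transform(qc_meta(2, region="r9"))


class TestTuneHyperparameters:
    def test_single_point_grid_returned(self):
        meta = qc_meta(10)
        X = encode_covariates(meta, ("acq_order",))
        y = np.linspace(-1, 1, 10)
        cfg = CorrectionConfig(c_grid=(7.0,), epsilon_grid=(0.02,), gamma_grid=(0.5,), seed=5)
        params, mse = tune_hyperparameters(y, X, cfg)
        assert params == {"C": 7.0, "epsilon": 0.02, "gamma": 0.5}
        assert np.isfinite(mse)

    def test_linear_kernel_beats_rbf_on_linear_signal(self):
        meta = qc_meta(15)
        X = encode_covariates(meta, ("acq_order",))
        y = 2.0 * X[:, 0] - 1.0  # exactly linear, no noise
        lin = CorrectionConfig(kernel="linear", c_grid=(100.0,), epsilon_grid=(0.0,), gamma_grid=("scale",), seed=2)
        rbf = CorrectionConfig(kernel="rbf", seed=2)
        _, mse_lin = tune_hyperparameters(y, X, lin)
        _, mse_rbf = tune_hyperparameters(y, X, rbf)
        assert mse_lin <= mse_rbf

    def test_ties_resolve_to_smallest_hyperparameters(self):
        # y identically 0: every grid point predicts 0, all CV scores tie
        meta = qc_meta(10)
        X = encode_covariates(meta, ("acq_order",))
        y = np.zeros(10)
        cfg = CorrectionConfig(
            c_grid=(10.0, 0.1, 1.0), epsilon_grid=(0.1, 0.01), gamma_grid=(1.0, 0.1), seed=0
        )
        params, mse = tune_hyperparameters(y, X, cfg)
        assert params == {"C": 0.1, "epsilon": 0.01, "gamma": 0.1}
        assert mse == 0.0

    def test_too_few_qc_rows_is_error(self):
        meta = qc_meta(3)
        X = encode_covariates(meta, ("acq_order",))
        with pytest.raises(ValidationError, match="cv_folds"):
            tune_hyperparameters(np.zeros(3), X, CorrectionConfig())


class TestFitDriftModels:
    def test_flat_qc_gives_near_zero_drift(self):
        meta = qc_meta(10)
        z = z_table(meta, {"f1": np.zeros(10)})
        cfg = CorrectionConfig(covariates=("acq_order",), seed=0)
        models = fit_drift_models(z, meta, cfg)
        pred = models.predict(meta)["f1"].to_numpy()
        assert np.all(np.abs(pred) <= 0.1 + 1e-9)  # within the epsilon tube

    def test_linear_drift_matches_ols_oracle(self):
        meta = qc_meta(12)
        u = encode_covariates(meta, ("acq_order",))[:, 0]
        y = 2.0 * u - 1.0
        z = z_table(meta, {"f1": y})
        cfg = CorrectionConfig(
            kernel="linear", c_grid=(1e4,), epsilon_grid=(0.001,), gamma_grid=("scale",),
            covariates=("acq_order",), seed=0,
        )
        models = fit_drift_models(z, meta, cfg)
        pred = models.predict(meta)["f1"].to_numpy()
        ols = np.polyval(np.polyfit(u, y, 1), u)  # oracle: exact least-squares line
        assert np.max(np.abs(pred - ols)) < 0.05

    def test_dropped_feature_has_no_model(self, tiny_dataset):
        stats = compute_qc_stats(tiny_dataset)
        z = zscore_transform(tiny_dataset, stats)  # drops the constant feature
        cfg = CorrectionConfig(cv_folds=2, covariates=("acq_order", "region"), seed=0)
        models = fit_drift_models(z, tiny_dataset.meta, cfg)
        assert "mz_300.0" not in models.feature_ids
        assert set(models.feature_ids) == set(z.z.columns)

    def test_cells_never_influence_fit(self, rng):
        """Permuting cell-row values leaves the drift predictions unchanged."""
        n_qc, n_cell = 10, 8
        rows = [(f"q{i}", "qc", "b1", "r1", 2 * i) for i in range(n_qc)]
        rows += [(f"c{i}", "cell", "b1", "r1", 2 * i + 1) for i in range(n_cell)]
        meta = make_meta(rows)
        z_qc = rng.normal(size=n_qc)
        z_cell = rng.normal(size=n_cell)
        cfg = CorrectionConfig(covariates=("acq_order",), seed=7)
        preds = []
        for cell_values in (z_cell, z_cell[::-1] * 3.0):
            z = z_table(meta, {"f1": np.concatenate([z_qc, cell_values])})
            models = fit_drift_models(z, meta, cfg)
            preds.append(models.predict(meta)["f1"].to_numpy())
        assert np.array_equal(preds[0], preds[1])


class TestApplyCorrection:
    def test_constant_shift_removed(self):
        meta = qc_meta(10)
        z = z_table(meta, {"f1": np.ones(10)})
        cfg = CorrectionConfig(covariates=("acq_order",), seed=0)
        models = fit_drift_models(z, meta, cfg)
        table = FeatureTable(pd.DataFrame({"f1": np.ones(10) * 5}, index=meta["sample_id"]))
        ds = Dataset(table, meta)
        result = apply_correction(z, models, ds)
        assert np.all(np.abs(result.corrected_z.z["f1"]) < 0.15)

    def test_unseen_batch_is_error(self):
        meta = qc_meta(10)
        z = z_table(meta, {"f1": np.zeros(10)})
        cfg = CorrectionConfig(covariates=("acq_order", "batch"), seed=0)
        models = fit_drift_models(z, meta, cfg)
        other = qc_meta(4, batch="b9")
        with pytest.raises(ValidationError, match="unseen"):
            models.predict(other)


class TestRunNormSVR:
    @pytest.fixture(scope="class")
    def small_study(self):
        from normsvr import SyntheticConfig, generate_dataset

        cfg = SyntheticConfig(
            n_cells_per_batch=16, n_batches=2, n_regions_per_batch=2, n_features=12, seed=42
        )
        return generate_dataset(cfg)

    def test_deterministic_given_seed(self, small_study):
        ds, _ = small_study
        cfg = CorrectionConfig(c_grid=(1.0, 10.0), epsilon_grid=(0.05,), gamma_grid=("scale",), seed=9)
        r1 = run_norm_svr(ds, cfg)
        r2 = run_norm_svr(ds, cfg)
        assert np.array_equal(
            r1.corrected.intensities.to_numpy(), r2.corrected.intensities.to_numpy()
        )

    def test_no_drift_no_noise_near_identity(self):
        from normsvr import SyntheticConfig, generate_dataset

        cfg = SyntheticConfig(
            n_cells_per_batch=16, n_batches=1, n_regions_per_batch=1, n_features=8,
            drift_amplitude=0.0, tech_cv=0.05, bio_cv=0.5, seed=7,
        )
        ds, _ = generate_dataset(cfg)
        result = run_norm_svr(ds, CorrectionConfig(seed=7))
        # QC z-scores are pure noise: fitted drift must stay inside a small band
        assert float(result.drift.abs().to_numpy().mean()) < 0.5

    def test_correction_reduces_qc_rsd(self, small_study):
        ds, gt = small_study
        result = run_norm_svr(ds, CorrectionConfig(seed=1))
        d = result.diagnostics.dropna()
        drifted = [f for f in gt.drifted_features if f in d.index]
        improved = (d.loc[drifted, "qc_rsd_after"] < d.loc[drifted, "qc_rsd_before"]).mean()
        assert improved >= 0.9

    def test_per_batch_stats_mode_runs(self, small_study):
        ds, _ = small_study
        cfg = CorrectionConfig(
            c_grid=(1.0,), epsilon_grid=(0.05,), gamma_grid=("scale",),
            stats_scope="per_batch", seed=3,
        )
        result = run_norm_svr(ds, cfg)
        assert result.corrected.intensities.shape[0] == ds.intensities.shape[0]
        assert result.models.scope == "per_batch"
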