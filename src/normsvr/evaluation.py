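"""Diagnostic battery for judging a correction: RSD distributions, PCA,
correlation structure, rank preservation, LOESS ion trends, batch mixing.

The repeatability of QC samples is summarized by per-feature relative
standard deviations (RSD, %); drift or batch structure shows up as
separated clusters in PCA score space and as block structure in the
sample-sample Pearson matrix; whether a correction preserved biology is
judged by per-sample Spearman rank correlation between the uncorrected and
corrected feature vectors, and by the linearity of per-sample log10 mean
intensities before vs after.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import silhouette_score
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_tables import Dataset, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# RSD
# ---------------------------------------------------------------------------

@dataclass
class RSDSummary:
    """Per-feature RSD (%) for one sample role, with distribution summaries.

    Zero-mean features get RSD = +inf; they are excluded from every
    fraction-below denominator and listed in ``infinite_features``.
    """

    role: str
    rsd: pd.Series  # % ; may contain +inf
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    cumulative_x: np.ndarray
    cumulative_y: np.ndarray
    infinite_features: list

    @property
    def finite(self) -> pd.Series:
        return self.rsd[np.isfinite(self.rsd)]

    def median(self) -> float:
        return float(self.finite.median())


def compute_rsd(
    ds: Dataset, role: str, bin_width: float = 10.0, hist_max: float = 200.0
) -> RSDSummary:
    """RSD_j = 100·sd_j/mean_j over rows of the requested role (sample sd)."""
    mask = (ds.meta["role"] == role).to_numpy()
    if mask.sum() < 2:
        raise ValidationError(f"need >= 2 rows of role {role!r}, got {int(mask.sum())}")
    sub = ds.intensities.loc[mask]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = (100.0 * sd / mean).where(mean != 0, np.inf)
    infinite = sorted(rsd.index[~np.isfinite(rsd)])
    if infinite:
        logger.info("%d zero-mean feature(s) with infinite RSD (role=%s)", len(infinite), role)
    finite = rsd[np.isfinite(rsd)].to_numpy()
    edges = np.arange(0.0, hist_max + bin_width, bin_width)
    counts, _ = np.histogram(np.clip(finite, 0, None), bins=edges)
    overflow = int((finite >= hist_max).sum())
    edges = np.append(edges, np.inf)
    counts = np.append(counts, overflow)
    xs = np.sort(finite)
    ys = np.arange(1, len(xs) + 1) / len(xs) if len(xs) else np.array([])
    return RSDSummary(
        role=role,
        rsd=rsd,
        hist_edges=edges,
        hist_counts=counts,
        cumulative_x=xs,
        cumulative_y=ys,
        infinite_features=infinite,
    )


def fraction_below(summary: RSDSummary, threshold_pct: float) -> float:
    """Fraction of finite-RSD features with RSD strictly below the threshold."""
    if threshold_pct <= 0:
        raise ValidationError("threshold must be positive")
    finite = summary.finite
    if len(finite) == 0:
        return float("nan")
    return float((finite < threshold_pct).mean())


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples × PCs
    explained_variance_pct: np.ndarray
    preprocessing: str


def run_pca(ds_or_matrix, scale_features: bool = True, n_components: int | None = None) -> PCAResult:
    """PCA on mean-centered (and by default unit-variance-scaled) features.

    Scaling to unit variance makes raw and normalized tables comparable in
    the same convention (correlation PCA).  Component signs are fixed by
    making each component's largest-magnitude loading positive, so score
    plots are reproducible.
    """
    if isinstance(ds_or_matrix, Dataset):
        X = ds_or_matrix.intensities
    else:
        X = pd.DataFrame(ds_or_matrix)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValidationError("PCA needs >= 3 samples and >= 2 features")
    values = X.to_numpy(dtype=float)
    centered = values - values.mean(axis=0)
    sd = centered.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValidationError("constant matrix: no variance to decompose")
    if scale_features:
        keep = sd > 0
        if not keep.all():
            logger.info("excluding %d constant feature(s) from scaled PCA", int((~keep).sum()))
        centered = centered[:, keep] / sd[keep]
        prep = "centered+unit-variance"
    else:
        prep = "centered"
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    # fix sign: largest-|loading| entry of each component made positive
    for k in range(len(S)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = S**2 / (centered.shape[0] - 1)
    total = centered.var(axis=0, ddof=1).sum()
    explained = 100.0 * var / total
    scores = U * S
    if n_components is not None:
        scores = scores[:, :n_components]
        explained = explained[:n_components]
    cols = [f"PC{k + 1}" for k in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=cols),
        explained_variance_pct=explained,
        preprocessing=prep,
    )


# ---------------------------------------------------------------------------
# correlation / rank preservation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    pearson: pd.DataFrame  # samples × samples, on the "after" table
    per_sample_spearman: pd.Series
    group_summaries: pd.DataFrame
    log10_fit: dict  # slope, intercept, r_squared


def correlation_report(before: Dataset, after: Dataset) -> CorrelationReport:
    """Sample-sample Pearson on the corrected table, per-sample Spearman
    between each sample's feature vector before vs after, and the OLS fit of
    log10 per-sample mean intensity (after vs before)."""
    if before.intensities.shape != after.intensities.shape or list(
        before.intensities.index
    ) != list(after.intensities.index):
        raise ValidationError("before/after tables must share samples and features")
    A = after.intensities.to_numpy(dtype=float)
    B = before.intensities.to_numpy(dtype=float)
    ids = after.intensities.index
    pearson = pd.DataFrame(np.corrcoef(A), index=ids, columns=ids)
    np.fill_diagonal(pearson.values, 1.0)
    spear = pd.Series(
        [sps.spearmanr(B[i], A[i]).statistic for i in range(len(ids))], index=ids
    )
    groups = after.meta.copy()
    groups["spearman"] = spear.to_numpy()
    group_summaries = (
        groups.groupby(["role", "batch", "region"])["spearman"]
        .median()
        .reset_index()
        .rename(columns={"spearman": "median_spearman"})
    )
    mb, ma = B.mean(axis=1), A.mean(axis=1)
    ok = (mb > 0) & (ma > 0)
    if not ok.all():
        logger.warning("excluding %d zero-mean sample(s) from log10 fit", int((~ok).sum()))
    fit = sps.linregress(np.log10(mb[ok]), np.log10(ma[ok]))
    log10_fit = {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
    }
    return CorrelationReport(
        pearson=pearson,
        per_sample_spearman=spear,
        group_summaries=group_summaries,
        log10_fit=log10_fit,
    )


# ---------------------------------------------------------------------------
# LOESS trends and batch mixing
# ---------------------------------------------------------------------------

def loess_trend(
    ds: Dataset, feature, by: str = "acq_order", span: float = 0.75
) -> pd.DataFrame:
    """Tricube-weighted local linear trend of one ion over the sequence.

    Returns a frame with columns x, y, trend sorted by x.
    """
    if feature not in ds.intensities.columns:
        raise ValidationError(f"feature {feature!r} not found")
    if by == "acq_order":
        x = ds.meta["acq_order"].to_numpy(dtype=float)
    elif by == "sample_index":
        x = np.arange(len(ds.meta), dtype=float)
    else:
        raise ValidationError(f"unknown covariate {by!r}")
    y = ds.intensities[feature].to_numpy(dtype=float)
    if len(y) < 5:
        raise ValidationError("need >= 5 points for a LOESS trend")
    smoothed = lowess(y, x, frac=span, it=0, return_sorted=True)
    order = np.argsort(x, kind="stable")
    return pd.DataFrame(
        {"x": smoothed[:, 0], "y": y[order], "trend": smoothed[:, 1]}
    )


REPORT_FILES = (
    "rsd_qc.csv",
    "rsd_cell.csv",
    "rsd_summary.csv",
    "pca_scores.csv",
    "pca_variance.csv",
    "pearson.csv",
    "spearman_per_sample.csv",
    "log10_fit.csv",
)

RSD_THRESHOLDS = (10.0, 20.0, 30.0, 50.0, 100.0)


def write_report(
    before: Dataset,
    after: Dataset,
    outdir,
    make_figures: bool = True,
    loess_features: int = 5,
) -> dict:
    """Write the full diagnostic report for a before/after pair.

    Emits eight CSV tables (QC and cell RSD, fraction-below summary, PCA
    scores and explained variance, sample Pearson matrix, per-sample
    Spearman, log10 mean-intensity fit) plus score-plot / RSD / heatmap /
    trend figures.  Returns the headline numbers as a dict.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # a correction may drop features (zero-sigma screen): compare on the
    # common set, keeping the corrected table's column order
    if list(after.intensities.columns) != list(before.intensities.columns):
        common = [c for c in after.intensities.columns if c in set(before.intensities.columns)]
        if not common:
            raise ValidationError("before/after tables share no features")
        before = before.with_intensities(before.intensities[common])
        after = after.with_intensities(after.intensities[common])

    summaries = {}
    rsd_rows = []
    for role, fname in (("qc", "rsd_qc.csv"), ("cell", "rsd_cell.csv")):
        per_ds = {}
        for tag, ds in (("before", before), ("after", after)):
            s = compute_rsd(ds, role)
            per_ds[tag] = s
            for thr in RSD_THRESHOLDS:
                rsd_rows.append(
                    {
                        "role": role,
                        "stage": tag,
                        "threshold_pct": thr,
                        "fraction_below": fraction_below(s, thr),
                    }
                )
        pd.DataFrame(
            {"rsd_before": per_ds["before"].rsd, "rsd_after": per_ds["after"].rsd}
        ).rename_axis("feature_id").to_csv(outdir / fname)
        summaries[role] = per_ds
    pd.DataFrame(rsd_rows).to_csv(outdir / "rsd_summary.csv", index=False)

    pca_before = run_pca(before)
    pca_after = run_pca(after)
    scores = pca_after.scores.iloc[:, :5].copy()
    scores.insert(0, "sample_id", scores.index)
    scores.to_csv(outdir / "pca_scores.csv", index=False)
    pd.DataFrame(
        {
            "component": [f"PC{k+1}" for k in range(len(pca_after.explained_variance_pct))],
            "explained_variance_pct_after": pca_after.explained_variance_pct,
            "explained_variance_pct_before": pca_before.explained_variance_pct,
        }
    ).to_csv(outdir / "pca_variance.csv", index=False)

    corr = correlation_report(before, after)
    corr.pearson.rename_axis("sample_id").to_csv(outdir / "pearson.csv")
    corr.per_sample_spearman.rename("spearman").rename_axis("sample_id").to_csv(
        outdir / "spearman_per_sample.csv"
    )
    pd.DataFrame([corr.log10_fit]).to_csv(outdir / "log10_fit.csv", index=False)

    headline = {
        "qc_rsd_median_before": summaries["qc"]["before"].median(),
        "qc_rsd_median_after": summaries["qc"]["after"].median(),
        "qc_fraction_rsd_lt30_before": fraction_below(summaries["qc"]["before"], 30.0),
        "qc_fraction_rsd_lt30_after": fraction_below(summaries["qc"]["after"], 30.0),
        "pc1_variance_pct_before": float(pca_before.explained_variance_pct[0]),
        "pc1_variance_pct_after": float(pca_after.explained_variance_pct[0]),
        "median_spearman": float(corr.per_sample_spearman.median()),
        "log10_fit_r_squared": corr.log10_fit["r_squared"],
    }
    for label in ("batch", "region"):
        if before.meta[label].nunique() >= 2 and before.meta[label].value_counts().min() >= 2:
            headline[f"{label}_silhouette_before"] = batch_mixing_score(
                pca_before, before.meta[label]
            )
            headline[f"{label}_silhouette_after"] = batch_mixing_score(
                pca_after, after.meta[label]
            )
    if make_figures:
        _render_figures(before, after, pca_before, pca_after, corr, summaries, outdir, loess_features)
    return headline


def _render_figures(before, after, pca_before, pca_after, corr, summaries, outdir, loess_features):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    label = "batch" if before.meta["batch"].nunique() > 1 else "region"

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, pca, title in ((axes[0], pca_before, "before"), (axes[1], pca_after, "after")):
        for lv in sorted(before.meta[label].unique()):
            m = (before.meta[label] == lv).to_numpy()
            ax.scatter(pca.scores.iloc[m, 0], pca.scores.iloc[m, 1], s=12, label=str(lv))
        qc = (before.meta["role"] == "qc").to_numpy()
        ax.scatter(pca.scores.iloc[qc, 0], pca.scores.iloc[qc, 1], s=24, marker="x", c="k", label="QC")
        ax.set_xlabel(f"PC1 ({pca.explained_variance_pct[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({pca.explained_variance_pct[1]:.1f}%)")
        ax.set_title(title)
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "pca_scores.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    for row, role in enumerate(("qc", "cell")):
        for col, tag in enumerate(("before", "after")):
            s = summaries[role][tag]
            axes[row, col].hist(np.clip(s.finite, 0, 200), bins=20, range=(0, 200))
            axes[row, col].set_title(f"{role} RSD, {tag}")
            axes[row, col].set_xlabel("RSD (%)")
    fig.tight_layout()
    fig.savefig(outdir / "rsd_hist.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(corr.pearson.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title("sample-sample correlation (after)")
    fig.tight_layout()
    fig.savefig(outdir / "pearson_heatmap.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 3.5))
    spear = corr.per_sample_spearman
    colors = {lv: f"C{k}" for k, lv in enumerate(sorted(before.meta[label].unique()))}
    ax.scatter(
        range(len(spear)), spear,
        c=[colors[lv] for lv in before.meta[label]], s=14,
    )
    ax.set_xlabel("sample index")
    ax.set_ylabel("Spearman r (before vs after)")
    ax.set_ylim(min(0.9, float(spear.min()) - 0.02), 1.005)
    fig.tight_layout()
    fig.savefig(outdir / "spearman_per_sample.png", dpi=120)
    plt.close(fig)

    cols = list(after.intensities.columns[:loess_features])
    if cols:
        fig, axes = plt.subplots(len(cols), 1, figsize=(7, 2.2 * len(cols)), squeeze=False)
        for ax, feat in zip(axes[:, 0], cols):
            for ds, tag in ((before, "before"), (after, "after")):
                tr = loess_trend(ds, feat)
                ax.scatter(tr["x"], tr["y"], s=6, alpha=0.5)
                ax.plot(tr["x"], tr["trend"], label=tag)
            ax.set_title(str(feat), fontsize=8)
            ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "loess_trends.png", dpi=120)
        plt.close(fig)


def batch_mixing_score(pca: PCAResult, labels) -> float:
    """Mean silhouette of the labels on the first two PC scores.

    Lower (near zero or negative) means better mixed groups; high positive
    values mean the labels form separated clusters in the score plot.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValidationError("need >= 2 label groups with >= 2 samples each")
    X = pca.scores.iloc[:, :2].to_numpy()
    return float(silhouette_score(X, labels, metric="euclidean"))
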