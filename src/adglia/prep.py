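"""Count filtering, TMM normalization, log-CPM precision weights, sample QC.

The pipeline order mirrors standard bulk RNA-seq practice: abundance filtering
on raw library sizes, between-sample scaling by the trimmed mean of M-values
(TMM), then a log2-CPM transformation whose per-observation precision weights
come from a smoothed mean-variance trend (the voom construction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)


@dataclass
class WeightedExpression:
    """log2-CPM matrix with inverse-variance precision weights.

    Attributes
    ----------
    log2_cpm : DataFrame, features x samples.
    weights : DataFrame, same shape, finite and strictly positive.
    norm_factors : Series of per-sample TMM factors (geometric mean 1).
    effective_lib_size : Series, library size x norm factor.
    """
    log2_cpm: pd.DataFrame
    weights: pd.DataFrame
    norm_factors: pd.Series
    effective_lib_size: pd.Series

    def __post_init__(self):
        if self.log2_cpm.shape != self.weights.shape:
            raise ValueError("log2_cpm and weights shapes differ")
        w = self.weights.to_numpy()
        if not np.all(np.isfinite(w)) or (w <= 0).any():
            raise ValueError("weights must be finite and > 0")


def cpm(counts: pd.DataFrame, lib_size: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on raw (or supplied) library sizes."""
    if lib_size is None:
        lib_size = counts.sum(axis=0)
    return counts.div(lib_size, axis=1) * 1e6


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million given per-feature effective lengths."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("lengths must be positive for every feature")
    rate = counts.div(lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def filter_features(counts: pd.DataFrame, metric: str = "CPM",
                    threshold: float = 1.0, min_fraction: float = 0.15,
                    lengths: pd.Series | None = None) -> pd.DataFrame:
    """Keep features with ``metric > threshold`` in >= ceil(frac * n) samples.

    The abundance metric is computed on raw library sizes (filtering precedes
    normalization).  Row order is preserved; the operation is idempotent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if metric.upper() == "CPM":
        abundance = cpm(counts)
    elif metric.upper() == "TPM":
        if lengths is None:
            raise ValueError("TPM filtering requires per-feature lengths")
        abundance = tpm(counts, lengths)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    required = math.ceil(min_fraction * counts.shape[1])
    keep = (abundance > threshold).sum(axis=1) >= required
    return counts.loc[keep]


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05) -> pd.Series:
    """Per-sample TMM normalization factors (Robinson-Oshlack).

    M-values (log2 sample/reference abundance ratios) are doubly trimmed --
    by M (default 30% each tail) and by average abundance A (default 5%) --
    and combined with inverse-delta-method variance weights.  The reference
    is the sample whose upper-quartile CPM is closest to the mean upper
    quartile.  Factors are rescaled to geometric mean 1.
    """
    lib = counts.sum(axis=0).astype(float)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total count: {list(zero.index)}")
    x = counts.to_numpy(dtype=float)
    n_feat, n_samp = x.shape
    if n_feat < 2:
        logger.warning("too few features for TMM trimming; "
                       "falling back to library-size-only factors")
        return pd.Series(1.0, index=counts.columns, name="norm_factor")

    rel = x / lib.to_numpy()
    uq = np.array([np.quantile(rel[:, j][rel[:, j] > 0], 0.75)
                   if (rel[:, j] > 0).any() else 0.0 for j in range(n_samp)])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(n_samp)
    ref = x[:, ref_idx]
    lib_ref = lib.iloc[ref_idx]
    for j in range(n_samp):
        obs = x[:, j]
        lib_obs = lib.iloc[j]
        pos = (obs > 0) & (ref > 0)
        if pos.sum() < 2:
            factors[j] = 1.0
            continue
        o, r = obs[pos], ref[pos]
        m = np.log2((o / lib_obs) / (r / lib_ref))
        a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
        # delta-method variance of M
        w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
        finite = np.isfinite(m) & np.isfinite(a) & np.isfinite(w)
        m, a, w = m[finite], a[finite], w[finite]
        if len(m) == 0 or np.max(np.abs(m)) < 1e-6:
            factors[j] = 1.0
            continue
        n = len(m)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & \
               (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0 or w[keep].sum() == 0:
            factors[j] = 1.0
            continue
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def _check_design(design: np.ndarray, names=None) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        names = list(names) if names is not None else \
            [f"col{i}" for i in range(design.shape[1])]
        collinear = []
        kept: list[int] = []
        for i in range(design.shape[1]):
            trial = design[:, kept + [i]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(i)
            else:
                collinear.append(names[i])
        raise ValueError(f"design is rank deficient; collinear columns: {collinear}")


def voom_transform(counts: pd.DataFrame, norm_factors: pd.Series | None = None,
                   design: np.ndarray | pd.DataFrame | None = None,
                   span: float = 0.5) -> WeightedExpression:
    """log2-CPM with precision weights from a smoothed mean-variance trend.

    For each feature a linear model (default: intercept only) is fitted to
    log2-CPM; the square-root residual SD is regressed on average log-count
    with a local-regression smoother (span 0.5).  Predicted square-root SDs at
    the fitted count of each observation give weights ``1 / sd_hat**4``, with
    constant extrapolation beyond the trend's range.
    """
    lib = counts.sum(axis=0).astype(float)
    if norm_factors is None:
        norm_factors = pd.Series(1.0, index=counts.columns)
    eff_lib = lib * norm_factors.reindex(counts.columns)
    y = np.log2((counts.to_numpy(dtype=float) + 0.5)
                / (eff_lib.to_numpy() + 1.0) * 1e6)
    n_feat, n_samp = y.shape

    if design is None:
        X = np.ones((n_samp, 1))
        names = ["intercept"]
    else:
        names = list(design.columns) if isinstance(design, pd.DataFrame) else None
        X = np.asarray(design, dtype=float)
    if X.shape[0] != n_samp:
        raise ValueError("design rows must match number of samples")
    if n_samp <= X.shape[1]:
        raise ValueError("need more samples than covariates")
    _check_design(X, names)

    # per-feature OLS fit (shared design): residual sd and fitted values
    pinv = np.linalg.pinv(X)
    coef = y @ pinv.T                       # features x p
    fitted = coef @ X.T                     # features x samples
    resid = y - fitted
    df_resid = n_samp - X.shape[1]
    sigma = np.sqrt(np.sum(resid ** 2, axis=1) / df_resid)

    amean = y.mean(axis=1)
    sx = amean + np.mean(np.log2(eff_lib.to_numpy() + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)

    ok = np.isfinite(sx) & np.isfinite(sy)
    trend = lowess(sy[ok], sx[ok], frac=span, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-4)

    fitted_cpm = 2.0 ** fitted
    fitted_count = fitted_cpm * (eff_lib.to_numpy() + 1.0)[None, :] * 1e-6
    fitted_logcount = np.log2(fitted_count)
    sqrt_sd_hat = np.interp(fitted_logcount, tx, ty)  # constant beyond ends
    weights = 1.0 / np.maximum(sqrt_sd_hat, 1e-4) ** 4

    idx, cols = counts.index, counts.columns
    return WeightedExpression(
        log2_cpm=pd.DataFrame(y, index=idx, columns=cols),
        weights=pd.DataFrame(weights, index=idx, columns=cols),
        norm_factors=norm_factors.reindex(cols),
        effective_lib_size=eff_lib,
    )


def detect_sample_outliers(log2_cpm: pd.DataFrame | WeightedExpression,
                           sd_cutoff: float = 3.0) -> list[str]:
    """Flag samples by low mean inter-sample expression correlation.

    A sample is an outlier when its mean Pearson correlation with all other
    samples falls more than ``sd_cutoff`` SDs below the across-sample mean of
    that statistic.  Single pass (not iterative).
    """
    if isinstance(log2_cpm, WeightedExpression):
        log2_cpm = log2_cpm.log2_cpm
    if log2_cpm.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    mat = log2_cpm.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(mat.T)
    np.fill_diagonal(cor, np.nan)
    cor = np.nan_to_num(cor, nan=1.0)  # identical samples -> corr 1
    np.fill_diagonal(cor, np.nan)
    mean_cor = np.nanmean(cor, axis=1)
    mu, sd = mean_cor.mean(), mean_cor.std(ddof=1)
    if not np.isfinite(sd_cutoff):
        return []
    if sd == 0:
        return []
    flagged = mean_cor < mu - sd_cutoff * sd
    return [s for s, f in zip(log2_cpm.columns, flagged) if f]
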