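"""Per-feature weighted regression with a random cohort-source intercept.

Each feature's log2-CPM profile is regressed on a phenotype contrast plus
fixed covariates using the voom precision weights; the biobank contributing
each sample enters as a random intercept estimated by REML (profiled over the
variance ratio).  Small-sample degrees of freedom for the contrast use a
Satterthwaite-style approximation from the REML information of the two
variance components.  Downstream utilities: Benjamini-Hochberg adjustment,
Storey's pi1 signal-fraction estimate, and signature comparison (Spearman of
log2 fold changes + Fisher overlap of significant genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class DesignSpec:
    """Model specification for one contrast.

    ``contrast`` names the phenotype column; ``encoding`` is 'binary'
    (case/control two-level factor), 'ordinal' (numeric linear score) or
    'continuous'.  ``covariates`` are fixed-effect columns; ``random_group``
    optionally names the cohort-source column modeled as a random intercept.
    """
    contrast: str
    encoding: str = "binary"
    covariates: list[str] = field(default_factory=list)
    random_group: str | None = None

    def __post_init__(self):
        if self.contrast in self.covariates:
            raise ValueError("contrast column cannot also be a covariate")
        if self.encoding not in {"binary", "ordinal", "continuous"}:
            raise ValueError(f"unknown encoding {self.encoding!r}")


# ---------------------------------------------------------------------------
# single-feature weighted mixed fit (shared with the differential-correlation
# scan, which reuses _fit_weighted_lmm for its interaction contrast)
# ---------------------------------------------------------------------------

def _reml_neg2ll(log_lam: float, y, X, w, Zi, q) -> float:
    lam = np.exp(log_lam)
    return _reml_pieces(lam, y, X, w, Zi, q)[0]


def _reml_pieces(lam, y, X, w, Zi, q):
    """Profiled REML criterion and GLS pieces for V0 = W^-1 + lam Z Z'.

    Uses the Woodbury identity; Zi is the per-sample group index.
    """
    n, p = X.shape
    if lam <= 0:
        Vinv_y = w * y
        Vinv_X = w[:, None] * X
        logdet = -np.sum(np.log(w))
    else:
        # Z' W Z is diagonal (indicator Z): entries = group-summed weights
        gw = np.bincount(Zi, weights=w, minlength=q)
        mid = 1.0 / lam + gw                     # (I/lam + Z'WZ) diagonal
        def apply_vinv(v):
            wv = w * v
            gs = np.bincount(Zi, weights=wv, minlength=q)
            return wv - w * (gs / mid)[Zi]
        Vinv_y = apply_vinv(y)
        Vinv_X = np.column_stack([apply_vinv(X[:, j]) for j in range(p)])
        logdet = -np.sum(np.log(w)) + np.sum(np.log1p(lam * gw))
    B = X.T @ Vinv_X
    b = X.T @ Vinv_y
    try:
        L = np.linalg.cholesky(B)
    except np.linalg.LinAlgError:
        return np.inf, None
    beta = np.linalg.solve(L.T, np.linalg.solve(L, b))
    r = y - X @ beta
    if lam <= 0:
        Vinv_r = w * r
    else:
        wr = w * r
        gs = np.bincount(Zi, weights=wr, minlength=q)
        Vinv_r = wr - w * (gs / mid)[Zi]
    qform = float(r @ Vinv_r)
    if qform <= 0:
        return np.inf, None
    sigma2 = qform / (n - p)
    sign, logdetB = np.linalg.slogdet(B)
    crit = (n - p) * np.log(sigma2) + logdet + logdetB
    return crit, (beta, sigma2, B, Vinv_X, Vinv_y)


def _satterthwaite_df(c, X, w, Zi, q, sigma2, tau2):
    """Satterthwaite df for contrast c'beta under Sigma = s2 W^-1 + t2 ZZ'."""
    n, p = X.shape
    Winv = 1.0 / w
    Z = np.zeros((n, q))
    Z[np.arange(n), Zi] = 1.0
    Sigma = sigma2 * np.diag(Winv) + tau2 * (Z @ Z.T)
    Sinv = np.linalg.inv(Sigma)
    SiX = Sinv @ X
    B = X.T @ SiX
    Binv = np.linalg.inv(B)
    P = Sinv - SiX @ Binv @ SiX.T

    derivs = [np.diag(Winv), Z @ Z.T]           # d Sigma / d (sigma2, tau2)
    info = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            info[i, j] = 0.5 * np.trace(P @ derivs[i] @ P @ derivs[j])
    try:
        A = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float(n - p)
    v = float(c @ Binv @ c)
    g = np.empty(2)
    for i in range(2):
        M = Binv @ (SiX.T @ derivs[i] @ SiX) @ Binv
        g[i] = float(c @ M @ c)
    denom = float(g @ A @ g)
    if denom <= 0 or not np.isfinite(denom):
        return float(n - p)
    df = 2.0 * v ** 2 / denom
    return float(np.clip(df, 1.0, n - p))


def _fit_weighted_lmm(y, X, w, groups=None, contrast=None):
    """Weighted linear (mixed) fit of one response.

    Returns dict with beta, se/df/t/p for ``contrast`` (index or vector c),
    plus residuals.  ``groups`` is an integer group index for the random
    intercept; with < 3 levels (or None) the fit is fixed-effects WLS.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    w = np.ones_like(y) if w is None else np.asarray(w, float)
    n, p = X.shape
    if contrast is None:
        contrast = p - 1
    c = np.zeros(p)
    if np.isscalar(contrast):
        c[int(contrast)] = 1.0
    else:
        c = np.asarray(contrast, float)

    if groups is not None:
        Zi = np.asarray(groups)
        levels, Zi = np.unique(Zi, return_inverse=True)
        q = len(levels)
    else:
        Zi, q = None, 0

    if Zi is None or q < 3:
        if Zi is not None and 1 < q < 3:
            logger.warning("random group has %d levels; using fixed-effects fit", q)
        crit, pieces = _reml_pieces(0.0, y, X, w, np.zeros(n, int), 1)
        if pieces is None:
            return None
        beta, sigma2, B, _, _ = pieces
        Binv = np.linalg.inv(B)
        se = float(np.sqrt(sigma2 * c @ Binv @ c))
        df = float(n - p)
        lam_hat, tau2 = 0.0, 0.0
    else:
        res = optimize.minimize_scalar(
            _reml_neg2ll, bounds=(-12.0, 12.0), method="bounded",
            args=(y, X, w, Zi, q), options={"xatol": 1e-6})
        lam_hat = float(np.exp(res.x))
        crit0 = _reml_pieces(0.0, y, X, w, Zi, q)[0]
        if crit0 <= res.fun:                    # boundary: no source variance
            lam_hat = 0.0
        crit, pieces = _reml_pieces(lam_hat, y, X, w, Zi, q)
        if pieces is None:
            return None
        beta, sigma2, B, _, _ = pieces
        tau2 = lam_hat * sigma2
        Binv = np.linalg.inv(B)
        se = float(np.sqrt(sigma2 * c @ Binv @ c))
        df = _satterthwaite_df(c, X, w, Zi, q, sigma2, tau2)

    est = float(c @ beta)
    if se == 0 or not np.isfinite(se):
        return None
    t = est / se
    pval = 2.0 * stats.t.sf(abs(t), df)
    return {"beta": beta, "estimate": est, "se": se, "df": df, "t": t,
            "p": max(pval, np.finfo(float).tiny), "sigma2": sigma2,
            "tau2": tau2, "resid": y - X @ beta}


# ---------------------------------------------------------------------------
# design construction + per-feature scan
# ---------------------------------------------------------------------------

def build_design(data: pd.DataFrame, spec: DesignSpec):
    """Build (X, contrast_index, groups, kept_samples) from a sample table.

    Binary contrasts keep only case/control samples (control = 0, case = 1);
    ordinal/continuous contrasts keep samples with a finite numeric value.
    Categorical covariates are dummy-encoded (first level dropped).
    """
    y = data[spec.contrast]
    if spec.encoding == "binary":
        keep = y.isin(["case", "control"])
        contrast_vals = (y[keep] == "case").astype(float)
        if contrast_vals.nunique() < 2 or contrast_vals.value_counts().min() < 3:
            raise ValueError("binary contrast needs >= 3 samples per level")
    else:
        vals = pd.to_numeric(y, errors="coerce")
        keep = vals.notna()
        contrast_vals = vals[keep].astype(float)
        if contrast_vals.nunique() < 2:
            raise ValueError("contrast has no variation")
    sub = data.loc[keep]

    cols = [pd.Series(1.0, index=sub.index, name="intercept")]
    for cov in spec.covariates:
        v = sub[cov]
        if pd.api.types.is_numeric_dtype(v):
            cols.append(v.astype(float))
        else:
            dummies = pd.get_dummies(v, prefix=cov, drop_first=True, dtype=float)
            cols.extend(dummies[c] for c in dummies.columns)
    cols.append(contrast_vals.rename(spec.contrast))
    X = pd.concat(cols, axis=1)

    groups = None
    if spec.random_group is not None:
        g = sub[spec.random_group]
        if g.nunique() < 1:
            raise ValueError("random_group has no levels")
        groups = g.to_numpy()
    return X, X.shape[1] - 1, groups, sub.index


def fit_de(expr, data: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    """Per-feature weighted (mixed) regression for one contrast.

    ``expr`` is a :class:`~adglia.prep.WeightedExpression` (or a bare
    log2-CPM DataFrame, in which case unit weights are used).  Returns a
    DataFrame indexed by feature with columns ``logFC, se, df, t, p, fdr,
    avg_expr, reason`` (``reason`` is non-empty for features whose fit
    failed; those rows carry NaNs and are excluded from BH).
    """
    from .prep import WeightedExpression  # local import to avoid cycle
    if isinstance(expr, WeightedExpression):
        log2_cpm, weights = expr.log2_cpm, expr.weights
    else:
        log2_cpm, weights = expr, None

    X_df, c_idx, groups, samples = build_design(data, spec)
    missing = [s for s in samples if s not in log2_cpm.columns]
    if missing:
        raise ValueError(f"samples missing from expression matrix: {missing[:5]}")
    Y = log2_cpm[samples].to_numpy(dtype=float)
    W = None if weights is None else weights[samples].to_numpy(dtype=float)
    X = X_df.to_numpy(dtype=float)

    from .prep import _check_design
    _check_design(X, X_df.columns)

    records = []
    for i, feat in enumerate(log2_cpm.index):
        w = None if W is None else W[i]
        fit = _fit_weighted_lmm(Y[i], X, w, groups=groups, contrast=c_idx)
        if fit is None:
            records.append((feat, np.nan, np.nan, np.nan, np.nan, np.nan,
                            float(np.mean(Y[i])), "singular_fit"))
            continue
        records.append((feat, fit["estimate"], fit["se"], fit["df"], fit["t"],
                        fit["p"], float(np.mean(Y[i])), ""))
    out = pd.DataFrame.from_records(
        records, columns=["feature", "logFC", "se", "df", "t", "p",
                          "avg_expr", "reason"]).set_index("feature")
    ok = out["p"].notna()
    out["fdr"] = np.nan
    out.loc[ok, "fdr"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out[["logFC", "se", "df", "t", "p", "fdr", "avg_expr", "reason"]]


def residuals_from_design(expr, data: pd.DataFrame, spec: DesignSpec,
                          drop_contrast: bool = False) -> pd.DataFrame:
    """Per-feature residual matrix from the same fit used for DE.

    By default the contrast stays in the design, so residuals have all
    modeled effects removed (the input the transcript-correlation estimate
    expects).  With ``drop_contrast`` the phenotype term is excluded and the
    residuals retain the disease signal (useful for trajectory input that
    keeps selected coefficients).
    """
    from .prep import WeightedExpression
    if isinstance(expr, WeightedExpression):
        log2_cpm, weights = expr.log2_cpm, expr.weights
    else:
        log2_cpm, weights = expr, None
    X_df, c_idx, groups, samples = build_design(data, spec)
    if drop_contrast:
        X_df = X_df.drop(columns=[X_df.columns[c_idx]])
    X = X_df.to_numpy(float)
    Y = log2_cpm[samples].to_numpy(float)
    W = None if weights is None else weights[samples].to_numpy(float)
    out = np.empty_like(Y)
    for i in range(Y.shape[0]):
        w = None if W is None else W[i]
        fit = _fit_weighted_lmm(Y[i], X, w, groups=groups, contrast=X.shape[1] - 1)
        out[i] = fit["resid"] if fit is not None else np.nan
    return pd.DataFrame(out, index=log2_cpm.index, columns=samples)


# ---------------------------------------------------------------------------
# multiple testing + signal fraction
# ---------------------------------------------------------------------------

def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_pi1(p: np.ndarray,
               lambda_grid: np.ndarray | None = None) -> float:
    """Storey's pi1 = 1 - pi0, the estimated fraction of non-null tests.

    pi0(lambda) = #{p > lambda} / (n (1 - lambda)) is evaluated over the
    grid, smoothed with a precision-weighted cubic least-squares fit (the
    binomial variance of the tail count grows like 1/(1 - lambda), so
    weights are sqrt(1 - lambda)), and read off at the largest lambda; the
    result is clipped to [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) < 100:
        logger.warning("pi1 estimated from only %d p-values", len(p))
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.951, 0.05)
    lam = np.asarray(lambda_grid, float)
    n = len(p)
    pi0 = np.array([(p > l).sum() / (n * (1.0 - l)) for l in lam])
    coef = np.polyfit(lam, pi0, deg=3, w=np.sqrt(1.0 - lam))
    pi0_hat = float(np.polyval(coef, lam.max()))
    pi0_hat = float(np.clip(pi0_hat, 0.0, 1.0))
    return 1.0 - pi0_hat


def compare_signatures(a: pd.DataFrame, b: pd.DataFrame,
                       fdr_threshold: float = 0.05):
    """Spearman correlation of log2FC plus Fisher overlap of significant sets.

    Returns ``(spearman_r, odds_ratio, fisher_p)`` over the shared features.
    """
    shared = a.index.intersection(b.index)
    if len(shared) < 10:
        raise ValueError("need >= 10 shared features")
    fa, fb = a.loc[shared], b.loc[shared]
    rho = stats.spearmanr(fa["logFC"], fb["logFC"]).statistic
    siga = fa["fdr"] <= fdr_threshold
    sigb = fb["fdr"] <= fdr_threshold
    table = [[int((siga & sigb).sum()), int((siga & ~sigb).sum())],
             [int((~siga & sigb).sum()), int((~siga & ~sigb).sum())]]
    odds, pval = stats.fisher_exact(table)
    return float(rho), float(odds), float(pval)
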