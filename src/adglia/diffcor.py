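"""Differential gene-gene correlation around an anchor gene.

For an anchor gene (e.g. *PTPRG*) and each partner gene, the partner's
expression is regressed on group-specific anchor slopes (separate slope for
case and control samples) plus the standard covariates; the interaction
p-value tests equality of the two slopes.  Direction calls compare the
absolute within-group correlations of covariate-residualized expression:
``stronger_in_case`` vs ``stronger_in_control``.  The scan is summarized by
Storey's pi1 (fraction of the transcriptome with an altered anchor
relationship) and by the fraction of significant partners whose correlation
is stronger in controls.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .de import _fit_weighted_lmm, bh_adjust, storey_pi1
from .prep import WeightedExpression, _check_design

logger = logging.getLogger(__name__)


def residualize(expr: pd.DataFrame, covariates: pd.DataFrame,
                weights: pd.DataFrame | None = None,
                add_intercept: bool = True) -> pd.DataFrame:
    """Per-feature residuals from (weighted) regression on covariates only.

    ``expr`` is features x samples; ``covariates`` is samples x p.  With no
    weights a single shared projection is used; per-feature weights trigger
    per-feature WLS fits.
    """
    samples = expr.columns
    X = covariates.loc[samples].to_numpy(float)
    if add_intercept:
        X = np.column_stack([np.ones(len(samples)), X])
        names = ["intercept", *covariates.columns]
    else:
        names = list(covariates.columns)
    _check_design(X, names)
    Y = expr.to_numpy(float)
    if weights is None:
        pinv = np.linalg.pinv(X)
        resid = Y - (Y @ pinv.T) @ X.T
    else:
        W = weights[samples].to_numpy(float)
        resid = np.empty_like(Y)
        for i in range(Y.shape[0]):
            w = W[i]
            Xw = X * w[:, None]
            beta = np.linalg.solve(X.T @ Xw, Xw.T @ Y[i])
            resid[i] = Y[i] - X @ beta
    return pd.DataFrame(resid, index=expr.index, columns=samples)


def diffcor_scan(expr, anchor: str, group: pd.Series,
                 covariates: pd.DataFrame | None = None,
                 random_group: pd.Series | None = None,
                 use_weights: bool = True) -> pd.DataFrame:
    """Interaction scan: does each partner's anchor slope differ by group?

    ``expr`` is a :class:`WeightedExpression` or log2-CPM DataFrame;
    ``group`` holds 'case'/'control' per sample (others dropped).  The anchor
    enters as its covariate-residualized profile; the model per partner is
    ``partner ~ anchor:case + anchor:control + covariates`` with a Wald test
    of slope equality.  With ``random_group`` the cohort source is modeled
    as a random intercept (slower, per-partner REML).
    """
    if isinstance(expr, WeightedExpression):
        log2_cpm = expr.log2_cpm
        weights = expr.weights if use_weights else None
    else:
        log2_cpm, weights = expr, None

    keep = group.isin(["case", "control"])
    samples = group.index[keep].intersection(log2_cpm.columns)
    g = group.loc[samples]
    n_case, n_ctrl = int((g == "case").sum()), int((g == "control").sum())
    if min(n_case, n_ctrl) < 10:
        raise ValueError("need >= 10 samples in each group")
    if anchor not in log2_cpm.index:
        raise ValueError(f"anchor {anchor!r} not in expression matrix")

    Y_all = log2_cpm[samples]
    cov = covariates.loc[samples] if covariates is not None \
        else pd.DataFrame(index=samples)
    anchor_raw = Y_all.loc[[anchor]]
    if float(anchor_raw.iloc[0].std()) == 0:
        raise ValueError("anchor expression is constant")
    a_res = residualize(anchor_raw, cov).iloc[0].to_numpy(float)

    case_ind = (g == "case").to_numpy(float)
    ctrl_ind = 1.0 - case_ind
    Xcols = [a_res * case_ind, a_res * ctrl_ind, np.ones(len(samples))]
    names = ["anchor:case", "anchor:control", "intercept"]
    for c in cov.columns:
        v = cov[c]
        if pd.api.types.is_numeric_dtype(v):
            Xcols.append(v.to_numpy(float))
            names.append(c)
        else:
            dm = pd.get_dummies(v, prefix=c, drop_first=True, dtype=float)
            for dc in dm.columns:
                Xcols.append(dm[dc].to_numpy())
                names.append(dc)
    X = np.column_stack(Xcols)
    _check_design(X, names)
    n, p = X.shape
    contrast = np.zeros(p)
    contrast[0], contrast[1] = 1.0, -1.0

    partners = [f for f in log2_cpm.index if f != anchor]
    # drop features constant within a group
    sub = Y_all.loc[partners]
    const = ((sub.loc[:, g == "case"].std(axis=1) == 0)
             | (sub.loc[:, g == "control"].std(axis=1) == 0))
    if const.any():
        logger.warning("dropping %d partner(s) constant within a group",
                       int(const.sum()))
        partners = [f for f, c in zip(partners, const) if not c]

    Y = Y_all.loc[partners].to_numpy(float)
    W = None if weights is None else weights[samples].loc[partners].to_numpy(float)
    groups_arr = None if random_group is None \
        else random_group.loc[samples].to_numpy()

    if W is None and groups_arr is None:
        # vectorized multi-response OLS
        XtX_inv = np.linalg.inv(X.T @ X)
        H = XtX_inv @ X.T
        B = Y @ H.T                              # partners x p
        resid = Y - B @ X.T
        dof = n - p
        sigma2 = np.sum(resid ** 2, axis=1) / dof
        cvar = float(contrast @ XtX_inv @ contrast)
        delta = B @ contrast
        se = np.sqrt(sigma2 * cvar)
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = delta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
        slope_case, slope_ctrl = B[:, 0], B[:, 1]
        dfs = np.full(len(partners), float(dof))
    else:
        slope_case = np.empty(len(partners))
        slope_ctrl = np.empty(len(partners))
        delta = np.empty(len(partners))
        pvals = np.empty(len(partners))
        dfs = np.empty(len(partners))
        for i in range(len(partners)):
            w = None if W is None else W[i]
            fit = _fit_weighted_lmm(Y[i], X, w, groups=groups_arr,
                                    contrast=contrast)
            if fit is None:
                slope_case[i] = slope_ctrl[i] = delta[i] = np.nan
                pvals[i] = np.nan
                dfs[i] = np.nan
                continue
            slope_case[i], slope_ctrl[i] = fit["beta"][0], fit["beta"][1]
            delta[i] = fit["estimate"]
            pvals[i] = fit["p"]
            dfs[i] = fit["df"]

    # residualized within-group correlations
    resid_expr = residualize(Y_all.loc[partners], cov)
    a_case = a_res[case_ind == 1]
    a_ctrl = a_res[case_ind == 0]
    Rc = resid_expr.loc[:, g == "case"].to_numpy(float)
    Rt = resid_expr.loc[:, g == "control"].to_numpy(float)

    def _cor_with(anchor_vec, M):
        ac = anchor_vec - anchor_vec.mean()
        Mc = M - M.mean(axis=1, keepdims=True)
        num = Mc @ ac
        den = np.sqrt((Mc ** 2).sum(axis=1) * (ac ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            return num / den

    r_case = _cor_with(a_case, Rc)
    r_ctrl = _cor_with(a_ctrl, Rt)
    direction = np.where(np.abs(r_case) >= np.abs(r_ctrl),
                         "stronger_in_case", "stronger_in_control")

    out = pd.DataFrame({
        "slope_case": slope_case,
        "slope_control": slope_ctrl,
        "delta": delta,
        "df": dfs,
        "p": np.clip(pvals, np.finfo(float).tiny, 1.0),
        "r_case": r_case,
        "r_control": r_ctrl,
        "direction": direction,
    }, index=pd.Index(partners, name="partner"))
    ok = out["p"].notna()
    out["fdr"] = np.nan
    out.loc[ok, "fdr"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out.sort_values("p")


def summarize_interactome(results: pd.DataFrame,
                          alpha: float = 0.05) -> dict[str, float]:
    """pi1 and direction fractions for a differential-correlation scan.

    Returns ``pi1``, plus the fraction of partners stronger in controls among
    those with p <= alpha and among those with FDR <= alpha (NaN when no
    partner is significant).
    """
    if len(results) < 100:
        raise ValueError("need >= 100 partners for a stable summary")
    p = results["p"].dropna()
    pi1 = storey_pi1(p.to_numpy())

    def _frac(mask):
        sub = results.loc[mask]
        if len(sub) == 0:
            return float("nan")
        return float((sub["direction"] == "stronger_in_control").mean())

    return {
        "pi1": pi1,
        "frac_stronger_in_control_p05": _frac(results["p"] <= alpha),
        "frac_stronger_in_control_fdr05": _frac(results["fdr"] <= alpha),
    }
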