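"""Simulation experiments that measure the toolkit's statistical contracts.

Each function generates data under a stated scenario, runs the package's own
operations, and returns the measured quantity: oracle agreement for the
fixed-effect pooling, type-I error of the omnibus tests under a correlated
null, power separation in the heterogeneous-transcript scenario, effect-size
recovery and calibration of the differential-expression pipeline, pi1
behaviour, differential-correlation null/power, and pseudotime recovery.
These back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import (CohortConfig, DesignSpec, TranscriptEffects, TrajectorySpec,
               bh_adjust, classify_genes, compute_pseudotime, diffcor_scan,
               embed_and_tree, estimate_stat_correlation, fe_corr_meta,
               filter_features, fit_de, harmonize, re2c_corr_meta,
               simulate_cohort, simulate_trajectory_cohort, storey_pi1,
               tmm_factors, voom_transform, assign_branches)


def _equicorrelation(m: int, rho: float) -> np.ndarray:
    R = np.full((m, m), rho)
    np.fill_diagonal(R, 1.0)
    return R


# ---------------------------------------------------------------- FE oracle

def fe_oracle_equivalence(n_problems: int = 1000, seed: int = 0) -> float:
    """Max |difference| between GLS pooling at sigma = I and classic
    inverse-variance fixed-effect meta-analysis (estimate and statistic)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_problems):
        m = int(rng.integers(1, 8))
        beta = rng.normal(0, 1, m)
        se = rng.uniform(0.05, 2.0, m)
        eff = TranscriptEffects("g", [f"t{i}" for i in range(m)],
                                beta, se, np.eye(m))
        stat, _, pooled = fe_corr_meta(eff)
        w = 1.0 / se ** 2
        ivw = np.sum(w * beta) / np.sum(w)
        ivw_stat = ivw ** 2 * np.sum(w)
        worst = max(worst, abs(pooled - ivw), abs(stat - ivw_stat))
    return worst


# ------------------------------------------------------- omnibus calibration

def omnibus_null_calibration(n_reps: int = 5000, m: int = 4, rho: float = 0.6,
                             n: int = 100, seed: int = 0,
                             alpha: float = 0.05) -> dict[str, float]:
    """Type-I error of FE and RE2C under a correlated transcript null.

    Per replicate: draw n samples of m equicorrelated transcript profiles
    with no group effect, estimate per-transcript effects/SEs by regression
    on a balanced binary label, estimate the statistic correlation from the
    residuals, and run both omnibus tests.
    """
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(_equicorrelation(m, rho))
    x = rng.permutation(np.repeat([0.0, 1.0], n // 2))
    xc = x - x.mean()
    sxx = float(xc @ xc)
    nu = n - 2
    tx_ids = [f"t{i}" for i in range(m)]
    fe_rej = re_rej = 0
    for _ in range(n_reps):
        Y = rng.normal(0, 1, (n, m)) @ L.T
        beta = (xc @ Y) / sxx
        resid = Y - np.outer(x, beta)
        resid = resid - resid.mean(axis=0)
        se = np.sqrt((resid ** 2).sum(axis=0) / nu / sxx)
        sigma = estimate_stat_correlation(resid.T, shrink=0.05)
        sigma_raw = estimate_stat_correlation(resid.T, shrink=0.0)
        eff = TranscriptEffects("g", tx_ids, beta, se, sigma,
                                sigma_raw=sigma_raw, nu=nu)
        fe_rej += fe_corr_meta(eff)[1] <= alpha
        re_rej += re2c_corr_meta(eff)[1] <= alpha
    return {"fe_type1": fe_rej / n_reps, "re2c_type1": re_rej / n_reps}


# ------------------------------------------------------ heterogeneity power

HET_BETAS = (1.0 / 3, 1.0 / 3, 1.0 / 3, -1.0)   # mean ~ 0, one flipped


def heterogeneity_power(n_reps: int = 1000, se: float = 0.25,
                        rho: float = 0.6, seed: int = 0,
                        alpha: float = 0.05) -> dict[str, float]:
    """Rejection rates when one of four transcripts flips sign (|beta| = 1).

    Effect estimates are drawn from their sampling distribution
    N(beta_true, V); the concordance (FE) test sees a near-zero mean while
    the joint test picks up the heterogeneity.
    """
    rng = np.random.default_rng(seed)
    true = np.asarray(HET_BETAS)
    m = len(true)
    R = _equicorrelation(m, rho)
    ses = np.full(m, se)
    V = np.outer(ses, ses) * R
    L = np.linalg.cholesky(V)
    tx_ids = [f"t{i}" for i in range(m)]
    fe_rej = re_rej = 0
    for _ in range(n_reps):
        bh = true + L @ rng.normal(0, 1, m)
        eff = TranscriptEffects("g", tx_ids, bh, ses, R)
        fe_rej += fe_corr_meta(eff)[1] <= alpha
        re_rej += re2c_corr_meta(eff)[1] <= alpha
    return {"fe_power": fe_rej / n_reps, "re2c_power": re_rej / n_reps,
            "power_gap": (re_rej - fe_rej) / n_reps}


def serpinf1_like_classification(n_reps: int = 200, n: int = 100,
                                 rho: float = 0.6, bio_sd: float = 0.7,
                                 seed: int = 0) -> float:
    """Fraction of replicates classified omnibus_only for a gene whose four
    transcripts carry effects (1/3, 1/3, 1/3, -1): the flipped transcript
    cancels the summed gene-level signal while driving RE2C heterogeneity."""
    rng = np.random.default_rng(seed)
    true = np.asarray(HET_BETAS)
    m = len(true)
    L = np.linalg.cholesky(_equicorrelation(m, rho))
    x = rng.permutation(np.repeat([0.0, 1.0], n // 2))
    xc = x - x.mean()
    sxx = float(xc @ xc)
    nu = n - 2
    tx_ids = [f"t{i}" for i in range(m)]
    omnibus_only = 0
    for _ in range(n_reps):
        latent = bio_sd * (rng.normal(0, 1, (n, m)) @ L.T)
        tx_expr = 5.0 + true[None, :] * x[:, None] + latent
        gene_expr = np.log2((2.0 ** tx_expr).sum(axis=1))

        beta = (xc @ tx_expr) / sxx
        resid = tx_expr - np.outer(x, beta)
        resid = resid - resid.mean(axis=0)
        se = np.sqrt((resid ** 2).sum(axis=0) / nu / sxx)
        sigma = estimate_stat_correlation(resid.T, shrink=0.05)
        sigma_raw = estimate_stat_correlation(resid.T, shrink=0.0)
        eff = TranscriptEffects("g", tx_ids, beta, se, sigma,
                                sigma_raw=sigma_raw, nu=nu)
        _, re_p, _ = re2c_corr_meta(eff)

        gb = float(xc @ gene_expr / sxx)
        gr = gene_expr - x * gb
        gr = gr - gr.mean()
        gse = float(np.sqrt((gr ** 2).sum() / nu / sxx))
        gene_p = 2 * stats.t.sf(abs(gb / gse), nu)

        gene_de = pd.DataFrame({"p": [gene_p]}, index=["g"])
        meta = pd.DataFrame({"re2c_p": [re_p]}, index=["g"])
        omnibus_only += (classify_genes(gene_de, meta).iloc[0]
                         == "omnibus_only")
    return omnibus_only / n_reps


# --------------------------------------------------------------- DE pipeline

def _de_pipeline(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    cohort = simulate_cohort(cfg)
    labels = harmonize(cohort.metadata)
    data = pd.concat([cohort.metadata, labels[["ad_cerad"]]], axis=1)
    kept = filter_features(cohort.gene_counts)
    expr = voom_transform(kept, tmm_factors(kept))
    spec = DesignSpec("ad_cerad", covariates=["sex", "tech_1", "tech_2",
                                              "tech_3"],
                      random_group="source")
    de = fit_de(expr, data, spec)
    truth = cohort.truth_genes.loc[de.index]
    return de, truth


def de_recovery_and_calibration(seed: int = 0, n_donors: int = 180,
                                n_genes: int = 2000) -> dict[str, float]:
    """Effect recovery, null calibration and FDR control of the DE fit.

    Runs the full pipeline (simulation, filtering, TMM, voom, REML fit with
    random source intercept) twice: once with 10% affected genes for the
    recovery slope and empirical FDR, once fully null for the p <= 0.05
    fraction.
    """
    cfg = CohortConfig(n_donors=n_donors, n_genes=n_genes,
                       affected_fraction=0.1, source_effect_sd=0.5,
                       seed=seed)
    de, truth = _de_pipeline(cfg)
    ok = de["p"].notna()
    slope = float(np.polyfit(truth.loc[ok, "true_log2fc"],
                             de.loc[ok, "logFC"], 1)[0])
    disc = de.index[(de["fdr"] <= 0.05) & ok]
    null_gene = truth["true_log2fc"].abs() < 1e-9
    emp_fdr = float(null_gene.loc[disc].mean()) if len(disc) else 0.0

    null_cfg = CohortConfig(n_donors=n_donors, n_genes=n_genes,
                            affected_fraction=0.0, source_effect_sd=0.5,
                            seed=seed + 1)
    de0, _ = _de_pipeline(null_cfg)
    p0 = de0["p"].dropna()
    return {"recovery_slope": slope,
            "empirical_fdr": emp_fdr,
            "n_discoveries": int(len(disc)),
            "null_p05_fraction": float((p0 <= 0.05).mean()),
            "n_genes_tested": int(ok.sum())}


# ----------------------------------------------------------------------- pi1

def pi1_benchmarks(seed: int = 0, n: int = 10_000) -> dict[str, float]:
    """pi1 on a uniform null and on a 30% Beta(0.1, 1) mixture."""
    rng = np.random.default_rng(seed)
    uniform = storey_pi1(rng.uniform(0, 1, n))
    k = int(0.3 * n)
    mix = np.concatenate([rng.beta(0.1, 1.0, k), rng.uniform(0, 1, n - k)])
    return {"pi1_uniform": float(uniform),
            "pi1_mixture": float(storey_pi1(mix))}


# ---------------------------------------------------- differential correlation

def _diffcor_frame(rng, n_per: int, n_partners: int, planted: bool):
    n = 2 * n_per
    samples = [f"s{i}" for i in range(n)]
    anchor = rng.normal(0, 1, n)
    Y = 0.3 * anchor[None, :] + rng.normal(0, 1, (n_partners, n))
    if planted:
        Y[0] = rng.normal(0, 1, n)
        Y[0, n_per:] = anchor[n_per:] + 0.5 * rng.normal(0, 1, n_per)
    expr = pd.DataFrame(np.vstack([anchor, Y]),
                        index=["ANCHOR"] + [f"g{i}" for i in range(n_partners)],
                        columns=samples)
    group = pd.Series(["case"] * n_per + ["control"] * n_per, index=samples)
    return expr, group


def diffcor_null_uniformity(seed: int = 0, n_partners: int = 500,
                            n_per: int = 100) -> float:
    """KS uniformity p-value of the scan under permuted group labels."""
    rng = np.random.default_rng(seed)
    expr, group = _diffcor_frame(rng, n_per, n_partners, planted=False)
    permuted = pd.Series(rng.permutation(group.to_numpy()), index=group.index)
    res = diffcor_scan(expr, "ANCHOR", permuted)
    return float(stats.kstest(res["p"].to_numpy(), "uniform").pvalue)


def diffcor_planted_detection(n_seeds: int = 100, n_per: int = 200,
                              n_partners: int = 150,
                              seed: int = 0) -> float:
    """Fraction of seeds where a control-only anchor coupling is found at
    FDR <= 0.05 with direction stronger_in_control."""
    hits = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 7919 * s)
        expr, group = _diffcor_frame(rng, n_per, n_partners, planted=True)
        res = diffcor_scan(expr, "ANCHOR", group)
        row = res.loc["g0"]
        hits += (row["fdr"] <= 0.05
                 and row["direction"] == "stronger_in_control")
    return hits / n_seeds


# ------------------------------------------------------------------ pseudotime

def pseudotime_linear_recovery(seed: int = 0,
                               n_donors: int = 150) -> dict[str, float]:
    """|Spearman| between fitted pseudotime and the true latent position on a
    single-branch synthetic trajectory."""
    cfg = CohortConfig(n_donors=n_donors, n_genes=400,
                       affected_fraction=0.0, source_effect_sd=0.0,
                       seed=seed,
                       trajectory=TrajectorySpec(n_branches=1, length=10.0,
                                                 n_responsive=200,
                                                 response_scale=3.0))
    co = simulate_trajectory_cohort(cfg)
    expr = _panel_expression(co)
    traj = embed_and_tree(expr, random_state=seed % (2 ** 31))
    pt = compute_pseudotime(traj)
    rho = stats.spearmanr(pt.to_numpy(),
                          co.truth_samples["position"].to_numpy()).statistic
    return {"pseudotime_spearman": float(abs(rho))}


def pseudotime_branch_recovery(seed: int = 0,
                               n_donors: int = 150) -> dict[str, float]:
    """Branch structure recovered from a two-branch (Y) trajectory."""
    cfg = CohortConfig(n_donors=n_donors, n_genes=400,
                       affected_fraction=0.0, source_effect_sd=0.0,
                       seed=seed,
                       trajectory=TrajectorySpec(n_branches=2, length=10.0,
                                                 n_responsive=200,
                                                 response_scale=3.0))
    co = simulate_trajectory_cohort(cfg)
    expr = _panel_expression(co)
    traj = embed_and_tree(expr, random_state=seed % (2 ** 31))
    compute_pseudotime(traj)
    assign_branches(traj, n_clusters=6)
    max_degree = max(d for _, d in traj.tree.degree)
    return {"n_branches": float(traj.branch.nunique()),
            "max_node_degree": float(max_degree)}


def _panel_expression(cohort) -> pd.DataFrame:
    resp = cohort.truth_genes.index[cohort.truth_genes["trajectory_responsive"]]
    log2cpm = np.log2(cohort.gene_counts.div(
        cohort.gene_counts.sum(axis=0), axis=1) * 1e6 + 0.5)
    expr = log2cpm.loc[resp]
    return expr.sub(expr.mean(axis=1), axis=0)
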