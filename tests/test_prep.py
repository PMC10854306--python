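"""Filtering, TMM, voom weights and sample-QC behaviour."""

import numpy as np
import pandas as pd
import pytest

import adglia as ag


def _df(arr, prefix="g"):
    arr = np.asarray(arr)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=[f"s{j}" for j in range(arr.shape[1])])


# ---------------------------------------------------------------------- filter

def test_filter_required_sample_count_rule():
    # 10 samples at 15% -> ceil(1.5) = 2 samples must exceed the threshold
    counts = np.zeros((2, 10), int)
    counts[0, :2] = 1000   # above 1 CPM in exactly 2 samples
    counts[1, :1] = 1000   # only 1 sample
    filler = np.full((1, 10), 10_000)
    df = _df(np.vstack([counts, filler]))
    kept = ag.filter_features(df, "CPM", 1.0, 0.15)
    assert "g0" in kept.index and "g1" not in kept.index


def test_filter_cpm_hand_oracle():
    # library sizes forced to 1e6 so counts == CPM
    n = 10
    g1 = np.full(n, 2)            # 2 CPM everywhere -> kept
    g2 = np.zeros(n, int); g2[0] = 2   # 2 CPM in 1/10 -> dropped
    g3 = np.zeros(n, int)              # all zero -> dropped
    filler = 1_000_000 - (g1 + g2 + g3)
    df = _df(np.vstack([g1, g2, g3, filler]))
    kept = ag.filter_features(df, "CPM", 1.0, 0.15)
    assert "g0" in kept.index
    assert "g1" not in kept.index and "g2" not in kept.index


def test_filter_idempotent(small_cohort):
    once = ag.filter_features(small_cohort.gene_counts)
    twice = ag.filter_features(once)
    assert once.equals(twice)


def test_filter_tpm_requires_lengths(small_cohort):
    with pytest.raises(ValueError, match="lengths"):
        ag.filter_features(small_cohort.gene_counts, metric="TPM")


# ------------------------------------------------------------------------- TMM

def test_tmm_identical_columns_unit_factors():
    col = np.array([10, 200, 3000, 40, 500, 60, 7, 800, 90, 1000])
    df = _df(np.tile(col[:, None], (1, 5)))
    f = ag.tmm_factors(df)
    assert np.allclose(f, 1.0, atol=1e-12)


def test_tmm_matches_edger_reference():
    """Frozen factors computed with edgeR::calcNormFactors on this fixture."""
    rng = np.random.default_rng(42)
    n_genes = 2000
    mu = rng.lognormal(4, 1.5, n_genes)
    lib_mult = np.array([1.0, 2.0, 0.5, 1.0, 1.5, 0.8])
    phi = 0.1
    r = 1 / phi
    mean = mu[:, None] * lib_mult[None, :]
    counts = rng.negative_binomial(n=r, p=r / (r + mean),
                                   size=(n_genes, 6))
    f = ag.tmm_factors(_df(counts))
    expected = [0.995420, 0.970753, 0.990258, 1.040015, 0.986034, 1.019072]
    assert np.allclose(f.to_numpy(), expected, atol=1e-5)


def test_tmm_compensates_pure_depth_doubling():
    rng = np.random.default_rng(3)
    base = rng.negative_binomial(5, 0.05, size=(3000, 4))
    doubled = np.column_stack([base, 2 * base[:, 0]])
    f = ag.tmm_factors(_df(doubled))
    assert abs(f.iloc[4] / f.iloc[0] - 1) < 0.01


def test_tmm_global_rescale_invariant(small_cohort):
    counts = ag.filter_features(small_cohort.gene_counts)
    f1 = ag.tmm_factors(counts)
    f2 = ag.tmm_factors(counts * 3)
    assert np.allclose(f1, f2, atol=1e-10)


def test_tmm_single_feature_falls_back():
    df = _df(np.array([[100, 220, 340]]))
    assert np.allclose(ag.tmm_factors(df), 1.0)


def test_tmm_zero_sample_error():
    df = _df(np.array([[5, 0], [3, 0]]))
    with pytest.raises(ValueError, match="s1"):
        ag.tmm_factors(df)


# ------------------------------------------------------------------------ voom

def test_voom_flat_trend_for_homoskedastic_pseudocounts():
    rng = np.random.default_rng(0)
    mu = rng.uniform(6, 12, 400)
    y = mu[:, None] + rng.normal(0, 0.3, (400, 30))
    counts = _df(np.rint(2.0 ** y).astype(int))
    expr = ag.voom_transform(counts)
    w = expr.weights.to_numpy()
    assert w.max() / w.min() < 2.0


def test_voom_weights_increase_with_expression_for_nb_counts():
    # low-count regime: Poisson noise dominates, so precision rises with mean
    rng = np.random.default_rng(11)
    mu = 2.0 ** rng.uniform(0.5, 6, 500)        # means ~1.4 .. 64
    phi = 0.1
    r = 1 / phi
    counts = rng.negative_binomial(r, r / (r + mu[:, None]), (500, 40))
    expr = ag.voom_transform(_df(counts))
    from scipy.stats import spearmanr
    mean_w = expr.weights.mean(axis=1)
    assert spearmanr(mu, mean_w).statistic > 0.5


def test_voom_scale_invariance_of_log2cpm():
    rng = np.random.default_rng(1)
    counts = rng.poisson(1.2e6, size=(40, 6))
    df = _df(counts)
    doubled = df.copy()
    doubled["s0"] = df["s0"] * 2
    e1 = ag.voom_transform(df, ag.tmm_factors(df))
    e2 = ag.voom_transform(doubled, ag.tmm_factors(doubled))
    diff = (e1.log2_cpm["s0"] - e2.log2_cpm["s0"]).abs().max()
    assert diff < 1e-6


def test_voom_rank_deficient_design_reports_columns(small_cohort):
    counts = ag.filter_features(small_cohort.gene_counts)
    n = counts.shape[1]
    design = pd.DataFrame({"intercept": np.ones(n), "x": np.arange(n),
                           "x_copy": np.arange(n)})
    with pytest.raises(ValueError, match="x_copy"):
        ag.voom_transform(counts, design=design)


# -------------------------------------------------------------------- outliers

def test_outlier_detection_flags_noise_sample():
    rng = np.random.default_rng(7)
    shared = rng.normal(0, 1, 300)
    mat = shared[:, None] + rng.normal(0, 0.3, (300, 50))
    mat[:, 13] = rng.normal(0, 1, 300)          # unrelated sample
    df = _df(mat)
    assert ag.detect_sample_outliers(df) == ["s13"]


def test_outlier_detection_edge_cases():
    df = _df(np.tile(np.arange(20.0)[:, None], (1, 6)))
    assert ag.detect_sample_outliers(df) == []
    rng = np.random.default_rng(0)
    df2 = _df(rng.normal(0, 1, (50, 8)))
    assert ag.detect_sample_outliers(df2, sd_cutoff=np.inf) == []
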