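"""Synthetic-cohort generator: determinism, truth tables, calibration hooks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import adglia as ag
from adglia.simulate import CohortConfigError


def test_same_seed_identical_output(small_cohort):
    other = ag.simulate_cohort(ag.CohortConfig(n_donors=60, n_genes=150,
                                               seed=20240901))
    assert other.gene_counts.equals(small_cohort.gene_counts)
    assert other.transcript_counts.equals(small_cohort.transcript_counts)
    assert other.metadata.equals(small_cohort.metadata)
    third = ag.simulate_cohort(ag.CohortConfig(n_donors=60, n_genes=150,
                                               seed=20240902))
    assert not third.gene_counts.equals(small_cohort.gene_counts)


def test_cohort_structural_invariants(small_cohort):
    co = small_cohort
    counts = co.transcript_counts.to_numpy()
    assert (counts >= 0).all() and np.issubdtype(counts.dtype, np.integer)
    # every transcript maps to exactly one gene; truth covers every feature
    assert co.tx2gene.index.equals(co.transcript_counts.index)
    assert not co.tx2gene.index.has_duplicates
    assert set(co.truth_transcripts.index) == set(co.transcript_counts.index)
    assert set(co.truth_genes.index) == set(co.gene_counts.index)
    # gene counts are the sum of their transcript counts
    summed = co.transcript_counts.groupby(co.tx2gene.values, sort=False).sum()
    assert np.array_equal(summed.loc[co.gene_counts.index].to_numpy(),
                          co.gene_counts.to_numpy())


def test_null_config_gives_zero_truth():
    cfg = ag.CohortConfig(n_donors=30, n_genes=60, affected_fraction=0.0,
                          seed=1)
    co = ag.simulate_cohort(cfg)
    assert np.abs(co.truth_genes["true_log2fc"]).max() < 1e-12
    assert np.abs(co.truth_transcripts["true_log2fc"]).max() < 1e-12


def test_config_validation():
    with pytest.raises(CohortConfigError):
        ag.CohortConfig(n_donors=3).validate()
    with pytest.raises(CohortConfigError):
        ag.CohortConfig(transcript_cor=1.0).validate()
    with pytest.raises(CohortConfigError):
        ag.CohortConfig(case_fraction=1.5).validate()
    with pytest.raises(CohortConfigError):
        ag.CohortConfig(transcripts_per_gene=(0, 3)).validate()
    with pytest.raises(CohortConfigError):
        ag.CohortConfig(library_size=(-1.0, 0.3)).validate()
    with pytest.raises(CohortConfigError):
        cfg = ag.CohortConfig(trajectory=ag.TrajectorySpec(n_branches=0))
        cfg.validate()


def test_phenotypes_rank_correlated_and_age_confounded():
    cfg = ag.CohortConfig(n_donors=800, age_confounding=0.02, seed=2)
    md = ag.simulate_cohort(cfg).metadata
    sub = md.dropna(subset=["cerad", "braak", "cdr"])
    assert stats.spearmanr(sub["cerad"], sub["braak"]).statistic > 0.3
    assert stats.spearmanr(sub["cerad"], sub["cdr"]).statistic > 0.3
    # cases are older on average under positive age confounding
    case_age = md.loc[md["true_case"] == 1, "age"].mean()
    ctrl_age = md.loc[md["true_case"] == 0, "age"].mean()
    assert case_age > ctrl_age


def test_case_fraction_matches_config():
    cfg = ag.CohortConfig(n_donors=500, case_fraction=0.3, seed=3)
    md = ag.simulate_cohort(cfg).metadata
    assert md["true_case"].mean() == pytest.approx(0.3, abs=0.01)


def test_effect_size_realized_in_counts():
    """Case/control mean-CPM ratio matches 2**log2FC (closed-form NB mean)."""
    cfg = ag.CohortConfig(n_donors=2000, n_genes=40,
                          transcripts_per_gene=(1, 1),
                          affected_fraction=0.3, effect_sd=0.6,
                          source_effect_sd=0.0, age_confounding=0.0,
                          seed=4)
    co = ag.simulate_cohort(cfg)
    cpm = ag.cpm(co.gene_counts)
    case = co.metadata["true_case"] == 1
    affected = co.truth_genes.index[co.truth_genes["true_log2fc"].abs() > 0.2]
    for g in affected:
        x1 = cpm.loc[g, case.values].to_numpy()
        x0 = cpm.loc[g, ~case.values].to_numpy()
        log_ratio = np.log2(x1.mean() / x0.mean())
        # MC standard error of the log ratio by the delta method
        se = np.sqrt(x1.var() / (len(x1) * x1.mean() ** 2)
                     + x0.var() / (len(x0) * x0.mean() ** 2)) / np.log(2)
        truth = co.truth_genes.loc[g, "true_log2fc"]
        assert abs(log_ratio - truth) < 3 * se + 0.02


def test_transcript_correlation_recovered():
    """Within-gene residual correlation tracks transcript_cor at low noise."""
    cfg = ag.CohortConfig(n_donors=500, n_genes=120,
                          transcripts_per_gene=(3, 3), transcript_cor=0.6,
                          mean_log_expression=(8.0, 0.5),
                          dispersion=(0.01, 0.1), affected_fraction=0.0,
                          source_effect_sd=0.0, seed=5)
    co = ag.simulate_cohort(cfg)
    log2cpm = np.log2(ag.cpm(co.transcript_counts) + 0.5)
    resid = log2cpm.sub(log2cpm.mean(axis=1), axis=0)
    offs = []
    for gene, txs in co.tx2gene.groupby(co.tx2gene):
        R = np.corrcoef(resid.loc[txs.index].to_numpy())
        offs.extend(R[~np.eye(3, dtype=bool)])
    assert abs(np.mean(offs) - 0.6) < 0.05


def test_null_cohort_t_test_p_uniform():
    # fully null: no disease effect, no source effect, no covariate effects
    cfg = ag.CohortConfig(n_donors=120, n_genes=5000, affected_fraction=0.0,
                          source_effect_sd=0.0, age_confounding=0.0,
                          sex_effect_sd=0.0, tech_effect_sd=0.0, seed=6)
    co = ag.simulate_cohort(cfg)
    kept = ag.filter_features(co.gene_counts)
    log2cpm = np.log2(ag.cpm(kept) + 0.5)
    case = (co.metadata["true_case"] == 1).to_numpy()
    res = stats.ttest_ind(log2cpm.loc[:, case], log2cpm.loc[:, ~case],
                          axis=1, equal_var=False)
    assert stats.kstest(res.pvalue, "uniform").pvalue > 0.01


# ------------------------------------------------------------ trajectory mode

def test_trajectory_requires_spec():
    with pytest.raises(CohortConfigError):
        ag.simulate_trajectory_cohort(ag.CohortConfig(n_donors=30,
                                                      n_genes=40, seed=7))


def test_trajectory_truth_structure_two_branches():
    cfg = ag.CohortConfig(n_donors=150, n_genes=60, seed=8,
                          trajectory=ag.TrajectorySpec(n_branches=2,
                                                       length=10.0,
                                                       n_responsive=40))
    co = ag.simulate_trajectory_cohort(cfg)
    t = co.truth_samples
    assert set(t["branch"].unique()) <= {0, 1, 2}
    # trunk below the split point, branches strictly beyond: one branch point
    assert (t.loc[t["branch"] == 0, "position"] <= 5.0 + 1e-9).all()
    assert (t.loc[t["branch"] > 0, "position"] > 5.0).all()
    assert t["branch"].nunique() == 3
    same = ag.simulate_trajectory_cohort(cfg)
    assert same.truth_samples.equals(t)


def test_trajectory_single_branch_noiseless_ordering():
    cfg = ag.CohortConfig(n_donors=20, n_genes=30,
                          transcripts_per_gene=(1, 1),
                          mean_log_expression=(8.0, 0.2),
                          dispersion=(1e-8, 0.0), biological_sd=0.0,
                          affected_fraction=0.0, source_effect_sd=0.0,
                          sex_effect_sd=0.0, tech_effect_sd=0.0,
                          library_size=(1e8, 0.0), seed=9,
                          trajectory=ag.TrajectorySpec(n_branches=1,
                                                       length=10.0,
                                                       n_responsive=30,
                                                       response_scale=8.0))
    co = ag.simulate_trajectory_cohort(cfg)
    pos = co.truth_samples["position"]
    # library sizes are fixed, so raw counts carry the ordering directly
    # (strong responders dominate the library total, distorting CPM shares)
    log2c = np.log2(co.gene_counts + 0.5)
    resp = co.truth_genes.index[co.truth_genes["trajectory_responsive"]]
    rhos = [abs(stats.spearmanr(log2c.loc[g], pos).statistic)
            for g in resp]
    assert np.median(rhos) == pytest.approx(1.0)
    assert min(rhos) > 0.99


def test_write_cohort_roundtrip(tmp_path, small_cohort):
    from adglia import io
    ag.write_cohort(small_cohort, tmp_path)
    gc = io.read_counts(tmp_path / "gene_counts.tsv")
    assert np.array_equal(gc.to_numpy(), small_cohort.gene_counts.to_numpy())
    tx2gene = io.read_tx2gene(tmp_path / "tx2gene.tsv")
    assert tx2gene.equals(small_cohort.tx2gene)
    cfg = ag.load_config(tmp_path / "config.yaml")
    assert cfg == small_cohort.config
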