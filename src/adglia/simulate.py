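"""Synthetic microglia-cohort generator with ground truth.

Emulates the statistical structure the downstream analyses assume: donors
from a small number of source biobanks, clinical AD phenotypes (CERAD,
Braak, CDR, regional amyloid densities, ApoE genotype) derived from a shared
age-confounded latent severity score, negative-binomial transcript counts
whose log-means combine a baseline, technical/sex covariate effects, a
per-source random intercept, a disease effect for a configurable fraction of
genes, and a per-gene latent factor that makes transcripts of the same gene
equicorrelated.  A configurable fraction of affected genes carries one
opposite-sign transcript (the SERPINF1-type heterogeneous pattern).  Gene
counts are the sum of their transcript counts, and the true per-feature
log2 fold changes (plus optional latent trajectory positions) are recorded.

The defaults describe a cohort of 189 donors from three sources with ~40% AD
prevalence, 10% of genes affected with effect SD 0.5 on the log2 scale, and
within-gene transcript correlation 0.6.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import io as _io


class CohortConfigError(ValueError):
    pass


@dataclass
class TrajectorySpec:
    """Latent branching path: a trunk of length/2 splitting into branches."""
    n_branches: int = 2
    length: float = 10.0
    n_responsive: int = 300
    response_scale: float = 2.0   # total log2 swing along the full path

    def validate(self):
        if self.n_branches < 1:
            raise CohortConfigError("n_branches must be >= 1")
        if self.length <= 0:
            raise CohortConfigError("trajectory length must be > 0")


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort (all rates on natural scales).

    ``mean_log_expression`` and ``library_size`` are (location, spread)
    pairs: log2-scale normal for expression, log-normal (median, sigma) for
    library sizes.  ``dispersion`` is (median NB dispersion phi, SD of log
    phi); variance of a count with mean mu is mu + phi * mu**2.
    ``age_confounding`` is approximately the slope of case probability per
    year of age at the cohort median.
    """
    n_donors: int = 189
    n_genes: int = 2000
    transcripts_per_gene: tuple[int, int] = (1, 5)
    case_fraction: float = 0.4
    mean_log_expression: tuple[float, float] = (5.0, 2.0)
    dispersion: tuple[float, float] = (0.1, 0.5)
    effect_sd: float = 0.5
    affected_fraction: float = 0.1
    het_fraction: float = 0.2
    transcript_cor: float = 0.6
    biological_sd: float = 0.7
    sex_effect_sd: float = 0.1
    tech_effect_sd: float = 0.05
    source_effect_sd: float = 0.5
    n_sources: int = 3
    age_confounding: float = 0.02
    library_size: tuple[float, float] = (2e6, 0.3)
    trajectory: TrajectorySpec | None = None
    seed: int = 0

    def validate(self):
        for name in ("case_fraction", "affected_fraction", "het_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise CohortConfigError(f"{name} must be in [0, 1]")
        if not 0 <= self.transcript_cor < 1:
            raise CohortConfigError("transcript_cor must be in [0, 1)")
        if self.n_donors < 4:
            raise CohortConfigError("n_donors must be >= 4")
        if self.n_sources < 1:
            raise CohortConfigError("n_sources must be >= 1")
        tmin, tmax = self.transcripts_per_gene
        if not (1 <= tmin <= tmax):
            raise CohortConfigError("invalid transcripts_per_gene spec")
        for name in ("mean_log_expression", "dispersion", "library_size"):
            loc, spread = getattr(self, name)
            if spread < 0 or (name != "mean_log_expression" and loc <= 0):
                raise CohortConfigError(f"invalid distribution spec for {name}")
        if self.trajectory is not None:
            self.trajectory.validate()


@dataclass
class SyntheticCohort:
    gene_counts: pd.DataFrame
    transcript_counts: pd.DataFrame
    tx2gene: pd.Series
    metadata: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_transcripts: pd.DataFrame
    truth_samples: pd.DataFrame | None
    config: CohortConfig = field(repr=False)


# fractions of the severity scale mapped onto each ordinal level
_CERAD_PROBS = None  # filled from case_fraction at run time
_BRAAK_PROBS = (0.15, 0.10, 0.15, 0.15, 0.15, 0.15, 0.15)
_CDR_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
_CDR_PROBS = (0.35, 0.12, 0.13, 0.12, 0.12, 0.08, 0.08)
_SOURCE_PROBS = (0.60, 0.25, 0.15)
_PHENO_NOISE_SD = 0.6     # noise added to severity before thresholding
_FLAG_RATE = 0.02         # per-flag exclusion prevalence
_MISSING_RATE = 0.03      # per-phenotype missingness


def _ordinal_from_latent(latent, probs, levels, rng, missing_rate):
    """Threshold a noisy latent copy into ordinal levels with set fractions."""
    cuts = np.quantile(latent, np.cumsum(probs)[:-1])
    vals = np.asarray(levels, float)[np.searchsorted(cuts, latent)]
    out = vals.astype(float)
    miss = rng.random(len(out)) < missing_rate
    out[miss] = np.nan
    return out


def _simulate_metadata(cfg: CohortConfig, rng: np.random.Generator):
    n = cfg.n_donors
    donor_ids = [f"D{i:04d}" for i in range(n)]
    age = rng.normal(80.0, 9.0, n)
    young = rng.random(n) < 0.03
    age[young] = rng.uniform(25.0, 45.0, young.sum())
    age = np.clip(age, 25.0, 105.0)

    sex = np.where(rng.random(n) < 0.45, "male", "female")
    nsrc = cfg.n_sources
    probs = np.asarray(_SOURCE_PROBS[:nsrc] if nsrc <= 3
                       else [1 / nsrc] * nsrc, float)
    probs = probs / probs.sum()
    source = rng.choice([f"source_{k+1}" for k in range(nsrc)], n, p=probs)

    # latent severity: age-confounded; dP(case)/d(age) ~ age_confounding
    sev = rng.normal(0.0, 1.0, n) + 2.5 * cfg.age_confounding * (age - 80.0)

    cerad_latent = sev + rng.normal(0, _PHENO_NOISE_SD, n)
    # CERAD >= 2 defines the disease indicator; calibrate level fractions
    cf = cfg.case_fraction
    cerad_probs = (1 - cf, cf * 0.4, cf * 0.35, cf * 0.25)
    cerad = _ordinal_from_latent(cerad_latent, cerad_probs, (1, 2, 3, 4),
                                 rng, _MISSING_RATE)
    # the expression-effect carrier (recorded even where CERAD is missing)
    is_case = cerad_latent >= np.quantile(cerad_latent, 1 - cf) if cf > 0 \
        else np.zeros(n, bool)

    braak = _ordinal_from_latent(sev + rng.normal(0, _PHENO_NOISE_SD, n),
                                 _BRAAK_PROBS, tuple(range(7)), rng,
                                 _MISSING_RATE)
    cdr = _ordinal_from_latent(sev + rng.normal(0, _PHENO_NOISE_SD, n),
                               _CDR_PROBS, _CDR_LEVELS, rng, _MISSING_RATE)

    region_scale = np.array([1.0, 0.8, 1.2, 0.9, 1.1])
    plaque = np.maximum(
        0.0, (sev[:, None] + 1.2 + rng.normal(0, 0.5, (n, 5)))
        * region_scale[None, :])
    plaque[rng.random(n) < 0.10] = np.nan          # donors without the assay
    spot = rng.random((n, 5)) < 0.03
    plaque[spot] = np.nan

    p4 = np.clip(0.12 + 0.10 * (sev > 0), 0, 1)
    geno = []
    for i in range(n):
        alleles = rng.choice(["2", "3", "4"], size=2,
                             p=[0.08, 0.92 - p4[i], p4[i]])
        geno.append("/".join(sorted(alleles)))
    geno = np.asarray(geno, object)
    geno[rng.random(n) < 0.05] = None

    flags = {f: rng.random(n) < _FLAG_RATE for f in (
        "flag_psychiatric", "flag_other_neurodegenerative", "flag_autoimmune",
        "flag_brain_cancer", "flag_sepsis", "flag_alcoholism")}

    tech = {f"tech_{k+1}": rng.normal(0, 1, n) for k in range(3)}

    md = pd.DataFrame({
        "age": np.round(age, 1), "sex": sex, "source": source,
        "cerad": cerad, "braak": braak, "cdr": cdr,
        **{f"plaque_r{k+1}": np.round(plaque[:, k], 2) for k in range(5)},
        "apoe_genotype": geno, **flags, **tech,
        "pmi_minutes": np.round(rng.lognormal(np.log(360), 0.4, n), 0),
    }, index=pd.Index(donor_ids, name="donor_id"))
    return md, is_case.astype(float), sev


def _feature_truth(cfg: CohortConfig, rng: np.random.Generator):
    """Draw per-gene structure: transcript counts/shares, effects, dispersion."""
    tmin, tmax = cfg.transcripts_per_gene
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    m = rng.integers(tmin, tmax + 1, cfg.n_genes)
    mu = rng.normal(*cfg.mean_log_expression, cfg.n_genes)
    phi_med, phi_sd = cfg.dispersion
    phi = np.exp(rng.normal(np.log(phi_med), phi_sd, cfg.n_genes))

    n_aff = int(round(cfg.affected_fraction * cfg.n_genes))
    affected = np.zeros(cfg.n_genes, bool)
    affected[rng.choice(cfg.n_genes, n_aff, replace=False)] = True
    beta_gene = np.where(affected, rng.normal(0, cfg.effect_sd, cfg.n_genes), 0.0)

    het = np.zeros(cfg.n_genes, bool)
    aff_idx = np.flatnonzero(affected & (m > 1))
    n_het = int(round(cfg.het_fraction * len(aff_idx)))
    if n_het:
        het[rng.choice(aff_idx, n_het, replace=False)] = True

    genes = []
    for gi, gid in enumerate(gene_ids):
        shares = rng.dirichlet(np.full(m[gi], 1.2))
        beta_tx = np.full(m[gi], beta_gene[gi])
        if het[gi]:
            flip = rng.integers(m[gi])
            beta_tx[flip] = -beta_gene[gi]
        genes.append({"gene": gid, "m": int(m[gi]), "mu": mu[gi],
                      "phi": phi[gi], "shares": shares, "beta_tx": beta_tx,
                      "het": bool(het[gi]),
                      "beta_gene_nominal": beta_gene[gi]})
    return genes


def _draw_counts(cfg, genes, metadata, case, rng, extra_logfc=None):
    """NB transcript counts given per-gene structure and donor covariates.

    ``extra_logfc`` optionally adds a transcripts x donors log2 term
    (trajectory response).  Returns transcript counts, tx2gene, and the
    per-transcript log2 baseline used for normalization.
    """
    n = cfg.n_donors
    src_codes = pd.Categorical(metadata["source"]).codes
    sex_num = (metadata["sex"] == "male").to_numpy(float)
    tech = metadata[["tech_1", "tech_2", "tech_3"]].to_numpy(float)
    lib_med, lib_sd = cfg.library_size
    lib = rng.lognormal(np.log(lib_med), lib_sd, n)

    rho = cfg.transcript_cor
    bio = cfg.biological_sd

    tx_rows, tx_ids, tx_gene = [], [], []
    base_list = []
    row = 0
    for g in genes:
        mg = g["m"]
        ids = [f"{g['gene']}.T{t+1}" for t in range(mg)]
        base = g["mu"] + np.log2(g["shares"])
        # covariate effects shared across the gene's transcripts
        gamma = rng.normal(0, cfg.tech_effect_sd, 3)
        delta_sex = rng.normal(0, cfg.sex_effect_sd)
        u_src = rng.normal(0, cfg.source_effect_sd, cfg.n_sources)
        z_gene = rng.normal(0, 1, n)                      # shared latent
        eps = rng.normal(0, 1, (mg, n))
        latent = bio * (np.sqrt(rho) * z_gene[None, :]
                        + np.sqrt(1 - rho) * eps)
        x = (base[:, None] + g["beta_tx"][:, None] * case[None, :]
             + (tech @ gamma)[None, :] + delta_sex * sex_num[None, :]
             + u_src[src_codes][None, :] + latent)
        if extra_logfc is not None:
            x = x + extra_logfc[row:row + mg]
        tx_rows.append(x)
        tx_ids.extend(ids)
        tx_gene.extend([g["gene"]] * mg)
        base_list.append(base)
        row += mg

    x_all = np.vstack(tx_rows)
    base_all = np.concatenate(base_list)
    norm = float(np.sum(2.0 ** base_all))                 # fixed normalizer
    mean = (2.0 ** x_all) * (lib[None, :] / norm)

    phi_tx = np.concatenate([np.full(g["m"], g["phi"]) for g in genes])
    shape = 1.0 / phi_tx
    lam = rng.gamma(shape[:, None], mean * phi_tx[:, None])
    counts = rng.poisson(lam)

    tx_counts = pd.DataFrame(counts, index=pd.Index(tx_ids, name="feature_id"),
                             columns=metadata.index)
    tx2gene = pd.Series(tx_gene, index=pd.Index(tx_ids, name="transcript_id"),
                        name="gene_id")
    return tx_counts, tx2gene


def _truth_tables(genes):
    tx_rows, gene_rows = [], []
    for g in genes:
        w = g["shares"]
        true_gene_fc = float(np.log2(np.sum(w * 2.0 ** g["beta_tx"])))
        gene_rows.append((g["gene"], true_gene_fc, g["het"],
                          g["beta_gene_nominal"], g["m"]))
        for t in range(g["m"]):
            tx_rows.append((f"{g['gene']}.T{t+1}", g["gene"],
                            float(g["beta_tx"][t]), g["het"]))
    truth_genes = pd.DataFrame(
        gene_rows, columns=["gene", "true_log2fc", "het", "nominal_log2fc",
                            "m"]).set_index("gene")
    truth_tx = pd.DataFrame(
        tx_rows, columns=["transcript", "gene", "true_log2fc",
                          "het"]).set_index("transcript")
    return truth_genes, truth_tx


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; output is a pure function of config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    metadata, case, _sev = _simulate_metadata(config, rng)
    genes = _feature_truth(config, rng)
    tx_counts, tx2gene = _draw_counts(config, genes, metadata, case, rng)
    gene_counts = tx_counts.groupby(tx2gene.reindex(tx_counts.index).values,
                                    sort=False).sum()
    gene_counts.index.name = "feature_id"
    truth_genes, truth_tx = _truth_tables(genes)
    metadata = metadata.copy()
    metadata["true_case"] = case.astype(int)
    return SyntheticCohort(gene_counts=gene_counts,
                           transcript_counts=tx_counts, tx2gene=tx2gene,
                           metadata=metadata, truth_genes=truth_genes,
                           truth_transcripts=truth_tx, truth_samples=None,
                           config=config)


def simulate_trajectory_cohort(config: CohortConfig) -> SyntheticCohort:
    """Cohort whose samples sit on a branching 1-D latent path.

    Each donor receives a position on a trunk [0, L/2] that splits into
    ``n_branches`` branches covering (L/2, L] (a single branch means one
    unbroken path).  A panel of responsive genes varies monotonically in
    position within each branch (trunk slope continuing into a
    branch-specific slope) on the log2 scale, on top of the usual NB noise.
    """
    config.validate()
    if config.trajectory is None:
        raise CohortConfigError("trajectory spec required")
    spec = config.trajectory
    rng = np.random.default_rng(config.seed)
    metadata, case, _sev = _simulate_metadata(config, rng)
    genes = _feature_truth(config, rng)

    n = config.n_donors
    L = spec.length
    pos = rng.uniform(0.0, L, n)
    if spec.n_branches == 1:
        branch = np.zeros(n, int)
        split = L            # no split point
    else:
        split = L / 2.0
        branch = np.where(pos <= split, 0,
                          rng.integers(1, spec.n_branches + 1, n))

    n_tx = sum(g["m"] for g in genes)
    n_resp = min(spec.n_responsive, config.n_genes)
    resp_genes = rng.choice(config.n_genes, n_resp, replace=False)
    is_resp = np.zeros(config.n_genes, bool)
    is_resp[resp_genes] = True

    slope_scale = spec.response_scale / L
    extra = np.zeros((n_tx, n))
    resp_rows = []
    row = 0
    for gi, g in enumerate(genes):
        mg = g["m"]
        if is_resp[gi]:
            a0 = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0) * slope_scale
            a_branch = a0 * rng.uniform(0.25, 1.75, spec.n_branches + 1)
            a_branch[0] = a0
            trunk = a0 * np.minimum(pos, split)
            beyond = np.maximum(pos - split, 0.0)
            eff = trunk + a_branch[branch] * beyond
            extra[row:row + mg] = eff[None, :]
            resp_rows.append((g["gene"], a0))
        row += mg

    tx_counts, tx2gene = _draw_counts(config, genes, metadata, case, rng,
                                      extra_logfc=extra)
    gene_counts = tx_counts.groupby(tx2gene.reindex(tx_counts.index).values,
                                    sort=False).sum()
    gene_counts.index.name = "feature_id"
    truth_genes, truth_tx = _truth_tables(genes)
    truth_genes["trajectory_responsive"] = truth_genes.index.isin(
        [g for g, _ in resp_rows])
    truth_samples = pd.DataFrame({"position": pos, "branch": branch},
                                 index=metadata.index)
    metadata = metadata.copy()
    metadata["true_case"] = case.astype(int)
    return SyntheticCohort(gene_counts=gene_counts,
                           transcript_counts=tx_counts, tx2gene=tx2gene,
                           metadata=metadata, truth_genes=truth_genes,
                           truth_transcripts=truth_tx,
                           truth_samples=truth_samples, config=config)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | os.PathLike) -> None:
    os.makedirs(outdir, exist_ok=True)
    j = os.path.join
    _io.write_counts(cohort.gene_counts, j(outdir, "gene_counts.tsv"))
    _io.write_counts(cohort.transcript_counts, j(outdir, "transcript_counts.tsv"))
    _io.write_tx2gene(cohort.tx2gene, j(outdir, "tx2gene.tsv"))
    _io.write_table(cohort.metadata, j(outdir, "metadata.tsv"),
                    index_label="donor_id")
    _io.write_table(cohort.truth_genes, j(outdir, "truth_genes.tsv"),
                    index_label="gene")
    _io.write_table(cohort.truth_transcripts, j(outdir, "truth_transcripts.tsv"),
                    index_label="transcript")
    if cohort.truth_samples is not None:
        _io.write_table(cohort.truth_samples, j(outdir, "truth_samples.tsv"),
                        index_label="donor_id")
    cfg = asdict(cohort.config)  # nested dataclasses become dicts
    with open(j(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(_yaml_safe(cfg), fh, sort_keys=False)


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_config(path: str | os.PathLike) -> CohortConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    traj = raw.pop("trajectory", None)
    for key in ("transcripts_per_gene", "mean_log_expression", "dispersion",
                "library_size"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    try:
        cfg = CohortConfig(**raw)
    except TypeError as err:
        raise CohortConfigError(str(err)) from err
    if traj is not None:
        cfg.trajectory = TrajectorySpec(**traj)
    cfg.validate()
    return cfg
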