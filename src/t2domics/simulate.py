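"""Synthetic multi-omics cohorts with recorded ground truth.

The generator emulates the joint structure the downstream stages assume:

* genotypes with two ancestry components, explicit sib-pair families (so
  kinship estimation is genuinely exercised) and SNP positions spread over
  several chromosomes to give both cis and trans meQTL geometry;
* methylation beta values produced by an inverse-logit linear predictor over
  SNP dosage, disease status, age, sex, batch (including a batch-by-sex
  interaction), cell-count composition, a latent-smoking surrogate CpG and
  Gaussian noise on the logit scale;
* a metabolite panel drawn from a sparse-precision Gaussian graphical model,
  with planted disease mean shifts and linear CpG effects, exponentiated to a
  positive raw scale so the QC log-transform is meaningful;
* phenotypes whose case/control rule has the shape used in the cohort design
  (self-reported diagnosis OR HbA1c >= 6.5 with onset above 30), age made
  collinear with disease status in the two EWAS cohorts by construction, and
  BMI distributed differently between cases and controls.

Every planted parameter, the realized kinship expectation and the metabolite
precision matrix are returned in :class:`GroundTruth` for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd

CHROMOSOMES = (1, 2, 3, 4)
CHROM_LENGTH = 240_000_000  # bp span used when laying out positions


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# --------------------------------------------------------------------------
# configuration and ground truth containers
# --------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Effect tables are keyed by feature index; values are on the scale noted:
    ``snp_cpg`` and ``cpg_t2d`` act on the methylation logit, ``t2d_metabolite``
    and ``cpg_metabolite`` in metabolite SD units, ``cpg_hba1c`` in HbA1c
    percentage points per methylation beta unit.
    """

    n_samples: int = 900
    n_cpgs: int = 300
    n_snps: int = 2000
    n_metabolites: int = 60
    case_fraction: float = 0.43
    n_families: int = 50
    family_size: int = 2
    maf_range: Tuple[float, float] = (0.05, 0.5)
    snp_cpg: Dict[Tuple[int, int], float] = field(default_factory=dict)
    cpg_t2d: Dict[int, float] = field(default_factory=dict)
    t2d_metabolite: Dict[int, float] = field(default_factory=dict)
    cpg_metabolite: Dict[Tuple[int, int], float] = field(default_factory=dict)
    cpg_hba1c: Dict[int, float] = field(default_factory=dict)
    ggm_edge_density: float = 0.1
    ggm_pcor_range: Tuple[float, float] = (0.25, 0.45)
    methylation_noise_sd: float = 0.4
    metabolite_log_sd: float = 0.35
    smoking_prevalence: float = 0.2
    smoking_effect: float = -1.5
    fst: float = 0.01
    ancestry_fraction: float = 0.5
    # study condition: cases are older than controls in the EWAS cohorts.
    # Disable for exchangeable-label null cohorts (no disease-age link).
    age_collinear_t2d: bool = True
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_cpgs": self.n_cpgs,
            "n_snps": self.n_snps,
            "n_metabolites": self.n_metabolites,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if not 0 < self.case_fraction < 1:
            raise ConfigError("case_fraction must lie in (0, 1)")
        if not 0 < self.ggm_edge_density < 1:
            raise ConfigError("ggm_edge_density must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_families < 0 or self.family_size < 2:
            raise ConfigError("need n_families >= 0 and family_size >= 2")
        if self.n_families * self.family_size > self.n_samples:
            raise ConfigError("families cannot contain more samples than n_samples")
        for (i, j) in self.snp_cpg:
            if not (0 <= i < self.n_snps and 0 <= j < self.n_cpgs):
                raise ConfigError(f"snp_cpg effect ({i},{j}) outside feature range")
        for j in self.cpg_t2d:
            if not 0 <= j < self.n_cpgs:
                raise ConfigError(f"cpg_t2d effect on CpG {j} outside range")
        for k in self.t2d_metabolite:
            if not 0 <= k < self.n_metabolites:
                raise ConfigError(f"t2d_metabolite effect on metabolite {k} outside range")
        for (j, k) in self.cpg_metabolite:
            if not (0 <= j < self.n_cpgs and 0 <= k < self.n_metabolites):
                raise ConfigError(f"cpg_metabolite effect ({j},{k}) outside feature range")


def default_effects(config: SimulationConfig) -> SimulationConfig:
    """Plant a standard panel of effects used by the end-to-end analyses.

    Effects are placed on fixed feature indices (away from the smoking
    surrogate at CpG 0): five disease-associated CpGs, four SNP->CpG pairs
    alternating cis/trans geometry, three disease-shifted metabolites and two
    CpG->metabolite links, plus an HbA1c effect of the first disease CpG.
    Requires n_cpgs >= 16, n_snps >= 401, n_metabolites >= 8.
    """
    if config.n_cpgs < 16 or config.n_snps < 401 or config.n_metabolites < 8:
        raise ConfigError(
            "default effect panel needs n_cpgs >= 16, n_snps >= 401, "
            "n_metabolites >= 8; pass explicit effect tables for smaller runs"
        )
    config.cpg_t2d = {10: 0.35, 11: 0.30, 12: 0.25, 13: -0.30, 14: 0.20}
    config.snp_cpg = {(100, 10): 0.5, (200, 11): 0.45, (300, 12): 0.5, (400, 15): 0.4}
    config.t2d_metabolite = {5: 0.5, 6: -0.5, 7: 0.35}
    # links target disease-associated metabolites so they survive the
    # MWAS funnel and reach the CpG-metabolite meta-analysis
    config.cpg_metabolite = {(10, 5): 0.4, (12, 6): -0.4}
    config.cpg_hba1c = {10: 8.0}
    return config


@dataclass
class GenotypeMatrix:
    """Dosage matrix (SNPs x samples) with per-SNP genomic annotation."""

    dosages: pd.DataFrame
    info: pd.DataFrame  # index snp id; columns chrom, pos, ref, alt, maf

    @property
    def samples(self) -> pd.Index:
        return self.dosages.columns


@dataclass
class MethylationMatrix:
    """Beta-value matrix (CpGs x samples) with CpG coordinates."""

    beta: pd.DataFrame
    info: pd.DataFrame  # index cpg id; columns chrom, pos


@dataclass
class MetaboliteMatrix:
    """Metabolite abundances (metabolites x samples) with pathway labels."""

    values: pd.DataFrame
    info: pd.DataFrame  # index metabolite id; columns pathway, subpathway


@dataclass
class GroundTruth:
    config: SimulationConfig
    kinship_expected: np.ndarray  # expected relationship (GRM scale) from pedigree
    precision: np.ndarray  # metabolite GGM precision matrix (correlation scale)
    smoking: np.ndarray
    ancestry: np.ndarray
    snp_cpg_beta_scale: Dict[Tuple[str, str], float]
    cpg_t2d_beta_scale: Dict[str, float]
    t2d_metabolite: Dict[str, float]
    cpg_metabolite: Dict[Tuple[str, str], float]
    cpg_hba1c: Dict[str, float]


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------


def _snp_positions(n_snps: int, rng: np.random.Generator) -> pd.DataFrame:
    chroms = np.array([CHROMOSOMES[i % len(CHROMOSOMES)] for i in range(n_snps)])
    pos = rng.integers(1, CHROM_LENGTH, size=n_snps)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index([f"snp{i}" for i in range(n_snps)], name="snp"),
    )


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Draw dosages with family and ancestry structure.

    Families are sib groups: parental haplotypes are drawn from the
    population frequencies and each sib inherits one haplotype per parent
    independently at every SNP, so sibs share alleles with the Mendelian
    probability and the expected genomic relationship between sibs is 0.5
    (kinship coefficient 0.25).

    Returns the genotype matrix, the pedigree-expected relationship matrix
    (GRM scale: 1 on the diagonal, 0.5 within sib groups) and the per-sample
    ancestry labels.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_snps

    # ancestry-specific allele frequencies (Balding-Nichols divergence)
    anc_freq = rng.uniform(*config.maf_range, size=m)
    f = config.fst
    freqs = np.empty((2, m))
    if f > 0:
        a = anc_freq * (1 - f) / f
        b = (1 - anc_freq) * (1 - f) / f
        for k in range(2):
            freqs[k] = np.clip(rng.beta(a, b), 1e-3, 1 - 1e-3)
    else:
        freqs[:] = anc_freq

    ancestry = (rng.random(n) < config.ancestry_fraction).astype(int)
    n_fam_samples = config.n_families * config.family_size
    # families share one ancestry label
    for fam in range(config.n_families):
        sl = slice(fam * config.family_size, (fam + 1) * config.family_size)
        ancestry[sl] = ancestry[fam * config.family_size]

    dosage = np.empty((n, m), dtype=np.float64)
    for fam in range(config.n_families):
        start = fam * config.family_size
        p = freqs[ancestry[start]]
        mother = rng.random((2, m)) < p
        father = rng.random((2, m)) < p
        for s in range(config.family_size):
            pick_m = rng.integers(0, 2, size=m)
            pick_f = rng.integers(0, 2, size=m)
            dosage[start + s] = (
                mother[pick_m, np.arange(m)].astype(float)
                + father[pick_f, np.arange(m)]
            )
    if n_fam_samples < n:
        p = freqs[ancestry[n_fam_samples:]]
        dosage[n_fam_samples:] = rng.binomial(2, p).astype(float)

    kin = np.eye(n)
    for fam in range(config.n_families):
        sl = slice(fam * config.family_size, (fam + 1) * config.family_size)
        block = np.full((config.family_size, config.family_size), 0.5)
        np.fill_diagonal(block, 1.0)
        kin[sl, sl] = block

    info = _snp_positions(m, rng)
    info["maf"] = dosage.mean(axis=0) / 2.0
    samples = pd.Index([f"S{i:04d}" for i in range(n)], name="sample")
    geno = GenotypeMatrix(
        dosages=pd.DataFrame(dosage.T, index=info.index, columns=samples), info=info
    )
    return geno, kin, ancestry


# --------------------------------------------------------------------------
# sample table
# --------------------------------------------------------------------------


def _simulate_sample_table(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = config.n_samples
    samples = pd.Index([f"S{i:04d}" for i in range(n)], name="sample")

    # cohorts 1/2 feed the EWAS; cohort 3 adds power to the meQTL stage
    cohort = rng.choice([1, 2, 3], size=n, p=[0.44, 0.37, 0.19])
    t2d = (rng.random(n) < config.case_fraction).astype(int)

    # age is collinear with disease in cohorts 1-2 (older cases); cohort 3
    # cases and controls have similar ages
    if config.age_collinear_t2d:
        age = np.where(t2d == 1, rng.normal(53.5, 9.0, n), rng.normal(36.0, 10.5, n))
    else:
        age = rng.normal(42.0, 12.0, n)
    in3 = cohort == 3
    age[in3] = rng.normal(54.0, 10.5, in3.sum())
    age = np.clip(age, 18, 85)

    sex = rng.integers(0, 2, size=n)  # 0 female, 1 male
    bmi = np.where(t2d == 1, rng.normal(32.0, 5.8, n), rng.normal(28.5, 5.8, n))
    bmi = np.clip(bmi, 15, 55)

    # case rule shape: self-report OR HbA1c >= 6.5, onset above 30
    self_report = (t2d == 1) & (rng.random(n) < 0.8)
    hba1c = np.empty(n)
    cases = t2d == 1
    hba1c[cases] = 6.6 + rng.gamma(2.0, 0.6, cases.sum())
    hba1c[~cases] = np.clip(rng.normal(5.4, 0.4, (~cases).sum()), 4.0, 6.2)
    # non-self-reported cases must satisfy the biochemical arm of the rule
    hba1c[cases & ~self_report] = np.maximum(hba1c[cases & ~self_report], 6.5)
    onset_age = np.where(cases, np.maximum(31.0, age - rng.gamma(2.0, 3.0, n)), np.nan)

    # lab cell counts: Dirichlet composition (neut/baso/eos/mono/lymph)
    cells = rng.dirichlet([48.0, 1.0, 2.5, 7.0, 30.0], size=n)

    plate = 1 + (np.arange(n) // 96)
    well_row = np.array(list("ABCDEFGH"))[np.arange(n) % 8]
    batch = cohort.copy()  # methylation profiling batch tracks the cohort
    # genomic profiling batch defines the meQTL discovery/replication split
    geno_batch = np.where(rng.random(n) < 0.685, 1, 2)
    met_batch = 1 + (rng.random(n) < 0.49).astype(int)

    return pd.DataFrame(
        {
            "cohort": cohort,
            "t2d": t2d,
            "self_report": self_report.astype(int),
            "age": age,
            "onset_age": onset_age,
            "sex": sex,
            "bmi": bmi,
            "hba1c": hba1c,
            "neut": cells[:, 0],
            "baso": cells[:, 1],
            "eos": cells[:, 2],
            "mono": cells[:, 3],
            "lymph": cells[:, 4],
            "plate": plate,
            "well": well_row,
            "batch": batch,
            "geno_batch": geno_batch,
            "met_batch": met_batch,
        },
        index=samples,
    )


# --------------------------------------------------------------------------
# methylation
# --------------------------------------------------------------------------


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    config: SimulationConfig,
    smoking: np.ndarray,
    rng: np.random.Generator,
) -> Tuple[MethylationMatrix, Dict[str, float], Dict[Tuple[str, str], float]]:
    """Beta values from an inverse-logit linear predictor.

    CpG 0 is the smoking surrogate (driven by the latent smoking variable);
    planted SNP and disease effects act on the logit scale. Returns the
    matrix plus the derived beta-scale effect sizes — exact finite-difference
    contrasts of the inverse-logit at the realized linear predictors (average
    effect of disease status, or of one extra dosage unit, on the beta
    scale) — which are the estimands the linear association stages recover.
    """
    n, p = config.n_samples, config.n_cpgs
    cpg_ids = [f"cg{j:07d}" for j in range(p)]

    intercepts = rng.uniform(-1.3, 1.3, size=p)
    eta = np.tile(intercepts, (n, 1))

    age_slopes = rng.normal(0.0, 0.004, size=p)
    sex_effects = rng.normal(0.0, 0.05, size=p)
    batch_effects = rng.normal(0.0, 0.05, size=(3, p))
    batch_sex = rng.normal(0.0, 0.03, size=(3, p))
    cell_load = rng.normal(0.0, 0.3, size=(2, p))

    age = samples["age"].to_numpy()
    sex = samples["sex"].to_numpy()
    batch = samples["batch"].to_numpy() - 1
    eta += np.outer(age - age.mean(), age_slopes)
    eta += np.outer(sex, sex_effects)
    eta += batch_effects[batch]
    eta += batch_sex[batch] * sex[:, None]
    # cell composition enters through two latent contrasts of the counts
    cells = samples[["neut", "baso", "eos", "mono", "lymph"]].to_numpy()
    cc = cells - cells.mean(axis=0)
    contrasts = cc @ rng.normal(size=(5, 2))
    eta += contrasts @ cell_load

    eta[:, 0] += config.smoking_effect * smoking

    dos = genotypes.dosages.to_numpy().T  # samples x snps
    for (i, j), b in config.snp_cpg.items():
        eta[:, j] += b * dos[:, i]
    t2d = samples["t2d"].to_numpy()
    for j, b in config.cpg_t2d.items():
        eta[:, j] += b * t2d

    eta += rng.normal(0.0, config.methylation_noise_sd, size=(n, p))
    beta = np.clip(_inv_logit(eta), 1e-6, 1 - 1e-6)

    # derived beta-scale effects: exact finite-difference contrasts through
    # the logistic link at the realized linear predictors (incl. noise)
    snp_cpg_beta = {}
    for (i, j), b in config.snp_cpg.items():
        base = eta[:, j] - b * dos[:, i]
        per_unit = _inv_logit(base + b * (dos[:, i] + 1)) - _inv_logit(
            base + b * dos[:, i]
        )
        snp_cpg_beta[(f"snp{i}", cpg_ids[j])] = float(per_unit.mean())
    cpg_t2d_beta = {}
    for j, b in config.cpg_t2d.items():
        base = eta[:, j] - b * t2d
        contrast = _inv_logit(base + b) - _inv_logit(base)
        cpg_t2d_beta[cpg_ids[j]] = float(contrast.mean())

    # CpG coordinates: same chromosome layout as SNPs; planted pairs
    # alternate cis (within 30 kb of their SNP) and trans geometry
    chroms = np.array([CHROMOSOMES[j % len(CHROMOSOMES)] for j in range(p)])
    pos = rng.integers(1, CHROM_LENGTH, size=p)
    snp_info = genotypes.info
    for rank, ((i, j), _) in enumerate(sorted(config.snp_cpg.items())):
        sc, sp = snp_info.iloc[i][["chrom", "pos"]]
        if rank % 2 == 0:  # cis
            chroms[j] = sc
            pos[j] = max(1, int(sp) + 30_000)
        else:  # trans: same chromosome but far away, or different chromosome
            chroms[j] = sc
            pos[j] = int(sp) + 150_000_000 if sp < 90_000_000 else int(sp) - 150_000_000
    info = pd.DataFrame(
        {"chrom": chroms, "pos": pos}, index=pd.Index(cpg_ids, name="cpg")
    )
    meth = MethylationMatrix(
        beta=pd.DataFrame(beta.T, index=info.index, columns=samples.index), info=info
    )
    return meth, cpg_t2d_beta, snp_cpg_beta


# --------------------------------------------------------------------------
# metabolites
# --------------------------------------------------------------------------

_PATHWAYS = ("Amino Acid", "Carbohydrate", "Lipid", "Xenobiotics", "Nucleotide")


def make_precision(
    n_metabolites: int,
    edge_density: float,
    pcor_range: Tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Sparse symmetric positive-definite precision matrix with unit diagonal.

    Edge weights are drawn so the implied partial correlations
    (pcor_ij = -P_ij / sqrt(P_ii P_jj)) sit in ``pcor_range`` up to the
    positive-definiteness rescaling applied when the raw draw is indefinite.
    """
    p = n_metabolites
    P = np.eye(p)
    iu = np.triu_indices(p, k=1)
    n_pairs = len(iu[0])
    n_edges = int(round(edge_density * n_pairs))
    chosen = rng.choice(n_pairs, size=n_edges, replace=False)
    weights = rng.uniform(*pcor_range, size=n_edges) * rng.choice([-1, 1], size=n_edges)
    # P_ij = -pcor_ij for unit diagonal
    off = np.zeros(n_pairs)
    off[chosen] = -weights
    P[iu] = off
    P.T[iu] = off
    w = np.linalg.eigvalsh(P)
    if w[0] < 0.05:
        # shrink off-diagonal until the smallest eigenvalue clears the floor
        scale = (1.0 - 0.05) / (1.0 - w[0])
        P = np.eye(p) + scale * (P - np.eye(p))
    return P


def simulate_metabolites(
    samples: pd.DataFrame,
    methylation: MethylationMatrix,
    precision: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Tuple[MetaboliteMatrix, Dict[str, float], Dict[Tuple[str, str], float]]:
    """Raw-scale metabolite panel over a GGM dependence structure.

    Latent z-scores are multivariate normal with covariance = inverse
    precision; planted effects add disease mean shifts (SD units) and linear
    terms in standardized CpG beta values. Values are exponentiated so the
    QC log-transform recovers the latent scale.
    """
    w = np.linalg.eigvalsh(precision)
    if w[0] <= 0:
        raise ConfigError("metabolite precision matrix must be positive definite")
    n, q = config.n_samples, config.n_metabolites
    cov = np.linalg.inv(precision)
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((n, q)) @ L.T
    marginal_sd = np.sqrt(np.diag(cov))  # effects below are in these SD units

    t2d = samples["t2d"].to_numpy()
    t2d_truth: Dict[str, float] = {}
    met_ids = [f"met{k:03d}" for k in range(q)]
    for k, d in config.t2d_metabolite.items():
        z[:, k] += d * marginal_sd[k] * t2d
        t2d_truth[met_ids[k]] = d
    cpg_truth: Dict[Tuple[str, str], float] = {}
    beta = methylation.beta.to_numpy().T  # samples x cpgs
    for (j, k), g in config.cpg_metabolite.items():
        cpg = beta[:, j]
        cpg_std = (cpg - cpg.mean()) / cpg.std()
        z[:, k] += g * marginal_sd[k] * cpg_std
        cpg_truth[(methylation.info.index[j], met_ids[k])] = g

    mu = rng.uniform(2.0, 8.0, size=q)  # log-scale abundance level
    raw = np.exp(mu + config.metabolite_log_sd * z)
    # sprinkle missingness (platform dropouts)
    mask = rng.random((n, q)) < 0.01
    raw[mask] = np.nan

    info = pd.DataFrame(
        {
            "pathway": [_PATHWAYS[k % len(_PATHWAYS)] for k in range(q)],
            "subpathway": [f"sub{k % 7}" for k in range(q)],
        },
        index=pd.Index(met_ids, name="metabolite"),
    )
    mat = MetaboliteMatrix(
        values=pd.DataFrame(raw.T, index=info.index, columns=samples.index), info=info
    )
    return mat, t2d_truth, cpg_truth


# --------------------------------------------------------------------------
# cohort orchestration
# --------------------------------------------------------------------------


def simulate_cohort(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, GenotypeMatrix, MethylationMatrix, MetaboliteMatrix, GroundTruth]:
    """Generate a full cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genotypes, kin, ancestry = simulate_genotypes(config, rng)
    samples = _simulate_sample_table(config, rng)
    smoking = (rng.random(config.n_samples) < config.smoking_prevalence).astype(float)
    methylation, cpg_t2d_beta, snp_cpg_beta = simulate_methylation(
        genotypes, samples, config, smoking, rng
    )

    # HbA1c picks up planted CpG effects (kept small so the case rule holds)
    hba1c_truth: Dict[str, float] = {}
    if config.cpg_hba1c:
        hba1c = samples["hba1c"].to_numpy().copy()
        beta = methylation.beta.to_numpy().T
        for j, e in config.cpg_hba1c.items():
            c = beta[:, j]
            hba1c += e * (c - c.mean())
            hba1c_truth[methylation.info.index[j]] = e
        controls = samples["t2d"].to_numpy() == 0
        no_report = (samples["t2d"].to_numpy() == 1) & (
            samples["self_report"].to_numpy() == 0
        )
        hba1c[controls] = np.minimum(hba1c[controls], 6.4)
        hba1c[no_report] = np.maximum(hba1c[no_report], 6.5)
        samples["hba1c"] = hba1c

    precision = make_precision(
        config.n_metabolites, config.ggm_edge_density, config.ggm_pcor_range, rng
    )
    metabolites, t2d_met_truth, cpg_met_truth = simulate_metabolites(
        samples, methylation, precision, config, rng
    )

    truth = GroundTruth(
        config=config,
        kinship_expected=kin,
        precision=precision,
        smoking=smoking,
        ancestry=ancestry,
        snp_cpg_beta_scale=snp_cpg_beta,
        cpg_t2d_beta_scale=cpg_t2d_beta,
        t2d_metabolite=t2d_met_truth,
        cpg_metabolite=cpg_met_truth,
        cpg_hba1c=hba1c_truth,
    )
    return samples, genotypes, methylation, metabolites, truth
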