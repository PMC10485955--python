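"""Shared loading helpers for the numbered analysis drivers.

Driver 01 writes the cohort to results/cohort/; later drivers reload it from
disk and re-derive the covariate designs, so each step can be rerun in
isolation.
"""

from pathlib import Path

from t2domics import io, preprocess

RESULTS = Path(__file__).resolve().parent.parent / "results"
COHORT_DIR = RESULTS / "cohort"


def load_cohort():
    samples = io.read_sample_table(COHORT_DIR / "samples.tsv")
    geno = io.read_vcf_dosages(COHORT_DIR / "genotypes.vcf")
    meth = io.read_methylation(COHORT_DIR / "methylation.tsv")
    mets = io.read_metabolites(COHORT_DIR / "metabolites_raw.tsv")
    return samples, geno, meth, mets


def derive(samples, geno, meth):
    gpcs = preprocess.genomic_pcs(geno)
    age_model = preprocess.fit_age_model(meth.beta, samples["age"],
                                         samples["t2d"] == 0)
    meth_adj = preprocess.age_residualize(meth.beta, samples["age"], age_model)
    covs = {
        tag: preprocess.build_covariates(samples, meth, geno, tag, gpcs=gpcs).design
        for tag in preprocess.MODEL_TAGS
    }
    return gpcs, meth_adj, covs
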