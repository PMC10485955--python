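"""Shared fixtures: synthetic cohorts generated once per session."""

import numpy as np
import pytest

from t2domics import preprocess
from t2domics.simulate import SimulationConfig, default_effects, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Study-scale cohort with the standard planted-effect panel."""
    cfg = default_effects(SimulationConfig(seed=1))
    samples, geno, meth, mets, truth = simulate_cohort(cfg)
    return {
        "config": cfg,
        "samples": samples,
        "genotypes": geno,
        "methylation": meth,
        "metabolites": mets,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with every planted effect zero (calibration checks).

    The null includes no disease-age link either: under the global null the
    disease label is exchangeable, so the age-residual step only adds noise
    orthogonal to the label. (With the study's age-collinear design the
    two-step age adjustment leaves residual inflation; see the methods note.)
    """
    cfg = SimulationConfig(seed=2, n_cpgs=500, n_snps=1500, n_metabolites=40,
                           age_collinear_t2d=False)
    samples, geno, meth, mets, truth = simulate_cohort(cfg)
    return {
        "config": cfg,
        "samples": samples,
        "genotypes": geno,
        "methylation": meth,
        "metabolites": mets,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def prepared(cohort):
    """Derived objects shared by the association-stage tests."""
    samples = cohort["samples"]
    meth = cohort["methylation"]
    geno = cohort["genotypes"]
    gpcs = preprocess.genomic_pcs(geno)
    age_model = preprocess.fit_age_model(meth.beta, samples["age"], samples["t2d"] == 0)
    meth_adj = preprocess.age_residualize(meth.beta, samples["age"], age_model)
    covs = {
        tag: preprocess.build_covariates(samples, meth, geno, tag, gpcs=gpcs).design
        for tag in preprocess.MODEL_TAGS
    }
    mets_qc, _ = preprocess.metabolite_qc(cohort["metabolites"])
    return {
        "gpcs": gpcs,
        "age_model": age_model,
        "meth_adj": meth_adj,
        "covariates": covs,
        "metabolites_qc": mets_qc,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
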