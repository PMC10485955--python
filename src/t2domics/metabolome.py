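"""Metabolome-wide association and two-batch CpG-metabolite meta-analysis.

The MWAS regresses each QC'd metabolite on disease status with age, sex, BMI
and three genomic principal components as covariates, over a random 70/30
discovery/replication split; discovery keeps metabolites at the panel-wide
Bonferroni level 0.05/m and replication at 0.05/(number of discovery hits)
with a concordant effect sign.

CpG-metabolite associations reuse the EWAS model (CpG dependent, metabolite
as the predictor, no BMI) within each profiling batch; the two batch tables
are then combined by fixed-effect inverse-variance meta-analysis in the METAL
STDERR scheme, with Cochran's Q / I-squared heterogeneity, and pairs with
heterogeneity p < 0.05 excluded. With two batches that exclusion rule is
mathematically equivalent to I-squared > 73.96% (Q > 3.841 on 1 df).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import AssociationError, association_scan
from .simulate import MetaboliteMatrix


@dataclass
class MwasResult:
    discovery: pd.DataFrame
    replication: pd.DataFrame
    significant: pd.DataFrame  # replicated metabolites with both-stage stats
    n_discovery_hits: int


def _metabolite_scan(
    metabolites: MetaboliteMatrix,
    predictor: np.ndarray,
    covariates: pd.DataFrame,
    samples: pd.Index,
) -> pd.DataFrame:
    """Per-metabolite OLS handling per-row missingness."""
    X = covariates.loc[samples].to_numpy(dtype=float)
    x = np.asarray(predictor, dtype=float)
    Y = metabolites.values.loc[:, samples].to_numpy(dtype=float)
    rows = []
    complete = ~np.isnan(Y).any(axis=0)
    # fast path: metabolites with no missing values share one scan
    full = ~np.isnan(Y).any(axis=1)
    if full.any():
        beta, se, t, p, df = association_scan(Y[full], x, X)
        for k, idx in enumerate(np.flatnonzero(full)):
            rows.append((metabolites.values.index[idx], beta[k], se[k], t[k], p[k], df, len(samples)))
    for idx in np.flatnonzero(~full):
        y = Y[idx]
        ok = np.isfinite(y)
        beta, se, t, p, df = association_scan(y[ok][None, :], x[ok], X[ok])
        rows.append((metabolites.values.index[idx], beta[0], se[0], t[0], p[0], df, int(ok.sum())))
    out = pd.DataFrame(
        rows, columns=["metabolite", "beta", "se", "t", "p", "df", "n"]
    ).set_index("metabolite")
    return out.loc[metabolites.values.index]


def run_mwas(
    metabolites: MetaboliteMatrix,
    sample_table: pd.DataFrame,
    covariates: pd.DataFrame,
    *,
    split_fraction: float = 0.7,
    seed: int = 0,
    predictor: str = "t2d",
) -> MwasResult:
    """Discovery/replication MWAS with Bonferroni thresholds.

    The split is a seeded random partition of the samples present in both
    the metabolite matrix and the covariate design.
    """
    samples = metabolites.values.columns.intersection(covariates.index)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    n_disc = int(round(split_fraction * len(samples)))
    if n_disc == 0 or n_disc == len(samples):
        raise AssociationError("split produces an empty cohort")
    disc_samples = samples[perm[:n_disc]]
    rep_samples = samples[perm[n_disc:]]

    x_disc = sample_table.loc[disc_samples, predictor].to_numpy(dtype=float)
    x_rep = sample_table.loc[rep_samples, predictor].to_numpy(dtype=float)
    disc = _metabolite_scan(metabolites, x_disc, covariates, disc_samples)
    rep = _metabolite_scan(metabolites, x_rep, covariates, rep_samples)

    m_total = len(metabolites.values.index)
    hits = disc.index[disc["p"] < 0.05 / m_total]
    k = len(hits)
    if k:
        rep_hits = [
            m
            for m in hits
            if rep.loc[m, "p"] < 0.05 / k
            and np.sign(rep.loc[m, "beta"]) == np.sign(disc.loc[m, "beta"])
        ]
    else:
        rep_hits = []
    sig = pd.DataFrame(
        {
            "beta_disc": disc.loc[rep_hits, "beta"],
            "p_disc": disc.loc[rep_hits, "p"],
            "beta_rep": rep.loc[rep_hits, "beta"],
            "p_rep": rep.loc[rep_hits, "p"],
        }
    )
    return MwasResult(discovery=disc, replication=rep, significant=sig, n_discovery_hits=k)


def cpg_metabolite_batch(
    methylation_adj: pd.DataFrame,
    metabolites: MetaboliteMatrix,
    covariates: pd.DataFrame,
    batch_samples: pd.Index,
    *,
    cpgs: list[str] | None = None,
    metabolite_ids: list[str] | None = None,
    model_tag: str = "cpg_metabolite",
) -> pd.DataFrame:
    """CpG ~ metabolite associations within one batch.

    ``methylation_adj`` is the age-residualized CpG x sample matrix; the
    covariate design is the EWAS set without BMI. Returns one row per
    (CpG, metabolite) pair.
    """
    samples = pd.Index(batch_samples)
    samples = samples.intersection(methylation_adj.columns).intersection(
        metabolites.values.columns
    )
    if len(samples) == 0:
        raise AssociationError("no samples with both methylation and metabolites")
    from .ewas import prune_design

    X = prune_design(covariates.loc[samples])
    if len(samples) <= X.shape[1] + 2:
        raise AssociationError("batch smaller than the covariate design rank")
    cpg_list = cpgs if cpgs is not None else list(methylation_adj.index)
    met_list = (
        metabolite_ids if metabolite_ids is not None else list(metabolites.values.index)
    )
    Y = methylation_adj.loc[cpg_list, samples].to_numpy(dtype=float)
    Xn = X.to_numpy(dtype=float)
    rows = []
    for met in met_list:
        x = metabolites.values.loc[met, samples].to_numpy(dtype=float)
        ok = np.isfinite(x)
        beta, se, t, p, df = association_scan(Y[:, ok], x[ok], Xn[ok])
        for j, cpg in enumerate(cpg_list):
            rows.append((cpg, met, beta[j], se[j], p[j], int(ok.sum()), model_tag))
    return pd.DataFrame(
        rows, columns=["cpg", "metabolite", "beta", "se", "p", "n", "model_tag"]
    )


def inverse_variance_meta(
    records_batch1: pd.DataFrame, records_batch2: pd.DataFrame
) -> pd.DataFrame:
    """Fixed-effect inverse-variance meta-analysis of two batch tables.

    Tables must carry ``cpg``/``metabolite`` keys with ``beta`` and ``se``.
    Weights are 1/SE^2; heterogeneity is Cochran's Q against chi-square(1)
    and I-squared = max(0, (Q - df)/Q) * 100. ``excluded`` flags pairs with
    heterogeneity p < 0.05.
    """
    keys = ["cpg", "metabolite"]
    merged = records_batch1.merge(
        records_batch2, on=keys, suffixes=("_1", "_2"), validate="one_to_one"
    )
    if (merged["se_1"] <= 0).any() or (merged["se_2"] <= 0).any():
        raise AssociationError("non-positive SE in meta-analysis input")
    b = merged[["beta_1", "beta_2"]].to_numpy()
    w = 1.0 / merged[["se_1", "se_2"]].to_numpy() ** 2
    wsum = w.sum(axis=1)
    beta = (w * b).sum(axis=1) / wsum
    se = np.sqrt(1.0 / wsum)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = (w * (b - beta[:, None]) ** 2).sum(axis=1)
    df = b.shape[1] - 1
    q_p = stats.chi2.sf(q, df=df)
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.where(q > 0, np.maximum(0.0, (q - df) / q) * 100.0, 0.0)
    out = merged[keys + ["beta_1", "se_1", "beta_2", "se_2"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["q"] = q
    out["q_p"] = q_p
    out["i2"] = i2
    out["excluded"] = q_p < 0.05
    return out


def select_cpg_metabolite(
    meta_table: pd.DataFrame, n_cpgs: int, n_metabolites: int
) -> Tuple[pd.DataFrame, int, int]:
    """Bonferroni selection over all CpG x metabolite pairs, then drop
    heterogeneous pairs.

    Returns (final table, count passing the p threshold, count after the
    heterogeneity exclusion).
    """
    if len(meta_table) == 0:
        return meta_table, 0, 0
    threshold = 0.05 / (n_cpgs * n_metabolites)
    passing = meta_table[meta_table["p"] < threshold]
    final = passing[~passing["excluded"]]
    return final, len(passing), len(final)
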