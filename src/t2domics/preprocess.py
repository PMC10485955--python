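"""Deterministic transformations applied before association testing.

Three concerns live here:

* metabolite quality control: natural-log transform, single-shot +/-3 SD
  outlier masking per metabolite, re-standardization to mean 0 / SD 1, and
  removal of zero-variance or excessively missing metabolites;
* the control-only age model for methylation: per-CpG OLS of beta value on
  age fitted in controls, whose (intercept, slope) pair is then subtracted
  from all samples — used instead of an age design column because age and
  disease status are collinear in the EWAS cohorts;
* covariate design construction for each named model (EWAS with/without BMI,
  meQTL, metabolome-wide association, CpG-metabolite, CpG-HbA1c), including
  cell-count principal components, genomic principal components from
  standardized dosages, and full-rank indicator coding of the categorical
  plate / batch / well factors with a batch-by-sex interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix, MetaboliteMatrix, MethylationMatrix

SMOKING_SURROGATE_CPG = "cg0000000"  # first simulated CpG plays the AHRR role


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise unusable covariate designs."""


# --------------------------------------------------------------------------
# metabolite QC
# --------------------------------------------------------------------------


def metabolite_qc(
    raw: MetaboliteMatrix,
    *,
    log_transform: bool = True,
    sd_limit: float = 3.0,
    max_missing: float = 0.2,
) -> Tuple[MetaboliteMatrix, pd.DataFrame]:
    """Log-transform, mask +/-3 SD outliers, z-score, drop bad metabolites.

    Returns the cleaned matrix together with a QC report (one row per input
    metabolite: number of outliers masked, non-positive values masked, and a
    drop reason where applicable). Outlier masking is single-shot: limits are
    computed once on the log scale and values beyond them set missing before
    the final standardization.
    """
    values = raw.values.to_numpy(dtype=float).copy()
    report = pd.DataFrame(
        index=raw.values.index,
        data={"n_nonpositive": 0, "n_outliers": 0, "dropped_reason": ""},
    )

    if log_transform:
        nonpos = np.isfinite(values) & (values <= 0)
        if nonpos.any():
            warnings.warn(
                f"{int(nonpos.sum())} non-positive metabolite values set missing "
                "before log transform"
            )
            report["n_nonpositive"] = nonpos.sum(axis=1)
            values[nonpos] = np.nan
        values = np.log(values)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean = np.nanmean(values, axis=1, keepdims=True)
        sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
    out = np.abs(values - mean) > sd_limit * sd
    report["n_outliers"] = np.nansum(out, axis=1).astype(int)
    values[out] = np.nan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(values, axis=1, keepdims=True)
        sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
    keep = np.ones(values.shape[0], dtype=bool)
    # relative floor: float dust from nanmean must not count as variance
    floor = 1e-12 * np.maximum(1.0, np.abs(mean[:, 0]))
    zero_var = ~(sd[:, 0] > floor) | ~np.isfinite(sd[:, 0])
    report.loc[zero_var, "dropped_reason"] = "zero_variance"
    missing_frac = np.isnan(values).mean(axis=1)
    too_missing = (missing_frac > max_missing) & ~zero_var
    report.loc[too_missing, "dropped_reason"] = "missingness"
    keep &= ~zero_var & ~too_missing

    z = (values - mean) / sd
    cleaned = MetaboliteMatrix(
        values=pd.DataFrame(
            z[keep], index=raw.values.index[keep], columns=raw.values.columns
        ),
        info=raw.info.loc[raw.values.index[keep]],
    )
    return cleaned, report


# --------------------------------------------------------------------------
# age model
# --------------------------------------------------------------------------


@dataclass
class AgeAdjustModel:
    """Per-CpG (intercept, slope) pairs fitted on controls only."""

    coef: pd.DataFrame  # index cpg; columns beta0, beta1
    n_controls: int


def fit_age_model(
    cpg_values: pd.DataFrame, age: pd.Series, control_mask: pd.Series
) -> AgeAdjustModel:
    """OLS of each CpG on age within controls.

    ``cpg_values`` is CpGs x samples. Requires at least three controls with
    non-missing age and non-degenerate age variance.
    """
    controls = control_mask.reindex(cpg_values.columns).astype(bool)
    a = age.reindex(cpg_values.columns).to_numpy(dtype=float)
    use = controls.to_numpy() & np.isfinite(a)
    if use.sum() < 3:
        raise DesignError("need >= 3 controls with non-missing age")
    a_c = a[use]
    if np.ptp(a_c) == 0:
        raise DesignError("all controls share the same age; age model degenerate")
    y = cpg_values.to_numpy(dtype=float)[:, use]
    a_centered = a_c - a_c.mean()
    denom = float(a_centered @ a_centered)
    beta1 = (y @ a_centered) / denom
    beta0 = y.mean(axis=1) - beta1 * a_c.mean()
    coef = pd.DataFrame({"beta0": beta0, "beta1": beta1}, index=cpg_values.index)
    return AgeAdjustModel(coef=coef, n_controls=int(use.sum()))


def age_residualize(
    cpg_values: pd.DataFrame, age: pd.Series, model: AgeAdjustModel
) -> pd.DataFrame:
    """Subtract the control-fitted age line from every sample's CpG values.

    Samples with missing age are dropped with a warning.
    """
    a = age.reindex(cpg_values.columns).to_numpy(dtype=float)
    ok = np.isfinite(a)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} samples with missing age")
    coef = model.coef.reindex(cpg_values.index)
    pred = coef["beta0"].to_numpy()[:, None] + np.outer(
        coef["beta1"].to_numpy(), a[ok]
    )
    adjusted = cpg_values.to_numpy(dtype=float)[:, ok] - pred
    return pd.DataFrame(
        adjusted, index=cpg_values.index, columns=cpg_values.columns[ok]
    )


# --------------------------------------------------------------------------
# covariate designs
# --------------------------------------------------------------------------

MODEL_TAGS = (
    "ewas_noBMI",
    "ewas_BMI",
    "meqtl",
    "cpg_metabolite",
    "mwas",
    "cpg_hba1c",
)


@dataclass
class CovariateSet:
    """A named, full-rank covariate design (samples x columns)."""

    design: pd.DataFrame
    model_tag: str

    @property
    def columns(self) -> pd.Index:
        return self.design.columns


def cellcount_pcs(sample_table: pd.DataFrame, n_components: int = 2) -> np.ndarray:
    cells = sample_table[["neut", "baso", "eos", "mono", "lymph"]].to_numpy()
    centered = cells - cells.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    scores = centered @ vt[:n_components].T
    return scores / np.linalg.norm(scores, axis=0)


def genomic_pcs(genotypes: GenotypeMatrix, n_components: int = 3) -> pd.DataFrame:
    """Principal components of centered, frequency-scaled dosages."""
    dos = genotypes.dosages.to_numpy(dtype=float).T  # samples x snps
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    z = (dos[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    pcs = u[:, :n_components]
    return pd.DataFrame(
        pcs,
        index=genotypes.dosages.columns,
        columns=[f"gPC{k + 1}" for k in range(n_components)],
    )


def _indicator(series: pd.Series, prefix: str) -> pd.DataFrame:
    dummies = pd.get_dummies(series.astype("category"), prefix=prefix, drop_first=True)
    return dummies.astype(float)


def _base_technical(
    sample_table: pd.DataFrame, methylation: MethylationMatrix
) -> pd.DataFrame:
    """Technical + biological covariates shared by the EWAS-family models."""
    parts = [pd.Series(sample_table["sex"].astype(float), name="sex")]
    ccpc = cellcount_pcs(sample_table)
    parts.append(pd.Series(ccpc[:, 0], index=sample_table.index, name="ccPC1"))
    parts.append(pd.Series(ccpc[:, 1], index=sample_table.index, name="ccPC2"))
    parts.append(_indicator(sample_table["plate"], "plate"))
    batch = _indicator(sample_table["batch"], "batch")
    parts.append(batch)
    inter = batch.mul(sample_table["sex"].astype(float), axis=0)
    inter.columns = [c + ":sex" for c in batch.columns]
    parts.append(inter)
    parts.append(_indicator(sample_table["well"], "well"))
    smoke = methylation.beta.loc[SMOKING_SURROGATE_CPG]
    parts.append(pd.Series(smoke.reindex(sample_table.index), name="smoking_surrogate"))
    return pd.concat(parts, axis=1)


def _check_full_rank(design: pd.DataFrame, tag: str) -> pd.DataFrame:
    X = design.to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = design.columns[np.isnan(X).any(axis=0)].tolist()
        raise DesignError(f"missing values in covariates {bad} for model {tag}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns by greedy QR elimination
        keep: list[int] = []
        culprits: list[str] = []
        for j in range(X.shape[1]):
            cand = keep + [j]
            if np.linalg.matrix_rank(X[:, cand]) == len(cand):
                keep.append(j)
            else:
                culprits.append(str(design.columns[j]))
        raise DesignError(f"rank-deficient design for model {tag}: {culprits}")
    return design


def build_covariates(
    sample_table: pd.DataFrame,
    methylation: MethylationMatrix | None,
    genotypes: GenotypeMatrix | None,
    model_tag: str,
    *,
    gpcs: pd.DataFrame | None = None,
) -> CovariateSet:
    """Assemble the design matrix for a named model.

    ``mwas`` uses age, sex, BMI and three genomic PCs only; the EWAS-family
    models add the technical covariates (plate, batch, batch-by-sex, well,
    cell-count PCs, smoking surrogate). ``meqtl`` additionally includes
    disease status, BMI and age as fixed effects; ``cpg_hba1c`` is the EWAS
    set without disease status (age handled by residualization upstream).
    Precomputed genomic PCs may be passed to avoid repeated SVDs.
    """
    if model_tag not in MODEL_TAGS:
        raise DesignError(f"unknown model tag {model_tag!r}; expected one of {MODEL_TAGS}")
    if gpcs is None:
        if genotypes is None:
            raise DesignError("genomic PCs require genotypes (or pass gpcs=...)")
        gpcs = genomic_pcs(genotypes)
    gpcs = gpcs.reindex(sample_table.index)

    if model_tag == "mwas":
        design = pd.concat(
            [
                sample_table["age"].astype(float),
                sample_table["sex"].astype(float),
                sample_table["bmi"].astype(float),
                gpcs,
            ],
            axis=1,
        )
    else:
        if methylation is None:
            raise DesignError(f"model {model_tag} needs methylation (smoking surrogate)")
        design = pd.concat([_base_technical(sample_table, methylation), gpcs], axis=1)
        if model_tag == "ewas_BMI":
            design["bmi"] = sample_table["bmi"].astype(float)
        elif model_tag == "meqtl":
            design["t2d"] = sample_table["t2d"].astype(float)
            design["bmi"] = sample_table["bmi"].astype(float)
            design["age"] = sample_table["age"].astype(float)
        # ewas_noBMI, cpg_metabolite and cpg_hba1c use the shared set as-is

    design.insert(0, "intercept", 1.0)
    return CovariateSet(design=_check_full_rank(design, model_tag), model_tag=model_tag)


def qc_idempotent(cleaned: MetaboliteMatrix, **kwargs) -> MetaboliteMatrix:
    """Re-apply QC without the log step (used by the idempotence property)."""
    out, _ = metabolite_qc(cleaned, log_transform=False, **kwargs)
    return out
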