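"""Two-sample Mendelian randomization from summary statistics.

The exposure x is methylation at a CpG (per-SNP effect Bx with SE Bxse, from
the cohort's meQTL scan) and the outcome y is HbA1c (per-SNP effect By with
SE Byse, from public GWAS databases). Three estimators are provided:

* :func:`wald_ratio` — the single-variant ratio By/Bx;
* :func:`ml_single_snp` — single-SNP maximum likelihood under the bivariate
  model Bx ~ N(xi, Bxse^2), By ~ N(theta * xi, Byse^2), maximized
  numerically over (xi, theta) with the SE taken from the Fisher
  information. Analytically the MLE of theta is exactly the Wald ratio and
  the information-based SE equals the second-order delta expression
  sqrt((Byse/Bx)^2 + (By*Bxse/Bx^2)^2); both identities are enforced in the
  test suite against the numerical path;
* :func:`ivw` — fixed-effect inverse-variance weighting of per-SNP Wald
  ratios with first-order SEs Byse/|Bx|, with Cochran's Q and I-squared
  heterogeneity over the J-1 degrees of freedom.

A packaged table of per-SNP summary statistics for the HK1 and PFKFB2
methylation sites versus HbA1c (exposure effects from cohort meQTLs, outcome
effects from GWAS databases) ships with the module for worked examples; load
it with :func:`load_packaged_inputs`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


class MRError(ValueError):
    pass


@dataclass
class MRInput:
    """Per-SNP summary statistics for one variant."""

    snp: str
    bx: float
    bxse: float
    by: float
    byse: float

    def __post_init__(self) -> None:
        if self.bxse <= 0 or self.byse <= 0:
            raise MRError("standard errors must be positive")


@dataclass
class MRResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    method: str
    n_snps: int
    q: float | None = None
    q_p: float | None = None
    i2: float | None = None


def _finalize(estimate: float, se: float, method: str, n_snps: int, **kw) -> MRResult:
    z = estimate / se
    return MRResult(
        estimate=estimate,
        se=se,
        ci_low=estimate - 1.96 * se,
        ci_high=estimate + 1.96 * se,
        p=float(2.0 * stats.norm.sf(abs(z))),
        method=method,
        n_snps=n_snps,
        **kw,
    )


def wald_ratio(bx: float, by: float) -> float:
    """Single-variant causal estimate: outcome effect over exposure effect."""
    if bx == 0:
        raise MRError("exposure effect Bx = 0; ratio undefined")
    return by / bx


def ml_single_snp(inp: MRInput) -> MRResult:
    """Single-SNP maximum-likelihood estimate with Fisher-information SE.

    The likelihood is maximized numerically over (xi, theta); the variance
    of theta-hat is the (theta, theta) entry of the inverse Fisher
    information at the optimum, Var = (Byse^2 + theta^2 * Bxse^2) / xi^2.
    """
    if inp.bx == 0:
        raise MRError("exposure effect Bx = 0")

    bx, bxse, by, byse = inp.bx, inp.bxse, inp.by, inp.byse

    def negloglik(params: np.ndarray) -> float:
        xi, theta = params
        return 0.5 * (((bx - xi) / bxse) ** 2 + ((by - theta * xi) / byse) ** 2)

    start = np.array([bx, by / bx])
    res = optimize.minimize(negloglik, start, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    if not res.success and res.fun > negloglik(start) + 1e-10:
        raise MRError(f"single-SNP ML did not converge: {res.message}")
    xi, theta = res.x if res.fun <= negloglik(start) else start
    var = (byse**2 + theta**2 * bxse**2) / xi**2
    return _finalize(float(theta), float(np.sqrt(var)), "maxlik", 1)


def ivw(inputs: Sequence[MRInput]) -> MRResult:
    """Fixed-effect inverse-variance-weighted estimate over >= 2 variants.

    Per-SNP ratios are weighted by first-order variances (Byse/Bx)^2 — the
    standard IVW scheme whose combined SE matches the per-variant
    delta-method SEs to first order.
    """
    if len(inputs) < 2:
        raise MRError("IVW needs >= 2 SNPs; use the single-SNP methods")
    b = np.array([wald_ratio(i.bx, i.by) for i in inputs])
    s = np.array([i.byse / abs(i.bx) for i in inputs])
    w = 1.0 / s**2
    estimate = float((w * b).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    q = float((w * (b - estimate) ** 2).sum())
    dof = len(inputs) - 1
    q_p = float(stats.chi2.sf(q, df=dof))
    i2 = float(max(0.0, (q - dof) / q) * 100.0) if q > 0 else 0.0
    return _finalize(estimate, se, "ivw", len(inputs), q=q, q_p=q_p, i2=i2)


def cpg_outcome_assoc(
    methylation_adj: pd.DataFrame,
    sample_table: pd.DataFrame,
    covariates: pd.DataFrame,
    *,
    outcome: str = "hba1c",
    cohort: int | None = None,
    cpgs: list[str] | None = None,
) -> pd.DataFrame:
    """CpG ~ outcome regressions with the EWAS covariates minus disease status.

    Thin wrapper over the EWAS scan supporting the discovery/replication
    reporting used when confirming exposure-outcome associations before MR.
    """
    from .ewas import run_ewas

    meth = methylation_adj.loc[cpgs] if cpgs is not None else methylation_adj
    return run_ewas(
        meth,
        sample_table,
        covariates,
        cohort=cohort,
        predictor=outcome,
        model_tag="cpg_hba1c",
    )


def load_packaged_inputs() -> pd.DataFrame:
    """Summary statistics for the HK1 / PFKFB2 methylation sites vs HbA1c.

    Exposure effects (Bx, Bxse) are cohort meQTL statistics; outcome effects
    (By, Byse) come from GWAS databases (GWAS catalogue / Stanford portal).
    """
    with resources.files("t2domics.data").joinpath("mr_hba1c_inputs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def mr_from_table(table: pd.DataFrame, *, method: str = "maxlik") -> pd.DataFrame:
    """Run MR per CpG over an input table (columns snp, cpg, bx, bxse, by, byse).

    ``method='maxlik'`` fits each SNP separately; ``method='ivw'`` combines
    all SNPs of each CpG (falling back to single-SNP ML when only one is
    available).
    """
    rows = []
    for cpg, grp in table.groupby("cpg", sort=False):
        inputs = [
            MRInput(r.snp, r.bx, r.bxse, r.by, r.byse) for r in grp.itertuples()
        ]
        if method == "maxlik":
            for inp in inputs:
                res = ml_single_snp(inp)
                rows.append({"cpg": cpg, "snp": inp.snp, **res.__dict__})
        elif method == "ivw":
            res = ivw(inputs) if len(inputs) >= 2 else ml_single_snp(inputs[0])
            rows.append({"cpg": cpg, "snp": ",".join(i.snp for i in inputs), **res.__dict__})
        else:
            raise MRError(f"unknown method {method!r}")
    return pd.DataFrame(rows)
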