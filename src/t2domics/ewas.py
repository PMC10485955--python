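"""Epigenome-wide association and two-way discovery/replication selection.

Methylation is the dependent variable throughout: each CpG's beta value is
regressed on the predictor of interest (disease status, a metabolite, or
HbA1c) plus the model's covariates. Age is handled by the control-fitted
residualization in :mod:`t2domics.preprocess` rather than as a design column,
because age and disease status are collinear in the cohort design.

Selection follows the two-way scheme: CpGs passing the epigenome-wide
discovery threshold in one cohort are tested in the other at a Bonferroni
replication threshold of 0.05 divided by the number of discovery hits, the
procedure is repeated with the cohort roles swapped, the two passes are
unioned, and (after the with/without-BMI models are combined) only CpGs with
direction-consistent effects in both cohorts are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DISCOVERY_ALPHA = 5.8e-8  # epigenome-wide significance for the 850K array

CHI2_MEDIAN_1DF = 0.4549364231195728  # median of chi-square(1)


class AssociationError(ValueError):
    """Raised for degenerate association inputs (rank deficiency, no data)."""


@dataclass
class AssociationRecord:
    """One fitted feature ~ predictor result; the atom of every stage."""

    feature: str
    predictor: str
    beta: float
    se: float
    t: float
    p: float
    df: int
    n: int
    model_tag: str


def fit_linear_assoc(
    y: pd.Series | np.ndarray,
    x: pd.Series | np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    *,
    feature: str = "y",
    predictor: str = "x",
    model_tag: str = "",
) -> AssociationRecord:
    """OLS of ``y`` on ``x`` with covariates partialled by inclusion.

    Complete-case analysis: rows with any missing value are dropped. The
    fit itself is delegated to statsmodels OLS.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if covariates is None:
        X = np.column_stack([np.ones_like(x), x])
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        has_const = np.any(np.all(C == C[0], axis=0) & (C[0] != 0))
        cols = [C] if has_const else [np.ones((len(x), 1)), C]
        X = np.column_stack([*cols, x])
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[ok], X[ok]
    rank = np.linalg.matrix_rank(X)
    if len(y) < rank + 2:
        raise AssociationError("too few complete cases for the design")
    if rank < X.shape[1]:
        raise AssociationError("rank-deficient design (collinear predictor?)")
    if np.ptp(y) == 0:
        raise AssociationError("zero-variance response")
    res = sm.OLS(y, X).fit()
    j = X.shape[1] - 1  # predictor of interest is the last column
    return AssociationRecord(
        feature=feature,
        predictor=predictor,
        beta=float(res.params[j]),
        se=float(res.bse[j]),
        t=float(res.tvalues[j]),
        p=float(res.pvalues[j]),
        df=int(res.df_resid),
        n=int(len(y)),
        model_tag=model_tag,
    )


def prune_design(X: pd.DataFrame) -> pd.DataFrame:
    """Drop columns that become constant or aliased on a sample subset.

    Restricting a global covariate design to one cohort can make indicator
    or interaction columns constant (a batch absent from the cohort) or
    exact duplicates of another column (a batch-by-sex interaction when the
    cohort has a single batch). Columns are kept greedily in order while
    they increase the design rank.
    """
    M = X.to_numpy(dtype=float)
    keep: List[int] = [0]  # the intercept
    for j in range(1, M.shape[1]):
        if np.ptp(M[:, j]) == 0:
            continue
        cand = keep + [j]
        if np.linalg.matrix_rank(M[:, cand]) == len(cand):
            keep.append(j)
    return X.iloc[:, keep]


def association_scan(
    Y: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Many-response OLS scan sharing one design.

    ``Y`` is features x samples; ``x`` the predictor; ``covariates`` a
    full-rank design including the intercept. Residualizes both sides
    against the covariates (Frisch-Waugh) and computes per-feature slope,
    SE, t and two-sided p. Returns (beta, se, t, p, df).
    """
    X = np.asarray(covariates, dtype=float)
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() < 1e-10 * max(diag.max(), 1.0):
        raise AssociationError("rank-deficient covariate design in scan")
    x = np.asarray(x, dtype=float)
    x_r = x - Q @ (Q.T @ x)
    xx = float(x_r @ x_r)
    if xx <= 1e-10 * float(x @ x):
        raise AssociationError("predictor lies in the covariate span")
    Yt = np.asarray(Y, dtype=float)
    Y_r = Yt - (Yt @ Q) @ Q.T
    beta = (Y_r @ x_r) / xx
    resid = Y_r - np.outer(beta, x_r)
    df = Yt.shape[1] - X.shape[1] - 1
    sigma2 = np.einsum("ij,ij->i", resid, resid) / df
    se = np.sqrt(sigma2 / xx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, df


def run_ewas(
    methylation_adj: pd.DataFrame,
    sample_table: pd.DataFrame,
    covariates: pd.DataFrame,
    *,
    cohort: int | None = None,
    predictor: str = "t2d",
    model_tag: str = "ewas_noBMI",
) -> pd.DataFrame:
    """Per-CpG association with the predictor within one cohort.

    ``methylation_adj`` is the age-residualized CpG x sample matrix. The
    covariate design must already be restricted to (or indexable by) the
    cohort's samples. Returns one row per CpG with beta/SE/t/p/df/n.
    """
    samples = sample_table.index
    if cohort is not None:
        samples = samples[sample_table["cohort"] == cohort]
    if len(samples) == 0:
        raise AssociationError(f"cohort {cohort} is empty")
    samples = samples.intersection(methylation_adj.columns)
    X = prune_design(covariates.loc[samples])
    if len(samples) <= X.shape[1] + 2:
        raise AssociationError("cohort too small for the covariate design")
    x = sample_table.loc[samples, predictor].to_numpy(dtype=float)
    Y = methylation_adj[samples].to_numpy(dtype=float)
    beta, se, t, p, df = association_scan(Y, x, X.to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "cpg": methylation_adj.index,
            "predictor": predictor,
            "beta": beta,
            "se": se,
            "t": t,
            "p": p,
            "df": df,
            "n": len(samples),
            "model_tag": model_tag,
            "cohort": cohort if cohort is not None else 0,
        }
    ).set_index("cpg")


def genomic_inflation(p_values: Iterable[float]) -> float:
    """Genomic inflation factor: median chi-square over its null median."""
    p = np.asarray(list(p_values), dtype=float)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


@dataclass
class EwasSelection:
    """Outcome of one two-way discovery/replication pass pair."""

    table: pd.DataFrame  # index cpg; discovery_cohort, p_disc, p_rep, model_tag
    k_pass1: int  # discovery hits in cohort A
    k_pass2: int  # discovery hits in cohort B

    @property
    def cpgs(self) -> pd.Index:
        return self.table.index


def two_way_discovery_replication(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    *,
    alpha_disc: float = DISCOVERY_ALPHA,
    model_tag: str = "",
) -> EwasSelection:
    """Two-way selection over cohort association tables sharing a CpG universe.

    Pass 1: CpGs with p < ``alpha_disc`` in A are kept if their B p-value is
    below 0.05/k_A where k_A counts A's discovery hits. Pass 2 swaps the
    roles. The union is returned, each CpG tagged with its discovery cohort
    (the more significant discovery when hit both ways).
    """
    if not table_a.index.equals(table_b.index):
        raise AssociationError("cohort tables must share the same CpG universe")

    def one_pass(disc: pd.DataFrame, rep: pd.DataFrame, label: int) -> Tuple[pd.DataFrame, int]:
        hits = disc.index[disc["p"] < alpha_disc]
        k = len(hits)
        if k == 0:
            return pd.DataFrame(), 0
        thr = 0.05 / k
        replicated = [c for c in hits if rep.loc[c, "p"] < thr]
        out = pd.DataFrame(
            {
                "discovery_cohort": label,
                "p_disc": disc.loc[replicated, "p"],
                "p_rep": rep.loc[replicated, "p"],
                "beta_disc": disc.loc[replicated, "beta"],
                "beta_rep": rep.loc[replicated, "beta"],
                "model_tag": model_tag,
            },
            index=pd.Index(replicated, name="cpg"),
        )
        return out, k

    pass1, k1 = one_pass(table_a, table_b, 1)
    pass2, k2 = one_pass(table_b, table_a, 2)
    both = [c for c in pass2.index if c in pass1.index]
    for c in both:  # keep the more significant discovery's tag
        if pass2.loc[c, "p_disc"] < pass1.loc[c, "p_disc"]:
            pass1.loc[c] = pass2.loc[c]
    pass2 = pass2.drop(index=both)
    table = pd.concat([pass1, pass2])
    table.index.name = "cpg"
    return EwasSelection(table=table, k_pass1=k1, k_pass2=k2)


def combine_models(
    selection_nobmi: EwasSelection,
    selection_bmi: EwasSelection,
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
) -> pd.DataFrame:
    """Union the with/without-BMI selections and keep direction-consistent CpGs.

    Direction consistency is judged on the no-BMI cohort tables: the CpG's
    effect must have the same sign in cohort 1 and cohort 2. The output
    records which model(s) selected each CpG.
    """
    union = selection_nobmi.table.index.union(selection_bmi.table.index)
    rows = []
    for cpg in union:
        in_nobmi = cpg in selection_nobmi.table.index
        in_bmi = cpg in selection_bmi.table.index
        src = selection_nobmi.table if in_nobmi else selection_bmi.table
        sign_a = np.sign(table_a.loc[cpg, "beta"])
        sign_b = np.sign(table_b.loc[cpg, "beta"])
        consistent = bool(sign_a == sign_b and sign_a != 0)
        rows.append(
            {
                "cpg": cpg,
                "discovery_cohort": src.loc[cpg, "discovery_cohort"],
                "p_disc": src.loc[cpg, "p_disc"],
                "models": "both" if (in_nobmi and in_bmi) else ("no_bmi" if in_nobmi else "bmi"),
                "direction_consistent": consistent,
            }
        )
    out = pd.DataFrame(rows).set_index("cpg") if rows else pd.DataFrame(
        columns=["discovery_cohort", "p_disc", "models", "direction_consistent"]
    )
    return out[out["direction_consistent"]] if len(out) else out
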