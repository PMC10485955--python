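"""Kinship-aware meQTL mapping: polygenic fit, score test, cis/trans, replication.

The association model per CpG is the Gaussian mixed model

    y ~ N(X beta, sigma2_g * 2K + sigma2_e * I)

with K the kinship matrix estimated from genome-wide dosages (so 2K is the
genomic relationship matrix). Variance components are fitted once per CpG by
maximum likelihood with a one-dimensional profile search over the heritability
ratio h2 = sigma2_g / (sigma2_g + sigma2_e) on the spectral decomposition of
2K. Each SNP is then tested with the score statistic

    T = (g'V^-1 r)^2 / (g'V^-1 g),        g centered,  r the polygenic residuals,

against chi-square(1) — the classical family of mixed-model score tests for
dense genotype scans. Pairs are labeled cis when SNP and CpG share a
chromosome at < 1 Mb, trans otherwise; discovery pairs replicate when the
replication scan finds the same CpG either at the identical SNP or at any SNP
within a +/-500 kb locus window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import GenotypeMatrix, MethylationMatrix

CIS_WINDOW = 1_000_000  # bp; exclusive upper bound for the cis label
LOCUS_WINDOW = 500_000  # bp; replication search window around the SNP
MEQTL_ALPHA = 8.7e-10  # genome-wide discovery threshold for the SNP-CpG scan


class KinshipError(ValueError):
    pass


# --------------------------------------------------------------------------
# kinship
# --------------------------------------------------------------------------


def estimate_kinship(genotypes: GenotypeMatrix, *, bend_floor: float = 1e-6) -> np.ndarray:
    """Genomic relationship matrix from centered, frequency-scaled dosages.

    GRM = Z Z' / m with z_ij = (g_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)); any
    negative eigenvalues are bent up to ``bend_floor`` so downstream solves
    are positive semi-definite. Requires >= 100 polymorphic SNPs.
    """
    dos = genotypes.dosages.to_numpy(dtype=float).T  # samples x snps
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() == 0:
        raise KinshipError("all SNPs are monomorphic; cannot estimate kinship")
    if poly.sum() < 100:
        raise KinshipError(f"need >= 100 polymorphic SNPs, got {int(poly.sum())}")
    p = p[poly]
    z = (dos[:, poly] - 2 * p) / np.sqrt(2 * p * (1 - p))
    grm = z @ z.T / poly.sum()
    w, v = np.linalg.eigh(grm)
    if w.min() < bend_floor:
        w = np.maximum(w, bend_floor)
        grm = (v * w) @ v.T
    return grm


# --------------------------------------------------------------------------
# polygenic mixed model
# --------------------------------------------------------------------------


@dataclass
class PolygenicFit:
    """ML fit of the polygenic model on one phenotype.

    Stores the spectral pieces of V^-1 (eigenvectors of the GRM and the
    per-eigenvalue weights at the optimum) so score tests can apply V^-1
    without refactorizing.
    """

    beta: np.ndarray
    sigma2_g: float
    sigma2_e: float
    h2: float
    residuals: np.ndarray
    eigvecs: np.ndarray  # eigenvectors of the relationship matrix (2K)
    vinv_weights: np.ndarray  # 1 / (sigma2_total * (h2 * d + 1 - h2))
    loglik: float

    def vinv(self, x: np.ndarray) -> np.ndarray:
        """Apply V^-1 to a vector or matrix of column vectors."""
        rot = self.eigvecs.T @ x
        if rot.ndim == 1:
            return self.eigvecs @ (self.vinv_weights * rot)
        return self.eigvecs @ (self.vinv_weights[:, None] * rot)


def fit_polygenic(
    y: np.ndarray,
    covariates: np.ndarray,
    kinship: np.ndarray,
    *,
    h2_grid_tol: float = 1e-6,
) -> PolygenicFit:
    """Maximize the Gaussian likelihood by profiling over h2 in [0, 1).

    The relationship matrix 2K is eigendecomposed once; for each candidate h2
    the model reduces to weighted least squares in the rotated basis, with
    the total variance profiled out analytically.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(covariates, dtype=float)
    n = len(y)
    rel = 2.0 * np.asarray(kinship, dtype=float)
    d, U = np.linalg.eigh(rel)
    if d.min() < -1e-8:
        raise KinshipError("relationship matrix not PSD even after bending")
    d = np.maximum(d, 0.0)
    yr = U.T @ y
    Xr = U.T @ X

    def profile_negloglik(h2: float) -> float:
        lam = h2 * d + (1.0 - h2)
        w = 1.0 / lam
        Xw = Xr * w[:, None]
        beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
        r = yr - Xr @ beta
        rss = float(r @ (w * r))
        sigma2 = rss / n
        return 0.5 * (n * np.log(sigma2) + np.log(lam).sum() + n)

    res = optimize.minimize_scalar(
        profile_negloglik, bounds=(0.0, 1.0 - 1e-6), method="bounded",
        options={"xatol": h2_grid_tol},
    )
    h2 = float(res.x)
    # accept a boundary solution when the interior optimum is no better
    for edge in (0.0,):
        if profile_negloglik(edge) <= res.fun + 1e-10:
            h2 = edge
            break
    lam = h2 * d + (1.0 - h2)
    w = 1.0 / lam
    Xw = Xr * w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    r_rot = yr - Xr @ beta
    sigma2_total = float(r_rot @ (w * r_rot)) / n
    fit = PolygenicFit(
        beta=beta,
        sigma2_g=h2 * sigma2_total,
        sigma2_e=(1.0 - h2) * sigma2_total,
        h2=h2,
        residuals=U @ r_rot,
        eigvecs=U,
        vinv_weights=w / sigma2_total,
        loglik=-profile_negloglik(h2),
    )
    return fit


def mmscore_test(
    fit: PolygenicFit, genotype: np.ndarray
) -> Tuple[float, float, float, float]:
    """Mixed-model score test of one SNP on the polygenic residuals.

    Returns (beta, se, chi2, p). The genotype is centered; monomorphic input
    raises ValueError (callers skip such SNPs).
    """
    g = np.asarray(genotype, dtype=float)
    if np.ptp(g) == 0:
        raise ValueError("monomorphic SNP")
    g = g - g.mean()
    vg = fit.vinv(g)
    denom = float(g @ vg)
    num = float(g @ fit.vinv(fit.residuals))
    chi2 = num * num / denom
    beta = num / denom
    se = 1.0 / np.sqrt(denom)
    p = float(stats.chi2.sf(chi2, df=1))
    return beta, se, chi2, p


def mmscore_scan(fit: PolygenicFit, dosages: np.ndarray) -> pd.DataFrame:
    """Vectorized score test over a SNPs x samples dosage matrix."""
    G = np.asarray(dosages, dtype=float)
    Gc = G - G.mean(axis=1, keepdims=True)
    poly = np.ptp(G, axis=1) > 0
    VG = fit.vinv(Gc.T)  # samples x snps
    denom = np.einsum("ij,ji->i", Gc, VG)
    num = Gc @ fit.vinv(fit.residuals)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(poly, num * num / denom, np.nan)
        beta = np.where(poly, num / denom, np.nan)
        se = np.where(poly, 1.0 / np.sqrt(denom), np.nan)
    p = stats.chi2.sf(chi2, df=1)
    return pd.DataFrame({"beta": beta, "se": se, "chi2": chi2, "p": p, "tested": poly})


# --------------------------------------------------------------------------
# scan + classification + replication
# --------------------------------------------------------------------------


def classify_cis_trans(
    snp_chrom, snp_pos, cpg_chrom, cpg_pos, *, window: int = CIS_WINDOW
) -> str:
    """cis when same chromosome and distance strictly below the window."""
    if pd.isna(snp_chrom) or pd.isna(cpg_chrom) or pd.isna(snp_pos) or pd.isna(cpg_pos):
        import warnings

        warnings.warn("missing coordinates; pair left unlabeled")
        return "unlabeled"
    if snp_chrom == cpg_chrom and abs(int(snp_pos) - int(cpg_pos)) < window:
        return "cis"
    return "trans"


def run_meqtl(
    methylation: MethylationMatrix,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    kinship: np.ndarray,
    *,
    cpg_set: list[str] | None = None,
    samples: pd.Index | None = None,
    alpha: float = MEQTL_ALPHA,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """All SNP x CpG mixed-model score tests for the supplied CpG set.

    One polygenic fit per CpG (covariate design shared), then the score scan
    over every SNP passing the MAF filter. Pairs with p < ``alpha`` are
    returned with coordinates, distances and cis/trans labels.
    """
    cpgs = list(cpg_set) if cpg_set is not None else list(methylation.beta.index)
    if not cpgs:
        return _empty_pairs()
    if samples is None:
        samples = covariates.index
    samples = pd.Index(samples)
    from .ewas import prune_design

    X = prune_design(covariates.loc[samples]).to_numpy(dtype=float)
    kin_idx = genotypes.dosages.columns.get_indexer(samples)
    K = kinship[np.ix_(kin_idx, kin_idx)]

    dos = genotypes.dosages.loc[:, samples].to_numpy(dtype=float)
    maf = dos.mean(axis=1) / 2.0
    maf = np.minimum(maf, 1 - maf)
    snp_ok = maf > maf_min
    dos = dos[snp_ok]
    snp_info = genotypes.info.loc[snp_ok]

    rows = []
    for cpg in cpgs:
        y = methylation.beta.loc[cpg, samples].to_numpy(dtype=float)
        fit = fit_polygenic(y, X, K)
        scan = mmscore_scan(fit, dos)
        hits = scan.index[(scan["p"] < alpha) & scan["tested"]]
        c_chrom = methylation.info.loc[cpg, "chrom"]
        c_pos = int(methylation.info.loc[cpg, "pos"])
        for i in hits:
            s_chrom = snp_info.iloc[i]["chrom"]
            s_pos = int(snp_info.iloc[i]["pos"])
            dist = abs(s_pos - c_pos) if s_chrom == c_chrom else np.nan
            rows.append(
                {
                    "snp": snp_info.index[i],
                    "snp_chrom": s_chrom,
                    "snp_pos": s_pos,
                    "cpg": cpg,
                    "cpg_chrom": c_chrom,
                    "cpg_pos": c_pos,
                    "beta": scan.loc[i, "beta"],
                    "se": scan.loc[i, "se"],
                    "p": scan.loc[i, "p"],
                    "distance": dist,
                    "label": classify_cis_trans(s_chrom, s_pos, c_chrom, c_pos),
                }
            )
    return pd.DataFrame(rows) if rows else _empty_pairs()


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "snp", "snp_chrom", "snp_pos", "cpg", "cpg_chrom", "cpg_pos",
            "beta", "se", "p", "distance", "label",
        ]
    )


def locus_replicate(
    discovery_pairs: pd.DataFrame,
    replication_pairs: pd.DataFrame,
    *,
    window: int = LOCUS_WINDOW,
    alpha_rep: float | None = None,
) -> pd.Series:
    """Replication status per discovery pair.

    A discovery pair replicates when the replication table has the same CpG
    at the identical SNP, or at any SNP on the same chromosome within
    +/-``window`` bp, passing ``alpha_rep`` (default 0.05 / n_discovery).
    """
    if alpha_rep is None:
        alpha_rep = 0.05 / max(len(discovery_pairs), 1)
    rep = replication_pairs[replication_pairs["p"] < alpha_rep]
    status = []
    for _, row in discovery_pairs.iterrows():
        cand = rep[rep["cpg"] == row["cpg"]]
        hit = False
        if len(cand):
            exact = cand["snp"] == row["snp"]
            nearby = (cand["snp_chrom"] == row["snp_chrom"]) & (
                (cand["snp_pos"] - row["snp_pos"]).abs() <= window
            )
            hit = bool((exact | nearby).any())
        status.append(hit)
    return pd.Series(status, index=discovery_pairs.index, name="replicated")
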