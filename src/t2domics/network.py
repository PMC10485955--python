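"""Tripartite multi-omics network: SNP, CpG and metabolite nodes.

Metabolite-metabolite edges come from a Gaussian graphical model: metabolite
residuals (after covariate correction) are summarized by a correlation matrix
shrunk toward the identity with the analytic Ledoit-Wolf/Schafer-Strimmer
intensity, partial correlations are read off its inverse via

    pcor_ij = -P_ij / sqrt(P_ii * P_jj),

and each edge is tested with the Fisher z transform at an effective sample
size of n minus the number of conditioning variables, keeping edges below the
Bonferroni threshold over all metabolite pairs. SNP-CpG edges are meQTL
pairs, CpG-metabolite edges the meta-analytic associations; the three layers
are joined into one typed undirected graph, with duplicate edges collapsed to
the smaller p-value, and connected components reported by size.
"""

from __future__ import annotations

import warnings
from typing import Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .ewas import AssociationError


# --------------------------------------------------------------------------
# residualization and the GGM
# --------------------------------------------------------------------------


def residualize_metabolites(
    metabolites: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Per-metabolite OLS residuals against the full covariate design.

    ``metabolites`` is metabolites x samples; rows with missing values are
    mean-imputed per metabolite before projection (the GGM needs a complete
    matrix), which is noted in the methods documentation.
    """
    samples = metabolites.columns.intersection(covariates.index)
    X = covariates.loc[samples].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise AssociationError("rank-deficient covariate design")
    Y = metabolites[samples].to_numpy(dtype=float)
    row_mean = np.nanmean(Y, axis=1, keepdims=True)
    Y = np.where(np.isnan(Y), row_mean, Y)
    Q, _ = np.linalg.qr(X)
    resid = Y - (Y @ Q) @ Q.T
    return pd.DataFrame(resid, index=metabolites.index, columns=samples)


def shrinkage_correlation(data: np.ndarray) -> Tuple[np.ndarray, float]:
    """Correlation matrix shrunk toward identity with analytic intensity.

    ``data`` is samples x variables. The intensity is the standard ratio of
    the summed sampling variances of the empirical correlations to their
    summed squares, clipped into [0, 1].
    """
    n, p = data.shape
    z = (data - data.mean(axis=0)) / data.std(axis=0, ddof=1)
    r = (z.T @ z) / (n - 1)
    np.fill_diagonal(r, 1.0)
    # var of r_ij estimated from the variance of the cross-product terms
    w = z[:, :, None] * z[:, None, :]  # n x p x p
    var_r = w.var(axis=0, ddof=1) * n / (n - 1) ** 2
    iu = np.triu_indices(p, k=1)
    denom = float((r[iu] ** 2).sum())
    lam = float(var_r[iu].sum() / denom) if denom > 0 else 1.0
    if not 0.0 <= lam <= 1.0:
        warnings.warn(f"shrinkage intensity {lam:.3f} clipped into [0, 1]")
        lam = min(max(lam, 0.0), 1.0)
    r_shrunk = (1.0 - lam) * r
    np.fill_diagonal(r_shrunk, 1.0)
    return r_shrunk, lam


def partial_correlations(corr: np.ndarray) -> np.ndarray:
    """Partial correlations from the inverse of a correlation matrix."""
    P = np.linalg.inv(corr)
    d = np.sqrt(np.diag(P))
    pcor = -P / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def partial_correlation_network(
    residuals: pd.DataFrame,
    *,
    alpha_total: float = 0.05,
) -> pd.DataFrame:
    """Bonferroni-thresholded GGM edge list over metabolite residuals.

    ``residuals`` is metabolites x samples. Edges are tested by Fisher z on
    the shrunk partial correlations with effective sample size
    n - (p - 2) - 3; the threshold is ``alpha_total`` divided by the number
    of metabolite pairs.
    """
    p, n = residuals.shape
    if n <= 3:
        raise AssociationError("need more than 3 samples for partial correlations")
    corr, lam = shrinkage_correlation(residuals.to_numpy(dtype=float).T)
    pcor = partial_correlations(corr)
    n_eff = n - (p - 2) - 3
    if n_eff < 1:
        raise AssociationError("too few samples for the panel size (n_eff < 1)")
    iu = np.triu_indices(p, k=1)
    r = np.clip(pcor[iu], -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(r) * np.sqrt(n_eff)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    n_pairs = len(r)
    threshold = alpha_total / n_pairs
    keep = pvals < threshold
    ids = residuals.index
    return pd.DataFrame(
        {
            "a": ids[iu[0][keep]],
            "b": ids[iu[1][keep]],
            "pcor": r[keep],
            "p": pvals[keep],
            "shrinkage": lam,
        }
    )


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

LAYER_BY_EDGE = {
    "meqtl": ("snp", "cpg"),
    "cpg_met": ("cpg", "metabolite"),
    "met_met": ("metabolite", "metabolite"),
}


def assemble_network(
    meqtl_pairs: pd.DataFrame | None = None,
    cpg_met_pairs: pd.DataFrame | None = None,
    met_met_edges: pd.DataFrame | None = None,
) -> nx.Graph:
    """Typed undirected union of the three edge sets.

    Node layers are inferred from edge types; conflicting assignments raise.
    Duplicate edges keep the smaller p-value. Edge weights are the effect
    size (meqtl, cpg_met) or the partial correlation (met_met).
    """
    g = nx.Graph()

    def add(u: str, v: str, etype: str, weight: float, p: float) -> None:
        lu, lv = LAYER_BY_EDGE[etype]
        if u == v:
            raise AssociationError(f"self-edge on {u}")
        for node, layer in ((u, lu), (v, lv)):
            if node in g.nodes and g.nodes[node]["layer"] != layer:
                raise AssociationError(
                    f"node {node} assigned to layers "
                    f"{g.nodes[node]['layer']} and {layer}"
                )
            g.add_node(node, layer=layer)
        if g.has_edge(u, v) and g.edges[u, v]["p"] <= p:
            return
        g.add_edge(u, v, type=etype, weight=float(weight), p=float(p))

    if meqtl_pairs is not None:
        for r in meqtl_pairs.itertuples():
            add(str(r.snp), str(r.cpg), "meqtl", r.beta, r.p)
    if cpg_met_pairs is not None:
        for r in cpg_met_pairs.itertuples():
            add(str(r.cpg), str(r.metabolite), "cpg_met", r.beta, r.p)
    if met_met_edges is not None:
        for r in met_met_edges.itertuples():
            add(str(r.a), str(r.b), "met_met", r.pcor, r.p)
    return g


def component_stats(g: nx.Graph) -> pd.DataFrame:
    """Node and edge counts per connected component, largest first."""
    rows = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        rows.append({"n_nodes": sub.number_of_nodes(), "n_edges": sub.number_of_edges()})
    out = pd.DataFrame(rows, columns=["n_nodes", "n_edges"])
    return out.sort_values(["n_nodes", "n_edges"], ascending=False).reset_index(drop=True)


# --------------------------------------------------------------------------
# exports
# --------------------------------------------------------------------------


def write_sif(g: nx.Graph, path) -> None:
    """Simple interaction format: `node1 edgetype node2` per line."""
    with open(path, "w") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{data['type']}\t{v}\n")


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def write_tables(g: nx.Graph, node_path, edge_path) -> None:
    """Cytoscape-loadable node and edge attribute tables."""
    nodes = pd.DataFrame(
        [{"id": n, "layer": d["layer"]} for n, d in g.nodes(data=True)]
    ).sort_values("id")
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, "type": d["type"], "weight": d["weight"], "p": d["p"]}
            for u, v, d in g.edges(data=True)
        ]
    )
    if len(edges):
        edges = edges.sort_values(["source", "target"])
    nodes.to_csv(node_path, sep="\t", index=False)
    edges.to_csv(edge_path, sep="\t", index=False)
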