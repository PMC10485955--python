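"""Assemble the tripartite SNP-CpG-metabolite network.

Metabolite residuals (after the MWAS covariates) feed the shrinkage GGM;
Bonferroni-significant partial correlations become metabolite-metabolite
edges, joined with the meQTL pairs and the meta-analytic CpG-metabolite
associations. Exports SIF/GraphML/TSV and per-component counts under
results/network/.
"""

import pandas as pd
from _common import RESULTS, derive, load_cohort

from t2domics import network, preprocess


def main() -> None:
    samples, geno, meth, mets = load_cohort()
    _, _, covs = derive(samples, geno, meth)
    mets_qc, _ = preprocess.metabolite_qc(mets)

    resid = network.residualize_metabolites(mets_qc.values, covs["mwas"])
    met_edges = network.partial_correlation_network(resid)

    meqtl_pairs = pd.read_csv(RESULTS / "meqtl" / "meqtl_pairs.tsv", sep="\t")
    cpgmet = pd.read_csv(RESULTS / "metabolome" / "cpg_metabolite_selected.tsv",
                         sep="\t")
    g = network.assemble_network(
        meqtl_pairs if len(meqtl_pairs) else None,
        cpgmet if len(cpgmet) else None,
        met_edges if len(met_edges) else None,
    )

    out = RESULTS / "network"
    out.mkdir(parents=True, exist_ok=True)
    network.write_sif(g, out / "network.sif")
    network.write_graphml(g, out / "network.graphml")
    network.write_tables(g, out / "network_nodes.tsv", out / "network_edges.tsv")
    comp = network.component_stats(g)
    comp.to_csv(out / "network_components.tsv", sep="\t", index=False)

    layers = pd.Series([d["layer"] for _, d in g.nodes(data=True)]).value_counts()
    print(f"network: {g.number_of_nodes()} nodes "
          f"({layers.to_dict()}), {g.number_of_edges()} edges, "
          f"{len(comp)} connected components")
    if len(comp):
        print(f"largest component: {comp.loc[0, 'n_nodes']} nodes, "
              f"{comp.loc[0, 'n_edges']} edges")


if __name__ == "__main__":
    main()
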