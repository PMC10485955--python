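"""T2D MWAS funnel and two-batch CpG-metabolite meta-analysis.

QC's the metabolite panel (log, +/-3 SD outliers, z-score), runs the 70/30
Bonferroni discovery/replication MWAS, then associates the EWAS-selected
CpGs with the replicated metabolites in two profiling batches and combines
them by fixed-effect inverse-variance meta-analysis, excluding heterogeneous
pairs (Q p < 0.05, equivalently I2 > 74% with two batches). Writes
results/metabolome/.
"""

import pandas as pd
from _common import RESULTS, derive, load_cohort

from t2domics import metabolome, preprocess


def main() -> None:
    samples, geno, meth, mets = load_cohort()
    _, meth_adj, covs = derive(samples, geno, meth)
    mets_qc, qc_report = preprocess.metabolite_qc(mets)
    selected = pd.read_csv(RESULTS / "ewas" / "ewas_selected.tsv", sep="\t")
    cpgs = list(selected["cpg"])

    out = RESULTS / "metabolome"
    out.mkdir(parents=True, exist_ok=True)
    qc_report.to_csv(out / "metabolite_qc_report.tsv", sep="\t")

    mwas = metabolome.run_mwas(mets_qc, samples, covs["mwas"], seed=1)
    mwas.significant.to_csv(out / "mwas_significant.tsv", sep="\t")
    print(f"MWAS funnel: {len(mets_qc.values)} metabolites -> "
          f"{mwas.n_discovery_hits} discovery hits -> "
          f"{len(mwas.significant)} replicated")

    met_ids = list(mwas.significant.index)
    if cpgs and met_ids:
        b1 = samples.index[samples["met_batch"] == 1]
        b2 = samples.index[samples["met_batch"] == 2]
        t1 = metabolome.cpg_metabolite_batch(meth_adj, mets_qc,
                                             covs["cpg_metabolite"], b1,
                                             cpgs=cpgs, metabolite_ids=met_ids)
        t2 = metabolome.cpg_metabolite_batch(meth_adj, mets_qc,
                                             covs["cpg_metabolite"], b2,
                                             cpgs=cpgs, metabolite_ids=met_ids)
        meta = metabolome.inverse_variance_meta(t1, t2)
        final, n_pass, n_final = metabolome.select_cpg_metabolite(
            meta, len(cpgs), len(met_ids)
        )
        meta.to_csv(out / "cpg_metabolite_meta.tsv", sep="\t", index=False)
        final.to_csv(out / "cpg_metabolite_selected.tsv", sep="\t", index=False)
        print(f"CpG-metabolite meta-analysis: {len(meta)} pairs tested, "
              f"{n_pass} below the Bonferroni threshold, "
              f"{n_pass - n_final} removed for heterogeneity, {n_final} kept")
    else:
        print("no CpGs or metabolites survived upstream selection")


if __name__ == "__main__":
    main()
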