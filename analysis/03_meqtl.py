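"""Kinship-aware meQTL mapping for the EWAS-selected CpGs.

Estimates the genomic relationship matrix, fits the polygenic model per CpG
on the meQTL covariates (disease status, BMI, age plus the technical set),
scans every SNP with the mixed-model score test in the genotyping-batch
discovery split, labels pairs cis/trans and checks 500-kb locus replication
in the second batch. Writes results/meqtl/meqtl_pairs.tsv.
"""

import pandas as pd
from _common import RESULTS, derive, load_cohort

from t2domics import meqtl


def main() -> None:
    samples, geno, meth, _ = load_cohort()
    _, _, covs = derive(samples, geno, meth)
    selected = pd.read_csv(RESULTS / "ewas" / "ewas_selected.tsv", sep="\t")
    cpgs = list(selected["cpg"])

    kin = meqtl.estimate_kinship(geno)
    disc = samples.index[samples["geno_batch"] == 1]
    rep = samples.index[samples["geno_batch"] == 2]
    pairs = meqtl.run_meqtl(meth, geno, covs["meqtl"], kin,
                            cpg_set=cpgs, samples=disc)
    pairs_rep = meqtl.run_meqtl(meth, geno, covs["meqtl"], kin,
                                cpg_set=cpgs, samples=rep, alpha=1e-3)
    if len(pairs):
        pairs["replicated"] = meqtl.locus_replicate(pairs, pairs_rep)

    out = RESULTS / "meqtl"
    out.mkdir(parents=True, exist_ok=True)
    pairs.to_csv(out / "meqtl_pairs.tsv", sep="\t", index=False)
    n_cis = int((pairs["label"] == "cis").sum()) if len(pairs) else 0
    n_rep = int(pairs["replicated"].sum()) if len(pairs) else 0
    print(f"{len(pairs)} significant SNP-CpG pairs over {len(cpgs)} CpGs "
          f"({n_cis} cis, {len(pairs) - n_cis} trans); "
          f"{n_rep} replicated within the 500-kb locus window")


if __name__ == "__main__":
    main()
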