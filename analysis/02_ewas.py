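"""Two-way discovery/replication EWAS of methylation on T2D.

Runs the with- and without-BMI models on cohorts 1 and 2 (age handled by the
control-fitted residual adjustment), applies the two-way selection with the
epigenome-wide discovery threshold and Bonferroni replication, combines the
two models and keeps direction-consistent CpGs. Writes the full summary
statistics and the selected set under results/ewas/.
"""

import pandas as pd
from _common import RESULTS, derive, load_cohort

from t2domics import ewas, preprocess


def main() -> None:
    samples, geno, meth, _ = load_cohort()
    _, meth_adj, covs = derive(samples, geno, meth)
    meth_scan = meth_adj.drop(index=[preprocess.SMOKING_SURROGATE_CPG])

    tables = {}
    for tag in ("ewas_noBMI", "ewas_BMI"):
        for cohort in (1, 2):
            tables[(tag, cohort)] = ewas.run_ewas(
                meth_scan, samples, covs[tag], cohort=cohort, model_tag=tag
            )
    selections = {
        tag: ewas.two_way_discovery_replication(
            tables[(tag, 1)], tables[(tag, 2)], model_tag=tag
        )
        for tag in ("ewas_noBMI", "ewas_BMI")
    }
    final = ewas.combine_models(
        selections["ewas_noBMI"], selections["ewas_BMI"],
        tables[("ewas_noBMI", 1)], tables[("ewas_noBMI", 2)],
    )

    out = RESULTS / "ewas"
    out.mkdir(parents=True, exist_ok=True)
    pd.concat(tables.values()).to_csv(out / "ewas_full.tsv", sep="\t")
    final.to_csv(out / "ewas_selected.tsv", sep="\t")
    for tag, sel in selections.items():
        print(f"{tag}: {sel.k_pass1} discovery hits in cohort 1, "
              f"{sel.k_pass2} in cohort 2, {len(sel.table)} replicated")
    print(f"combined direction-consistent selection: {len(final)} CpGs "
          f"-> {out / 'ewas_selected.tsv'}")


if __name__ == "__main__":
    main()
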