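"""Generate the synthetic study cohort and write its tables.

A 900-sample cohort in three profiling batches with the standard planted
panel: five disease-associated CpGs, four SNP-CpG pairs (cis and trans),
three disease-shifted metabolites, two CpG-metabolite links and one
CpG-HbA1c effect. Ground truth goes to results/cohort/ground_truth.json.
"""

from _common import COHORT_DIR

from t2domics import io
from t2domics.simulate import SimulationConfig, default_effects, simulate_cohort


def main() -> None:
    cfg = default_effects(SimulationConfig(seed=1))
    samples, geno, meth, mets, truth = simulate_cohort(cfg)
    COHORT_DIR.mkdir(parents=True, exist_ok=True)
    io.write_sample_table(samples, COHORT_DIR / "samples.tsv")
    io.write_vcf(geno, COHORT_DIR / "genotypes.vcf")
    io.write_methylation(meth, COHORT_DIR / "methylation.tsv")
    io.write_metabolites(mets, COHORT_DIR / "metabolites_raw.tsv")
    io.write_ground_truth(truth, COHORT_DIR / "ground_truth.json")
    n_case = int(samples["t2d"].sum())
    print(f"cohort written: {len(samples)} samples ({n_case} cases, "
          f"{n_case / len(samples):.1%}), {len(meth.beta)} CpGs, "
          f"{len(geno.dosages)} SNPs, {len(mets.values)} metabolites")
    print(f"planted: {len(truth.cpg_t2d_beta_scale)} disease CpGs, "
          f"{len(truth.snp_cpg_beta_scale)} meQTL pairs, "
          f"{len(truth.t2d_metabolite)} disease metabolites, "
          f"{len(truth.cpg_metabolite)} CpG-metabolite links")


if __name__ == "__main__":
    main()
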