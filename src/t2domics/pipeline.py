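"""End-to-end orchestration of the analysis stages on one cohort.

``run_pipeline`` executes simulate -> preprocess -> EWAS -> meQTL ->
metabolome -> MR -> network, writing each stage's TSV outputs plus a JSON
manifest (input hashes, seed, thresholds, counts) into the artifact
directory. Reruns with the same configuration are byte-identical because
every random draw sits behind the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd
import yaml

from . import ewas, io, meqtl, metabolome, mr, network, preprocess
from .simulate import SimulationConfig, default_effects, simulate_cohort


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Thresholds, seeds and split rules for one pipeline run."""

    simulation: SimulationConfig = field(default_factory=lambda: default_effects(SimulationConfig()))
    alpha_disc: float = ewas.DISCOVERY_ALPHA
    alpha_meqtl: float = meqtl.MEQTL_ALPHA
    locus_window: int = meqtl.LOCUS_WINDOW
    mwas_split: float = 0.7
    mwas_seed: int = 0
    ggm_alpha_total: float = 0.05

    def validate(self) -> None:
        for name in ("alpha_disc", "alpha_meqtl"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise PipelineError(f"{name} must lie in (0, 1], got {v}")
        if self.locus_window <= 0:
            raise PipelineError("locus_window must be positive")
        self.simulation.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = default_effects(SimulationConfig(**raw.pop("simulation", {})))
        cfg = cls(simulation=sim, **raw)
        cfg.validate()
        return cfg


def run_pipeline(config: PipelineConfig, out_dir) -> Dict[str, object]:
    """Run every stage; returns a dict of in-memory stage results.

    Stage failures raise :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # ---- simulate ---------------------------------------------------------
    def _simulate():
        samples, geno, meth, mets, truth = simulate_cohort(config.simulation)
        io.write_sample_table(samples, out / "samples.tsv")
        io.write_methylation(meth, out / "methylation.tsv")
        io.write_metabolites(mets, out / "metabolites_raw.tsv")
        io.write_vcf(geno, out / "genotypes.vcf")
        io.write_ground_truth(truth, out / "ground_truth.json")
        io.write_manifest(
            out / "manifest_simulate.json",
            stage="simulate",
            inputs={},
            seed=config.simulation.seed,
            thresholds={},
            counts={
                "n_samples": config.simulation.n_samples,
                "n_cpgs": config.simulation.n_cpgs,
                "n_snps": config.simulation.n_snps,
                "n_metabolites": config.simulation.n_metabolites,
            },
        )
        return samples, geno, meth, mets, truth

    samples, geno, meth, mets, truth = stage("simulate")(_simulate)
    results["truth"] = truth

    # ---- preprocess -------------------------------------------------------
    def _preprocess():
        mets_qc, report = preprocess.metabolite_qc(mets)
        report.to_csv(out / "metabolite_qc_report.tsv", sep="\t")
        gpcs = preprocess.genomic_pcs(geno)
        age_model = preprocess.fit_age_model(
            meth.beta, samples["age"], samples["t2d"] == 0
        )
        meth_adj = preprocess.age_residualize(meth.beta, samples["age"], age_model)
        covs = {
            tag: preprocess.build_covariates(samples, meth, geno, tag, gpcs=gpcs).design
            for tag in preprocess.MODEL_TAGS
        }
        return mets_qc, meth_adj, covs, gpcs

    mets_qc, meth_adj, covs, gpcs = stage("preprocess")(_preprocess)
    results["metabolites_qc"] = mets_qc

    # ---- EWAS -------------------------------------------------------------
    def _ewas():
        # the smoking surrogate serves as a covariate, never as a response
        meth_scan = meth_adj.drop(index=[preprocess.SMOKING_SURROGATE_CPG],
                                  errors="ignore")
        tables = {}
        for tag in ("ewas_noBMI", "ewas_BMI"):
            for cohort in (1, 2):
                tables[(tag, cohort)] = ewas.run_ewas(
                    meth_scan, samples, covs[tag], cohort=cohort, model_tag=tag
                )
        sel = {
            tag: ewas.two_way_discovery_replication(
                tables[(tag, 1)], tables[(tag, 2)],
                alpha_disc=config.alpha_disc, model_tag=tag,
            )
            for tag in ("ewas_noBMI", "ewas_BMI")
        }
        final = ewas.combine_models(
            sel["ewas_noBMI"], sel["ewas_BMI"],
            tables[("ewas_noBMI", 1)], tables[("ewas_noBMI", 2)],
        )
        pd.concat(tables.values()).to_csv(out / "ewas_full.tsv", sep="\t")
        final.to_csv(out / "ewas_selected.tsv", sep="\t")
        io.write_manifest(
            out / "manifest_ewas.json",
            stage="ewas",
            inputs={"methylation": out / "methylation.tsv"},
            seed=None,
            thresholds={"alpha_disc": config.alpha_disc},
            counts={"selected": len(final)},
        )
        return tables, final

    ewas_tables, ewas_selected = stage("ewas")(_ewas)
    results["ewas_selected"] = ewas_selected

    # ---- meQTL ------------------------------------------------------------
    def _meqtl():
        kin = meqtl.estimate_kinship(geno)
        disc = samples.index[samples["geno_batch"] == 1]
        rep = samples.index[samples["geno_batch"] == 2]
        cpgs = list(ewas_selected.index)
        pairs_disc = meqtl.run_meqtl(
            meth, geno, covs["meqtl"], kin,
            cpg_set=cpgs, samples=disc, alpha=config.alpha_meqtl,
        )
        pairs_rep = meqtl.run_meqtl(
            meth, geno, covs["meqtl"], kin,
            cpg_set=cpgs, samples=rep, alpha=1e-3,
        )
        if len(pairs_disc):
            pairs_disc["replicated"] = meqtl.locus_replicate(
                pairs_disc, pairs_rep, window=config.locus_window
            )
        pairs_disc.to_csv(out / "meqtl_pairs.tsv", sep="\t", index=False)
        io.write_manifest(
            out / "manifest_meqtl.json",
            stage="meqtl",
            inputs={"genotypes": out / "genotypes.vcf"},
            seed=None,
            thresholds={"alpha_meqtl": config.alpha_meqtl,
                        "locus_window": config.locus_window},
            counts={"pairs": len(pairs_disc)},
        )
        return kin, pairs_disc

    kinship, meqtl_pairs = stage("meqtl")(_meqtl)
    results["meqtl_pairs"] = meqtl_pairs

    # ---- metabolome -------------------------------------------------------
    def _metabolome():
        mwas = metabolome.run_mwas(
            mets_qc, samples, covs["mwas"],
            split_fraction=config.mwas_split, seed=config.mwas_seed,
        )
        mwas.significant.to_csv(out / "mwas_significant.tsv", sep="\t")
        batch1 = samples.index[samples["met_batch"] == 1]
        batch2 = samples.index[samples["met_batch"] == 2]
        cpgs = list(ewas_selected.index)
        met_ids = list(mwas.significant.index)
        if cpgs and met_ids:
            b1 = metabolome.cpg_metabolite_batch(
                meth_adj, mets_qc, covs["cpg_metabolite"], batch1,
                cpgs=cpgs, metabolite_ids=met_ids,
            )
            b2 = metabolome.cpg_metabolite_batch(
                meth_adj, mets_qc, covs["cpg_metabolite"], batch2,
                cpgs=cpgs, metabolite_ids=met_ids,
            )
            meta = metabolome.inverse_variance_meta(b1, b2)
            final, n_pass, n_final = metabolome.select_cpg_metabolite(
                meta, len(cpgs), len(met_ids)
            )
        else:
            meta = pd.DataFrame()
            final, n_pass, n_final = pd.DataFrame(), 0, 0
        meta.to_csv(out / "cpg_metabolite_meta.tsv", sep="\t", index=False)
        final.to_csv(out / "cpg_metabolite_selected.tsv", sep="\t", index=False)
        io.write_manifest(
            out / "manifest_metabolome.json",
            stage="metabolome",
            inputs={"metabolites": out / "metabolites_raw.tsv"},
            seed=config.mwas_seed,
            thresholds={"mwas_split": config.mwas_split},
            counts={"mwas_hits": len(mwas.significant),
                    "pairs_pass": n_pass, "pairs_final": n_final},
        )
        return mwas, final

    mwas_result, cpgmet_final = stage("metabolome")(_metabolome)
    results["mwas"] = mwas_result
    results["cpg_metabolite"] = cpgmet_final

    # ---- MR ---------------------------------------------------------------
    def _mr():
        inputs = mr.load_packaged_inputs()
        single = mr.mr_from_table(inputs, method="maxlik")
        combined = mr.mr_from_table(inputs, method="ivw")
        single.to_csv(out / "mr_single_snp.tsv", sep="\t", index=False)
        combined.to_csv(out / "mr_ivw.tsv", sep="\t", index=False)
        return single, combined

    mr_single, mr_ivw = stage("mr")(_mr)
    results["mr_single"] = mr_single
    results["mr_ivw"] = mr_ivw

    # ---- network ----------------------------------------------------------
    def _network():
        resid = network.residualize_metabolites(mets_qc.values, covs["mwas"])
        met_edges = network.partial_correlation_network(
            resid, alpha_total=config.ggm_alpha_total
        )
        cpgmet = cpgmet_final if len(cpgmet_final) else None
        g = network.assemble_network(
            meqtl_pairs if len(meqtl_pairs) else None, cpgmet, met_edges
        )
        network.write_sif(g, out / "network.sif")
        network.write_graphml(g, out / "network.graphml")
        network.write_tables(g, out / "network_nodes.tsv", out / "network_edges.tsv")
        comp = network.component_stats(g)
        comp.to_csv(out / "network_components.tsv", sep="\t", index=False)
        io.write_manifest(
            out / "manifest_network.json",
            stage="network",
            inputs={},
            seed=None,
            thresholds={"ggm_alpha_total": config.ggm_alpha_total},
            counts={"nodes": g.number_of_nodes(), "edges": g.number_of_edges()},
        )
        return g, comp

    g, comp = stage("network")(_network)
    results["network"] = g
    results["components"] = comp
    return results
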