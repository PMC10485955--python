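"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: TSV matrices (features in rows, samples in
columns, with annotation columns first), a minimal VCF for genotypes (GT or
DS), a ground-truth JSON and per-stage JSON manifests recording inputs,
seeds, thresholds and output counts. Coordinates are 1-based inclusive (VCF
convention); distances are in base pairs.
"""

from __future__ import annotations

import hashlib
import json
from typing import Dict

import numpy as np
import pandas as pd

from .simulate import (
    GenotypeMatrix,
    GroundTruth,
    MetaboliteMatrix,
    MethylationMatrix,
)


class FormatError(ValueError):
    pass


# --------------------------------------------------------------------------
# sample sheet / matrices
# --------------------------------------------------------------------------


def write_sample_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_sample_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_methylation(meth: MethylationMatrix, path) -> None:
    out = pd.concat([meth.info, meth.beta], axis=1)
    out.to_csv(path, sep="\t")


def read_methylation(path) -> MethylationMatrix:
    df = pd.read_csv(path, sep="\t", index_col="cpg")
    info = df[["chrom", "pos"]]
    beta = df.drop(columns=["chrom", "pos"])
    return MethylationMatrix(beta=beta, info=info)


def write_metabolites(mets: MetaboliteMatrix, path) -> None:
    out = pd.concat([mets.info, mets.values], axis=1)
    out.to_csv(path, sep="\t")


def read_metabolites(path) -> MetaboliteMatrix:
    df = pd.read_csv(path, sep="\t", index_col="metabolite")
    info = df[["pathway", "subpathway"]]
    values = df.drop(columns=["pathway", "subpathway"])
    return MetaboliteMatrix(values=values, info=info)


# --------------------------------------------------------------------------
# genotypes: minimal VCF
# --------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=t2domics-simulate
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">
"""


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF with a DS (dosage) FORMAT field, sorted by coordinate."""
    samples = list(genotypes.dosages.columns)
    info = genotypes.info.sort_values(["chrom", "pos"])
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in sorted(info["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        dosages = genotypes.dosages.loc[info.index]
        for snp, row in info.iterrows():
            ds = "\t".join(f"{v:g}" for v in dosages.loc[snp])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{snp}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tDS\t{ds}\n"
            )


def read_vcf_dosages(path) -> GenotypeMatrix:
    """Parse a VCF into a dosage matrix using cyvcf2.

    Dosage is the DS value when present, otherwise the alternate-allele
    count from GT. Multiallelic records are skipped with a warning.
    """
    import warnings

    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 dosage, 3 unknown
    samples = vcf.samples
    snp_ids, chroms, pos, refs, alts = [], [], [], [], []
    rows = []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            warnings.warn(f"skipping multiallelic record at line index {i}")
            continue
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            vals = ds[:, 0].astype(float)
        else:
            gts = rec.gt_types  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            if (gts == 3).any():
                raise FormatError(f"missing genotype in record {rec.ID or i}")
            vals = gts.astype(float)
        rows.append(vals)
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    info = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "ref": refs, "alt": alts},
        index=pd.Index(snp_ids, name="snp"),
    )
    try:
        info["chrom"] = pd.to_numeric(info["chrom"])
    except (ValueError, TypeError):
        pass  # non-numeric contig names stay as strings
    dosages = pd.DataFrame(np.array(rows), index=info.index, columns=samples)
    info["maf"] = dosages.mean(axis=1) / 2.0
    return GenotypeMatrix(dosages=dosages, info=info)


# --------------------------------------------------------------------------
# ground truth and manifests
# --------------------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "snp_cpg_beta_scale": {f"{k[0]}|{k[1]}": v for k, v in truth.snp_cpg_beta_scale.items()},
        "cpg_t2d_beta_scale": truth.cpg_t2d_beta_scale,
        "t2d_metabolite": truth.t2d_metabolite,
        "cpg_metabolite": {f"{k[0]}|{k[1]}": v for k, v in truth.cpg_metabolite.items()},
        "cpg_hba1c": truth.cpg_hba1c,
        "precision": truth.precision.tolist(),
        "seed": truth.config.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, stage: str, inputs: Dict[str, str], seed: int | None,
                   thresholds: Dict[str, float], counts: Dict[str, int]) -> None:
    payload = {
        "stage": stage,
        "inputs_sha256": {k: file_sha256(v) for k, v in inputs.items()},
        "seed": seed,
        "thresholds": thresholds,
        "counts": counts,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
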