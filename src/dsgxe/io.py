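"""Readers and writers for the external interchange formats.

Genotypes travel as a subjects-by-SNPs dosage TSV (missing = "NA") with a
companion SNP allele table, or as a minimal unphased VCF carrying GT and DS
fields.  Weights, phenotypes and SES indicators are flat TSV/CSV.
Every writer has a matching reader and round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


def write_dosage_tsv(gm: GenotypeMatrix, dosage_path, snp_path) -> None:
    gm.dosages.to_csv(dosage_path, sep="\t", na_rep="NA", index_label="subject_id")
    gm.snps.to_csv(snp_path, sep="\t", index_label="snp")


def read_dosage_tsv(dosage_path, snp_path) -> GenotypeMatrix:
    dos = pd.read_csv(dosage_path, sep="\t", index_col="subject_id", na_values="NA")
    snps = pd.read_csv(snp_path, sep="\t", index_col="snp")
    return GenotypeMatrix(dos.astype(float), snps)


def write_weights_tsv(weights: pd.DataFrame, path) -> None:
    weights.to_csv(path, sep="\t", index=False)


def read_weights_tsv(path) -> pd.DataFrame:
    w = pd.read_csv(path, sep="\t")
    required = {"gene", "rsid", "ref_allele", "eff_allele", "weight"}
    missing = required - set(w.columns)
    if missing:
        raise ValueError(f"weight table missing columns {sorted(missing)}")
    return w


def write_phenotype_csv(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index_label="subject_id")


def read_phenotype_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")


write_ses_csv = write_phenotype_csv
read_ses_csv = read_phenotype_csv


def write_qc_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index_label="snp")


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2: diploid unphased GT (rounded dosage) plus exact DS."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt-allele dosage">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.subjects),
    ]
    for pos, snp in enumerate(gm.snp_ids, start=1):
        ref = gm.snps.loc[snp, "ref"]
        alt = gm.snps.loc[snp, "alt"]
        fields = []
        for d in gm.dosages[snp].to_numpy(dtype=float):
            if np.isnan(d):
                fields.append("./.:.")
            else:
                fields.append(f"{_GT[int(round(d))]}:{d:g}")
        lines.append(
            f"1\t{pos}\t{snp}\t{ref}\t{alt}\t.\t.\t.\tGT:DS\t" + "\t".join(fields)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a minimal VCF; DS preferred when present, otherwise GT allele count."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snp_ids, refs, alts, rows = [], [], [], []
    for var in vcf:
        snp_ids.append(var.ID)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where(col < 0, np.nan, col)
        else:
            col = np.array(
                [np.nan if g[0] < 0 else float(g[0] + g[1]) for g in var.genotypes]
            )
        rows.append(col)
    vcf.close()
    dos = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(subjects), 0)),
        index=subjects,
        columns=snp_ids,
    )
    snps = pd.DataFrame(
        {"ref": refs, "alt": alts}, index=pd.Index(snp_ids, name="snp")
    )
    return GenotypeMatrix(dos, snps)


def write_cohort(cohort, outdir) -> dict[str, str]:
    """Write every cohort artifact to ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dosages": str(outdir / "dosages.tsv"),
        "snps": str(outdir / "snps.tsv"),
        "weights": str(outdir / "weights.tsv"),
        "phenotypes": str(outdir / "phenotypes.csv"),
        "ses": str(outdir / "ses.csv"),
        "vcf": str(outdir / "genotypes.vcf"),
    }
    write_dosage_tsv(cohort.genotypes, paths["dosages"], paths["snps"])
    write_weights_tsv(cohort.weights, paths["weights"])
    write_phenotype_csv(cohort.phenotypes, paths["phenotypes"])
    write_ses_csv(cohort.ses, paths["ses"])
    write_vcf(cohort.genotypes, paths["vcf"])
    return paths
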