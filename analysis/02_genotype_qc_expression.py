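#!/usr/bin/env python
"""Genotype quality control, predicted expression and ancestry PCs.

Filters SNPs on call rate >= 0.95, Hardy-Weinberg exact p >= 0.001 and
minor allele frequency >= 0.05, then computes the weighted-dosage predicted
expression for each gene in the weight set and the top two ancestry PCs.
"""

from pathlib import Path

from dsgxe.genotypes import ancestry_pcs, predict_expression, qc_filter
from dsgxe.io import read_dosage_tsv, read_weights_tsv, write_qc_report

BASE = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    gm = read_dosage_tsv(BASE / "data" / "dosages.tsv", BASE / "data" / "snps.tsv")
    weights = read_weights_tsv(BASE / "data" / "weights.tsv")

    gm_qc, report = qc_filter(gm)
    write_qc_report(report, BASE / "qc_report.tsv")
    n_fail = int((report["status"] == "fail").sum())
    print(f"QC: {len(report)} SNPs, {n_fail} removed "
          f"({report.loc[report['status'] == 'fail', 'reason'].value_counts().to_dict()})")

    expr, info = predict_expression(gm_qc, weights)
    expr.to_csv(BASE / "predicted_expression.tsv", sep="\t", index_label="subject_id")
    for gene in expr.columns:
        print(f"predicted {gene}: {info['used'][gene]} SNPs used, "
              f"{info['flipped'][gene]} allele-flipped, "
              f"{len(info['skipped'][gene])} skipped; "
              f"mean {expr[gene].mean():.3f}, SD {expr[gene].std(ddof=1):.3f}")

    pcs = ancestry_pcs(gm_qc, k=2)
    pcs.to_csv(BASE / "ancestry_pcs.tsv", sep="\t", index_label="subject_id")
    print(f"ancestry PCs written (orthogonality |pc1.pc2| = "
          f"{abs(pcs['pc1'] @ pcs['pc2']):.2e})")


if __name__ == "__main__":
    main()
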