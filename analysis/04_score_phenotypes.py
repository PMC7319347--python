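#!/usr/bin/env python
"""Score the behavioral phenotypes: buffet intake into snack/pizza/fruit-veg
kcal and macronutrient grams, PSS-10 totals with Cronbach's alpha, and
go/no-go commission errors with the attention-based exclusion rules."""

from pathlib import Path

import pandas as pd

from dsgxe.io import read_phenotype_csv
from dsgxe.phenotypes import (
    FOOD_TABLE,
    aggregate_intake_table,
    gng_metrics_from_counts,
    pss_total,
)

BASE = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main() -> None:
    pheno = read_phenotype_csv(BASE / "data" / "phenotypes.csv")

    item_cols = [c for c in pheno.columns if c in FOOD_TABLE]
    intake = aggregate_intake_table(pheno[item_cols])
    print("intake means (SD):")
    for col in intake.columns:
        print(f"  {col}: {intake[col].mean():.1f} ({intake[col].std(ddof=1):.1f})")

    totals, alpha = pss_total(pheno[[f"pss_item_{j}" for j in range(1, 11)]])
    print(f"PSS total mean (SD): {totals.mean():.1f} ({totals.std(ddof=1):.1f}); "
          f"Cronbach alpha = {alpha:.3f}")

    gng = pd.DataFrame(
        [
            {"gng_commissions": s.commissions, "gng_excluded": s.excluded}
            for s in (
                gng_metrics_from_counts(
                    int(r["gng_go"]), int(r["gng_nogo"]),
                    int(r["gng_commissions"]), int(r["gng_omissions"]),
                    int(r["gng_fast_rt"]),
                )
                for _, r in pheno.iterrows()
            )
        ],
        index=pheno.index,
    )
    print(f"go/no-go: {int(gng['gng_excluded'].sum())} excluded; commission errors "
          f"mean {gng['gng_commissions'].mean():.1f}")

    scored = pd.concat(
        [pheno[["age", "sex", "bmi_z"]], intake,
         totals.rename("pss_total"), gng], axis=1
    )
    scored.to_csv(BASE / "scored_phenotypes.csv", index_label="subject_id")
    print(f"wrote {BASE / 'scored_phenotypes.csv'}")


if __name__ == "__main__":
    main()
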