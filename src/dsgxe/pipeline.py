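"""Config-driven orchestration: raw (or simulated) inputs to fitted
interaction tables, differential-susceptibility reports and figures.

Stage order mirrors the analysis: genotype QC -> predicted expression ->
ancestry PCs -> SES composite -> phenotype scoring -> interaction models
with BH-FDR -> quadratic robustness check and the confirmation suite for
every outcome whose interaction term is significant (raw p below alpha --
the gate precedes FDR adjustment).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig
from . import io as dio
from .genotypes import qc_filter, predict_expression, ancestry_pcs
from .ses import (
    standardize_indicators,
    pca_first_component,
    composite_score,
    median_split,
    diagnostics_table,
)
from .phenotypes import (
    FOOD_TABLE,
    aggregate_intake_table,
    pss_total,
    gng_metrics_from_counts,
    group_correlations,
)
from .moderation import ModelSpec, fit_model, model_table, bh_fdr, quadratic_robustness
from .diffsusc import ds_report, POI_BAND, PA_BAND

log = logging.getLogger("dsgxe")

DEFAULT_OUTCOMES = (
    "snack_kcal", "pizza_kcal", "fruit_veg_kcal",
    "carb_g", "sugar_g", "fat_g", "protein_g",
    "gng_commissions", "pss_total",
)

CONVENTIONS = {
    "standardized_betas": "standardize-then-multiply (interaction = product of z-scored Z and X)",
    "binary_covariates": "left unstandardized in the standardized refit",
    "median_split_ties": "ties at the median go to the lower group",
    "pa_ties": "X values tied with the crossover count below",
    "poi_favorable_side": "high-X side regardless of outcome valence",
    "pss_reverse_coding": "positively stated items reverse-coded before summing",
    "ds_gate": "raw (pre-FDR) interaction p < alpha",
    "hwe": "exact test on rounded dosages, chi-square above 1000 subjects",
    "missing_dosage_in_prediction": "imputed to the SNP's mean observed dosage",
}


@dataclass
class PipelineConfig:
    outdir: str
    simulate: SimulationConfig | None = None
    inputs: dict | None = None  # paths: dosages, snps, weights, phenotypes, ses
    min_call_rate: float = 0.95
    min_hwe_p: float = 0.001
    min_maf: float = 0.05
    alpha: float = 0.05
    fdr_q: float = 0.15
    poi_band: tuple[float, float] = POI_BAND
    pa_band: tuple[float, float] = PA_BAND
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES
    seed: int = 0
    make_figures: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if self.simulate is None and self.inputs is None:
            raise ValueError("either a simulation config or input paths are required")
        if self.inputs is not None:
            missing = [p for p in self.inputs.values() if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"missing input file(s): {missing}")


def _stage(manifest: dict, outdir: Path, name: str):
    """Context manager that tags failures with the stage name."""
    import contextlib

    @contextlib.contextmanager
    def runner():
        log.info("stage: %s", name)
        try:
            yield
        except Exception as exc:
            (outdir / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages_completed"].append(name)

    return runner()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "conventions": dict(CONVENTIONS),
        "stages_completed": [],
        "outputs": {},
        "verdicts": {},
    }

    with _stage(manifest, outdir, "inputs"):
        if config.simulate is not None:
            from .simulate import simulate_cohort

            cohort = simulate_cohort(config.simulate)
            paths = dio.write_cohort(cohort, outdir / "data")
            manifest["simulation"] = config.simulate.to_dict()
        else:
            paths = dict(config.inputs)
        gm = dio.read_dosage_tsv(paths["dosages"], paths["snps"])
        weights = dio.read_weights_tsv(paths["weights"])
        pheno = dio.read_phenotype_csv(paths["phenotypes"])
        ses_table = dio.read_ses_csv(paths["ses"])
        manifest["outputs"]["inputs"] = {k: str(v) for k, v in paths.items()}

    with _stage(manifest, outdir, "genotype_qc"):
        gm_qc, qc_report = qc_filter(
            gm, config.min_call_rate, config.min_hwe_p, config.min_maf
        )
        dio.write_qc_report(qc_report, outdir / "qc_report.tsv")
        manifest["outputs"]["qc_report"] = str(outdir / "qc_report.tsv")
        manifest["n_snps_pass"] = int((qc_report["status"] == "pass").sum())

    with _stage(manifest, outdir, "predicted_expression"):
        expr, pred_info = predict_expression(gm_qc, weights)
        expr.to_csv(outdir / "predicted_expression.tsv", sep="\t",
                    index_label="subject_id")
        manifest["outputs"]["predicted_expression"] = str(
            outdir / "predicted_expression.tsv"
        )
        manifest["prediction"] = {
            g: {"used": pred_info["used"][g], "flipped": pred_info["flipped"][g],
                "skipped": len(pred_info["skipped"][g])}
            for g in pred_info["used"]
        }

    with _stage(manifest, outdir, "ancestry_pcs"):
        pcs = ancestry_pcs(gm_qc, k=2)
        pcs.to_csv(outdir / "ancestry_pcs.tsv", sep="\t", index_label="subject_id")
        manifest["outputs"]["ancestry_pcs"] = str(outdir / "ancestry_pcs.tsv")

    with _stage(manifest, outdir, "ses_composite"):
        z_ind = standardize_indicators(ses_table)
        pca = pca_first_component(z_ind)
        composite = composite_score(z_ind, pca.loadings)
        composite = (composite - composite.mean()) / composite.std(ddof=1)
        diag = diagnostics_table(ses_table, pca)
        with open(outdir / "ses_diagnostics.tsv", "w") as fh:
            diag.to_csv(fh, sep="\t", index_label="variable")
            fh.write(f"# variance_explained\t{pca.variance_explained:.4f}\n")
            fh.write(f"# KMO\t{pca.kmo:.4f}\n")
            fh.write(f"# Bartlett_chi2\t{pca.bartlett_stat:.4f}\n")
            fh.write(f"# Bartlett_p\t{pca.bartlett_p:.3e}\n")
        manifest["outputs"]["ses_diagnostics"] = str(outdir / "ses_diagnostics.tsv")
        manifest["ses_pca"] = {
            "variance_explained": pca.variance_explained,
            "kmo": pca.kmo,
            "bartlett_p": pca.bartlett_p,
        }

    with _stage(manifest, outdir, "phenotype_scoring"):
        item_cols = [c for c in pheno.columns if c in FOOD_TABLE]
        intake = aggregate_intake_table(pheno[item_cols])
        pss_cols = [f"pss_item_{j}" for j in range(1, 11)]
        totals, alpha_hat = pss_total(pheno[pss_cols])
        gng = pd.DataFrame(
            [
                {
                    "gng_commissions": s.commissions,
                    "gng_excluded": s.excluded,
                }
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
        manifest["pss_cronbach_alpha"] = float(alpha_hat)
        manifest["gng_n_excluded"] = int(gng["gng_excluded"].sum())

    with _stage(manifest, outdir, "analysis_frame"):
        z = expr.iloc[:, 0]
        frame = pd.DataFrame(
            {
                "pred_expr": (z - z.mean()) / z.std(ddof=1),
                "ses_composite": composite,
            },
            index=pheno.index,
        )
        for c in ("age", "sex", "bmi_z"):
            frame[c] = pheno[c]
        frame["pc1"] = pcs["pc1"]
        frame["pc2"] = pcs["pc2"]
        frame = pd.concat([frame, intake], axis=1)
        frame["gng_commissions"] = gng["gng_commissions"].astype(float)
        frame["pss_total"] = totals.astype(float)
        keep = ~gng["gng_excluded"]
        frame = frame[keep]
        scored_path = outdir / "scored_phenotypes.csv"
        frame.to_csv(scored_path, index_label="subject_id")
        manifest["outputs"]["scored_phenotypes"] = str(scored_path)

    with _stage(manifest, outdir, "moderation"):
        specs = {o: ModelSpec(outcome=o) for o in config.outcomes}
        fits = {o: fit_model(frame, s) for o, s in specs.items()}
        family = pd.Series(
            {
                f"{o}::{t}": fits[o].pvalues[t]
                for o in config.outcomes
                for t in fits[o].pvalues.index
                if t != "const"
            }
        )
        fdr = bh_fdr(family, q=config.fdr_q)
        tables = {}
        for o in config.outcomes:
            adj = pd.Series(
                {
                    t: fdr.adjusted[f"{o}::{t}"]
                    for t in fits[o].pvalues.index
                    if t != "const"
                }
            )
            tab = model_table(frame, specs[o], fdr_adjusted=adj)
            tables[o] = tab
            path = outdir / f"model_{o}.tsv"
            with open(path, "w") as fh:
                tab.table.round(6).to_csv(fh, sep="\t", index_label="term")
                fh.write(f"# R2\t{tab.r2:.6f}\n")
                fh.write(f"# interaction_dR2\t{tab.dr2:.6f}\tp\t{tab.dr2_p:.6f}\n")
            manifest["outputs"][f"model_{o}"] = str(path)

    with _stage(manifest, outdir, "differential_susceptibility"):
        for o in config.outcomes:
            spec, fit = specs[o], fits[o]
            p_int = float(fit.pvalues[spec.interaction])
            if p_int >= config.alpha:
                manifest["verdicts"][o] = {
                    "gated": False,
                    "interaction_p": p_int,
                    "note": "interaction not significant; confirmation suite skipped",
                }
                continue
            quad = quadratic_robustness(frame, spec, alpha=config.alpha)
            report = ds_report(
                frame, spec, fit, quad.nonlinear_flag,
                alpha=config.alpha, poi_band=config.poi_band, pa_band=config.pa_band,
            )
            report["quadratic_check"] = {
                "p_x2": quad.p_x2,
                "p_zx2": quad.p_zx2,
                "p_interaction_augmented": quad.p_interaction_augmented,
            }
            path = outdir / f"ds_report_{o}.json"
            path.write_text(json.dumps(report, indent=2))
            manifest["outputs"][f"ds_report_{o}"] = str(path)
            manifest["verdicts"][o] = {
                "gated": True,
                "interaction_p": p_int,
                "verdict": report["verdict"]["verdict"],
            }
            if config.make_figures:
                from .plots import interaction_plot

                fig_path = outdir / f"interaction_{o}.svg"
                interaction_plot(frame, spec, fit, report, fig_path)
                manifest["outputs"][f"figure_{o}"] = str(fig_path)

    with _stage(manifest, outdir, "exploratory_correlations"):
        groups = median_split(frame["ses_composite"])
        corr = group_correlations(
            groups, frame["pss_total"], frame[["sugar_g", "snack_kcal"]]
        )
        corr.to_csv(outdir / "group_correlations.tsv", sep="\t", index=False)
        manifest["outputs"]["group_correlations"] = str(
            outdir / "group_correlations.tsv"
        )

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
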