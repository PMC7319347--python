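"""Synthetic cohort generator.

Builds complete cohorts with the statistical structure the downstream
analysis assumes: binomial genotype dosages with missingness, a sparse
expression weight set, a single-factor five-indicator SES battery, and
outcomes carrying a crossover gene-by-environment interaction whose
location encodes the scenario (differential susceptibility: crossover at
the environment median; diathesis-stress: crossover at mean + 2 SD;
null: no interaction; nonlinear: an extra quadratic environment term).

Every generator is a pure function of (config, seed): the same
configuration always yields the same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .genotypes import GenotypeMatrix, predict_expression
from .phenotypes import (
    FOOD_TABLE,
    SNACK_ITEMS,
    PIZZA_ITEMS,
    FRUIT_VEG_ITEMS,
    PSS_POSITIVE_ITEMS,
)

_ALLELES = np.array(list("ACGT"))

#: latent-to-phenotype maps: ad-libitum snack intake in kcal and PSS total
SNACK_KCAL_MEAN, SNACK_KCAL_SD = 500.0, 200.0
PSS_MEAN, PSS_SD = 17.0, 6.0


def _rng(config: SimulationConfig, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Binomial(2, p) dosages with p uniform in ``maf_range`` per SNP.

    Missing entries are dropped uniformly at ``missing_rate``.
    """
    rng = rng if rng is not None else _rng(config, 1)
    n, m = config.n_subjects, config.n_snps
    p = rng.uniform(*config.maf_range, size=m)
    dos = rng.binomial(2, p, size=(n, m)).astype(float)
    if config.missing_rate > 0:
        dos[rng.random((n, m)) < config.missing_rate] = np.nan
    subjects = [f"S{i + 1:04d}" for i in range(n)]
    snp_ids = [f"rs{i + 1:06d}" for i in range(m)]
    ref = rng.choice(_ALLELES, size=m)
    alt = np.array(
        [rng.choice(_ALLELES[_ALLELES != r]) for r in ref]
    )
    snps = pd.DataFrame({"ref": ref, "alt": alt}, index=pd.Index(snp_ids, name="snp"))
    return GenotypeMatrix(
        pd.DataFrame(dos, index=subjects, columns=snp_ids), snps
    )


def simulate_weights(
    config: SimulationConfig,
    gm: GenotypeMatrix,
    rng: np.random.Generator | None = None,
    gene: str = "DRD4",
    tissue: str = "frontal_cortex",
) -> pd.DataFrame:
    """Sparse expression weight table over the simulated SNPs.

    A ``weight_sparsity`` fraction of SNPs (at least one) carries a normal
    weight; most weights are expressed on the alt allele, a few on the ref
    allele to exercise the allele-flip path in prediction.
    """
    rng = rng if rng is not None else _rng(config, 2)
    k = max(1, int(round(config.weight_sparsity * config.n_snps)))
    chosen = rng.choice(gm.snp_ids.to_numpy(), size=k, replace=False)
    rows = []
    for rsid in chosen:
        on_ref = rng.random() < 0.1
        eff = gm.snps.loc[rsid, "ref" if on_ref else "alt"]
        other = gm.snps.loc[rsid, "alt" if on_ref else "ref"]
        rows.append((gene, tissue, rsid, other, eff, rng.normal(0, 0.2)))
    return pd.DataFrame(
        rows, columns=["gene", "tissue", "rsid", "ref_allele", "eff_allele", "weight"]
    )


def simulate_ses_indicators(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n: int | None = None,
    discretize: bool = True,
    return_latent: bool = False,
):
    """Five-indicator battery with a single latent SES factor.

    Each indicator is ``loading * latent + sqrt(1 - loading^2) * noise``,
    then mapped to its survey type: income to 10 ordered categories
    (anchored at mean 6.2, SD 3.2), maternal education to 6 (mean 4.6,
    SD 1.4), public assistance and food security dichotomized at a 0.8
    base rate (oriented so 1 = the favorable state), perceived resource
    availability left continuous (mean 12.1, SD 5.3).  With
    ``discretize=False`` the continuous reflective indicators are returned
    unmapped, which keeps the factor structure exactly recoverable.
    """
    rng = rng if rng is not None else _rng(config, 3)
    n = n if n is not None else config.n_subjects
    lam = np.asarray(config.ses_loadings, dtype=float)
    latent = rng.standard_normal(n)
    cont = latent[:, None] * lam + rng.standard_normal((n, 5)) * np.sqrt(1 - lam**2)
    cols = ["income", "education", "public_assistance", "food_security",
            "perceived_resources"]
    if discretize:
        income = np.clip(np.rint(6.2 + 3.2 * cont[:, 0]), 1, 10)
        education = np.clip(np.rint(4.6 + 1.4 * cont[:, 1]), 1, 6)
        cut = -0.8416212  # standard-normal 20% quantile -> base rate 0.8
        assistance = (cont[:, 2] > cut).astype(float)
        security = (cont[:, 3] > cut).astype(float)
        resources = 12.1 + 5.3 * cont[:, 4]
        table = pd.DataFrame(
            np.column_stack([income, education, assistance, security, resources]),
            columns=cols,
        )
    else:
        table = pd.DataFrame(cont, columns=cols)
    if return_latent:
        return table, pd.Series(latent, name="ses_latent")
    return table


def simulate_covariates(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n: int | None = None,
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Demographics: age uniform 14-18y, sex Bernoulli(0.5), BMI z-score
    normal(0.54, 1.23); ancestry PCs supplied or standard normal."""
    rng = rng if rng is not None else _rng(config, 4)
    n = n if n is not None else config.n_subjects
    cov = pd.DataFrame(
        {
            "age": rng.uniform(14, 18, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "bmi_z": rng.normal(0.54, 1.23, n),
        }
    )
    if pcs is not None:
        cov.index = pcs.index
        cov["pc1"] = pcs.iloc[:, 0].to_numpy() if pcs.shape[1] > 0 else 0.0
        cov["pc2"] = pcs.iloc[:, 1].to_numpy() if pcs.shape[1] > 1 else 0.0
    else:
        cov["pc1"] = rng.standard_normal(n)
        cov["pc2"] = rng.standard_normal(n)
    return cov


def _standardize_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """z-score continuous covariates, center binary ones; effects stay
    on a standardized scale whatever the raw units."""
    out = covariates.astype(float).copy()
    for c in out.columns:
        col = out[c]
        if col.nunique() <= 2:
            out[c] = col - col.mean()
        else:
            sd = col.std(ddof=1)
            out[c] = (col - col.mean()) / (sd if sd > 0 else 1.0)
    return out


def outcome_design(
    config: SimulationConfig,
    predicted_expression,
    composite,
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray]:
    """The exact design used by :func:`simulate_outcomes` and its coefficients.

    Returns (design frame with columns const, Z, X, Z:X [, X^2], covariates;
    coefficient vector in the same order).  The scenario sets the moderator
    main effect b1 so the crossover -b1/b3 lands at the sample median of X
    (differential susceptibility, nonlinear) or at mean + 2 SD
    (diathesis-stress).
    """
    z = np.asarray(predicted_expression, dtype=float)
    x = np.asarray(composite, dtype=float)
    if not (len(z) == len(x) == len(covariates)):
        raise ValueError(
            "misaligned inputs: "
            f"Z has {len(z)}, X has {len(x)}, covariates have {len(covariates)} rows"
        )
    b3 = config.effect_b3
    if config.scenario == "null":
        b1 = config.effect_b1
    elif config.scenario == "diathesis_stress":
        b1 = -b3 * (float(np.mean(x)) + 2 * float(np.std(x, ddof=1)))
    else:  # differential_susceptibility, nonlinear: crossover at the median
        b1 = -b3 * float(np.median(x))
    cols = {"const": np.ones(len(z)), "Z": z, "X": x, "Z:X": z * x}
    coef = [config.effect_b0, b1, config.effect_b2, b3]
    if config.scenario == "nonlinear":
        cols["X^2"] = x * x
        coef.append(config.quadratic_effect)
    std_cov = _standardize_covariates(covariates)
    for name, effect in config.covariate_effects.items():
        if name not in std_cov.columns:
            raise ValueError(f"covariate {name!r} missing from covariate table")
        cols[name] = std_cov[name].to_numpy()
        coef.append(effect)
    return pd.DataFrame(cols), np.asarray(coef)


def simulate_outcomes(
    config: SimulationConfig,
    predicted_expression,
    composite,
    covariates: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Latent outcome draw plus its phenotype-scale mappings.

    Returns columns ``y`` (the unbounded latent value on the model scale,
    used by recovery tests), ``snack_kcal`` (affine map floored at 0) and
    ``pss_total`` (affine map rounded and bounded to [0, 40]).  Flooring
    and bounding happen after the noise draw and slightly bias coefficient
    recovery on the bounded scales, which is why tests work on ``y``.
    """
    rng = rng if rng is not None else _rng(config, 5)
    design, coef = outcome_design(config, predicted_expression, composite, covariates)
    y = design.to_numpy() @ coef + config.noise_sd * rng.standard_normal(len(design))
    snack = np.maximum(0.0, SNACK_KCAL_MEAN + SNACK_KCAL_SD * y)
    pss = np.clip(np.rint(PSS_MEAN + PSS_SD * y), 0, 40)
    return pd.DataFrame(
        {"y": y, "snack_kcal": snack, "pss_total": pss},
        index=covariates.index,
    )


def simulate_analysis_frame(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """One ready-to-fit cohort on the model scale, without the genotype layer.

    Draws standard-normal moderator (``pred_expr``) and environment
    (``ses_composite``), demographics, and the latent outcome; used by the
    calibration and recovery studies where the genotype-to-expression and
    indicator-to-composite steps are exercised separately.
    """
    rng = rng if rng is not None else _rng(config, 6)
    n = config.n_subjects
    z = rng.standard_normal(n)
    x = rng.standard_normal(n)
    cov = simulate_covariates(config, rng=rng, n=n)
    out = simulate_outcomes(config, z, x, cov, rng=rng)
    frame = cov.copy()
    frame.insert(0, "pred_expr", z)
    frame.insert(1, "ses_composite", x)
    frame["y"] = out["y"].to_numpy()
    frame["snack_kcal"] = out["snack_kcal"].to_numpy()
    frame["pss_total"] = out["pss_total"].to_numpy()
    return frame


def _split_total(
    total: float, items: tuple[str, ...], rng: np.random.Generator
) -> dict[str, float]:
    """Split a group kcal total across items (Dirichlet shares), in grams."""
    shares = rng.dirichlet(np.full(len(items), 2.0)) * total
    return {
        name: share / FOOD_TABLE[name].kcal_per_g if FOOD_TABLE[name].kcal_per_g else 0.0
        for name, share in zip(items, shares)
    }


def _pss_items(total: int, rng: np.random.Generator) -> np.ndarray:
    """Raw PSS responses whose scored sum (with reverse coding) equals total."""
    scored = np.full(10, total // 10, dtype=int)
    extra = rng.choice(10, size=total % 10, replace=False)
    scored[extra] += 1
    # two swap attempts put sample Cronbach's alpha near the instrument's
    # published reliability (~0.87); more jitter degrades it
    for _ in range(2):
        i, j = rng.integers(0, 10, 2)
        if scored[i] < 4 and scored[j] > 0 and i != j:
            scored[i] += 1
            scored[j] -= 1
    raw = scored.copy()
    raw[list(PSS_POSITIVE_ITEMS)] = 4 - raw[list(PSS_POSITIVE_ITEMS)]
    return raw


@dataclass
class Cohort:
    """A complete synthetic cohort and its generative ground truth."""

    phenotypes: pd.DataFrame  # demographics, per-item grams, PSS items, gng counts
    ses: pd.DataFrame  # five-indicator battery
    genotypes: GenotypeMatrix
    weights: pd.DataFrame
    truth: dict = field(default_factory=dict)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Compose genotypes, weights, SES battery, demographics and outcomes.

    The snack-intake and PSS outcomes carry the configured scenario (with
    independent noise draws); pizza, fruit/vegetable intake and go/no-go
    performance are generated without any interaction, mirroring the
    null results expected for them.
    """
    gm = simulate_genotypes(config)
    weights = simulate_weights(config, gm)
    expr, _ = predict_expression(gm, weights)
    z = expr.iloc[:, 0]
    z_std = (z - z.mean()) / z.std(ddof=1)
    ses, latent = simulate_ses_indicators(config, return_latent=True)
    ses.index = gm.subjects
    latent.index = gm.subjects
    x = (latent - latent.mean()) / latent.std(ddof=1)

    from .genotypes import ancestry_pcs

    try:
        pcs = ancestry_pcs(gm, k=2)
    except ValueError:
        pcs = pd.DataFrame(0.0, index=gm.subjects, columns=["pc1", "pc2"])
    cov = simulate_covariates(config, pcs=pcs)

    rng = _rng(config, 7)
    snack = simulate_outcomes(config, z_std, x, cov, rng=rng)
    pss = simulate_outcomes(config, z_std, x, cov, rng=_rng(config, 8))

    n = config.n_subjects
    pheno = cov.copy()
    rows_items: list[dict[str, float]] = []
    for i in range(n):
        item_g: dict[str, float] = {}
        item_g.update(_split_total(float(snack["snack_kcal"].iloc[i]), SNACK_ITEMS, rng))
        pizza_kcal = max(0.0, rng.normal(600, 250))
        item_g.update(_split_total(pizza_kcal, PIZZA_ITEMS, rng))
        fv_kcal = max(0.0, rng.normal(150, 80))
        item_g.update(_split_total(fv_kcal, FRUIT_VEG_ITEMS, rng))
        item_g["water"] = rng.uniform(0, 500)
        item_g["regular_coke"] = rng.uniform(0, 400)
        item_g["diet_coke"] = rng.uniform(0, 200)
        item_g["hummus"] = rng.uniform(0, 60)
        item_g["ranch_dressing"] = rng.uniform(0, 60)
        rows_items.append(item_g)
    items = pd.DataFrame(rows_items, index=gm.subjects)
    pheno = pd.concat([pheno, items], axis=1)

    pss_items = np.vstack(
        [_pss_items(int(t), rng) for t in pss["pss_total"].to_numpy()]
    )
    for j in range(10):
        pheno[f"pss_item_{j + 1}"] = pss_items[:, j]

    pheno["gng_go"] = 156
    pheno["gng_nogo"] = 52
    pheno["gng_commissions"] = rng.binomial(52, 0.2, n)
    pheno["gng_omissions"] = rng.binomial(156, 0.03, n)
    pheno["gng_fast_rt"] = rng.binomial(156, 0.02, n)
    pheno.index.name = "subject_id"
    ses.index.name = "subject_id"

    crossovers = {
        "null": None,
        "differential_susceptibility": float(x.median()),
        "nonlinear": float(x.median()),
        "diathesis_stress": float(x.mean() + 2 * x.std(ddof=1)),
    }
    return Cohort(
        phenotypes=pheno,
        ses=ses,
        genotypes=gm,
        weights=weights,
        truth={
            "pred_expr": z_std,
            "ses_latent": x,
            "y_snack": snack["y"],
            "y_pss": pss["y"],
            "crossover_x": crossovers[config.scenario],
            "scenario": config.scenario,
        },
    )
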