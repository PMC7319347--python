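"""Configuration objects for the synthetic cohort generator and the pipeline.

The simulation knobs default to the study conditions the analysis assumes:
a 76-subject adolescent cohort, a five-indicator single-factor SES battery,
and a crossover gene-by-environment interaction with a standardized
interaction effect of 0.4 on the primary outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

SCENARIOS = ("null", "differential_susceptibility", "diathesis_stress", "nonlinear")

#: Standardized covariate effects on the latent outcome (age, sex, BMI z-score
#: and two ancestry PCs).  Values sized like the adjusted snack-intake model.
DEFAULT_COVARIATE_EFFECTS: Mapping[str, float] = {
    "age": -0.118,
    "sex": -0.297,
    "bmi_z": 0.058,
    "pc1": 0.186,
    "pc2": -0.129,
}

#: Target loadings of the five SES indicators on the latent SES factor
#: (income, maternal education, public assistance, food security,
#: perceived resource availability).
DEFAULT_SES_LOADINGS = (0.891, 0.772, 0.793, 0.690, 0.678)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Parameters
    ----------
    n_subjects, n_snps : int
        Cohort size and number of simulated genotyped SNPs.
    seed : int
        Seed for every random draw; the generator is a pure function of
        ``(config, seed)``.
    maf_range : (float, float)
        Uniform range for per-SNP allele frequencies, within ``(0, 0.5]``.
    missing_rate : float
        Per-entry genotype missingness proportion.
    weight_sparsity : float
        Fraction of SNPs carrying a nonzero expression weight.
    ses_loadings : tuple of 5 floats in (0, 1)
        Target single-factor loadings of the SES indicators.
    effect_b0..effect_b3 : float
        Latent-outcome model ``y = b0 + b1*Z + b2*X + b3*Z*X + covariates + e``
        where Z is standardized predicted expression and X the standardized
        SES composite.  ``b1`` is overridden by the scenario's crossover
        placement (see :func:`dsgxe.simulate.simulate_outcomes`).
    covariate_effects : mapping
        Standardized effects for age, sex, bmi_z, pc1, pc2.
    noise_sd : float
        Residual standard deviation of the latent outcome.  The default 0.87,
        together with the default effects, puts the model R-squared near 0.25,
        typical of adjusted behavioral G-by-E models at this effect size.
    scenario : str
        ``null`` (no interaction), ``differential_susceptibility`` (crossover
        at the X median), ``diathesis_stress`` (crossover at mean + 2 SD of X)
        or ``nonlinear`` (adds a quadratic X term).
    quadratic_effect : float
        Standardized X**2 coefficient used by the ``nonlinear`` scenario.
    """

    n_subjects: int = 76
    n_snps: int = 400
    seed: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    weight_sparsity: float = 0.05
    ses_loadings: tuple[float, ...] = DEFAULT_SES_LOADINGS
    effect_b0: float = 0.0
    effect_b1: float = 0.0
    effect_b2: float = 0.125
    effect_b3: float = 0.4
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    noise_sd: float = 0.87
    scenario: str = "differential_susceptibility"
    quadratic_effect: float = 0.4

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range!r}"
            )
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.weight_sparsity <= 1.0:
            raise ConfigurationError("weight_sparsity must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if len(self.ses_loadings) != 5 or not all(0 < l < 1 for l in self.ses_loadings):
            raise ConfigurationError("ses_loadings must be 5 values in (0, 1)")
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; choose one of {SCENARIOS}"
            )
        if self.scenario == "null":
            # a null cohort has no interaction by definition
            self.effect_b3 = 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["covariate_effects"] = dict(self.covariate_effects)
        return d
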