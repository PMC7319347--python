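"""Monte-Carlo studies over the synthetic cohort: null calibration of the
interaction test, generative recovery of the differential-susceptibility
verdict, and size/power of the quadratic robustness check.

These are the package's own operating-characteristic experiments: each
replicate draws a cohort on the model scale, fits the adjusted interaction
model and runs the confirmation suite end to end.
"""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig
from .diffsusc import classify_ds, crossover_point, pa, poi, ros_bounds, DSIndices
from .moderation import ModelSpec, fit_model, quadratic_robustness, standardized_betas
from .simulate import simulate_analysis_frame

SPEC = ModelSpec(outcome="y")


def _rep_seed(seed: int, r: int) -> int:
    # distinct, reproducible per-replicate seeds below 2**31
    return (seed * 65537 + r) % (2**31 - 1)


def null_calibration(
    seed: int, n_subjects: int = 150, reps: int = 2000, alpha: float = 0.05
) -> dict:
    """Type-I error of the interaction t-test under the null scenario."""
    hits = 0
    for r in range(reps):
        cfg = SimulationConfig(
            n_subjects=n_subjects, seed=_rep_seed(seed, r), scenario="null"
        )
        frame = simulate_analysis_frame(cfg)
        fit = fit_model(frame, SPEC)
        hits += fit.pvalues[SPEC.interaction] < alpha
    return {"rejection_rate": hits / reps, "reps": reps, "n": n_subjects}


def ds_recovery(
    seed: int,
    scenario: str = "differential_susceptibility",
    n_subjects: int = 500,
    reps: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Verdict recovery and standardized-interaction recovery per scenario.

    Each replicate runs the full confirmation chain: adjusted fit,
    standardized interaction beta, quadratic robustness check, RoS bounds,
    PoI, PA and the categorical verdict.
    """
    verdicts: dict[str, int] = {}
    betas = []
    for r in range(reps):
        cfg = SimulationConfig(
            n_subjects=n_subjects, seed=_rep_seed(seed, 10_000 + r), scenario=scenario
        )
        frame = simulate_analysis_frame(cfg)
        fit = fit_model(frame, SPEC)
        betas.append(float(standardized_betas(frame, SPEC)[SPEC.interaction]))
        quad = quadratic_robustness(frame, SPEC, alpha=alpha)
        x = frame["ses_composite"]
        xm, xs = float(x.mean()), float(x.std(ddof=1))
        ros = ros_bounds(fit, alpha=alpha)
        try:
            xc = crossover_point(fit)
        except ValueError:
            verdicts["degenerate"] = verdicts.get("degenerate", 0) + 1
            continue
        idx = DSIndices(
            crossover_x=xc, poi=poi(fit, xm, xs), pa=pa(x, xc), x_mean=xm, x_sd=xs
        )
        verdict = classify_ds(ros, idx, quad.nonlinear_flag, xm, xs).verdict
        verdicts[verdict] = verdicts.get(verdict, 0) + 1
    return {
        "scenario": scenario,
        "reps": reps,
        "n": n_subjects,
        "beta3_mean": float(np.mean(betas)),
        "verdict_rates": {k: v / reps for k, v in sorted(verdicts.items())},
    }


def quadratic_check_study(
    seed: int, n_subjects: int = 500, reps_power: int = 200, reps_size: int = 400
) -> dict:
    """Power against a true quadratic environment term and size under a
    purely linear crossover model."""
    flags_nl = 0
    for r in range(reps_power):
        cfg = SimulationConfig(
            n_subjects=n_subjects, seed=_rep_seed(seed, 20_000 + r),
            scenario="nonlinear",
        )
        frame = simulate_analysis_frame(cfg)
        flags_nl += quadratic_robustness(frame, SPEC).nonlinear_flag
    flags_lin = 0
    for r in range(reps_size):
        cfg = SimulationConfig(
            n_subjects=n_subjects, seed=_rep_seed(seed, 30_000 + r)
        )
        frame = simulate_analysis_frame(cfg)
        flags_lin += quadratic_robustness(frame, SPEC).nonlinear_flag
    return {
        "power_nonlinear": flags_nl / reps_power,
        "size_linear": flags_lin / reps_size,
        "reps_power": reps_power,
        "reps_size": reps_size,
        "n": n_subjects,
    }
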