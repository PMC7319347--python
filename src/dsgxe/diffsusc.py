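"""Differential-susceptibility confirmation suite (Roisman-style).

Given a fitted crossover interaction model, this module locates the
crossover point, solves the Johnson-Neyman regions of significance for the
moderator effect, computes the Proportion of Interaction (PoI) and the
Proportion Affected (PA), runs mean-split simple slopes, and combines
everything into a categorical verdict:

* prototypical differential susceptibility — both RoS bounds fall inside
  mean +/- 2 SD of the observed environment, PoI and PA are near 0.5, and
  no nonlinearity was flagged;
* not supported — the interaction is real but its geometry is
  diathesis-stress-like (crossover at or beyond the observed range);
* excluded for nonlinearity — the quadratic robustness check fired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .moderation import ModelSpec, RegressionFit, fit_ols

#: "roughly within 0.40 and 0.60" for PoI; PA "close to 0.50" is
#: operationalized with the same symmetric band.
POI_BAND = (0.40, 0.60)
PA_BAND = (0.40, 0.60)


@dataclass
class RoSResult:
    lower: float | None
    upper: float | None
    t_crit: float
    df: int
    status: str  # two_real_roots | no_real_roots | degenerate_no_interaction
    significant_outside: bool | None = None  # orientation of the significant region
    note: str = ""


@dataclass
class DSIndices:
    crossover_x: float
    poi: float
    pa: float
    x_mean: float
    x_sd: float


@dataclass
class SimpleSlopeResult:
    group: str  # "low" / "high" moderator by mean split
    slope: float
    se: float
    t: float
    df: int
    p: float


@dataclass
class DSVerdict:
    ros_within_range: bool
    poi_in_band: bool
    pa_near_half: bool
    nonlinear_excluded: bool
    verdict: str  # prototypical_differential_susceptibility | not_supported | excluded_nonlinear


def _zx_terms(fit: RegressionFit) -> tuple[str, str]:
    if fit.spec is None:
        raise ValueError("fit carries no ModelSpec; cannot locate Z and Z:X terms")
    return fit.spec.moderator, fit.spec.interaction


def crossover_point(fit: RegressionFit) -> float:
    """X value where the moderator effect b1 + b3*X vanishes: -b1/b3."""
    z, zx = _zx_terms(fit)
    b1, b3 = fit.term(z), fit.term(zx)
    if abs(b3) < 1e-12:
        raise ValueError("degenerate interaction (b3 ~ 0): crossover undefined")
    return -b1 / b3


def ros_bounds(fit: RegressionFit, alpha: float = 0.05) -> RoSResult:
    """Johnson-Neyman regions of significance for the moderator effect.

    The moderator's conditional effect b1 + b3*X has variance
    v11 + 2*X*v13 + X^2*v33; bounds are the real roots in X of
    ``(b1 + b3 X)^2 = t_crit^2 (v11 + 2 X v13 + X^2 v33)``.  When the
    quadratic opens upward (``significant_outside=True``) the effect is
    significant outside [lower, upper] and nonsignificant between them.
    """
    z, zx = _zx_terms(fit)
    b1, b3 = fit.term(z), fit.term(zx)
    v11, v13, v33 = fit.vcov(z, z), fit.vcov(z, zx), fit.vcov(zx, zx)
    df = fit.df_resid
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    t_crit = float(stats.t.ppf(1 - alpha / 2, df))
    A = b3 * b3 - t_crit**2 * v33
    B = 2 * (b1 * b3 - t_crit**2 * v13)
    C = b1 * b1 - t_crit**2 * v11
    if abs(A) < 1e-14 and abs(B) < 1e-14:
        return RoSResult(
            lower=None, upper=None, t_crit=t_crit, df=df,
            status="degenerate_no_interaction",
            note="conditional-effect significance does not depend on X",
        )
    if abs(A) < 1e-14:
        root = -C / B
        sig_right = B > 0
        return RoSResult(
            lower=float(root), upper=float(root), t_crit=t_crit, df=df,
            status="two_real_roots", significant_outside=None,
            note=f"linear boundary; significant on the {'right' if sig_right else 'left'}",
        )
    disc = B * B - 4 * A * C
    if disc < 0:
        everywhere = A > 0  # quadratic never crosses zero; sign of A decides
        return RoSResult(
            lower=None, upper=None, t_crit=t_crit, df=df,
            status="no_real_roots",
            note="moderator effect significant everywhere"
            if everywhere else "moderator effect significant nowhere",
        )
    r1 = (-B - math.sqrt(disc)) / (2 * A)
    r2 = (-B + math.sqrt(disc)) / (2 * A)
    lo, hi = (r1, r2) if r1 <= r2 else (r2, r1)
    return RoSResult(
        lower=float(lo), upper=float(hi), t_crit=t_crit, df=df,
        status="two_real_roots", significant_outside=bool(A > 0),
    )


def moderator_effect_t(fit: RegressionFit, x: np.ndarray) -> np.ndarray:
    """t statistic of the conditional moderator effect over a grid of X."""
    z, zx = _zx_terms(fit)
    b1, b3 = fit.term(z), fit.term(zx)
    v11, v13, v33 = fit.vcov(z, z), fit.vcov(z, zx), fit.vcov(zx, zx)
    x = np.asarray(x, dtype=float)
    return (b1 + b3 * x) / np.sqrt(v11 + 2 * x * v13 + x * x * v33)


def poi(
    fit: RegressionFit,
    x_mean: float,
    x_sd: float,
    z_low: float | None = None,
    z_high: float | None = None,
) -> float:
    """Proportion of Interaction: favorable-side share of the crossover area.

    The regression lines for two moderator levels over the window
    ``[x_mean - 2 x_sd, x_mean + 2 x_sd]`` bound two triangles split at the
    crossover; PoI is the area on the high-X (favorable-environment) side
    divided by the total.  The value depends only on the crossover location
    and the window (triangle areas scale with squared widths); the moderator
    levels (defaults: mean -/+ 1 SD of Z) only set the plotted lines.  A
    crossover outside the window clamps PoI to 0 or 1.
    """
    if z_low is not None and z_high is not None and not z_low < z_high:
        raise ValueError("z_low must be < z_high")
    xc = crossover_point(fit)
    lo, hi = x_mean - 2 * x_sd, x_mean + 2 * x_sd
    xcc = min(max(xc, lo), hi)
    right = (hi - xcc) ** 2
    left = (xcc - lo) ** 2
    return float(right / (right + left))


def pa(x_values, crossover: float) -> float:
    """Proportion Affected: share of observed X strictly above the crossover.

    Ties at the crossover count below (toward the adverse side).
    """
    x = np.asarray(x_values, dtype=float)
    if x.size == 0:
        raise ValueError("PA undefined for empty input")
    return float(np.mean(x > crossover))


def simple_slopes_split(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[SimpleSlopeResult, SimpleSlopeResult]:
    """Simple slopes of X for low/high moderator groups (mean split).

    The moderator is dichotomized at its mean into an indicator G and the
    model refit as ``y ~ G + X + G*X + covariates``; the low-group slope is
    the X coefficient, the high-group slope adds the interaction, with the
    linear-combination variance for its SE.
    """
    z = data[spec.moderator].astype(float)
    g = (z > z.mean()).astype(float)
    n_low, n_high = int((g == 0).sum()), int((g == 1).sum())
    needed = len(spec.covariates) + 2
    if n_low < needed or n_high < needed:
        raise ValueError(
            f"mean-split groups too small (low={n_low}, high={n_high}, need {needed})"
        )
    x = data[spec.environment].astype(float)
    cols = {"const": np.ones(len(data)), "G": g, spec.environment: x, "G:X": g * x}
    for c in spec.covariates:
        cols[c] = data[c].astype(float)
    design = pd.DataFrame(cols, index=data.index)
    fit = fit_ols(design, data[spec.outcome].astype(float))
    bx = fit.term(spec.environment)
    bi = fit.term("G:X")
    vxx = fit.vcov(spec.environment, spec.environment)
    vii = fit.vcov("G:X", "G:X")
    vxi = fit.vcov(spec.environment, "G:X")
    df = fit.df_resid

    def make(group: str, slope: float, var: float) -> SimpleSlopeResult:
        se = math.sqrt(var)
        t = slope / se
        return SimpleSlopeResult(
            group=group, slope=float(slope), se=float(se), t=float(t), df=df,
            p=float(2 * stats.t.sf(abs(t), df)),
        )

    return (
        make("low", bx, vxx),
        make("high", bx + bi, vxx + vii + 2 * vxi),
    )


def classify_ds(
    ros: RoSResult,
    idx: DSIndices,
    nonlinear_flag: bool,
    x_mean: float,
    x_sd: float,
    poi_band: tuple[float, float] = POI_BAND,
    pa_band: tuple[float, float] = PA_BAND,
) -> DSVerdict:
    """Combine RoS geometry, PoI, PA and the nonlinearity flag into a verdict.

    Prototypical differential susceptibility requires both RoS bounds inside
    mean +/- 2 SD of observed X, PoI and PA within their bands, and no
    flagged nonlinearity.
    """
    lo, hi = x_mean - 2 * x_sd, x_mean + 2 * x_sd
    ros_ok = (
        ros.status == "two_real_roots"
        and ros.lower is not None
        and ros.upper is not None
        and lo <= ros.lower <= hi
        and lo <= ros.upper <= hi
    )
    poi_ok = poi_band[0] <= idx.poi <= poi_band[1]
    pa_ok = pa_band[0] <= idx.pa <= pa_band[1]
    if nonlinear_flag:
        verdict = "excluded_nonlinear"
    elif ros_ok and poi_ok and pa_ok:
        verdict = "prototypical_differential_susceptibility"
    else:
        verdict = "not_supported"
    return DSVerdict(
        ros_within_range=ros_ok,
        poi_in_band=poi_ok,
        pa_near_half=pa_ok,
        nonlinear_excluded=bool(nonlinear_flag),
        verdict=verdict,
    )


def ds_report(
    data: pd.DataFrame,
    spec: ModelSpec,
    fit: RegressionFit,
    nonlinear_flag: bool,
    alpha: float = 0.05,
    poi_band: tuple[float, float] = POI_BAND,
    pa_band: tuple[float, float] = PA_BAND,
) -> dict:
    """Full confirmation suite for one outcome, as a JSON-serializable dict."""
    x = data[spec.environment].astype(float)
    x_mean, x_sd = float(x.mean()), float(x.std(ddof=1))
    ros = ros_bounds(fit, alpha=alpha)
    xc = crossover_point(fit)
    idx = DSIndices(
        crossover_x=xc,
        poi=poi(fit, x_mean, x_sd),
        pa=pa(x, xc),
        x_mean=x_mean,
        x_sd=x_sd,
    )
    low, high = simple_slopes_split(data, spec)
    verdict = classify_ds(ros, idx, nonlinear_flag, x_mean, x_sd, poi_band, pa_band)
    return {
        "outcome": spec.outcome,
        "scale": "raw-scale fit (bounds in units of the supplied X column)",
        "ros": asdict(ros),
        "indices": asdict(idx),
        "simple_slopes": {"low": asdict(low), "high": asdict(high)},
        "nonlinear_flag": bool(nonlinear_flag),
        "verdict": asdict(verdict),
        "conventions": {
            "poi_band": list(poi_band),
            "pa_band": list(pa_band),
            "pa_ties": "ties at the crossover count below",
            "poi_favorable_side": "high-X side regardless of outcome valence",
            "alpha": alpha,
        },
    }
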