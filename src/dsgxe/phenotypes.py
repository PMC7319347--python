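"""Behavioral phenotype scoring.

Buffet-meal aggregation into food-group energy and macronutrient intake,
Perceived Stress Scale (PSS-10) totals with Cronbach's alpha, food go/no-go
metrics with attention-based exclusion rules, and the exploratory per-group
Pearson correlations between stress and intake.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class FoodItem:
    """One buffet item: group membership, energy and macronutrient densities.

    Energy density is served kcal / served grams; macronutrient densities
    are grams of nutrient per gram of food, seeded from typical nutrition
    labels for the named products.
    """

    name: str
    group: str  # snack | pizza | fruit_veg | beverage | condiment
    served_g: float
    served_kcal: float
    carb_frac: float
    sugar_frac: float
    fat_frac: float
    protein_frac: float

    @property
    def kcal_per_g(self) -> float:
        return self.served_kcal / self.served_g if self.served_g else 0.0


def _item(name, group, g, kcal, carb, sugar, fat, protein):
    return FoodItem(name, group, g, kcal, carb, sugar, fat, protein)


#: The multi-item ad-libitum buffet.  Served portions and kcal follow the
#: study buffet; macronutrient fractions are label-typical values.
FOOD_TABLE: dict[str, FoodItem] = {
    f.name: f
    for f in [
        _item("cheese_pizza", "pizza", 790, 2009, 0.28, 0.035, 0.10, 0.11),
        _item("vegetable_pizza", "pizza", 940, 2050, 0.26, 0.040, 0.08, 0.09),
        _item("pepperoni_pizza", "pizza", 825, 2199, 0.27, 0.035, 0.12, 0.12),
        _item("hummus", "condiment", 283, 700, 0.14, 0.010, 0.18, 0.08),
        _item("ranch_dressing", "condiment", 224, 880, 0.06, 0.040, 0.42, 0.01),
        _item("vanilla_ice_cream", "snack", 250, 530, 0.24, 0.210, 0.11, 0.035),
        _item("chocolate_chip_cookies", "snack", 200, 970, 0.64, 0.350, 0.24, 0.05),
        _item("fudge_brownies", "snack", 350, 1200, 0.57, 0.400, 0.12, 0.04),
        _item("mms", "snack", 200, 1000, 0.71, 0.640, 0.21, 0.04),
        _item("ruffles_chips", "snack", 200, 1143, 0.50, 0.020, 0.36, 0.07),
        _item("cheetos", "snack", 250, 1339, 0.54, 0.020, 0.32, 0.07),
        _item("baby_carrots", "fruit_veg", 250, 103, 0.096, 0.047, 0.001, 0.009),
        _item("cherry_tomatoes", "fruit_veg", 300, 55, 0.039, 0.026, 0.002, 0.009),
        _item("celery_sticks", "fruit_veg", 200, 32, 0.030, 0.013, 0.002, 0.007),
        _item("grapes", "fruit_veg", 600, 414, 0.180, 0.155, 0.002, 0.007),
        _item("water", "beverage", 591, 0, 0.0, 0.0, 0.0, 0.0),
        _item("regular_coke", "beverage", 591, 240, 0.109, 0.109, 0.0, 0.0),
        _item("diet_coke", "beverage", 591, 11, 0.0, 0.0, 0.0, 0.0),
    ]
}

SNACK_ITEMS = tuple(n for n, f in FOOD_TABLE.items() if f.group == "snack")
PIZZA_ITEMS = tuple(n for n, f in FOOD_TABLE.items() if f.group == "pizza")
FRUIT_VEG_ITEMS = tuple(n for n, f in FOOD_TABLE.items() if f.group == "fruit_veg")

INTAKE_OUTPUTS = (
    "snack_kcal", "pizza_kcal", "fruit_veg_kcal",
    "carb_g", "sugar_g", "fat_g", "protein_g",
)


def aggregate_intake(consumed_g) -> dict[str, float]:
    """Aggregate per-item grams consumed into group kcal and macronutrients.

    Group kcal sums grams x energy density over the group's items
    (beverages and condiments are tracked for macronutrients but belong to
    no primary group); macronutrient grams sum over every item.
    """
    consumed = dict(consumed_g)
    unknown = sorted(set(consumed) - set(FOOD_TABLE))
    if unknown:
        raise KeyError(
            f"unknown food item(s) {unknown}; valid names: {sorted(FOOD_TABLE)}"
        )
    out = dict.fromkeys(INTAKE_OUTPUTS, 0.0)
    group_key = {"snack": "snack_kcal", "pizza": "pizza_kcal", "fruit_veg": "fruit_veg_kcal"}
    for name, grams in consumed.items():
        if grams < 0:
            raise ValueError(f"negative grams for {name}")
        item = FOOD_TABLE[name]
        kcal = grams * item.kcal_per_g
        if item.group in group_key:
            out[group_key[item.group]] += kcal
        out["carb_g"] += grams * item.carb_frac
        out["sugar_g"] += grams * item.sugar_frac
        out["fat_g"] += grams * item.fat_frac
        out["protein_g"] += grams * item.protein_frac
    return out


def aggregate_intake_table(grams: pd.DataFrame) -> pd.DataFrame:
    """Row-wise :func:`aggregate_intake` over a subjects-by-items table."""
    rows = [aggregate_intake(row.to_dict()) for _, row in grams.iterrows()]
    return pd.DataFrame(rows, index=grams.index)


#: PSS-10 positively stated items (1-based: 4, 5, 7, 8) that are
#: reverse-coded before summing under the published scoring rule.
PSS_POSITIVE_ITEMS = (3, 4, 6, 7)


def pss_total(
    items: pd.DataFrame, reverse_code: bool = True
) -> tuple[pd.Series, float]:
    """PSS-10 total per subject and Cronbach's alpha over the sample.

    ``items`` is a subjects-by-10 table of responses in 0..4.  With
    ``reverse_code`` (default, the published scoring) the positively stated
    items are scored 4 - response before summing.  Higher totals indicate
    more perceived stress; totals lie in [0, 40].
    """
    vals = items.to_numpy(dtype=float)
    if vals.shape[1] != 10:
        raise ValueError(f"PSS-10 needs 10 item columns, got {vals.shape[1]}")
    if np.isnan(vals).any() or vals.min() < 0 or vals.max() > 4:
        raise ValueError("PSS item responses must lie in 0..4")
    scored = vals.copy()
    if reverse_code:
        scored[:, list(PSS_POSITIVE_ITEMS)] = 4 - scored[:, list(PSS_POSITIVE_ITEMS)]
    totals = pd.Series(scored.sum(axis=1), index=items.index, name="pss_total")
    alpha = cronbach_alpha(scored)
    return totals, alpha


def cronbach_alpha(item_matrix) -> float:
    """alpha = k/(k-1) * (1 - sum of item variances / variance of total)."""
    m = np.asarray(item_matrix, dtype=float)
    k = m.shape[1]
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")  # degenerate sample: reliability undefined
    return float(k / (k - 1) * (1 - m.var(axis=0, ddof=1).sum() / total_var))


@dataclass
class GngSummary:
    go_trials: int
    nogo_trials: int
    commissions: int
    omissions: int
    fast_rt_prop: float  # proportion of go trials with RT < 200 ms
    excluded: bool

    def __post_init__(self) -> None:
        if self.commissions > self.nogo_trials:
            raise ValueError("commissions cannot exceed no-go trials")
        if self.omissions > self.go_trials:
            raise ValueError("omissions cannot exceed go trials")


def gng_metrics_from_counts(
    go_trials: int,
    nogo_trials: int,
    commissions: int,
    omissions: int,
    fast_rt_count: int = 0,
) -> GngSummary:
    """Go/no-go summary with attention-based exclusion.

    Excluded when the proportion of go trials with RT < 200 ms exceeds 0.30
    or the omission error rate exceeds 0.50 (strict inequalities).
    """
    if min(go_trials, nogo_trials, commissions, omissions, fast_rt_count) < 0:
        raise ValueError("counts must be non-negative")
    if go_trials == 0:
        raise ValueError("need at least one go trial")
    fast_prop = fast_rt_count / go_trials
    omission_rate = omissions / go_trials
    return GngSummary(
        go_trials=go_trials,
        nogo_trials=nogo_trials,
        commissions=commissions,
        omissions=omissions,
        fast_rt_prop=fast_prop,
        excluded=bool(fast_prop > 0.30 or omission_rate > 0.50),
    )


def gng_metrics(trials: pd.DataFrame) -> GngSummary:
    """Summarize a trial log with columns trial_type ('go'/'nogo'),
    responded (bool), rt_ms (float, NaN when no response)."""
    required = {"trial_type", "responded"}
    if not required.issubset(trials.columns):
        raise ValueError(f"trial log needs columns {sorted(required)}")
    bad = set(trials["trial_type"].unique()) - {"go", "nogo"}
    if bad:
        raise ValueError(f"malformed trial types: {sorted(bad)}")
    go = trials[trials["trial_type"] == "go"]
    nogo = trials[trials["trial_type"] == "nogo"]
    responded = trials["responded"].astype(bool)
    fast = 0
    if "rt_ms" in trials.columns:
        fast = int(((go["rt_ms"] < 200) & go["responded"].astype(bool)).sum())
    return gng_metrics_from_counts(
        go_trials=len(go),
        nogo_trials=len(nogo),
        commissions=int(responded[nogo.index].sum()),
        omissions=int((~responded[go.index]).sum()),
        fast_rt_count=fast,
    )


def group_correlations(
    groups: pd.Series, pss_totals: pd.Series, outcomes: pd.DataFrame
) -> pd.DataFrame:
    """Per-group Pearson correlations of the PSS total with each outcome.

    Returns a tidy frame (group, outcome, n, r, p).  A constant vector in a
    group is an error, as is a group with fewer than 3 subjects.
    """
    rows = []
    for label in sorted(groups.unique()):
        idx = groups.index[groups == label]
        if len(idx) < 3:
            raise ValueError(f"group {label!r} has fewer than 3 subjects")
        x = pss_totals.loc[idx].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"constant PSS vector in group {label!r}")
        for col in outcomes.columns:
            y = outcomes.loc[idx, col].to_numpy(dtype=float)
            if np.std(y) == 0:
                raise ValueError(f"constant {col!r} vector in group {label!r}")
            r, p = stats.pearsonr(x, y)
            rows.append((label, col, len(idx), float(r), float(p)))
    return pd.DataFrame(rows, columns=["group", "outcome", "n", "r", "p"])
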