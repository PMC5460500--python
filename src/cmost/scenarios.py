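"""Canned screening experiments with paired no-screening baselines.

Every scenario runs both arms with the same master seed, so natural-history
randomness is shared (common random numbers) and arm differences are pure
screening effects.
"""

from __future__ import annotations

import numpy as np

from .econ import CostTable, EconConfig, compare_arms
from .engine import LifeTable, simulate_population
from .screening import EndoscopyModel, ScreeningPlan, StoolTestModel


def _defaults(life_table, endoscopy, stool, costs):
    return (life_table or LifeTable.us_2008(),
            endoscopy or EndoscopyModel(),
            stool or StoolTestModel(),
            costs or CostTable.default())


def run_sigmoidoscopy_trial(params, n: int = 77_445, seed: int = 1,
                            life_table: LifeTable | None = None,
                            endoscopy: EndoscopyModel | None = None,
                            enroll_age_range=(55, 74),
                            screen_offsets_y=(0, 4),
                            second_screen_fraction: float = 0.5,
                            adherence: float = 0.835,
                            followup_adherence: float = 0.72,
                            followup_window_y: float = 11.9) -> dict:
    """Emulate a randomized one/two-time rectosigmoidoscopy trial (ITT).

    Enrollment age is drawn uniformly over ``enroll_age_range``; screens
    happen at the given offsets after enrollment (later offsets only for the
    two-screen fraction); positives are referred to colonoscopy.  Reports
    incidence (overall / left / right) and CRC-mortality reduction over the
    follow-up window versus the paired no-screening arm.
    """
    lt, endo, stool, costs = _defaults(life_table, endoscopy, None, None)
    common = dict(enroll_age_range=tuple(enroll_age_range),
                  screen_offsets_y=tuple(screen_offsets_y),
                  followup_window_y=followup_window_y,
                  second_screen_fraction=second_screen_fraction)
    plan_s = ScreeningPlan(modality="sigmoidoscopy", adherence=adherence,
                           followup_adherence=followup_adherence, **common)
    plan_b = ScreeningPlan(modality="none", **common)
    arm_s = simulate_population(params, lt, plan_s, n=n, seed=seed,
                                endoscopy=endo)
    arm_b = simulate_population(params, lt, plan_b, n=n, seed=seed,
                                endoscopy=endo)
    ws, wb = arm_s.window, arm_b.window
    from ._kernel import W_DEATH, W_INC, W_LEFT, W_RIGHT

    def red(i):
        return float(1.0 - ws[i] / wb[i]) if wb[i] > 0 else 0.0

    return {
        "n": n, "seed": seed,
        "incidence_reduction": red(W_INC),
        "left_incidence_reduction": red(W_LEFT),
        "right_incidence_reduction": red(W_RIGHT),
        "mortality_reduction": red(W_DEATH),
        "cases": (float(ws[W_INC]), float(wb[W_INC])),
        "crc_deaths": (float(ws[W_DEATH]), float(wb[W_DEATH])),
    }


def run_trial_emulation(params, n: int = 77_445, seed: int = 1, **kw) -> dict:
    """One/two-time rectosigmoidoscopy trial, ages 55-74, 11.9-year follow-up."""
    return run_sigmoidoscopy_trial(params, n=n, seed=seed, **kw)


def run_decennial_colonoscopy(params, n: int = 100_000, seed: int = 1,
                              life_table: LifeTable | None = None,
                              endoscopy: EndoscopyModel | None = None,
                              costs: CostTable | None = None,
                              econ_config: EconConfig | None = None) -> dict:
    """Screening colonoscopy every 10 years between ages 50 and 75.

    Reports per-1000 reductions, life years gained and colonoscopy counts
    versus the paired no-screening arm.
    """
    lt, endo, stool, ct = _defaults(life_table, endoscopy, None, costs)
    plan = ScreeningPlan(modality="colonoscopy", start_age=50, stop_age=75,
                         interval_y=10, adherence=1.0)
    arm_s = simulate_population(params, lt, plan, n=n, seed=seed,
                                endoscopy=endo, costs=ct)
    arm_b = simulate_population(params, lt, None, n=n, seed=seed,
                                endoscopy=endo, costs=ct)
    cmp_ = compare_arms(arm_s, arm_b, econ_config)
    per1000 = 1000.0 / n
    lyg = cmp_.lyg * per1000
    screen = arm_s.colonoscopies("screening") * per1000
    surv = arm_s.colonoscopies("surveillance") * per1000
    total = arm_s.colonoscopies() * per1000
    extra = (arm_s.colonoscopies() - arm_b.colonoscopies()) * per1000
    prevented = (arm_b.total_cases - arm_s.total_cases) * per1000
    deaths_prevented = (arm_b.total_crc_deaths - arm_s.total_crc_deaths) * per1000
    return {
        "n": n, "seed": seed,
        "incidence_reduction": cmp_.incidence_reduction,
        "mortality_reduction": cmp_.mortality_reduction,
        "lyg_per_1000": lyg,
        "lyg_discounted_per_1000": cmp_.lyg_discounted * per1000,
        "screening_colonoscopies_per_1000": screen,
        "surveillance_colonoscopies_per_1000": surv,
        "total_colonoscopies_per_1000": total,
        "crc_cases_prevented_per_1000": prevented,
        "crc_deaths_prevented_per_1000": deaths_prevented,
        "colonoscopies_per_case_prevented":
            extra / prevented if prevented > 0 else float("nan"),
        "colonoscopies_per_lyg": extra / lyg if lyg > 0 else float("nan"),
        "comparison": cmp_.as_dict(),
    }


def run_max_clinical_incidence_reduction(params, n: int = 100_000,
                                         seed: int = 1, age: int = 65,
                                         life_table: LifeTable | None = None) -> dict:
    """Hypothetical perfect intervention removing every lesion at one age.

    Returns CRC incidence per 100,000 by age for intervention and baseline.
    """
    lt = life_table or LifeTable.us_2008()
    plan = ScreeningPlan(modality="perfect", screen_ages=(age,),
                         start_age=age, stop_age=age + 1, adherence=1.0,
                         surveillance=False)
    arm_s = simulate_population(params, lt, plan, n=n, seed=seed)
    arm_b = simulate_population(params, lt, None, n=n, seed=seed)

    def curve(arm):
        py = arm.py.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(py > 0, 1e5 * arm.inc.sum(axis=0) / py, 0.0)

    return {"age": age, "ages": np.arange(101),
            "incidence_intervention": curve(arm_s),
            "incidence_baseline": curve(arm_b)}


def run_single_colonoscopy_sweep(params, ages=tuple(range(40, 76)),
                                 n: int = 200_000, seed: int = 1,
                                 life_table: LifeTable | None = None,
                                 endoscopy: EndoscopyModel | None = None,
                                 costs: CostTable | None = None,
                                 econ_config: EconConfig | None = None) -> dict:
    """Sweep the age of a single lifetime screening colonoscopy.

    One paired baseline serves every age point.  Reports per-age incidence
    and mortality reduction, discounted LYG per 1000 and cost per LYG, plus
    the optimum ages on the grid.
    """
    ages = [int(a) for a in ages]
    if any(a < 40 or a > 75 for a in ages):
        raise ValueError("sweep ages must lie in [40, 75]")
    lt, endo, stool, ct = _defaults(life_table, endoscopy, None, costs)
    cfg = econ_config or EconConfig()
    arm_b = simulate_population(params, lt, None, n=n, seed=seed,
                                endoscopy=endo, costs=ct)
    rows = {"age": [], "incidence_reduction": [], "mortality_reduction": [],
            "lyg_per_1000": [], "lyg_discounted_per_1000": [],
            "cost_per_lyg": []}
    for a in ages:
        plan = ScreeningPlan(modality="colonoscopy", screen_ages=(a,),
                             start_age=a, stop_age=a + 1, adherence=1.0)
        arm_s = simulate_population(params, lt, plan, n=n, seed=seed,
                                    endoscopy=endo, costs=ct)
        cmp_ = compare_arms(arm_s, arm_b, cfg)
        rows["age"].append(a)
        rows["incidence_reduction"].append(cmp_.incidence_reduction)
        rows["mortality_reduction"].append(cmp_.mortality_reduction)
        rows["lyg_per_1000"].append(cmp_.per_1000(cmp_.lyg))
        rows["lyg_discounted_per_1000"].append(cmp_.per_1000(cmp_.lyg_discounted))
        rows["cost_per_lyg"].append(cmp_.cost_per_lyg)
    out = {k: np.asarray(v) for k, v in rows.items()}
    ages_arr = out["age"]
    finite = np.isfinite(out["cost_per_lyg"])
    out["optimal_incidence_age"] = int(ages_arr[np.argmax(out["incidence_reduction"])])
    out["optimal_mortality_age"] = int(ages_arr[np.argmax(out["mortality_reduction"])])
    out["optimal_lyg_age"] = int(ages_arr[np.argmax(out["lyg_discounted_per_1000"])])
    out["max_incidence_reduction"] = float(np.max(out["incidence_reduction"]))
    out["max_mortality_reduction"] = float(np.max(out["mortality_reduction"]))
    out["max_lyg_discounted_per_1000"] = float(np.max(out["lyg_discounted_per_1000"]))
    if finite.any():
        i = np.nanargmin(np.where(finite, out["cost_per_lyg"], np.nan))
        out["optimal_cost_age"] = int(ages_arr[i])
        out["min_cost_per_lyg"] = float(out["cost_per_lyg"][i])
    else:
        out["optimal_cost_age"] = -1
        out["min_cost_per_lyg"] = float("nan")
    out["n"] = n
    out["seed"] = seed
    return out
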