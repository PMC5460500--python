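"""Quarterly-step life-history simulator.

Two code paths share one event model:

* :func:`simulate_population` — the fast numba kernel, used everywhere.
* the reference operations (:func:`step_natural_history`,
  :func:`initiate_cancer`, :func:`resolve_death`) — a plain-Python
  implementation of the same per-quarter rules, used by the unit tests and
  cross-validated against the kernel.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel as K
from .params import (FEMALE, MALE, N_SEGMENTS, NaturalHistoryParams,
                     advanced_progression_rate, early_progression_rate)

DATA_DIR = Path(__file__).parent / "data"

LEFT_MAX_SEG = K.LEFT_MAX_SEG
RECTUM_MAX_SEG = K.RECTUM_MAX_SEG


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Annual probabilities of non-CRC death for ages 0..100."""

    qx: np.ndarray

    def __post_init__(self) -> None:
        if self.qx.shape != (101,):
            raise ValueError("life table must cover ages 0..100")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValueError("death probabilities must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        if not {"age", "qx"} <= set(df.columns):
            raise ValueError("life table CSV needs columns age,qx")
        qx = np.zeros(101)
        qx[df["age"].to_numpy()] = df["qx"].to_numpy()
        return cls(qx=qx)

    @classmethod
    def us_2008(cls) -> "LifeTable":
        return cls.from_csv(DATA_DIR / "life_table_2008.csv")

    def quarterly_hazard(self) -> np.ndarray:
        """Per-quarter death probability for quarters 0..403."""
        qq = 1.0 - (1.0 - self.qx) ** 0.25
        return np.repeat(qq, 4)[: K.MAX_Q]

    def natural_death_cdf(self) -> np.ndarray:
        """P(natural death quarter <= q); final entry forced to 1 (age cap)."""
        h = self.quarterly_hazard()
        surv = np.cumprod(1.0 - h)
        cdf = 1.0 - surv
        cdf[-1] = 1.0
        return cdf

    def survivorship(self) -> np.ndarray:
        """S(age) at exact integer ages 0..100 (S(0)=1)."""
        s = np.ones(101)
        s[1:] = np.cumprod(1.0 - self.qx[:-1])[:100]
        return s


def load_survival(path=None) -> np.ndarray:
    """Stage-specific 5-year CRC survival probabilities (stages 1..4)."""
    df = pd.read_csv(path or DATA_DIR / "crc_survival.csv")
    out = np.zeros(4)
    out[df["stage"].to_numpy() - 1] = df["five_year_survival"].to_numpy()
    if np.any((out <= 0) | (out > 1)):
        raise ValueError("five-year survival must lie in (0, 1]")
    return out


def load_location_distribution(path=None) -> np.ndarray:
    """Adenoma location weights over the 13 colon segments (sums to 1)."""
    df = pd.read_csv(path or DATA_DIR / "adenoma_location_dist.csv")
    w = np.zeros(N_SEGMENTS)
    w[df["segment"].to_numpy() - 1] = df["weight"].to_numpy()
    return w / w.sum()


def survival_to_quarterly_hazard(surv5: np.ndarray) -> np.ndarray:
    """Constant quarterly CRC-death hazard over the 5-year (20-quarter) window."""
    return 1.0 - np.asarray(surv5) ** (1.0 / 20.0)


# ---------------------------------------------------------------------------
# domain types (reference path)
# ---------------------------------------------------------------------------

ADENOMA, CANCER = "adenoma", "cancer"
ORIGINS = ("adenomatous", "fast", "direct")


@dataclass
class Lesion:
    kind: str
    segment: int
    birth_quarter: int
    adenoma_stage: int = 1
    cancer_stage: int = 1
    mult_early: float = 1.0
    mult_advanced: float = 1.0
    # cancer fields
    origin: str = "adenomatous"
    cancer_quarter: int = -1
    sojourn_quarters: int = 0
    symptomatic_stage: int = 0
    dwell_cum: tuple = (0, 0, 0, 0)
    symptomatic: bool = False
    removed: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.segment <= N_SEGMENTS:
            raise ValueError("segment must lie in 1..13")


@dataclass
class Individual:
    sex: int
    risk_multiplier: float
    natural_death_quarter: int
    lesions: list = field(default_factory=list)
    alive: bool = True
    cause_of_death: str | None = None
    death_quarter: int = -1
    diagnosis_quarter: int = -1
    diagnosis_stage: int = 0
    years_lost: float = 0.0
    counters: dict = field(default_factory=lambda: dict(
        initiated=0, regressed=0, resected=0, to_cancer=0))


def partition_dwell(sojourn_q: int, symptomatic_stage: int,
                    weights) -> tuple[int, int, int, int]:
    """Cumulative quarter boundaries of preclinical stages 1..4.

    Splits the sojourn over stages ``1..symptomatic_stage`` proportionally to
    ``weights`` (floor for the lower stages, remainder in the symptomatic
    stage), matching the kernel exactly.
    """
    wsum = float(sum(weights[:symptomatic_stage]))
    cum = [0, 0, 0, 0]
    acc = 0
    for k in range(3):
        if k < symptomatic_stage - 1:
            acc += int(np.floor(sojourn_q * weights[k] / wsum))
            cum[k] = acc
        else:
            cum[k] = sojourn_q
    cum[3] = sojourn_q
    return tuple(cum)


def cancer_stage_at(lesion: Lesion, quarter: int) -> int:
    elapsed = quarter - lesion.cancer_quarter
    stage = 1
    for k in range(3):
        if elapsed >= lesion.dwell_cum[k]:
            stage = k + 2
    return stage


def initiate_cancer(lesion_or_segment, origin: str, quarter: int,
                    params: NaturalHistoryParams, rng: np.random.Generator) -> Lesion:
    """Turn an adenoma into (or create) a preclinical cancer.

    Sojourn ~ Normal(mean, sd) truncated > 0, rounded to quarters; the
    symptomatic stage is drawn from the symptomatic-stage distribution and
    the per-stage dwell quarters partition the sojourn.
    """
    if origin not in ORIGINS:
        raise ValueError(f"unknown cancer origin: {origin!r}")
    if isinstance(lesion_or_segment, Lesion):
        les = lesion_or_segment
    else:
        les = Lesion(kind=CANCER, segment=int(lesion_or_segment),
                     birth_quarter=quarter)
    mean_q, sd_q = params.sojourn_mean_y * 4.0, params.sojourn_sd_y * 4.0
    t = 0.0
    while t < 0.5:
        t = rng.normal(mean_q, sd_q)
    soj = max(1, int(np.floor(t + 0.5)))
    sstage = int(rng.choice(4, p=params.symptomatic_stage_dist)) + 1
    les.kind = CANCER
    les.origin = origin
    les.cancer_quarter = quarter
    les.cancer_stage = 1
    les.sojourn_quarters = soj
    les.symptomatic_stage = sstage
    les.dwell_cum = partition_dwell(soj, sstage, params.stage_dwell_weights)
    return les


def step_natural_history(ind: Individual, quarter: int,
                         params: NaturalHistoryParams,
                         location_dist: np.ndarray,
                         rng: np.random.Generator) -> Individual:
    """One quarter of adenoma/cancer natural history (reference path).

    Applies, in order: new-adenoma initiation; per-adenoma progression /
    fast-cancer / regression (at most one event per lesion per quarter);
    direct cancer initiation; cancer stage advance and symptom onset.
    """
    if not ind.alive:
        raise ValueError("individual is dead")
    age = quarter / 4.0
    sexm = ind.sex == MALE
    # initiation
    from .params import initiation_rate
    p_new = float(initiation_rate(params, age, ind.sex, ind.risk_multiplier))
    if rng.random() < p_new:
        seg = int(rng.choice(N_SEGMENTS, p=location_dist)) + 1
        les = Lesion(kind=ADENOMA, segment=seg, birth_quarter=quarter)
        les.mult_early = float(params.adenoma_risk_anchors_early.sample(rng.random()))
        les.mult_advanced = float(
            params.adenoma_risk_anchors_advanced.sample(rng.random()))
        ind.lesions.append(les)
        ind.counters["initiated"] += 1
    er = float(early_progression_rate(params, age)) * (
        params.sex_factors[1] if sexm else 1.0)
    ar = float(advanced_progression_rate(params, age)) * (
        params.sex_factors[2] if sexm else 1.0)
    for les in ind.lesions:
        if les.removed:
            continue
        if les.kind == ADENOMA and les.birth_quarter < quarter:
            stg = les.adenoma_stage
            rect = les.segment <= RECTUM_MAX_SEG
            re = params.rectum_factors[0] if rect else 1.0
            ra = params.rectum_factors[1] if rect else 1.0
            if stg <= 4:
                p_prog = er * les.mult_early * params.stage_progression[stg - 1] * re
            else:
                p_prog = ar * les.mult_advanced * params.stage_progression[stg - 1] * ra
            p_fast = 0.0
            if stg <= 5:
                p_fast = ar * les.mult_advanced * params.stage_cancer_risk[stg - 1] * ra
            p_reg = params.stage_regression[stg - 1]
            tot = p_prog + p_fast + p_reg
            if tot > 1.0:
                p_prog, p_fast, p_reg = (p / tot for p in (p_prog, p_fast, p_reg))
            u = rng.random()
            if u < p_prog:
                if stg == 6:
                    initiate_cancer(les, "adenomatous", quarter, params, rng)
                    ind.counters["to_cancer"] += 1
                else:
                    les.adenoma_stage = stg + 1
            elif u < p_prog + p_fast:
                initiate_cancer(les, "fast", quarter, params, rng)
                ind.counters["to_cancer"] += 1
            elif u < p_prog + p_fast + p_reg:
                if stg == 1:
                    les.removed = True
                    ind.counters["regressed"] += 1
                else:
                    les.adenoma_stage = stg - 1
        elif les.kind == CANCER and not les.symptomatic:
            les.cancer_stage = cancer_stage_at(les, quarter)
            if quarter - les.cancer_quarter >= les.sojourn_quarters:
                les.cancer_stage = les.symptomatic_stage
                les.symptomatic = True
    # direct cancer
    shape = np.exp(-((params.c1 * age - params.c2) ** 2))
    p_direct = float(np.sum(params.direct_cancer_risk)) * shape
    if rng.random() < p_direct:
        w = np.asarray(params.direct_cancer_risk, dtype=float)
        seg = int(rng.choice(N_SEGMENTS, p=w / w.sum())) + 1
        les = initiate_cancer(seg, "direct", quarter, params, rng)
        les.birth_quarter = quarter
        ind.lesions.append(les)
    return ind


def resolve_death(ind: Individual, quarter: int, crc_hazard_q: np.ndarray,
                  rng: np.random.Generator) -> Individual:
    """CRC death (within 5 years of diagnosis) then other-cause death."""
    if not ind.alive:
        raise ValueError("individual is dead")
    if ind.diagnosis_quarter >= 0 and 0 <= quarter - ind.diagnosis_quarter <= 20:
        if rng.random() < crc_hazard_q[ind.diagnosis_stage - 1]:
            ind.alive = False
            ind.cause_of_death = "crc"
            ind.death_quarter = quarter
            ind.years_lost = max(0.0, (ind.natural_death_quarter - quarter) / 4.0)
            return ind
    if quarter >= ind.natural_death_quarter:
        ind.alive = False
        ind.cause_of_death = "other"
        ind.death_quarter = quarter
    return ind


# ---------------------------------------------------------------------------
# packing for the kernel
# ---------------------------------------------------------------------------

def build_nh_pack(params: NaturalHistoryParams, life_table: LifeTable,
                  survival5: np.ndarray | None = None,
                  location_dist: np.ndarray | None = None,
                  male_fraction: float = 0.5):
    """Precompute per-quarter rate tables and CDFs for the kernel."""
    if survival5 is None:
        survival5 = load_survival()
    if location_dist is None:
        location_dist = load_location_distribution()
    ages = np.arange(K.MAX_Q) / 4.0
    sig = params.a0 / (1.0 + np.exp(-(params.a1 * ages - params.a2)))
    gb = params.b0 * np.exp(-((params.b1 * ages - params.b2) ** 2))
    gc = params.c0 * np.exp(-((params.c1 * ages - params.c2) ** 2))
    init_rate_q = np.stack([sig, sig * params.sex_factors[0]])
    early_rate_q = np.stack([gb, gb * params.sex_factors[1]])
    adv_rate_q = np.stack([gc, gc * params.sex_factors[2]])
    rect_e = np.ones(N_SEGMENTS)
    rect_a = np.ones(N_SEGMENTS)
    rect_e[:RECTUM_MAX_SEG] = params.rectum_factors[0]
    rect_a[:RECTUM_MAX_SEG] = params.rectum_factors[1]
    direct = np.asarray(params.direct_cancer_risk, dtype=float)
    shape = np.exp(-((params.c1 * ages - params.c2) ** 2))
    direct_total_q = direct.sum() * shape
    direct_seg_cdf = (np.cumsum(direct / direct.sum()) if direct.sum() > 0
                      else np.linspace(1 / 13, 1.0, 13))
    ind_a = params.individual_risk_anchors
    ea = params.adenoma_risk_anchors_early
    aa = params.adenoma_risk_anchors_advanced
    return (
        init_rate_q, early_rate_q, adv_rate_q, rect_e, rect_a,
        np.asarray(params.stage_progression, dtype=float),
        np.asarray(params.stage_regression, dtype=float),
        np.asarray(params.stage_cancer_risk, dtype=float),
        direct_total_q, direct_seg_cdf, np.cumsum(location_dist),
        np.asarray(ind_a.quantiles, dtype=float), np.asarray(ind_a.multipliers, dtype=float),
        np.asarray(ea.quantiles, dtype=float), np.asarray(ea.multipliers, dtype=float),
        np.asarray(aa.quantiles, dtype=float), np.asarray(aa.multipliers, dtype=float),
        params.sojourn_mean_y * 4.0, params.sojourn_sd_y * 4.0,
        np.cumsum(np.asarray(params.symptomatic_stage_dist, dtype=float)),
        np.asarray(params.stage_dwell_weights, dtype=float),
        survival_to_quarterly_hazard(survival5),
        life_table.natural_death_cdf(), float(male_fraction),
    )


def allocate_tallies():
    return (
        np.zeros((2, 101)), np.zeros((2, 101)), np.zeros((2, 101)),
        np.zeros(101), np.zeros(101), np.zeros(101),
        np.zeros((2, 101)), np.zeros((2, 101)), np.zeros((101, 4)),
        np.zeros(4), np.zeros(4),
        np.zeros(101), np.zeros(101), np.zeros(101),
        np.zeros((2, 101)), np.zeros(101), np.zeros(101),
        np.zeros((101, 3, 4)), np.zeros(101), np.zeros(4),
        np.zeros((101, 3)), np.zeros(K.N_MISC), np.zeros(480),
        np.zeros(K.N_WINDOW),
    )


_TALLY_NAMES = (
    "alive_at_age", "ge1_early", "ge1_adv", "ge1_any", "ge2", "ge3",
    "py", "inc", "inc_mode", "inc_stage_sympt", "inc_stage_screen",
    "inc_left", "inc_right", "inc_rectum", "crc_death", "other_death",
    "compl_death", "procedures", "polypectomies", "compl_counts",
    "costs_year", "misc", "dwell_hist", "window",
)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """Per-population tallies for one screening arm."""

    n: int
    seed: int
    plan_label: str
    tallies: dict

    def __getattr__(self, name):
        t = object.__getattribute__(self, "tallies")
        if name in t:
            return t[name]
        raise AttributeError(name)

    # -- epidemiology ---------------------------------------------------
    def prevalence(self, kind: str, sex, age: int) -> float:
        """Prevalence of >=1 early/advanced/any adenoma at an integer age."""
        num = {"early": self.ge1_early, "advanced": self.ge1_adv}.get(kind)
        alive = self.alive_at_age
        if sex == "A":
            if kind == "any":
                return self.ge1_any[age] / max(alive.sum(axis=0)[age], 1.0)
            return num.sum(axis=0)[age] / max(alive.sum(axis=0)[age], 1.0)
        s = MALE if sex in ("M", MALE, 1) else FEMALE
        return num[s, age] / max(alive[s, age], 1.0)

    def rate_per_100k(self, what: str, sex, age_lo: int, age_hi: int) -> float:
        """Incidence or mortality rate per 100,000 person-years."""
        arr = {"inc": self.inc, "mort": self.crc_death}[what]
        if sex == "A":
            ev = arr[:, age_lo:age_hi + 1].sum()
            pyr = self.py[:, age_lo:age_hi + 1].sum()
        else:
            s = MALE if sex in ("M", MALE, 1) else FEMALE
            ev = arr[s, age_lo:age_hi + 1].sum()
            pyr = self.py[s, age_lo:age_hi + 1].sum()
        return 1e5 * ev / max(pyr, 1e-9)

    # -- totals ---------------------------------------------------------
    @property
    def total_cases(self) -> float:
        return float(self.inc.sum())

    @property
    def total_crc_deaths(self) -> float:
        return float(self.crc_death.sum())

    @property
    def life_years(self) -> np.ndarray:
        """Life years lived per age-year (both sexes)."""
        return self.py.sum(axis=0)

    @property
    def total_life_years(self) -> float:
        return float(self.py.sum())

    @property
    def costs_by_year(self) -> np.ndarray:
        """Total costs per age-year (procedures + complications + treatment)."""
        return self.costs_year.sum(axis=1)

    def colonoscopies(self, context: str | None = None) -> float:
        ctx = {"screening": 0, "surveillance": 1, "diagnostic": 2, "followup": 3}
        p = self.procedures[:, K.P_COLO, :]
        return float(p.sum() if context is None else p[:, ctx[context]].sum())

    def stage_distribution(self, detected: str) -> np.ndarray:
        arr = (self.inc_stage_sympt if detected == "symptomatic"
               else self.inc_stage_screen)
        tot = arr.sum()
        return arr / tot if tot > 0 else np.full(4, np.nan)

    def median_dwell_years(self) -> float:
        """Median adenoma dwell time of adenoma-pathway cancers (years)."""
        h = self.dwell_hist
        tot = h.sum()
        if tot == 0:
            return np.nan
        cum = np.cumsum(h)
        q = int(np.searchsorted(cum, tot / 2.0))
        return q / 4.0

    def as_dict(self) -> dict:
        return {
            "n": self.n, "seed": self.seed, "plan": self.plan_label,
            "total_cases": self.total_cases,
            "total_crc_deaths": self.total_crc_deaths,
            "total_life_years": self.total_life_years,
            "total_cost": float(self.costs_year.sum()),
            "colonoscopies": self.colonoscopies(),
        }


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

def params_digest(params: NaturalHistoryParams) -> str:
    import yaml
    return hashlib.sha256(
        yaml.safe_dump(params.as_dict(), sort_keys=True).encode()).hexdigest()[:16]


def simulate_population(params: NaturalHistoryParams, life_table: LifeTable,
                        plan=None, n: int = 10_000, seed: int = 1,
                        endoscopy=None, stool=None, costs=None,
                        survival5=None, location_dist=None) -> ScenarioResult:
    """Simulate ``n`` individual life histories under a screening plan.

    Deterministic given ``(params, plan, n, seed)``.  ``plan=None`` means no
    screening.  Returns per-age tallies of adenoma prevalence, CRC
    incidence/mortality/stage/mode, deaths, procedures, complications, costs
    and life-years.
    """
    from .econ import CostTable
    from .screening import EndoscopyModel, ScreeningPlan, StoolTestModel

    if n < 1:
        raise ValueError("n must be >= 1")
    if plan is None:
        plan = ScreeningPlan.none()
    if endoscopy is None:
        endoscopy = EndoscopyModel()
    if stool is None:
        stool = StoolTestModel()
    if costs is None:
        costs = CostTable.default()

    nh = build_nh_pack(params, life_table, survival5=survival5,
                       location_dist=location_dist)
    scr = plan.build_pack(endoscopy, stool)
    econ = costs.build_pack()
    tallies = allocate_tallies()
    K.run_population(int(n), int(seed), nh, scr, econ, tallies)
    return ScenarioResult(n=int(n), seed=int(seed), plan_label=plan.label(),
                          tallies=dict(zip(_TALLY_NAMES, tallies)))
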