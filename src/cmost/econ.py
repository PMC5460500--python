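"""Cost accrual, discounting, and paired-arm comparison (LYG, cost/LYG)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import ScenarioResult

DATA_DIR = Path(__file__).parent / "data"

#: conventional cost-effectiveness threshold (USD per life-year gained)
COST_EFFECTIVE_THRESHOLD = 100_000.0

COMPLICATION_ITEMS = ("major_bleed", "minor_bleed", "mucosal_burn", "perforation")


@dataclass
class CostTable:
    """Unit costs: procedures, complications, stage x phase treatment."""

    colonoscopy: float
    polypectomy: float
    sigmoidoscopy: float
    fobt: float
    complications: tuple          # per COMPLICATION_ITEMS
    initial: tuple                # per cancer stage 1..4 (first 3 months)
    continuing_annual: tuple      # per stage, per year
    terminal: tuple               # per stage, last 12 months of life

    def __post_init__(self) -> None:
        vals = (self.colonoscopy, self.polypectomy, self.sigmoidoscopy,
                self.fobt, *self.complications, *self.initial,
                *self.continuing_annual, *self.terminal)
        if any(v < 0 for v in vals):
            raise ValueError("costs must be >= 0")
        for name in ("complications", "initial", "continuing_annual", "terminal"):
            if len(getattr(self, name)) != 4:
                raise ValueError(f"{name} needs 4 entries")

    @classmethod
    def from_csv(cls, path) -> "CostTable":
        df = pd.read_csv(path, dtype={"stage": "Int64"})
        proc = df[df.kind == "procedure"].set_index("item")["value"]
        compl = df[df.kind == "complication"].set_index("item")["value"]
        treat = df[df.kind == "treatment"].set_index(["stage", "phase"])["value"]
        return cls(
            colonoscopy=float(proc["colonoscopy"]),
            polypectomy=float(proc["polypectomy"]),
            sigmoidoscopy=float(proc["sigmoidoscopy"]),
            fobt=float(proc["fobt"]),
            complications=tuple(float(compl[i]) for i in COMPLICATION_ITEMS),
            initial=tuple(float(treat[(s, "initial")]) for s in range(1, 5)),
            continuing_annual=tuple(float(treat[(s, "continuing")]) for s in range(1, 5)),
            terminal=tuple(float(treat[(s, "terminal")]) for s in range(1, 5)),
        )

    @classmethod
    def default(cls) -> "CostTable":
        return cls.from_csv(DATA_DIR / "costs_2012.csv")

    @classmethod
    def zero(cls) -> "CostTable":
        z4 = (0.0,) * 4
        return cls(0.0, 0.0, 0.0, 0.0, z4, z4, z4, z4)

    def build_pack(self):
        return (
            np.asarray([self.colonoscopy, self.polypectomy,
                        self.sigmoidoscopy, self.fobt]),
            np.asarray(self.complications, dtype=float),
            np.asarray(self.initial, dtype=float),
            np.asarray(self.continuing_annual, dtype=float) / 4.0,
            np.asarray(self.terminal, dtype=float),
        )


@dataclass
class EconConfig:
    annual_discount_rate: float = 0.03
    #: age (years) to which present values are discounted
    reference_age: float = 0.0
    treatment_horizon_y: int = 5

    def __post_init__(self) -> None:
        if self.annual_discount_rate < 0:
            raise ValueError("discount rate must be >= 0")


def discount(stream, config: EconConfig | float = 0.03,
             t0: float | None = None) -> float:
    """Present value of a stream indexed by age-year (end-year convention).

    ``sum_t x_t / (1+r)^(t - t0)``.
    """
    if isinstance(config, EconConfig):
        rate, ref = config.annual_discount_rate, config.reference_age
    else:
        rate, ref = float(config), 0.0
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if t0 is not None:
        ref = t0
    stream = np.asarray(stream, dtype=float)
    t = np.arange(stream.shape[0])
    return float(np.sum(stream / (1.0 + rate) ** (t - ref)))


def accrue_treatment_costs(stage: int, diagnosis_quarter: int,
                           crc_death_quarter: int | None,
                           table: CostTable,
                           horizon_y: int = 5) -> dict[int, float]:
    """Treatment cost stream by quarter for one detected cancer.

    Initial-phase cost in the diagnosis quarter; continuing costs quarterly
    until the 5-year horizon; in case of CRC death the terminal phase (up to
    12 months) replaces continuing costs.  Mirrors the simulation kernel.
    """
    if stage not in (1, 2, 3, 4):
        raise ValueError("stage must be 1..4")
    out: dict[int, float] = {diagnosis_quarter: table.initial[stage - 1]}
    cont_q = table.continuing_annual[stage - 1] / 4.0
    hq = 4 * horizon_y
    end = diagnosis_quarter + hq
    if crc_death_quarter is not None:
        end = min(end, crc_death_quarter)
    for q in range(diagnosis_quarter + 1, end + 1):
        if q - diagnosis_quarter > hq:
            break
        out[q] = out.get(q, 0.0) + cont_q
    if crc_death_quarter is not None and crc_death_quarter - diagnosis_quarter <= hq:
        tq_el = crc_death_quarter - diagnosis_quarter
        nterm = min(tq_el + 1, 4)
        refund = cont_q * min(nterm, max(tq_el, 0))
        out[crc_death_quarter] = (out.get(crc_death_quarter, 0.0)
                                  + table.terminal[stage - 1] * (nterm / 4.0)
                                  - refund)
    return out


@dataclass
class ArmComparison:
    lyg: float
    lyg_discounted: float
    delta_cost: float
    delta_cost_discounted: float
    cost_per_lyg: float          # NaN when discounted LYG <= 0
    incidence_reduction: float
    mortality_reduction: float
    n: int

    @property
    def cost_effective(self) -> bool:
        return (np.isfinite(self.cost_per_lyg)
                and self.cost_per_lyg < COST_EFFECTIVE_THRESHOLD)

    def per_1000(self, value: float) -> float:
        return 1000.0 * value / self.n

    def as_dict(self) -> dict:
        return {
            "lyg_per_1000": self.per_1000(self.lyg),
            "lyg_discounted_per_1000": self.per_1000(self.lyg_discounted),
            "delta_cost_per_person": self.delta_cost / self.n,
            "delta_cost_discounted_per_person": self.delta_cost_discounted / self.n,
            "cost_per_lyg": self.cost_per_lyg,
            "incidence_reduction": self.incidence_reduction,
            "mortality_reduction": self.mortality_reduction,
        }


def compare_arms(screened: ScenarioResult, unscreened: ScenarioResult,
                 config: EconConfig | None = None) -> ArmComparison:
    """Paired comparison of a screening arm against its no-screening baseline."""
    config = config or EconConfig()
    if screened.n != unscreened.n or screened.seed != unscreened.seed:
        raise ValueError("arms must be paired: same n and seed")
    n = screened.n
    dly = screened.life_years - unscreened.life_years
    dcost = screened.costs_by_year - unscreened.costs_by_year
    lyg = float(dly.sum())
    lyg_d = discount(dly, config)
    dc = float(dcost.sum())
    dc_d = discount(dcost, config)
    ratio = dc_d / lyg_d if lyg_d > 0 else float("nan")
    inc_red = (1.0 - screened.total_cases / unscreened.total_cases
               if unscreened.total_cases > 0 else 0.0)
    mort_red = (1.0 - screened.total_crc_deaths / unscreened.total_crc_deaths
                if unscreened.total_crc_deaths > 0 else 0.0)
    return ArmComparison(lyg=lyg, lyg_discounted=lyg_d, delta_cost=dc,
                         delta_cost_discounted=dc_d, cost_per_lyg=ratio,
                         incidence_reduction=inc_red,
                         mortality_reduction=mort_red, n=n)
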