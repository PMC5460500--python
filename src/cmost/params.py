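"""Natural-history parameters and the age/sex/location risk functions.

All rates are expressed as per-quarter (3-month) transition probabilities.
Annual probabilities can be converted with :func:`annual_to_quarterly`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "NaturalHistoryParams",
    "AnchorCDF",
    "initiation_rate",
    "early_progression_rate",
    "advanced_progression_rate",
    "sample_individual_risk",
    "annual_to_quarterly",
    "load_params",
    "save_params",
]

SCHEMA_VERSION = 1

N_SEGMENTS = 13
N_ADENOMA_STAGES = 6
N_CANCER_STAGES = 4

#: segment index (1-based) of the rectum
RECTUM_SEGMENT = 1
#: deepest segment reachable by rectosigmoidoscopy on an average exam
LEFT_FLEXURE_SEGMENT = 6


def annual_to_quarterly(p_annual: float) -> float:
    """Convert an annual event probability to the per-quarter equivalent."""
    return 1.0 - (1.0 - p_annual) ** 0.25


@dataclass(frozen=True)
class AnchorCDF:
    """Piecewise-linear CDF through anchor points.

    Maps a uniform quantile ``u`` in [0, 1] to a risk multiplier.  The
    quantile axis must start at 0, end at 1 and be nondecreasing.
    """

    quantiles: tuple[float, ...]
    multipliers: tuple[float, ...]

    def __post_init__(self) -> None:
        q = np.asarray(self.quantiles, dtype=float)
        v = np.asarray(self.multipliers, dtype=float)
        if q.shape != v.shape or q.size < 2:
            raise ValueError("anchor arrays must have equal length >= 2")
        if q[0] != 0.0 or q[-1] != 1.0:
            raise ValueError("quantile axis must start at 0 and end at 1")
        if np.any(np.diff(q) < 0) or np.any(np.diff(v) < 0):
            raise ValueError("anchor CDF must be nondecreasing")
        if np.any(v < 0):
            raise ValueError("risk multipliers must be >= 0")

    def sample(self, u):
        """Multiplier at quantile ``u`` (scalar or array)."""
        u = np.asarray(u, dtype=float)
        if np.any(u < 0) or np.any(u > 1):
            raise ValueError("quantile must lie in [0, 1]")
        return np.interp(u, self.quantiles, self.multipliers)

    def mean(self) -> float:
        """Population mean multiplier (trapezoid integral over u)."""
        return float(np.trapezoid(self.multipliers, self.quantiles))

    def as_dict(self) -> dict:
        return {
            "quantiles": [float(x) for x in self.quantiles],
            "multipliers": [float(x) for x in self.multipliers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnchorCDF":
        return cls(tuple(d["quantiles"]), tuple(d["multipliers"]))


def _default_individual_anchors() -> AnchorCDF:
    return AnchorCDF((0.0, 0.25, 0.5, 0.75, 1.0), (0.04, 0.25, 0.65, 1.4, 4.2))


def _default_early_anchors() -> AnchorCDF:
    return AnchorCDF((0.0, 0.5, 0.75, 0.9, 1.0), (0.05, 0.3, 0.8, 1.8, 5.0))


def _default_advanced_anchors() -> AnchorCDF:
    return AnchorCDF((0.0, 0.5, 0.75, 0.9, 1.0), (0.1, 0.45, 1.0, 2.0, 4.0))


@dataclass
class NaturalHistoryParams:
    """Every calibratable constant of the natural-history model.

    Rate-function coefficients follow the functional forms

    * adenoma initiation:  ``a0 / (1 + exp(-(a1*y - a2)))``   (sigmoid in age y)
    * early progression:   ``b0 * exp(-(b1*y - b2)**2)``      (Gaussian)
    * advanced progression:``c0 * exp(-(c1*y - c2)**2)``      (Gaussian)

    evaluated per quarter-year time step.
    """

    # sigmoid: age-dependent adenoma initiation (per quarter)
    a0: float = 0.006
    a1: float = 0.055
    a2: float = 2.0
    # Gaussian: early adenoma progression
    b0: float = 0.025
    b1: float = 0.030
    b2: float = 2.2
    # Gaussian: advanced adenoma progression
    c0: float = 0.020
    c1: float = 0.025
    c2: float = 2.0

    individual_risk_anchors: AnchorCDF = field(default_factory=_default_individual_anchors)
    adenoma_risk_anchors_early: AnchorCDF = field(default_factory=_default_early_anchors)
    adenoma_risk_anchors_advanced: AnchorCDF = field(default_factory=_default_advanced_anchors)

    # male multipliers (female = 1.0): initiation, early prog., advanced prog.
    sex_factors: tuple[float, float, float] = (1.35, 1.1, 1.15)
    # rectum-vs-colon multipliers: early prog., advanced prog.
    rectum_factors: tuple[float, float] = (1.3, 1.3)

    # per adenoma stage I..VI
    stage_progression: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    # not calibrated; highest for stage I, lowest for VI (per quarter)
    stage_regression: tuple[float, ...] = (0.014, 0.010, 0.007, 0.005, 0.004, 0.002)
    # fast-cancer risk from adenoma stages I..V (relative to advanced rate)
    stage_cancer_risk: tuple[float, ...] = (0.0002, 0.0005, 0.001, 0.002, 0.01)
    # per colon segment 1..13 (per quarter, modulated by the advanced Gaussian shape)
    direct_cancer_risk: tuple[float, ...] = (
        0.0000005, 0.0000005, 0.0000005, 0.0000005, 0.0000005, 0.0000005,
        0.000001, 0.000002, 0.000002, 0.000002, 0.000003, 0.000003, 0.000004,
    )

    sojourn_mean_y: float = 3.0
    sojourn_sd_y: float = 0.5

    # stage at which a preclinical cancer turns symptomatic
    symptomatic_stage_dist: tuple[float, ...] = (0.12, 0.32, 0.31, 0.25)
    # relative time spent in preclinical stages 1..4 (partition of the
    # sojourn); adjusted so screen-detected cancers reproduce the
    # asymptomatic stage-distribution target
    stage_dwell_weights: tuple[float, ...] = (0.1785, 0.2182, 0.2834, 0.32)

    dwell_variant: int = 13

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        for name in ("a0", "a1", "b0", "c0", "sojourn_mean_y"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sojourn_sd_y <= 0:
            raise ValueError("sojourn_sd_y must be > 0")
        if len(self.stage_progression) != N_ADENOMA_STAGES:
            raise ValueError("stage_progression needs 6 entries")
        if len(self.stage_regression) != N_ADENOMA_STAGES:
            raise ValueError("stage_regression needs 6 entries")
        if len(self.stage_cancer_risk) != N_ADENOMA_STAGES - 1:
            raise ValueError("stage_cancer_risk needs 5 entries")
        if len(self.direct_cancer_risk) != N_SEGMENTS:
            raise ValueError(f"direct_cancer_risk needs {N_SEGMENTS} entries")
        if len(self.sex_factors) != 3:
            raise ValueError("sex_factors needs 3 entries")
        if len(self.rectum_factors) != 2:
            raise ValueError("rectum_factors needs 2 entries")
        if len(self.symptomatic_stage_dist) != N_CANCER_STAGES:
            raise ValueError("symptomatic_stage_dist needs 4 entries")
        if abs(sum(self.symptomatic_stage_dist) - 1.0) > 1e-6:
            raise ValueError("symptomatic_stage_dist must sum to 1")
        if len(self.stage_dwell_weights) != N_CANCER_STAGES:
            raise ValueError("stage_dwell_weights needs 4 entries")
        for arr_name in ("stage_progression", "stage_regression", "stage_cancer_risk",
                         "direct_cancer_risk", "sex_factors", "rectum_factors",
                         "stage_dwell_weights"):
            if any(x < 0 for x in getattr(self, arr_name)):
                raise ValueError(f"{arr_name} entries must be >= 0")

    # -- convenience ----------------------------------------------------
    def replace(self, **kw) -> "NaturalHistoryParams":
        return dataclasses.replace(self, **kw)

    def as_dict(self) -> dict:
        d = {
            "schema_version": SCHEMA_VERSION,
            "dwell_variant": int(self.dwell_variant),
        }
        for name in ("a0", "a1", "a2", "b0", "b1", "b2", "c0", "c1", "c2",
                     "sojourn_mean_y", "sojourn_sd_y"):
            d[name] = float(getattr(self, name))
        for name in ("sex_factors", "rectum_factors", "stage_progression",
                     "stage_regression", "stage_cancer_risk", "direct_cancer_risk",
                     "symptomatic_stage_dist", "stage_dwell_weights"):
            d[name] = [float(x) for x in getattr(self, name)]
        d["individual_risk_anchors"] = self.individual_risk_anchors.as_dict()
        d["adenoma_risk_anchors_early"] = self.adenoma_risk_anchors_early.as_dict()
        d["adenoma_risk_anchors_advanced"] = self.adenoma_risk_anchors_advanced.as_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NaturalHistoryParams":
        d = dict(d)
        version = d.pop("schema_version", None)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported parameter schema version: {version!r}")
        kw = {}
        scalar = ("a0", "a1", "a2", "b0", "b1", "b2", "c0", "c1", "c2",
                  "sojourn_mean_y", "sojourn_sd_y", "dwell_variant")
        vector = ("sex_factors", "rectum_factors", "stage_progression",
                  "stage_regression", "stage_cancer_risk", "direct_cancer_risk",
                  "symptomatic_stage_dist", "stage_dwell_weights")
        anchors = ("individual_risk_anchors", "adenoma_risk_anchors_early",
                   "adenoma_risk_anchors_advanced")
        for name in scalar + vector + anchors:
            if name not in d:
                raise ValueError(f"missing parameter field: {name}")
        for name in scalar:
            kw[name] = d[name]
        for name in vector:
            kw[name] = tuple(float(x) for x in d[name])
        for name in anchors:
            kw[name] = AnchorCDF.from_dict(d[name])
        return cls(**kw)


# -- rate functions -----------------------------------------------------

FEMALE, MALE = 0, 1

_SEX_CODES = {"f": FEMALE, "female": FEMALE, 0: FEMALE,
              "m": MALE, "male": MALE, 1: MALE}


def _sex_code(sex) -> int:
    try:
        return _SEX_CODES[sex.lower() if isinstance(sex, str) else int(sex)]
    except (KeyError, AttributeError) as exc:
        raise ValueError(f"unknown sex: {sex!r}") from exc


def _check_age(age) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    if np.any(age < 0) or np.any(age > 100):
        raise ValueError("age must lie in [0, 100]")
    return age


def initiation_rate(p: NaturalHistoryParams, age, sex=FEMALE, individual_multiplier=1.0):
    """Per-quarter probability of a new adenoma appearing.

    ``a0 / (1 + exp(-(a1*age - a2)))`` scaled by the sex factor and the
    individual risk multiplier, clipped to [0, 1].
    """
    age = _check_age(age)
    base = p.a0 / (1.0 + np.exp(-(p.a1 * age - p.a2)))
    f = p.sex_factors[0] if _sex_code(sex) == MALE else 1.0
    return np.clip(base * f * individual_multiplier, 0.0, 1.0)


def early_progression_rate(p: NaturalHistoryParams, age):
    """Per-quarter base rate of early-adenoma progression, ``b0*exp(-(b1*y-b2)^2)``."""
    age = _check_age(age)
    return p.b0 * np.exp(-((p.b1 * age - p.b2) ** 2))


def advanced_progression_rate(p: NaturalHistoryParams, age):
    """Per-quarter base rate of advanced-adenoma progression, ``c0*exp(-(c1*y-c2)^2)``."""
    age = _check_age(age)
    return p.c0 * np.exp(-((p.c1 * age - p.c2) ** 2))


def sample_individual_risk(p: NaturalHistoryParams, u):
    """Individual adenoma-initiation multiplier at population quantile ``u``."""
    return p.individual_risk_anchors.sample(u)


# -- persistence --------------------------------------------------------

def save_params(p: NaturalHistoryParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(p.as_dict(), sort_keys=True))


def load_params(path) -> NaturalHistoryParams:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ValueError(f"not a parameter file: {path}")
    return NaturalHistoryParams.from_dict(d)


def builtin_params(dwell_variant: int = 13) -> NaturalHistoryParams:
    """Load one of the calibrated parameter sets shipped with the package."""
    here = Path(__file__).parent / "data" / f"params_cmost{int(dwell_variant)}.yaml"
    if not here.exists():
        raise ValueError(f"no built-in parameter set for dwell variant {dwell_variant}")
    return load_params(here)
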