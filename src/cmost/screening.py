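"""Endoscopic and stool-test screening: models, plans, surveillance rules.

The numba kernel consumes packed arrays built here; the module-level
``perform_*`` operations are the plain-Python reference implementations used
by the unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel as K
from .engine import ADENOMA, CANCER, Individual, LEFT_MAX_SEG
from .params import N_SEGMENTS

CECUM_SEGMENT = 13
FLEXURE_SEGMENTS = (6, 10)   # splenic, hepatic

#: sigmoidoscopy complication probabilities relative to colonoscopy
SIG_COMPLICATION_FACTOR = 0.1


@dataclass
class EndoscopyModel:
    """Reach, per-stage detection, and complication model of an endoscopy."""

    cecal_intubation: float = 0.95
    #: detection probability per adenoma stage I..VI
    detection_by_stage: tuple = (0.75, 0.75, 0.85, 0.85, 0.95, 0.95)
    detection_cancer: float = 0.95
    flexure_penalty: float = 0.9
    #: sigmoidoscopy detection penalties (early, advanced/cancer)
    sig_penalty_early: float = 0.75
    sig_penalty_advanced: float = 0.875
    #: major bleed, minor bleed, mucosal burn, perforation (per procedure)
    complication_p: tuple = (4e-4, 11e-4, 3e-4, 7e-4)
    polypectomy_multiplier: float = 2.0
    #: case fatality per complication type (perforation only by default)
    complication_fatality: tuple = (0.0, 0.0, 0.0, 0.05)

    def __post_init__(self) -> None:
        probs = (self.cecal_intubation, *self.detection_by_stage,
                 self.detection_cancer, *self.complication_p,
                 *self.complication_fatality)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")

    def reach_distribution(self) -> np.ndarray:
        """Probability of the deepest segment reached by a colonoscopy."""
        w = np.zeros(N_SEGMENTS)
        w[CECUM_SEGMENT - 1] = self.cecal_intubation
        # incomplete exams turn around in the proximal colon
        w[7:12] = (1.0 - self.cecal_intubation) / 5.0
        return w

    def sig_reach_distribution(self) -> np.ndarray:
        """Deepest segment of a rectosigmoidoscopy (mean 6 of 13 segments)."""
        w = np.zeros(N_SEGMENTS)
        w[4], w[5], w[6] = 0.15, 0.70, 0.15
        return w

    def flexure_multipliers(self) -> np.ndarray:
        m = np.ones(N_SEGMENTS)
        for s in FLEXURE_SEGMENTS:
            m[s - 1] = self.flexure_penalty
        return m

    def detection(self, lesion, sigmoidoscopy: bool = False) -> float:
        if lesion.kind == CANCER:
            d = self.detection_cancer
            pen = self.sig_penalty_advanced
        else:
            d = self.detection_by_stage[lesion.adenoma_stage - 1]
            pen = (self.sig_penalty_early if lesion.adenoma_stage <= 4
                   else self.sig_penalty_advanced)
        if lesion.segment in FLEXURE_SEGMENTS:
            d *= self.flexure_penalty
        if sigmoidoscopy:
            d *= pen
        return d


@dataclass
class StoolTestModel:
    """Generic stool test with per-lesion-class sensitivity."""

    sensitivity_early: float = 0.02
    sensitivity_advanced: float = 0.12
    sensitivity_cancer: float = 0.40
    specificity: float = 0.98

    def __post_init__(self) -> None:
        for p in (self.sensitivity_early, self.sensitivity_advanced,
                  self.sensitivity_cancer, self.specificity):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SurveillanceRules:
    """Guideline follow-up intervals after a positive colonoscopy."""

    advanced_or_multiple_y: int = 3     # advanced adenoma or >=3 adenomas
    small_y: int = 5                    # 1-2 small adenomas
    post_crc_y: int = 1


@dataclass
class Findings:
    n_small: int = 0
    n_advanced: int = 0
    n_cancers: int = 0
    cancer_stages: list = field(default_factory=list)
    referral: bool = False
    polypectomy: bool = False
    complications: list = field(default_factory=list)
    fatal_complication: bool = False

    @property
    def any(self) -> bool:
        return self.n_small + self.n_advanced + self.n_cancers > 0


@dataclass
class ScreeningPlan:
    """A screening schedule: modality, ages, interval, adherence."""

    modality: str = "none"   # none|colonoscopy|sigmoidoscopy|fobt|perfect
    start_age: int = 50
    stop_age: int = 75
    interval_y: int = 10
    adherence: float = 1.0
    followup_adherence: float = 1.0
    surveillance: bool = True
    surveillance_adherence: float = 1.0
    surveillance_stop_age: int = 85
    rules: SurveillanceRules = field(default_factory=SurveillanceRules)
    screen_ages: tuple | None = None          # explicit ages, overrides interval
    enroll_age_range: tuple | None = None     # (lo, hi): per-individual enrollment
    screen_offsets_y: tuple = (0,)            # offsets from enrollment (years)
    second_screen_fraction: float = 1.0       # applies to offsets after the first
    followup_window_y: float = 0.0            # tally window after enrollment

    _MODES = {"none": K.MODE_NONE, "colonoscopy": K.MODE_COLO,
              "sigmoidoscopy": K.MODE_SIG, "fobt": K.MODE_FOBT,
              "perfect": K.MODE_PERFECT}

    def __post_init__(self) -> None:
        if self.modality not in self._MODES:
            raise ValueError(f"unknown modality: {self.modality!r}")
        if self.modality != "none" and self.enroll_age_range is None:
            if not self.start_age < self.stop_age:
                raise ValueError("start age must precede stop age")
            if self.interval_y < 1:
                raise ValueError("screening interval must be >= 1 year")
        for a in (self.adherence, self.followup_adherence,
                  self.surveillance_adherence, self.second_screen_fraction):
            if not 0.0 <= a <= 1.0:
                raise ValueError("adherence must lie in [0, 1]")

    @classmethod
    def none(cls) -> "ScreeningPlan":
        return cls(modality="none")

    def label(self) -> str:
        if self.modality == "none":
            return "no-screening"
        if self.enroll_age_range is not None:
            return (f"{self.modality}@enroll{self.enroll_age_range}"
                    f"+{self.screen_offsets_y}y")
        ages = self.screen_quarters()
        return f"{self.modality}@{[q // 4 for q in ages]}"

    def screen_quarters(self) -> list[int]:
        """Absolute screening quarters (or offsets when enrollment is drawn)."""
        if self.modality == "none":
            return []
        if self.enroll_age_range is not None:
            return [int(4 * y) for y in self.screen_offsets_y]
        if self.screen_ages is not None:
            return [int(4 * a) for a in self.screen_ages]
        return [4 * a for a in
                range(self.start_age, self.stop_age + 1, self.interval_y)]

    def build_pack(self, endoscopy: EndoscopyModel, stool: StoolTestModel):
        enroll = self.enroll_age_range is not None
        lo, hi = self.enroll_age_range if enroll else (0, 0)
        return (
            self._MODES[self.modality],
            np.asarray(self.screen_quarters(), dtype=np.int64),
            1 if enroll else 0, int(4 * lo), int(4 * hi),
            int(round(4 * self.followup_window_y)) if self.followup_window_y else -1,
            float(self.adherence), float(self.followup_adherence),
            float(self.second_screen_fraction),
            np.cumsum(endoscopy.reach_distribution()),
            np.cumsum(endoscopy.sig_reach_distribution()),
            np.asarray(list(endoscopy.detection_by_stage)
                       + [endoscopy.detection_cancer]),
            endoscopy.flexure_multipliers(),
            np.asarray([endoscopy.sig_penalty_early,
                        endoscopy.sig_penalty_advanced]),
            np.asarray(endoscopy.complication_p),
            float(endoscopy.polypectomy_multiplier),
            np.asarray(endoscopy.complication_fatality),
            np.asarray([stool.sensitivity_early, stool.sensitivity_advanced,
                        stool.sensitivity_cancer]),
            float(stool.specificity),
            4 * self.rules.advanced_or_multiple_y, 4 * self.rules.small_y,
            4 * self.rules.post_crc_y,
            1 if self.surveillance else 0,
            float(self.surveillance_adherence),
            4 * int(self.surveillance_stop_age),
        )


# ---------------------------------------------------------------------------
# reference operations (plain Python, mirror the kernel)
# ---------------------------------------------------------------------------

def _draw_reach(cdf: np.ndarray, rng: np.random.Generator) -> int:
    return int(np.searchsorted(cdf, rng.random())) + 1


def perform_colonoscopy(ind: Individual, model: EndoscopyModel,
                        rng: np.random.Generator, context: str = "screening",
                        rules: SurveillanceRules | None = None) -> Findings:
    """Colonoscopy with polypectomy: detect, resect, complicate.

    Detected adenomas are removed; a detected cancer starts curative
    treatment.  Complication probabilities double after polypectomy.
    Returns the findings; the individual is mutated in place.
    """
    if not ind.alive:
        raise ValueError("individual is dead")
    reach = _draw_reach(np.cumsum(model.reach_distribution()), rng)
    f = Findings()
    for les in ind.lesions:
        if les.removed or les.kind not in (ADENOMA, CANCER):
            continue
        forced = les.kind == CANCER and les.symptomatic
        if les.segment > reach and not forced:
            continue
        d = 1.0 if forced else model.detection(les)
        if rng.random() >= d:
            continue
        if les.kind == ADENOMA:
            les.removed = True
            ind.counters["resected"] += 1
            f.polypectomy = True
            if les.adenoma_stage >= 5:
                f.n_advanced += 1
            else:
                f.n_small += 1
        else:
            les.removed = True
            f.n_cancers += 1
            f.cancer_stages.append(les.cancer_stage)
    if f.n_cancers:
        ind.diagnosis_stage = max(f.cancer_stages)
    mult = model.polypectomy_multiplier if f.polypectomy else 1.0
    for t, p in enumerate(model.complication_p):
        if rng.random() < p * mult:
            f.complications.append(t)
            if rng.random() < model.complication_fatality[t]:
                f.fatal_complication = True
                ind.alive = False
                ind.cause_of_death = "complication"
    return f


def perform_sigmoidoscopy(ind: Individual, model: EndoscopyModel,
                          rng: np.random.Generator) -> Findings:
    """Rectosigmoidoscopy: distal detection only, no resection.

    Any finding sets the referral flag (triggering a colonoscopy).
    """
    if not ind.alive:
        raise ValueError("individual is dead")
    reach = _draw_reach(np.cumsum(model.sig_reach_distribution()), rng)
    f = Findings()
    for les in ind.lesions:
        if les.removed or les.segment > reach:
            continue
        if rng.random() < model.detection(les, sigmoidoscopy=True):
            if les.kind == CANCER:
                f.n_cancers += 1
            elif les.adenoma_stage >= 5:
                f.n_advanced += 1
            else:
                f.n_small += 1
    f.referral = f.any
    for t, p in enumerate(model.complication_p):
        if rng.random() < p * SIG_COMPLICATION_FACTOR:
            f.complications.append(t)
            if rng.random() < model.complication_fatality[t]:
                f.fatal_complication = True
                ind.alive = False
                ind.cause_of_death = "complication"
    return f


def perform_stool_test(ind: Individual, model: StoolTestModel,
                       rng: np.random.Generator) -> tuple[bool, bool]:
    """Stool test; returns (positive, referral)."""
    if not ind.alive:
        raise ValueError("individual is dead")
    positive = False
    has_lesion = False
    for les in ind.lesions:
        if les.removed:
            continue
        has_lesion = True
        if les.kind == CANCER:
            s = model.sensitivity_cancer
        elif les.adenoma_stage >= 5:
            s = model.sensitivity_advanced
        else:
            s = model.sensitivity_early
        if rng.random() < s:
            positive = True
    if not has_lesion and rng.random() < 1.0 - model.specificity:
        positive = True
    return positive, positive


def schedule_surveillance(findings: Findings,
                          rules: SurveillanceRules | None = None) -> int | None:
    """Years until the next surveillance colonoscopy, or None (back to screening)."""
    rules = rules or SurveillanceRules()
    if findings.n_cancers > 0:
        return rules.post_crc_y
    if findings.n_advanced > 0 or findings.n_advanced + findings.n_small >= 3:
        return rules.advanced_or_multiple_y
    if findings.n_small > 0:
        return rules.small_y
    if not findings.any:
        return None
    raise ValueError("unknown finding class")
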