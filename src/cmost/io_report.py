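"""Run manifests, result persistence (CSV/JSON) and benchmark plots."""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import ScenarioResult, _TALLY_NAMES

MANIFEST_NAME = "manifest.json"
TALLIES_NAME = "tallies.json"
BY_AGE_NAME = "by_age.csv"


@dataclass(frozen=True)
class RunManifest:
    params_digest: str
    seed: int
    n: int
    scenario: str
    code_version: str
    timestamp: str

    def as_dict(self) -> dict:
        return dict(params_digest=self.params_digest, seed=self.seed,
                    n=self.n, scenario=self.scenario,
                    code_version=self.code_version, timestamp=self.timestamp)

    @classmethod
    def create(cls, result: ScenarioResult, params_digest: str = "") -> "RunManifest":
        from . import __version__
        return cls(params_digest=params_digest, seed=result.seed, n=result.n,
                   scenario=result.plan_label, code_version=__version__,
                   timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))


def write_outputs(result: ScenarioResult, out_dir,
                  params_digest: str = "") -> Path:
    """Write manifest + tallies (JSON) + per-age summary (CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest.create(result, params_digest)
    (out / MANIFEST_NAME).write_text(json.dumps(manifest.as_dict(), indent=2))
    tallies = {k: np.asarray(v).tolist() for k, v in result.tallies.items()}
    payload = {"n": result.n, "seed": result.seed,
               "plan_label": result.plan_label, "tallies": tallies}
    (out / TALLIES_NAME).write_text(json.dumps(payload))
    ages = np.arange(101)
    df = pd.DataFrame({
        "age": ages,
        "alive": result.alive_at_age.sum(axis=0),
        "person_years": result.py.sum(axis=0),
        "early_adenoma_prev": _safe_div(result.ge1_early.sum(axis=0),
                                        result.alive_at_age.sum(axis=0)),
        "advanced_adenoma_prev": _safe_div(result.ge1_adv.sum(axis=0),
                                           result.alive_at_age.sum(axis=0)),
        "crc_incidence_per_100k": _safe_div(1e5 * result.inc.sum(axis=0),
                                            result.py.sum(axis=0)),
        "crc_mortality_per_100k": _safe_div(1e5 * result.crc_death.sum(axis=0),
                                            result.py.sum(axis=0)),
        "colonoscopies": result.procedures[:, 0, :].sum(axis=1),
        "cost": result.costs_year.sum(axis=1),
    })
    df.to_csv(out / BY_AGE_NAME, index=False)
    # aggregate procedure log: counts by age x type x context
    ptypes = ("colonoscopy", "sigmoidoscopy", "stool_test")
    ctxs = ("screening", "surveillance", "diagnostic", "followup")
    rows = [(a, t, c, result.procedures[a, ti, ci])
            for a in range(101)
            for ti, t in enumerate(ptypes)
            for ci, c in enumerate(ctxs)
            if result.procedures[a, ti, ci] > 0]
    pd.DataFrame(rows, columns=["age", "procedure", "context", "count"]) \
        .to_csv(out / "procedures.csv", index=False)
    return out


def plot_by_age(result: ScenarioResult, path) -> None:
    """Prevalence, incidence and mortality curves for one run."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ages = np.arange(101)
    alive = result.alive_at_age.sum(axis=0)
    py = result.py.sum(axis=0)
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    axes[0].plot(ages, _safe_div(result.ge1_early.sum(axis=0), alive), "k-")
    axes[0].set_title("early adenoma prevalence")
    axes[1].plot(ages, _safe_div(result.ge1_adv.sum(axis=0), alive), "k-")
    axes[1].set_title("advanced adenoma prevalence")
    axes[2].plot(ages, _safe_div(1e5 * result.inc.sum(axis=0), py), "k-",
                 label="incidence")
    axes[2].plot(ages, _safe_div(1e5 * result.crc_death.sum(axis=0), py),
                 "k--", label="mortality")
    axes[2].set_title("CRC per 100,000")
    axes[2].legend(frameon=False, fontsize=8)
    for ax in axes:
        ax.set_xlabel("age")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _safe_div(a, b):
    b = np.asarray(b, dtype=float)
    return np.where(b > 0, np.asarray(a, dtype=float) / np.maximum(b, 1e-300), 0.0)


def read_outputs(out_dir) -> ScenarioResult:
    """Round-trip inverse of :func:`write_outputs` (tallies only)."""
    out = Path(out_dir)
    f = out / TALLIES_NAME
    if not f.exists():
        raise FileNotFoundError(f"no tallies in {out_dir}")
    payload = json.loads(f.read_text())
    missing = set(_TALLY_NAMES) - set(payload.get("tallies", {}))
    if missing:
        raise ValueError(f"corrupt output directory, missing tallies: {missing}")
    tallies = {k: np.asarray(v, dtype=float) for k, v in payload["tallies"].items()}
    return ScenarioResult(n=payload["n"], seed=payload["seed"],
                          plan_label=payload["plan_label"], tallies=tallies)


def read_manifest(out_dir) -> RunManifest:
    d = json.loads((Path(out_dir) / MANIFEST_NAME).read_text())
    return RunManifest(**d)


def plot_benchmark_comparison(calibration_result, path) -> None:
    """Targets vs predictions; green squares within 20%, red outside."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = calibration_result.table
    panels = [("early_prev", "Early adenoma prevalence"),
              ("adv_prev", "Advanced adenoma prevalence"),
              ("crc_inc", "CRC incidence /100k")]
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, (cat, title) in zip(axes, panels):
        sub = df[(df.category == cat) & (df.sex == "A")]
        ax.plot(sub.age_lo, sub.target, "ks--", mfc="none", label="benchmark")
        ok = sub[sub.within_20pct]
        bad = sub[~sub.within_20pct]
        ax.plot(sub.age_lo, sub.predicted, "k-", lw=1)
        ax.plot(ok.age_lo, ok.predicted, "gs", label="within 20%")
        if len(bad):
            ax.plot(bad.age_lo, bad.predicted, "rs", label="outside 20%")
        ax.set_title(title)
        ax.set_xlabel("age")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
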