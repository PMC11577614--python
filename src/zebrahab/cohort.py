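"""Synthetic cohorts of virtual larvae for end-to-end pipeline testing.

No behavioural data are bundled with the package; instead this module
generates control, low-impact and high-impact cohorts across the six
assay timepoints (pre-injury baseline, 5 min, 1 h, 2 h, 24 h, 48 h) with
the statistical structure the analysis assumes:

* per-larva escape distances over the 30-stimulus habituation train follow
  the rectified habituation-fatigue model output (scaled to millimetres)
  plus zero-truncated Gaussian noise;
* pre-habituation and sub-threshold responses are Bernoulli at
  supra-threshold (~85%) and sub-threshold (~20%) probabilities;
* a small fraction of non-responders is injected;
* per-timepoint attrition thins the injured groups.

Each group's per-timepoint mean gains encode the observed phenotypes:
controls habituate normally throughout (decay constant 1.3 stimuli);
low-impact larvae show impaired habituation (decay constant 4) for the
first hours and recover by 24 h; high-impact larvae combine impaired
habituation with pronounced fatigue, the fatigue persisting at 24 h and
easing (with the decay constant recovering) by 48 h.  True generating
parameters are stored separately from observables for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .assay import StimulusSchedule, build_schedule
from .model import ModelGains, combined_response

__all__ = [
    "TIMEPOINTS",
    "GroupEffectProfile",
    "CohortDataset",
    "default_profiles",
    "load_profiles",
    "save_profiles",
    "generate_cohort",
    "emit_tracking_files",
]

TIMEPOINTS = ("pre", "5min", "1h", "2h", "24h", "48h")

_GAIN_BOUNDS = {
    "h1": (1e-6, np.inf),
    "h2": (0.0, np.inf),
    "h3": (0.0, None),  # upper bound is h1, applied after drawing h1
    "f1": (0.0, np.inf),
    "f2": (0.0, np.inf),
    "f3": (1e-6, 1.0),
}


@dataclass
class GroupEffectProfile:
    """Generating distribution for one experimental group.

    ``gains_by_timepoint`` holds the mean gains at each timepoint;
    per-larva true gains are drawn from normals truncated to the gain
    validity bounds with coefficient of variation ``gain_cv``.  The
    no-fatigue configuration (0, 0, 1) is kept exact (no jitter), so
    control larvae never acquire spurious fatigue.
    """

    name: str
    n_baseline: int
    gains_by_timepoint: Dict[str, ModelGains]
    attrition: Dict[str, float]  # per-timepoint hazard of death before tp
    p_supra: float = 0.85
    p_sub: float = 0.20
    non_responder_fraction: float = 0.05
    non_responder_p_supra: float = 0.20
    gain_cv: float = 0.10
    sigma_mm: float = 3.0
    scale_mm: float = 30.0
    spontaneous_mean_mm: float = 110.0
    spontaneous_sd_mm: float = 25.0

    def __post_init__(self):
        for p in (self.p_supra, self.p_sub, self.non_responder_fraction,
                  self.non_responder_p_supra):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.gain_cv < 0 or self.sigma_mm < 0:
            raise ValueError("dispersions must be non-negative")
        for tp, h in self.attrition.items():
            if not 0 <= h <= 1:
                raise ValueError(f"attrition hazard out of [0, 1] at {tp}: {h}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gains_by_timepoint"] = {
            tp: g.to_dict() if isinstance(g, ModelGains) else g
            for tp, g in self.gains_by_timepoint.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroupEffectProfile":
        d = dict(d)
        d["gains_by_timepoint"] = {
            tp: ModelGains(**g) if not isinstance(g, ModelGains) else g
            for tp, g in d["gains_by_timepoint"].items()
        }
        return cls(**d)


def default_profiles() -> List[GroupEffectProfile]:
    """The three bundled group profiles (control / low- / high-impact).

    Baseline sizes are 136/70/69 and per-timepoint attrition hazards are
    chosen so the expected surviving counts follow the canonical
    longitudinal pattern (e.g. high-impact 69 -> 61 -> 60 -> 60 -> 46 -> 39).
    """
    normal = ModelGains.normal_habituation()
    impaired = ModelGains.impaired_habituation()
    imp_fat = ModelGains.impaired_with_fatigue()
    residual_fat = ModelGains(h1=1.0, h2=1.0 / 1.3, h3=0.2, f1=0.3, f2=0.8, f3=0.6)

    control = GroupEffectProfile(
        name="control",
        n_baseline=136,
        gains_by_timepoint={tp: normal for tp in TIMEPOINTS},
        attrition={"pre": 0.0, "5min": 0.0, "1h": 0.0,
                   "2h": 2 / 136, "24h": 2 / 134, "48h": 4 / 132},
    )
    low = GroupEffectProfile(
        name="low_impact",
        n_baseline=70,
        gains_by_timepoint={
            "pre": normal, "5min": impaired, "1h": impaired, "2h": impaired,
            "24h": normal, "48h": normal,
        },
        attrition={"pre": 0.0, "5min": 0.0, "1h": 0.0,
                   "2h": 4 / 70, "24h": 2 / 66, "48h": 5 / 64},
    )
    high = GroupEffectProfile(
        name="high_impact",
        n_baseline=69,
        gains_by_timepoint={
            "pre": normal, "5min": imp_fat, "1h": imp_fat, "2h": imp_fat,
            "24h": imp_fat, "48h": residual_fat,
        },
        attrition={"pre": 0.0, "5min": 8 / 69, "1h": 1 / 61,
                   "2h": 0.0, "24h": 14 / 60, "48h": 7 / 46},
    )
    return [control, low, high]


def save_profiles(profiles: Sequence[GroupEffectProfile], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"groups": [p.to_dict() for p in profiles]}, fh,
                       sort_keys=False)


def load_profiles(path) -> List[GroupEffectProfile]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [GroupEffectProfile.from_dict(d) for d in doc["groups"]]


@dataclass
class CohortDataset:
    """A generated cohort: observables plus the hidden generating truth.

    ``observations`` is the tidy response table (larva_id, group,
    timepoint, phase, stimulus_index, distance_mm, responded);
    ``truth`` holds each larva's true per-timepoint gains; ``survival``
    the per-timepoint alive flags; ``spontaneous`` the per-break activity
    totals.  Truths never leak into the observable tables.
    """

    observations: pd.DataFrame
    truth: pd.DataFrame
    survival: pd.DataFrame
    spontaneous: pd.DataFrame
    profiles: List[GroupEffectProfile]
    seed: int
    timepoints: tuple = TIMEPOINTS

    def n_alive(self, group: str, timepoint: str) -> int:
        s = self.survival
        m = (s["group"] == group) & (s["timepoint"] == timepoint) & s["alive"]
        return int(m.sum())

    def group_of(self, larva_id: str) -> str:
        return larva_id.rsplit("-", 1)[0]


def _draw_gain(rng, mean: float, cv: float, lo: float, hi: float) -> float:
    if cv == 0 or mean == 0:
        return float(np.clip(mean, lo, hi))
    sd = cv * abs(mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _draw_larva_gains(rng, mean: ModelGains, cv: float) -> ModelGains:
    h1 = _draw_gain(rng, mean.h1, cv, *(_GAIN_BOUNDS["h1"]))
    h2 = _draw_gain(rng, mean.h2, cv, 0.0, np.inf)
    h3 = _draw_gain(rng, mean.h3, cv, 0.0, h1)
    if mean.fatigue_absent:
        f1, f2, f3 = 0.0, 0.0, 1.0  # keep the no-fatigue identity exact
    else:
        f1 = _draw_gain(rng, mean.f1, cv, 0.0, np.inf)
        f2 = _draw_gain(rng, mean.f2, cv, 0.0, np.inf)
        f3 = _draw_gain(rng, mean.f3, cv, 1e-6, 1.0)
    return ModelGains(h1=h1, h2=h2, h3=h3, f1=f1, f2=f2, f3=f3)


def generate_cohort(
    profiles: Optional[Sequence[GroupEffectProfile]] = None,
    seed: int = 0,
    n_per_group: Optional[Dict[str, int]] = None,
) -> CohortDataset:
    """Draw a full virtual cohort; reproducible given ``seed``.

    ``n_per_group`` overrides each profile's baseline size (useful for
    small test cohorts).
    """
    if profiles is None:
        profiles = default_profiles()
    rng = np.random.default_rng(seed)

    obs_rows, truth_rows, surv_rows, spont_rows = [], [], [], []
    n_hab = 30
    n_phase10 = 10
    hab_n = np.arange(1, n_hab + 1)

    for prof in profiles:
        n = prof.n_baseline if n_per_group is None else n_per_group[prof.name]
        for i in range(n):
            lid = f"{prof.name}-{i:03d}"
            non_resp = rng.random() < prof.non_responder_fraction
            alive = True
            for tp in TIMEPOINTS:
                if alive and rng.random() < prof.attrition.get(tp, 0.0):
                    alive = False
                surv_rows.append(
                    {"larva_id": lid, "group": prof.name, "timepoint": tp,
                     "alive": alive}
                )
                if not alive:
                    continue
                gains = _draw_larva_gains(
                    rng, prof.gains_by_timepoint[tp], prof.gain_cv
                )
                truth_rows.append(
                    {"larva_id": lid, "group": prof.name, "timepoint": tp,
                     "is_non_responder": non_resp, **gains.to_dict()}
                )
                s1 = float(combined_response(1, gains, rectify=True))
                # sub-threshold and pre-habituation phases: Bernoulli responses
                p_supra = (prof.non_responder_p_supra if non_resp
                           else prof.p_supra)
                for phase, p_resp in (("subthreshold", prof.p_sub),
                                      ("prehabituation", p_supra)):
                    hits = rng.random(n_phase10) < p_resp
                    dists = np.where(
                        hits,
                        np.maximum(
                            0.0,
                            prof.scale_mm * s1
                            + rng.normal(0.0, max(prof.sigma_mm, 1e-12),
                                         n_phase10),
                        ),
                        0.0,
                    )
                    for si in range(n_phase10):
                        obs_rows.append(
                            {"larva_id": lid, "group": prof.name,
                             "timepoint": tp, "phase": phase,
                             "stimulus_index": si + 1,
                             "distance_mm": float(dists[si]),
                             "responded": bool(hits[si] and dists[si] > 0)}
                        )
                # habituation phase: model trace + truncated Gaussian noise
                clean = prof.scale_mm * combined_response(
                    hab_n, gains, rectify=True
                )
                noise = (rng.normal(0.0, prof.sigma_mm, n_hab)
                         if prof.sigma_mm > 0 else np.zeros(n_hab))
                dists = np.maximum(0.0, clean + noise)
                for si in range(n_hab):
                    obs_rows.append(
                        {"larva_id": lid, "group": prof.name,
                         "timepoint": tp, "phase": "habituation",
                         "stimulus_index": si + 1,
                         "distance_mm": float(dists[si]),
                         "responded": bool(dists[si] > 0)}
                    )
                spont = max(0.0, rng.normal(prof.spontaneous_mean_mm,
                                            prof.spontaneous_sd_mm))
                spont_rows.append(
                    {"larva_id": lid, "group": prof.name, "timepoint": tp,
                     "spontaneous_mm": spont}
                )

    return CohortDataset(
        observations=pd.DataFrame(obs_rows),
        truth=pd.DataFrame(truth_rows),
        survival=pd.DataFrame(surv_rows),
        spontaneous=pd.DataFrame(spont_rows),
        profiles=list(profiles),
        seed=seed,
    )


def emit_tracking_files(
    dataset: CohortDataset,
    out_dir,
    schedule: Optional[StimulusSchedule] = None,
) -> dict:
    """Write per-timepoint ZebraLab-style tracking CSVs plus metadata.

    Each file holds contiguous 1-s bins spanning the whole assay for every
    larva alive at that timepoint.  Escape distances land in the >20 mm/s
    category of the stimulus bin; spontaneous activity is spread uniformly
    over the break bins in the 2-20 mm/s category, so the per-break totals
    round-trip exactly through the assay readers.

    Returns a manifest dict mapping timepoint to file path.
    """
    schedule = schedule or build_schedule()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_bins = int(np.ceil(schedule.total_duration_s)) if len(schedule) else 0
    onset_bins = {}
    for ev in schedule.events:
        onset_bins[(ev.phase, ev.index_in_phase)] = int(ev.onset_s)

    break_bins = []
    for (b0, b1) in schedule.break_windows:
        break_bins.extend(range(int(b0), int(b1)))
    n_break_bins = len(break_bins)

    manifest = {"files": {}, "seed": dataset.seed,
                "groups": [p.name for p in dataset.profiles],
                "scale_mm": {p.name: p.scale_mm for p in dataset.profiles}}
    obs = dataset.observations
    spont = dataset.spontaneous.set_index(["larva_id", "timepoint"]) \
        if not dataset.spontaneous.empty else None

    for tp in dataset.timepoints:
        rows = []
        tp_obs = obs[obs["timepoint"] == tp] if not obs.empty else obs
        larvae = sorted(tp_obs["larva_id"].unique()) if len(tp_obs) else []
        for lid in larvae:
            large = np.zeros(n_bins)
            mid = np.zeros(n_bins)
            small = np.zeros(n_bins)
            sub = tp_obs[tp_obs["larva_id"] == lid]
            for _, r in sub.iterrows():
                b = onset_bins.get((r["phase"], r["stimulus_index"]))
                if b is not None and r["distance_mm"] > 0:
                    large[b] = r["distance_mm"]
            if spont is not None and (lid, tp) in spont.index:
                total = float(spont.loc[(lid, tp), "spontaneous_mm"])
                if n_break_bins:
                    mid[break_bins] = total / n_break_bins
            rows.append(pd.DataFrame({
                "larva_id": lid,
                "bin_start_s": np.arange(n_bins, dtype=float),
                "dist_small_mm": small,
                "dist_mid_mm": mid,
                "dist_large_mm": large,
            }))
        path = out_dir / f"tracking_{tp}.csv"
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(path, index=False)
        else:
            pd.DataFrame(columns=["larva_id", "bin_start_s", "dist_small_mm",
                                  "dist_mid_mm", "dist_large_mm"]
                         ).to_csv(path, index=False)
        manifest["files"][tp] = str(path)

    meta_path = out_dir / "metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(
            {"seed": dataset.seed,
             "profiles": [p.to_dict() for p in dataset.profiles]},
            fh, indent=2,
        )
    manifest["metadata"] = str(meta_path)
    return manifest
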