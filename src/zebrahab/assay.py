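"""The three-phase acoustic assay: schedule, escape criterion, responsiveness.

The behavioural protocol delivers 50 identical vibratory pulses (0.5 s,
300 Hz) in three phases: 10 sub-threshold stimuli (20 dB) at 60 s ISI to
probe acoustic sensitivity, 10 supra-threshold stimuli (108 dB) at 60 s
ISI to measure baseline responsiveness ("pre-habituation"), and 30
supra-threshold stimuli at 1 s ISI that evoke short-term habituation.
Phases are separated by 5-min breaks during which spontaneous activity is
recorded.

Tracking is binned at 1 s into three speed categories (<2, 2-20 and
>20 mm/s).  An escape response is movement above 20 mm/s during a
stimulus; larvae responding to fewer than 40% of the pre-habituation
stimuli are non-responders and are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "PhaseSpec",
    "ScheduleConfig",
    "StimulusEvent",
    "StimulusSchedule",
    "TrackingRecord",
    "build_schedule",
    "classify_escape",
    "auc_responsiveness",
    "non_responder_filter",
    "spontaneous_activity",
    "read_tracking_csv",
    "responses_from_tracking",
    "ESCAPE_SPEED_MM_S",
    "NON_RESPONDER_THRESHOLD",
]

ESCAPE_SPEED_MM_S = 20.0
NON_RESPONDER_THRESHOLD = 0.40

PHASES = ("subthreshold", "prehabituation", "habituation")


@dataclass(frozen=True)
class PhaseSpec:
    name: str
    n_stimuli: int
    isi_s: float
    intensity_db: float

    def __post_init__(self):
        if self.n_stimuli < 0:
            raise ValueError("n_stimuli must be >= 0")
        if self.isi_s <= 0:
            raise ValueError("isi must be positive")


@dataclass(frozen=True)
class ScheduleConfig:
    """Protocol configuration; the defaults are the standard assay."""

    phases: tuple = (
        PhaseSpec("subthreshold", 10, 60.0, 20.0),
        PhaseSpec("prehabituation", 10, 60.0, 108.0),
        PhaseSpec("habituation", 30, 1.0, 108.0),
    )
    pulse_duration_s: float = 0.5
    frequency_hz: float = 300.0
    break_s: float = 300.0

    def __post_init__(self):
        if self.pulse_duration_s <= 0:
            raise ValueError("pulse duration must be positive")
        if self.break_s < 0:
            raise ValueError("break must be non-negative")


@dataclass(frozen=True)
class StimulusEvent:
    phase: str
    index_in_phase: int  # 1-based
    onset_s: float
    duration_s: float
    frequency_hz: float
    intensity_db: float


@dataclass
class StimulusSchedule:
    """Deterministic, timed list of every stimulus in the assay."""

    events: list
    config: ScheduleConfig = field(default_factory=ScheduleConfig)
    break_windows: list = field(default_factory=list)  # [(start_s, end_s), ...]

    def __len__(self) -> int:
        return len(self.events)

    def phase_events(self, phase: str) -> list:
        return [e for e in self.events if e.phase == phase]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "phase": e.phase,
                    "index_in_phase": e.index_in_phase,
                    "onset_s": e.onset_s,
                    "duration_s": e.duration_s,
                    "frequency_hz": e.frequency_hz,
                    "intensity_db": e.intensity_db,
                }
                for e in self.events
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def total_duration_s(self) -> float:
        if not self.events:
            return 0.0
        last = self.events[-1]
        return last.onset_s + last.duration_s


def build_schedule(config: Optional[ScheduleConfig] = None) -> StimulusSchedule:
    """Lay out stimulus onsets phase by phase.

    Within a phase, onsets are spaced at the phase ISI; after each phase a
    break of ``break_s`` starts one ISI after the last onset (once the slot
    of the final stimulus has elapsed).
    """
    config = config or ScheduleConfig()
    events: list = []
    breaks: list = []
    cursor = 0.0
    for pi, phase in enumerate(config.phases):
        for i in range(phase.n_stimuli):
            events.append(
                StimulusEvent(
                    phase=phase.name,
                    index_in_phase=i + 1,
                    onset_s=cursor,
                    duration_s=config.pulse_duration_s,
                    frequency_hz=config.frequency_hz,
                    intensity_db=phase.intensity_db,
                )
            )
            cursor += phase.isi_s
        if pi < len(config.phases) - 1:
            breaks.append((cursor, cursor + config.break_s))
            cursor += config.break_s
    return StimulusSchedule(events=events, config=config, break_windows=breaks)


@dataclass
class TrackingRecord:
    """One larva's binned tracking output (ZebraLab-style).

    ``bins`` is a DataFrame with columns ``bin_start_s`` and per-category
    distances ``dist_small_mm`` (<2 mm/s), ``dist_mid_mm`` (2-20 mm/s) and
    ``dist_large_mm`` (>20 mm/s), one row per contiguous 1-s bin.
    """

    larva_id: str
    bins: pd.DataFrame
    bin_width_s: float = 1.0

    REQUIRED = ("bin_start_s", "dist_small_mm", "dist_mid_mm", "dist_large_mm")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.bins.columns]
        if missing:
            raise ValueError(f"tracking record missing columns {missing}")
        d = self.bins[list(self.REQUIRED[1:])].to_numpy()
        if np.any(d < 0):
            raise ValueError("tracked distances must be non-negative")
        starts = self.bins["bin_start_s"].to_numpy()
        if len(starts) > 1 and not np.allclose(np.diff(starts), self.bin_width_s):
            raise ValueError("tracking bins must be contiguous")
        self.bins = self.bins.reset_index(drop=True)

    def bin_at(self, t_s: float) -> Optional[pd.Series]:
        starts = self.bins["bin_start_s"].to_numpy()
        idx = np.searchsorted(starts, t_s + 1e-9, side="right") - 1
        if idx < 0 or idx >= len(starts):
            return None
        if not starts[idx] <= t_s < starts[idx] + self.bin_width_s:
            return None
        return self.bins.iloc[idx]


def classify_escape(record: TrackingRecord, event: StimulusEvent):
    """Escape-response decision for one stimulus.

    The larva responded iff the distance travelled in the >20 mm/s speed
    category within the stimulus's 1-s bin is positive; the escape
    distance is that category's distance.  Movement in the fast category
    outside stimulus bins is a swim bout, not an escape, and is never
    consulted here.  A missing bin yields ``(None, nan)`` — explicitly
    missing, not a zero.
    """
    row = record.bin_at(event.onset_s)
    if row is None:
        return None, float("nan")
    dist = float(row["dist_large_mm"])
    return dist > 0.0, dist


def auc_responsiveness(distances) -> float:
    """Trapezoidal area under escape distance vs stimulus index over a
    10-stimulus phase (baseline responsiveness / acoustic sensitivity)."""
    y = np.asarray(distances, dtype=float)
    if len(y) != 10:
        raise ValueError(f"responsiveness AUC expects 10 stimuli, got {len(y)}")
    return float(np.trapezoid(y, x=np.arange(1, 11)))


def non_responder_filter(responses: pd.DataFrame):
    """Drop larvae that responded to <40% of pre-habituation stimuli.

    Parameters
    ----------
    responses : DataFrame
        Tidy table with at least ``larva_id``, ``phase`` and ``responded``
        columns (one row per stimulus).

    Returns
    -------
    retained : DataFrame
        The input restricted to retained larvae.
    exclusion_log : DataFrame
        One row per excluded larva with its pre-habituation response rate.

    A rate of exactly 0.40 is retained (the rule is strictly "<40%").
    Larvae with no pre-habituation rows cannot be assessed and are kept.
    """
    if responses.empty:
        return responses.copy(), pd.DataFrame(
            columns=["larva_id", "prehab_response_rate"]
        )
    pre = responses[responses["phase"] == "prehabituation"]
    rates = pre.groupby("larva_id")["responded"].mean()
    excluded = rates[rates < NON_RESPONDER_THRESHOLD]
    log = pd.DataFrame(
        {"larva_id": excluded.index, "prehab_response_rate": excluded.to_numpy()}
    ).reset_index(drop=True)
    retained = responses[~responses["larva_id"].isin(excluded.index)].copy()
    return retained, log


def spontaneous_activity(
    record: TrackingRecord, break_windows: Iterable
) -> float:
    """Total distance moved (all three speed categories) over the breaks.

    ``break_windows`` are the two 300-s inter-phase windows; the result is
    the distance summed over the full 10 min.  If the record does not
    cover a window completely the result is NaN with a warning, since a
    partial sum would understate activity.
    """
    total = 0.0
    starts = record.bins["bin_start_s"].to_numpy()
    cat = record.bins[["dist_small_mm", "dist_mid_mm", "dist_large_mm"]].sum(axis=1)
    cat = cat.to_numpy()
    for w_start, w_end in break_windows:
        mask = (starts >= w_start - 1e-9) & (starts < w_end - 1e-9)
        n_expected = int(round((w_end - w_start) / record.bin_width_s))
        if mask.sum() < n_expected:
            warnings.warn(
                f"tracking record {record.larva_id!r} covers only "
                f"{int(mask.sum())}/{n_expected} bins of break "
                f"({w_start}, {w_end}); spontaneous activity is missing"
            )
            return float("nan")
        total += float(cat[mask].sum())
    return total


def read_tracking_csv(path) -> dict:
    """Read a ZebraLab-style long CSV into per-larva TrackingRecords.

    The file has columns larva_id, bin_start_s, dist_small_mm,
    dist_mid_mm, dist_large_mm; returns ``{larva_id: TrackingRecord}``.
    """
    df = pd.read_csv(path)
    out = {}
    for lid, sub in df.groupby("larva_id", sort=True):
        out[str(lid)] = TrackingRecord(
            larva_id=str(lid),
            bins=sub.drop(columns=["larva_id"]).sort_values("bin_start_s"),
        )
    return out


def responses_from_tracking(
    records: dict, schedule: StimulusSchedule
) -> pd.DataFrame:
    """Apply the escape criterion to every stimulus of every larva.

    Returns the tidy response table (larva_id, phase, stimulus_index,
    distance_mm, responded); missing bins yield responded=NA.
    """
    rows = []
    for lid in sorted(records):
        rec = records[lid]
        for ev in schedule.events:
            responded, dist = classify_escape(rec, ev)
            rows.append(
                {
                    "larva_id": lid,
                    "phase": ev.phase,
                    "stimulus_index": ev.index_in_phase,
                    "distance_mm": dist,
                    "responded": responded,
                }
            )
    return pd.DataFrame(rows)
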