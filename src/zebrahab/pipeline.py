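"""Reproducible generate -> metrics -> fit -> compare pipeline.

One global seed is fanned out to per-stage substreams by fixed integer
labels, so toggling one stage never perturbs another's draws.  Every run
writes versioned CSV outputs plus a ``manifest.json`` echoing the config
and recording a SHA-256 checksum of each output file; identical configs
produce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assay import (
    auc_responsiveness,
    build_schedule,
    non_responder_filter,
    read_tracking_csv,
    responses_from_tracking,
    spontaneous_activity,
)
from .cohort import default_profiles, emit_tracking_files, generate_cohort, load_profiles
from .decay import HabituationDecay
from .stats import compare_parameters

__all__ = ["RunConfig", "run_pipeline", "fit_cohort"]

_STAGE_LABELS = {"generate": 0}

COMPARED_PARAMETERS = (
    "amplitude", "decay_constant", "offset",
    "auc_prehab", "auc_sub", "spontaneous_mm",
)


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    seed: int
    out_dir: str
    profile: Optional[str] = None  # YAML path; None = bundled defaults
    n_per_group: Optional[Dict[str, int]] = None
    allow_negative_offset: bool = False
    alpha: float = 0.05
    apply_non_responder_filter: bool = True
    emit_tracking: bool = True
    control_group: str = "control"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([seed, _STAGE_LABELS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def fit_cohort(
    responses: pd.DataFrame, allow_negative_offset: bool = False
) -> pd.DataFrame:
    """Per-larva, per-timepoint single-exponential fits of the habituation
    phase plus AUC responsiveness metrics.

    ``responses`` is the tidy table with columns larva_id, group,
    timepoint, phase, stimulus_index, distance_mm (responded optional).
    """
    rows = []
    hab = responses[responses["phase"] == "habituation"]
    for (lid, tp), sub in hab.groupby(["larva_id", "timepoint"], sort=True):
        y = sub.sort_values("stimulus_index")["distance_mm"].to_numpy()
        res = HabituationDecay(
            y, allow_negative_offset=allow_negative_offset
        ).fit()
        row = {
            "larva_id": lid,
            "group": sub["group"].iloc[0] if "group" in sub else
            lid.rsplit("-", 1)[0],
            "timepoint": tp,
            "a": res.a, "b": res.b, "c": res.c,
            "amplitude": res.amplitude,
            "decay_constant": res.decay_constant,
            "offset": res.offset,
            "rss": res.rss,
            "converged": res.converged,
        }
        for phase, col in (("prehabituation", "auc_prehab"),
                           ("subthreshold", "auc_sub")):
            ph = responses[
                (responses["larva_id"] == lid)
                & (responses["timepoint"] == tp)
                & (responses["phase"] == phase)
            ]
            if len(ph) == 10:
                row[col] = auc_responsiveness(
                    ph.sort_values("stimulus_index")["distance_mm"].to_numpy()
                )
            else:
                row[col] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest.

    Any stage failure raises ``RuntimeError`` naming the stage; outputs of
    completed stages stay on disk for inspection.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "stage_seeds": {"generate": _stage_seed(config.seed, "generate")},
        "stages": [],
        "checksums": {},
    }
    outputs: Dict[str, Path] = {}
    schedule = build_schedule()

    stage = "generate"
    try:
        profiles = (load_profiles(config.profile) if config.profile
                    else default_profiles())
        dataset = generate_cohort(
            profiles,
            seed=manifest["stage_seeds"]["generate"],
            n_per_group=config.n_per_group,
        )
        manifest["stages"].append(stage)

        stage = "metrics"
        if config.emit_tracking:
            tracking_manifest = emit_tracking_files(
                dataset, out / "tracking", schedule
            )
            frames = []
            for tp, path in tracking_manifest["files"].items():
                records = read_tracking_csv(path)
                resp = responses_from_tracking(records, schedule)
                resp["timepoint"] = tp
                # spontaneous activity from the tracked break windows
                spont = {
                    lid: spontaneous_activity(rec, schedule.break_windows)
                    for lid, rec in records.items()
                }
                resp["spontaneous_mm"] = resp["larva_id"].map(spont)
                frames.append(resp)
            responses = (pd.concat(frames, ignore_index=True)
                         if frames else pd.DataFrame())
            manifest["tracking"] = tracking_manifest["files"]
        else:
            responses = dataset.observations.copy()
            responses = responses.merge(
                dataset.spontaneous[["larva_id", "timepoint",
                                     "spontaneous_mm"]],
                on=["larva_id", "timepoint"], how="left",
            )
        if "group" not in responses.columns and len(responses):
            responses["group"] = [
                lid.rsplit("-", 1)[0] for lid in responses["larva_id"]
            ]
        exclusions = pd.DataFrame(
            columns=["larva_id", "timepoint", "prehab_response_rate"])
        if config.apply_non_responder_filter and len(responses):
            kept, logs = [], []
            for tp, sub in responses.groupby("timepoint"):
                retained, log = non_responder_filter(sub)
                kept.append(retained)
                log["timepoint"] = tp
                logs.append(log)
            responses = pd.concat(kept, ignore_index=True)
            exclusions = pd.concat(logs, ignore_index=True)
        outputs["responses"] = out / "responses.csv"
        responses.to_csv(outputs["responses"], index=False)
        outputs["exclusions"] = out / "exclusions.csv"
        exclusions.to_csv(outputs["exclusions"], index=False)
        manifest["stages"].append(stage)

        stage = "fit"
        fit_table = fit_cohort(
            responses, allow_negative_offset=config.allow_negative_offset
        )
        if len(responses) and "spontaneous_mm" in responses.columns:
            spont = responses.groupby(["larva_id", "timepoint"])[
                "spontaneous_mm"].first().reset_index()
            fit_table = fit_table.merge(
                spont, on=["larva_id", "timepoint"], how="left")
        outputs["fit_table"] = out / "fit_table.csv"
        fit_table.to_csv(outputs["fit_table"], index=False)
        manifest["stages"].append(stage)

        stage = "compare"
        params = [p for p in COMPARED_PARAMETERS
                  if p in fit_table.columns]
        comparisons = (
            compare_parameters(fit_table, params,
                               control=config.control_group,
                               alpha=config.alpha)
            if len(fit_table) else pd.DataFrame()
        )
        outputs["comparisons"] = out / "comparisons.csv"
        comparisons.to_csv(outputs["comparisons"], index=False)
        manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for name, path in outputs.items():
        manifest["checksums"][name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
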