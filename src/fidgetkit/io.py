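"""CSV/JSON interchange and the end-to-end session pipeline.

Actigraphy travels as CSV with columns ``time_s,x,y,z`` (one file per
sensor site); trial events as CSV with columns
``trial_index,type,onset_ms,response,correct,rt_ms`` (rt empty for
omissions).  All times share one session clock starting at 0;
sample timestamps are in seconds, event times in milliseconds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from fidgetkit.analysis import split_trials
from fidgetkit.metrics import (
    aggregate_metrics,
    combine_sensor_tables,
    epoch_metrics,
)
from fidgetkit.signal import (
    AccelerometerRecording,
    FrequencyBand,
    band_reconstruct,
    differentiate,
)
from fidgetkit.task import TRIAL_TYPES, TrialEvent

logger = logging.getLogger("fidgetkit")

EVENT_COLUMNS = ["trial_index", "type", "onset_ms", "response", "correct", "rt_ms"]

_JITTER_TOL = 0.01  # warn when inter-sample intervals vary by more than 1%


@dataclass(frozen=True)
class SessionBundle:
    """Paths and resolved configuration for one session's pipeline run."""

    actigraphy_paths: dict[str, Path]  # sensor site -> CSV path
    events_path: Path
    out_dir: Path
    band: FrequencyBand = FrequencyBand()
    threshold: float = 0.0
    epoch: str = "stimulus_plus_iti"
    seed: int = 0

    def config(self) -> dict:
        return {
            "band_low_hz": self.band.low_hz,
            "band_high_hz": self.band.high_hz,
            "threshold": self.threshold,
            "epoch": self.epoch,
            "seed": self.seed,
        }


def write_actigraphy(recording: AccelerometerRecording, path: Path | str) -> None:
    times = recording.start_time_ms / 1000.0 + np.arange(recording.n_samples) / recording.sample_rate_hz
    df = pd.DataFrame(
        {
            "time_s": times,
            "x": recording.samples[:, 0],
            "y": recording.samples[:, 1],
            "z": recording.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_actigraphy(path: Path | str, sensor_site: str = "wrist") -> AccelerometerRecording:
    """Read a ``time_s,x,y,z`` CSV; the sample rate is inferred from the
    median inter-sample interval, warning if jitter exceeds 1%."""
    df = pd.read_csv(path)
    missing = {"time_s", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"actigraphy CSV missing columns {sorted(missing)}")
    if len(df) < 2:
        raise ValueError("actigraphy CSV needs at least 2 samples")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time_s must be strictly increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > _JITTER_TOL * step:
        logger.warning("sampling jitter above 1%% in %s", path)
    return AccelerometerRecording(
        sensor_site=sensor_site,
        sample_rate_hz=1.0 / step,
        samples=df[["x", "y", "z"]].to_numpy(dtype=float),
        start_time_ms=float(t[0]) * 1000.0,
    )


def write_events(events: list[TrialEvent], path: Path | str) -> None:
    rows = [
        {
            "trial_index": e.trial_index,
            "type": e.trial_type,
            "onset_ms": e.onset_ms,
            "response": e.response,
            "correct": e.correct,
            "rt_ms": "" if e.rt_ms is None else e.rt_ms,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path: Path | str) -> list[TrialEvent]:
    """Read and validate a trial-event CSV, sorted by onset."""
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events CSV missing columns {sorted(missing)}")
    events = []
    for row in df.itertuples(index=False):
        ttype = str(row.type).strip().lower()
        if ttype not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {row.type!r}")
        correct_raw = str(row.correct).strip().lower()
        if correct_raw not in {"true", "false", "0", "1"}:
            raise ValueError(f"malformed correctness value {row.correct!r}")
        correct = correct_raw in {"true", "1"}
        rt = None if pd.isna(row.rt_ms) or row.rt_ms == "" else float(row.rt_ms)
        response = str(row.response).strip().lower()
        if response == "none" and rt is not None:
            raise ValueError(
                f"trial {row.trial_index}: rt present with response 'none'"
            )
        events.append(
            TrialEvent(
                trial_index=int(row.trial_index),
                trial_type=ttype,
                onset_ms=float(row.onset_ms),
                response=response,
                correct=correct,
                rt_ms=rt,
            )
        )
    return sorted(events, key=lambda e: e.onset_ms)


def run_pipeline(bundle: SessionBundle) -> dict:
    """differentiate -> band_reconstruct -> detect peaks -> epoch ->
    combine sensors -> aggregate -> trial-grouped summaries.

    Writes a per-trial metrics CSV and a JSON report (with the resolved
    config embedded) into ``bundle.out_dir``; deterministic given config.
    """
    events = read_events(bundle.events_path)
    logger.info("pipeline: %d trials, band (%g, %g), threshold %g, epoch %s",
                len(events), bundle.band.low_hz, bundle.band.high_hz,
                bundle.threshold, bundle.epoch)
    tables = {}
    for site, path in sorted(bundle.actigraphy_paths.items()):
        recording = read_actigraphy(path, sensor_site=site)
        movement = differentiate(recording)
        if bundle.band.high_hz > movement.nyquist_hz:
            raise ValueError(
                f"configured band high {bundle.band.high_hz} Hz exceeds "
                f"Nyquist {movement.nyquist_hz} Hz"
            )
        filtered = band_reconstruct(movement, bundle.band)
        tables[site] = epoch_metrics(
            filtered, events, epoch=bundle.epoch, threshold=bundle.threshold
        )
        logger.info("pipeline: %s -> %d trial epochs", site, len(tables[site]))

    metrics = pd.concat(tables.values(), ignore_index=True)
    if len(tables) == 2:
        sites = sorted(tables)
        combined = combine_sensor_tables(tables[sites[0]], tables[sites[1]])
        metrics = pd.concat([metrics, combined], ignore_index=True)

    bundle.out_dir.mkdir(parents=True, exist_ok=True)
    metrics_path = bundle.out_dir / "trial_metrics.csv"
    metrics.to_csv(metrics_path, index=False, float_format="%.12g")

    report: dict = {"config": bundle.config(), "aggregates": {}}
    subsets = {
        "all": events,
        **split_trials(events, "correctness"),
        **split_trials(events, "trial_type"),
        **split_trials(events, "quartile"),
    }
    for site in metrics["sensor_site"].unique():
        site_table = metrics[metrics["sensor_site"] == site]
        report["aggregates"][site] = {}
        for name, subset in subsets.items():
            wanted = {e.trial_index for e in subset}
            mask = site_table["trial_index"].isin(wanted)
            if not mask.any():
                continue
            agg = aggregate_metrics(site_table, mask.to_numpy())
            report["aggregates"][site][name] = {
                var: {
                    "mean": None if pd.isna(row["mean"]) else row["mean"],
                    "sd": None if pd.isna(row["sd"]) else row["sd"],
                    "n_trials": row["n_trials"],
                }
                for var, row in agg.iterrows()
            }
    report_path = bundle.out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("pipeline: wrote %s and %s", metrics_path, report_path)
    return report
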