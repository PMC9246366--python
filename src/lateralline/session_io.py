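"""Readers and writers for session containers and event tables.

Sessions are stored as HDF5 files (datasets ``/afferent`` and ``/motor``,
root attributes for the sampling rate and fish metadata, an optional
``/stimulus`` group for the sweep schedule) with a JSON sidecar mirroring
the metadata for quick inspection.  Event tables are plain CSV with fixed
column order and 9-significant-digit floats, so identical inputs always
produce byte-identical files.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import (
    BoutRates,
    FishMetadata,
    FishSummary,
    RecordingSession,
    SpikeTrain,
    StimulusSchedule,
    SwimBout,
    ValidationError,
)

FORMAT_VERSION = "1"
FLOAT_FORMAT = "%.9g"

SPIKE_COLUMNS = ["fish_id", "time_s"]
BOUT_COLUMNS = [
    "fish_id", "onset_s", "offset_s", "n_bursts", "duration_s",
    "swim_frequency_hz",
]
BOUT_RATES_COLUMNS = [
    "fish_id", "onset_s", "offset_s", "duration_s",
    "pre_count", "swim_count", "post_count",
    "pre_rate_hz", "swim_rate_hz", "post_rate_hz",
    "relative_rate", "inhibition", "label", "retained",
]
FISH_SUMMARY_COLUMNS = [
    "fish_id", "population", "treatment", "n_swims",
    "mean_pre_rate", "mean_swim_rate", "mean_post_rate",
    "mean_spontaneous_rate", "mean_inhibition", "weight",
]


class SessionIOError(Exception):
    """Base class for session container errors."""


class MissingChannelError(SessionIOError):
    """A required channel dataset is absent from the container."""


class VersionMismatchError(SessionIOError):
    """The container was written with an unsupported format version."""


class CorruptSessionError(SessionIOError):
    """The file cannot be opened or parsed as a session container."""


class TableFormatError(ValueError):
    """An event table violates the documented CSV contract."""


# --------------------------------------------------------------------------
# session container
# --------------------------------------------------------------------------

def write_session(
    session: RecordingSession,
    path: str | Path,
    schedule: StimulusSchedule | None = None,
) -> None:
    """Write a session container plus its JSON metadata sidecar."""
    path = Path(path)
    meta = session.metadata
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["sampling_rate"] = session.sampling_rate
        f.attrs["fish_id"] = meta.fish_id
        f.attrs["population"] = meta.population
        f.attrs["treatment"] = meta.treatment
        f.attrs["age_dpf"] = -1 if meta.age_dpf is None else int(meta.age_dpf)
        f.attrs["amplifier_gain"] = meta.amplifier_gain
        f.create_dataset("afferent", data=session.afferent_trace)
        f.create_dataset("motor", data=session.motor_trace)
        if schedule is not None:
            g = f.create_group("stimulus")
            g.attrs["stim_duration"] = schedule.stim_duration
            g.attrs["rest_duration"] = schedule.rest_duration
            g.create_dataset("sweep_onsets", data=schedule.sweep_onsets)
            g.create_dataset("sweep_frequencies", data=schedule.sweep_frequencies)
    sidecar = {
        "format_version": FORMAT_VERSION,
        "sampling_rate": session.sampling_rate,
        "n_samples": int(session.n_samples),
        "duration_s": session.duration,
        "fish_id": meta.fish_id,
        "population": meta.population,
        "treatment": meta.treatment,
        "age_dpf": meta.age_dpf,
        "amplifier_gain": meta.amplifier_gain,
        "has_stimulus_schedule": schedule is not None,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def read_session(
    path: str | Path,
) -> tuple[RecordingSession, StimulusSchedule | None]:
    """Read a session container; validates version, channels and metadata."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except (OSError, ValueError) as exc:
        raise CorruptSessionError(f"cannot open {path}: {exc}") from exc
    with f:
        version = str(f.attrs.get("format_version", ""))
        if version != FORMAT_VERSION:
            raise VersionMismatchError(
                f"unsupported format version {version!r} (expected {FORMAT_VERSION})"
            )
        for channel in ("afferent", "motor"):
            if channel not in f:
                raise MissingChannelError(f"container lacks /{channel}")
        age = int(f.attrs["age_dpf"])
        metadata = FishMetadata(
            fish_id=str(f.attrs["fish_id"]),
            population=str(f.attrs["population"]),
            treatment=str(f.attrs["treatment"]),
            age_dpf=None if age < 0 else age,
            amplifier_gain=float(f.attrs["amplifier_gain"]),
        )
        session = RecordingSession(
            afferent_trace=f["afferent"][...],
            motor_trace=f["motor"][...],
            sampling_rate=float(f.attrs["sampling_rate"]),
            metadata=metadata,
        )
        schedule = None
        if "stimulus" in f:
            g = f["stimulus"]
            schedule = StimulusSchedule(
                sweep_onsets=g["sweep_onsets"][...],
                sweep_frequencies=g["sweep_frequencies"][...],
                stim_duration=float(g.attrs["stim_duration"]),
                rest_duration=float(g.attrs["rest_duration"]),
            )
    return session, schedule


# --------------------------------------------------------------------------
# event tables (CSV)
# --------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    df[columns].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_spike_table(trains: list[SpikeTrain], path: str | Path) -> None:
    """Write spike trains as a long CSV (fish_id, time_s)."""
    rows = [
        {"fish_id": tr.fish_id, "time_s": t}
        for tr in trains for t in tr.times
    ]
    _write_csv(pd.DataFrame(rows, columns=SPIKE_COLUMNS), SPIKE_COLUMNS, path)


def read_spike_table(path: str | Path) -> list[SpikeTrain]:
    """Read and validate a spike CSV; times must increase within each fish."""
    df = _read_table(path, SPIKE_COLUMNS)
    trains = []
    for fish_id, sub in df.groupby("fish_id", sort=False):
        t = sub["time_s"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            row = sub.index[bad[0] + 1] + 2  # header + 1-based
            raise TableFormatError(
                f"spike times not strictly increasing for fish {fish_id!r} "
                f"at row {row}"
            )
        trains.append(SpikeTrain(t, str(fish_id)))
    return trains


def write_bout_table(
    bouts_by_fish: dict[str, list[SwimBout]], path: str | Path
) -> None:
    """Write bouts as CSV (one row per bout)."""
    rows = []
    for fish_id, bouts in bouts_by_fish.items():
        for b in bouts:
            rows.append({
                "fish_id": fish_id, "onset_s": b.onset, "offset_s": b.offset,
                "n_bursts": b.n_bursts, "duration_s": b.duration,
                "swim_frequency_hz": b.swim_frequency,
            })
    _write_csv(pd.DataFrame(rows, columns=BOUT_COLUMNS), BOUT_COLUMNS, path)


def read_bout_table(path: str | Path) -> dict[str, list[SwimBout]]:
    """Read and validate a bout CSV; intervals must be sane and disjoint."""
    df = _read_table(path, BOUT_COLUMNS)
    out: dict[str, list[SwimBout]] = {}
    for fish_id, sub in df.groupby("fish_id", sort=False):
        onsets = sub["onset_s"].to_numpy(dtype=float)
        offsets = sub["offset_s"].to_numpy(dtype=float)
        bad = np.flatnonzero(offsets <= onsets)
        if bad.size:
            row = sub.index[bad[0]] + 2
            raise TableFormatError(
                f"bout with offset <= onset for fish {fish_id!r} at row {row}"
            )
        order = np.argsort(onsets)
        overlap = np.flatnonzero(onsets[order][1:] < offsets[order][:-1])
        if overlap.size:
            i = sub.index[order[overlap[0]]] + 2
            j = sub.index[order[overlap[0] + 1]] + 2
            raise TableFormatError(
                f"overlapping bouts for fish {fish_id!r} at rows {i} and {j}"
            )
        out[str(fish_id)] = [
            SwimBout(o, f, n_bursts=int(n))
            for o, f, n in zip(
                onsets, offsets, sub["n_bursts"].to_numpy(dtype=float)
            )
        ]
    return out


def write_bout_rates_table(
    rates_by_fish: dict[str, list[BoutRates]], path: str | Path
) -> None:
    rows = []
    for fish_id, rates in rates_by_fish.items():
        for r in rates:
            rows.append({
                "fish_id": fish_id,
                "onset_s": r.bout.onset, "offset_s": r.bout.offset,
                "duration_s": r.bout.duration,
                "pre_count": r.pre_count, "swim_count": r.swim_count,
                "post_count": r.post_count,
                "pre_rate_hz": r.pre_rate, "swim_rate_hz": r.swim_rate,
                "post_rate_hz": r.post_rate,
                "relative_rate": r.relative_rate, "inhibition": r.inhibition,
                "label": "" if r.label is None else r.label,
                "retained": r.retained,
            })
    _write_csv(
        pd.DataFrame(rows, columns=BOUT_RATES_COLUMNS), BOUT_RATES_COLUMNS, path
    )


def write_fish_summary_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_csv(df, FISH_SUMMARY_COLUMNS, path)


def read_fish_summary_table(path: str | Path) -> pd.DataFrame:
    return _read_table(path, FISH_SUMMARY_COLUMNS)


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TableFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path} lacks required columns: {', '.join(missing)}"
        )
    return df


# --------------------------------------------------------------------------
# schedules and ground truth (JSON)
# --------------------------------------------------------------------------

def write_schedule(schedule: StimulusSchedule, path: str | Path) -> None:
    payload = {
        "stim_duration": schedule.stim_duration,
        "rest_duration": schedule.rest_duration,
        "sweep_onsets": schedule.sweep_onsets.tolist(),
        "sweep_frequencies": schedule.sweep_frequencies.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_schedule(path: str | Path) -> StimulusSchedule:
    payload = json.loads(Path(path).read_text())
    return StimulusSchedule(
        sweep_onsets=np.asarray(payload["sweep_onsets"], dtype=float),
        sweep_frequencies=np.asarray(payload["sweep_frequencies"], dtype=float),
        stim_duration=float(payload["stim_duration"]),
        rest_duration=float(payload["rest_duration"]),
    )


def write_ground_truth(truth, path: str | Path) -> None:
    """Write a simulation's ground-truth sidecar (events plus config echo)."""
    from dataclasses import asdict

    payload = {
        "spike_times": truth.spike_times.tolist(),
        "bouts": truth.bouts.tolist(),
        "burst_times": truth.burst_times.tolist(),
        "inhibition_fraction": truth.inhibition_fraction,
        "config": asdict(truth.config),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_ground_truth(path: str | Path):
    from .simulate import GroundTruth, SimulationConfig

    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        spike_times=np.asarray(payload["spike_times"], dtype=float),
        bouts=np.asarray(payload["bouts"], dtype=float).reshape(-1, 2),
        burst_times=np.asarray(payload["burst_times"], dtype=float),
        inhibition_fraction=float(payload["inhibition_fraction"]),
        config=SimulationConfig(**payload["config"]),
    )
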