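"""Session readers and writers.

Two on-disk formats are supported: a columnar-text dialect (spikes.csv,
kinematics.csv, events.csv, labels.csv; header row mandatory, UTF-8, "."
decimal) and NWB-layout HDF5 files (units spike-time table, 2-D cursor
position series, trial-interval table) read directly through h5py. Times in
the CSV dialect are milliseconds; NWB times are seconds and converted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import InputError
from .preprocess import KinematicsTrace, SpikeTrainSet, StateLabels
from .synthetic import SimulatedTrial

def _fmt(v) -> str:
    """Shortest round-trip decimal representation (locale-independent)."""
    return repr(float(v))


__all__ = [
    "SessionManifest",
    "Trial",
    "write_session_csv",
    "load_session_csv",
    "load_session_nwb",
    "load_session",
    "write_labels_csv",
]


@dataclass
class Trial:
    """One loaded trial: spikes + kinematics + optional reference labels."""

    trial_id: int
    spikes: SpikeTrainSet
    kin: KinematicsTrace
    labels: StateLabels | None = None


@dataclass
class SessionManifest:
    subject: str
    trial_ids: list[int]
    sample_rate: float
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(
            {"subject": self.subject, "trial_ids": self.trial_ids,
             "sample_rate": self.sample_rate, "provenance": self.provenance},
            indent=2))


def write_session_csv(trials: list[SimulatedTrial] | list[Trial], outdir) -> Path:
    """Write a session in the columnar-text dialect (full float precision)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spike_rows, kin_rows, event_rows, label_rows = [], [], [], []
    for tid, tr in enumerate(trials):
        spikes = tr.spikes
        kin = tr.kin
        labels = tr.truth if isinstance(tr, SimulatedTrial) else tr.labels
        for c, ts in enumerate(spikes.channel_spikes):
            for t in ts:
                spike_rows.append((tid, c, t))
        cols = {"trial_id": tid, "time_ms": kin.time_grid, "x": kin.x, "y": kin.y}
        if kin.vx is not None:
            cols["vx"] = kin.vx
            cols["vy"] = kin.vy
        kin_rows.append(pd.DataFrame(cols))
        event_rows.append((tid, kin.go_cue_ms if kin.go_cue_ms is not None else np.nan))
        if labels is not None:
            label_rows.append(pd.DataFrame(
                {"trial_id": tid, "time_ms": labels.time_grid,
                 "label": labels.labels}))
    pd.DataFrame(spike_rows, columns=["trial_id", "channel", "time_ms"]).to_csv(
        outdir / "spikes.csv", index=False, float_format=_fmt)
    pd.concat(kin_rows, ignore_index=True).to_csv(outdir / "kinematics.csv",
                                                  index=False, float_format=_fmt)
    pd.DataFrame(event_rows, columns=["trial_id", "go_cue_ms"]).to_csv(
        outdir / "events.csv", index=False, float_format=_fmt)
    if label_rows:
        pd.concat(label_rows, ignore_index=True).to_csv(outdir / "labels.csv",
                                                        index=False, float_format=_fmt)
    return outdir


def write_labels_csv(labels_per_trial: list[StateLabels], path,
                     predicted: list[StateLabels] | None = None) -> Path:
    """labels.csv schema, optionally with a predicted_label column."""
    frames = []
    for tid, lab in enumerate(labels_per_trial):
        d = {"trial_id": tid, "time_ms": lab.time_grid, "label": lab.labels}
        if predicted is not None:
            d["predicted_label"] = predicted[tid].labels
        frames.append(pd.DataFrame(d))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_fmt)
    return path


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{name}: missing columns {missing}")


def load_session_csv(path) -> list[Trial]:
    """Load a columnar-text session directory into per-trial objects."""
    path = Path(path)
    spikes = pd.read_csv(path / "spikes.csv", float_precision="round_trip")
    kin = pd.read_csv(path / "kinematics.csv", float_precision="round_trip")
    events = pd.read_csv(path / "events.csv", float_precision="round_trip")
    _require_columns(spikes, ["trial_id", "channel", "time_ms"], "spikes.csv")
    _require_columns(kin, ["trial_id", "time_ms", "x", "y"], "kinematics.csv")
    _require_columns(events, ["trial_id", "go_cue_ms"], "events.csv")
    labels_df = None
    labels_path = path / "labels.csv"
    if labels_path.exists():
        labels_df = pd.read_csv(labels_path, float_precision="round_trip")
        _require_columns(labels_df, ["trial_id", "time_ms", "label"], "labels.csv")

    n_channels = int(spikes["channel"].max()) + 1 if len(spikes) else 1
    go_cues = dict(zip(events["trial_id"], events["go_cue_ms"]))
    trials: list[Trial] = []
    step_seen: float | None = None
    for tid, kin_t in kin.groupby("trial_id", sort=True):
        t = kin_t["time_ms"].to_numpy(dtype=float)
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise InputError(f"kinematics.csv: non-monotone time in trial {tid}")
        if t.size >= 2:
            step = float(np.median(np.diff(t)))
            if step_seen is None:
                step_seen = step
            elif abs(step - step_seen) > 1e-9:
                raise InputError(
                    f"kinematics.csv: trial {tid} sample rate differs "
                    f"({step} ms vs {step_seen} ms steps)")
        duration = t[-1] - t[0] + (t[1] - t[0] if t.size >= 2 else 1.0)
        sp_t = spikes[spikes["trial_id"] == tid]
        channel_spikes = [
            np.sort(sp_t.loc[sp_t["channel"] == c, "time_ms"].to_numpy(dtype=float))
            for c in range(n_channels)
        ]
        ktrace = KinematicsTrace(
            time_grid=t,
            x=kin_t["x"].to_numpy(dtype=float),
            y=kin_t["y"].to_numpy(dtype=float),
            vx=kin_t["vx"].to_numpy(dtype=float) if "vx" in kin_t else None,
            vy=kin_t["vy"].to_numpy(dtype=float) if "vy" in kin_t else None,
            go_cue_ms=float(go_cues.get(tid, np.nan)),
        )
        lab = None
        if labels_df is not None:
            lab_t = labels_df[labels_df["trial_id"] == tid]
            if len(lab_t):
                lab = StateLabels(labels=lab_t["label"].to_numpy(),
                                  time_grid=lab_t["time_ms"].to_numpy(dtype=float))
        trials.append(Trial(
            trial_id=int(tid),
            spikes=SpikeTrainSet(channel_spikes, duration_ms=float(duration)),
            kin=ktrace,
            labels=lab,
        ))
    if not trials:
        raise InputError(f"no trials found under {path}")
    return trials


def _find_spatial_series(f: h5py.File):
    """Locate a 2-D cursor position series anywhere under processing/acquisition."""
    found = {}

    def visitor(name, obj):
        if isinstance(obj, h5py.Group) and "data" in obj:
            data = obj["data"]
            if isinstance(data, h5py.Dataset) and data.ndim == 2 and data.shape[1] >= 2:
                if obj.attrs.get("neurodata_type", b"") in (b"SpatialSeries", "SpatialSeries") \
                        or "position" in name.lower() or "cursor" in name.lower():
                    found.setdefault("group", obj)

    for top in ("processing", "acquisition"):
        if top in f:
            f[top].visititems(visitor)
    return found.get("group")


def load_session_nwb(path) -> list[Trial]:
    """Read an NWB-layout HDF5 file (units, cursor position, trial intervals).

    Expects ``/units`` with ragged ``spike_times``/``spike_times_index``, a
    2-D position series with either ``timestamps`` or
    ``starting_time``+``rate``, and ``/intervals/trials`` with ``start_time``,
    ``stop_time`` and a go-cue column. NWB times are seconds.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "units" not in f:
            raise InputError(f"{path}: no /units group")
        st = f["units/spike_times"][:]
        sti = f["units/spike_times_index"][:]
        unit_spikes = np.split(st, sti[:-1]) if sti.size else []

        pos_grp = _find_spatial_series(f)
        if pos_grp is None:
            raise InputError(f"{path}: no cursor position series found")
        pos = pos_grp["data"][:, :2].astype(float)
        if "timestamps" in pos_grp:
            t_s = pos_grp["timestamps"][:].astype(float)
        else:
            rate = float(pos_grp["starting_time"].attrs["rate"])
            t0 = float(pos_grp["starting_time"][()])
            t_s = t0 + np.arange(pos.shape[0]) / rate
        dt_s = np.diff(t_s).mean() if t_s.size >= 2 else 1e-3
        fs = 1.0 / dt_s

        if "intervals" not in f or "trials" not in f["intervals"]:
            raise InputError(f"{path}: no /intervals/trials table")
        tr = f["intervals/trials"]
        start = tr["start_time"][:].astype(float)
        stop = tr["stop_time"][:].astype(float)
        go_name = next((k for k in tr if "go" in k.lower()), None)
        go = tr[go_name][:].astype(float) if go_name else np.full(start.shape, np.nan)

    trials: list[Trial] = []
    for tid, (t0, t1, g) in enumerate(zip(start, stop, go)):
        sel = (t_s >= t0) & (t_s < t1)
        t_ms = (t_s[sel] - t0) * 1000.0
        duration = (t1 - t0) * 1000.0
        channel_spikes = []
        for ts in unit_spikes:
            ts = ts[(ts >= t0) & (ts <= t1)]
            channel_spikes.append(np.clip((ts - t0) * 1000.0, 0.0, duration))
        trials.append(Trial(
            trial_id=tid,
            spikes=SpikeTrainSet(channel_spikes, duration_ms=duration,
                                 sample_rate=fs),
            kin=KinematicsTrace(time_grid=t_ms, x=pos[sel, 0], y=pos[sel, 1],
                                go_cue_ms=(g - t0) * 1000.0 if np.isfinite(g) else None),
        ))
    if not trials:
        raise InputError(f"{path}: trial table is empty")
    return trials


def load_session(path, format: str = "auto") -> list[Trial]:
    """Load a session from a CSV directory or an NWB/HDF5 file."""
    path = Path(path)
    if format == "auto":
        format = "csv" if path.is_dir() else "nwb"
    if format == "csv":
        return load_session_csv(path)
    if format == "nwb":
        return load_session_nwb(path)
    raise InputError(f"unknown format: {format!r}")
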