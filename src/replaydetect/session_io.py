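"""Session file formats and the in-memory session bundle.

A *session* is a directory holding one manifest (``manifest.yaml``) plus one
delimited table per (epoch, kind):

* ``spikes_<epoch>.csv``   — columns ``tetrode_id, t, a1, a2, a3, a4``
  (seconds, microvolts); one row per spike event with its 4-channel peak
  amplitude mark.
* ``position_<epoch>.csv`` — columns ``t, x, y, arm, lin_pos, speed``
  (seconds, centimeters, cm/s); ``x/y`` are raw 2D tracking coordinates,
  ``arm``/``lin_pos`` the linearized position (arm index and distance from
  the central platform), ``speed`` the running speed. Missing values are
  written as empty fields, never as sentinel numbers.
* ``events_<epoch>.csv``   — columns ``t, label`` plus free-form payload
  columns (used for simulator ground truth and detector output).

All times are epoch-absolute seconds; no consumer may assume a zero origin.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

SPIKE_COLUMNS = ["tetrode_id", "t", "a1", "a2", "a3", "a4"]
AMPLITUDE_COLUMNS = ["a1", "a2", "a3", "a4"]
POSITION_COLUMNS = ["t", "x", "y", "arm", "lin_pos", "speed"]
EVENT_COLUMNS = ["t", "label"]

MANIFEST_NAME = "manifest.yaml"


class SessionFormatError(ValueError):
    """A session directory or one of its tables violates the format contract."""


def empty_spike_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tetrode_id": pd.Series(dtype="int64"),
            "t": pd.Series(dtype="float64"),
            "a1": pd.Series(dtype="float64"),
            "a2": pd.Series(dtype="float64"),
            "a3": pd.Series(dtype="float64"),
            "a4": pd.Series(dtype="float64"),
        }
    )


def empty_event_table() -> pd.DataFrame:
    return pd.DataFrame({"t": pd.Series(dtype="float64"), "label": pd.Series(dtype="object")})


@dataclass
class SessionBundle:
    """In-memory view of one recording (or simulated) session.

    Parameters
    ----------
    epochs
        Mapping epoch name -> (start, end) in seconds. Intervals must not
        overlap.
    tetrodes
        Registry of tetrode ids present in the session. Every
        ``tetrode_id`` in any spike table must appear here.
    spikes
        Per-epoch spike tables.
    positions
        Per-epoch position tables (run epochs only, typically).
    events
        Per-epoch event tables; simulated sessions carry ground-truth burst
        schedules here.
    meta
        Free-form metadata stored in the manifest.
    """

    epochs: dict[str, tuple[float, float]]
    tetrodes: list[int]
    spikes: dict[str, pd.DataFrame] = field(default_factory=dict)
    positions: dict[str, pd.DataFrame] = field(default_factory=dict)
    events: dict[str, pd.DataFrame] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Check all bundle invariants; raise :class:`SessionFormatError` on failure."""
        intervals = sorted(self.epochs.values())
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            if b0 < a1:
                raise SessionFormatError(
                    f"epoch intervals overlap: [{a0}, {a1}) and [{b0}, {b1})"
                )
        for name, (t0, t1) in self.epochs.items():
            if not t1 > t0:
                raise SessionFormatError(f"epoch {name!r} has non-positive duration")
        registry = set(self.tetrodes)
        for name, table in self.spikes.items():
            if name not in self.epochs:
                raise SessionFormatError(f"spike table for unknown epoch {name!r}")
            _validate_spike_table(table, registry, name, self.epochs[name])
        for name, table in self.positions.items():
            if name not in self.epochs:
                raise SessionFormatError(f"position table for unknown epoch {name!r}")
            _validate_position_table(table, name, self.epochs[name])
        for name, table in self.events.items():
            if name not in self.epochs:
                raise SessionFormatError(f"event table for unknown epoch {name!r}")
            t = np.asarray(table["t"], dtype=float)
            if t.size and np.any(np.diff(t) < 0):
                raise SessionFormatError(f"event times not sorted in epoch {name!r}")


def _validate_spike_table(
    table: pd.DataFrame, registry: set[int], epoch: str, interval: tuple[float, float]
) -> None:
    missing = [c for c in SPIKE_COLUMNS if c not in table.columns]
    if missing:
        raise SessionFormatError(f"spike table {epoch!r} missing columns {missing}")
    if len(table) == 0:
        return
    t = np.asarray(table["t"], dtype=float)
    amps = np.asarray(table[AMPLITUDE_COLUMNS], dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise SessionFormatError(f"spike table {epoch!r}: spike times must be finite and >= 0")
    if not np.all(np.isfinite(amps)):
        raise SessionFormatError(f"spike table {epoch!r}: amplitudes must be finite")
    if np.any(t < interval[0]) or np.any(t >= interval[1]):
        raise SessionFormatError(f"spike table {epoch!r}: spike times outside epoch interval")
    ids = set(np.unique(np.asarray(table["tetrode_id"], dtype=int)).tolist())
    unknown = ids - registry
    if unknown:
        raise SessionFormatError(
            f"spike table {epoch!r}: tetrode ids {sorted(unknown)} not in registry"
        )
    # per-tetrode monotone spike times
    for tid, sub in table.groupby("tetrode_id"):
        st = np.asarray(sub["t"], dtype=float)
        if np.any(np.diff(st) < 0):
            raise SessionFormatError(
                f"spike table {epoch!r}: times not sorted for tetrode {tid}"
            )


def _validate_position_table(
    table: pd.DataFrame, epoch: str, interval: tuple[float, float]
) -> None:
    for col in ("t", "lin_pos"):
        if col not in table.columns:
            raise SessionFormatError(f"position table {epoch!r} missing column {col!r}")
    t = np.asarray(table["t"], dtype=float)
    if t.size and (np.any(t < interval[0]) or np.any(t >= interval[1])):
        raise SessionFormatError(f"position table {epoch!r}: times outside epoch interval")
    if "speed" in table.columns:
        speed = np.asarray(table["speed"], dtype=float)
        if np.any(speed[np.isfinite(speed)] < 0):
            raise SessionFormatError(f"position table {epoch!r}: negative speed")


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def write_session(bundle: SessionBundle, path: str | Path) -> Path:
    """Write ``bundle`` to directory ``path``; return the manifest path.

    The layout is deterministic: tables are written with a fixed column
    order and floats in shortest round-trip representation, and the
    manifest with sorted keys, so two writes of the same bundle produce
    byte-identical files.
    """
    bundle.validate()
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise SessionFormatError(f"cannot create session directory {path}: {exc}") from exc

    manifest: dict = {
        "format": "replaydetect-session/1",
        "tetrodes": [int(t) for t in sorted(bundle.tetrodes)],
        "epochs": {},
        "meta": _plain(bundle.meta),
    }
    for name in sorted(bundle.epochs):
        t0, t1 = bundle.epochs[name]
        entry: dict = {"start": float(t0), "end": float(t1)}
        if name in bundle.spikes:
            entry["spikes"] = f"spikes_{name}.csv"
            _write_table(bundle.spikes[name], SPIKE_COLUMNS, path / entry["spikes"])
        if name in bundle.positions:
            entry["position"] = f"position_{name}.csv"
            cols = [c for c in POSITION_COLUMNS if c in bundle.positions[name].columns]
            _write_table(bundle.positions[name], cols, path / entry["position"])
        if name in bundle.events:
            entry["events"] = f"events_{name}.csv"
            table = bundle.events[name]
            cols = EVENT_COLUMNS + sorted(c for c in table.columns if c not in EVENT_COLUMNS)
            _write_table(table, cols, path / entry["events"])
        manifest["epochs"][name] = entry

    manifest_path = path / MANIFEST_NAME
    text = yaml.safe_dump(manifest, sort_keys=True, default_flow_style=False)
    manifest_path.write_text(text)
    return manifest_path


def read_session(path: str | Path) -> SessionBundle:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.is_file():
        raise SessionFormatError(f"missing manifest: {manifest_path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    if not isinstance(manifest, dict) or "epochs" not in manifest:
        raise SessionFormatError(f"malformed manifest: {manifest_path}")

    bundle = SessionBundle(
        epochs={},
        tetrodes=[int(t) for t in manifest.get("tetrodes", [])],
        meta=manifest.get("meta", {}) or {},
    )
    for name, entry in manifest["epochs"].items():
        bundle.epochs[name] = (float(entry["start"]), float(entry["end"]))
        if "spikes" in entry:
            bundle.spikes[name] = _read_table(path / entry["spikes"], SPIKE_COLUMNS)
            bundle.spikes[name]["tetrode_id"] = bundle.spikes[name]["tetrode_id"].astype("int64")
        if "position" in entry:
            bundle.positions[name] = _read_table(path / entry["position"], ["t", "lin_pos"])
        if "events" in entry:
            bundle.events[name] = _read_table(path / entry["events"], EVENT_COLUMNS)
    bundle.validate()
    return bundle


def _write_table(table: pd.DataFrame, columns: list[str], file: Path) -> None:
    out = table.loc[:, columns]
    buf = io.StringIO()
    out.to_csv(buf, index=False, lineterminator="\n")
    file.write_text(buf.getvalue())


def _read_table(file: Path, required: list[str]) -> pd.DataFrame:
    if not file.is_file():
        raise SessionFormatError(f"manifest references nonexistent file: {file}")
    try:
        table = pd.read_csv(file)
    except Exception as exc:
        raise SessionFormatError(f"malformed table {file}: {exc}") from exc
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SessionFormatError(f"table {file} missing columns {missing}")
    return table


def _plain(obj):
    """Recursively convert numpy scalars so YAML output stays dialect-free."""
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
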