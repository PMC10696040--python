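"""Session containers: HDF5 (primary) and per-channel CSV + JSON sidecar.

One HDF5 file per session::

    /channels/<label>   dataset, attrs: fs, t0, kind, units
    /events/<label>     dataset of event times
    /protocol           attrs: site, agent, pre/post durations; injections dataset
    /truth/<column>     per-cycle ground-truth columns (synthetic sessions)

The plain-text fallback writes a directory with ``<label>.csv`` per channel
(full ``%.17g`` precision, so round trips are bit-exact) and ``meta.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import DrugProtocol, EventSeries, RecordingSession, Trace

__all__ = ["save_session", "load_session", "FormatError"]


class FormatError(ValueError):
    """Malformed or incomplete session container."""


def save_session(session: RecordingSession, path) -> Path:
    """Write a session to ``path``: ``.h5``/``.hdf5`` for HDF5, otherwise a
    directory of CSVs with a JSON sidecar."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _save_h5(session, path)
    else:
        _save_csv(session, path)
    return path


def load_session(path) -> RecordingSession:
    """Load a session saved by :func:`save_session` (lossless round trip)."""
    path = Path(path)
    if path.is_dir():
        return _load_csv(path)
    if path.suffix in (".h5", ".hdf5"):
        return _load_h5(path)
    raise FormatError(f"unrecognised session container: {path}")


# --- HDF5 ----------------------------------------------------------------

def _save_h5(session: RecordingSession, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "phrenic-session-1"
        f.attrs["subject_id"] = session.subject_id
        ch = f.create_group("channels")
        for label, tr in session.traces.items():
            d = ch.create_dataset(label, data=tr.samples)
            d.attrs["fs"] = tr.fs
            d.attrs["t0"] = tr.t0
            d.attrs["kind"] = tr.kind
            d.attrs["units"] = tr.units
        ev = f.create_group("events")
        for label, series in session.events.items():
            ev.create_dataset(label, data=series.times)
        if session.protocol is not None:
            pg = f.create_group("protocol")
            pg.attrs["site"] = session.protocol.site
            pg.attrs["agent"] = session.protocol.agent
            pg.attrs["pre_duration"] = session.protocol.pre_duration
            pg.attrs["post_duration"] = session.protocol.post_duration
            pg.create_dataset("injection_times",
                              data=np.asarray(session.protocol.injection_times))
        if session.truth is not None:
            tg = f.create_group("truth")
            for col in session.truth.columns:
                tg.create_dataset(col, data=session.truth[col].to_numpy())
            tg.attrs["columns"] = json.dumps(list(session.truth.columns))


def _load_h5(path: Path) -> RecordingSession:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"cannot open session container {path}: {exc}") from exc
    with f:
        if "channels" not in f:
            raise FormatError("container lacks a 'channels' group")
        traces: dict[str, Trace] = {}
        for label, d in f["channels"].items():
            if "fs" not in d.attrs:
                raise FormatError(f"channel {label!r} is missing the 'fs' attribute")
            traces[label] = Trace(
                channel=label, fs=float(d.attrs["fs"]), samples=d[()],
                t0=float(d.attrs.get("t0", 0.0)),
                kind=str(d.attrs.get("kind", "raw")),
                units=str(d.attrs.get("units", "a.u.")),
            )
        events = {label: EventSeries(label, d[()]) for label, d in f.get("events", {}).items()}
        protocol = None
        if "protocol" in f:
            pg = f["protocol"]
            protocol = DrugProtocol(
                site=str(pg.attrs["site"]), agent=str(pg.attrs["agent"]),
                injection_times=list(pg["injection_times"][()]),
                pre_duration=float(pg.attrs["pre_duration"]),
                post_duration=float(pg.attrs["post_duration"]),
            )
        truth = None
        if "truth" in f:
            cols = json.loads(f["truth"].attrs["columns"])
            truth = pd.DataFrame({c: f["truth"][c][()] for c in cols})
        subject = str(f.attrs.get("subject_id", "s0"))
    try:
        return RecordingSession(traces=traces, events=events, protocol=protocol,
                                truth=truth, subject_id=subject)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


# --- CSV + JSON sidecar --------------------------------------------------

def _save_csv(session: RecordingSession, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {"format": "phrenic-session-1", "subject_id": session.subject_id,
                  "channels": {}, "events": {}}
    for label, tr in session.traces.items():
        np.savetxt(path / f"{label}.csv", tr.samples, fmt="%.17g")
        meta["channels"][label] = {"fs": tr.fs, "t0": tr.t0, "kind": tr.kind,
                                   "units": tr.units}
    for label, series in session.events.items():
        meta["events"][label] = list(map(float, series.times))
    if session.protocol is not None:
        p = session.protocol
        meta["protocol"] = {"site": p.site, "agent": p.agent,
                            "injection_times": p.injection_times,
                            "pre_duration": p.pre_duration,
                            "post_duration": p.post_duration}
    if session.truth is not None:
        session.truth.to_csv(path / "truth.csv", index=False,
                             float_format="%.17g")
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def _load_csv(path: Path) -> RecordingSession:
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"{path} has no meta.json sidecar")
    meta = json.loads(meta_path.read_text())
    traces: dict[str, Trace] = {}
    for label, info in meta.get("channels", {}).items():
        if "fs" not in info:
            raise FormatError(f"channel {label!r} is missing 'fs' in meta.json")
        samples = np.loadtxt(path / f"{label}.csv", ndmin=1)
        traces[label] = Trace(channel=label, fs=info["fs"], samples=samples,
                              t0=info.get("t0", 0.0), kind=info.get("kind", "raw"),
                              units=info.get("units", "a.u."))
    events = {label: EventSeries(label, np.asarray(times))
              for label, times in meta.get("events", {}).items()}
    protocol = None
    if "protocol" in meta:
        protocol = DrugProtocol(**meta["protocol"])
    truth_path = path / "truth.csv"
    truth = (pd.read_csv(truth_path, float_precision="round_trip")
             if truth_path.exists() else None)
    try:
        return RecordingSession(traces=traces, events=events, protocol=protocol,
                                truth=truth,
                                subject_id=meta.get("subject_id", "s0"))
    except ValueError as exc:
        raise FormatError(str(exc)) from exc
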