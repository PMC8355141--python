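"""Read/write the canonical on-disk session format.

A session is stored as four files:

* ``events.csv`` — ``iteration_index,position,stimulus_id,onset_s,offset_s,is_probe``
* ``spikes.csv`` — ``unit_id,channel_id,unit_class,spike_time_s`` (one row per spike;
  a unit with no spikes still contributes a header-only presence via the sidecar)
* ``lfp.f32``   — raw little-endian float32 samples, channel-major
* ``session.json`` — session id, stimulus count, unit→channel map, and the LFP
  sidecar (``fs_hz``, channel order, ``n_samples``, units)

The format is deliberately plain: desk-scale, language-agnostic, and bit-exact
for everything except the float32 quantisation of the LFP.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, SessionValidationError
from .session import LFPChannel, SequenceEvent, Session, SpikeTrain

EVENT_COLUMNS = ["iteration_index", "position", "stimulus_id", "onset_s", "offset_s", "is_probe"]
SPIKE_COLUMNS = ["unit_id", "channel_id", "unit_class", "spike_time_s"]


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_session(
    events_path: str | Path,
    spikes_path: str | Path,
    lfp_path: str | Path,
    sidecar_path: str | Path,
) -> Session:
    """Load a session from its four canonical files and validate it."""
    events_path, spikes_path = Path(events_path), Path(spikes_path)
    lfp_path, sidecar_path = Path(lfp_path), Path(sidecar_path)

    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for key in ("session_id", "n_stimuli", "unit_to_lfp", "lfp"):
        if key not in meta:
            raise SchemaError(f"{sidecar_path}: missing key {key!r}")
    lfp_meta = meta["lfp"]
    for key in ("fs_hz", "channels", "n_samples"):
        if key not in lfp_meta:
            raise SchemaError(f"{sidecar_path}: missing lfp key {key!r}")

    ev = pd.read_csv(events_path)
    _require_columns(ev, EVENT_COLUMNS, events_path)
    events = []
    for i, row in enumerate(ev.itertuples(index=False)):
        e = SequenceEvent(
            iteration_index=int(row.iteration_index),
            position=int(row.position),
            stimulus_id=int(row.stimulus_id),
            onset_s=float(row.onset_s),
            offset_s=float(row.offset_s),
            is_probe=bool(row.is_probe),
        )
        if e.offset_s <= e.onset_s:
            raise SessionValidationError(
                f"{events_path} row {i}: offset_s <= onset_s"
            )
        events.append(e)

    sp = pd.read_csv(spikes_path)
    _require_columns(sp, SPIKE_COLUMNS, spikes_path)
    spikes: list[SpikeTrain] = []
    unit_meta: dict[str, tuple[str, str]] = {}
    unit_times: dict[str, list[float]] = {}
    for row in sp.itertuples(index=False):
        uid = str(row.unit_id)
        unit_meta.setdefault(uid, (str(row.channel_id), str(row.unit_class)))
        unit_times.setdefault(uid, []).append(float(row.spike_time_s))
    # units present only in the mapping (empty spike trains) are kept too
    for uid, ch in meta["unit_to_lfp"].items():
        unit_meta.setdefault(uid, (ch, "unknown"))
        unit_times.setdefault(uid, [])
    for uid in sorted(unit_meta):
        ch, cls = unit_meta[uid]
        times = np.asarray(unit_times[uid], dtype=float)
        if times.size and np.any(np.diff(times) < 0):
            raise SessionValidationError(f"{spikes_path}: unit {uid} spike times unsorted")
        spikes.append(SpikeTrain(unit_id=uid, channel_id=ch, spike_times_s=times, unit_class=cls))

    n_samples = int(lfp_meta["n_samples"])
    channels = list(lfp_meta["channels"])
    raw = np.fromfile(lfp_path, dtype="<f4")
    if raw.size != n_samples * len(channels):
        raise SchemaError(
            f"{lfp_path}: expected {n_samples * len(channels)} float32 samples, got {raw.size}"
        )
    traces = raw.reshape(len(channels), n_samples)
    lfp = [
        LFPChannel(channel_id=cid, fs_hz=float(lfp_meta["fs_hz"]), samples_uv=traces[i].astype(float))
        for i, cid in enumerate(channels)
    ]

    session = Session(
        session_id=str(meta["session_id"]),
        n_stimuli=int(meta["n_stimuli"]),
        events=events,
        spikes=spikes,
        lfp=lfp,
        unit_to_lfp={str(k): str(v) for k, v in meta["unit_to_lfp"].items()},
    )
    session.validate()
    return session


def read_session_dir(session_dir: str | Path) -> Session:
    d = Path(session_dir)
    return read_session(d / "events.csv", d / "spikes.csv", d / "lfp.f32", d / "session.json")


def write_session(session: Session, out_dir: str | Path) -> list[Path]:
    """Write a session to ``out_dir`` as the four canonical files.

    Output ordering is deterministic (events by onset, spikes by unit then
    time, channels in session order), so the same session always produces
    byte-identical files.
    """
    session.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ev = session.events_df()
    ev["is_probe"] = ev["is_probe"].astype(int)
    events_path = out / "events.csv"
    ev.to_csv(events_path, index=False)

    rows = []
    for st in sorted(session.spikes, key=lambda s: s.unit_id):
        for t in st.spike_times_s:
            rows.append((st.unit_id, st.channel_id, st.unit_class, float(t)))
    sp = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    spikes_path = out / "spikes.csv"
    sp.to_csv(spikes_path, index=False)

    n_samples = session.lfp[0].samples_uv.size if session.lfp else 0
    for ch in session.lfp:
        if ch.samples_uv.size != n_samples:
            raise SessionValidationError("all LFP channels must share one length")
    stack = np.concatenate([ch.samples_uv for ch in session.lfp]) if session.lfp else np.empty(0)
    lfp_path = out / "lfp.f32"
    stack.astype("<f4").tofile(lfp_path)

    meta = {
        "session_id": session.session_id,
        "n_stimuli": session.n_stimuli,
        "unit_to_lfp": {uid: session.unit_to_lfp[uid] for uid in sorted(session.unit_to_lfp)},
        "lfp": {
            "fs_hz": float(session.lfp[0].fs_hz) if session.lfp else 0.0,
            "channels": [ch.channel_id for ch in session.lfp],
            "n_samples": int(n_samples),
            "units": "uV",
        },
    }
    sidecar_path = out / "session.json"
    with open(sidecar_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=False)
        fh.write("\n")

    return [events_path, spikes_path, lfp_path, sidecar_path]
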