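"""Session data model: sequence events, spike trains, and LFP channels.

Conventions used throughout the package:

* time is in seconds from the start of the session;
* sequence positions and iteration indices are 0-based;
* event windows are half-open ``[onset, offset)`` so that a spike falling
  exactly on an event boundary belongs to the *next* window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ChannelReferenceError, SessionValidationError

UNIT_CLASSES = ("single", "multi", "unknown")


@dataclass
class SequenceEvent:
    """One stimulus presentation (or probe) within the learned sequence."""

    iteration_index: int
    position: int
    stimulus_id: int
    onset_s: float
    offset_s: float
    is_probe: bool = False

    def validate(self) -> None:
        if not self.offset_s > self.onset_s:
            raise SessionValidationError(
                f"event (iteration={self.iteration_index}, position={self.position}): "
                f"offset_s={self.offset_s} must exceed onset_s={self.onset_s}"
            )
        if self.iteration_index < 0 or self.position < 0 or self.stimulus_id < 0:
            raise SessionValidationError(
                "iteration_index, position and stimulus_id must be non-negative"
            )


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit, tied to the microwire it was recorded on."""

    unit_id: str
    channel_id: str
    spike_times_s: np.ndarray
    unit_class: str = "unknown"

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    def validate(self, duration_s: float | None = None) -> None:
        if self.unit_class not in UNIT_CLASSES:
            raise SessionValidationError(
                f"unit {self.unit_id}: unit_class {self.unit_class!r} not in {UNIT_CLASSES}"
            )
        t = self.spike_times_s
        if t.size and np.any(np.diff(t) < 0):
            raise SessionValidationError(f"unit {self.unit_id}: spike times not sorted")
        if t.size and t[0] < 0:
            raise SessionValidationError(f"unit {self.unit_id}: negative spike time")
        if duration_s is not None and t.size and t[-1] > duration_s:
            raise SessionValidationError(
                f"unit {self.unit_id}: spike at {t[-1]:.3f}s beyond session end {duration_s:.3f}s"
            )


@dataclass
class LFPChannel:
    """One regularly sampled LFP trace.

    ``samples_uv`` is nominally microvolts but any consistent unit is fine:
    every downstream statistic is either ratio- or phase-based.
    """

    channel_id: str
    fs_hz: float
    samples_uv: np.ndarray

    def __post_init__(self) -> None:
        self.samples_uv = np.asarray(self.samples_uv, dtype=float)

    @property
    def duration_s(self) -> float:
        return self.samples_uv.size / self.fs_hz

    def validate(self) -> None:
        if self.fs_hz <= 0:
            raise SessionValidationError(f"channel {self.channel_id}: fs_hz must be > 0")
        if not np.all(np.isfinite(self.samples_uv)):
            raise SessionValidationError(
                f"channel {self.channel_id}: non-finite LFP samples"
            )


@dataclass
class Session:
    """Container tying events, spikes, and LFP for one recording session."""

    session_id: str
    n_stimuli: int
    events: list[SequenceEvent]
    spikes: list[SpikeTrain]
    lfp: list[LFPChannel]
    unit_to_lfp: dict[str, str] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    def get_unit(self, unit_id: str) -> SpikeTrain:
        for st in self.spikes:
            if st.unit_id == unit_id:
                return st
        raise KeyError(f"no unit {unit_id!r} in session {self.session_id}")

    def get_channel(self, channel_id: str) -> LFPChannel:
        for ch in self.lfp:
            if ch.channel_id == channel_id:
                return ch
        raise KeyError(f"no LFP channel {channel_id!r} in session {self.session_id}")

    def lfp_for_unit(self, unit_id: str) -> LFPChannel:
        return self.get_channel(self.unit_to_lfp[unit_id])

    @property
    def unit_ids(self) -> list[str]:
        return [st.unit_id for st in self.spikes]

    @property
    def duration_s(self) -> float:
        d = max((e.offset_s for e in self.events), default=0.0)
        for ch in self.lfp:
            d = max(d, ch.duration_s)
        return d

    @property
    def n_iterations(self) -> int:
        return 1 + max((e.iteration_index for e in self.events), default=-1)

    def events_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration_index": [e.iteration_index for e in self.events],
                "position": [e.position for e in self.events],
                "stimulus_id": [e.stimulus_id for e in self.events],
                "onset_s": [e.onset_s for e in self.events],
                "offset_s": [e.offset_s for e in self.events],
                "is_probe": [e.is_probe for e in self.events],
            }
        )

    def sequence_order(self) -> list[int]:
        """Stimulus ids in presentation order (position 0..n_stimuli-1).

        Derived from the first iteration that contains every position.
        """
        order: dict[int, int] = {}
        for e in self.events:
            if e.position not in order:
                order[e.position] = e.stimulus_id
            if len(order) == self.n_stimuli:
                break
        if len(order) != self.n_stimuli:
            raise SessionValidationError(
                f"session {self.session_id}: cannot derive full sequence order"
            )
        return [order[p] for p in range(self.n_stimuli)]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not (1 <= self.n_stimuli):
            raise SessionValidationError("n_stimuli must be >= 1")
        prev_offset = -np.inf
        prev_onset = -np.inf
        for i, e in enumerate(self.events):
            e.validate()
            if e.onset_s < prev_onset:
                raise SessionValidationError(f"events not sorted by onset at row {i}")
            if e.onset_s < prev_offset - 1e-9:
                raise SessionValidationError(
                    f"event at row {i} overlaps the previous event"
                )
            if not (0 <= e.stimulus_id < self.n_stimuli):
                raise SessionValidationError(
                    f"event at row {i}: stimulus_id {e.stimulus_id} outside "
                    f"[0, {self.n_stimuli})"
                )
            prev_offset = e.offset_s
            prev_onset = e.onset_s
        # positions consecutive within each iteration
        by_iter: dict[int, list[int]] = {}
        for e in self.events:
            by_iter.setdefault(e.iteration_index, []).append(e.position)
        for it, positions in by_iter.items():
            if positions != list(range(positions[0], positions[0] + len(positions))):
                raise SessionValidationError(
                    f"iteration {it}: positions {positions} are not consecutive"
                )
        for ch in self.lfp:
            ch.validate()
        dur = self.duration_s
        channel_ids = {ch.channel_id for ch in self.lfp}
        for st in self.spikes:
            st.validate(duration_s=dur if self.lfp else None)
            mapped = self.unit_to_lfp.get(st.unit_id)
            if mapped is None:
                raise ChannelReferenceError(
                    f"unit {st.unit_id} has no entry in unit_to_lfp"
                )
            if mapped not in channel_ids:
                raise ChannelReferenceError(
                    f"unit {st.unit_id} mapped to absent channel {mapped!r}"
                )
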