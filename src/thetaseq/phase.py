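"""Theta-phase coding of sequence items: per-stimulus spike-phase
distributions, phase-precession statistics, and control analyses.

Each consistent unit contributes spike phases grouped by *sequence offset*
from its preferred stimulus (-1 = preceding, 0 = preferred, +1 = following).
Only sequence iterations where the preceding, preferred and following items
occurred consecutively and none was a probe are included. The population
summary averages per-cell circular means (cells weighted equally), tests
pairwise offset differences with Watson-Williams (Bonferroni x3), and
quantifies precession two ways:

* consecutive phase difference: circular mean of the two signed wrapped
  steps between adjacent offsets (negative = spikes move to earlier phases
  as the sequence advances);
* phase lag = ``wrap(mean_prec - mean_foll) / 2`` in degrees/stimulus (the
  positive magnitude convention), tested preceding vs. following.

Controls: spike-count matching between preceding and following iterations,
inter-trial coherence and removal of stimulus-locked spikes at the phase
reset, a theta-power median split, spiking-vs-LFP frequency comparison, and
arbitrary subgroup summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .circstats import (
    CircMean,
    CircularTestResult,
    circ_diff_deg,
    circ_mean,
    circ_median,
    circ_median_test,
    mean_ci_valid,
    watson_williams,
    wrap_deg,
)
from .errors import EmptyResultError, InsufficientDataError
from .session import LFPChannel, Session, SpikeTrain
from .spectral import PhaseSeries, fit_one_over_f, power_spectrum_rel_1f
from .tuning import CellTuning

TRIPLET_OFFSETS = (-1, 0, +1)


@dataclass
class OffsetPhases:
    """Spikes of one unit at one sequence offset, across included iterations."""

    phases_deg: np.ndarray
    times_rel_s: np.ndarray  # relative to the preferred-stimulus onset
    iteration: np.ndarray  # index of the included triplet each spike belongs to
    envelope: np.ndarray

    @property
    def n(self) -> int:
        return int(self.phases_deg.size)


@dataclass
class StimulusPhaseSet:
    """Per-offset spike phases for one unit in one band."""

    unit_id: str
    band_label: str
    offsets: dict[int, OffsetPhases]
    included_iterations: int
    trial_dur_s: float = 2.0

    def phases(self, offset: int) -> np.ndarray:
        return self.offsets[offset].phases_deg if offset in self.offsets else np.empty(0)

    def counts_per_iteration(self, offset: int) -> np.ndarray:
        c = np.zeros(self.included_iterations, dtype=int)
        if offset in self.offsets:
            it, n = np.unique(self.offsets[offset].iteration, return_counts=True)
            c[it.astype(int)] = n
        return c

    def restricted(self, keep_iterations: np.ndarray) -> "StimulusPhaseSet":
        """Copy keeping only spikes from the given triplet indices."""
        keep = np.zeros(self.included_iterations, dtype=bool)
        keep[np.asarray(keep_iterations, dtype=int)] = True
        new: dict[int, OffsetPhases] = {}
        for off, op in self.offsets.items():
            sel = keep[op.iteration.astype(int)]
            new[off] = OffsetPhases(
                op.phases_deg[sel], op.times_rel_s[sel], op.iteration[sel], op.envelope[sel]
            )
        return StimulusPhaseSet(
            self.unit_id, self.band_label, new, self.included_iterations, self.trial_dur_s
        )


def phases_by_sequence_offset(
    session: Session,
    tuning: CellTuning,
    phase_series: PhaseSeries,
    window: tuple[float, float] = (0.0, 2.0),
    extra_offsets: tuple[int, ...] = (),
) -> StimulusPhaseSet:
    """Group a unit's spike phases by sequence offset from its preferred item.

    A sequence iteration enters the analysis only when the preceding,
    preferred, and following stimuli occurred consecutively and none of them
    was a probe. Spikes are assigned to each event's half-open response
    window ``[onset + w0, onset + w1)`` and phases looked up at the nearest
    LFP sample.
    """
    unit = session.get_unit(tuning.unit_id)
    t = unit.spike_times_s
    events = session.events
    w0, w1 = window
    offsets_wanted = tuple(sorted(set(TRIPLET_OFFSETS) | set(extra_offsets)))

    order = session.sequence_order()
    n = len(order)
    pref_pos = order.index(tuning.preferred_id)

    acc: dict[int, list[tuple[np.ndarray, np.ndarray, int]]] = {o: [] for o in offsets_wanted}
    trial_dur = np.inf
    k = 0
    for i, e in enumerate(events):
        if e.stimulus_id != tuning.preferred_id or e.is_probe:
            continue
        if i == 0 or i + 1 >= len(events):
            continue
        prev, nxt = events[i - 1], events[i + 1]
        if prev.stimulus_id != tuning.preceding_id or nxt.stimulus_id != tuning.following_id:
            continue
        if prev.is_probe or nxt.is_probe:
            continue
        trial_dur = min(trial_dur, e.onset_s - prev.onset_s)
        for off in offsets_wanted:
            j = i + off
            if not (0 <= j < len(events)):
                continue
            ej = events[j]
            if off not in (-1, 0, 1):
                if ej.is_probe or ej.stimulus_id != order[(pref_pos + off) % n]:
                    continue
            lo = np.searchsorted(t, ej.onset_s + w0, side="left")
            hi = np.searchsorted(t, ej.onset_s + w1, side="left")
            if hi > lo:
                acc[off].append((t[lo:hi], t[lo:hi] - e.onset_s, k))
        k += 1

    if k == 0:
        raise EmptyResultError(
            f"unit {tuning.unit_id}: no iteration with a consecutive non-probe "
            "preceding/preferred/following triplet"
        )

    fs = phase_series.fs_hz
    nsamp = phase_series.phase_deg.size
    out: dict[int, OffsetPhases] = {}
    for off, chunks in acc.items():
        if not chunks:
            out[off] = OffsetPhases(np.empty(0), np.empty(0), np.empty(0, dtype=int), np.empty(0))
            continue
        times = np.concatenate([c[0] for c in chunks])
        rel = np.concatenate([c[1] for c in chunks])
        iters = np.concatenate([np.full(c[0].size, c[2], dtype=int) for c in chunks])
        idx = np.round(times * fs).astype(int)
        keep = (idx >= 0) & (idx < nsamp)
        out[off] = OffsetPhases(
            phases_deg=phase_series.phase_deg[idx[keep]],
            times_rel_s=rel[keep],
            iteration=iters[keep],
            envelope=phase_series.envelope[idx[keep]],
        )
    return StimulusPhaseSet(
        unit_id=tuning.unit_id,
        band_label=phase_series.label,
        offsets=out,
        included_iterations=k,
        trial_dur_s=float(trial_dur if np.isfinite(trial_dur) else w1 - w0),
    )


# ---------------------------------------------------------------------------
# population summary and lag statistics


@dataclass
class OffsetSummary:
    circ_mean_deg: float  # reported on the 0-360 display scale
    angular_sd_deg: float  # across-cell angular deviation
    n_cells: int


@dataclass
class PopulationPhaseSummary:
    per_offset: dict[int, OffsetSummary]
    pairwise_ww: dict[tuple[int, int], CircularTestResult]  # Bonferroni-corrected
    consecutive_diff_deg: float | None
    phase_lag_deg_per_stim: float | None
    phase_lag_test: CircularTestResult | None
    per_cell_lags: list[float] = field(default_factory=list)
    per_cell_lag_median: float | None = None
    per_cell_lag_test: CircularTestResult | None = None
    flags: list[str] = field(default_factory=list)


def per_cell_circular_means(
    phase_sets: list[StimulusPhaseSet],
    offsets: tuple[int, ...] = TRIPLET_OFFSETS,
    min_spikes: int = 1,
) -> dict[int, list[tuple[str, CircMean]]]:
    means: dict[int, list[tuple[str, CircMean]]] = {o: [] for o in offsets}
    for ps in phase_sets:
        for off in offsets:
            p = ps.phases(off)
            if p.size >= min_spikes:
                means[off].append((ps.unit_id, circ_mean(p)))
    return means


def per_cell_phase_lag(phase_set: StimulusPhaseSet, min_spikes: int = 5) -> float:
    """One cell's phase lag ``wrap(mean_prec - mean_foll)/2`` in deg/stimulus."""
    prec, foll = phase_set.phases(-1), phase_set.phases(+1)
    if prec.size < min_spikes or foll.size < min_spikes:
        raise InsufficientDataError(
            f"unit {phase_set.unit_id}: needs >= {min_spikes} spikes at offsets -1 and +1"
        )
    return float(
        circ_diff_deg(circ_mean(prec).mean_deg, circ_mean(foll).mean_deg) / 2.0
    )


def phase_lag(
    preceding_means_deg: np.ndarray, following_means_deg: np.ndarray
) -> tuple[float, CircularTestResult]:
    """Population phase lag ``wrap(mean_prec - mean_foll)/2`` (deg/stimulus),
    with a Watson-Williams test of the two per-cell mean-phase distributions."""
    prec = np.asarray(preceding_means_deg, dtype=float)
    foll = np.asarray(following_means_deg, dtype=float)
    if prec.size < 5 or foll.size < 5:
        raise InsufficientDataError("phase_lag needs >= 5 cells per group")
    m_prec = circ_mean(prec).mean_deg
    m_foll = circ_mean(foll).mean_deg
    lag = float(circ_diff_deg(m_prec, m_foll) / 2.0)
    return lag, watson_williams(prec, foll)


def population_phase_summary(
    phase_sets: list[StimulusPhaseSet],
    min_spikes: int = 1,
    min_spikes_lag: int = 5,
    bonferroni: int = 3,
) -> PopulationPhaseSummary:
    """Across-cell summary of per-offset phase preferences and precession.

    Per-cell circular means are computed first; the population mean, the
    across-cell angular SD, the pairwise Watson-Williams tests (p x 3), the
    consecutive phase difference, and the phase lag all operate on those
    per-cell means so that every cell is weighted equally.
    """
    flags: list[str] = []
    means = per_cell_circular_means(phase_sets, TRIPLET_OFFSETS, min_spikes)
    per_offset: dict[int, OffsetSummary] = {}
    pop_mean: dict[int, float] = {}
    for off in TRIPLET_OFFSETS:
        vals = np.array([cm.mean_deg for _, cm in means[off]])
        if vals.size == 0:
            flags.append(f"offset {off}: no cells")
            continue
        cm = circ_mean(vals)
        pop_mean[off] = cm.mean_deg
        per_offset[off] = OffsetSummary(
            circ_mean_deg=float(cm.mean_deg % 360.0),
            angular_sd_deg=cm.angular_sd_deg,
            n_cells=cm.n,
        )

    pairwise: dict[tuple[int, int], CircularTestResult] = {}
    for a, b in ((-1, 0), (0, 1), (-1, 1)):
        va = np.array([cm.mean_deg for _, cm in means[a]])
        vb = np.array([cm.mean_deg for _, cm in means[b]])
        if va.size >= 5 and vb.size >= 5:
            res = watson_williams(va, vb)
            pairwise[(a, b)] = CircularTestResult(
                statistic=res.statistic,
                p_value=min(1.0, res.p_value * bonferroni),
                df=res.df,
                n_per_group=res.n_per_group,
            )
        else:
            flags.append(f"pairwise ({a},{b}): too few cells")

    consecutive = None
    if all(off in pop_mean for off in TRIPLET_OFFSETS):
        steps = np.array(
            [
                circ_diff_deg(pop_mean[0], pop_mean[-1]),
                circ_diff_deg(pop_mean[1], pop_mean[0]),
            ]
        )
        consecutive = circ_mean(steps).mean_deg

    lag = lag_test = None
    va = np.array([cm.mean_deg for _, cm in means[-1]])
    vb = np.array([cm.mean_deg for _, cm in means[1]])
    if va.size >= 5 and vb.size >= 5:
        lag, lag_test = phase_lag(va, vb)
    else:
        flags.append("phase lag: too few cells")

    lags: list[float] = []
    for ps in phase_sets:
        try:
            lags.append(per_cell_phase_lag(ps, min_spikes=min_spikes_lag))
        except InsufficientDataError:
            continue
    lag_median = lag_median_test = None
    if lags:
        lag_median = circ_median(np.array(lags))
        if len(lags) >= 5:
            try:
                lag_median_test = circ_median_test(np.array(lags), 0.0)
            except InsufficientDataError:
                flags.append("per-cell lag sign test undefined (all lags tie with 0)")

    return PopulationPhaseSummary(
        per_offset=per_offset,
        pairwise_ww=pairwise,
        consecutive_diff_deg=consecutive,
        phase_lag_deg_per_stim=lag,
        phase_lag_test=lag_test,
        per_cell_lags=lags,
        per_cell_lag_median=lag_median,
        per_cell_lag_test=lag_median_test,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# phase as a function of time


@dataclass
class PhaseTimecourse:
    times_s: np.ndarray
    mean_deg: np.ndarray
    angular_sd_deg: np.ndarray
    n_cells: np.ndarray
    valid: np.ndarray  # confidence-limit requirement met


def phase_vs_time(
    phase_sets: list[StimulusPhaseSet],
    window_s: float = 1.5,
    n_steps: int = 50,
    span: tuple[float, float] = (-2.0, 3.5),
    min_spikes_per_cell: int = 1,
    conf: float = 0.95,
) -> PhaseTimecourse:
    """Across-cell circular mean phase in sliding windows over the triplet.

    Windows of ``window_s`` are centred on ``n_steps`` equally spaced times
    spanning ``span`` (0.112 s steps for the defaults) and truncated at the
    span edges. Per step, each cell contributes the circular mean of its
    spike phases inside the window; the across-cell mean is flagged invalid
    where the standard confidence-limit requirement for a mean direction
    fails.
    """
    centers = np.linspace(span[0], span[1], n_steps)
    cell_data = []
    for ps in phase_sets:
        times = np.concatenate(
            [ps.offsets[o].times_rel_s for o in ps.offsets]
        )
        phases = np.concatenate([ps.offsets[o].phases_deg for o in ps.offsets])
        cell_data.append((times, phases))

    mean = np.full(n_steps, np.nan)
    sd = np.full(n_steps, np.nan)
    ncells = np.zeros(n_steps, dtype=int)
    valid = np.zeros(n_steps, dtype=bool)
    for i, c in enumerate(centers):
        lo = max(span[0], c - window_s / 2)
        hi = min(span[1], c + window_s / 2)
        cm_list = []
        for times, phases in cell_data:
            sel = (times >= lo) & (times < hi)
            if np.sum(sel) >= min_spikes_per_cell:
                cm_list.append(circ_mean(phases[sel]).mean_deg)
        if len(cm_list) >= 2:
            cm = circ_mean(np.array(cm_list))
            mean[i] = cm.mean_deg
            sd[i] = cm.angular_sd_deg
            ncells[i] = cm.n
            valid[i] = mean_ci_valid(cm.n, cm.resultant, conf)
    return PhaseTimecourse(times_s=centers, mean_deg=mean, angular_sd_deg=sd, n_cells=ncells, valid=valid)


# ---------------------------------------------------------------------------
# controls


def match_spike_counts(phase_set: StimulusPhaseSet) -> tuple[StimulusPhaseSet, np.ndarray]:
    """Keep only iterations where preceding and following spike counts differ
    by at most one spike; returns the restricted set and the kept indices."""
    c_prec = phase_set.counts_per_iteration(-1)
    c_foll = phase_set.counts_per_iteration(+1)
    keep = np.flatnonzero(np.abs(c_prec - c_foll) <= 1)
    if keep.size == 0:
        raise EmptyResultError(
            f"unit {phase_set.unit_id}: no iterations survive spike-count matching"
        )
    return phase_set.restricted(keep), keep


@dataclass
class ITCMap:
    """Inter-trial coherence per stimulus type on a (frequency x time) grid."""

    freqs_hz: np.ndarray
    times_s: np.ndarray
    itc: dict[str, np.ndarray]  # each (n_freqs, n_times), values in [0, 1]
    n_trials: int

    def theta_peak_time(self, band: tuple[float, float] = (4.0, 8.0)) -> float:
        """Latency of the maximal theta-band ITC, averaged over stimulus types."""
        rows = (self.freqs_hz >= band[0]) & (self.freqs_hz <= band[1])
        mean_map = np.mean([m[rows].mean(axis=0) for m in self.itc.values()], axis=0)
        return float(self.times_s[np.argmax(mean_map)])


def inter_trial_coherence(
    lfp: LFPChannel,
    events_by_type: dict[str, np.ndarray],
    seed: int | np.random.Generator | None = None,
    freqs_hz: np.ndarray | None = None,
    times_s: np.ndarray | None = None,
    cycles: float = 2.0,
    min_trials: int = 5,
) -> ITCMap:
    """Inter-trial coherence around stimulus onsets.

    For each frequency a Hanning-tapered window of ``cycles / f`` seconds
    slides over −0.5..1.5 s in 50 ms steps; the ITC at each (f, t) is the
    magnitude of the trial average of the amplitude-normalised complex
    coefficients, between 0 (no phase locking) and 1 (perfect phase
    locking). Trial counts are equalised across stimulus types by seeded
    random subsampling.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if freqs_hz is None:
        freqs_hz = np.logspace(np.log10(1.7), np.log10(98.7), 32)
    if times_s is None:
        times_s = np.arange(-0.5, 1.5 + 1e-9, 0.05)
    x = np.asarray(lfp.samples_uv, dtype=float)
    fs = lfp.fs_hz

    counts = {k: len(v) for k, v in events_by_type.items()}
    n_eq = min(counts.values())
    if n_eq < min_trials:
        raise InsufficientDataError(f"need >= {min_trials} trials per type, got {counts}")
    chosen = {
        k: np.sort(rng.choice(len(v), size=n_eq, replace=False))
        for k, v in events_by_type.items()
    }

    itc: dict[str, np.ndarray] = {}
    for label, onsets in events_by_type.items():
        onsets = np.asarray(onsets, dtype=float)[chosen[label]]
        out = np.zeros((freqs_hz.size, times_s.size))
        for fi, f in enumerate(freqs_hz):
            w = max(4, int(round(cycles / f * fs)))
            taper = np.hanning(w)
            tau = (np.arange(w) - w / 2) / fs
            carrier = taper * np.exp(-2j * np.pi * f * tau)
            centers = (
                np.round((onsets[:, None] + times_s[None, :]) * fs).astype(int) - w // 2
            )
            valid = (centers >= 0) & (centers + w <= x.size)
            coef = np.zeros(centers.shape, dtype=complex)
            starts = centers[valid]
            seg = x[starts[:, None] + np.arange(w)[None, :]]
            coef[valid] = seg @ carrier
            mag = np.abs(coef)
            unit = np.where(mag > 0, coef / np.where(mag > 0, mag, 1.0), 0.0)
            nv = valid.sum(axis=0)
            with np.errstate(invalid="ignore"):
                out[fi] = np.abs(unit.sum(axis=0) / np.maximum(nv, 1))
            out[fi, nv == 0] = np.nan
        itc[label] = out
    return ITCMap(freqs_hz=freqs_hz, times_s=times_s, itc=itc, n_trials=n_eq)


def remove_phase_reset_spikes(
    phase_set: StimulusPhaseSet,
    itc_map: ITCMap,
    removal_window_s: float = 0.2,
    theta_band: tuple[float, float] = (4.0, 8.0),
) -> tuple[StimulusPhaseSet, dict]:
    """Drop spikes around the latency of maximal theta phase reset.

    Spikes within ``removal_window_s`` (centred) of the theta-band ITC peak
    latency, measured within each stimulus trial, are excluded; phase
    statistics can then be recomputed on the remainder.
    """
    t_peak = itc_map.theta_peak_time(theta_band)
    half = removal_window_s / 2.0
    new: dict[int, OffsetPhases] = {}
    n_before = n_removed = 0
    for off, op in phase_set.offsets.items():
        within_trial = op.times_rel_s - off * phase_set.trial_dur_s
        keep = ~((within_trial >= t_peak - half) & (within_trial < t_peak + half))
        n_before += op.n
        n_removed += int(np.sum(~keep))
        new[off] = OffsetPhases(
            op.phases_deg[keep], op.times_rel_s[keep], op.iteration[keep], op.envelope[keep]
        )
    info = {
        "itc_peak_time_s": t_peak,
        "n_spikes_before": n_before,
        "n_spikes_removed": n_removed,
        "evaluable": n_removed < n_before,
    }
    if n_before > 0 and n_removed == n_before:
        info["flag"] = "all spikes fell in the removal window"
    return (
        StimulusPhaseSet(
            phase_set.unit_id,
            phase_set.band_label,
            new,
            phase_set.included_iterations,
            phase_set.trial_dur_s,
        ),
        info,
    )


def theta_power_median_split(
    phase_set: StimulusPhaseSet, envelope_median: float
) -> dict[str, StimulusPhaseSet | list[str]]:
    """Split a cell's spikes into low/high theta-power halves.

    Each spike is labelled by whether the theta envelope at spike time is
    below/at or above the session median envelope.
    """
    flags: list[str] = []
    halves: dict[str, dict[int, OffsetPhases]] = {"low": {}, "high": {}}
    n_low = n_high = 0
    for off, op in phase_set.offsets.items():
        is_high = op.envelope > envelope_median
        for label, sel in (("low", ~is_high), ("high", is_high)):
            halves[label][off] = OffsetPhases(
                op.phases_deg[sel], op.times_rel_s[sel], op.iteration[sel], op.envelope[sel]
            )
        n_low += int(np.sum(~is_high))
        n_high += int(np.sum(is_high))
    if n_low == 0 or n_high == 0:
        flags.append("degenerate split: all spikes in one half")
    out: dict[str, StimulusPhaseSet | list[str]] = {
        label: StimulusPhaseSet(
            phase_set.unit_id,
            phase_set.band_label,
            halves[label],
            phase_set.included_iterations,
            phase_set.trial_dur_s,
        )
        for label in ("low", "high")
    }
    out["flags"] = flags
    return out


@dataclass
class SpikeLFPFrequency:
    spike_peak_hz: float | None
    lfp_theta_peak_hz: float | None
    spike_peak_db: float
    flags: list[str]


def spike_vs_lfp_frequency(
    spike_train: SpikeTrain,
    lfp: LFPChannel,
    search_band: tuple[float, float] = (3.0, 10.0),
    min_spikes: int = 200,
    min_peak_db: float = 2.0,
) -> SpikeLFPFrequency:
    """Compare the rhythmic frequency of spiking with the LFP theta peak.

    The spike train is binned at the LFP rate, its epoch spectrum expressed
    in dB relative to its own power-law fit, and the peak within the search
    band compared with the LFP theta peak. Phase precession predicts a spike
    rhythm slightly faster than the LFP theta oscillation. Peaks below
    ``min_peak_db`` are flagged as not detectable.
    """
    if spike_train.n_spikes < min_spikes:
        raise InsufficientDataError(
            f"need >= {min_spikes} spikes, got {spike_train.n_spikes}"
        )
    flags: list[str] = []
    fs = lfp.fs_hz
    n = np.asarray(lfp.samples_uv).size
    binned = np.bincount(
        np.clip(np.round(spike_train.spike_times_s * fs).astype(int), 0, n - 1), minlength=n
    ).astype(float)
    binned -= binned.mean()
    spike_fit = power_spectrum_rel_1f([LFPChannel("spikes", fs, binned)])
    sel = (spike_fit.freqs_hz >= search_band[0]) & (spike_fit.freqs_hz <= search_band[1])
    idx = np.flatnonzero(sel)
    best = idx[np.argmax(spike_fit.db_ratio[idx])]
    spike_peak_db = float(spike_fit.db_ratio[best])
    spike_peak = float(spike_fit.freqs_hz[best])
    if spike_peak_db < min_peak_db:
        flags.append("no clear rhythmic peak in the spike spectrum")
        spike_peak = None

    lfp_fit = power_spectrum_rel_1f([lfp])
    lsel = (lfp_fit.freqs_hz >= search_band[0]) & (lfp_fit.freqs_hz <= search_band[1])
    lidx = np.flatnonzero(lsel)
    lbest = lidx[np.argmax(lfp_fit.db_ratio[lidx])]
    lfp_peak = float(lfp_fit.freqs_hz[lbest])
    if lfp_fit.db_ratio[lbest] < min_peak_db:
        flags.append("no clear theta peak in the LFP spectrum")
        lfp_peak = None
    return SpikeLFPFrequency(
        spike_peak_hz=spike_peak,
        lfp_theta_peak_hz=lfp_peak,
        spike_peak_db=spike_peak_db,
        flags=flags,
    )


def subgroup_summary(
    phase_sets: list[StimulusPhaseSet],
    grouping_fn: Callable[[StimulusPhaseSet], str],
    min_cells: int = 10,
    **summary_kwargs,
) -> tuple[dict[str, PopulationPhaseSummary], dict[str, int]]:
    """Population summary per subgroup of cells; undersized groups skipped."""
    groups: dict[str, list[StimulusPhaseSet]] = {}
    for ps in phase_sets:
        groups.setdefault(str(grouping_fn(ps)), []).append(ps)
    summaries: dict[str, PopulationPhaseSummary] = {}
    skipped: dict[str, int] = {}
    for label, members in sorted(groups.items()):
        if len(members) < min_cells:
            skipped[label] = len(members)
            continue
        summaries[label] = population_phase_summary(members, **summary_kwargs)
    return summaries, skipped


def cycles_spanned(
    trial_dur_s: float = 2.0, n_trials: float = 2.0, freq_hz: float = 6.0
) -> float:
    """Number of oscillation cycles spanned by a stretch of sequence trials.

    For the defaults (2 s per stimulus, a two-stimulus activity span, 6 Hz
    theta) this is 24 cycles — the theta 'distance' over which the phase
    advance unfolds, far more cycles than a rodent place-field traversal.
    """
    return trial_dur_s * n_trials * freq_hz


# ---------------------------------------------------------------------------
# display histogram


@dataclass
class PhaseHistogram:
    bin_edges_deg: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray  # display copy only; statistics never use it


def phase_histogram(
    phases_deg: np.ndarray, n_bins: int = 15, smooth_bins: int = 2
) -> PhaseHistogram:
    """Circular histogram with a smoothed display copy.

    Smoothing is a circular moving average over ``+/- smooth_bins`` bins and
    exists purely for plotting; every statistic in this module operates on
    raw phases.
    """
    p = wrap_deg(np.asarray(phases_deg, dtype=float))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(p, bins=edges)
    counts = counts.astype(float)
    if smooth_bins > 0:
        kernel = np.ones(2 * smooth_bins + 1) / (2 * smooth_bins + 1)
        padded = np.concatenate([counts[-smooth_bins:], counts, counts[:smooth_bins]])
        smoothed = np.convolve(padded, kernel, mode="valid")
    else:
        smoothed = counts.copy()
    return PhaseHistogram(bin_edges_deg=edges, counts=counts, smoothed=smoothed)
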