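"""Synthetic sequence-learning sessions with controlled spike-LFP structure.

The generator emulates the statistical structure the analysis pipeline
assumes, so that every downstream stage can be exercised and validated
without real recordings:

* a sequence of ``n_stimuli`` images shown for 1.5 s with a 0.5 s ISI,
  repeated 60 times, with 20% probe trials;
* LFP channels with a ``1/f^alpha`` aperiodic background (alpha = 1.98 by
  default) plus band-limited theta (4-8 Hz) and beta (10-18 Hz) components,
  optionally fragmented into alternating low/high-power bouts;
* units with a preferred stimulus, elevated firing for its sequence
  neighbours, optional anticipatory ramping during the preceding trial, and
  von Mises spike-phase coupling to the theta component whose per-offset
  population mean phases default to 233 deg (preceding), 181 deg (preferred)
  and 117 deg (following), dispersed across cells with SDs 35/16/9 deg.

Spikes are drawn by thinning a homogeneous Poisson process at the
instantaneous modulated rate; a fixed seed makes the whole session
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import signal
from scipy.special import i0

from .errors import ThetaseqError
from .session import LFPChannel, SequenceEvent, Session, SpikeTrain
from .spectral import PhaseSeries

# population-level phase-coupling defaults (degrees) and across-cell SDs,
# offsets relative to the preferred stimulus
DEFAULT_PHASE_MU_DEG = {-1: 233.0, 0: 181.0, +1: 117.0}
DEFAULT_PHASE_SD_DEG = {-1: 35.0, 0: 16.0, +1: 9.0}
DEFAULT_RATE_BY_OFFSET = {-1: 1.5, 0: 3.0, +1: 1.5}

THETA_BAND_HZ = (4.0, 8.0)
BETA_BAND_HZ = (10.0, 18.0)


@dataclass
class OscillationSpec:
    """One band-limited oscillatory LFP component.

    ``amplitude_uv`` is the target RMS of the component; ``bandwidth_hz`` = 0
    produces a pure sinusoid at ``center_hz``, otherwise narrow-band filtered
    noise over ``center_hz +/- bandwidth_hz / 2``. ``fragmentation``
    (``{"bout_rate_hz": .., "bout_dur_s": .., "low_gain": ..}``) switches the
    component between high-power bouts and a low-power floor.
    """

    band_label: str
    center_hz: float
    amplitude_uv: float
    bandwidth_hz: float = 0.0
    fragmentation: dict | None = None

    def __post_init__(self) -> None:
        if self.center_hz <= 0:
            raise ThetaseqError("oscillation center_hz must be > 0")
        if self.amplitude_uv < 0:
            raise ThetaseqError("oscillation amplitude must be >= 0")


@dataclass
class CellSpec:
    """Generative description of one unit.

    Firing rate is ``base_rate_hz * rate_by_offset[offset]`` during the 2 s
    trial at each signed sequence offset from the preferred stimulus
    (unlisted offsets multiply by 1), further modulated by a von Mises factor
    ``exp(kappa cos(theta - mu_offset)) / I0(kappa)`` of the theta phase for
    offsets listed in ``phase_mu_by_offset`` (time-average 1, so mean rates
    are preserved). ``anticipatory_ramp`` shapes the preceding-trial rate as
    a linear ramp (mean-preserving), emulating anticipation of the preferred
    stimulus.
    """

    unit_id: str
    channel_id: str
    preferred_stimulus: int
    base_rate_hz: float = 0.8
    rate_by_offset: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RATE_BY_OFFSET)
    )
    anticipatory_ramp: bool = True
    ramp_gain: float = 0.5
    phase_mu_by_offset: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_MU_DEG)
    )
    kappa: float = 2.0
    cross_cell_phase_sd_deg: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_SD_DEG)
    )

    def __post_init__(self) -> None:
        if self.base_rate_hz < 0 or any(m < 0 for m in self.rate_by_offset.values()):
            raise ThetaseqError("firing rates must be >= 0")
        if self.kappa < 0:
            raise ThetaseqError("kappa must be >= 0")


@dataclass
class GeneratorConfig:
    """Full description of one synthetic session."""

    n_stimuli: int = 6
    n_iterations: int = 60
    stim_dur_s: float = 1.5
    isi_s: float = 0.5
    probe_rate: float = 0.2
    deterministic_probes: bool = False
    fs_hz: float = 1000.0
    one_over_f_alpha: float = 1.98
    background_rms_uv: float = 15.0  # RMS of the aperiodic part within 1-40 Hz
    oscillations: list[OscillationSpec] = field(default_factory=list)
    cells: list[CellSpec] = field(default_factory=list)
    seed: int = 0

    @property
    def trial_dur_s(self) -> float:
        return self.stim_dur_s + self.isi_s

    @property
    def n_events(self) -> int:
        return self.n_stimuli * self.n_iterations

    @property
    def duration_s(self) -> float:
        # one extra second of LFP so edge spikes keep full phase context
        return self.n_events * self.trial_dur_s + 1.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["oscillations"] = [OscillationSpec(**o) for o in d.get("oscillations", [])]
        cells = []
        for c in d.get("cells", []):
            c = dict(c)
            for key in ("rate_by_offset", "phase_mu_by_offset", "cross_cell_phase_sd_deg"):
                if key in c and c[key] is not None:
                    c[key] = {int(k): float(v) for k, v in c[key].items()}
            cells.append(CellSpec(**c))
        d["cells"] = cells
        return cls(**d)


def default_config(
    n_cells: int,
    seed: int = 0,
    n_channels: int = 4,
    kappa: float = 2.0,
    fragmented_theta: bool = True,
) -> GeneratorConfig:
    """Study-condition defaults: 6 stimuli x 60 iterations, 2 s trials, 20%
    probes, alpha = 1.98 background with theta and beta components, and cells
    whose per-offset mean phases are drawn around 233/181/117 deg with
    across-cell SDs 35/16/9 deg.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC311]))
    cells = []
    for i in range(n_cells):
        mus = {
            off: float((DEFAULT_PHASE_MU_DEG[off] + rng.normal(0.0, DEFAULT_PHASE_SD_DEG[off])) % 360.0)
            for off in DEFAULT_PHASE_MU_DEG
        }
        cells.append(
            CellSpec(
                unit_id=f"u{i:04d}",
                channel_id=f"ch{i % n_channels}",
                preferred_stimulus=i % 6,
                phase_mu_by_offset=mus,
                kappa=kappa,
            )
        )
    oscillations = [
        OscillationSpec(
            band_label="theta",
            center_hz=6.0,
            amplitude_uv=10.0,
            bandwidth_hz=4.0,
            fragmentation=(
                {"bout_rate_hz": 0.15, "bout_dur_s": 3.0, "low_gain": 0.45}
                if fragmented_theta
                else None
            ),
        ),
        OscillationSpec(band_label="beta", center_hz=14.0, amplitude_uv=6.0, bandwidth_hz=8.0),
    ]
    return GeneratorConfig(oscillations=oscillations, cells=cells, seed=int(seed))


# ---------------------------------------------------------------------------
# LFP synthesis


def _one_over_f_noise(n: int, fs: float, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise spectrally shaped to power ~ 1/f^alpha, unit-normalised
    so that the RMS of its 1-40 Hz content is 1."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    sel = (freqs >= 1.0) & (freqs <= 40.0)
    band_power = np.sum(np.abs(np.fft.rfft(x))[sel] ** 2) * 2.0 / n**2
    return x / np.sqrt(band_power) if band_power > 0 else x


def _fragmentation_envelope(
    n: int, fs: float, frag: dict, rng: np.random.Generator
) -> np.ndarray:
    """Envelope alternating between high-power bouts and a low-power floor."""
    low = float(frag.get("low_gain", 0.45))
    rate = float(frag["bout_rate_hz"])
    dur = float(frag["bout_dur_s"])
    env = np.full(n, low)
    t = 0.0
    duration = n / fs
    while t < duration:
        t += rng.exponential(1.0 / rate)
        i0_, i1 = int(t * fs), int((t + dur) * fs)
        env[i0_:min(i1, n)] = 1.0
        t += dur
    # light smoothing so bout edges are not step discontinuities
    win = int(0.1 * fs)
    if win > 1:
        env = np.convolve(env, np.ones(win) / win, mode="same")
    return env


def _oscillation_component(
    spec: OscillationSpec, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    if spec.amplitude_uv == 0:
        return np.zeros(n)
    if spec.center_hz + spec.bandwidth_hz / 2 >= fs / 2:
        raise ThetaseqError(
            f"oscillation {spec.band_label!r} at {spec.center_hz} Hz requires fs > "
            f"{2 * (spec.center_hz + spec.bandwidth_hz / 2)} Hz"
        )
    if spec.bandwidth_hz == 0:
        t = np.arange(n) / fs
        phi = rng.uniform(0, 2 * np.pi)
        x = np.sqrt(2.0) * np.cos(2 * np.pi * spec.center_hz * t + phi)
    else:
        lo = max(0.1, spec.center_hz - spec.bandwidth_hz / 2)
        hi = spec.center_hz + spec.bandwidth_hz / 2
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, rng.standard_normal(n))
        x = x / np.std(x)
    if spec.fragmentation:
        x = x * _fragmentation_envelope(n, fs, spec.fragmentation, rng)
        x = x / np.std(x)
    return spec.amplitude_uv * x


def _synth_channel(
    config: GeneratorConfig, duration_s: float, rng: np.random.Generator, channel_id: str
) -> tuple[LFPChannel, dict[str, np.ndarray]]:
    n = int(round(duration_s * config.fs_hz))
    trace = config.background_rms_uv * _one_over_f_noise(
        n, config.fs_hz, config.one_over_f_alpha, rng
    )
    components: dict[str, np.ndarray] = {}
    for osc in config.oscillations:
        comp = _oscillation_component(osc, n, config.fs_hz, rng)
        components[osc.band_label] = comp
        trace = trace + comp
    return LFPChannel(channel_id=channel_id, fs_hz=config.fs_hz, samples_uv=trace), components


def generate_lfp(
    config: GeneratorConfig,
    seed: int | None = None,
    duration_s: float | None = None,
    channel_id: str = "ch0",
) -> LFPChannel:
    """Synthesise one LFP channel: 1/f^alpha background plus the configured
    oscillatory components."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    dur = config.duration_s if duration_s is None else duration_s
    channel, _ = _synth_channel(config, dur, rng, channel_id)
    return channel


def _component_phase(component: np.ndarray, fs: float, label: str) -> PhaseSeries:
    analytic = signal.hilbert(component)
    return PhaseSeries(
        channel_id="",
        band_hz=(0.0, 0.0),
        label=label,
        fs_hz=fs,
        phase_deg=np.degrees(np.angle(analytic)),
        envelope=np.abs(analytic),
    )


# ---------------------------------------------------------------------------
# spike synthesis


def _signed_offset(position: int, preferred_position: int, n_stimuli: int) -> int:
    raw = (position - preferred_position) % n_stimuli
    return raw if raw <= n_stimuli // 2 else raw - n_stimuli


def generate_spikes(
    cell_spec: CellSpec,
    phase_series: PhaseSeries,
    events: list[SequenceEvent],
    seed: int | np.random.Generator,
    trial_dur_s: float = 2.0,
    n_stimuli: int | None = None,
) -> SpikeTrain:
    """Draw one unit's spikes by thinning a homogeneous Poisson process.

    The instantaneous rate is ``base * rate_by_offset * ramp * vonMises``;
    outside events (and during probe trials, where no stimulus is shown) the
    rate falls back to the unmodulated, uncoupled baseline. The coupling
    phase is taken from ``phase_series`` (nearest sample).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if cell_spec.kappa < 0:
        raise ThetaseqError("kappa must be >= 0")
    n_stim = n_stimuli if n_stimuli is not None else 1 + max(e.stimulus_id for e in events)
    order: dict[int, int] = {}
    for e in events:
        order.setdefault(e.position, e.stimulus_id)
    pref_position = next(p for p, s in order.items() if s == cell_spec.preferred_stimulus)

    onsets = np.array([e.onset_s for e in events])
    probes = np.array([e.is_probe for e in events])
    offsets = np.array(
        [_signed_offset(e.position, pref_position, n_stim) for e in events]
    )
    mults = np.array([cell_spec.rate_by_offset.get(int(o), 1.0) for o in offsets])
    mults[probes] = 1.0
    coupled = np.array(
        [(int(o) in cell_spec.phase_mu_by_offset) and not pr for o, pr in zip(offsets, probes)]
    )
    mus_deg = np.array(
        [cell_spec.phase_mu_by_offset.get(int(o), 0.0) for o in offsets]
    )

    duration = phase_series.duration_s
    kappa = cell_spec.kappa
    vm_max = float(np.exp(kappa) / i0(kappa))
    ramp_hi = 1.0 + cell_spec.ramp_gain if cell_spec.anticipatory_ramp else 1.0
    lam_max = cell_spec.base_rate_hz * max(1.0, mults.max(initial=1.0)) * vm_max * ramp_hi
    if lam_max == 0:
        return SpikeTrain(cell_spec.unit_id, cell_spec.channel_id, np.empty(0), "single")

    n_cand = rng.poisson(lam_max * duration)
    t = np.sort(rng.uniform(0.0, duration, n_cand))

    ev = np.searchsorted(onsets, t, side="right") - 1
    in_event = (ev >= 0) & (t < onsets[np.clip(ev, 0, None)] + trial_dur_s)
    evc = np.clip(ev, 0, None)

    rate = np.full(t.size, cell_spec.base_rate_hz)
    rate[in_event] *= mults[evc[in_event]]
    if cell_spec.anticipatory_ramp:
        prec = in_event & (offsets[evc] == -1) & ~probes[evc]
        frac = (t[prec] - onsets[evc[prec]]) / trial_dur_s
        rate[prec] *= 1.0 + cell_spec.ramp_gain * (2.0 * frac - 1.0)
    cpl = in_event & coupled[evc]
    if kappa > 0 and cpl.any():
        idx = np.clip(np.round(t[cpl] * phase_series.fs_hz).astype(int), 0, phase_series.phase_deg.size - 1)
        theta = np.radians(phase_series.phase_deg[idx])
        mu = np.radians(mus_deg[evc[cpl]])
        rate[cpl] *= np.exp(kappa * np.cos(theta - mu)) / i0(kappa)

    accept = rng.uniform(0.0, 1.0, t.size) < rate / lam_max
    return SpikeTrain(
        unit_id=cell_spec.unit_id,
        channel_id=cell_spec.channel_id,
        spike_times_s=t[accept],
        unit_class="single",
    )


# ---------------------------------------------------------------------------
# full session


def _make_events(config: GeneratorConfig, rng: np.random.Generator) -> list[SequenceEvent]:
    events = []
    k = 0
    total = config.n_events
    if config.deterministic_probes:
        step = int(round(1.0 / config.probe_rate)) if config.probe_rate > 0 else 0
        probe_flags = [step > 0 and (i % step == step - 1) for i in range(total)]
    else:
        probe_flags = list(rng.uniform(size=total) < config.probe_rate)
    for it in range(config.n_iterations):
        for pos in range(config.n_stimuli):
            onset = k * config.trial_dur_s
            events.append(
                SequenceEvent(
                    iteration_index=it,
                    position=pos,
                    stimulus_id=pos,
                    onset_s=onset,
                    offset_s=onset + config.stim_dur_s,
                    is_probe=bool(probe_flags[k]),
                )
            )
            k += 1
    return events


def generate_session(config: GeneratorConfig) -> Session:
    """Generate a complete synthetic session (events, LFP, spikes).

    All randomness derives from ``config.seed`` through named substreams, so
    a fixed seed yields a bit-identical session.
    """
    ss = np.random.SeedSequence(config.seed)
    ev_seed, lfp_seed, cell_seed = ss.spawn(3)
    events = _make_events(config, np.random.default_rng(ev_seed))

    channel_ids = sorted({c.channel_id for c in config.cells}) or ["ch0"]
    duration = config.duration_s
    lfp: list[LFPChannel] = []
    theta_phase: dict[str, PhaseSeries] = {}
    for cid, child in zip(channel_ids, lfp_seed.spawn(len(channel_ids))):
        channel, components = _synth_channel(
            config, duration, np.random.default_rng(child), cid
        )
        lfp.append(channel)
        if "theta" in components:
            theta_phase[cid] = _component_phase(components["theta"], config.fs_hz, "theta")
        else:  # uncoupled fallback: uniform drifting phase
            theta_phase[cid] = _component_phase(
                np.cos(2 * np.pi * 6.0 * np.arange(int(duration * config.fs_hz)) / config.fs_hz),
                config.fs_hz,
                "theta",
            )

    spikes = []
    for cell, child in zip(config.cells, cell_seed.spawn(len(config.cells))):
        spikes.append(
            generate_spikes(
                cell,
                theta_phase[cell.channel_id],
                events,
                np.random.default_rng(child),
                trial_dur_s=config.trial_dur_s,
                n_stimuli=config.n_stimuli,
            )
        )

    session = Session(
        session_id=f"synthetic-seed{config.seed}",
        n_stimuli=config.n_stimuli,
        events=events,
        spikes=spikes,
        lfp=lfp,
        unit_to_lfp={c.unit_id: c.channel_id for c in config.cells},
    )
    session.validate()
    return session
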