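"""LFP preprocessing, 1/f^alpha-relative power spectra, spike-triggered power,
and band-limited phase extraction.

Spectra are expressed relative to an aperiodic ``c / f^alpha`` background:
band-limited oscillations (theta 4-8 Hz, beta 10-18 Hz) appear as positive
deviations of the dB ratio ``10 log10(power / fit)``.

Phase convention: 0 deg at the peak of the band-passed oscillation,
+/-180 deg at the trough (angle of the analytic signal of a cosine).
Band-pass filtering is zero-phase (second-order Butterworth applied
forward-backward) so spike phases carry no filter delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal, stats

from .errors import EmptyResultError, InsufficientDataError, SessionValidationError, ThetaseqError
from .session import LFPChannel, SpikeTrain

TARGET_FS_HZ = 1000.0
NOTCH_BANDS_HZ = ((45.0, 55.0), (98.0, 102.0))
SPECTRUM_FMIN_HZ = 1.0
SPECTRUM_FMAX_HZ = 40.0
EPOCH_S = 2.0  # 2 s Hanning epochs -> 0.5 Hz resolution -> 79 bins in 1-40 Hz


@dataclass
class SpectralFit:
    """Power spectrum with its aperiodic 1/f^alpha fit.

    ``power`` and ``db_ratio`` are averages across the input channels (or
    spike-centred segments); ``significant_mask`` marks frequencies whose
    dB ratio differs from 0 by a Bonferroni-corrected t-test across the
    averaging dimension.
    """

    freqs_hz: np.ndarray
    power: np.ndarray
    alpha: float
    scale: float
    db_ratio: np.ndarray
    significant_mask: np.ndarray

    def peak_frequency(self, fmin: float | None = None, fmax: float | None = None) -> float:
        """Frequency of the maximal dB ratio within [fmin, fmax]."""
        sel = np.ones_like(self.freqs_hz, dtype=bool)
        if fmin is not None:
            sel &= self.freqs_hz >= fmin
        if fmax is not None:
            sel &= self.freqs_hz <= fmax
        if not sel.any():
            raise ValueError("empty frequency selection")
        idx = np.flatnonzero(sel)
        return float(self.freqs_hz[idx[np.argmax(self.db_ratio[idx])]])


@dataclass
class PhaseSeries:
    """Instantaneous phase and amplitude envelope of one LFP band."""

    channel_id: str
    band_hz: tuple[float, float]
    label: str
    fs_hz: float
    phase_deg: np.ndarray  # (-180, 180], 0 = oscillation peak
    envelope: np.ndarray  # >= 0

    @property
    def duration_s(self) -> float:
        return self.phase_deg.size / self.fs_hz


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_lfp(raw: LFPChannel) -> LFPChannel:
    """Downsample to 1 kHz and notch-filter line noise (45-55, 98-102 Hz).

    Uses polyphase resampling (built-in anti-alias low-pass) followed by
    zero-phase second-order Butterworth band-stop filters. Traces already at
    or below 1 kHz are notch filtered without resampling (with a warning when
    below).
    """
    x = np.asarray(raw.samples_uv, dtype=float)
    if not np.all(np.isfinite(x)):
        raise SessionValidationError(f"channel {raw.channel_id}: non-finite samples")
    fs = float(raw.fs_hz)
    if fs > TARGET_FS_HZ:
        frac = Fraction(int(round(TARGET_FS_HZ * 1000)), int(round(fs * 1000)))
        x = signal.resample_poly(x, frac.numerator, frac.denominator)
        fs = TARGET_FS_HZ
    elif fs < TARGET_FS_HZ:
        warnings.warn(
            f"channel {raw.channel_id}: fs {fs} Hz < 1000 Hz, downsampling skipped",
            stacklevel=2,
        )
    for lo, hi in NOTCH_BANDS_HZ:
        if hi < fs / 2:
            sos = signal.butter(2, [lo, hi], btype="bandstop", fs=fs, output="sos")
            x = signal.sosfiltfilt(sos, x)
    return LFPChannel(channel_id=raw.channel_id, fs_hz=fs, samples_uv=x)


# ---------------------------------------------------------------------------
# power spectra relative to 1/f^alpha


def fit_one_over_f(freqs_hz: np.ndarray, power: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of ``power = c / f^alpha`` in log-log space.

    Returns ``(alpha, c)``.
    """
    f = np.asarray(freqs_hz, dtype=float)
    p = np.asarray(power, dtype=float)
    if f.size < 5:
        raise InsufficientDataError("need >= 5 frequencies for a 1/f fit")
    if np.any(p <= 0) or np.any(f <= 0):
        raise ThetaseqError("1/f fit requires strictly positive frequencies and power")
    slope, intercept = np.polyfit(np.log10(f), np.log10(p), 1)
    return float(-slope), float(10.0**intercept)


def _epoch_power(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean Hanning-tapered power over consecutive non-overlapping 2 s epochs."""
    n_epoch = int(round(EPOCH_S * fs))
    n_full = x.size // n_epoch
    if n_full < 1:
        raise InsufficientDataError(f"trace shorter than one {EPOCH_S:g} s epoch")
    segs = x[: n_full * n_epoch].reshape(n_full, n_epoch)
    taper = np.hanning(n_epoch)
    spec = np.fft.rfft(segs * taper, axis=1)
    power = (np.abs(spec) ** 2).mean(axis=0)
    freqs = np.fft.rfftfreq(n_epoch, d=1.0 / fs)
    sel = (freqs >= SPECTRUM_FMIN_HZ - 1e-9) & (freqs <= SPECTRUM_FMAX_HZ + 1e-9)
    return freqs[sel], power[sel]


def _fit_and_mask(
    freqs: np.ndarray, per_item_power: np.ndarray, alpha_sig: float = 0.05
) -> SpectralFit:
    """Shared tail: per-item 1/f fits, dB ratios, and t-test significance mask."""
    n_items = per_item_power.shape[0]
    db = np.empty_like(per_item_power)
    alphas = np.empty(n_items)
    scales = np.empty(n_items)
    for i in range(n_items):
        a, c = fit_one_over_f(freqs, per_item_power[i])
        alphas[i] = a
        scales[i] = c
        db[i] = 10.0 * np.log10(per_item_power[i] / (c / freqs**a))
    mean_power = per_item_power.mean(axis=0)
    mean_db = db.mean(axis=0)
    n_freqs = freqs.size
    if n_items >= 2:
        tt = stats.ttest_1samp(db, 0.0, axis=0)
        mask = tt.pvalue * n_freqs < alpha_sig  # Bonferroni across frequencies
    else:
        warnings.warn("fewer than 2 channels: significance mask undefined (all False)", stacklevel=3)
        mask = np.zeros(n_freqs, dtype=bool)
    return SpectralFit(
        freqs_hz=freqs,
        power=mean_power,
        alpha=float(alphas.mean()),
        scale=float(scales.mean()),
        db_ratio=mean_db,
        significant_mask=mask,
    )


def power_spectrum_rel_1f(lfp_set: list[LFPChannel]) -> SpectralFit:
    """Channel-averaged power spectrum expressed in dB relative to a 1/f^alpha fit.

    Each channel is decomposed into consecutive non-overlapping 2 s Hanning
    epochs over the whole trace, giving a 0.5 Hz grid of 79 frequencies in
    1-40 Hz; each channel receives its own aperiodic fit, and per-frequency
    significance is a Bonferroni-corrected one-sample t-test of the dB ratios
    across channels against 0.
    """
    if not lfp_set:
        raise InsufficientDataError("need at least one LFP channel")
    freqs_ref = None
    rows = []
    for ch in lfp_set:
        freqs, power = _epoch_power(np.asarray(ch.samples_uv, dtype=float), ch.fs_hz)
        if freqs_ref is None:
            freqs_ref = freqs
        elif freqs.size != freqs_ref.size or not np.allclose(freqs, freqs_ref):
            raise ThetaseqError("channels have incompatible sampling rates")
        rows.append(power)
    return _fit_and_mask(freqs_ref, np.asarray(rows))


def spike_triggered_power(
    lfp: LFPChannel, spike_train: SpikeTrain, segment_s: float = 1.0
) -> SpectralFit:
    """Average power spectrum of LFP segments centred on each spike.

    Extracts a 1 s Hanning-tapered segment around every spike with full
    context (edge spikes dropped), averages the per-segment power spectra,
    and expresses the result relative to a 1/f^alpha fit. Significance is a
    t-test of per-segment dB ratios (each segment evaluated against the fit
    of the mean spectrum) across segments.
    """
    fs = lfp.fs_hz
    x = np.asarray(lfp.samples_uv, dtype=float)
    half = int(round(segment_s * fs / 2))
    idx = np.round(np.asarray(spike_train.spike_times_s) * fs).astype(int)
    keep = (idx >= half) & (idx + half <= x.size)
    idx = idx[keep]
    if idx.size == 0:
        raise EmptyResultError("no spikes with full LFP context")
    if idx.size < 10:
        raise InsufficientDataError(f"need >= 10 usable spikes, got {idx.size}")
    n_seg = 2 * half
    segs = np.stack([x[i - half : i + half] for i in idx])
    taper = np.hanning(n_seg)
    spec = np.fft.rfft(segs * taper, axis=1)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n_seg, d=1.0 / fs)
    sel = (freqs >= SPECTRUM_FMIN_HZ - 1e-9) & (freqs <= SPECTRUM_FMAX_HZ + 1e-9)
    freqs, power = freqs[sel], power[:, sel]
    mean_power = power.mean(axis=0)
    alpha, scale = fit_one_over_f(freqs, mean_power)
    fit = scale / freqs**alpha
    db_ratio = 10.0 * np.log10(mean_power / fit)
    per_seg_db = 10.0 * np.log10(np.maximum(power, 1e-300) / fit)
    tt = stats.ttest_1samp(per_seg_db, 0.0, axis=0)
    mask = tt.pvalue * freqs.size < 0.05
    return SpectralFit(
        freqs_hz=freqs,
        power=mean_power,
        alpha=alpha,
        scale=scale,
        db_ratio=db_ratio,
        significant_mask=mask,
    )


# ---------------------------------------------------------------------------
# band-limited phase


def bandpass_phase(
    lfp: LFPChannel, band_hz: tuple[float, float], label: str | None = None
) -> PhaseSeries:
    """Band-pass the trace and return analytic-signal phase and envelope.

    Second-order Butterworth band-pass applied forward-backward (zero phase),
    then the Hilbert transform: phase 0 deg at the oscillation peak, +/-180 at
    the trough; envelope = magnitude of the analytic signal.
    """
    lo, hi = band_hz
    if not (0 < lo < hi < lfp.fs_hz / 2):
        raise ValueError(f"band {band_hz} invalid for fs {lfp.fs_hz}")
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=lfp.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, np.asarray(lfp.samples_uv, dtype=float))
    analytic = signal.hilbert(filtered)
    phase = np.degrees(np.angle(analytic))
    phase = np.where(phase == -180.0, 180.0, phase)
    return PhaseSeries(
        channel_id=lfp.channel_id,
        band_hz=(float(lo), float(hi)),
        label=label or f"{lo:g}-{hi:g}Hz",
        fs_hz=lfp.fs_hz,
        phase_deg=phase,
        envelope=np.abs(analytic),
    )


def spike_phase_assignment(
    phase_series: PhaseSeries, spike_train: SpikeTrain
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-spike phase and envelope by nearest-sample lookup.

    Returns ``(times_s, phases_deg, envelopes, n_dropped)``; spikes outside
    the trace span are dropped and counted.
    """
    t = np.asarray(spike_train.spike_times_s, dtype=float)
    idx = np.round(t * phase_series.fs_hz).astype(int)
    keep = (idx >= 0) & (idx < phase_series.phase_deg.size)
    n_dropped = int(np.sum(~keep))
    idx = idx[keep]
    return (
        t[keep],
        phase_series.phase_deg[idx],
        phase_series.envelope[idx],
        n_dropped,
    )
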