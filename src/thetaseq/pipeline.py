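"""End-to-end orchestration: simulate (or load) -> spectra -> tuning -> phase
coding -> controls, in one reproducible JSON report.

All randomness flows from a single master seed through named substreams
(simulation, consistency splits, ITC subsampling), so the same configuration
always produces a byte-identical report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import phase as ph
from .io import read_session_dir
from .session import Session
from .spectral import bandpass_phase, power_spectrum_rel_1f, preprocess_lfp
from .synth import GeneratorConfig, default_config, generate_session
from .tuning import CellTuning, compute_tuning

DEFAULT_BANDS = {"theta": (4.0, 8.0), "beta": (10.0, 18.0)}
DEFAULT_CONTROLS = {
    "matched_counts": True,
    "phase_reset": True,
    "theta_median_split": True,
    "spike_vs_lfp_frequency": True,
}


@dataclass
class PipelineConfig:
    n_cells: int = 452
    seed: int = 0
    bands: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BANDS))
    response_window: tuple[float, float] = (0.0, 2.0)
    n_consistency_splits: int = 100_000
    alpha: float = 0.05
    bonferroni: int = 3
    min_spikes_lag: int = 5
    controls: dict[str, bool] = field(default_factory=lambda: dict(DEFAULT_CONTROLS))
    session_dir: str | None = None  # analyse an on-disk session instead of simulating
    generator: dict | None = None  # full GeneratorConfig dict (overrides default_config)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        if "response_window" in d:
            d["response_window"] = tuple(d["response_window"])
        return cls(**d)


def _summary_dict(s: ph.PopulationPhaseSummary) -> dict:
    def test_dict(t):
        if t is None:
            return None
        return {
            "statistic": t.statistic,
            "p_value": t.p_value,
            "df": list(t.df) if t.df else None,
            "n_per_group": list(t.n_per_group),
        }

    return {
        "per_offset": {
            str(off): {
                "circ_mean_deg": o.circ_mean_deg,
                "angular_sd_deg": o.angular_sd_deg,
                "n_cells": o.n_cells,
            }
            for off, o in sorted(s.per_offset.items())
        },
        "pairwise_ww": {f"{a}|{b}": test_dict(t) for (a, b), t in sorted(s.pairwise_ww.items())},
        "consecutive_diff_deg": s.consecutive_diff_deg,
        "phase_lag_deg_per_stim": s.phase_lag_deg_per_stim,
        "phase_lag_test": test_dict(s.phase_lag_test),
        "per_cell_lag_median": s.per_cell_lag_median,
        "per_cell_lag_test": test_dict(s.per_cell_lag_test),
        "n_cells_with_lag": len(s.per_cell_lags),
        "flags": s.flags,
    }


def run_pipeline(config: PipelineConfig, session: Session | None = None) -> dict:
    """Run the full analysis and return a JSON-serialisable report."""
    ss = np.random.SeedSequence(config.seed)
    sim_seed, split_seed, itc_seed = ss.spawn(3)

    if session is None:
        if config.session_dir is not None:
            session = read_session_dir(config.session_dir)
        else:
            if config.generator is not None:
                gen = GeneratorConfig.from_dict(config.generator)
            else:
                gen = default_config(config.n_cells, seed=int(sim_seed.generate_state(1)[0] % 2**31))
            session = generate_session(gen)

    report: dict = {
        "params": config.to_dict(),
        "session": {
            "session_id": session.session_id,
            "n_stimuli": session.n_stimuli,
            "n_units": len(session.spikes),
            "n_channels": len(session.lfp),
            "n_events": len(session.events),
            "n_probe_events": int(sum(e.is_probe for e in session.events)),
        },
    }

    # -- spectra ---------------------------------------------------------
    clean = {ch.channel_id: preprocess_lfp(ch) for ch in session.lfp}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spec = power_spectrum_rel_1f(list(clean.values()))
    report["spectra"] = {
        "freqs_hz": spec.freqs_hz.tolist(),
        "db_ratio": spec.db_ratio.tolist(),
        "alpha": spec.alpha,
        "significant_freqs_hz": spec.freqs_hz[spec.significant_mask].tolist(),
    }

    phase_series = {
        label: {cid: bandpass_phase(ch, band, label) for cid, ch in clean.items()}
        for label, band in config.bands.items()
    }

    # -- tuning ----------------------------------------------------------
    split_rng = np.random.default_rng(split_seed)
    tunings: list[CellTuning] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for uid in session.unit_ids:
            tunings.append(
                compute_tuning(
                    session,
                    uid,
                    window=config.response_window,
                    n_splits=config.n_consistency_splits,
                    seed=split_rng,
                    alpha=config.alpha,
                )
            )
    consistent = [t for t in tunings if t.tuning_class != "inconsistent"]
    n_strong = sum(t.tuning_class == "strong" for t in tunings)
    report["tuning"] = {
        "n_units": len(tunings),
        "n_consistent": len(consistent),
        "n_strong": n_strong,
        "strong_fraction_pct": 100.0 * n_strong / max(1, len(consistent)),
        "cells": [asdict(t) for t in tunings],
    }

    # -- phase coding per band ------------------------------------------
    report["bands"] = {}
    theta_sets: list[ph.StimulusPhaseSet] = []
    tuning_by_unit = {t.unit_id: t for t in consistent}
    for label in config.bands:
        sets = []
        for t in consistent:
            series = phase_series[label][session.unit_to_lfp[t.unit_id]]
            try:
                sets.append(
                    ph.phases_by_sequence_offset(
                        session, t, series, window=config.response_window
                    )
                )
            except ph.EmptyResultError:
                continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = ph.population_phase_summary(
                sets, min_spikes_lag=config.min_spikes_lag, bonferroni=config.bonferroni
            )
        tc = ph.phase_vs_time(sets)
        block = {
            "summary": _summary_dict(summary),
            "mean_included_iterations": float(
                np.mean([s.included_iterations for s in sets])
            )
            if sets
            else None,
            "phase_vs_time": {
                "times_s": tc.times_s.tolist(),
                "mean_deg": tc.mean_deg.tolist(),
                "angular_sd_deg": tc.angular_sd_deg.tolist(),
                "valid": tc.valid.astype(bool).tolist(),
            },
            "phase_histograms": {
                str(off): {
                    "counts": ph.phase_histogram(
                        np.concatenate([s.phases(off) for s in sets]) if sets else np.empty(0)
                    ).counts.tolist(),
                    "smoothed": ph.phase_histogram(
                        np.concatenate([s.phases(off) for s in sets]) if sets else np.empty(0)
                    ).smoothed.tolist(),
                }
                for off in (-1, 0, 1)
            },
        }
        report["bands"][label] = block
        if label == "theta":
            theta_sets = sets

    # -- controls (theta band) ------------------------------------------
    controls: dict = {}
    if theta_sets and config.controls.get("matched_counts", False):
        matched = []
        retained = []
        for s in theta_sets:
            try:
                ms, keep = ph.match_spike_counts(s)
            except ph.EmptyResultError:
                continue
            matched.append(ms)
            retained.append(keep.size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            controls["matched_counts"] = {
                "summary": _summary_dict(
                    ph.population_phase_summary(matched, min_spikes_lag=config.min_spikes_lag)
                ),
                "mean_retained_iterations": float(np.mean(retained)) if retained else None,
            }

    if theta_sets and config.controls.get("phase_reset", False):
        itc_rng = np.random.default_rng(itc_seed)
        itc_by_channel = {}
        for cid, ch in clean.items():
            by_type = {}
            for s in range(session.n_stimuli):
                onsets = np.array(
                    [e.onset_s for e in session.events if e.stimulus_id == s and not e.is_probe]
                )
                by_type[str(s)] = onsets
            itc_by_channel[cid] = ph.inter_trial_coherence(ch, by_type, seed=itc_rng)
        filtered = []
        removed = 0
        for s in theta_sets:
            cid = session.unit_to_lfp[s.unit_id]
            fs_, info = ph.remove_phase_reset_spikes(s, itc_by_channel[cid])
            removed += info["n_spikes_removed"]
            if info["evaluable"]:
                filtered.append(fs_)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            controls["phase_reset"] = {
                "summary": _summary_dict(
                    ph.population_phase_summary(filtered, min_spikes_lag=config.min_spikes_lag)
                ),
                "n_spikes_removed": int(removed),
                "itc_theta_peak_time_s": {
                    cid: m.theta_peak_time() for cid, m in itc_by_channel.items()
                },
            }

    if theta_sets and config.controls.get("theta_median_split", False):
        env_median = {
            cid: float(np.median(series.envelope))
            for cid, series in phase_series["theta"].items()
        }
        halves: dict[str, list[ph.StimulusPhaseSet]] = {"low": [], "high": []}
        for s in theta_sets:
            split = ph.theta_power_median_split(s, env_median[session.unit_to_lfp[s.unit_id]])
            for label in ("low", "high"):
                halves[label].append(split[label])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            controls["theta_median_split"] = {
                label: _summary_dict(
                    ph.population_phase_summary(halves[label], min_spikes_lag=config.min_spikes_lag)
                )
                for label in ("low", "high")
            }

    if theta_sets and config.controls.get("spike_vs_lfp_frequency", False):
        spike_peaks, lfp_peaks, peak_dbs, n_eval = [], [], [], 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for t in consistent:
                unit = session.get_unit(t.unit_id)
                if unit.n_spikes < 200:
                    continue
                n_eval += 1
                res = ph.spike_vs_lfp_frequency(unit, clean[session.unit_to_lfp[t.unit_id]])
                peak_dbs.append(res.spike_peak_db)
                if res.spike_peak_hz is not None and res.lfp_theta_peak_hz is not None:
                    spike_peaks.append(res.spike_peak_hz)
                    lfp_peaks.append(res.lfp_theta_peak_hz)
        controls["spike_vs_lfp_frequency"] = {
            "n_cells_evaluated": n_eval,
            "n_cells_with_clear_peaks": len(spike_peaks),
            "mean_spike_peak_db": float(np.mean(peak_dbs)) if peak_dbs else None,
            "mean_spike_peak_hz": float(np.mean(spike_peaks)) if spike_peaks else None,
            "mean_lfp_theta_peak_hz": float(np.mean(lfp_peaks)) if lfp_peaks else None,
        }

    report["controls"] = controls
    report["seeds"] = {
        "master": config.seed,
        "substreams": ["simulation", "consistency_splits", "itc_subsampling"],
    }
    return report


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def make_figures(report: dict, out_dir: str | Path, fmt: str = "png") -> list[Path]:
    """Render the report's display blocks (spectra, phase histograms,
    phase-vs-time) to files. Histogram smoothing is display-only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    spec = report.get("spectra")
    if spec:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(spec["freqs_hz"], spec["db_ratio"], color="0.3")
        ax.axhline(0, color="k", lw=0.5)
        for lo, hi in ((4, 8), (10, 18)):
            ax.axvspan(lo, hi, alpha=0.12, color="tab:blue")
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("power rel. 1/f fit (dB)")
        ax.set_title(f"LFP power (alpha = {spec['alpha']:.2f})")
        fig.tight_layout()
        p = out / f"spectra.{fmt}"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

    colors = {"-1": "tab:blue", "0": "tab:red", "1": "tab:orange"}
    for band, block in report.get("bands", {}).items():
        hists = block.get("phase_histograms", {})
        if hists and any(sum(h["counts"]) > 0 for h in hists.values()):
            fig, ax = plt.subplots(figsize=(5, 3.2))
            edges = np.linspace(-180, 180, 16)
            centers = (edges[:-1] + edges[1:]) / 2
            for off, h in sorted(hists.items(), key=lambda kv: int(kv[0])):
                total = sum(h["smoothed"]) or 1
                ax.plot(centers, np.asarray(h["smoothed"]) / total, color=colors.get(off, "k"),
                        label={"-1": "preceding", "0": "preferred", "1": "following"}.get(off, off))
            ax.set_xlabel("theta phase (deg)")
            ax.set_ylabel("fraction of spikes (smoothed)")
            ax.set_title(f"{band}: spike phase by sequence offset")
            ax.legend(frameon=False, fontsize=8)
            fig.tight_layout()
            p = out / f"phase_hist_{band}.{fmt}"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            paths.append(p)
        tc = block.get("phase_vs_time")
        if tc:
            t = np.asarray(tc["times_s"])
            m = np.asarray(tc["mean_deg"], dtype=float) % 360
            valid = np.asarray(tc["valid"], dtype=bool)
            fig, ax = plt.subplots(figsize=(5, 3.2))
            ax.plot(t[valid], m[valid], "k.")
            for x0 in (-2, 0, 2):
                ax.axvspan(x0, x0 + 1.5, alpha=0.1, color="tab:purple")
            ax.set_xlabel("time from preferred onset (s)")
            ax.set_ylabel("mean phase (deg, 0-360)")
            ax.set_title(f"{band}: phase vs time")
            fig.tight_layout()
            p = out / f"phase_vs_time_{band}.{fmt}"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            paths.append(p)
    return paths
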