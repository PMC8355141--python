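import numpy as np
import pytest

from thetaseq.circstats import circ_mean, wrap_deg
from thetaseq.errors import EmptyResultError, InsufficientDataError
from thetaseq.phase import (
    OffsetPhases,
    StimulusPhaseSet,
    inter_trial_coherence,
    match_spike_counts,
    per_cell_phase_lag,
    phase_histogram,
    phase_lag,
    phase_vs_time,
    phases_by_sequence_offset,
    population_phase_summary,
    remove_phase_reset_spikes,
    spike_vs_lfp_frequency,
    subgroup_summary,
    theta_power_median_split,
)
from thetaseq.session import LFPChannel, SpikeTrain
from thetaseq.spectral import bandpass_phase, preprocess_lfp
from thetaseq.synth import default_config, generate_session
from thetaseq.tuning import CellTuning, compute_tuning

from conftest import make_toy_session


def make_phase_set(
    phases_by_offset, times_by_offset=None, env_by_offset=None, n_iter=None, uid="u"
):
    """Build a StimulusPhaseSet from raw per-offset phase arrays, one spike
    per iteration unless times/envelopes are given."""
    offs = {}
    nmax = 0
    for off, phases in phases_by_offset.items():
        phases = np.asarray(phases, dtype=float)
        times = (
            np.asarray(times_by_offset[off], dtype=float)
            if times_by_offset
            else np.full(phases.size, 2.0 * off + 1.0)
        )
        env = (
            np.asarray(env_by_offset[off], dtype=float)
            if env_by_offset
            else np.ones(phases.size)
        )
        offs[off] = OffsetPhases(phases, times, np.arange(phases.size), env)
        nmax = max(nmax, phases.size)
    return StimulusPhaseSet(uid, "theta", offs, n_iter or nmax, 2.0)


def vm(rng, mu, kappa, n):
    return np.degrees(rng.vonmises(np.radians(mu), kappa, n))


@pytest.fixture(scope="module")
def small_tuning():
    return CellTuning("u0", 1, 0, 2, 1.0, 1e-6, "strong")


class TestPhasesBySequenceOffset:
    def test_all_iterations_included_without_probes(self, small_tuning):
        sess = make_toy_session(n_stimuli=3, n_iterations=6)
        ps = bandpass_phase(sess.lfp[0], (4.0, 8.0), "theta")
        out = phases_by_sequence_offset(sess, small_tuning, ps)
        assert out.included_iterations == 6

    def test_probe_at_preferred_excludes_iteration(self, small_tuning):
        sess = make_toy_session(n_stimuli=3, n_iterations=6, probe_events={(2, 1)})
        ps = bandpass_phase(sess.lfp[0], (4.0, 8.0), "theta")
        out = phases_by_sequence_offset(sess, small_tuning, ps)
        assert out.included_iterations == 5

    def test_probe_at_neighbour_also_excludes(self, small_tuning):
        sess = make_toy_session(n_stimuli=3, n_iterations=6, probe_events={(3, 0)})
        ps = bandpass_phase(sess.lfp[0], (4.0, 8.0), "theta")
        out = phases_by_sequence_offset(sess, small_tuning, ps)
        assert out.included_iterations == 5

    def test_all_probed_raises_empty(self, small_tuning):
        sess = make_toy_session(
            n_stimuli=3, n_iterations=3, probe_events={(i, 1) for i in range(3)}
        )
        ps = bandpass_phase(sess.lfp[0], (4.0, 8.0), "theta")
        with pytest.raises(EmptyResultError):
            phases_by_sequence_offset(sess, small_tuning, ps)

    def test_generator_inclusion_matches_probe_model(self, synthetic_session, synthetic_theta):
        """With independent 20% probes, a triplet survives with p = 0.8^3,
        i.e. ~30.7 of 60 iterations on average."""
        rng = np.random.default_rng(0)
        included = []
        for uid in synthetic_session.unit_ids[:6]:
            t = compute_tuning(synthetic_session, uid, n_splits=300, seed=rng)
            series = synthetic_theta[synthetic_session.unit_to_lfp[uid]]
            out = phases_by_sequence_offset(synthetic_session, t, series)
            included.append(out.included_iterations)
        assert 24 <= np.mean(included) <= 37


class TestPopulationSummary:
    def test_printed_means_give_minus_58_per_stimulus(self):
        """Population means 233/181/117 deg correspond to a consecutive
        phase difference of -58 deg/stimulus and a lag of +58 deg/stimulus."""
        rng = np.random.default_rng(0)
        sets = [
            make_phase_set(
                {-1: np.full(20, 233.0), 0: np.full(20, 181.0), 1: np.full(20, 117.0)},
                uid=f"u{i}",
            )
            for i in range(6)
        ]
        summ = population_phase_summary(sets)
        assert summ.consecutive_diff_deg == pytest.approx(-58.0, abs=1e-9)
        assert summ.phase_lag_deg_per_stim == pytest.approx(58.0, abs=1e-9)
        assert summ.per_offset[-1].circ_mean_deg == pytest.approx(233.0)

    def test_identical_offsets_show_no_precession(self):
        rng = np.random.default_rng(1)
        sets = [
            make_phase_set({off: vm(rng, 100.0, 4.0, 40) for off in (-1, 0, 1)}, uid=f"u{i}")
            for i in range(10)
        ]
        summ = population_phase_summary(sets)
        assert abs(summ.consecutive_diff_deg) < 15.0
        for res in summ.pairwise_ww.values():
            assert res.p_value > 0.05

    def test_wrapped_means_difference(self):
        sets = [
            make_phase_set(
                {-1: np.full(10, 0.0), 0: np.full(10, 350.0), 1: np.full(10, 340.0)},
                uid=f"u{i}",
            )
            for i in range(6)
        ]
        summ = population_phase_summary(sets)
        assert summ.consecutive_diff_deg == pytest.approx(-10.0, abs=1e-9)

    def test_bonferroni_caps_at_one(self):
        rng = np.random.default_rng(2)
        sets = [
            make_phase_set({off: vm(rng, 50.0, 3.0, 30) for off in (-1, 0, 1)}, uid=f"u{i}")
            for i in range(8)
        ]
        summ = population_phase_summary(sets, bonferroni=3)
        raw = population_phase_summary(sets, bonferroni=1)
        for key in summ.pairwise_ww:
            assert summ.pairwise_ww[key].p_value == pytest.approx(
                min(1.0, raw.pairwise_ww[key].p_value * 3)
            )


class TestPhaseLag:
    def test_lag_from_printed_means(self):
        prec = np.full(20, 233.0) + np.linspace(-1, 1, 20)
        foll = np.full(20, 117.0) + np.linspace(-1, 1, 20)
        lag, res = phase_lag(prec, foll)
        assert lag == pytest.approx(58.0, abs=0.1)
        assert res.p_value < 1e-10

    def test_identical_groups_have_zero_lag(self):
        rng = np.random.default_rng(3)
        g = vm(rng, 200.0, 4.0, 30)
        lag, res = phase_lag(g, g)
        assert lag == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_per_cell_lag_identity(self):
        ps = make_phase_set({-1: np.full(10, 233.0), 1: np.full(10, 117.0)})
        assert per_cell_phase_lag(ps) == pytest.approx(58.0, abs=1e-9)

    def test_symmetric_cell_has_zero_lag(self):
        rng = np.random.default_rng(4)
        g = vm(rng, 90.0, 5.0, 50)
        ps = make_phase_set({-1: g, 1: g})
        assert per_cell_phase_lag(ps) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_spikes_raises(self):
        ps = make_phase_set({-1: [1.0, 2.0], 1: np.zeros(10)})
        with pytest.raises(InsufficientDataError):
            per_cell_phase_lag(ps)

    def test_generator_lag_recovered(self, synthetic_session, synthetic_theta):
        rng = np.random.default_rng(5)
        sets = []
        for uid in synthetic_session.unit_ids:
            t = compute_tuning(synthetic_session, uid, n_splits=300, seed=rng)
            series = synthetic_theta[synthetic_session.unit_to_lfp[uid]]
            sets.append(phases_by_sequence_offset(synthetic_session, t, series))
        summ = population_phase_summary(sets)
        assert abs(summ.phase_lag_deg_per_stim - 58.0) < 15.0  # 12 cells only


class TestPhaseVsTime:
    def test_constant_phase_gives_flat_valid_curve(self):
        rng = np.random.default_rng(6)
        sets = []
        for i in range(20):
            times = {off: rng.uniform(2 * off, 2 * off + 2, 50) for off in (-1, 0, 1)}
            phases = {off: vm(rng, 181.0, 50.0, 50) for off in (-1, 0, 1)}
            sets.append(make_phase_set(phases, times_by_offset=times, uid=f"u{i}"))
        tc = phase_vs_time(sets)
        assert tc.valid.all()
        assert np.abs(wrap_deg(tc.mean_deg - 181.0)).max() < 5.0

    def test_window_truncated_at_span_edges(self):
        rng = np.random.default_rng(7)
        sets = []
        for i in range(10):
            # phases depend on time: only spikes in [-2, -1.25] have phase 30
            times = {-1: rng.uniform(-2.0, 0.0, 200)}
            phases = {-1: np.where(times[-1] < -1.25, 30.0, 150.0)}
            sets.append(make_phase_set(phases, times_by_offset=times, uid=f"u{i}"))
        tc = phase_vs_time(sets, window_s=1.5, span=(-2.0, 3.5))
        # first step is centred at -2 s; its window is [-2, -1.25] after truncation
        assert tc.times_s[0] == pytest.approx(-2.0)
        assert abs(wrap_deg(tc.mean_deg[0] - 30.0)) < 1e-6

    def test_linear_drift_slope_recovered(self):
        rng = np.random.default_rng(8)
        drift = -30.0  # deg per second
        sets = []
        for i in range(30):
            times = {0: np.sort(rng.uniform(-2.0, 3.5, 300))}
            phases = {0: 100.0 + drift * times[0] + rng.normal(0, 10, 300)}
            sets.append(make_phase_set(phases, times_by_offset=times, uid=f"u{i}"))
        tc = phase_vs_time(sets)
        sel = tc.valid & ~np.isnan(tc.mean_deg)
        slope = np.polyfit(tc.times_s[sel], np.unwrap(tc.mean_deg[sel], period=360.0), 1)[0]
        assert abs(slope - drift) / abs(drift) < 0.15


class TestMatchSpikeCounts:
    def test_toy_example_keeps_matching_iterations(self):
        prec_counts = [2, 5, 3]
        foll_counts = [3, 1, 3]
        offs = {}
        for off, counts in ((-1, prec_counts), (1, foll_counts)):
            phases, iters = [], []
            for it, c in enumerate(counts):
                phases.extend([10.0] * c)
                iters.extend([it] * c)
            offs[off] = OffsetPhases(
                np.array(phases), np.zeros(len(phases)), np.array(iters), np.ones(len(phases))
            )
        ps = StimulusPhaseSet("u", "theta", offs, 3, 2.0)
        filtered, kept = match_spike_counts(ps)
        assert list(kept) == [0, 2]
        assert filtered.phases(-1).size == 2 + 3

    def test_identical_counts_keep_everything(self):
        rng = np.random.default_rng(9)
        phases = vm(rng, 0.0, 2.0, 30)
        iters = np.repeat(np.arange(10), 3)
        offs = {
            off: OffsetPhases(phases, np.zeros(30), iters, np.ones(30)) for off in (-1, 1)
        }
        ps = StimulusPhaseSet("u", "theta", offs, 10, 2.0)
        _, kept = match_spike_counts(ps)
        assert kept.size == 10

    def test_generator_retention_near_printed_value(self, synthetic_session, synthetic_theta):
        """Default rates were chosen so that roughly 60% of iterations
        survive the <=1 spike-count matching (14-16 of ~28)."""
        rng = np.random.default_rng(10)
        retained = []
        for uid in synthetic_session.unit_ids:
            t = compute_tuning(synthetic_session, uid, n_splits=300, seed=rng)
            series = synthetic_theta[synthetic_session.unit_to_lfp[uid]]
            ps = phases_by_sequence_offset(synthetic_session, t, series)
            _, kept = match_spike_counts(ps)
            retained.append(kept.size)
        assert 10.0 <= np.mean(retained) <= 20.0


class TestITC:
    def test_duplicated_trials_give_unit_coherence(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(10_000)
        lfp = LFPChannel("ch0", 1000.0, x)
        onsets = np.full(8, 4.0)  # identical segments on every trial
        itc = inter_trial_coherence(lfp, {"a": onsets}, seed=0)
        vals = itc.itc["a"]
        assert np.nanmax(vals) <= 1.0 + 1e-12
        assert np.allclose(vals[~np.isnan(vals)], 1.0, atol=1e-9)

    def test_independent_trials_have_low_coherence(self):
        rng = np.random.default_rng(12)
        lfp = LFPChannel("ch0", 1000.0, rng.standard_normal(500_000))
        onsets = np.sort(rng.uniform(2.0, 496.0, 200))
        itc = inter_trial_coherence(lfp, {"a": onsets}, seed=0)
        assert np.nanmax(itc.itc["a"]) < 0.2

    def test_single_trial_is_unity(self):
        rng = np.random.default_rng(13)
        lfp = LFPChannel("ch0", 1000.0, rng.standard_normal(10_000))
        itc = inter_trial_coherence(
            lfp, {"a": np.array([3.0, 3.5, 4.0, 4.5, 5.0])}, seed=0, min_trials=5
        )
        # with equalisation to n=1 the ITC of any single trial is exactly 1
        one = inter_trial_coherence(
            lfp,
            {"a": np.array([3.0, 3.5, 4.0, 4.5, 5.0]), "b": np.array([4.0])},
            seed=0,
            min_trials=1,
        )
        assert np.allclose(one.itc["b"][~np.isnan(one.itc["b"])], 1.0, atol=1e-9)

    def test_trial_counts_equalised(self):
        rng = np.random.default_rng(14)
        lfp = LFPChannel("ch0", 1000.0, rng.standard_normal(100_000))
        itc = inter_trial_coherence(
            lfp,
            {"a": np.linspace(2, 90, 40), "b": np.linspace(2, 90, 25)},
            seed=0,
        )
        assert itc.n_trials == 25

    def test_too_few_trials_raise(self):
        lfp = LFPChannel("ch0", 1000.0, np.zeros(10_000))
        with pytest.raises(InsufficientDataError):
            inter_trial_coherence(lfp, {"a": np.array([2.0, 3.0])}, seed=0)


class TestPhaseResetRemoval:
    def _itc_peaking_at(self, t_peak):
        freqs = np.logspace(np.log10(1.7), np.log10(98.7), 32)
        times = np.arange(-0.5, 1.5 + 1e-9, 0.05)
        vals = np.exp(-((times - t_peak) ** 2) / 0.01)[None, :] * np.ones((32, 1))
        from thetaseq.phase import ITCMap

        return ITCMap(freqs, times, {"a": vals}, 10)

    def test_zero_window_is_identity(self):
        rng = np.random.default_rng(15)
        ps = make_phase_set(
            {0: vm(rng, 0.0, 2.0, 40)},
            times_by_offset={0: rng.uniform(0, 2, 40)},
        )
        filtered, info = remove_phase_reset_spikes(ps, self._itc_peaking_at(0.1), 0.0)
        assert filtered.phases(0).size == 40
        assert info["n_spikes_removed"] == 0

    def test_all_spikes_in_window_flagged(self):
        ps = make_phase_set(
            {0: np.zeros(10)}, times_by_offset={0: np.full(10, 0.1)}
        )
        filtered, info = remove_phase_reset_spikes(ps, self._itc_peaking_at(0.1), 0.3)
        assert filtered.phases(0).size == 0
        assert not info["evaluable"]
        assert "flag" in info

    def test_removal_targets_peak_latency_in_each_trial(self):
        times = {-1: np.array([-1.9, -1.85, -0.5]), 0: np.array([0.1, 0.15, 1.0])}
        phases = {-1: np.zeros(3), 0: np.zeros(3)}
        ps = make_phase_set(phases, times_by_offset=times)
        filtered, info = remove_phase_reset_spikes(ps, self._itc_peaking_at(0.1), 0.2)
        # spikes at within-trial latency ~0.1-0.15 are removed at both offsets
        assert filtered.offsets[0].times_rel_s.tolist() == [1.0]
        assert filtered.offsets[-1].times_rel_s.tolist() == [-0.5]

    def test_coupled_spikes_keep_their_lag(self, synthetic_session, synthetic_theta):
        """Phase-coupled (non-reset) spiking: the lag barely moves when
        reset-window spikes are removed."""
        rng = np.random.default_rng(16)
        sets = []
        for uid in synthetic_session.unit_ids:
            t = compute_tuning(synthetic_session, uid, n_splits=300, seed=rng)
            series = synthetic_theta[synthetic_session.unit_to_lfp[uid]]
            sets.append(phases_by_sequence_offset(synthetic_session, t, series))
        before = population_phase_summary(sets).phase_lag_deg_per_stim
        itc = self._itc_peaking_at(0.2)
        filtered = [remove_phase_reset_spikes(s, itc, 0.2)[0] for s in sets]
        after = population_phase_summary(filtered).phase_lag_deg_per_stim
        assert abs(wrap_deg(after - before)) < 10.0


class TestThetaMedianSplit:
    def test_constant_envelope_is_degenerate(self):
        ps = make_phase_set({0: np.zeros(20)})
        out = theta_power_median_split(ps, 1.0)  # envelopes are all exactly 1
        assert "degenerate" in " ".join(out["flags"])

    def test_alternating_envelope_splits_evenly(self):
        rng = np.random.default_rng(17)
        env = np.where(np.arange(200) % 2 == 0, 1.0, 2.0)
        ps = make_phase_set(
            {0: vm(rng, 50.0, 2.0, 200)},
            times_by_offset={0: rng.uniform(0, 2, 200)},
            env_by_offset={0: env},
        )
        out = theta_power_median_split(ps, 1.5)
        assert out["low"].phases(0).size == 100
        assert out["high"].phases(0).size == 100

    def test_lag_sign_preserved_in_both_halves(self, synthetic_session, synthetic_theta):
        rng = np.random.default_rng(18)
        sets = []
        env_median = {
            cid: float(np.median(s.envelope)) for cid, s in synthetic_theta.items()
        }
        for uid in synthetic_session.unit_ids:
            t = compute_tuning(synthetic_session, uid, n_splits=300, seed=rng)
            series = synthetic_theta[synthetic_session.unit_to_lfp[uid]]
            sets.append(phases_by_sequence_offset(synthetic_session, t, series))
        halves = {"low": [], "high": []}
        for s in sets:
            out = theta_power_median_split(s, env_median[synthetic_session.unit_to_lfp[s.unit_id]])
            halves["low"].append(out["low"])
            halves["high"].append(out["high"])
        for label in ("low", "high"):
            summ = population_phase_summary(halves[label])
            assert summ.phase_lag_deg_per_stim > 0  # precession direction preserved


class TestSpikeVsLfpFrequency:
    def test_locked_spikes_match_lfp_frequency(self):
        t = np.arange(200_000) / 1000.0
        rng = np.random.default_rng(19)
        lfp = LFPChannel("ch0", 1000.0, np.cos(2 * np.pi * 6.0 * t) + 0.1 * rng.standard_normal(t.size))
        spikes = SpikeTrain("u", "ch0", np.arange(1.0, 199.0, 1.0 / 6.0))
        res = spike_vs_lfp_frequency(spikes, lfp)
        assert res.spike_peak_hz == pytest.approx(6.0, abs=0.5)
        assert res.lfp_theta_peak_hz == pytest.approx(6.0, abs=0.5)

    def test_precessing_spikes_run_faster_than_lfp(self):
        """A 30 deg/cycle phase advance shifts the spike rhythm by
        6 * 30/360 = 0.5 Hz above the LFP theta frequency."""
        t = np.arange(200_000) / 1000.0
        rng = np.random.default_rng(20)
        lfp = LFPChannel("ch0", 1000.0, np.cos(2 * np.pi * 6.0 * t) + 0.1 * rng.standard_normal(t.size))
        f_spike = 6.0 * (1 + 30.0 / 360.0)
        spikes = SpikeTrain("u", "ch0", np.arange(1.0, 199.0, 1.0 / f_spike))
        res = spike_vs_lfp_frequency(spikes, lfp)
        assert res.spike_peak_hz > res.lfp_theta_peak_hz

    def test_poisson_spikes_have_no_clear_peak(self):
        rng = np.random.default_rng(21)
        t = np.arange(200_000) / 1000.0
        lfp = LFPChannel("ch0", 1000.0, np.cos(2 * np.pi * 6.0 * t))
        spikes = SpikeTrain("u", "ch0", np.sort(rng.uniform(0, 200, 1500)))
        res = spike_vs_lfp_frequency(spikes, lfp)
        assert res.spike_peak_hz is None
        assert "no clear rhythmic peak" in res.flags[0]

    def test_too_few_spikes_rejected(self):
        lfp = LFPChannel("ch0", 1000.0, np.zeros(10_000))
        with pytest.raises(InsufficientDataError):
            spike_vs_lfp_frequency(SpikeTrain("u", "ch0", np.linspace(1, 9, 50)), lfp)


class TestSubgroups:
    def _sets(self, n, rng):
        return [
            make_phase_set(
                {-1: vm(rng, 233, 3, 40), 0: vm(rng, 181, 3, 40), 1: vm(rng, 117, 3, 40)},
                uid=f"u{i}",
            )
            for i in range(n)
        ]

    def test_groups_partition_population(self):
        rng = np.random.default_rng(22)
        sets = self._sets(30, rng)
        summaries, skipped = subgroup_summary(
            sets, lambda ps: "even" if int(ps.unit_id[1:]) % 2 == 0 else "odd"
        )
        total = sum(s.per_offset[0].n_cells for s in summaries.values())
        assert total == 30
        assert not skipped

    def test_undersized_groups_skipped(self):
        rng = np.random.default_rng(23)
        sets = self._sets(12, rng)
        summaries, skipped = subgroup_summary(
            sets, lambda ps: "big" if int(ps.unit_id[1:]) < 11 else "tiny"
        )
        assert "tiny" in skipped and skipped["tiny"] == 1
        assert list(summaries) == ["big"]

    def test_random_groups_have_similar_lags(self):
        rng = np.random.default_rng(24)
        n_differ = 0
        for _ in range(10):
            sets = self._sets(40, rng)
            labels = rng.permutation(np.repeat(["a", "b"], 20))
            mapping = {f"u{i}": labels[i] for i in range(40)}
            summaries, _ = subgroup_summary(sets, lambda ps: mapping[ps.unit_id])
            pa = summaries["a"].phase_lag_test.p_value
            pb = summaries["b"].phase_lag_test.p_value
            la = summaries["a"].phase_lag_deg_per_stim
            lb = summaries["b"].phase_lag_deg_per_stim
            if abs(wrap_deg(la - lb)) > 20.0:
                n_differ += 1
        assert n_differ <= 1


class TestPhaseHistogram:
    def test_uniform_phases_are_flat(self):
        h = phase_histogram(np.arange(-179.0, 180.0, 1.0), n_bins=15)
        assert h.counts.max() - h.counts.min() <= 1

    def test_mass_conserved_under_smoothing(self):
        rng = np.random.default_rng(25)
        phases = vm(rng, 90.0, 2.0, 500)
        h = phase_histogram(phases)
        assert h.counts.sum() == pytest.approx(500)
        assert h.smoothed.sum() == pytest.approx(500, abs=1e-9)

    def test_statistics_ignore_smoothing(self):
        """The smoothed histogram is display-only: the reported population
        mean is the circular mean of the raw (unbinned, unsmoothed) phases."""
        rng = np.random.default_rng(26)
        phases = vm(rng, 181.0, 4.0, 400)
        h = phase_histogram(phases)
        assert not np.allclose(h.counts, h.smoothed)  # smoothing does change bins
        sets = [make_phase_set({-1: phases, 0: phases, 1: phases}, uid=f"u{i}") for i in range(5)]
        summ = population_phase_summary(sets)
        expected = circ_mean(phases).mean_deg % 360.0
        assert summ.per_offset[0].circ_mean_deg == pytest.approx(expected, abs=1e-9)
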