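"""Theta-phase precession across consecutive sequence items.

Spike phases are grouped by sequence offset from each unit's preferred item
(-1 preceding, 0 preferred, +1 following), per-cell circular means are
averaged across cells, and the phase advance per stimulus is quantified.
"""

import numpy as np

from thetaseq import (
    bandpass_phase,
    compute_tuning,
    default_config,
    generate_session,
    phases_by_sequence_offset,
    population_phase_summary,
    preprocess_lfp,
)

session = generate_session(default_config(n_cells=48, seed=4))
theta = {
    ch.channel_id: bandpass_phase(preprocess_lfp(ch), (4.0, 8.0), "theta")
    for ch in session.lfp
}

rng = np.random.default_rng(0)
sets = []
for uid in session.unit_ids:
    t = compute_tuning(session, uid, n_splits=1000, seed=rng)
    if t.tuning_class == "inconsistent":
        continue
    sets.append(phases_by_sequence_offset(session, t, theta[session.unit_to_lfp[uid]]))

summ = population_phase_summary(sets)
for off, name in ((-1, "preceding"), (0, "preferred"), (1, "following")):
    o = summ.per_offset[off]
    print(f"{name:9s}: mean phase {o.circ_mean_deg:6.1f} deg "
          f"(SD {o.angular_sd_deg:.0f} deg across {o.n_cells} cells)")
print(f"consecutive phase difference: {summ.consecutive_diff_deg:.1f} deg/stimulus")
print(f"phase lag (prec-foll)/2:      {summ.phase_lag_deg_per_stim:.1f} deg/stimulus")
print(f"per-cell lag median:          {summ.per_cell_lag_median:.1f} deg/stimulus, "
      f"sign-test p = {summ.per_cell_lag_test.p_value:.1e}")
for pair, res in summ.pairwise_ww.items():
    print(f"Watson-Williams {pair}: F = {res.statistic:.1f}, "
          f"Bonferroni p = {res.p_value:.2e}")
# phases advance to earlier values along the sequence (~ -58 deg/stimulus
# for the default generative phases 233/181/117 deg)
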