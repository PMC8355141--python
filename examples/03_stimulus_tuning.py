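"""Preferred-stimulus identification and split-half reliability.

For each unit, the stimulus with the most spikes is its preferred item; the
preference is cross-validated by choosing it on one random half of the
iterations and confirming it on the other half (chance = 50%), with a
binomial test on the confirmation proportion over many splits.
"""

import numpy as np

from thetaseq import compute_tuning, default_config, generate_session, population_firing_timecourse

session = generate_session(default_config(n_cells=6, seed=3))
rng = np.random.default_rng(0)

tunings = []
for uid in session.unit_ids:
    t = compute_tuning(session, uid, n_splits=2000, seed=rng)
    tunings.append(t)
    print(f"{t.unit_id}: preferred={t.preferred_id} "
          f"(preceding={t.preceding_id}, following={t.following_id}) "
          f"consistency={t.consistency:.3f} p={t.consistency_p:.1e} -> {t.tuning_class}")
# consistency near 1 and tiny p: these simulated units have reliable
# preferences, so all are 'strong' or 'weak', never 'inconsistent'

times, rate = population_firing_timecourse(session, tunings)
pre = rate[(times >= -2.0) & (times < 0.0)].mean()
post = rate[(times >= 0.0) & (times < 1.5)].mean()
print(f"baseline-corrected rate: {pre:+.2f} Hz during the preceding trial, "
      f"{post:+.2f} Hz during the preferred stimulus")
# the positive pre-onset value is the anticipatory ramp before the preferred item
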