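"""Generate a synthetic sequence-learning session and write it to disk.

The default conditions: 6 images shown for 1.5 s + 0.5 s ISI, repeated 60
times with 20% probe trials; LFP with a 1/f^1.98 background plus theta and
beta oscillations; units preferring one image each, phase-coupled to theta.
"""

import numpy as np

from thetaseq import default_config, generate_session, write_session

cfg = default_config(n_cells=8, seed=1)
session = generate_session(cfg)
files = write_session(session, "scratch/example_session")

print(f"session {session.session_id}: {len(session.events)} events "
      f"({sum(e.is_probe for e in session.events)} probes), "
      f"{len(session.spikes)} units on {len(session.lfp)} LFP channels")
print(f"mean firing rate: "
      f"{np.mean([s.n_spikes for s in session.spikes]) / session.duration_s:.2f} Hz")
print("files written:")
for f in files:
    print(" ", f)
# 360 events (6 stimuli x 60 iterations), ~20% probes, ~1 Hz units: the
# conditions every later analysis stage assumes.
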