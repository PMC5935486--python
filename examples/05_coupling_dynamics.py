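"""Time-resolved coupling: sliding-window PLV and amplitude comodulation.

Simulates a participant whose gastric-BOLD coupling gain waxes and wanes
slowly (and scales the BOLD amplitude with it), then computes the 60 s /
10 s sliding-window PLV and its correlation with the window-mean Hilbert
envelope.
"""

import numpy as np

from gastrosync.dynamics import plv_amplitude_corr, sliding_plv, window_means
from gastrosync.io import RunConfig
from gastrosync.pipeline import analyze_participant
from gastrosync.simulate import EggSimParams, make_truth, simulate_bold, simulate_egg

truth = make_truth(shape=(4, 4, 4), cluster_size=2, delays=(0.0,), snr=2.5)
egg = simulate_egg(EggSimParams(seed=5))
bold = simulate_bold(truth, egg, seed=6, gain_mod_sd=0.6)
res = analyze_participant(egg, bold, RunConfig(), keep_series=True)

node = res.bold_analytic[truth.cluster_voxels(1)].mean(axis=0)
sp = sliding_plv(np.angle(node), res.egg_phase, tr=2.0)
amp = window_means(np.abs(node), tr=2.0)
r = plv_amplitude_corr(sp.plv, amp)

print(f"windows: {sp.plv.size} (60 s windows stepped by 10 s over 840 s)")
print(f"time-varying PLV: min {sp.plv.min():.2f}, median "
      f"{np.median(sp.plv):.2f}, max {sp.plv.max():.2f}")
print(f"PLV-amplitude correlation r = {r:.3f}")
print()
print("Because one slow gain multiplies both the coupled oscillation and its")
print("amplitude, windows of strong phase-locking coincide with windows of")
print("high BOLD envelope, giving a clearly positive correlation.")
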