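"""Voxelwise phase-locking of BOLD to the gastric rhythm in one participant.

Simulates a small brain (8^3 voxels) with two planted clusters coupled to the
stomach at different phase delays, then runs the single-participant chain:
detrend, 0.01-0.1 Hz bandpass, gastric-band filter, Hilbert phases, PLV per
voxel, and the chance level from 360 circularly time-shifted surrogates.
"""

import numpy as np

from gastrosync.pipeline import analyze_participant
from gastrosync.simulate import EggSimParams, make_truth, simulate_bold, simulate_egg

truth = make_truth(shape=(8, 8, 8), cluster_size=2, delays=(0.0, np.pi / 2), snr=2.5)
egg = simulate_egg(EggSimParams(seed=2))
bold = simulate_bold(truth, egg, seed=3)
res = analyze_participant(egg, bold)

coupled = truth.coupled_mask[truth.brain_mask]
print(f"voxels: {bold.n_voxels}, volumes: {bold.n_volumes}, "
      f"retained samples: {res.egg_phase.size}")
print(f"empirical PLV  coupled voxels : {res.maps.empirical[coupled].mean():.3f}")
print(f"empirical PLV  background     : {res.maps.empirical[~coupled].mean():.3f}")
print(f"chance PLV     (median shift) : {res.maps.chance.mean():.3f}")
print(f"coupling strength coupled     : {res.maps.strength[coupled].mean():.3f}")
print(f"coupling strength background  : {res.maps.strength[~coupled].mean():.3f}")
print()
print("Coupled voxels hold a stable phase relation to the EGG, so their PLV")
print("clears the time-shift chance level by a wide margin; background voxels")
print("sit at chance (strength ~ 0).")
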