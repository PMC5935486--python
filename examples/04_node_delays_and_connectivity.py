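"""Node phase delays, consistency, shared variance, delayed vs instant FC.

Uses the planted cluster layout as regions of interest across a cohort:
recovers each node's phase-locking angle relative to the gastric rhythm,
the across-participant consistency of the relative angles, the Watson-
Williams circular ANOVA across nodes, EGG-node shared variance (squared
coherence), and the two functional-connectivity readings between the nodes.
"""

import numpy as np
from scipy import stats

from gastrosync.io import RunConfig
from gastrosync.nodes import (
    angle_consistency,
    phase_angles,
    shared_variance_coherence,
    watson_williams,
)
from gastrosync.pipeline import analyze_participant
from gastrosync.simulate import make_cohort, make_truth

delays = (0.0, 2 * np.pi * 0.05 * 4)  # second node lags by ~4 s of gastric cycle
truth = make_truth(shape=(8, 8, 8), cluster_size=2, delays=delays, snr=2.5)
cohort = make_cohort(12, truth=truth, seed=9000)
cfg = RunConfig()

rel_angles, shared, inst_all, delayed_all = [], [], [], []
for egg, bold in zip(cohort.eggs, cohort.bolds):
    res = analyze_participant(egg, bold, cfg, keep_series=True)
    nodes = [res.bold_analytic[truth.cluster_voxels(k)].mean(axis=0) for k in (1, 2)]
    _, rel = phase_angles(np.stack([np.angle(n) for n in nodes]), res.egg_phase)
    rel_angles.append(rel)
    full = [res.bold_fullband[truth.cluster_voxels(k)].mean(axis=0) for k in (1, 2)]
    shared.append([
        shared_variance_coherence(res.egg_fullband, f, res.peak.peak_freq, 0.5)
        for f in full
    ])
    inst_all.append(np.corrcoef(np.real(nodes[0]), np.real(nodes[1]))[0, 1] ** 2)
    delayed_all.append(
        shared_variance_coherence(full[0], full[1], res.peak.peak_freq, 0.5)
    )

rel_angles = np.asarray(rel_angles)
planted_sep = np.angle(np.exp(1j * (delays[1] - delays[0])))
recovered_sep = np.angle(np.exp(1j * (rel_angles[:, 1] - rel_angles[:, 0]))).mean()
F, p = watson_williams([rel_angles[:, 0], rel_angles[:, 1]])

print(f"planted angle separation : {planted_sep:+.3f} rad "
      f"({planted_sep / (2 * np.pi * 0.05):.1f} s of gastric cycle)")
print(f"recovered separation     : {recovered_sep:+.3f} rad")
print(f"phase-delay consistency  : node1 {angle_consistency(rel_angles[:, 0]):.3f}, "
      f"node2 {angle_consistency(rel_angles[:, 1]):.3f}")
print(f"Watson-Williams          : F = {F:.1f}, p = {p:.2e}")
print(f"EGG-node shared variance : {np.mean(shared, axis=0).round(3)}")
print(f"instantaneous FC (r^2)   : {np.mean(inst_all):.3f}")
print(f"delayed FC (coh^2)       : {np.mean(delayed_all):.3f}")
wins = int(np.sum(np.asarray(delayed_all) > np.asarray(inst_all)))
print(f"delayed > instantaneous  : {wins}/12 participants "
      f"(sign test p = {stats.binomtest(wins, 12, 0.5, alternative='greater').pvalue:.1e})")
print()
print("A stable ~4 s lag between nodes is invisible to instantaneous")
print("correlation but fully captured by coherence: that gap is the")
print("delayed-connectivity signature, reproduced here on synthetic data.")
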