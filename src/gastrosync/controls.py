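"""Robustness controls for the coupling analysis.

Four checks mirror the published control analyses: (1) frequency
specificity -- coupling statistics should peak at the gastric frequency and
fall off when both signals are refiltered at offset centres; (2) a
group-level time-shift null -- randomly re-shifting every participant's EGG
should essentially never reproduce the empirical summary statistic; (3) an
alternative chance level built from *other participants'* EGGs, which should
recover a similar network; (4) confound correlations -- coupling strength
should be unrelated to nuisance quantities such as BOLD power at the gastric
frequency or motion susceptibility.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .cluster import GroupClusterResult, paired_t_map, run_group_cluster
from .coupling import plv, plv_all_shifts, surrogate_offsets
from .dynamics import fisher_z
from .io import RunConfig
from .pipeline import CohortResult, analyze_participant, detect_peak
from .simulate import Cohort

logger = logging.getLogger("gastrosync")

__all__ = [
    "frequency_offset_scan",
    "group_timeshift_null",
    "egg_swap_chance",
    "confound_correlations",
    "scalar_confound_node_test",
]


def frequency_offset_scan(
    cohort: Cohort,
    config: RunConfig | None = None,
    offsets: tuple[float, ...] = (-0.02, -0.015, -0.01, -0.005, 0.0, 0.005, 0.01, 0.015, 0.02),
    network_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum of |t| after refiltering EGG and BOLD at offset centres.

    For each offset (Hz, 0 must be included) the per-participant chain is
    re-run with the gastric filter centred at ``peak + offset`` and the
    voxelwise paired t map recomputed; the summary is sum(|t|) over the whole
    brain, or over ``network_mask`` (a boolean volume) when given.  Offsets
    that would push any participant's band outside the 0.01-0.1 Hz BOLD band
    are skipped with a warning.  Returns ``(offsets_used, sums)``.
    """
    config = config or RunConfig()
    if 0.0 not in offsets:
        raise ValueError("offsets must include 0")
    peaks = [detect_peak(egg, config) for egg in cohort.eggs]
    hw = config.filter_half_width
    lo, hi = config.bold_band
    mask = cohort.bolds[0].mask
    if network_mask is not None:
        sel = np.asarray(network_mask, dtype=bool)[mask]
    else:
        sel = slice(None)

    used, sums = [], []
    for off in offsets:
        centers = [pk.peak_freq + off for pk in peaks]
        if any(c - hw < lo or c + hw > hi for c in centers):
            logger.warning("offset %+0.3f Hz pushes the band outside %s; skipped",
                           off, config.bold_band)
            continue
        emp, cha = [], []
        for egg, bold, pk, c in zip(cohort.eggs, cohort.bolds, peaks, centers):
            res = analyze_participant(egg, bold, config, peak=pk, band_center=c)
            emp.append(res.maps.empirical)
            cha.append(res.maps.chance)
        t_map = paired_t_map(np.stack(emp), np.stack(cha))
        used.append(off)
        sums.append(float(np.abs(t_map[sel]).sum()))
    return np.asarray(used), np.asarray(sums)


def group_timeshift_null(
    cohort_result: CohortResult,
    n_datasets: int = 1000,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Group-level false-positive calibration by per-participant re-shifting.

    Builds ``n_datasets`` surrogate cohorts, each applying one random
    admissible (>= 60 s) circular shift to every participant's EGG phase,
    recomputes the voxelwise paired t map of surrogate-empirical vs the
    *standard* chance estimate, and records sum(|t|) over the brain.  Returns
    ``(empirical_sum, null_sums)``; the empirical summary falling outside the
    null distribution is the evidence that the network is not a fluke.
    Requires ``run_cohort(..., keep_series=True)``.
    """
    if n_datasets < 1:
        raise ValueError("need at least one surrogate dataset")
    rng = np.random.default_rng(seed)
    cfg = cohort_result.config
    parts = cohort_result.participants
    T = parts[0].egg_phase.shape[-1]
    offsets = surrogate_offsets(T, cfg.tr, cfg.min_shift_s)
    # all-shift PLV per participant: column s is the PLV with the EGG rolled by s
    all_shifts = [plv_all_shifts(p.bold_phase, p.egg_phase) for p in parts]
    chance = cohort_result.chance

    emp_t = paired_t_map(cohort_result.empirical, chance)
    empirical_sum = float(np.abs(emp_t).sum())

    null_sums = np.zeros(n_datasets)
    for d in range(n_datasets):
        picks = rng.choice(offsets, size=len(parts))
        surr = np.stack([all_shifts[p][:, s] for p, s in enumerate(picks)])
        t_map = paired_t_map(surr, chance)
        null_sums[d] = np.abs(t_map).sum()
    return empirical_sum, null_sums


def egg_swap_chance(
    cohort_result: CohortResult,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, GroupClusterResult]:
    """Alternative chance level from the other participants' EGG phases.

    For each participant the chance PLV at a voxel is the median PLV between
    that voxel's phase and every *other* participant's EGG phase (the
    participant's own EGG is excluded by construction).  The same cluster
    inference is then run against this chance level.  Returns
    ``(swap_chance_maps, group_result)``.
    """
    parts = cohort_result.participants
    P = len(parts)
    if P < 3:
        raise ValueError("need at least 3 participants for the swap control")
    lengths = [p.egg_phase.shape[-1] for p in parts]
    T = min(lengths)
    if len(set(lengths)) > 1:
        logger.warning("unequal series lengths; truncating all to %d samples", T)
    egg_phases = [p.egg_phase[..., :T] for p in parts]

    swap_chance = []
    for i, p in enumerate(parts):
        bp = p.bold_phase[..., :T]
        others = np.stack(
            [plv(bp, egg_phases[j]) for j in range(P) if j != i], axis=1
        )
        assert others.shape[1] == P - 1  # own EGG never in its chance set
        swap_chance.append(np.median(others, axis=1))
    swap_chance = np.stack(swap_chance)

    cfg = cohort_result.config
    group = run_group_cluster(
        cohort_result.empirical,
        swap_chance,
        cohort_result.mask,
        voxel_p=cfg.voxel_p,
        alpha=cfg.cluster_alpha,
        n_perm=n_perm,
        connectivity=cfg.connectivity,
        seed=seed,
    )
    return swap_chance, group


def confound_correlations(
    strength: np.ndarray,
    confound: np.ndarray,
) -> tuple[np.ndarray, float, float]:
    """Voxelwise confound check: is coupling strength related to a nuisance map?

    ``strength`` is ``(P, V)``; ``confound`` is ``(P, V)`` (per-participant
    maps, e.g. BOLD power at the gastric frequency) or ``(V,)`` (one shared
    map).  Computes each participant's Pearson r across voxels, Fisher
    z-transforms them and t-tests the z against zero.  Returns
    ``(r_per_participant, t, p)``.
    """
    strength = np.asarray(strength, dtype=float)
    confound = np.asarray(confound, dtype=float)
    if confound.ndim == 1:
        confound = np.broadcast_to(confound, strength.shape)
    if confound.shape != strength.shape:
        raise ValueError("confound and strength shapes differ")
    P = strength.shape[0]
    r = np.array(
        [np.corrcoef(strength[p], confound[p])[0, 1] for p in range(P)]
    )
    t, p = stats.ttest_1samp(fisher_z(r), 0.0)
    return r, float(t), float(p)


def scalar_confound_node_test(
    node_strength: np.ndarray,
    confound: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node covariate test for scalar confounds (EGG power, peak frequency).

    ``node_strength`` is ``(P, K)``, ``confound`` ``(P,)``.  Returns per-node
    Pearson r across participants and its two-sided p value.
    """
    node_strength = np.atleast_2d(np.asarray(node_strength, dtype=float))
    confound = np.asarray(confound, dtype=float)
    K = node_strength.shape[1]
    r = np.zeros(K)
    p = np.zeros(K)
    for k in range(K):
        res = stats.pearsonr(confound, node_strength[:, k])
        r[k], p[k] = res.statistic, res.pvalue
    return r, p
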