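"""Node series, Eq.-style coherence, circular angle statistics, FC measures."""

import numpy as np
import pytest
from scipy import signal as sp_signal
from scipy import stats

from gastrosync.coupling import analytic_phase, plv
from gastrosync.nodes import (
    angle_consistency,
    coherence_spectrum,
    extract_node_series,
    node_fc,
    phase_angles,
    shared_variance_coherence,
    watson_williams,
    wrap_angle,
)

FS = 0.5
T_SEC = np.arange(0, 840, 2.0)


def _ww_textbook(groups):
    """Independent literal Watson-Williams implementation (oracle).

    Straight transcription of the textbook recipe: per-group resultants R_k,
    grand resultant R, F = g (N-K)(sum R_k - R) / ((K-1)(N - sum R_k)) with
    g = 1 + 3/(8 kappa), kappa from the standard r -> kappa approximation.
    """
    K = len(groups)
    N = sum(len(g) for g in groups)
    Rk = []
    for g in groups:
        C, S = np.sum(np.cos(g)), np.sum(np.sin(g))
        Rk.append(np.hypot(C, S))
    allg = np.concatenate(groups)
    R = np.hypot(np.sum(np.cos(allg)), np.sum(np.sin(allg)))
    rw = sum(Rk) / N
    if rw < 0.53:
        kappa = 2 * rw + rw**3 + 5 * rw**5 / 6
    elif rw < 0.85:
        kappa = -0.4 + 1.39 * rw + 0.43 / (1 - rw)
    else:
        kappa = 1.0 / (rw**3 - 4 * rw**2 + 3 * rw)
    g = 1 + 3 / (8 * kappa)
    F = g * ((N - K) * (sum(Rk) - R)) / ((K - 1) * (N - sum(Rk)))
    F = max(F, 0.0)
    return F, float(stats.f.sf(F, K - 1, N - K))


class TestNodeSeries:
    def test_single_voxel_identity(self):
        data = np.arange(20.0).reshape(2, 10)
        np.testing.assert_array_equal(extract_node_series(data, [1]), data[1])

    def test_opposite_voxels_cancel(self):
        a = np.sin(np.linspace(0, 10, 50))
        out = extract_node_series(np.stack([a, -a]), [0, 1])
        np.testing.assert_allclose(out, 0.0, atol=1e-15)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            extract_node_series(np.zeros((3, 5)), [])

    def test_roi_averaging_raises_plv(self):
        """Averaging voxels of a noisy planted region beats its single voxels
        (SNR gain; mean over 20 replicates)."""
        rng = np.random.default_rng(0)
        egg_phase = 2 * np.pi * 0.05 * T_SEC
        clean = np.cos(egg_phase + 0.7)
        gains = []
        for rep in range(20):
            voxels = clean + rng.normal(0, 1.5, (9, T_SEC.size))
            single = np.mean(
                [plv(analytic_phase(v).phase, egg_phase) for v in voxels]
            )
            roi = plv(analytic_phase(voxels.mean(axis=0)).phase, egg_phase)
            gains.append(roi - single)
        assert np.mean(gains) > 0.05


class TestCoherence:
    def test_exact_copy_full_coherence(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=420)
        assert shared_variance_coherence(x, x.copy(), 0.05, FS) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_matches_scipy_welch_coherence(self):
        """Dual route: the windowed-spectrum coherence equals the square root
        of scipy.signal.coherence at identical segmentation."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=420)
        y = 0.5 * x + rng.normal(size=420)
        freqs, coh = coherence_spectrum(x, y, FS, 120.0, 20.0)
        nper, nover = int(120 * FS), int(20 * FS)
        f2, cxy = sp_signal.coherence(
            x, y, fs=FS, window="hann", nperseg=nper, noverlap=nover, detrend="constant"
        )
        np.testing.assert_allclose(freqs, f2)
        np.testing.assert_allclose(coh, np.sqrt(cxy), atol=1e-10)

    def test_independent_noise_near_bias_floor(self):
        """Independent pairs: coh^2 stays near the small-sample bias floor,
        inside the 95% Monte-Carlo band of a 300-pair null simulation."""
        rng = np.random.default_rng(3)
        null = np.array(
            [
                shared_variance_coherence(
                    rng.normal(size=420), rng.normal(size=420), 0.05, FS
                )
                for _ in range(300)
            ]
        )
        lo, hi = np.quantile(null, [0.025, 0.975])
        fresh = shared_variance_coherence(
            np.random.default_rng(999).normal(size=420),
            np.random.default_rng(998).normal(size=420),
            0.05,
            FS,
        )
        assert lo <= fresh <= hi
        assert np.median(null) < 0.5  # far from coupled values

    def test_delay_tolerant_unlike_pearson(self):
        """A 4 s delayed copy keeps coh^2 ~ 1 while Pearson^2 drops."""
        x = np.cos(2 * np.pi * 0.05 * T_SEC)
        y = np.cos(2 * np.pi * 0.05 * (T_SEC - 4.0))
        c2 = shared_variance_coherence(x, y, 0.05, FS)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert c2 > 0.99
        assert r2 < 0.75

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            shared_variance_coherence(np.zeros(30), np.zeros(30), 0.05, FS)


class TestPhaseAngles:
    def test_identical_nodes_zero_relative(self):
        ph = np.tile(2 * np.pi * 0.05 * T_SEC + 0.3, (4, 1))
        egg = 2 * np.pi * 0.05 * T_SEC
        _, rel = phase_angles(ph, egg)
        np.testing.assert_allclose(rel, 0.0, atol=1e-9)

    def test_symmetric_pair_recovers_offsets(self):
        egg = 2 * np.pi * 0.05 * T_SEC
        ph = np.stack([egg + np.pi / 6, egg - np.pi / 6])
        _, rel = phase_angles(ph, egg)
        np.testing.assert_allclose(np.sort(rel), [-np.pi / 6, np.pi / 6], atol=1e-9)

    def test_single_node_warns(self):
        egg = 2 * np.pi * 0.05 * T_SEC
        with pytest.warns(UserWarning, match="single"):
            _, rel = phase_angles(egg + 0.5, egg)
        assert rel[0] == 0.0

    def test_wraparound_safe_circular_mean(self):
        """Angles straddling +-pi: relative angles stay small, as they must
        for a circular (not arithmetic) mean."""
        egg = 2 * np.pi * 0.05 * T_SEC
        ph = np.stack([egg + np.pi - 0.1, egg - np.pi + 0.1])
        _, rel = phase_angles(ph, egg)
        assert np.abs(rel).max() < 0.2


class TestConsistency:
    def test_identical_angles_full_consistency(self):
        assert angle_consistency(np.full(20, 0.8)) == pytest.approx(1.0)

    def test_uniform_angles_near_zero(self):
        rng = np.random.default_rng(5)
        r = angle_consistency(rng.uniform(-np.pi, np.pi, 100))
        assert r < 0.2

    def test_antipodal_pair_cancels_exactly(self):
        assert angle_consistency(np.array([0.0, np.pi])) == pytest.approx(0.0, abs=1e-12)


class TestWatsonWilliams:
    def test_matches_textbook_oracle_exactly(self):
        rng = np.random.default_rng(6)
        groups = [rng.vonmises(mu, 5.0, 25) for mu in (0.0, 0.4, -0.3)]
        F, p = watson_williams(groups)
        Fo, po = _ww_textbook(groups)
        assert F == pytest.approx(Fo, abs=1e-10)
        assert p == pytest.approx(po, abs=1e-10)

    def test_null_p_values_roughly_uniform(self):
        """Same-direction groups: p uniform over 200 simulations (KS check)."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            groups = [rng.vonmises(0.3, 5.0, 20) for _ in range(3)]
            ps.append(watson_williams(groups)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(8)
        g1 = rng.vonmises(0.0, 8.0, 30)
        g2 = rng.vonmises(np.pi / 2, 8.0, 30)
        F, p = watson_williams([g1, g2])
        assert p < 0.001

    def test_identical_groups_give_zero_f(self):
        g = np.array([0.1, 0.2, 0.15, 0.12])
        F, _ = watson_williams([g.copy(), g.copy(), g.copy()])
        assert F == pytest.approx(0.0, abs=1e-9)

    def test_low_concentration_warns(self):
        rng = np.random.default_rng(9)
        with pytest.warns(UserWarning, match="resultant"):
            watson_williams([rng.uniform(-np.pi, np.pi, 30) for _ in range(2)])

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            watson_williams([np.array([0.1])])
        with pytest.raises(ValueError):
            watson_williams([np.array([0.1, 0.2])])


class TestNodeFC:
    def test_identical_series(self):
        x = np.cos(2 * np.pi * 0.05 * T_SEC) + 0.01 * np.sin(2 * np.pi * 0.03 * T_SEC)
        inst, delayed = node_fc(x, x.copy(), FS, 0.05)
        assert inst == pytest.approx(1.0, abs=1e-9)
        assert delayed == pytest.approx(1.0, abs=1e-6)

    def test_quarter_cycle_delay_splits_measures(self):
        """5 s shift at 0.05 Hz (quarter cycle): instantaneous ~ 0, delayed ~ 1."""
        x = np.cos(2 * np.pi * 0.05 * T_SEC)
        y = np.cos(2 * np.pi * 0.05 * (T_SEC - 5.0))
        inst, delayed = node_fc(x, y, FS, 0.05)
        assert inst < 0.05
        assert delayed > 0.95

    def test_advancing_the_lagged_series_restores_instantaneous(self):
        """Undoing the delay brings instantaneous FC up to the delayed value."""
        lag = 2  # samples = 4 s
        x = np.cos(2 * np.pi * 0.05 * T_SEC)
        y = np.roll(x, lag)
        inst_lagged, delayed = node_fc(x[50:-50], y[50:-50], FS, 0.05)
        inst_fixed, _ = node_fc(x[50:-50], np.roll(y, -lag)[50:-50], FS, 0.05)
        assert inst_fixed > inst_lagged
        assert inst_fixed == pytest.approx(delayed, abs=0.05)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            node_fc(np.ones(420), np.cos(T_SEC), FS, 0.05)


def test_wrap_angle_range():
    a = wrap_angle(np.array([3 * np.pi, -3 * np.pi, np.pi, -np.pi, 0.1]))
    assert np.all(a > -np.pi - 1e-12) and np.all(a <= np.pi + 1e-12)
    assert a[2] == pytest.approx(np.pi)
    assert a[3] == pytest.approx(np.pi)  # -pi wraps to +pi
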