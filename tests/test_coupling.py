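"""Phase extraction, PLV, surrogate enumeration and chance-level estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gastrosync.coupling import (
    analytic_phase,
    chance_plv_map,
    coupling_strength_map,
    plv,
    plv_all_shifts,
    surrogate_offsets,
)


class TestAnalyticPhase:
    tr = 2.0
    t = np.arange(0, 840, 2.0)

    def test_cosine_phase_advances_linearly(self):
        ps = analytic_phase(np.cos(2 * np.pi * 0.05 * self.t))
        dphi = np.angle(np.exp(1j * np.diff(ps.phase)))
        core = dphi[20:-20]
        assert np.abs(core - 2 * np.pi * 0.05 * self.tr).max() < 0.01

    def test_amplitude_recovered(self):
        A = 3.7
        ps = analytic_phase(A * np.cos(2 * np.pi * 0.05 * self.t))
        core = ps.amplitude[30:-30]
        assert np.abs(core - A).max() < 0.02 * A

    def test_sin_lags_cos_by_half_pi(self):
        pc = analytic_phase(np.cos(2 * np.pi * 0.05 * self.t)).phase
        psn = analytic_phase(np.sin(2 * np.pi * 0.05 * self.t)).phase
        diff = np.angle(np.exp(1j * (pc - psn)))
        assert np.abs(diff[30:-30] - np.pi / 2).max() < 0.02

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            analytic_phase(np.zeros(100))

    def test_trim_applied_after_transform(self):
        full = analytic_phase(np.cos(2 * np.pi * 0.05 * self.t))
        trimmed = analytic_phase(np.cos(2 * np.pi * 0.05 * self.t), n_trim=15)
        np.testing.assert_array_equal(trimmed.phase, full.phase[15:-15])


class TestPLV:
    def test_equal_frequency_sinusoids_lock_at_one(self):
        """Two pure sinewaves at the same frequency always have PLV 1."""
        t = np.arange(420) * 2.0
        for offset in (0.0, np.pi / 3, -2.4):
            px = analytic_phase(np.cos(2 * np.pi * 0.05 * t)).phase
            py = analytic_phase(np.cos(2 * np.pi * 0.05 * t + offset)).phase
            assert plv(px, py) == pytest.approx(1.0, abs=1e-6)

    def test_antipodal_differences_cancel(self):
        assert plv(np.array([0.0, np.pi]), np.zeros(2)) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_pair(self):
        assert plv(np.array([0.0, np.pi / 2]), np.zeros(2)) == pytest.approx(
            np.sqrt(2) / 2, abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            plv(np.zeros(10), np.zeros(11))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_constant_offset_invariance(self, seed):
        rng = np.random.default_rng(seed)
        px = rng.uniform(-np.pi, np.pi, 64)
        py = rng.uniform(-np.pi, np.pi, 64)
        c = rng.uniform(-10, 10)
        base = plv(px, py)
        assert 0.0 <= base <= 1.0
        assert plv(px + c, py) == pytest.approx(base, abs=1e-9)
        assert plv(px, py + c) == pytest.approx(base, abs=1e-9)

    def test_amplitude_invariance_through_phase_extraction(self):
        t = np.arange(0, 840, 2.0)
        rng = np.random.default_rng(1)
        x = np.sin(2 * np.pi * 0.05 * t) + 0.3 * rng.standard_normal(t.size)
        y = np.sin(2 * np.pi * 0.05 * t + 1.0)
        p1 = plv(analytic_phase(x).phase, analytic_phase(y).phase)
        p2 = plv(analytic_phase(17.0 * x).phase, analytic_phase(y).phase)
        assert p1 == pytest.approx(p2, abs=1e-6)


class TestSurrogateOffsets:
    def test_published_count(self):
        """T=420, TR=2, min shift 60 s -> 360 admissible circular shifts."""
        assert surrogate_offsets(420, 2.0, 60.0).size == 360

    def test_every_shift_respects_bound(self):
        s = surrogate_offsets(420, 2.0, 60.0)
        assert np.all(np.minimum(s, 420 - s) >= 30)

    def test_zero_bound_gives_all_nonzero_shifts(self):
        s = surrogate_offsets(420, 2.0, 0.0)
        assert s.size == 419
        assert 0 not in s

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            surrogate_offsets(50, 2.0, 60.0)


class TestChanceLevel:
    def test_fft_shifts_match_direct_roll_oracle(self):
        """The FFT cross-correlation equals explicit np.roll recomputation."""
        rng = np.random.default_rng(0)
        bp = rng.uniform(-np.pi, np.pi, (7, 60))
        ep = rng.uniform(-np.pi, np.pi, 60)
        fast = plv_all_shifts(bp, ep)
        direct = np.stack(
            [plv(bp, np.roll(ep, s)) for s in range(60)], axis=1
        )
        np.testing.assert_allclose(fast, direct, atol=1e-12)

    def test_single_offset_is_that_surrogate(self):
        rng = np.random.default_rng(1)
        bp = rng.uniform(-np.pi, np.pi, (3, 50))
        ep = rng.uniform(-np.pi, np.pi, 50)
        chance, surr = chance_plv_map(bp, ep, np.array([13]))
        np.testing.assert_allclose(chance, plv(bp, np.roll(ep, 13)), atol=1e-12)
        assert surr.shape == (3, 1)

    def test_locked_voxel_beats_its_chance_level(self):
        """A voxel identical to a jittered narrowband EGG: empirical PLV 1,
        chance well below (coupling strength > 0.5), over 5 replicates."""
        from gastrosync.simulate import EggSimParams, simulate_egg
        from gastrosync.egg import bandpass_zero_phase, downsample_to_tr

        for rep in range(5):
            egg = simulate_egg(EggSimParams(seed=400 + rep, freq_jitter_sd=5e-4))
            filt = bandpass_zero_phase(egg.data[0], egg.fs, 0.05)
            slow = downsample_to_tr(filt, egg.fs, 2.0, egg.trigger_index)
            ph = analytic_phase(slow, n_trim=15).phase
            offsets = surrogate_offsets(ph.size, 2.0, 60.0)
            chance, _ = chance_plv_map(ph[None, :], ph, offsets)
            emp = plv(ph, ph)
            assert emp == pytest.approx(1.0, abs=1e-9)
            assert chance[0] < 1.0
            assert emp - chance[0] > 0.5

    def test_uniform_phases_chance_near_rayleigh_mean(self):
        rng = np.random.default_rng(2)
        T = 420
        bp = rng.uniform(-np.pi, np.pi, (2000, T))
        ep = rng.uniform(-np.pi, np.pi, T)
        chance, _ = chance_plv_map(bp, ep, surrogate_offsets(T, 2.0, 60.0))
        assert chance.mean() == pytest.approx(np.sqrt(np.pi) / (2 * np.sqrt(T)), abs=0.004)

    def test_empty_offsets_rejected(self):
        with pytest.raises(ValueError):
            chance_plv_map(np.zeros((1, 10)), np.zeros(10), np.array([]))


class TestCouplingStrength:
    def test_equal_maps_give_zero(self):
        m = coupling_strength_map(np.full(5, 0.3), np.full(5, 0.3))
        np.testing.assert_array_equal(m.strength, 0.0)

    def test_arithmetic(self):
        m = coupling_strength_map(np.array([1.0]), np.array([0.04]))
        assert m.strength[0] == pytest.approx(0.96)

    def test_bounded_for_random_inputs(self):
        rng = np.random.default_rng(3)
        e = rng.uniform(0, 1, 100)
        c = rng.uniform(0, 1, 100)
        m = coupling_strength_map(e, c)
        assert np.all(m.strength >= -1.0) and np.all(m.strength <= 1.0)

    def test_plv_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            coupling_strength_map(np.array([1.2]), np.array([0.5]))


class TestSurrogateValidity:
    """With no coupling, the empirical PLV behaves like one more surrogate."""

    def test_iid_phases_central_95_coverage(self):
        """Independent phases: empirical falls inside its surrogates' central
        95% interval for ~95% of voxels (binomial band at 3000 voxels)."""
        rng = np.random.default_rng(0)
        T = 420
        bp = rng.uniform(-np.pi, np.pi, (3000, T))
        ep = rng.uniform(-np.pi, np.pi, T)
        emp = plv(bp, ep)
        _, surr = chance_plv_map(bp, ep, surrogate_offsets(T, 2.0, 60.0))
        lo = np.quantile(surr, 0.025, axis=1)
        hi = np.quantile(surr, 0.975, axis=1)
        assert np.mean((emp >= lo) & (emp <= hi)) == pytest.approx(0.95, abs=0.02)

    def test_null_pipeline_coverage_reduced_by_autocorrelation(self):
        """Full narrow-band null pipeline: the 360 surrogate PLVs are serially
        correlated across shifts (the gastric band leaves ~25 independent
        phase stretches in 840 s), so interval coverage is noisier than for
        iid draws; it must stay high (> 0.85) and the empirical PLV must not
        be systematically extreme."""
        from gastrosync.simulate import EggSimParams, make_truth, simulate_bold, simulate_egg
        from gastrosync.pipeline import analyze_participant

        truth = make_truth(shape=(8, 8, 8), cluster_size=1, delays=(0.0,))
        truth.coupling_amplitude[1] = 0.0
        fracs = []
        for rep in range(4):
            egg = simulate_egg(EggSimParams(seed=500 + rep))
            bold = simulate_bold(truth, egg, seed=600 + rep)
            res = analyze_participant(egg, bold, keep_series=True)
            ph = np.angle(res.bold_analytic)
            offsets = surrogate_offsets(ph.shape[-1], 2.0, 60.0)
            _, surr = chance_plv_map(ph, res.egg_phase, offsets)
            lo = np.quantile(surr, 0.025, axis=1)
            hi = np.quantile(surr, 0.975, axis=1)
            emp = res.maps.empirical
            fracs.append(np.mean((emp >= lo) & (emp <= hi)))
        assert np.mean(fracs) > 0.85
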