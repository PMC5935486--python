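"""Synthetic EGG + BOLD cohorts with planted, known coupling structure.

The generator emulates the study conditions end to end: a narrow-band gastric
oscillator in the normogastric range (0.033-0.066 Hz) whose instantaneous
frequency drifts as a reflected Gaussian random walk -- the stomach "goes
faster and slower" rather than ticking like a metronome -- recorded on
several channels with different gains plus broadband sensor noise; and a 4D
BOLD volume in which chosen voxel clusters oscillate phase-locked to the
gastric phase at planted per-cluster delays, embedded in 1/f-shaped noise.
Everything is deterministic given seeds, so every downstream stage of the
pipeline can be checked against ground truth.

No hemodynamic convolution or head-motion model is included: the planted
signal is the phase-locked oscillation itself, which is the quantity the
analysis is meant to recover.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .io import BoldSeries, EggRecording

__all__ = [
    "EggSimParams",
    "SyntheticTruth",
    "Cohort",
    "simulate_egg",
    "simulate_bold",
    "make_truth",
    "make_cohort",
    "gastric_band_noise_sd",
    "amplitude_for_snr",
]

NORMOGASTRIC = (0.033, 0.066)


@dataclass
class EggSimParams:
    """Parameters of the synthetic gastric oscillator.

    ``freq_jitter_sd`` is the diffusion rate of the instantaneous-frequency
    random walk in Hz per sqrt(second); over the 900 s scan the default drift
    explores a few mHz around ``base_freq`` while the reflecting bounds keep
    it inside the normogastric range.  ``amplitude`` (μV) is calibrated so the
    selected channel's Welch peak power clears the 15 μV² acceptance floor by
    orders of magnitude, as a clean recording does.
    """

    base_freq: float = 0.05
    freq_jitter_sd: float = 2e-4
    amplitude: float = 120.0
    n_channels: int = 4
    channel_gains: tuple[float, ...] = (1.0, 0.65, 0.45, 0.3)
    noise_sd: float = 15.0
    fs: float = 10.0
    duration: float = 960.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = NORMOGASTRIC
        if not lo <= self.base_freq <= hi:
            raise ValueError(f"base_freq {self.base_freq} outside normogastric {NORMOGASTRIC}")
        if self.fs < 10 * self.base_freq:
            raise ValueError("fs must be at least 10x base_freq")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if len(self.channel_gains) != self.n_channels:
            raise ValueError("one gain per channel required")


@dataclass
class SyntheticTruth:
    """Ground truth for a planted cohort.

    ``cluster_id`` is 0 for background; planted delays are the phase of the
    BOLD oscillation *relative to the gastric phase* (radians, in (−π, π]),
    and coupling amplitudes are in the BOLD signal's arbitrary units.
    """

    brain_mask: np.ndarray
    cluster_id: np.ndarray
    planted_delay: dict[int, float]
    coupling_amplitude: dict[int, float]
    egg_params: EggSimParams = field(default_factory=EggSimParams)

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.cluster_id = np.asarray(self.cluster_id, dtype=int)
        if self.cluster_id.shape != self.brain_mask.shape:
            raise ValueError("cluster_id and brain_mask shapes differ")
        if np.any(self.cluster_id[~self.brain_mask] != 0):
            raise ValueError("coupled voxels must lie inside the brain mask")
        ids = set(np.unique(self.cluster_id)) - {0}
        if ids != set(self.planted_delay) or ids != set(self.coupling_amplitude):
            raise ValueError("per-cluster delay/amplitude must cover exactly the planted ids")
        for k, d in self.planted_delay.items():
            if not -np.pi < d <= np.pi:
                raise ValueError(f"delay of cluster {k} outside (−π, π]")

    @property
    def coupled_mask(self) -> np.ndarray:
        return self.cluster_id > 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.brain_mask.shape

    def cluster_voxels(self, cluster: int) -> np.ndarray:
        """Flat indices (within the masked voxel vector) of one cluster."""
        return np.flatnonzero(self.cluster_id[self.brain_mask] == cluster)


@dataclass
class Cohort:
    """Per-participant recordings sharing one planted truth."""

    eggs: list[EggRecording]
    bolds: list[BoldSeries]
    truth: SyntheticTruth
    base_freqs: np.ndarray
    seed: int

    @property
    def n_participants(self) -> int:
        return len(self.eggs)


def _reflect(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold a random walk back into [lo, hi] by reflection at the bounds."""
    span = hi - lo
    y = np.mod(values - lo, 2 * span)
    return lo + np.where(y > span, 2 * span - y, y)


def simulate_egg(
    params: EggSimParams,
    tr: float = 2.0,
    n_volumes: int | None = None,
    pad_s: float = 30.0,
) -> EggRecording:
    """Generate a multichannel EGG recording with known oscillator phase.

    Volume-onset triggers are placed every ``tr`` seconds starting ``pad_s``
    seconds into the recording (the scanner starts after the EGG), leaving
    ``pad_s`` of padding at each end for filter transients.  The ground-truth
    phase is stored on the returned recording for use by the BOLD simulator.
    """
    n = int(round(params.duration * params.fs))
    rng = np.random.default_rng(params.seed)
    steps = rng.normal(0.0, params.freq_jitter_sd / np.sqrt(params.fs), size=n)
    freq = _reflect(params.base_freq + np.cumsum(steps), *NORMOGASTRIC)
    phase = 2 * np.pi * np.cumsum(freq) / params.fs
    osc = np.cos(phase)
    gains = np.asarray(params.channel_gains, dtype=float)
    data = params.amplitude * gains[:, None] * osc[None, :]
    data = data + rng.normal(0.0, params.noise_sd, size=data.shape)

    if n_volumes is None:
        n_volumes = int(np.floor((params.duration - 2 * pad_s) / tr))
    trigger = (np.round((pad_s + tr * np.arange(n_volumes)) * params.fs)).astype(int)
    if trigger[-1] >= n:
        raise ValueError(
            f"duration {params.duration}s too short for {n_volumes} volumes at "
            f"TR={tr}s with {pad_s}s padding"
        )
    return EggRecording(
        data=data,
        fs=params.fs,
        channel_labels=[f"chan{i + 1}" for i in range(params.n_channels)],
        trigger_index=trigger,
        true_phase=phase,
    )


def _oneoverf_weights(n_volumes: int, tr: float, exponent: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    w = np.zeros_like(freqs)
    w[1:] = freqs[1:] ** (-exponent / 2.0)
    return w


def gastric_band_noise_sd(
    noise_sd: float,
    exponent: float,
    n_volumes: int,
    tr: float,
    band: tuple[float, float],
) -> float:
    """Standard deviation of the 1/f noise that falls inside ``band``.

    Analytic, from the spectral shaping weights: the fraction of total noise
    variance carried by the band's frequency bins.
    """
    w = _oneoverf_weights(n_volumes, tr, exponent)
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    total = np.sum(w**2)
    in_band = np.sum(w[(freqs >= band[0]) & (freqs <= band[1])] ** 2)
    return float(noise_sd * np.sqrt(in_band / total))


def amplitude_for_snr(
    snr: float,
    noise_sd: float = 1.0,
    exponent: float = 1.0,
    n_volumes: int = 450,
    tr: float = 2.0,
    base_freq: float = 0.05,
    half_width: float = 0.015,
) -> float:
    """Coupling amplitude giving an RMS signal-to-noise ratio of ``snr``
    inside the gastric analysis band ``base_freq ± half_width``."""
    sigma = gastric_band_noise_sd(
        noise_sd, exponent, n_volumes, tr, (base_freq - half_width, base_freq + half_width)
    )
    return float(snr * np.sqrt(2.0) * sigma)


def simulate_bold(
    truth: SyntheticTruth,
    egg: EggRecording,
    noise_exponent: float = 1.0,
    noise_sd: float = 1.0,
    tr: float = 2.0,
    n_volumes: int = 450,
    seed: int = 0,
    affine: np.ndarray | None = None,
    gain_mod_sd: float = 0.0,
    gain_timescale_s: float = 120.0,
) -> BoldSeries:
    """BOLD volume series phase-locked to the EGG in the planted clusters.

    Coupled voxels carry ``amplitude · g(t) · cos(θ_egg(t) + delay)`` plus
    noise; background voxels carry noise only.  Noise is spectrally shaped
    white noise with power ∝ 1/f^exponent (so 1/f within the 0.01-0.1 Hz
    analysis band), unit-variance normalised then scaled to ``noise_sd``.
    ``gain_mod_sd`` > 0 adds a slow multiplicative gain g(t) (mean 1,
    smoothed over ``gain_timescale_s``) shared by all coupled voxels, which
    comodulates coupling strength and BOLD amplitude -- the mechanism behind
    the time-varying PLV/amplitude correlation analysis.
    """
    if egg.true_phase is None:
        raise ValueError("EGG recording lacks ground-truth phase; use simulate_egg")
    if len(egg.trigger_index) < n_volumes:
        raise ValueError(
            f"EGG has {len(egg.trigger_index)} triggers but {n_volumes} volumes requested"
        )
    pad_needed = egg.trigger_index[0] / egg.fs
    if pad_needed < 30.0 - 1e-9:
        raise ValueError("EGG must cover the scan plus 30 s padding at each end")

    rng = np.random.default_rng(seed)
    mask = truth.brain_mask
    V = int(mask.sum())

    # 1/f noise via spectral shaping of white noise
    white = rng.standard_normal((V, n_volumes))
    spec = np.fft.rfft(white, axis=1) * _oneoverf_weights(n_volumes, tr, noise_exponent)
    noise = np.fft.irfft(spec, n=n_volumes, axis=1)
    noise *= noise_sd / noise.std(axis=1, keepdims=True)

    theta = egg.true_phase[egg.trigger_index[:n_volumes]]
    if gain_mod_sd > 0:
        raw = rng.standard_normal(n_volumes)
        w = np.exp(-0.5 * (np.fft.rfftfreq(n_volumes, d=tr) * gain_timescale_s) ** 2)
        slow = np.fft.irfft(np.fft.rfft(raw) * w, n=n_volumes)
        slow /= slow.std()
        gain = np.clip(1.0 + gain_mod_sd * slow, 0.0, None)
    else:
        gain = np.ones(n_volumes)

    data = noise
    cluster_vec = truth.cluster_id[mask]
    for k, delay in truth.planted_delay.items():
        rows = cluster_vec == k
        data[rows] += truth.coupling_amplitude[k] * gain * np.cos(theta + delay)

    if affine is None:
        affine = np.eye(4)
    return BoldSeries(data=data, shape=mask.shape, affine=affine, tr=tr, mask=mask)


def make_truth(
    shape: tuple[int, int, int] = (20, 20, 20),
    cluster_size: int = 3,
    delays: tuple[float, ...] = (0.0, np.pi / 2, -2 * np.pi / 3),
    snr: float = 2.5,
    noise_sd: float = 1.0,
    noise_exponent: float = 1.0,
    n_volumes: int = 450,
    tr: float = 2.0,
    egg_params: EggSimParams | None = None,
    brain_mask: np.ndarray | None = None,
) -> SyntheticTruth:
    """Default desk-scale truth: cubic clusters at well-separated corners.

    One ``cluster_size``³ cube per requested delay, placed far apart on the
    grid; amplitudes are set from ``snr`` (RMS signal over in-band noise) via
    :func:`amplitude_for_snr`.
    """
    if brain_mask is None:
        brain_mask = np.ones(shape, dtype=bool)
    cluster_id = np.zeros(shape, dtype=int)
    m = 1  # one-voxel margin keeps opposite corners well separated even on
    # small grids (no pair of cubes closer than 2 voxels in any axis)
    hi = [s - m - cluster_size for s in shape]
    corners = [
        (m, m, m),
        (hi[0], hi[1], m),
        (m, hi[1], hi[2]),
        (hi[0], m, hi[2]),
    ]
    for a, b in itertools.combinations(corners[: len(delays)], 2):
        if all(abs(x - y) <= cluster_size for x, y in zip(a, b)):
            raise ValueError("grid too small to separate the requested clusters")
    if len(delays) > len(corners):
        raise ValueError(f"at most {len(corners)} clusters supported by the default layout")
    egg_params = egg_params or EggSimParams()
    amp = amplitude_for_snr(
        snr, noise_sd, noise_exponent, n_volumes, tr, egg_params.base_freq
    )
    delay_map: dict[int, float] = {}
    amp_map: dict[int, float] = {}
    for k, d in enumerate(delays, start=1):
        x, y, z = corners[k - 1]
        cluster_id[x:x + cluster_size, y:y + cluster_size, z:z + cluster_size] = k
        delay_map[k] = float(d)
        amp_map[k] = amp
    return SyntheticTruth(
        brain_mask=brain_mask,
        cluster_id=cluster_id,
        planted_delay=delay_map,
        coupling_amplitude=amp_map,
        egg_params=egg_params,
    )


def make_cohort(
    n_participants: int = 30,
    truth: SyntheticTruth | None = None,
    seed: int = 0,
    freq_range: tuple[float, float] = (0.041, 0.053),
    tr: float = 2.0,
    n_volumes: int = 450,
    noise_sd: float = 1.0,
    noise_exponent: float = 1.0,
    gain_mod_sd: float = 0.0,
) -> Cohort:
    """A cohort of participants sharing the planted cluster layout.

    Each participant draws a gastric base frequency uniformly from
    ``freq_range`` (matching the published 0.041-0.053 Hz spread across 30
    participants) and independent EGG/BOLD noise; all per-participant seeds
    derive deterministically from the master seed.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if truth is None:
        truth = make_truth(n_volumes=n_volumes, tr=tr, noise_sd=noise_sd,
                           noise_exponent=noise_exponent)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants)
    rng = np.random.default_rng(ss.spawn(1)[0])
    base_freqs = rng.uniform(freq_range[0], freq_range[1], size=n_participants)

    eggs, bolds = [], []
    for i in range(n_participants):
        egg_seed, bold_seed = children[i].generate_state(2) % (2**31)
        params = replace(truth.egg_params, base_freq=float(base_freqs[i]),
                         seed=int(egg_seed))
        egg = simulate_egg(params, tr=tr, n_volumes=n_volumes)
        bold = simulate_bold(
            truth, egg,
            noise_exponent=noise_exponent, noise_sd=noise_sd,
            tr=tr, n_volumes=n_volumes, seed=int(bold_seed),
            gain_mod_sd=gain_mod_sd,
        )
        eggs.append(egg)
        bolds.append(bold)
    return Cohort(eggs=eggs, bolds=bolds, truth=truth, base_freqs=base_freqs, seed=seed)
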