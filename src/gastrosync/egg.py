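"""Gastric peak detection and the gastric-band phase reference.

The electrogastrogram (EGG) carries the stomach's basal electrical rhythm, a
narrow-band oscillation near 0.05 Hz.  This module finds each participant's
spectral peak inside the normogastric window (0.033-0.066 Hz), band-pass
filters the selected channel around that peak with a zero-phase FIR filter,
and resamples the result to the BOLD acquisition rate so that EGG and BOLD
phases live on the same clock.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger("gastrosync")

NORMOGASTRIC_BAND = (0.033, 0.066)
POWER_FLOOR_UV2 = 15.0  # exclusion criterion on peak power, μV²

__all__ = [
    "GastricPeak",
    "GastricPeakNotFound",
    "welch_psd",
    "n_welch_windows",
    "select_gastric_peak",
    "fir_bandpass_taps",
    "bandpass_zero_phase",
    "downsample_to_tr",
]


class GastricPeakNotFound(RuntimeError):
    """No channel shows an in-band peak above the power floor (participant
    would be excluded, as in the published protocol)."""


@dataclass
class GastricPeak:
    """A participant's selected gastric peak.

    ``band`` is the analysis band ``peak_freq ± half_width`` used for both the
    EGG and the BOLD gastric-band filters.
    """

    channel: str
    peak_freq: float
    peak_power: float
    band: tuple[float, float]
    selection_mode: str = "auto"
    sharpness: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if not self.band[0] < self.peak_freq < self.band[1]:
            raise ValueError("peak_freq must lie inside its band")


def n_welch_windows(n_samples: int, nperseg: int, noverlap: int) -> int:
    """Number of Welch segments: floor((L - nperseg)/(nperseg - noverlap)) + 1."""
    if noverlap >= nperseg:
        raise ValueError("overlap must be shorter than the window")
    return (n_samples - nperseg) // (nperseg - noverlap) + 1


def welch_psd(
    series: np.ndarray,
    fs: float,
    window_len: float = 200.0,
    overlap: float = 150.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch power spectrum in μV² (Hann window, linear detrend).

    ``window_len`` and ``overlap`` are in seconds; the published protocol uses
    200 s windows with 150 s overlap over a 900 s recording (15 segments).
    Returns ``(freqs, power)``; ``power`` keeps the leading channel axis when
    ``series`` is 2D.
    """
    series = np.asarray(series, dtype=float)
    nperseg = int(round(window_len * fs))
    noverlap = int(round(overlap * fs))
    if noverlap >= nperseg:
        raise ValueError("overlap must be shorter than the window")
    if series.shape[-1] < nperseg:
        raise ValueError(
            f"series ({series.shape[-1]} samples) shorter than one window ({nperseg})"
        )
    freqs, power = signal.welch(
        series,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="linear",
        scaling="spectrum",
        axis=-1,
    )
    return freqs, power


def _in_band_peaks(freqs: np.ndarray, power: np.ndarray, band: tuple[float, float]):
    """Local maxima of one channel's spectrum restricted to ``band``.

    Returns (peak_freqs, peak_powers, prominences); empty arrays if none.
    One bin of margin is kept on each side so a peak on the band edge still
    counts as a local maximum.
    """
    sel = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    if sel.size == 0:
        return np.array([]), np.array([]), np.array([])
    lo = max(sel[0] - 1, 0)
    hi = min(sel[-1] + 2, len(freqs))
    seg = power[lo:hi]
    idx, props = signal.find_peaks(seg, prominence=0.0)
    idx = idx + lo
    keep = (freqs[idx] >= band[0]) & (freqs[idx] <= band[1])
    return freqs[idx[keep]], power[idx[keep]], props["prominences"][keep]


def select_gastric_peak(
    freqs: np.ndarray,
    power: np.ndarray,
    channel_labels: list[str] | None = None,
    band: tuple[float, float] = NORMOGASTRIC_BAND,
    power_floor: float = POWER_FLOOR_UV2,
    half_width: float = 0.015,
    override_channel: str | None = None,
) -> GastricPeak:
    """Pick the gastric peak across EGG channels.

    Auto mode keeps channels whose largest in-band local maximum exceeds
    ``power_floor``, ranks them by peak power, and promotes a weaker channel
    only when its sharpness (peak prominence over median in-band power) beats
    the leader's by more than a factor of two -- a quantitative stand-in for
    the visual "sharpness of the peak" judgement of the published protocol.
    ``override_channel`` reproduces a manual choice.

    Raises
    ------
    GastricPeakNotFound
        If no channel passes the power floor (auto mode).
    """
    power = np.atleast_2d(np.asarray(power, dtype=float))
    if channel_labels is None:
        channel_labels = [f"chan{i + 1}" for i in range(power.shape[0])]
    in_band = (freqs >= band[0]) & (freqs <= band[1])

    candidates = []  # (label, peak_freq, peak_power, sharpness)
    for ch, lab in enumerate(channel_labels):
        pf, pp, prom = _in_band_peaks(freqs, power[ch], band)
        if pf.size == 0:
            continue
        best = int(np.argmax(pp))
        med = float(np.median(power[ch, in_band]))
        sharp = float(prom[best] / med) if med > 0 else np.inf
        candidates.append((lab, float(pf[best]), float(pp[best]), sharp))

    if override_channel is not None:
        for lab, f0, p0, sharp in candidates:
            if lab == override_channel:
                return GastricPeak(
                    channel=lab,
                    peak_freq=f0,
                    peak_power=p0,
                    band=(f0 - half_width, f0 + half_width),
                    selection_mode="manual-override",
                    sharpness=sharp,
                )
        raise GastricPeakNotFound(
            f"override channel {override_channel!r} has no in-band peak"
        )

    candidates = [c for c in candidates if c[2] > power_floor]
    if not candidates:
        raise GastricPeakNotFound(
            f"no channel has an in-band peak above {power_floor} μV²; "
            "participant would be excluded"
        )
    candidates.sort(key=lambda c: c[2], reverse=True)
    chosen = candidates[0]
    for other in candidates[1:]:
        if other[3] > 2.0 * chosen[3]:
            logger.info(
                "channel %s promoted over %s on sharpness (%.2f vs %.2f)",
                other[0], chosen[0], other[3], chosen[3],
            )
            chosen = other
            break
    lab, f0, p0, sharp = chosen
    return GastricPeak(
        channel=lab,
        peak_freq=f0,
        peak_power=p0,
        band=(f0 - half_width, f0 + half_width),
        selection_mode="auto",
        sharpness=sharp,
    )


def fir_bandpass_taps(fs: float, center: float, half_width: float = 0.015) -> np.ndarray:
    """Hamming-window FIR bandpass meeting the gastric-band design contract.

    The -6 dB cutoffs sit at ``center ± 1.5·half_width`` with a transition
    width of one ``half_width``: single-pass gain is flat (< 1 dB ripple)
    inside ``center ± half_width``, already a few dB down at
    ``center ± 2·half_width``, and ≥ 40 dB down beyond
    ``center ± 3·half_width``.  The tap count follows the Hamming design rule
    N ≈ 3.3/Δf and therefore scales with the sampling rate; the filter is
    meant to be applied forward and backward (zero phase), which doubles the
    attenuation.
    """
    if center - half_width <= 0 or center + half_width >= fs / 2:
        raise ValueError(
            f"band {center}±{half_width} Hz outside (0, Nyquist={fs / 2}) at fs={fs}"
        )
    transition = half_width  # keep the roll-off tight around the nominal band
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2  # odd length, linear phase type I
    lo = max(center - 1.5 * half_width, 0.5 * transition / fs)
    hi = min(center + 1.5 * half_width, fs / 2 - 1e-9)
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=fs)


def bandpass_zero_phase(
    series: np.ndarray,
    fs: float,
    center: float,
    half_width: float = 0.015,
) -> np.ndarray:
    """Zero-phase (forward-backward) gastric-band FIR filter.

    Works along the last axis; accepts multi-channel/voxel arrays.  Callers
    should keep ~30 s of padding at each end of the series and discard it
    later, mirroring the published protocol's handling of filter transients.
    """
    series = np.asarray(series, dtype=float)
    taps = fir_bandpass_taps(fs, center, half_width)
    n = series.shape[-1]
    pad = min(3 * len(taps), n - 1)
    # forward-backward FIR == single convolution with the taps' autocorrelation,
    # done by FFT; odd edge reflection matches scipy.signal.filtfilt padding
    left = 2 * series[..., :1] - series[..., pad:0:-1]
    right = 2 * series[..., -1:] - series[..., -2:-pad - 2:-1]
    ext = np.concatenate([left, series, right], axis=-1)
    kernel = np.convolve(taps, taps[::-1])
    out = signal.fftconvolve(ext, kernel.reshape((1,) * (ext.ndim - 1) + (-1,)),
                             mode="same", axes=-1)
    return out[..., pad:pad + n]


def downsample_to_tr(
    series: np.ndarray,
    fs: float,
    tr: float = 2.0,
    trigger_index: np.ndarray | None = None,
) -> np.ndarray:
    """Resample a narrow-band series to one sample per fMRI volume.

    Takes the sample nearest each volume-onset trigger; with no triggers it
    falls back to uniform decimation by ``round(fs·tr)`` (logged).  No
    anti-aliasing is applied -- the caller guarantees the series is already
    narrow-band far below the new Nyquist rate.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if trigger_index is not None and len(trigger_index) > 0:
        idx = np.asarray(trigger_index, dtype=int)
        if idx.min() < 0 or idx.max() >= n:
            raise IndexError("trigger indices outside the series")
        return series[..., idx]
    step = int(round(fs * tr))
    logger.warning("no volume triggers supplied; uniform decimation by %d", step)
    return series[..., ::step]
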