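"""BOLD voxel-series conditioning ahead of phase analysis.

Assumes spatially preprocessed input (slice timing, motion, normalisation are
upstream concerns).  The fixed order is: polynomial detrend -> 0.01-0.1 Hz
Butterworth bandpass -> nuisance regression -> gastric-band filter shared with
the EGG -> trim.  ``PreprocChain`` records and validates that order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .egg import bandpass_zero_phase

logger = logging.getLogger("gastrosync")

STEP_ORDER = ("detrend", "bandpass", "nuisance", "gastric_band", "trim")

__all__ = [
    "PreprocChain",
    "detrend_poly2",
    "bandpass_bold",
    "regress_nuisance",
    "trim_series",
    "preprocess_bold",
]


@dataclass
class PreprocChain:
    """Ordered record of applied preprocessing steps."""

    steps: list[str] = field(default_factory=list)
    band: tuple[float, float] | None = None
    n_trimmed: int = 0

    def add(self, step: str) -> None:
        if step not in STEP_ORDER:
            raise ValueError(f"unknown step {step!r}")
        order = [STEP_ORDER.index(s) for s in self.steps]
        if order and STEP_ORDER.index(step) < order[-1]:
            raise ValueError(
                f"step {step!r} out of order after {self.steps[-1]!r}; "
                f"required order is {STEP_ORDER}"
            )
        if "trim" in self.steps:
            raise ValueError("no step may follow trimming")
        self.steps.append(step)


def detrend_poly2(series: np.ndarray) -> np.ndarray:
    """Remove per-series least-squares fit of {1, t, t²} (last axis).

    The residual is orthogonal to the constant, linear and quadratic
    regressors.  Constant input yields zeros (with a warning).
    """
    series = np.asarray(series, dtype=float)
    T = series.shape[-1]
    if T < 3:
        raise ValueError("need at least 3 time points for quadratic detrending")
    t = np.arange(T, dtype=float)
    X = np.column_stack([np.ones(T), t, t * t])
    flat = series.reshape(-1, T)
    if np.any(np.ptp(flat, axis=1) == 0):
        warnings.warn("constant series detrended to zeros", stacklevel=2)
    beta, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    resid = flat - (X @ beta).T
    return resid.reshape(series.shape)


def bandpass_bold(
    series: np.ndarray,
    tr: float,
    band: tuple[float, float] = (0.01, 0.1),
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth bandpass at the BOLD sampling rate."""
    fs = 1.0 / tr
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} outside (0, Nyquist={fs / 2}) at TR={tr}")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = np.asarray(series, dtype=float)
    # demean first: a large DC offset otherwise leaks through the reflective
    # edge padding of the zero-phase pass
    x = x - x.mean(axis=-1, keepdims=True)
    return signal.sosfiltfilt(sos, x, axis=-1)


def regress_nuisance(series: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Residualise voxel series against nuisance regressors plus an intercept.

    Rank-deficient designs (e.g. duplicated regressors) are tolerated: the
    minimum-norm least-squares fit leaves the residual identical to the one
    obtained after dropping the collinear columns (a warning is emitted).
    """
    series = np.asarray(series, dtype=float)
    T = series.shape[-1]
    R = np.atleast_2d(np.asarray(regressors, dtype=float))
    if R.shape[0] == T and R.shape[1] != T:
        R = R.T  # accept (T, k) column layout
    if R.shape[1] != T:
        raise ValueError(f"regressor length {R.shape[1]} does not match T={T}")
    X = np.column_stack([np.ones(T)] + list(R))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient nuisance design; collinear columns ignored",
                      stacklevel=2)
    flat = series.reshape(-1, T)
    beta, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    resid = flat - (X @ beta).T
    return resid.reshape(series.shape)


def trim_series(series: np.ndarray, n_trim: int = 15) -> np.ndarray:
    """Drop ``n_trim`` samples from each end of the last axis.

    With the published 450-volume acquisition and the default 15 volumes per
    end this leaves 420 samples (840 s at TR = 2 s).  Applied identically to
    BOLD-derived and EGG-derived series so that sample counts always match.
    """
    series = np.asarray(series)
    if n_trim == 0:
        return series
    if n_trim < 0:
        raise ValueError("n_trim must be non-negative")
    T = series.shape[-1]
    if T <= 2 * n_trim:
        raise ValueError(f"series of length {T} too short to trim {n_trim} per end")
    return series[..., n_trim:T - n_trim]


def preprocess_bold(
    data: np.ndarray,
    tr: float,
    gastric_band: tuple[float, float],
    regressors: np.ndarray | None = None,
    bold_band: tuple[float, float] = (0.01, 0.1),
) -> tuple[np.ndarray, PreprocChain]:
    """Full conditioning chain, stopping *before* the trim.

    Returns the gastric-band filtered voxel matrix at full length together
    with the chain record.  Trimming is deferred until after the Hilbert
    transform so phase estimation can use the full series; callers apply
    :func:`trim_series` to the phase/amplitude series and record it with
    ``chain.add("trim")``.
    """
    chain = PreprocChain(band=gastric_band)
    out = detrend_poly2(data)
    chain.add("detrend")
    out = bandpass_bold(out, tr, bold_band)
    chain.add("bandpass")
    if regressors is not None:
        out = regress_nuisance(out, regressors)
        chain.add("nuisance")
    center = 0.5 * (gastric_band[0] + gastric_band[1])
    half_width = 0.5 * (gastric_band[1] - gastric_band[0])
    out = bandpass_zero_phase(out, fs=1.0 / tr, center=center, half_width=half_width)
    chain.add("gastric_band")
    return out, chain
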