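"""Readers, writers and run configuration.

Volumes travel as NIfTI-1 (via :mod:`nibabel`), electrogastrogram (EGG)
recordings as plain TSV with a ``time_s`` column, one column per channel and an
optional ``volume_trigger`` column marking fMRI volume onsets.  Voxel
coordinates are 0-based grid indices throughout; world coordinates exist only
through the stored affine.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("gastrosync")

__all__ = [
    "EggRecording",
    "BoldSeries",
    "RunConfig",
    "FormatError",
    "DimensionError",
    "read_egg_tsv",
    "write_egg_tsv",
    "read_bold_nifti",
    "write_bold_nifti",
    "write_stat_map",
    "read_stat_map",
]


class FormatError(ValueError):
    """Malformed input file (ragged rows, non-monotone time, bad header)."""


class DimensionError(ValueError):
    """Shapes or grids that do not match."""


@dataclass
class EggRecording:
    """Multichannel EGG voltage series.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array in microvolts.
    fs
        Sampling rate in Hz.
    channel_labels
        One label per channel.
    trigger_index
        Sample indices of fMRI volume onsets (may be empty).
    true_phase
        Ground-truth oscillator phase, set only by the simulator; ``None``
        for real recordings.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    trigger_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    true_phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.trigger_index = np.asarray(self.trigger_index, dtype=int)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"chan{i + 1}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise DimensionError("one label per channel required")
        if self.trigger_index.size and (
            self.trigger_index.min() < 0 or self.trigger_index.max() >= self.n_samples
        ):
            raise IndexError("trigger indices outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class BoldSeries:
    """Masked 4D BOLD data as a ``(n_voxels, T)`` matrix plus grid geometry."""

    data: np.ndarray
    shape: tuple[int, int, int]
    affine: np.ndarray
    tr: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.shape = tuple(int(s) for s in self.shape)
        if self.tr <= 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if self.mask.shape != self.shape:
            raise DimensionError("mask shape differs from grid shape")
        if self.data.shape[0] != int(self.mask.sum()):
            raise DimensionError(
                f"{self.data.shape[0]} voxel rows but mask has {int(self.mask.sum())} voxels"
            )
        if np.isnan(self.data).any():
            raise ValueError("NaN inside the brain mask")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def to_4d(self) -> np.ndarray:
        """Scatter the masked matrix back onto the full 4D grid (zeros outside)."""
        vol = np.zeros(self.shape + (self.n_volumes,), dtype=self.data.dtype)
        vol[self.mask] = self.data
        return vol


@dataclass
class RunConfig:
    """Fixed analysis constants.

    Defaults reproduce the published protocol: normogastric search band
    0.033-0.066 Hz, gastric filter half-width 0.015 Hz, surrogate shifts of at
    least 60 s, voxel threshold p < 0.01 (two-sided), cluster threshold
    Monte-Carlo p < 0.05 over 10,000 permutations, sliding windows of 60 s
    stepped by 10 s, and 15 trimmed volumes per end.
    """

    normogastric_band: tuple[float, float] = (0.033, 0.066)
    filter_half_width: float = 0.015
    power_floor: float = 15.0
    bold_band: tuple[float, float] = (0.01, 0.1)
    tr: float = 2.0
    min_shift_s: float = 60.0
    voxel_p: float = 0.01
    cluster_alpha: float = 0.05
    n_permutations: int = 10000
    connectivity: int = 26
    sliding_window_s: float = 60.0
    sliding_step_s: float = 10.0
    coherence_window_s: float = 120.0
    coherence_overlap_s: float = 20.0
    welch_window_s: float = 200.0
    welch_overlap_s: float = 150.0
    n_trim: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.normogastric_band
        if not lo < hi:
            raise ValueError("band low must be below band high")
        for name in ("voxel_p", "cluster_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["normogastric_band"] = list(d["normogastric_band"])
        d["bold_band"] = list(d["bold_band"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["normogastric_band"] = tuple(d["normogastric_band"])
        d["bold_band"] = tuple(d["bold_band"])
        return cls(**d)


# ---------------------------------------------------------------------------
# EGG TSV


def write_egg_tsv(rec: EggRecording, path: str | Path) -> None:
    """Write an EGG recording as TSV (time_s, chan..., volume_trigger)."""
    t = np.arange(rec.n_samples) / rec.fs
    cols = {"time_s": t}
    for i, lab in enumerate(rec.channel_labels):
        cols[lab] = rec.data[i]
    trig = np.zeros(rec.n_samples, dtype=int)
    trig[rec.trigger_index] = 1
    cols["volume_trigger"] = trig
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_egg_tsv(path: str | Path) -> EggRecording:
    """Read a TSV EGG recording; sampling rate is inferred from ``time_s``.

    Raises
    ------
    FormatError
        If the time column is missing, non-monotone, or non-uniform beyond 1%.
    """
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing required 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    dt_med = np.median(dt)
    if np.any(np.abs(dt - dt_med) > 0.01 * dt_med):
        raise FormatError(f"{path}: non-uniform time steps beyond 1%")
    fs = 1.0 / dt_med

    chan_cols = [c for c in df.columns if c not in ("time_s", "volume_trigger")]
    if not chan_cols:
        raise FormatError(f"{path}: no channel columns")
    data = df[chan_cols].to_numpy(dtype=float).T
    if "volume_trigger" in df.columns:
        trigger = np.flatnonzero(df["volume_trigger"].to_numpy() != 0)
    else:
        logger.warning("%s: no volume_trigger column; trigger_index left empty", path)
        trigger = np.array([], dtype=int)
    return EggRecording(data=data, fs=fs, channel_labels=chan_cols, trigger_index=trigger)


# ---------------------------------------------------------------------------
# NIfTI


def read_bold_nifti(path: str | Path, mask_path: str | Path) -> BoldSeries:
    """Load a 4D BOLD NIfTI and a binary mask on the same grid."""
    img = nib.load(str(path))
    if img.ndim != 4:
        raise FormatError(f"{path}: expected a 4D NIfTI, got {img.ndim}D")
    mask_img = nib.load(str(mask_path))
    mask = np.asanyarray(mask_img.dataobj) > 0
    if mask.shape != img.shape[:3]:
        raise DimensionError(
            f"mask grid {mask.shape} does not match BOLD grid {img.shape[:3]}"
        )
    if not mask.any():
        raise FormatError(f"{mask_path}: mask is empty")
    tr = float(img.header.get_zooms()[3])
    data = np.asanyarray(img.dataobj)[mask].astype(float)
    return BoldSeries(data=data, shape=img.shape[:3], affine=img.affine, tr=tr, mask=mask)


def write_bold_nifti(bold: BoldSeries, path: str | Path, mask_path: str | Path | None = None) -> None:
    """Write a BoldSeries back to a 4D NIfTI (float32) and optionally its mask."""
    img = nib.Nifti1Image(bold.to_4d().astype(np.float32), bold.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (bold.tr,))
    nib.save(img, str(path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(bold.mask.astype(np.uint8), bold.affine), str(mask_path))


def write_stat_map(
    values: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    path: str | Path,
    background_nan: bool = False,
) -> None:
    """Write one value per in-mask voxel as a 3D NIfTI (background 0 or NaN)."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != (int(mask.sum()),):
        raise DimensionError(
            f"{values.shape[0] if values.ndim else 0} values for {int(mask.sum())} mask voxels"
        )
    vol = np.full(mask.shape, np.nan if background_nan else 0.0, dtype=np.float32)
    vol[mask] = values
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def read_stat_map(path: str | Path, mask: np.ndarray) -> np.ndarray:
    """Read a 3D stat map back to a per-voxel vector under ``mask``."""
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj)
    if vol.shape != mask.shape:
        raise DimensionError(f"map grid {vol.shape} does not match mask {mask.shape}")
    return vol[np.asarray(mask, dtype=bool)].astype(float)
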