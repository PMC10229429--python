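"""Shared data containers for the UIH analysis pipeline.

Conventions used throughout the package:

* image coordinates are 0-based ``(row, col)`` pixel indices; physical
  position in mm is ``index * pixel_size_mm``;
* time windows are half-open ``[start, end)`` in seconds;
* temperatures are degrees Celsius, metabolic rates ml/min.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "TimeSeries",
    "ThermalStack",
    "StimulusSchedule",
    "DiskROI",
    "BodyPose",
    "BackgroundStats",
    "CountMatrix",
]


@dataclass
class TimeSeries:
    """A sampled signal with unit tag.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing.
    values
        Sample values, same length as ``times``.
    unit
        Unit tag, e.g. ``"degC"``, ``"ml/min"``, ``"ratio"``, ``"a.u."``.
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = "a.u."

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size == 0:
            raise ValueError("empty time series")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("times must be finite")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def fs(self) -> float:
        """Sampling rate in Hz; requires uniform sampling."""
        dt = self.sample_interval
        return 1.0 / dt

    @property
    def sample_interval(self) -> float:
        """Uniform sampling interval in seconds; error if irregular."""
        if len(self) < 2:
            raise ValueError("need at least two samples")
        dts = np.diff(self.times)
        dt = float(np.median(dts))
        if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
            raise ValueError("time series is not uniformly sampled")
        return dt

    def is_uniform(self) -> bool:
        if len(self) < 2:
            return True
        dts = np.diff(self.times)
        return bool(np.allclose(dts, np.median(dts), rtol=1e-6, atol=1e-9))

    def window_mask(self, start: float, end: float) -> np.ndarray:
        """Boolean mask of samples with time in the half-open ``[start, end)``."""
        return (self.times >= start) & (self.times < end)

    def window(self, start: float, end: float) -> "TimeSeries":
        mask = self.window_mask(start, end)
        if not mask.any():
            raise ValueError(f"no samples in window [{start}, {end})")
        return TimeSeries(self.times[mask], self.values[mask], self.unit)

    def shifted(self, dt: float) -> "TimeSeries":
        """Return a copy with all timestamps shifted by ``dt`` seconds."""
        return TimeSeries(self.times + dt, self.values.copy(), self.unit)

    def copy(self) -> "TimeSeries":
        return TimeSeries(self.times.copy(), self.values.copy(), self.unit)


@dataclass
class ThermalStack:
    """Stack of temperature-calibrated thermal frames.

    ``frames`` has shape ``(n_frames, height, width)`` in degrees Celsius.
    """

    frames: np.ndarray
    times: np.ndarray
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n, height, width)")
        if self.times.ndim != 1 or self.times.size != self.frames.shape[0]:
            raise ValueError("times must have one entry per frame")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class StimulusSchedule:
    """Ordered on/off ultrasound events with per-event acoustic pressure.

    ``onsets``/``offsets`` are seconds; ``train_ids`` group consecutive
    stimuli delivered as one train (one trigger of the controller).
    """

    onsets: np.ndarray
    offsets: np.ndarray
    pressures: np.ndarray
    train_ids: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.train_ids = np.asarray(self.train_ids, dtype=int)
        n = self.onsets.size
        if not (self.offsets.size == n and self.pressures.size == n and self.train_ids.size == n):
            raise ValueError("all event arrays must have equal length")
        if n and not np.all(self.offsets > self.onsets):
            raise ValueError("every offset must follow its onset")
        if n > 1:
            if not np.all(np.diff(self.onsets) > 0):
                raise ValueError("events must be time-ordered")
            # 1-us tolerance absorbs float round-off in back-to-back trains
            if not np.all(self.onsets[1:] >= self.offsets[:-1] - 1e-6):
                raise ValueError("events must not overlap")

    @classmethod
    def empty(cls) -> "StimulusSchedule":
        z = np.empty(0)
        return cls(z, z.copy(), z.copy(), np.empty(0, dtype=int))

    @property
    def n_events(self) -> int:
        return self.onsets.size

    @property
    def n_trains(self) -> int:
        return np.unique(self.train_ids).size

    def train_onsets(self) -> np.ndarray:
        """Onset time of the first stimulus of each train, time-ordered."""
        if self.n_events == 0:
            return np.empty(0)
        first = np.ones(self.n_events, dtype=bool)
        first[1:] = self.train_ids[1:] != self.train_ids[:-1]
        return self.onsets[first]

    def train_pressures(self) -> np.ndarray:
        if self.n_events == 0:
            return np.empty(0)
        first = np.ones(self.n_events, dtype=bool)
        first[1:] = self.train_ids[1:] != self.train_ids[:-1]
        return self.pressures[first]

    @classmethod
    def concatenate(cls, schedules: list["StimulusSchedule"]) -> "StimulusSchedule":
        parts = [s for s in schedules if s.n_events]
        if not parts:
            return cls.empty()
        return cls(
            np.concatenate([s.onsets for s in parts]),
            np.concatenate([s.offsets for s in parts]),
            np.concatenate([s.pressures for s in parts]),
            np.concatenate([s.train_ids for s in parts]),
        )


@dataclass
class DiskROI:
    """Circular region of interest: pixel-center ``(row, col)`` and radius in mm."""

    center: tuple[float, float]
    radius_mm: float
    clipped: bool = False

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("radius_mm must be > 0")


@dataclass
class BodyPose:
    """Animal body pose estimated from a segmentation mask."""

    centroid: tuple[float, float]
    anterior_unit: np.ndarray
    body_length_mm: float
    mask: np.ndarray
    pixel_size_mm: float

    def __post_init__(self) -> None:
        self.anterior_unit = np.asarray(self.anterior_unit, dtype=float)
        norm = float(np.linalg.norm(self.anterior_unit))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("anterior_unit must have unit norm")
        if not self.body_length_mm > 0:
            raise ValueError("body_length_mm must be > 0")


@dataclass
class BackgroundStats:
    """Background intensity statistics used by the positivity rule."""

    mean: float
    sd: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def threshold(self) -> float:
        """Positivity threshold: mean + 3 * s.d."""
        return self.mean + 3.0 * self.sd


MITO_PREFIX = "mt-"


@dataclass
class CountMatrix:
    """Sparse genes x cells integer count matrix with gene/cell names."""

    matrix: sp.csr_matrix
    genes: list[str]
    barcodes: list[str]
    cluster_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError("matrix shape must be (n_genes, n_cells)")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.cluster_labels is not None:
            self.cluster_labels = np.asarray(self.cluster_labels)
            if self.cluster_labels.size != len(self.barcodes):
                raise ValueError("cluster_labels must have one entry per cell")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def features_per_cell(self) -> np.ndarray:
        """Number of detected (count > 0) genes per cell."""
        return np.asarray((self.matrix > 0).sum(axis=0)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Fraction of counts from mitochondrial ('mt-' prefixed) genes per cell."""
        mito_rows = [i for i, g in enumerate(self.genes) if g.startswith(MITO_PREFIX)]
        totals = self.counts_per_cell().astype(float)
        totals[totals == 0] = np.nan
        if not mito_rows:
            return np.zeros(self.n_cells)
        mito = np.asarray(self.matrix[mito_rows, :].sum(axis=0)).ravel()
        frac = mito / totals
        return np.nan_to_num(frac, nan=0.0)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask, dtype=bool)
        labels = self.cluster_labels[mask] if self.cluster_labels is not None else None
        return CountMatrix(
            self.matrix[:, mask].tocsr(),
            list(self.genes),
            [b for b, keep in zip(self.barcodes, mask) if keep],
            labels,
        )


def replace(obj, **changes):
    """dataclasses.replace passthrough, re-exported for convenience."""
    return dataclasses.replace(obj, **changes)
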