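"""Shared in-memory containers used across the pipeline.

Conventions
-----------
* 3D reciprocal-space arrays are stored *centred*: the zero-frequency voxel
  sits at index ``N // 2`` along every axis (``numpy.fft.fftshift`` layout).
* Friedel mates are point reflections through that centre; for even grids the
  aliased edge plane is its own mate.
* ``q`` denotes the scattering-vector magnitude in nm^-1 with the convention
  q = (4 pi / lambda) sin(theta / 2); real-space resolution is reported as
  1 / q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatternStack",
    "LabelSet",
    "DensityMap",
    "IntensityVolume",
    "ShellCurve",
    "point_reflect",
]


def point_reflect(a: np.ndarray) -> np.ndarray:
    """Point-reflect an array through its centre voxel ``N // 2`` per axis.

    Returns the view ``a[(2c - i) mod N]`` so that ``point_reflect(a)[i]``
    is the Friedel mate of ``a[i]``.  Works for any dimensionality.
    """
    out = a[tuple(slice(None, None, -1) for _ in a.shape)]
    shifts = [(2 * (n // 2) + 1 - n) % n for n in a.shape]
    if any(shifts):
        out = np.roll(out, shifts, axis=tuple(range(a.ndim)))
    return out


@dataclass
class PatternStack:
    """A stack of 2D detector frames with per-pattern identifiers.

    ``frames`` has shape (n, H, W); ``mask`` is True where a pixel is bad or
    missing and is shared by all frames (detector-level defect map).
    """

    frames: np.ndarray
    ids: np.ndarray
    mask: Optional[np.ndarray] = None
    geometry: Optional[object] = None  # simdata.DetectorGeometry

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, H, W)")
        if len(self.ids) != len(self.frames):
            raise ValueError("one id per frame required")
        if self.mask is None:
            self.mask = np.zeros(self.frames.shape[1:], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.frames.shape[1:]:
            raise ValueError("mask shape must match frame shape")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class LabelSet:
    """Per-pattern score in [0, 1] plus the binary class at a cutoff.

    Class 1 means "single hit".  The class is ``score > threshold`` (ties go
    to class 0 by the strict-inequality convention).
    """

    ids: np.ndarray
    scores: np.ndarray
    threshold: float = 0.5
    classes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores must align")
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("pattern ids must be unique")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")
        if self.classes is None:
            self.classes = self.scores > self.threshold
        self.classes = np.asarray(self.classes, dtype=bool)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def positives(self) -> set:
        """The set of pattern ids labelled class 1."""
        return {i for i, c in zip(self.ids, self.classes) if c}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pattern_id": self.ids,
                "score": self.scores,
                "class": self.classes.astype(int),
            }
        )

    def accuracy(self, truth: dict) -> float:
        """Fraction of patterns whose class matches ``truth[pattern_id]``."""
        hits = [int(c) == int(truth[i]) for i, c in zip(self.ids, self.classes)]
        return float(np.mean(hits))


@dataclass
class DensityMap:
    """Real-space electron-density map on a cubic grid."""

    values: np.ndarray
    voxel_size: float = 1.0  # nm
    support: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("density map must be 3D")
        if self.support is not None:
            self.support = np.asarray(self.support, dtype=bool)
            if self.support.shape != self.values.shape:
                raise ValueError("support shape must match values")


@dataclass
class IntensityVolume:
    """Oversampled 3D Fourier intensities |F|^2 on a centred cubic grid.

    ``amplitudes`` (complex F, same layout) is carried only for synthetic
    volumes where the generating density is known; measured data has none.
    """

    intensities: np.ndarray
    q_calibration: float = 1.0  # nm^-1 per voxel
    measured_mask: Optional[np.ndarray] = None
    amplitudes: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensity volume must be 3D")
        if self.measured_mask is None:
            self.measured_mask = np.ones(self.intensities.shape, dtype=bool)
        self.measured_mask = np.asarray(self.measured_mask, dtype=bool)
        if np.any(self.intensities[self.measured_mask] < 0):
            raise ValueError("measured intensities must be non-negative")

    @property
    def shape(self):
        return self.intensities.shape


@dataclass
class ShellCurve:
    """A radially binned curve over q (profile, R factor, FSC, PRTF...)."""

    q_edges: np.ndarray
    values: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.q_edges = np.asarray(self.q_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.q_edges) <= 0):
            raise ValueError("q_edges must be strictly increasing")
        if len(self.values) != len(self.q_edges) - 1:
            raise ValueError("one value per bin required")

    @property
    def q_centers(self) -> np.ndarray:
        return 0.5 * (self.q_edges[:-1] + self.q_edges[1:])

    def crossing(self, cutoff: float) -> Optional[float]:
        """First shell-centre q at which the curve falls below ``cutoff``.

        Returns None if the curve never drops below the cutoff (resolution
        limited by the grid edge).  Empty shells (count 0) are skipped.
        """
        for q, v, c in zip(self.q_centers, self.values, self.counts):
            if c > 0 and np.isfinite(v) and v < cutoff:
                return float(q)
        return None
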