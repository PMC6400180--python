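"""Raw-frame preprocessing: binning, Friedel bad-pixel repair, ADU-to-photon
conversion, log scaling and mean normalization.

Two branches leave this module: integer photon patterns (used for orientation
probability analysis and merging) and log-scaled, mean-normalized feature
images (used only as classifier inputs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .containers import PatternStack

__all__ = [
    "RawFrame",
    "PhotonPattern",
    "FeatureImage",
    "bin_pixels",
    "friedel_fix",
    "adu_to_photons",
    "log_scale",
    "mean_normalize",
    "preprocess_stack",
]

log = logging.getLogger(__name__)


@dataclass
class RawFrame:
    """One detector frame in ADU with its bad-pixel mask."""

    values: np.ndarray
    mask: np.ndarray
    pattern_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask must match frame shape")


@dataclass
class PhotonPattern:
    """Integer photon counts per pixel (non-negative)."""

    counts: np.ndarray
    pattern_id: str = ""
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("photon counts must be integral")
            self.counts = np.round(self.counts).astype(np.int64)
        if self.counts.min(initial=0) < 0:
            raise ValueError("photon counts must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(self.counts.shape, dtype=bool)


@dataclass
class FeatureImage:
    """Classifier input image (log-scaled, mean-normalized)."""

    values: np.ndarray
    pattern_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature image must be finite")


def bin_pixels(frame: RawFrame, factor: int = 4) -> RawFrame:
    """Down-sample by summing ``factor x factor`` blocks of unmasked pixels.

    Summation (rather than averaging) conserves total photon signal.  An
    output pixel is masked only when every contributing pixel was masked.
    Frames not divisible by the factor are padded with masked pixels.
    """
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    if factor == 1:
        return RawFrame(frame.values.copy(), frame.mask.copy(), frame.pattern_id)
    h, w = frame.values.shape
    ph = (-h) % factor
    pw = (-w) % factor
    vals = np.pad(frame.values, ((0, ph), (0, pw)))
    mask = np.pad(frame.mask, ((0, ph), (0, pw)), constant_values=True)
    vals = np.where(mask, 0.0, vals)
    hh, ww = vals.shape[0] // factor, vals.shape[1] // factor
    vb = vals.reshape(hh, factor, ww, factor).sum(axis=(1, 3))
    mb = mask.reshape(hh, factor, ww, factor).all(axis=(1, 3))
    return RawFrame(values=vb, mask=mb, pattern_id=frame.pattern_id)


def friedel_fix(frame: RawFrame, beam_center: Sequence[float]) -> RawFrame:
    """Repair masked pixels from their Friedel mates.

    The mate of pixel p is its point reflection through the (possibly
    fractional) beam centre, rounded to the nearest pixel.  Masked pixels
    with an unmasked in-bounds mate take the mate's value and become valid;
    the rest stay masked with value 0.  Unmasked pixels are never altered,
    so the operation is idempotent.
    """
    vals = frame.values.copy()
    mask = frame.mask.copy()
    bad = np.argwhere(mask)
    if bad.size == 0:
        return RawFrame(vals, mask, frame.pattern_id)
    cy, cx = float(beam_center[0]), float(beam_center[1])
    mates = np.round(np.stack([2 * cy - bad[:, 0], 2 * cx - bad[:, 1]], axis=1))
    mates = mates.astype(int)
    h, w = vals.shape
    inb = ((mates[:, 0] >= 0) & (mates[:, 0] < h)
           & (mates[:, 1] >= 0) & (mates[:, 1] < w))
    fixable = inb.copy()
    fixable[inb] = ~frame.mask[mates[inb, 0], mates[inb, 1]]
    src = mates[fixable]
    dst = bad[fixable]
    vals[dst[:, 0], dst[:, 1]] = frame.values[src[:, 0], src[:, 1]]
    mask[dst[:, 0], dst[:, 1]] = False
    still = bad[~fixable]
    vals[still[:, 0], still[:, 1]] = 0.0
    return RawFrame(vals, mask, frame.pattern_id)


def adu_to_photons(frame: RawFrame, gain: float) -> PhotonPattern:
    """Convert ADU to integer photon counts.

    Counts are ``round(values / gain)`` with round-half-even; any signal
    below one photon (including negative readout) is set to zero — weak
    analogue signal at this level is indistinguishable from detector noise.
    Masked pixels are zeroed and reported through the retained mask.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    photons = frame.values / gain
    counts = np.round(photons)  # numpy round = half-even
    counts[photons < 1.0] = 0.0
    counts[frame.mask] = 0.0
    return PhotonPattern(counts=counts.astype(np.int64),
                         pattern_id=frame.pattern_id,
                         mask=frame.mask.copy())


def log_scale(pattern: PhotonPattern) -> FeatureImage:
    """ln(1 + counts): compresses the dynamic range so weak-signal regions
    contribute to classifier distances."""
    return FeatureImage(values=np.log1p(pattern.counts.astype(float)),
                        pattern_id=pattern.pattern_id)


def mean_normalize(images: Sequence[FeatureImage],
                   target_mean: float = 1.0) -> List[FeatureImage]:
    """Scale every image to a common mean.

    All-zero images cannot be scaled; they are passed through unchanged with
    a logged warning.
    """
    out = []
    for im in images:
        m = im.values.mean()
        if m == 0:
            log.warning("mean_normalize: all-zero image %s passed through",
                        im.pattern_id)
            out.append(FeatureImage(im.values.copy(), im.pattern_id))
        else:
            out.append(FeatureImage(im.values * (target_mean / m), im.pattern_id))
    return out


def preprocess_stack(raw: PatternStack, beam_center: Sequence[float],
                     gain: float = 28.0, bin_factor: int = 1,
                     target_mean: float = 1.0,
                     ) -> Tuple[List[PhotonPattern], List[FeatureImage]]:
    """Full chain: bin -> friedel_fix -> adu_to_photons, then branch.

    Branch A keeps the integer photon patterns (for orientation analysis);
    branch B applies log scaling and mean normalization (classifier inputs).
    Pattern ids are preserved through both branches.
    """
    photons: List[PhotonPattern] = []
    features: List[FeatureImage] = []
    # binning maps pixel centre x to (x - (factor-1)/2) / factor
    bc = [(b - (bin_factor - 1) / 2) / bin_factor for b in beam_center]
    for i in range(len(raw)):
        fr = RawFrame(values=raw.frames[i], mask=raw.mask,
                      pattern_id=str(raw.ids[i]))
        fr = bin_pixels(fr, bin_factor)
        fr = friedel_fix(fr, bc)
        pp = adu_to_photons(fr, gain)
        photons.append(pp)
        features.append(log_scale(pp))
    features = mean_normalize(features, target_mean)
    return photons, features
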