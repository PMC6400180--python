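"""Cross-dataset comparison statistics: radial profiles, shell R factors,
Fourier shell correlation, single-step orientation-probability analysis
(p_max), orientation sphere maps, consensus/Venn selection and cross-section
eccentricity.

All shell statistics use the convention q = (4 pi / lambda) sin(theta / 2)
in nm^-1, with real-space lengths reported as 1 / q.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.ndimage import map_coordinates

from .containers import DensityMap, IntensityVolume, LabelSet, ShellCurve
from .preprocess import PhotonPattern
from .simdata import DetectorGeometry, _slice_volume, quaternion_to_matrix

__all__ = [
    "ProbabilityMatrix",
    "EllipseFit",
    "radial_profile",
    "r_factor",
    "fsc",
    "fibonacci_sphere",
    "make_orientation_grid",
    "orientation_probabilities",
    "pmax_stats",
    "orientation_sphere_map",
    "consensus",
    "eccentricity_analysis",
]

log = logging.getLogger(__name__)


@dataclass
class ProbabilityMatrix:
    """Pattern-by-orientation probabilities from one expectation step."""

    probabilities: np.ndarray  # (n_patterns, n_orientations), rows sum to 1
    orientation_grid: np.ndarray  # (n_orientations, 4) unit quaternions
    pattern_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        p = self.probabilities
        if p.ndim != 2 or p.shape[1] < 1:
            raise ValueError("probabilities must be patterns x orientations")
        if np.any(p < 0):
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1")

    @property
    def n_orientations(self) -> int:
        return self.probabilities.shape[1]


@dataclass
class EllipseFit:
    """Second-moment ellipse of a filled cross-section."""

    center: Tuple[float, float]
    semi_major: float
    semi_minor: float
    angle: float
    eccentricity: float

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor > 0:
            raise ValueError("need semi_major >= semi_minor > 0")
        if not 0 <= self.eccentricity < 1:
            raise ValueError("eccentricity must lie in [0, 1)")


# ---------------------------------------------------------------------------
# shell statistics
# ---------------------------------------------------------------------------

def _centered_radii(shape) -> np.ndarray:
    axes = [np.arange(n, dtype=float) - n // 2 for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum(g ** 2 for g in grids))


def _shell_average(q: np.ndarray, values: np.ndarray, valid: np.ndarray,
                   n_bins: int, q_max: Optional[float] = None) -> ShellCurve:
    q_max = q_max if q_max is not None else float(q[valid].max())
    edges = np.linspace(0.0, q_max, n_bins + 1)
    which = np.digitize(q.ravel(), edges) - 1
    keep = valid.ravel() & (which >= 0) & (which < n_bins)
    sums = np.bincount(which[keep], weights=values.ravel()[keep],
                       minlength=n_bins)
    counts = np.bincount(which[keep], minlength=n_bins)
    vals = np.divide(sums, counts, out=np.full(n_bins, np.nan),
                     where=counts > 0)  # empty shells flagged NaN, not zero
    return ShellCurve(q_edges=edges, values=vals, counts=counts)


def radial_profile(data, geometry: Union[DetectorGeometry, float, None] = None,
                   n_bins: int = 32, mask: Optional[np.ndarray] = None
                   ) -> ShellCurve:
    """Mean intensity per q shell of a 2D pattern or a 3D volume.

    For 2D input, ``geometry`` supplies per-pixel q; for 3D input pass an
    IntensityVolume (its calibration is used) or a float q-per-voxel.
    Masked / unmeasured elements are excluded; empty shells come back NaN.
    """
    if isinstance(data, IntensityVolume):
        values = data.intensities
        valid = data.measured_mask.copy()
        q = _centered_radii(values.shape) * data.q_calibration
    elif isinstance(data, PhotonPattern):
        values = data.counts.astype(float)
        valid = ~data.mask
        if not isinstance(geometry, DetectorGeometry):
            raise ValueError("2D radial profile needs a DetectorGeometry")
        q = geometry.q_radii()
        valid &= ~geometry.mask
    else:
        values = np.asarray(data, dtype=float)
        if values.ndim == 3:
            cal = float(geometry) if geometry is not None else 1.0
            q = _centered_radii(values.shape) * cal
            valid = np.ones(values.shape, dtype=bool)
        elif values.ndim == 2:
            if not isinstance(geometry, DetectorGeometry):
                raise ValueError("2D radial profile needs a DetectorGeometry")
            q = geometry.q_radii()
            valid = ~geometry.mask
        else:
            raise ValueError("radial_profile expects 2D or 3D data")
    if mask is not None:
        valid &= ~np.asarray(mask, dtype=bool)
    return _shell_average(q, values, valid, n_bins)


def _amplitudes(vol) -> Tuple[np.ndarray, np.ndarray, float]:
    if isinstance(vol, IntensityVolume):
        return (np.sqrt(np.clip(vol.intensities, 0, None)),
                vol.measured_mask, vol.q_calibration)
    arr = np.asarray(vol, dtype=float)
    return np.sqrt(np.clip(arr, 0, None)), np.ones(arr.shape, bool), 1.0


def r_factor(volume_a, volume_b, n_shells: int = 16
             ) -> Tuple[float, ShellCurve]:
    """Shell-wise and overall R factor between two intensity volumes.

    R = sum | |F_a| - |F_b| | / sum (|F_a| + |F_b|) / 2 with |F| = sqrt(I);
    the symmetrized denominator makes R(a, b) = R(b, a).  Volumes must
    already be aligned (same grid, same hand).
    """
    fa, ma, cal = _amplitudes(volume_a)
    fb, mb, _ = _amplitudes(volume_b)
    if fa.shape != fb.shape:
        raise ValueError("volumes must share a grid")
    valid = ma & mb
    den_all = 0.5 * (fa + fb)
    if den_all[valid].sum() == 0:
        raise ValueError("all-zero amplitudes: R factor undefined")
    q = _centered_radii(fa.shape) * cal
    r_max = (fa.shape[0] // 2) * cal
    diff = np.abs(fa - fb)
    edges = np.linspace(0.0, r_max, n_shells + 1)
    which = np.digitize(q.ravel(), edges) - 1
    keep = valid.ravel() & (which >= 0) & (which < n_shells)
    num = np.bincount(which[keep], weights=diff.ravel()[keep], minlength=n_shells)
    den = np.bincount(which[keep], weights=den_all.ravel()[keep], minlength=n_shells)
    counts = np.bincount(which[keep], minlength=n_shells)
    vals = np.divide(num, den, out=np.full(n_shells, np.nan), where=den > 0)
    curve = ShellCurve(q_edges=edges, values=vals, counts=counts)
    sel = valid & (q <= r_max)
    overall = float(diff[sel].sum() / den_all[sel].sum())
    return overall, curve


def fsc(map_a, map_b, n_shells: int = 16, cutoff: float = 0.5
        ) -> Tuple[ShellCurve, Optional[float]]:
    """Fourier shell correlation of two aligned real-space maps.

    FSC(shell) = Re(sum F_a conj(F_b)) / sqrt(sum |F_a|^2 sum |F_b|^2);
    the returned resolution is the real-space length 1/q of the first
    shell-centre where the curve falls below ``cutoff`` (None if it never
    does within the grid).
    """
    va = map_a.values if isinstance(map_a, DensityMap) else np.asarray(map_a, float)
    vb = map_b.values if isinstance(map_b, DensityMap) else np.asarray(map_b, float)
    if va.shape != vb.shape:
        raise ValueError("maps must share a grid")
    voxel = map_a.voxel_size if isinstance(map_a, DensityMap) else 1.0
    cal = 2.0 * math.pi / (va.shape[0] * voxel)
    fa = np.fft.fftshift(np.fft.fftn(va))
    fb = np.fft.fftshift(np.fft.fftn(vb))
    q = _centered_radii(va.shape) * cal
    r_max = (va.shape[0] // 2) * cal
    edges = np.linspace(0.0, r_max, n_shells + 1)
    which = np.digitize(q.ravel(), edges) - 1
    keep = (which >= 0) & (which < n_shells)
    cross = np.real(fa * np.conj(fb)).ravel()
    pa = (np.abs(fa) ** 2).ravel()
    pb = (np.abs(fb) ** 2).ravel()
    num = np.bincount(which[keep], weights=cross[keep], minlength=n_shells)
    da = np.bincount(which[keep], weights=pa[keep], minlength=n_shells)
    db = np.bincount(which[keep], weights=pb[keep], minlength=n_shells)
    counts = np.bincount(which[keep], minlength=n_shells)
    den = np.sqrt(da * db)
    vals = np.divide(num, den, out=np.full(n_shells, np.nan), where=den > 0)
    curve = ShellCurve(q_edges=edges, values=vals, counts=counts)
    q_cross = curve.crossing(cutoff)
    return curve, (1.0 / q_cross if q_cross else None)


# ---------------------------------------------------------------------------
# orientation probabilities (one expectation step)
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors: z_i = 1 - (2i+1)/n, azimuth 2 pi i / phi."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi_golden = 0.5 * (1.0 + math.sqrt(5.0))
    az = 2.0 * math.pi * i / phi_golden
    r = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    return np.stack([r * np.cos(az), r * np.sin(az), z], axis=1)


def make_orientation_grid(n_directions: int, n_inplane: int = 8) -> np.ndarray:
    """Quaternion grid: Fibonacci beam directions x in-plane angles.

    Each quaternion q satisfies R(q)^T e_z = d, so the slice normal (the
    beam axis in the particle frame) is the Fibonacci direction and the
    in-plane angle only spins the detector about it.
    """
    from scipy.spatial.transform import Rotation

    dirs = fibonacci_sphere(n_directions)
    ez = np.array([0.0, 0.0, 1.0])
    quats = []
    for d in dirs:
        v = np.cross(d, ez)
        s = np.linalg.norm(v)
        c = float(np.dot(d, ez))
        if s < 1e-12:
            r_dir = Rotation.identity() if c > 0 else Rotation.from_rotvec(
                [math.pi, 0, 0])
        else:
            r_dir = Rotation.from_rotvec(v / s * math.atan2(s, c))
        for a in np.arange(n_inplane) * (2.0 * math.pi / n_inplane):
            r = Rotation.from_rotvec([0, 0, a]) * r_dir
            x, y, z, w = r.as_quat()
            quats.append((w, x, y, z))
    return np.asarray(quats)


def orientation_probabilities(patterns: Sequence[PhotonPattern],
                              volume: IntensityVolume,
                              orientation_grid: np.ndarray,
                              geometry: DetectorGeometry) -> ProbabilityMatrix:
    """One expectation step of orientation recovery.

    For each pattern with photon counts K and each grid orientation j with
    rendered model slice W_j (scaled to the pattern's total counts and
    floored at 1e-12), the Poisson log-likelihood is
    sum_i [K_i log W_ij - W_ij]; rows become probabilities by softmax under
    a uniform orientation prior.
    """
    grid = np.asarray(orientation_grid, dtype=float)
    pix_ok = ~geometry.mask
    slices = np.stack([
        np.clip(_slice_volume(volume.intensities, geometry,
                              volume.q_calibration, q), 0.0, None)[pix_ok]
        for q in grid
    ])
    w_sums = slices.sum(axis=1)
    if np.any(w_sums <= 0):
        raise ValueError("an orientation slice has no intensity")
    log_w = np.log(np.maximum(slices / w_sums[:, None], 1e-12))

    counts = np.stack([p.counts.astype(float)[pix_ok] for p in patterns])
    totals = counts.sum(axis=1)
    # K . log(W_j * s/sum W_j) - s  (the -W term is constant after scaling)
    loglik = counts @ log_w.T
    loglik += totals[:, None] * np.log(np.maximum(totals[:, None], 1e-300))
    loglik -= totals[:, None]

    loglik -= loglik.max(axis=1, keepdims=True)
    probs = np.exp(loglik)
    probs /= probs.sum(axis=1, keepdims=True)
    ids = np.array([p.pattern_id for p in patterns], dtype=object)
    return ProbabilityMatrix(probabilities=probs, orientation_grid=grid,
                             pattern_ids=ids)


def pmax_stats(matrix: ProbabilityMatrix, low_cutoff: float = 1e-4,
               n_hist_bins: int = 50) -> Dict:
    """Per-pattern p_max summary.

    Reports each pattern's largest orientation probability, a histogram,
    the fraction of patterns whose orientation is uncertain
    (p_max < ``low_cutoff``), and the uniform-prior baseline
    1 / n_orientations.
    """
    pmax = matrix.probabilities.max(axis=1)
    hist, edges = np.histogram(pmax, bins=n_hist_bins, range=(0.0, 1.0))
    return {
        "pmax": pmax,
        "hist_counts": hist,
        "hist_edges": edges,
        "fraction_uncertain": float(np.mean(pmax < low_cutoff)),
        "low_cutoff": low_cutoff,
        "baseline": 1.0 / matrix.n_orientations,
    }


def orientation_sphere_map(matrix: ProbabilityMatrix, top_n: int = 10
                           ) -> Tuple[np.ndarray, np.ndarray]:
    """Accumulate each pattern's top-N orientation probabilities onto the
    unit sphere of beam axes (in-plane rotation discarded).

    Returns (points, weights): unique beam-axis unit vectors and the total
    probability mass deposited on each.
    """
    grid = matrix.orientation_grid
    axes = np.stack([quaternion_to_matrix(q).T @ [0.0, 0.0, 1.0]
                     for q in grid])
    keyed = np.round(axes, 9)
    uniq, inverse = np.unique(keyed, axis=0, return_inverse=True)
    weights = np.zeros(len(uniq))
    p = matrix.probabilities
    top = min(top_n, p.shape[1])
    for row in p:
        sel = np.argpartition(row, -top)[-top:]
        np.add.at(weights, inverse[sel], row[sel])
    return uniq, weights


# ---------------------------------------------------------------------------
# consensus selection
# ---------------------------------------------------------------------------

def consensus(label_sets: Sequence[LabelSet],
              names: Optional[Sequence[str]] = None
              ) -> Tuple[Dict[str, int], LabelSet]:
    """Venn decomposition of the class-1 ("single hit") selections.

    All sets must cover the same pattern-id universe (ids are the join key,
    the analogue of fiducial + event time).  Returns the exclusive-region
    counts (3 fields for two sets, 7 for three) and the common selection as
    a LabelSet whose scores are the per-set means.
    """
    if not 2 <= len(label_sets) <= 3:
        raise ValueError("consensus takes 2 or 3 label sets")
    names = list(names) if names else ["A", "B", "C"][:len(label_sets)]
    universe = set(label_sets[0].ids.tolist())
    for ls in label_sets[1:]:
        other = set(ls.ids.tolist())
        if other != universe:
            orphans = sorted(map(str, universe ^ other))[:10]
            raise ValueError(f"label sets cover different patterns: {orphans}")
    pos = [ls.positives for ls in label_sets]
    counts: Dict[str, int] = {}
    k = len(pos)
    for mask in range(1, 2 ** k):
        inc = [i for i in range(k) if mask >> i & 1]
        exc = [i for i in range(k) if not mask >> i & 1]
        region = set.intersection(*[pos[i] for i in inc])
        for i in exc:
            region -= pos[i]
        counts["_".join(names[i] for i in inc)] = len(region)
    common_ids = sorted(set.intersection(*pos), key=str)
    score_maps = [dict(zip(ls.ids, ls.scores)) for ls in label_sets]
    scores = np.array([np.mean([m[i] for m in score_maps]) for i in common_ids]
                      ) if common_ids else np.empty(0)
    common = LabelSet(ids=np.array(common_ids, dtype=object), scores=scores,
                      threshold=label_sets[0].threshold,
                      classes=np.ones(len(common_ids), dtype=bool))
    return counts, common


# ---------------------------------------------------------------------------
# cross-section eccentricity
# ---------------------------------------------------------------------------

def _plane_basis(normal: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def fit_ellipse_moments(mask: np.ndarray,
                        weights: Optional[np.ndarray] = None) -> EllipseFit:
    """Second-moment ellipse of a filled region.

    For a uniform ellipse the covariance eigenvalues are (a^2/4, b^2/4), so
    the semi-axes are twice the moment square roots and
    e = sqrt(1 - (b/a)^2).  Optional per-pixel weights (e.g. interpolated
    intensities) give sub-pixel boundary accuracy: the eccentricity is very
    sensitive to the moment ratio, and binary pixelation alone biases a
    digitized circle to e ~ 0.1.
    """
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("empty cross-section")
    w = weights[ys, xs] if weights is not None else np.ones(len(ys))
    pts = np.stack([ys, xs], axis=1).astype(float)
    center = (pts * w[:, None]).sum(axis=0) / w.sum()
    diff = pts - center
    cov = (diff[:, :, None] * diff[:, None, :] * w[:, None, None]).sum(axis=0)
    cov = cov / w.sum() + np.eye(2) / 12.0  # pixel-area term
    evals, evecs = np.linalg.eigh(cov)
    lam_min, lam_max = float(evals[0]), float(evals[1])
    a = 2.0 * math.sqrt(max(lam_max, 1e-12))
    b = 2.0 * math.sqrt(max(lam_min, 1e-12))
    ecc = math.sqrt(max(0.0, 1.0 - (b / a) ** 2))
    angle = math.atan2(evecs[1, 1], evecs[0, 1])
    return EllipseFit(center=(center[0], center[1]), semi_major=a,
                      semi_minor=b, angle=angle, eccentricity=ecc)


def _fit_section_ellipse(vals: np.ndarray, c: int, u: np.ndarray,
                         v: np.ndarray, contour_level: float,
                         n_angles: int = 180) -> EllipseFit:
    """Fit a centred ellipse to the contour of one central cross-section.

    The boundary is located with sub-pixel precision by casting rays from
    the section centroid and linearly interpolating the first crossing of
    ``contour_level`` x section max; the radii are then least-squares fit to
    the centred-ellipse form 1/r(t)^2 = x(t)^T M x(t) and the semi-axes read
    off the eigenvalues of M.  (Second moments of the thresholded region
    are offered by :func:`fit_ellipse_moments` but their pixelation bias is
    too coarse for eccentricities of near-circular sections.)
    """
    step = 0.5
    s = np.arange(-c, c + step, step)
    ss, tt = np.meshgrid(s, s, indexing="ij")
    coords = c + ss[..., None] * u + tt[..., None] * v
    section = map_coordinates(vals, np.moveaxis(coords, -1, 0),
                              order=1, mode="constant")
    peak = section.max()
    if peak <= 0:
        raise ValueError("empty cross-section")
    level = contour_level * peak
    inside = section >= level
    if not inside.any():
        raise ValueError("empty cross-section")
    ys, xs = np.nonzero(inside)
    w = section[ys, xs]
    cy = float((ys * w).sum() / w.sum())
    cx = float((xs * w).sum() / w.sum())
    center3 = coords[int(round(cy)), int(round(cx))]

    angles = np.arange(n_angles) * (2.0 * math.pi / n_angles)
    radii_steps = np.arange(0.0, c, 0.25)
    dirs = (np.cos(angles)[:, None] * u[None, :]
            + np.sin(angles)[:, None] * v[None, :])
    pts = center3[None, None, :] + radii_steps[None, :, None] * dirs[:, None, :]
    rays = map_coordinates(vals, np.moveaxis(pts, -1, 0), order=1,
                           mode="constant")
    boundary_r, boundary_t = [], []
    for k in range(n_angles):
        prof = rays[k]
        if prof[0] < level:
            continue
        below = np.flatnonzero(prof < level)
        if len(below) == 0:
            continue
        j = below[0]
        frac = (prof[j - 1] - level) / max(prof[j - 1] - prof[j], 1e-12)
        boundary_r.append(radii_steps[j - 1] + frac * 0.25)
        boundary_t.append(angles[k])
    if len(boundary_r) < 8:
        raise ValueError("too few contour crossings")
    r = np.asarray(boundary_r)
    t = np.asarray(boundary_t)
    design = np.stack([np.cos(t) ** 2, np.sin(t) ** 2,
                       2.0 * np.sin(t) * np.cos(t)], axis=1)
    m_coef, *_ = np.linalg.lstsq(design, 1.0 / r ** 2, rcond=None)
    m_mat = np.array([[m_coef[0], m_coef[2]], [m_coef[2], m_coef[1]]])
    evals, evecs = np.linalg.eigh(m_mat)
    if evals[0] <= 0:
        raise ValueError("degenerate contour")
    a = 1.0 / math.sqrt(evals[0])
    b = 1.0 / math.sqrt(evals[1])
    ecc = math.sqrt(max(0.0, 1.0 - (b / a) ** 2))
    angle = math.atan2(evecs[1, 0], evecs[0, 0])
    return EllipseFit(center=(cy * step - c, cx * step - c), semi_major=a,
                      semi_minor=b, angle=angle, eccentricity=ecc)


def eccentricity_analysis(density: Union[DensityMap, np.ndarray],
                          n_planes: int = 100,
                          contour_level: float = 0.5) -> Dict:
    """Eccentricity distribution of central cross-sections.

    Plane normals come from the Fibonacci sphere lattice; each central
    section is thresholded at ``contour_level`` times its own maximum and
    the filled region fit by a second-moment ellipse.  Sections with no
    above-threshold pixels are skipped with a warning.
    """
    vals = density.values if isinstance(density, DensityMap) else np.asarray(density)
    n = vals.shape[0]
    c = n // 2
    normals = fibonacci_sphere(n_planes)
    eccs, fits = [], []
    for normal in normals:
        u, v = _plane_basis(normal)
        try:
            fit = _fit_section_ellipse(vals, c, u, v, contour_level)
        except ValueError:
            log.warning("empty cross-section skipped")
            continue
        fits.append(fit)
        eccs.append(fit.eccentricity)
    eccs = np.asarray(eccs)
    hist, edges = np.histogram(eccs, bins=20, range=(0.0, 1.0))
    return {
        "eccentricities": eccs,
        "mean": float(eccs.mean()) if len(eccs) else math.nan,
        "max": float(eccs.max()) if len(eccs) else math.nan,
        "hist_counts": hist,
        "hist_edges": edges,
        "fits": fits,
        "normals": normals,
    }
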