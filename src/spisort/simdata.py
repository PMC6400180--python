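"""Synthetic single-particle-imaging datasets for classifier and phasing tests.

Emulates the statistical structure of an XFEL diffraction experiment on an
icosahedral virus: down-sampled photon-count patterns of single hits,
multi-particle interference hits and droplet/blank non-hits, with Poisson
photon noise, an ADU detector model, ground-truth labels/orientations and a
ground-truth oversampled 3D intensity volume for phase-retrieval tests.

Rendering uses the flat-Ewald (central-slice) approximation: at the
small-angle resolutions this pipeline targets, Ewald-sphere curvature is
negligible, so a detector frame is a central plane of the 3D intensity
volume rotated by the particle orientation.

Units: real-space voxels are ``voxel_size`` nm wide; reciprocal space uses
q = (4 pi / lambda) sin(theta/2) in nm^-1, with one volume voxel spanning
``2 pi / (N * voxel_size)`` nm^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.spatial.transform import Rotation

from .containers import DensityMap, IntensityVolume, PatternStack, point_reflect
from .preprocess import RawFrame

__all__ = [
    "ParticleModel",
    "DetectorGeometry",
    "SimConfig",
    "GroundTruth",
    "make_icosahedron_density",
    "ground_truth_intensity",
    "render_single_hit",
    "render_multi_hit",
    "render_nonhit",
    "sphere_form_factor",
    "generate_dataset",
    "random_quaternion",
    "quaternion_to_matrix",
]

#: ADU value written into bad-mask pixels of rendered frames.
SENTINEL_ADU = -1.0e4

#: circumradius / inradius for a regular icosahedron.
_CIRCUM_OVER_IN = math.sqrt(3.0) * math.sqrt(10.0 + 2.0 * math.sqrt(5.0)) / (
    2.0 * (0.5 * (1.0 + math.sqrt(5.0))) ** 2
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ParticleModel:
    """Icosahedral capsid with an optional dense interior core.

    The core mimics the packaged genome: a sphere of higher density than the
    capsid shell, optionally displaced toward a vertex (``core_offset``,
    voxels) to model an off-centre interior.
    """

    grid_size: int = 32
    inradius: float = 10.0
    capsid_density: float = 1.0
    core_density: float = 1.6
    core_offset: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    core_radius: Optional[float] = None  # default: half the inradius
    edge_softness: float = 0.8
    voxel_size: float = 2.2  # nm

    def __post_init__(self) -> None:
        if self.capsid_density < 0 or self.core_density < 0:
            raise ValueError("densities must be non-negative")
        if self.core_radius is None:
            self.core_radius = 0.5 * self.inradius
        circum = self.inradius * _CIRCUM_OVER_IN
        if circum + 3.0 * self.edge_softness > self.grid_size / 2:
            raise ValueError(
                f"particle exceeds grid: circumradius {circum:.2f} vox "
                f"(+3 sigma blur {3 * self.edge_softness:.2f}) > half grid "
                f"{self.grid_size / 2:.2f}"
            )

    @property
    def circumradius(self) -> float:
        return self.inradius * _CIRCUM_OVER_IN


@dataclass
class DetectorGeometry:
    """Square small-angle detector in the flat-Ewald approximation."""

    n_pixels: int = 64
    pixel_q_step: float = 2.0 * math.pi / (96 * 2.2)  # nm^-1 per pixel
    wavelength: float = 0.2262  # nm (5.48 keV, amo-style soft X-ray regime)
    beam_center: Tuple[float, float] = (31.5, 31.5)
    mask: Optional[np.ndarray] = None
    gain: float = 28.0  # ADU per photon
    read_noise_adu: float = 4.0

    def __post_init__(self) -> None:
        if self.pixel_q_step <= 0:
            raise ValueError("pixel_q_step must be positive")
        bc = np.asarray(self.beam_center, dtype=float)
        if np.any(bc < -0.5) or np.any(bc > self.n_pixels - 0.5):
            raise ValueError("beam_center must lie inside the detector")
        if self.mask is None:
            self.mask = np.zeros((self.n_pixels, self.n_pixels), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.n_pixels, self.n_pixels):
            raise ValueError("mask must be n_pixels x n_pixels")

    def q_grid(self) -> np.ndarray:
        """Per-pixel (qx, qy, 0) vectors, nm^-1, shape (H, W, 3)."""
        r = np.arange(self.n_pixels, dtype=float)
        qy, qx = np.meshgrid(
            (r - self.beam_center[0]) * self.pixel_q_step,
            (r - self.beam_center[1]) * self.pixel_q_step,
            indexing="ij",
        )
        return np.stack([qy, qx, np.zeros_like(qx)], axis=-1)

    def q_radii(self) -> np.ndarray:
        """Per-pixel |q| in nm^-1."""
        return np.linalg.norm(self.q_grid(), axis=-1)


@dataclass
class SimConfig:
    """Composition and noise settings for a synthetic dataset.

    Default class fractions mirror a 79:121-style single:non-single mix with
    the non-single share split between multi-particle hits and droplet/blank
    frames.  Photon statistics are chosen so the three classes are separable
    by the classifiers this dataset exercises; they are not calibrated to any
    particular beamline.
    """

    n_patterns: int = 700
    fraction_single: float = 0.395
    fraction_multi: float = 0.35
    fraction_nonhit: float = 0.255
    mean_photons: float = 50000.0
    multi_hit_separation_range: Tuple[float, float] = (12.0, 32.0)  # voxels
    droplet_radius_range: Tuple[float, float] = (8.0, 16.0)  # voxels
    background_photon_rate: float = 0.02  # photons / pixel
    rng_seed: int = 0
    train_size: int = 200
    train_singles: int = 79

    def __post_init__(self) -> None:
        fr = (self.fraction_single, self.fraction_multi, self.fraction_nonhit)
        if any(f < 0 or f > 1 for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(fr)}")
        if self.mean_photons <= 0:
            raise ValueError("mean_photons must be positive")


@dataclass
class GroundTruth:
    """Per-pattern truth: class label, orientation, multi-hit displacement."""

    labels: np.ndarray  # str in {single, multi, nonhit}
    orientations: np.ndarray  # (n, 4) unit quaternions (w, x, y, z)
    displacements: np.ndarray  # (n, 3) voxels; NaN for non-multi
    train_mask: np.ndarray  # bool: member of the labelled training subset

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.orientations) == len(self.displacements)
                == len(self.train_mask) == n):
            raise ValueError("one entry per pattern required")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("quaternions must be unit norm")

    def binary(self) -> np.ndarray:
        """1 for single hits, 0 otherwise."""
        return (np.asarray(self.labels) == "single").astype(int)


# ---------------------------------------------------------------------------
# quaternions
# ---------------------------------------------------------------------------

def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform rotation via a normalized 4-vector of standard Gaussians."""
    q = rng.standard_normal(4)
    return q / np.linalg.norm(q)


def quaternion_to_matrix(quat: Sequence[float]) -> np.ndarray:
    w, x, y, z = np.asarray(quat, dtype=float)
    return Rotation.from_quat([x, y, z, w]).as_matrix()


# ---------------------------------------------------------------------------
# particle model and ground-truth intensities
# ---------------------------------------------------------------------------

def _icosahedron_face_normals() -> np.ndarray:
    """The 20 outward unit face normals (vertices of the dual dodecahedron)."""
    phi = 0.5 * (1.0 + math.sqrt(5.0))
    pts = []
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                pts.append((sx, sy, sz))
    for a in (-1 / phi, 1 / phi):
        for b in (-phi, phi):
            pts.append((0.0, a, b))
            pts.append((a, b, 0.0))
            pts.append((b, 0.0, a))
    pts = np.asarray(pts, dtype=float)
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def icosahedron_indicator(points: np.ndarray, inradius: float) -> np.ndarray:
    """True where a point lies inside the icosahedron of given inradius.

    A point is inside iff its projection on every face normal is at most the
    inradius.  Usable directly for Monte-Carlo volume checks.
    """
    normals = _icosahedron_face_normals()
    proj = points @ normals.T
    return np.max(proj, axis=-1) <= inradius


def make_icosahedron_density(model: ParticleModel) -> DensityMap:
    """Voxelized icosahedral capsid with an (optionally offset) dense core."""
    n = model.grid_size
    c = n // 2
    ax = np.arange(n, dtype=float) - c
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)

    vals = np.zeros((n, n, n), dtype=float)
    inside = icosahedron_indicator(pts.reshape(-1, 3), model.inradius)
    inside = inside.reshape(n, n, n)
    vals[inside] = model.capsid_density

    off = np.asarray(model.core_offset, dtype=float)
    rr2 = np.sum((pts - off) ** 2, axis=-1)
    core = (rr2 <= model.core_radius ** 2) & inside
    vals[core] += model.core_density - model.capsid_density

    if model.edge_softness > 0:
        vals = gaussian_filter(vals, model.edge_softness, mode="constant")
    np.clip(vals, 0.0, None, out=vals)

    # hard bounding sphere: nothing survives outside circumradius + blur tail
    bound = model.circumradius + 3.0 * model.edge_softness
    vals[zz ** 2 + yy ** 2 + xx ** 2 > bound ** 2] = 0.0
    return DensityMap(values=vals, voxel_size=model.voxel_size)


def ground_truth_intensity(density: DensityMap, oversampling: float = 3.0) -> IntensityVolume:
    """|F|^2 of the zero-padded density on a centred cubic grid.

    ``oversampling`` is the linear padding ratio; values below 2 would make
    the support-constrained phase problem ill-posed and are rejected.  The
    complex amplitudes are retained for interference (multi-hit) rendering.
    """
    if oversampling < 2:
        raise ValueError("oversampling must be >= 2 (phasing would be ill-posed)")
    n = density.values.shape[0]
    big = int(round(n * oversampling))
    pad = np.zeros((big, big, big), dtype=float)
    lo = (big - n) // 2
    pad[lo:lo + n, lo:lo + n, lo:lo + n] = density.values
    amps = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(pad)))
    q_per_voxel = 2.0 * math.pi / (big * density.voxel_size)
    return IntensityVolume(
        intensities=np.abs(amps) ** 2,
        q_calibration=q_per_voxel,
        amplitudes=amps,
    )


def sphere_form_factor(q, radius: float):
    """Relative scattered intensity I(q)/I(0) of a uniform sphere.

    [3 (sin qR - qR cos qR) / (qR)^3]^2, with the analytic limit 1 at q = 0.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    x = np.asarray(q, dtype=float) * radius
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-8
    xn = x[nz]
    out[nz] = (3.0 * (np.sin(xn) - xn * np.cos(xn)) / xn ** 3) ** 2
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

def _slice_volume(arr: np.ndarray, geometry: DetectorGeometry,
                  q_calibration: float, quat: Sequence[float]) -> np.ndarray:
    """Trilinear central-slice sample of a centred volume; errors if the
    rotated detector plane exits the volume."""
    rot = quaternion_to_matrix(quat)
    qvec = geometry.q_grid() @ rot  # sample at R^T q: particle rotated by R
    coords = qvec / q_calibration + arr.shape[0] // 2
    if coords.min() < 0 or coords.max() > arr.shape[0] - 1:
        raise ValueError("requested slice exits the intensity volume")
    coords = np.moveaxis(coords, -1, 0)
    if np.iscomplexobj(arr):
        re = map_coordinates(arr.real, coords, order=1, mode="constant")
        im = map_coordinates(arr.imag, coords, order=1, mode="constant")
        return re + 1j * im
    return map_coordinates(arr, coords, order=1, mode="constant")


def _detect(intensity: np.ndarray, geometry: DetectorGeometry,
            mean_photons: Optional[float], rng: Optional[np.random.Generator],
            background_rate: float, noiseless: bool,
            pattern_id: str) -> RawFrame:
    """Common detection path: photon scaling, Poisson draw, ADU conversion."""
    lam = np.clip(intensity, 0.0, None)
    if mean_photons is not None:
        tot = lam.sum()
        lam = lam * (mean_photons / tot) if tot > 0 else lam
    lam = lam + background_rate
    if noiseless:
        values = lam.copy()
    else:
        photons = rng.poisson(lam).astype(float)
        values = photons * geometry.gain
        if geometry.read_noise_adu > 0:
            values = values + rng.normal(0.0, geometry.read_noise_adu, lam.shape)
    values[geometry.mask] = SENTINEL_ADU
    return RawFrame(values=values, mask=geometry.mask.copy(), pattern_id=pattern_id)


def render_single_hit(volume: IntensityVolume, orientation: Sequence[float],
                      geometry: DetectorGeometry, mean_photons: Optional[float],
                      rng: Optional[np.random.Generator] = None, *,
                      background_rate: float = 0.0, noiseless: bool = False,
                      pattern_id: str = "") -> RawFrame:
    """Detector frame of one particle at the given orientation.

    With ``noiseless=True`` the expected photon map is returned directly (no
    Poisson draw, no gain/read noise); with ``mean_photons=None`` the central
    slice is returned in the volume's native intensity units.
    """
    sl = _slice_volume(volume.intensities, geometry, volume.q_calibration, orientation)
    return _detect(sl, geometry, mean_photons, rng, background_rate, noiseless, pattern_id)


def render_multi_hit(volume: IntensityVolume, orientations: Sequence[Sequence[float]],
                     displacement: Sequence[float], geometry: DetectorGeometry,
                     mean_photons: Optional[float],
                     rng: Optional[np.random.Generator] = None, *,
                     volume2: Optional[IntensityVolume] = None,
                     background_rate: float = 0.0, noiseless: bool = False,
                     pattern_id: str = "") -> RawFrame:
    """Two-particle interference frame.

    Complex amplitudes are combined before squaring,
    F_tot(q) = F1(R1 q) + exp(-i q . d) F2(R2 q), so the frame carries
    interference fringes of period 2 pi / |d_xy| along the in-plane
    projection of the lab-frame displacement ``d`` (volume voxels); the
    axial component is invisible on a flat-Ewald detector.  ``mean_photons``
    is the expected photon count per particle (the frame totals twice that).
    """
    if volume.amplitudes is None:
        raise ValueError("multi-hit rendering needs complex amplitudes "
                         "(synthetic ground-truth volume)")
    vol2 = volume2 if volume2 is not None else volume
    if vol2.amplitudes is None:
        raise ValueError("second volume lacks complex amplitudes")
    q1, q2 = orientations
    f1 = _slice_volume(volume.amplitudes, geometry, volume.q_calibration, q1)
    f2 = _slice_volume(vol2.amplitudes, geometry, vol2.q_calibration, q2)
    d = np.asarray(displacement, dtype=float)  # lab frame, volume voxels
    n = volume.intensities.shape[0]
    kvec = geometry.q_grid() / volume.q_calibration  # lab-frame voxel offsets
    phase = np.exp(-2j * math.pi * (kvec @ d) / n)
    intensity = np.abs(f1 + phase * f2) ** 2
    mp = None if mean_photons is None else 2.0 * mean_photons
    return _detect(intensity, geometry, mp, rng, background_rate, noiseless, pattern_id)


def render_nonhit(geometry: DetectorGeometry, droplet_radius: float,
                  background_photon_rate: float,
                  rng: Optional[np.random.Generator] = None, *,
                  droplet_photons: float = 1500.0, noiseless: bool = False,
                  pattern_id: str = "") -> RawFrame:
    """Droplet or blank frame: uniform-sphere scattering plus flat background.

    ``droplet_radius`` is in nm (0 gives a pure-background frame).
    """
    if droplet_radius < 0:
        raise ValueError("droplet_radius must be >= 0")
    if droplet_radius > 0:
        ff = sphere_form_factor(geometry.q_radii(), droplet_radius)
        mp: Optional[float] = droplet_photons
    else:
        ff = np.zeros((geometry.n_pixels, geometry.n_pixels))
        mp = None
    return _detect(ff, geometry, mp, rng, background_photon_rate, noiseless, pattern_id)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def largest_remainder_counts(fractions: Sequence[float], n: int) -> np.ndarray:
    """Apportion n items to stated fractions; deterministic largest-remainder
    rounding with index-order tie-break."""
    f = np.asarray(fractions, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    exact = f * n
    base = np.floor(exact).astype(int)
    rem = exact - base
    short = n - base.sum()
    order = np.lexsort((np.arange(len(f)), -rem))
    for i in order[:short]:
        base[i] += 1
    return base


def generate_dataset(config: SimConfig,
                     model: Optional[ParticleModel] = None,
                     geometry: Optional[DetectorGeometry] = None, *,
                     oversampling: float = 3.0,
                     path: Optional[str] = None,
                     ) -> Tuple[PatternStack, GroundTruth, IntensityVolume]:
    """Render a labelled synthetic dataset.

    Returns the ADU frame stack, the ground truth (labels, orientations,
    displacements, training-subset flags) and the ground-truth oversampled
    intensity volume.  Fully reproducible from ``config.rng_seed``.  When
    ``path`` is given the dataset is also written in the CXI-style HDF5
    layout of :mod:`spisort.io_cli`.
    """
    model = model if model is not None else ParticleModel()
    geometry = geometry if geometry is not None else DetectorGeometry()
    rng = np.random.default_rng(config.rng_seed)

    density = make_icosahedron_density(model)
    volume = ground_truth_intensity(density, oversampling)

    counts = largest_remainder_counts(
        (config.fraction_single, config.fraction_multi, config.fraction_nonhit),
        config.n_patterns,
    )
    labels = np.array(
        ["single"] * counts[0] + ["multi"] * counts[1] + ["nonhit"] * counts[2],
        dtype=object,
    )
    rng.shuffle(labels)

    n = config.n_patterns
    frames = np.empty((n, geometry.n_pixels, geometry.n_pixels), dtype=float)
    quats = np.empty((n, 4))
    disps = np.full((n, 3), np.nan)
    for i, lab in enumerate(labels):
        pid = f"evt{i:06d}"
        quats[i] = random_quaternion(rng)
        if lab == "single":
            fr = render_single_hit(
                volume, quats[i], geometry, config.mean_photons, rng,
                background_rate=config.background_photon_rate, pattern_id=pid)
        elif lab == "multi":
            q2 = random_quaternion(rng)
            lo, hi = config.multi_hit_separation_range
            # the axial (beam-direction) separation is unobservable under
            # flat Ewald, so the configured range governs the in-plane,
            # fringe-forming component; a modest axial part is added on top
            r_xy = rng.uniform(lo, hi)
            az = rng.uniform(0.0, 2.0 * math.pi)
            dz = rng.uniform(-0.5, 0.5) * r_xy
            disps[i] = (r_xy * math.cos(az), r_xy * math.sin(az), dz)
            fr = render_multi_hit(
                volume, (quats[i], q2), disps[i], geometry,
                config.mean_photons, rng,
                background_rate=config.background_photon_rate, pattern_id=pid)
        else:
            lo, hi = config.droplet_radius_range
            radius_nm = rng.uniform(lo, hi) * model.voxel_size
            fr = render_nonhit(
                geometry, radius_nm, config.background_photon_rate, rng,
                droplet_photons=0.5 * config.mean_photons, pattern_id=pid)
        frames[i] = fr.values

    ids = np.array([f"evt{i:06d}" for i in range(n)], dtype=object)
    train_mask = _pick_training_subset(labels, config, rng)
    truth = GroundTruth(labels=labels, orientations=quats,
                        displacements=disps, train_mask=train_mask)
    stack = PatternStack(frames=frames, ids=ids,
                         mask=geometry.mask.copy(), geometry=geometry)
    if path is not None:
        from .io_cli import write_cxi
        write_cxi(path, stack, truth)
    return stack, truth, volume


def _pick_training_subset(labels: np.ndarray, config: SimConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Flag a labelled training subset (default 200 at a 79:121
    single:non-single ratio, falling back to what the composition allows)."""
    labels = np.asarray(labels)
    mask = np.zeros(len(labels), dtype=bool)
    if config.train_size <= 0:
        return mask
    singles = np.flatnonzero(labels == "single")
    others = np.flatnonzero(labels != "single")
    n_s = min(config.train_singles, len(singles))
    n_o = min(config.train_size - n_s, len(others))
    mask[rng.choice(singles, size=n_s, replace=False)] = True
    mask[rng.choice(others, size=n_o, replace=False)] = True
    return mask
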