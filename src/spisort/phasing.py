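"""Iterative phase retrieval: error reduction, difference map, dynamic
support, multi-run ensembles with alignment/averaging, and the PRTF.

The two constraint projections are

* P_M (modulus): replace Fourier amplitudes by sqrt(I) on measured voxels,
  keeping phases; unmeasured voxels (beamstop etc.) float freely;
* P_S (support): zero outside the support and clip negatives inside —
  electron density is real and non-negative.

Error reduction is the alternating projection P_S . P_M; the difference map
is the relaxed form x <- x + beta [P_S(2 P_M x - x) - P_M x] with beta = 1.
The support is re-derived every iteration as the ``support_size`` voxels of
largest density (a projection onto the set of non-negative maps with a
bounded support), so the ER modulus error is non-increasing step to step.

Because every run phases the *same* intensity volume, runs differ only by a
translation and the Friedel inversion twin rho(-r); alignment therefore
searches integer shifts for both hands and no rotational alignment is
needed.  The PRTF per reciprocal voxel is |mean_k exp(i phi_k)| over the
aligned runs, radially averaged; its 1/e crossing is the resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .containers import DensityMap, IntensityVolume, ShellCurve, point_reflect

__all__ = [
    "PhasingRun",
    "PhasingEnsemble",
    "er_iterate",
    "dm_iterate",
    "update_support",
    "run_phasing",
    "run_phasing_ensemble",
    "align_and_average",
    "prtf_curve",
    "phasing_errors",
]


@dataclass
class PhasingRun:
    """One phasing trajectory: final density plus per-iteration traces."""

    density: np.ndarray
    convergence: np.ndarray
    modulus_error: np.ndarray
    seed: int
    diverged: bool = False


@dataclass
class PhasingEnsemble:
    """A set of independent runs over one intensity volume."""

    runs: List[PhasingRun]
    schedule: Tuple[int, int, int]
    support_size: int
    seeds: List[int]
    q_calibration: float = 1.0
    aligned_densities: Optional[np.ndarray] = None  # (n_runs, N, N, N)

    @property
    def aligned(self) -> bool:
        return self.aligned_densities is not None


# ---------------------------------------------------------------------------
# projections and single iterations
# ---------------------------------------------------------------------------

def _reciprocal_data(volume: IntensityVolume):
    """sqrt(I) and the measured mask in natural FFT order."""
    sq = np.sqrt(np.clip(volume.intensities, 0.0, None))
    return np.fft.ifftshift(sq), np.fft.ifftshift(volume.measured_mask)


def _modulus_project(rho: np.ndarray, sqrt_i: np.ndarray,
                     measured: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    f = np.fft.fftn(rho)
    amp = np.abs(f)
    phasor = np.where(amp > 0, f / np.where(amp > 0, amp, 1.0), 1.0)
    f_new = np.where(measured, sqrt_i * phasor, f)
    return np.fft.ifftn(f_new).real, f


def _support_project(rho: np.ndarray, support: np.ndarray) -> np.ndarray:
    return np.where(support, np.maximum(rho, 0.0), 0.0)


def er_iterate(density: np.ndarray, volume: IntensityVolume,
               support: np.ndarray) -> np.ndarray:
    """One error-reduction cycle: P_S(P_M(density))."""
    sqrt_i, measured = _reciprocal_data(volume)
    rho_m, _ = _modulus_project(np.asarray(density, dtype=float), sqrt_i, measured)
    return _support_project(rho_m, support)


def dm_iterate(density: np.ndarray, volume: IntensityVolume,
               support: np.ndarray, beta: float = 1.0) -> np.ndarray:
    """One difference-map step, x + beta [P_S(2 P_M x - x) - P_M x]."""
    x = np.asarray(density, dtype=float)
    sqrt_i, measured = _reciprocal_data(volume)
    y, _ = _modulus_project(x, sqrt_i, measured)
    return x + beta * (_support_project(2.0 * y - x, support) - y)


def update_support(density: np.ndarray, n_voxels: int = 2000) -> np.ndarray:
    """The ``n_voxels`` voxels of largest |density|; ties broken by voxel
    index order so exactly ``n_voxels`` are always set."""
    flat = np.abs(np.asarray(density, dtype=float)).ravel()
    if n_voxels > flat.size:
        raise ValueError("n_voxels exceeds the grid")
    if n_voxels == flat.size:
        return np.ones(density.shape, dtype=bool)
    order = np.argsort(-flat, kind="stable")
    support = np.zeros(flat.size, dtype=bool)
    support[order[:n_voxels]] = True
    return support.reshape(density.shape)


def phasing_errors(model_k: np.ndarray, model_prev: np.ndarray,
                   volume: IntensityVolume) -> Tuple[float, float]:
    """(convergence, modulus error) of an iterate.

    convergence = ||rho_k - rho_{k-1}||_2 / ||rho_k||_2;
    modulus_error = || |F(rho_k)| - sqrt(I) ||_2 / ||sqrt(I)||_2 over the
    measured voxels.  A zero denominator with a zero numerator gives 0.
    """
    rho = np.asarray(model_k, dtype=float)
    diff = np.linalg.norm(rho - np.asarray(model_prev, dtype=float))
    norm = np.linalg.norm(rho)
    if norm == 0:
        if diff == 0:
            conv = 0.0
        else:
            raise ZeroDivisionError("convergence undefined: ||rho_k|| = 0")
    else:
        conv = float(diff / norm)

    sqrt_i, measured = _reciprocal_data(volume)
    amp = np.abs(np.fft.fftn(rho))
    num = np.linalg.norm((amp - sqrt_i)[measured])
    den = np.linalg.norm(sqrt_i[measured])
    if den == 0:
        if num == 0:
            return conv, 0.0
        raise ZeroDivisionError("modulus error undefined: ||sqrt(I)|| = 0")
    return conv, float(num / den)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def run_phasing(volume: IntensityVolume,
                schedule: Tuple[int, int, int] = (100, 200, 200),
                support_size: int = 2000, seed: int = 0) -> PhasingRun:
    """One seeded phasing run: ER, then difference map, then ER again.

    Starts from uniformly random phases on the measured amplitudes; the
    support is refreshed every iteration from the current phased model.
    Returns the final density together with per-iteration convergence and
    modulus-error traces.  NaN divergence aborts with a diagnostic.
    """
    sqrt_i, measured = _reciprocal_data(volume)
    n_er1, n_dm, n_er2 = schedule
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * math.pi, volume.shape)
    rho = np.fft.ifftn(sqrt_i * np.exp(1j * phases)).real

    sq_norm = np.linalg.norm(sqrt_i[measured])
    conv_trace: List[float] = []
    err_trace: List[float] = []
    prev = rho.copy()

    def _amp_err(f: np.ndarray) -> float:
        num = np.linalg.norm((np.abs(f) - sqrt_i)[measured])
        return float(num / sq_norm) if sq_norm > 0 else 0.0

    # trace entry k describes the OUTPUT of iteration k; the amplitude error
    # of an iterate is read off the FFT computed at the start of the next
    # iteration (one extra FFT closes the trace after the loop)
    first = True
    for stage, count in (("er", n_er1), ("dm", n_dm), ("er", n_er2)):
        for _ in range(count):
            y, f = _modulus_project(rho, sqrt_i, measured)
            if not first:
                err_trace.append(_amp_err(f))
            first = False
            if stage == "er":
                support = update_support(np.maximum(y, 0.0), support_size)
                rho_new = _support_project(y, support)
            else:
                t = 2.0 * y - rho
                support = update_support(np.maximum(t, 0.0), support_size)
                rho_new = rho + _support_project(t, support) - y
            if not np.all(np.isfinite(rho_new)):
                raise FloatingPointError(
                    f"phasing run (seed {seed}) diverged to non-finite values "
                    f"in the {stage} stage")
            nrm = np.linalg.norm(rho_new)
            conv_trace.append(float(np.linalg.norm(rho_new - prev) / nrm)
                              if nrm > 0 else 0.0)
            prev = rho_new.copy()
            rho = rho_new
    err_trace.append(_amp_err(np.fft.fftn(rho)))

    return PhasingRun(density=rho, convergence=np.asarray(conv_trace),
                      modulus_error=np.asarray(err_trace), seed=seed)


def run_phasing_ensemble(volume: IntensityVolume, n_runs: int = 40,
                         schedule: Tuple[int, int, int] = (100, 200, 200),
                         support_size: int = 2000,
                         seed: int = 0) -> PhasingEnsemble:
    """N independent seeded runs (seeds spawned deterministically)."""
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(seed).spawn(n_runs)]
    runs = [run_phasing(volume, schedule, support_size, s) for s in seeds]
    return PhasingEnsemble(runs=runs, schedule=tuple(schedule),
                           support_size=support_size, seeds=seeds,
                           q_calibration=volume.q_calibration)


# ---------------------------------------------------------------------------
# alignment, averaging, PRTF
# ---------------------------------------------------------------------------

def _best_alignment(ref_f: np.ndarray, cand: np.ndarray
                    ) -> Tuple[np.ndarray, float]:
    """Align ``cand`` to the reference (given as its FFT) over integer
    circular shifts and the inversion twin; returns the aligned array and
    the correlation peak value."""
    best, best_score = cand, -np.inf
    for hand in (cand, point_reflect(cand).copy()):
        corr = np.fft.ifftn(ref_f * np.conj(np.fft.fftn(hand))).real
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[peak] > best_score:
            best_score = corr[peak]
            best = np.roll(hand, peak, axis=(0, 1, 2))
    return best, best_score


def align_and_average(runs, voxel_size: float = 1.0) -> DensityMap:
    """Align every run to the first (integer shift + inversion twin) and
    average voxelwise.

    ``runs`` may be a PhasingEnsemble (its ``aligned_densities`` field is
    filled in as a side effect), a list of PhasingRun, or a list of arrays.
    """
    ensemble = runs if isinstance(runs, PhasingEnsemble) else None
    if ensemble is not None:
        dens = [r.density for r in ensemble.runs]
    elif len(runs) and isinstance(runs[0], PhasingRun):
        dens = [r.density for r in runs]
    else:
        dens = [np.asarray(r, dtype=float) for r in runs]
    if not dens:
        raise ValueError("need at least one run")
    ref = dens[0]
    ref_f = np.fft.fftn(ref)
    aligned = [ref.copy()]
    for d in dens[1:]:
        a, _ = _best_alignment(ref_f, d)
        aligned.append(a)
    stack = np.stack(aligned)
    if ensemble is not None:
        ensemble.aligned_densities = stack
    return DensityMap(values=stack.mean(axis=0), voxel_size=voxel_size)


def prtf_curve(runs: Union[PhasingEnsemble, Sequence[np.ndarray]],
               q_calibration: Optional[float] = None, n_bins: int = 16, *,
               aligned: bool = False) -> ShellCurve:
    """Phase-retrieval transfer function of an aligned ensemble.

    PRTF(q voxel) = |(1/N) sum_k exp(i phi_k(q))| with phi_k the reciprocal
    phases of run k, then radially averaged.  The curve's 1/e crossing
    (``curve.crossing(1 / math.e)``) is the conventional resolution.
    Unaligned inputs are rejected: without alignment the linear phase ramps
    of arbitrary shifts destroy the statistic.
    """
    if isinstance(runs, PhasingEnsemble):
        if not runs.aligned:
            raise ValueError("ensemble not aligned: call align_and_average first")
        dens = runs.aligned_densities
        if q_calibration is None:
            q_calibration = runs.q_calibration
    else:
        if not aligned:
            raise ValueError("pass aligned=True only for pre-aligned arrays")
        dens = np.stack([np.asarray(r, dtype=float) for r in runs])
    if len(dens) < 2:
        raise ValueError("need at least two runs")
    if q_calibration is None:
        q_calibration = 1.0

    phasors = np.zeros(dens.shape[1:], dtype=complex)
    for d in dens:
        f = np.fft.fftn(d)
        amp = np.abs(f)
        phasors += np.where(amp > 0, f / np.where(amp > 0, amp, 1.0), 1.0)
    prtf = np.abs(np.fft.fftshift(phasors)) / len(dens)

    shape = prtf.shape
    axes = [np.arange(n) - n // 2 for n in shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    radius = np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)
    r_max = shape[0] // 2
    edges = np.linspace(0.0, r_max, n_bins + 1)
    which = np.digitize(radius.ravel(), edges) - 1
    keep = (which >= 0) & (which < n_bins) & (radius.ravel() <= r_max)
    sums = np.bincount(which[keep], weights=prtf.ravel()[keep], minlength=n_bins)
    counts = np.bincount(which[keep], minlength=n_bins)
    vals = np.divide(sums, counts, out=np.full(n_bins, np.nan),
                     where=counts > 0)
    return ShellCurve(q_edges=edges * q_calibration, values=vals,
                      counts=counts)
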