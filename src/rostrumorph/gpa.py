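"""Generalized Procrustes Analysis with curve-sliding semilandmarks.

All configurations are translated to a common origin, scaled to unit centroid
size and rotated (reflections disallowed: biological specimens share
handedness) to a consensus that is re-estimated each iteration.  Curve
semilandmarks may additionally slide along their local tangent directions so
as to minimise the bending energy of the thin-plate-spline deformation from
the consensus to each specimen — the standard treatment of points that carry
curve rather than point homology.

The TPS bending-energy quadratic form is the upper-left block of the inverted
bordered kernel system; in 3D the kernel orientation is chosen so the form is
positive semidefinite, and it annihilates every affine transformation of the
reference (the 4-dimensional-per-coordinate null space of the spline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import LandmarkConfiguration, N_FIXED, N_LANDMARKS

logger = logging.getLogger(__name__)


class DegenerateConfigurationError(ValueError):
    """All landmarks coincident, or a TPS/tangent construction is singular."""


@dataclass
class AlignedSample:
    """Result of GPA: aligned unit-size shapes and their size components.

    Attributes
    ----------
    shapes : (n, 22, 3) array, dimensionless (unit centroid size).
    centroid_sizes : (n,) array in original length units.
    consensus : (22, 3) mean shape, unit centroid size.
    procrustes_distances : (n,) distance of each specimen to the consensus.
    specimen_ids : specimen identifiers in input order.
    iterations : outer GPA iterations performed.
    converged : whether the objective change fell below tolerance.
    """

    shapes: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    procrustes_distances: np.ndarray
    specimen_ids: list[str]
    iterations: int
    converged: bool
    objective_trace: list[float]


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of the summed squared distances of all landmarks from
    their centroid; the size component removed by Procrustes scaling."""
    coords = config.coordinates if isinstance(config, LandmarkConfiguration) else np.asarray(config, dtype=float)
    centred = coords - coords.mean(axis=0)
    size = float(np.sqrt((centred**2).sum()))
    if size == 0.0:
        raise DegenerateConfigurationError("all landmarks coincident")
    return size


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares proper rotation (det=+1) carrying ``source`` onto
    ``target``; both must be centred and share a landmark scheme.

    Row-vector convention: the rotation is applied as ``source @ R``.
    Sign-corrected SVD (Kabsch): reflections are disallowed, so for a chiral
    source and its mirror image the residual stays positive.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValueError(f"landmark counts differ: {source.shape} vs {target.shape}")
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    return u @ corr @ vt


def _centre_and_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    centred = coords - coords.mean(axis=0)
    size = float(np.sqrt((centred**2).sum()))
    if size == 0.0:
        raise DegenerateConfigurationError("all landmarks coincident")
    return centred / size, size


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Root-sum-of-squares residual between two centred unit-size shapes
    after optimal (proper) rotation of ``a`` onto ``b``. Symmetric."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mismatched landmark schemes")
    rot = optimal_rotation(a, b)
    return float(np.sqrt(((a @ rot - b) ** 2).sum()))


@dataclass
class BendingEnergyModel:
    """Thin-plate-spline system for a reference shape.

    ``bending_energy_form`` is the 22x22 symmetric PSD matrix B such that the
    bending energy of a mapping taking the reference to target coordinates Y
    is trace(Y' B Y); it is zero exactly when the deformation is affine.
    """

    reference: np.ndarray
    kernel_matrix: np.ndarray
    bending_energy_form: np.ndarray

    def energy(self, target: np.ndarray) -> float:
        y = np.asarray(target, dtype=float)
        return float(np.einsum("ic,ij,jc->", y, self.bending_energy_form, y))


def bending_energy_model(reference: np.ndarray) -> BendingEnergyModel:
    """Build the TPS bending-energy form for a 3D reference configuration.

    The bordered system uses the 3D radial kernel U(r)=r with the sign
    orientation that makes the resulting quadratic form positive
    semidefinite; its null space per coordinate is spanned by {1, x, y, z},
    so affine deformations of the reference cost exactly zero.
    """
    ref = np.asarray(reference, dtype=float)
    k = ref.shape[0]
    diff = ref[:, None, :] - ref[None, :, :]
    kernel = np.sqrt((diff**2).sum(axis=2))
    q = np.column_stack([np.ones(k), ref])
    bordered = np.zeros((k + 4, k + 4))
    bordered[:k, :k] = kernel
    bordered[:k, k:] = q
    bordered[k:, :k] = q.T
    try:
        inv = np.linalg.inv(bordered)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConfigurationError(
            "singular TPS system (coplanar or coincident landmarks); "
            "jitter or regularize the reference"
        ) from exc
    form = inv[:k, :k]
    form = 0.5 * (form + form.T)
    # U(r)=r yields the negative-definite orientation in 3D; flip to PSD
    if np.trace(form) < 0:
        form = -form
    return BendingEnergyModel(reference=ref, kernel_matrix=kernel, bending_energy_form=form)


def _tangent_directions(shape: np.ndarray, curve: Sequence[int], specimen: str) -> np.ndarray:
    """Unit tangents for each slider on one curve: chord direction of the two
    curve neighbours; endpoint sliders use their single neighbour."""
    curve = list(curve)
    tangents = np.zeros((len(curve), 3))
    for j, idx in enumerate(curve):
        if len(curve) == 1:
            raise DegenerateConfigurationError(
                f"specimen {specimen!r}: single-point curve has no tangent"
            )
        lo = curve[j - 1] if j > 0 else curve[j]
        hi = curve[j + 1] if j < len(curve) - 1 else curve[j]
        vec = shape[hi] - shape[lo]
        norm = np.linalg.norm(vec)
        if norm < 1e-12:
            raise DegenerateConfigurationError(
                f"specimen {specimen!r}: coincident curve neighbours at landmark {idx + 1}"
            )
        tangents[j] = vec / norm
    return tangents


def slide_semilandmarks(
    shapes: np.ndarray,
    consensus: np.ndarray,
    curves: Sequence[Sequence[int]],
    specimen_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Slide each specimen's semilandmarks along their local tangent
    directions to minimise TPS bending energy relative to the consensus.

    Fixed landmarks are untouched (bitwise); sliders move only along the
    chord direction of their curve neighbours.  The displacement solves the
    exact quadratic minimisation, so bending energy never increases.
    """
    shapes = np.asarray(shapes, dtype=float)
    single = shapes.ndim == 2
    if single:
        shapes = shapes[None]
    model = bending_energy_model(consensus)
    b = model.bending_energy_form
    slider_idx = [i for curve in curves for i in curve]
    out = shapes.copy()
    for s in range(shapes.shape[0]):
        name = specimen_ids[s] if specimen_ids is not None else f"#{s}"
        shape = shapes[s].copy()
        # tangents rotate as sliders move, so iterate the exact quadratic
        # solve to its fixed point (each pass is energy non-increasing)
        for _ in range(20):
            tangents = np.vstack(
                [_tangent_directions(shape, curve, name) for curve in curves]
            )
            # quadratic in slide amounts t: E(t) = E0 + g.t + 0.5 t'H t
            bsub = b[np.ix_(slider_idx, slider_idx)]
            hess = 2.0 * (tangents @ tangents.T) * bsub
            grad = 2.0 * np.einsum("jc,jc->j", tangents, (b @ shape)[slider_idx])
            # PSD least-squares solve: flat (null) directions stay put
            t, *_ = np.linalg.lstsq(hess, -grad, rcond=None)
            shape[slider_idx] = shape[slider_idx] + t[:, None] * tangents
            if np.abs(t).max() < 1e-10:
                break
        out[s] = shape
    return out[0] if single else out


def _principal_frame(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation taking the consensus to its principal-axis frame,
    with axis signs fixed deterministically by projection skewness."""
    centred = consensus - consensus.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    v = vt.T
    proj = centred @ v
    for k in (0, 1):
        if (proj[:, k] ** 3).sum() < 0:
            v[:, k] = -v[:, k]
    v[:, 2] = np.cross(v[:, 0], v[:, 1])
    return v


def gpa_align(
    configs: Sequence[LandmarkConfiguration],
    slide: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
    slide_iterations: int = 3,
) -> AlignedSample:
    """Iterative Generalized Procrustes superimposition.

    Each outer iteration centres every configuration, scales it to unit
    centroid size, rotates it onto the current consensus, optionally slides
    the curve semilandmarks by minimum bending energy, and recomputes the
    consensus (renormalised to unit size).  Iteration stops when the relative
    change of the summed squared Procrustes residuals falls below ``tol``.
    Deterministic given input order; the consensus is initialised from the
    first configuration's centred, scaled shape.

    Sliding runs only during the first ``slide_iterations`` outer iterations
    (then plain GPA runs to convergence): semilandmark positions along
    straight outline stretches are bending-energy-flat, so fully interleaved
    sliding against an evolving consensus drifts without converging.  A few
    passes recover the curve-homologous positions; more only chase the
    drift.
    """
    if len(configs) < 2:
        raise ValueError("GPA requires at least two configurations")
    ids = [c.specimen_id for c in configs]
    curves = (list(configs[0].ventral), list(configs[0].dorsal))
    raw = np.stack([c.coordinates for c in configs])
    shapes = np.empty_like(raw)
    sizes = np.empty(len(configs))
    for i, cfg in enumerate(configs):
        try:
            shapes[i], sizes[i] = _centre_and_scale(cfg.coordinates)
        except DegenerateConfigurationError as exc:
            raise DegenerateConfigurationError(
                f"specimen {cfg.specimen_id!r}: {exc}"
            ) from exc

    consensus = shapes[0].copy()
    objective = np.inf
    trace: list[float] = []
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        for i in range(len(configs)):
            rot = optimal_rotation(shapes[i], consensus)
            shapes[i] = shapes[i] @ rot
        if slide and iteration <= slide_iterations:
            shapes = slide_semilandmarks(shapes, consensus, curves, ids)
            for i in range(len(configs)):
                shapes[i], _ = _centre_and_scale(shapes[i])
                rot = optimal_rotation(shapes[i], consensus)
                shapes[i] = shapes[i] @ rot
        consensus = shapes.mean(axis=0)
        consensus, _ = _centre_and_scale(consensus)
        new_objective = float(((shapes - consensus) ** 2).sum())
        trace.append(new_objective)
        logger.info("GPA iteration %d: objective %.3e", iteration, new_objective)
        if np.isfinite(objective) and abs(objective - new_objective) < tol * (objective + tol):
            objective = new_objective
            converged = True
            break
        objective = new_objective
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)
    # canonical orientation: principal axes of the consensus, signs fixed by
    # the third moment of the projections, proper (det=+1) frame — so the
    # result does not depend on the input specimens' arbitrary orientation
    rot = _principal_frame(consensus)
    consensus = consensus @ rot
    shapes = shapes @ rot
    distances = np.array([procrustes_distance(s, consensus) for s in shapes])
    return AlignedSample(
        shapes=shapes,
        centroid_sizes=sizes,
        consensus=consensus,
        procrustes_distances=distances,
        specimen_ids=ids,
        iterations=iteration,
        converged=converged,
        objective_trace=trace,
    )
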