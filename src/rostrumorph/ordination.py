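"""Tangent-space PCA of Procrustes-aligned shapes: the morphospace.

PC1 of the belemnite rostrum morphospace captures the width-to-length
proportion of the rostrum ("robustness") and is used downstream as the main
morphology proxy.  Eigenvector signs are arbitrary, so a deterministic sign
convention is applied and PC1 is additionally oriented so that HIGHER
scores mean MORE robust shapes.  With contrasts ordered
earlier-sample-first, an increase in robustness through time then prints as
a negative Hedges' g, and negative allometric slopes mean smaller (younger)
specimens are more robust — reproducing the reported effect directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gpa import AlignedSample


@dataclass
class MorphospaceModel:
    """PCA decomposition of the aligned-shape sample.

    ``axes`` holds orthonormal loading vectors (one row per component) over
    the 66 flattened coordinates; ``scores`` the per-specimen coordinates on
    each axis (zero mean per axis).  ``center`` is the flattened morphospace
    origin: the consensus under tangent projection, otherwise the sample
    mean of the flattened aligned coordinates.
    """

    consensus: np.ndarray
    center: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    axes: np.ndarray
    scores: np.ndarray
    specimen_ids: list[str]
    tangent: bool
    pc1_flipped_for_robustness: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.axes.shape[0]


def _tangent_project(flat: np.ndarray, consensus_flat: np.ndarray) -> np.ndarray:
    """Orthogonal projection of unit-size shape vectors onto the tangent
    space of shape space at the consensus."""
    c = consensus_flat / np.linalg.norm(consensus_flat)
    dev = flat - c
    return c + dev - np.outer(dev @ c, c)


def shape_elongation_ratio(shape: np.ndarray) -> float:
    """Width/length proportion of a single configuration, measured as the
    ratio of its extents along its second and first principal directions.
    Rotation- and scale-invariant; higher values = more robust rostra."""
    coords = np.asarray(shape, dtype=float)
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    proj = centred @ vt.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    if extents[0] == 0:
        raise ValueError("degenerate configuration: zero extent")
    return float(extents[1] / extents[0])


def pca_fit(
    aligned: AlignedSample,
    tangent: bool = True,
    orient_robustness: bool = True,
    eigval_tol: float = 1e-12,
) -> MorphospaceModel:
    """Principal Component Analysis of the aligned shapes.

    Covariance PCA on the flattened (optionally tangent-projected)
    coordinates; Procrustes coordinates are commensurate so no per-coordinate
    standardisation is applied.  Axes with singular value below
    ``eigval_tol`` times the largest are dropped.  Sign convention: each
    axis's largest-magnitude loading is positive; if ``orient_robustness``,
    PC1 is then flipped (if needed) so lower scores mean more robust shapes.
    """
    n = aligned.shapes.shape[0]
    if n < 3:
        raise ValueError("PCA requires at least 3 specimens")
    flat = aligned.shapes.reshape(n, -1)
    consensus_flat = aligned.consensus.reshape(-1)
    if tangent:
        data = _tangent_project(flat, consensus_flat)
        center = consensus_flat / np.linalg.norm(consensus_flat)
    else:
        data = flat
        center = flat.mean(axis=0)
    centred = data - data.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    keep = s > eigval_tol * (s[0] if s[0] > 0 else 1.0)
    u, s, vt = u[:, keep], s[keep], vt[keep]
    eigenvalues = s**2 / (n - 1)
    scores = u * s
    axes = vt
    # deterministic sign: largest-|loading| element of each axis positive
    for k in range(axes.shape[0]):
        j = int(np.argmax(np.abs(axes[k])))
        if axes[k, j] < 0:
            axes[k] = -axes[k]
            scores[:, k] = -scores[:, k]
    pc1_flipped = False
    if orient_robustness and axes.shape[0] >= 1:
        ratios = np.array([shape_elongation_ratio(sh) for sh in aligned.shapes])
        if np.std(ratios) > 0 and np.std(scores[:, 0]) > 0:
            corr = float(np.corrcoef(scores[:, 0], ratios)[0, 1])
            if corr < 0:  # orient so higher PC1 = more robust
                axes[0] = -axes[0]
                scores[:, 0] = -scores[:, 0]
                pc1_flipped = True
    total = eigenvalues.sum()
    fractions = eigenvalues / total if total > 0 else eigenvalues
    return MorphospaceModel(
        consensus=aligned.consensus.copy(),
        center=center,
        eigenvalues=eigenvalues,
        variance_fractions=fractions,
        axes=axes,
        scores=scores,
        specimen_ids=list(aligned.specimen_ids),
        tangent=tangent,
        pc1_flipped_for_robustness=pc1_flipped,
        metadata={"n_specimens": n},
    )


def reconstruct_shape(model: MorphospaceModel, axis: int, score: float) -> np.ndarray:
    """Shape at ``score`` along one morphospace axis: the origin plus
    score x loading, folded back to 22x3.  Used to render the extreme
    (minimum/maximum) shapes bracketing an axis."""
    if not 0 <= axis < model.n_components:
        raise IndexError(f"axis {axis} out of range (0..{model.n_components - 1})")
    flat = model.center + score * model.axes[axis]
    return flat.reshape(-1, 3)


def reconstruct_full(model: MorphospaceModel, scores: np.ndarray) -> np.ndarray:
    """Shape at a full score vector (basis completeness: a specimen's own
    score vector returns its (tangent-projected) aligned shape)."""
    scores = np.asarray(scores, dtype=float)
    return (model.center + scores @ model.axes).reshape(-1, 3)


def robustness_scores(model: MorphospaceModel) -> np.ndarray:
    """Per-specimen PC1 scores, oriented so higher = more robust."""
    if model.n_components < 1:
        raise ValueError("model has no components")
    return model.scores[:, 0].copy()
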