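"""Generalized Procrustes analysis with sliding semilandmarks.

Every downstream statistic in the package lives in the shape space produced
here: configurations are translated to a common centroid, scaled to unit
centroid size and rotated to least-squares agreement with an iteratively
re-estimated consensus.  Outline semilandmarks may additionally slide along
the chord between their flanking landmarks, removing arbitrary point spacing
along the margin from the shape signal.  The sliding criterion is minimized
Procrustes distance to the consensus (closed-form 1-D projection of the
residual onto the chord tangent).

After convergence the whole sample is rotated into a canonical frame
(consensus principal axes, with a deterministic sign rule) so that results
do not depend on the input order through the arbitrary global rotation left
free by superimposition.

Shapes are used as-is after alignment (tangent-space projection omitted);
at the shape-variation scales handled here the difference is far below the
statistical tolerances of the analyses.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import LandmarkConfiguration, SliderDefinition

__all__ = [
    "AlignedSample",
    "PCAResult",
    "centroid_size",
    "align_pair",
    "slide_semilandmarks",
    "gpa",
    "procrustes_distance",
    "shape_pca",
    "shape_at_pc_extreme",
]


def _as_coords(obj) -> np.ndarray:
    if isinstance(obj, LandmarkConfiguration):
        return np.asarray(obj.coords, dtype=float)
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected (k, 2) coordinates, got shape {arr.shape}")
    return arr


def centroid_size(config) -> float:
    """Square root of summed squared landmark distances from their centroid."""
    coords = _as_coords(config)
    if coords.shape[0] < 2:
        raise ValueError("centroid size needs at least 2 landmarks")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs <= 1e-300:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


def _center_scale(coords: np.ndarray) -> np.ndarray:
    """Translate to centroid origin and scale to unit centroid size."""
    centered = coords - coords.mean(axis=0)
    return centered / centroid_size(centered)


def _optimal_rotation(
    target: np.ndarray, reference: np.ndarray, allow_reflection: bool
) -> np.ndarray:
    """Orthogonal 2x2 matrix R minimizing ||target @ R - reference||_F.

    Closed-form Kabsch solution; the determinant is constrained to +1
    (rotation only) unless reflections are allowed.
    """
    h = target.T @ reference
    u, _, vt = np.linalg.svd(h)
    rot = u @ vt
    if not allow_reflection and np.linalg.det(rot) < 0:
        rot = u @ np.diag([1.0, -1.0]) @ vt
    return rot


def align_pair(
    reference, target, allow_reflection: bool = False
) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes fit of ``target`` onto ``reference``.

    Both configurations are centred and scaled to unit centroid size; the
    target is then rotated to minimize the summed squared coordinate
    difference.  Returns the aligned target and the minimized distance.
    """
    ref = _as_coords(reference)
    tgt = _as_coords(target)
    if ref.shape != tgt.shape:
        raise ValueError(f"landmark count mismatch: {tgt.shape[0]} vs {ref.shape[0]}")
    ref = _center_scale(ref)
    tgt = _center_scale(tgt)
    rot = _optimal_rotation(tgt, ref, allow_reflection)
    aligned = tgt @ rot
    return aligned, float(np.sqrt(((aligned - ref) ** 2).sum()))


def slide_semilandmarks(
    config, reference, sliders: SliderDefinition
) -> np.ndarray:
    """Slide each semilandmark along its chord tangent toward the reference.

    The tangent at slider ``s`` is the unit vector from landmark ``before``
    to landmark ``after``; the point moves by the scalar that minimizes its
    squared distance to the reference (projection of the residual onto the
    tangent).  All sliders move simultaneously using the pre-slide chord
    geometry; fixed landmarks are untouched.  Sliding never increases any
    slider's distance to the reference.
    """
    coords = _as_coords(config).copy()
    ref = _as_coords(reference)
    if coords.shape != ref.shape:
        raise ValueError("config and reference landmark counts differ")
    sliders.validate_for(coords.shape[0])
    trip = sliders.zero_based()
    if trip.size == 0:
        return coords
    before, mid, after = trip[:, 0], trip[:, 1], trip[:, 2]
    tangent = coords[after] - coords[before]
    norm = np.linalg.norm(tangent, axis=1)
    if np.any(norm <= 1e-300):
        bad = int(mid[np.argmin(norm)]) + 1
        raise ValueError(f"zero-length tangent at slider {bad}")
    tangent = tangent / norm[:, None]
    shift = ((ref[mid] - coords[mid]) * tangent).sum(axis=1)
    coords[mid] = coords[mid] + shift[:, None] * tangent
    return coords


def _align_all(shapes: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Rotate every shape (batched Kabsch, rotations only) onto the consensus."""
    h = np.einsum("nki,kj->nij", shapes, consensus)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(u @ vt)
    diag = np.stack([np.ones_like(det), np.sign(det)], axis=1)
    rot = (u * diag[:, None, :]) @ vt
    return np.einsum("nki,nij->nkj", shapes, rot)


def _slide_all(
    shapes: np.ndarray, consensus: np.ndarray, trip: np.ndarray
) -> np.ndarray:
    """Simultaneous chord-tangent sliding of every shape in the sample."""
    before, mid, after = trip[:, 0], trip[:, 1], trip[:, 2]
    tangent = shapes[:, after] - shapes[:, before]
    norm = np.linalg.norm(tangent, axis=2)
    if np.any(norm <= 1e-300):
        raise ValueError("zero-length slider tangent during GPA")
    tangent = tangent / norm[..., None]
    shift = ((consensus[mid][None] - shapes[:, mid]) * tangent).sum(axis=2)
    out = shapes.copy()
    out[:, mid] = shapes[:, mid] + shift[..., None] * tangent
    return out


@dataclass(frozen=True)
class AlignedSample:
    """A jointly superimposed sample.

    ``shapes`` is ``(n, k, 2)``: every shape is centred at the origin with
    unit centroid size.  ``centroid_sizes`` holds the pre-alignment sizes in
    the input units (the "body size" used by allometric analyses).
    ``consensus`` is the coordinate-wise mean shape re-scaled to unit
    centroid size.
    """

    shapes: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    specimen_ids: tuple[str, ...]
    n_iterations: int
    converged: bool

    @property
    def n(self) -> int:
        return int(self.shapes.shape[0])

    @property
    def k(self) -> int:
        return int(self.shapes.shape[1])

    def flattened(self) -> np.ndarray:
        """Shapes as an ``(n, 2k)`` matrix (x1, y1, x2, y2, ...)."""
        return self.shapes.reshape(self.n, -1)


def _canonicalize(shapes: np.ndarray, consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate the whole frame so the consensus lies on its principal axes.

    The major axis goes to x, det(R) = +1, and the frame is spun by 180 deg
    if needed so the consensus coordinate of largest magnitude is positive.
    This removes the global rotational indeterminacy of the superimposition.
    """
    cov = consensus.T @ consensus
    eigval, eigvec = np.linalg.eigh(cov)
    rot = eigvec[:, ::-1]  # descending eigenvalue order
    if np.linalg.det(rot) < 0:
        rot = rot @ np.diag([1.0, -1.0])
    rotated = consensus @ rot
    flat = rotated.ravel()
    if flat[np.argmax(np.abs(flat))] < 0:
        rot = -rot  # 180-degree spin, still a rotation
    return shapes @ rot, consensus @ rot


def gpa(
    configs: Sequence,
    sliders: SliderDefinition | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    slide_iter: int = 3,
    specimen_ids: Sequence[str] | None = None,
) -> AlignedSample:
    """Generalized Procrustes analysis of homologous configurations.

    Plain GPA — iterate {align all shapes to the consensus; recompute the
    consensus (mean shape, re-scaled to unit centroid size)} — runs until
    the consensus' Procrustes change drops below ``tol``.  When sliders are
    given, ``slide_iter`` sliding passes (slide every shape against the
    consensus, renormalize, re-align, update the consensus) are interposed
    after the first convergence, followed by a final plain-GPA
    re-convergence with the slid positions frozen.  Sliding passes are kept
    few by design: iterating chord-tangent sliding against a moving
    consensus indefinitely lets semilandmarks drift along the outline and
    progressively contracts real shape differences toward the mean.

    The first configuration seeds the consensus; the result is
    deterministic given the input order, and the final canonical rotation
    makes it stable under reordering.  Non-convergence at ``max_iter`` is
    reported through the ``converged`` flag, not raised.
    """
    coords = [_as_coords(c) for c in configs]
    if len(coords) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    ks = {c.shape[0] for c in coords}
    if len(ks) > 1:
        raise ValueError(f"heterogeneous landmark counts {sorted(ks)}")
    if sliders is not None:
        sliders.validate_for(coords[0].shape[0])
    if specimen_ids is None:
        specimen_ids = tuple(
            c.specimen_id if isinstance(c, LandmarkConfiguration) else str(i + 1)
            for i, c in enumerate(configs)
        )
    sizes = np.array([centroid_size(c) for c in coords])
    shapes = np.stack([_center_scale(c) for c in coords])

    trip = sliders.zero_based() if sliders is not None else None

    def renorm(batch: np.ndarray) -> np.ndarray:
        centered = batch - batch.mean(axis=1, keepdims=True)
        cs = np.sqrt((centered**2).sum(axis=(1, 2), keepdims=True))
        return centered / cs

    consensus = shapes[0].copy()
    n_done = 0

    def plain_gpa(shapes, consensus):
        nonlocal n_done
        for _ in range(max_iter):
            n_done += 1
            shapes = _align_all(shapes, consensus)
            new_consensus = _center_scale(shapes.mean(axis=0))
            rot = _optimal_rotation(new_consensus, consensus, allow_reflection=False)
            new_consensus = new_consensus @ rot
            change = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
            consensus = new_consensus
            if change < tol:
                return shapes, consensus, True
        return shapes, consensus, False

    shapes, consensus, converged = plain_gpa(shapes, consensus)
    if trip is not None and trip.size:
        for _ in range(slide_iter):
            shapes = _align_all(renorm(_slide_all(shapes, consensus, trip)), consensus)
            consensus = _center_scale(shapes.mean(axis=0))
        shapes, consensus, slid_ok = plain_gpa(shapes, consensus)
        converged = converged and slid_ok
    # final pass: everything aligned to the converged consensus
    shapes = _align_all(shapes, consensus)
    shapes, consensus = _canonicalize(shapes, consensus)
    return AlignedSample(
        shapes=shapes,
        centroid_sizes=sizes,
        consensus=consensus,
        specimen_ids=tuple(specimen_ids),
        n_iterations=n_done,
        converged=converged,
    )


def procrustes_distance(shape_a, shape_b) -> float:
    """Square root of the summed squared coordinate differences.

    Both shapes must already live in a common superimposed frame; no
    re-fitting is performed here.
    """
    a = _as_coords(shape_a)
    b = _as_coords(shape_b)
    if a.shape != b.shape:
        raise ValueError(f"landmark count mismatch: {a.shape[0]} vs {b.shape[0]}")
    return float(np.sqrt(((a - b) ** 2).sum()))


@dataclass(frozen=True)
class PCAResult:
    """Tangent-space PCA of flattened aligned coordinates.

    Axes are sorted by eigenvalue; each loading is a unit vector in the
    2k-dimensional coordinate space, oriented so its largest-magnitude
    component is positive (ties to the lowest coordinate index), which makes
    axis directions reproducible across platforms.  ``axis`` arguments in
    this package are 1-based ("PC 2" is ``axis=2``).
    """

    mean: np.ndarray
    eigenvalues: np.ndarray
    proportion_variance: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray

    @property
    def n_axes(self) -> int:
        return int(self.eigenvalues.shape[0])

    def _axis_index(self, axis: int) -> int:
        if not (1 <= axis <= self.n_axes):
            raise ValueError(f"axis {axis} outside 1..{self.n_axes}")
        return axis - 1


_NULL_EIG_REL = 1e-12


def pca_of_rows(rows: np.ndarray) -> PCAResult:
    """PCA of arbitrary row vectors (shared by shape and vector PCAs)."""
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 observations")
    mean = rows.mean(axis=0)
    centered = rows - mean
    u, svals, vt = np.linalg.svd(centered, full_matrices=False)
    m = min(n - 1, rows.shape[1])
    u, svals, vt = u[:, :m], svals[:m], vt[:m]
    eigenvalues = svals**2 / (n - 1)
    scores = u * svals
    loadings = vt.copy()
    for i in range(m):
        pivot = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, pivot] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    total = eigenvalues.sum()
    if total > 0:
        proportions = eigenvalues / total
    else:
        proportions = np.zeros_like(eigenvalues)
    return PCAResult(
        mean=mean,
        eigenvalues=eigenvalues,
        proportion_variance=proportions,
        scores=scores,
        loadings=loadings,
    )


def shape_pca(aligned: AlignedSample) -> PCAResult:
    """Principal components of the aligned, flattened shape coordinates."""
    return pca_of_rows(aligned.flattened())


def shape_at_pc_extreme(pca: PCAResult, axis: int, which: str) -> np.ndarray:
    """Predicted shape at the minimum or maximum observed score on an axis.

    Returns ``mean + extreme_score * loading`` reshaped to ``(k, 2)``.
    """
    idx = pca._axis_index(axis)
    max_eig = max(float(pca.eigenvalues.max(initial=0.0)), 1.0)
    if pca.eigenvalues[idx] <= _NULL_EIG_REL * max_eig:
        raise ValueError(f"axis {axis} has (numerically) zero variance")
    if which not in ("min", "max"):
        raise ValueError("which must be 'min' or 'max'")
    score = float(pca.scores[:, idx].min() if which == "min" else pca.scores[:, idx].max())
    flat = pca.mean + score * pca.loadings[idx]
    return flat.reshape(-1, 2)
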