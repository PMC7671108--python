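"""Female-to-male shape-change vectors and their lengths and angles.

For each species one female and one male shape, taken from a common
superimposition, define a dimorphism vector (terminus minus origin in
flattened coordinate space).  Its Euclidean norm is the Procrustes distance
between the endpoint shapes — the magnitude of dimorphism — and its angle
to a common baseline vector (built between the shapes predicted at the
minimum and maximum scores of a chosen principal component, PC 2 by
default) measures the *direction* of shape change in the full
dimensionality of shape space.

With one specimen per sex and species no within-species test is possible;
lengths and angles are reported descriptively, and a PCA of the
length-normalized vectors summarizes the diversity of dimorphic directions.

Orientation conventions (both fixed and documented because the angle to the
baseline depends on them): dimorphism vectors run female -> male; the
baseline runs min-PC-score shape -> max-PC-score shape.  Supplementary
angles (180 - theta) are emitted alongside for robustness against baseline
sign flips.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .superimposition import (
    PCAResult,
    pca_of_rows,
    procrustes_distance,
    shape_at_pc_extreme,
)

__all__ = [
    "ShapeVector",
    "dimorphism_vector",
    "vector_angle",
    "baseline_vector",
    "angle_table",
    "scaled_vector_pca",
]


@dataclass(frozen=True)
class ShapeVector:
    """A shape-difference vector between two shapes in a common frame."""

    components: np.ndarray
    species: str = ""
    origin_label: str = "female"
    terminus_label: str = "male"

    def __post_init__(self) -> None:
        comp = np.asarray(self.components, dtype=float).ravel()
        if not np.all(np.isfinite(comp)):
            raise ValueError(f"{self.species}: non-finite vector components")
        object.__setattr__(self, "components", comp)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.components))


def dimorphism_vector(female_shape, male_shape, species: str = "") -> ShapeVector:
    """Vector from the female to the male shape of one species.

    Components are ``male - female`` over the flattened aligned coordinates;
    the length equals the Procrustes distance between the endpoints.
    """
    f = np.asarray(female_shape, dtype=float)
    m = np.asarray(male_shape, dtype=float)
    if f.shape != m.shape:
        raise ValueError(
            f"{species}: endpoint shapes disagree ({f.shape} vs {m.shape}); "
            "both must come from one alignment"
        )
    return ShapeVector(components=(m - f).ravel(), species=species)


def vector_angle(v1: ShapeVector, v2: ShapeVector) -> float:
    """Angle between two shape vectors, in degrees within [0, 180].

    arccos of the dot product of the unit-normalized component vectors;
    symmetric and invariant to rescaling either vector.
    """
    n1, n2 = v1.length, v2.length
    if n1 <= 0 or n2 <= 0:
        bad = [v.species or "<unnamed>" for v in (v1, v2) if v.length <= 0]
        raise ValueError(f"angle undefined for zero-length vector(s): {bad}")
    cosine = float(v1.components @ v2.components) / (n1 * n2)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosine))))


def baseline_vector(pca: PCAResult, axis: int = 2) -> ShapeVector:
    """Baseline shape-change vector along one principal component.

    Runs from the shape predicted at the minimum observed score on the axis
    to the shape at the maximum; by linearity its components equal
    ``(score_max - score_min) * loading``.
    """
    smin = shape_at_pc_extreme(pca, axis, "min")
    smax = shape_at_pc_extreme(pca, axis, "max")
    return ShapeVector(
        components=(smax - smin).ravel(),
        species=f"PC{axis}",
        origin_label=f"pc{axis}_min",
        terminus_label=f"pc{axis}_max",
    )


def angle_table(
    vectors: Sequence[ShapeVector], baseline: ShapeVector
) -> tuple[pd.DataFrame, float]:
    """Per-species lengths and angles to the baseline, plus the total range.

    Returns a frame with columns ``species, L, theta_deg,
    theta_supplement_deg`` and the angular range ``max(theta) - min(theta)``.
    Flipping the baseline maps every angle to its supplement, so the range
    is reported for the documented baseline orientation.
    """
    if not vectors:
        raise ValueError("angle_table needs at least one vector")
    rows = []
    for vec in vectors:
        theta = vector_angle(vec, baseline)
        rows.append(
            {
                "species": vec.species,
                "L": vec.length,
                "theta_deg": theta,
                "theta_supplement_deg": 180.0 - theta,
            }
        )
    table = pd.DataFrame(rows)
    theta_range = float(table["theta_deg"].max() - table["theta_deg"].min())
    return table, theta_range


def scaled_vector_pca(vectors: Sequence[ShapeVector]) -> PCAResult:
    """PCA of the length-normalized (unit) dimorphism vectors."""
    zero = [v.species or "<unnamed>" for v in vectors if v.length <= 0]
    if zero:
        raise ValueError(f"cannot normalize zero-length vector(s): {zero}")
    if len(vectors) < 3:
        raise ValueError("scaled-vector PCA needs at least 3 vectors")
    rows = np.stack([v.components / v.length for v in vectors])
    return pca_of_rows(rows)
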