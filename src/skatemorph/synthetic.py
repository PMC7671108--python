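"""Synthetic skate-fin datasets with the statistical structure the
analyses assume.

No machine-readable landmark data accompany the study system this package
models, so every stage of the pipeline is exercised on simulated fixtures:

* an *interspecific* design — one female and one male outline per species,
  species mean shapes diffusing by Brownian motion over a pure-birth
  phylogeny, and a species-specific dimorphism displacement of magnitude
  ``d_i`` applied to the male along a shared (slightly dispersed) unit
  deformation field;
* an *ontogenetic* series — males and females spanning 50.6-109.5 mm disc
  width (the sampled range of the pygmy-skate case study), sharing a mild
  allometric shape trend, with a maturation deformation switched on above
  an 84 mm threshold that is three times stronger in males than females;
* two-phase *clasper growth* — a continuous hinge with slopes 0.05 and 1.2
  mm/mm around the 84 mm breakpoint;
* nine *endoskeletal traits* on a log-log allometry, three of them
  slope-dimorphic, two intercept-dimorphic and four monomorphic
  (mirroring the qualitative pattern of the real skeletal data).

The dimorphism field combines an anterior-concavity bump and a posterior
lobe-expansion bump along the outline normals — the two features that
characterize mature male fins — and is projected orthogonal to the
similarity-transform directions (translation, rotation, scaling of the
template) so that superimposition does not absorb the effect; the exact
bump shapes are arbitrary.  Species shape evolution is Brownian on
landmark coordinates at small rates, with increments smoothed along the
outline so displacement is a coherent deformation of the margin, and a
brute-force self-intersection check as a guardrail.

Reproducibility: one RNG stream per output, spawned from the master seed,
so adding outputs never perturbs existing ones; identical (spec, seed)
yields byte-identical files.  Ground-truth parameters are persisted in a
sidecar manifest so recovery tests read truth from the manifest rather
than re-deriving it.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io_formats import (
    LandmarkConfiguration,
    PhyloTree,
    SliderDefinition,
    SpecimenRecord,
    default_outline_sliders,
    write_metadata,
    write_sliders,
    write_tps,
)

__all__ = [
    "SyntheticSpec",
    "OntogenySpec",
    "ClasperGrowthSpec",
    "SkeletalTraitSpec",
    "template_outline",
    "dimorphism_field",
    "ontogeny_field",
    "simulate_interspecific",
    "simulate_ontogeny",
    "simulate_clasper_growth",
    "simulate_skeletal_traits",
    "InterspecificDataset",
    "OntogenyDataset",
]


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OntogenySpec:
    """Design of the single-species ontogenetic series.

    Sample sizes and the disc-width range reproduce the pygmy-skate series
    (21 males, 22 females, 50.6-109.5 mm).  ``male_maturation_effect_scale``
    is the shape displacement (unit-centroid-size Procrustes units) a male
    at the top of the size range has acquired beyond the shared allometric
    trend; females experience ``female_effect_scale`` times that
    displacement, one third by default so the male ontogenetic trajectory
    is about three times the female one.  ``allometry_scale`` is the shared
    log-size shape trend across the whole range, kept modest relative to
    the maturation effect.
    """

    n_males: int = 21
    n_females: int = 22
    dw_range: tuple[float, float] = (50.6, 109.5)
    male_maturation_effect_scale: float = 0.06
    female_effect_scale: float = 1.0 / 3.0
    allometry_scale: float = 0.01


@dataclass(frozen=True)
class ClasperGrowthSpec:
    """Continuous-hinge clasper growth: slow below the 84 mm maturation
    breakpoint, rapid above, with Gaussian measurement noise in mm."""

    breakpoint: float = 84.0
    slope_below: float = 0.05
    slope_above: float = 1.2
    intercept: float = 1.0
    noise_sd: float = 0.5


@dataclass(frozen=True)
class SkeletalTraitSpec:
    """Log-log allometry of one endoskeletal trait:
    ln(trait) = intercept_sex + slope_sex * ln(DW) + N(0, noise_sd)."""

    name: str
    intercept_f: float
    intercept_m: float
    slope_f: float
    slope_m: float
    noise_sd: float = 0.05


def default_skeletal_traits() -> tuple[SkeletalTraitSpec, ...]:
    """Nine traits: 3 slope-dimorphic, 2 intercept-dimorphic, 4 monomorphic."""
    return (
        # slope-dimorphic (sexes diverge with size)
        SkeletalTraitSpec("puboischiadic_bar_length", -1.55, -2.50, 1.00, 1.20),
        SkeletalTraitSpec("palatoquadrate_length", -1.95, -2.90, 0.95, 1.15),
        SkeletalTraitSpec("scapulocoracoid_length", -1.60, -0.65, 1.05, 0.85),
        # intercept-dimorphic (parallel lines, different elevation)
        SkeletalTraitSpec("puboischiadic_bar_width", -2.60, -2.75, 1.00, 1.00),
        SkeletalTraitSpec("mesopterygium_length", -2.30, -2.18, 1.00, 1.00),
        # monomorphic
        SkeletalTraitSpec("scapulocoracoid_width", -2.90, -2.90, 1.00, 1.00),
        SkeletalTraitSpec("rostrum_length", -3.10, -3.10, 0.90, 0.90),
        SkeletalTraitSpec("propterygium_length", -1.05, -1.05, 1.00, 1.00),
        SkeletalTraitSpec("metapterygium_length", -1.20, -1.20, 1.00, 1.00),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of the simulated study.

    ``bm_rate`` is the per-coordinate Brownian variance accumulated over the
    unit-depth pure-birth tree; ``dimorphism_magnitudes`` fixes per-species
    d_i (Procrustes units at unit centroid size), or, when None, d_i is
    drawn log-uniformly from ``dimorphism_range`` — a five-fold span by
    default, matching the observed weakest-to-strongest ratio.
    ``digitizing_noise_sd`` is per-coordinate, in units of outline centroid
    size, emulating landmark placement error.
    """

    n_landmarks: int = 35
    n_species: int = 21
    bm_rate: float = 4e-4
    dimorphism_magnitudes: tuple[float, ...] | None = None
    dimorphism_range: tuple[float, float] = (0.03, 0.15)
    angular_dispersion_deg: float = 15.0
    digitizing_noise_sd: float = 0.002
    ontogeny: OntogenySpec = field(default_factory=OntogenySpec)
    clasper_growth: ClasperGrowthSpec = field(default_factory=ClasperGrowthSpec)
    skeletal: tuple[SkeletalTraitSpec, ...] = field(
        default_factory=default_skeletal_traits
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_landmarks < 8:
            raise ValueError("need at least 8 landmarks")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.bm_rate < 0 or self.digitizing_noise_sd < 0:
            raise ValueError("rates and noise must be >= 0")
        if self.dimorphism_magnitudes is not None:
            if any(d < 0 for d in self.dimorphism_magnitudes):
                raise ValueError("dimorphism magnitudes must be >= 0")
            if len(self.dimorphism_magnitudes) != self.n_species:
                raise ValueError("need one dimorphism magnitude per species")
        lo, hi = self.ontogeny.dw_range
        if not (0 < lo < hi):
            raise ValueError("dw_range must be positive and ordered")

    @property
    def n_sliders(self) -> int:
        return self.n_landmarks - 2

    def sliders(self) -> SliderDefinition:
        return default_outline_sliders(self.n_landmarks)


# ---------------------------------------------------------------------------
# Template outline and deformation fields
# ---------------------------------------------------------------------------


def template_outline(k: int) -> LandmarkConfiguration:
    """Deterministic right-facing fin-margin template.

    A half-ellipse arc from the anterior tip (top) to the posterior
    insertion (bottom), sampled at ``k`` points of equal arc length and
    normalized to unit centroid size.
    """
    if k < 8:
        raise ValueError("template outline needs k >= 8")
    a, b = 1.0, 0.8  # disc slightly wider than long
    t_dense = np.linspace(np.pi / 2, -np.pi / 2, 20001)
    dense = np.column_stack([a * np.cos(t_dense), b * np.sin(t_dense)])
    seglen = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = np.linspace(0.0, arc[-1], k)
    t_at = np.interp(targets, arc, t_dense)
    coords = np.column_stack([a * np.cos(t_at), b * np.sin(t_at)])
    coords -= coords.mean(axis=0)
    coords /= np.sqrt((coords**2).sum())
    return LandmarkConfiguration(specimen_id="template", coords=coords)


def _outward_normals(coords: np.ndarray) -> np.ndarray:
    """Unit outline normals oriented away from the centroid."""
    k = coords.shape[0]
    tangents = np.empty_like(coords)
    tangents[1:-1] = coords[2:] - coords[:-2]
    tangents[0] = coords[1] - coords[0]
    tangents[-1] = coords[-1] - coords[-2]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.column_stack([tangents[:, 1], -tangents[:, 0]])
    centered = coords - coords.mean(axis=0)
    flip = np.sign((normals * centered).sum(axis=1))
    flip[flip == 0] = 1.0
    return normals * flip[:, None]


def _similarity_nuisance_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis (4, 2k) of the similarity-transform directions at
    the template: x/y translation, rotation, scaling."""
    k = template.shape[0]
    centered = (template - template.mean(axis=0)).ravel()
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    rot = np.column_stack(
        [-(template[:, 1] - template[:, 1].mean()), template[:, 0] - template[:, 0].mean()]
    ).ravel()
    basis = np.stack([tx, ty, rot, centered])
    # Gram-Schmidt
    ortho = []
    for vec in basis:
        for prev in ortho:
            vec = vec - (vec @ prev) * prev
        norm = np.linalg.norm(vec)
        if norm > 1e-12:
            ortho.append(vec / norm)
    return np.stack(ortho)


def _project_out(vec: np.ndarray, basis: np.ndarray) -> np.ndarray:
    for row in basis:
        vec = vec - (vec @ row) * row
    return vec


def _project_into_normals(field: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Keep only the chord-normal component of a (k, 2) displacement field."""
    coeff = (field * normals).sum(axis=1)
    return coeff[:, None] * normals


def _nuisance_in_normal_subspace(
    template: np.ndarray, normals: np.ndarray
) -> np.ndarray:
    """Orthonormalized projections of the similarity-transform directions
    into the chord-normal subspace.

    Deformation fields built in the chord-normal subspace and orthogonal to
    these projections are (to first order) invariant under both
    superimposition and chord-tangent sliding, so the generator's effect
    sizes survive the alignment pipeline.
    """
    ortho: list[np.ndarray] = []
    for vec in _similarity_nuisance_basis(template):
        pv = _project_into_normals(vec.reshape(-1, 2), normals).ravel()
        for prev in ortho:
            pv = pv - (pv @ prev) * prev
        norm = np.linalg.norm(pv)
        if norm > 1e-12:
            ortho.append(pv / norm)
    return np.stack(ortho)


def _bump_weights(k: int, center_frac: float, width_frac: float) -> np.ndarray:
    idx = np.arange(k)
    return np.exp(-0.5 * ((idx - center_frac * (k - 1)) / (width_frac * k)) ** 2)


def dimorphism_field(template: LandmarkConfiguration) -> np.ndarray:
    """Unit deformation field (2k,) of male-typical shape change.

    Anterior concavity (inward chord-normal displacement around the front
    third of the margin) plus posterior lobe expansion (outward
    displacement near the insertion).  Built in the chord-normal subspace
    and orthogonalized against the similarity-transform directions so the
    effect is neither absorbed by superimposition nor slid away.
    """
    coords = template.coords
    k = coords.shape[0]
    normals = _outward_normals(coords)
    weights = -1.0 * _bump_weights(k, 0.25, 0.13) + 0.8 * _bump_weights(k, 0.82, 0.11)
    fld = (weights[:, None] * normals).ravel()
    fld = _project_out(fld, _nuisance_in_normal_subspace(coords, normals))
    return fld / np.linalg.norm(fld)


def ontogeny_field(template: LandmarkConfiguration) -> np.ndarray:
    """Unit deformation field of shared (sex-independent) growth allometry:
    a broad mid-margin (apex) elongation in the chord-normal subspace,
    orthogonal to both the similarity transforms and the dimorphism field."""
    coords = template.coords
    k = coords.shape[0]
    normals = _outward_normals(coords)
    weights = _bump_weights(k, 0.5, 0.16)
    fld = (weights[:, None] * normals).ravel()
    fld = _project_out(fld, _nuisance_in_normal_subspace(coords, normals))
    fld = _project_out(fld, dimorphism_field(template)[None, :])
    return fld / np.linalg.norm(fld)


def _random_unit_orthogonal(
    rng: np.random.Generator,
    anchor: np.ndarray,
    template: np.ndarray,
    normals: np.ndarray,
) -> np.ndarray:
    """Random unit chord-normal field orthogonal to nuisance and anchor."""
    coeff = rng.standard_normal(normals.shape[0])
    vec = (coeff[:, None] * normals).ravel()
    vec = _project_out(vec, _nuisance_in_normal_subspace(template, normals))
    vec = vec - (vec @ anchor) * anchor
    return vec / np.linalg.norm(vec)


def _self_intersects(coords: np.ndarray) -> bool:
    """Brute-force check for crossing segments in an open polyline."""

    def cross2(a, b) -> float:
        return float(a[0] * b[1] - a[1] * b[0])

    def crosses(p1, p2, p3, p4) -> bool:
        d1 = cross2(p4 - p3, p1 - p3)
        d2 = cross2(p4 - p3, p2 - p3)
        d3 = cross2(p2 - p1, p3 - p1)
        d4 = cross2(p2 - p1, p4 - p1)
        return (d1 * d2 < 0) and (d3 * d4 < 0)

    k = coords.shape[0]
    for i in range(k - 1):
        for j in range(i + 2, k - 1):  # skip adjacent segments
            if crosses(coords[i], coords[i + 1], coords[j], coords[j + 1]):
                return True
    return False


# ---------------------------------------------------------------------------
# Tree + Brownian motion
# ---------------------------------------------------------------------------


def _pure_birth_tree(n_species: int, seed_int: int) -> PhyloTree:
    """Pure-birth (Yule) tree on n extant species, scaled to unit depth,
    leaves labelled sp01..spNN.

    The birth-death simulator stops exactly at the speciation event that
    reaches n tips, which leaves a zero-length cherry (and a singular
    Brownian covariance); the memoryless waiting time to the next event,
    Exp(n * birth_rate), is therefore appended to every tip branch before
    rescaling, giving the tree as it stands between speciations.
    """
    import random as _random

    pyrng = _random.Random(seed_int)
    taxa = dendropy.TaxonNamespace(
        [f"sp{i + 1:02d}" for i in range(n_species)]
    )
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        taxon_namespace=taxa,
        rng=pyrng,
    )
    tail = pyrng.expovariate(float(n_species))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + tail
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return PhyloTree(tree)


def _outline_smoother(k: int, kernel_sd: float = 4.0) -> np.ndarray:
    """(k, k) Gaussian smoothing operator along the landmark index.

    Rows are normalized to unit L2 norm, so applying the operator to iid
    N(0, s^2) draws yields spatially correlated displacements with the same
    per-coordinate marginal variance — a smooth deformation of the margin
    rather than independent point jitter.
    """
    idx = np.arange(k)
    weights = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / kernel_sd) ** 2)
    return weights / np.linalg.norm(weights, axis=1, keepdims=True)


def _brownian_displacements(
    tree: PhyloTree, k: int, rate: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-leaf Brownian displacement fields accumulated root -> tip.

    Increments are drawn per coordinate at variance ``rate * edge_length``
    and smoothed along the outline (see :func:`_outline_smoother`), keeping
    the across-species covariance Brownian while making each species' shape
    displacement a coherent deformation of the margin.  Traversal order is
    fixed (preorder over the canonical tree) so draws are reproducible.
    """
    smoother = _outline_smoother(k)
    values: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = np.zeros(2 * k)
        else:
            edge = node.edge.length or 0.0
            raw = rng.standard_normal((k, 2)) * math.sqrt(rate * edge)
            step = (smoother @ raw).ravel()
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InterspecificDataset:
    configs: tuple[LandmarkConfiguration, ...]
    records: tuple[SpecimenRecord, ...]
    tree: PhyloTree
    sliders: SliderDefinition
    truth: dict[str, float | str]


@dataclass(frozen=True)
class OntogenyDataset:
    configs: tuple[LandmarkConfiguration, ...]
    records: tuple[SpecimenRecord, ...]
    skeletal: pd.DataFrame
    sliders: SliderDefinition
    truth: dict[str, float | str]


def _write_truth(truth: dict, path: Path) -> None:
    lines = [f"{key}={truth[key]}" for key in sorted(truth)]
    path.write_text("\n".join(lines) + "\n")


def _seed_int(child: np.random.SeedSequence) -> int:
    return int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31 - 1)


def simulate_interspecific(
    spec: SyntheticSpec, outdir: str | Path | None = None
) -> InterspecificDataset:
    """One female + one male outline per species over a simulated phylogeny.

    Species mean shapes are the template plus Brownian displacement along a
    unit-depth pure-birth tree.  The female equals the species mean plus
    digitizing noise; the male additionally receives ``d_i`` times the
    species' dimorphism direction (the shared field, angularly dispersed).
    Configurations are emitted in mm at species-specific sizes, clasper
    lengths follow a positive allometry on fin centroid size, and the
    dataset writes TPS, sliders, metadata CSV, newick and a truth manifest
    when ``outdir`` is given.
    """
    master = np.random.SeedSequence(spec.seed)
    s_tree, s_bm, s_dim, s_noise, s_sizes, s_clasper = master.spawn(6)
    k = spec.n_landmarks
    template = template_outline(k)
    u = dimorphism_field(template)
    normals = _outward_normals(template.coords)

    tree = _pure_birth_tree(spec.n_species, _seed_int(s_tree))
    species_names = list(tree.leaf_labels)

    rng_bm = np.random.default_rng(s_bm)
    disp = _brownian_displacements(tree, k, spec.bm_rate, rng_bm)

    rng_dim = np.random.default_rng(s_dim)
    if spec.dimorphism_magnitudes is not None:
        magnitudes = np.asarray(spec.dimorphism_magnitudes, dtype=float)
    else:
        lo, hi = spec.dimorphism_range
        magnitudes = np.exp(
            rng_dim.uniform(math.log(lo), math.log(hi), size=spec.n_species)
        )
    phi = np.radians(spec.angular_dispersion_deg) * rng_dim.standard_normal(
        spec.n_species
    )
    wobble = [
        _random_unit_orthogonal(rng_dim, u, template.coords, normals)
        for _ in range(spec.n_species)
    ]

    rng_noise = np.random.default_rng(s_noise)
    rng_sizes = np.random.default_rng(s_sizes)
    rng_clasper = np.random.default_rng(s_clasper)

    configs: list[LandmarkConfiguration] = []
    records: list[SpecimenRecord] = []
    truth: dict[str, float | str] = {
        "design": "interspecific",
        "n_species": spec.n_species,
        "n_landmarks": k,
        "bm_rate": spec.bm_rate,
        "angular_dispersion_deg": spec.angular_dispersion_deg,
        "digitizing_noise_sd": spec.digitizing_noise_sd,
        "seed": spec.seed,
    }
    bad_species: list[str] = []
    for i, name in enumerate(species_names):
        mean_shape = template.coords + disp[name].reshape(k, 2)
        direction = math.cos(phi[i]) * u + math.sin(phi[i]) * wobble[i]
        direction /= np.linalg.norm(direction)
        d_i = float(magnitudes[i])
        female = mean_shape + spec.digitizing_noise_sd * rng_noise.standard_normal(
            (k, 2)
        )
        male = (
            mean_shape
            + d_i * direction.reshape(k, 2)
            + spec.digitizing_noise_sd * rng_noise.standard_normal((k, 2))
        )
        if _self_intersects(male) or _self_intersects(female):
            bad_species.append(name)
        size_mm = float(np.exp(rng_sizes.normal(math.log(250.0), 0.3)))
        log_cl = -1.2 + 1.1 * math.log(size_mm) + rng_clasper.normal(0.0, 0.1)
        clasper_mm = float(np.exp(log_cl))
        for sex, shape in (("female", female), ("male", male)):
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{name}_{sex[0].upper()}",
                    coords=shape * size_mm,
                )
            )
            records.append(
                SpecimenRecord(
                    specimen_id=f"{name}_{sex[0].upper()}",
                    species=name,
                    sex=sex,
                    disc_width=size_mm,
                    clasper_length=clasper_mm if sex == "male" else None,
                    maturity="mature",
                )
            )
        truth[f"d_{name}"] = d_i
        truth[f"angle_offset_deg_{name}"] = math.degrees(abs(phi[i]))
    if bad_species:
        warnings.warn(
            "self-intersecting outlines for species: " + ", ".join(bad_species)
        )
    sliders = spec.sliders()
    dataset = InterspecificDataset(
        configs=tuple(configs),
        records=tuple(records),
        tree=tree,
        sliders=sliders,
        truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tps(configs, outdir / "interspecific.tps")
        write_sliders(sliders, outdir / "sliders.txt")
        write_metadata(records, outdir / "metadata.csv")
        tree.write_newick(outdir / "tree.nwk")
        _write_truth(truth, outdir / "truth.txt")
    return dataset


def _stratified_dw(
    n: int, lo: float, hi: float, breakpoint: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform disc widths with both sides of the threshold guaranteed."""
    frac_below = (breakpoint - lo) / (hi - lo)
    n_below = int(np.clip(round(n * frac_below), 1, n - 1))
    below = rng.uniform(lo, breakpoint, size=n_below)
    above = rng.uniform(breakpoint, hi, size=n - n_below)
    above = np.maximum(above, np.nextafter(breakpoint, hi))
    return np.concatenate([below, above])


def _clasper_curve(dw: np.ndarray, growth: ClasperGrowthSpec) -> np.ndarray:
    return (
        growth.intercept
        + growth.slope_below * dw
        + (growth.slope_above - growth.slope_below)
        * np.maximum(dw - growth.breakpoint, 0.0)
    )


def simulate_clasper_growth(
    spec: SyntheticSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Disc widths and clasper lengths for a male growth series."""
    master = np.random.SeedSequence(spec.seed)
    _, _, _, _, _, _, s_dw, s_cl = master.spawn(8)
    rng_dw = np.random.default_rng(s_dw)
    rng_cl = np.random.default_rng(s_cl)
    growth = spec.clasper_growth
    lo, hi = spec.ontogeny.dw_range
    dw = _stratified_dw(spec.ontogeny.n_males, lo, hi, growth.breakpoint, rng_dw)
    cl = _clasper_curve(dw, growth) + rng_cl.normal(0.0, growth.noise_sd, dw.size)
    return dw, np.maximum(cl, 0.0)


def _skeletal_values(
    dw: np.ndarray,
    sexes: np.ndarray,
    traits: tuple[SkeletalTraitSpec, ...],
    rng: np.random.Generator,
) -> pd.DataFrame:
    data: dict[str, np.ndarray] = {}
    log_dw = np.log(dw)
    for trait in traits:
        intercept = np.where(sexes == "male", trait.intercept_m, trait.intercept_f)
        slope = np.where(sexes == "male", trait.slope_m, trait.slope_f)
        log_val = intercept + slope * log_dw + rng.normal(0.0, trait.noise_sd, dw.size)
        data[trait.name] = np.exp(log_val)
    return pd.DataFrame(data)


def simulate_skeletal_traits(spec: SyntheticSpec) -> pd.DataFrame:
    """Standalone endoskeletal measurement table (one row per specimen)."""
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(10)
    rng_dw = np.random.default_rng(children[8])
    rng_traits = np.random.default_rng(children[9])
    ont = spec.ontogeny
    lo, hi = ont.dw_range
    bp = spec.clasper_growth.breakpoint
    dw = np.concatenate(
        [
            _stratified_dw(ont.n_males, lo, hi, bp, rng_dw),
            _stratified_dw(ont.n_females, lo, hi, bp, rng_dw),
        ]
    )
    sexes = np.array(["male"] * ont.n_males + ["female"] * ont.n_females)
    ids = [f"m{i + 1:02d}" for i in range(ont.n_males)] + [
        f"f{i + 1:02d}" for i in range(ont.n_females)
    ]
    frame = _skeletal_values(dw, sexes, spec.skeletal, rng_traits)
    frame.insert(0, "disc_width_mm", dw)
    frame.insert(0, "sex", sexes)
    frame.insert(0, "specimen_id", ids)
    return frame


def simulate_ontogeny(
    spec: SyntheticSpec, outdir: str | Path | None = None
) -> OntogenyDataset:
    """Single-species ontogenetic series of fin outlines + skeletal table.

    Disc widths are uniform over the sampled range (both sides of the
    maturity threshold guaranteed).  Every specimen shares an allometric
    shape trend in log disc width; specimens above the clasper-growth
    breakpoint additionally acquire the maturation deformation, scaled by
    (DW - breakpoint) and three times stronger in males than females at
    the defaults.  Male clasper lengths follow the two-phase growth curve.
    The metadata maturity column applies the same strict > threshold rule
    the analysis uses.
    """
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(12)
    rng_dw = np.random.default_rng(children[6])
    rng_cl = np.random.default_rng(children[7])
    rng_noise = np.random.default_rng(children[10])
    rng_skel = np.random.default_rng(children[11])

    k = spec.n_landmarks
    ont = spec.ontogeny
    growth = spec.clasper_growth
    lo, hi = ont.dw_range
    bp = growth.breakpoint
    template = template_outline(k)
    u = dimorphism_field(template).reshape(k, 2)
    v = ontogeny_field(template).reshape(k, 2)

    dw_m = _stratified_dw(ont.n_males, lo, hi, bp, rng_dw)
    dw_f = _stratified_dw(ont.n_females, lo, hi, bp, rng_dw)
    dw = np.concatenate([dw_m, dw_f])
    sexes = np.array(["male"] * ont.n_males + ["female"] * ont.n_females)
    ids = [f"m{i + 1:02d}" for i in range(ont.n_males)] + [
        f"f{i + 1:02d}" for i in range(ont.n_females)
    ]
    clasper = _clasper_curve(dw_m, growth) + rng_cl.normal(
        0.0, growth.noise_sd, dw_m.size
    )
    clasper = np.maximum(clasper, 0.0)

    configs: list[LandmarkConfiguration] = []
    records: list[SpecimenRecord] = []
    log_span = math.log(hi) - math.log(lo)
    for i, (specimen_id, sex, width) in enumerate(zip(ids, sexes, dw)):
        allo = ont.allometry_scale * (math.log(width) - math.log(lo)) / log_span
        mat_scale = max(width - bp, 0.0) / (hi - bp)
        effect = ont.male_maturation_effect_scale * mat_scale
        if sex == "female":
            effect *= ont.female_effect_scale
        shape = (
            template.coords
            + allo * v
            + effect * u
            + spec.digitizing_noise_sd * rng_noise.standard_normal((k, 2))
        )
        configs.append(
            LandmarkConfiguration(specimen_id=specimen_id, coords=shape * width)
        )
        records.append(
            SpecimenRecord(
                specimen_id=specimen_id,
                species="Fenestraja_plutonia_synthetic",
                sex=str(sex),
                disc_width=float(width),
                clasper_length=(
                    float(clasper[i]) if sex == "male" else None
                ),
                maturity="mature" if width > bp else "immature",
            )
        )
    skeletal = _skeletal_values(dw, sexes, spec.skeletal, rng_skel)
    skeletal.insert(0, "disc_width_mm", dw)
    skeletal.insert(0, "sex", sexes)
    skeletal.insert(0, "specimen_id", ids)

    truth: dict[str, float | str] = {
        "design": "ontogeny",
        "n_males": ont.n_males,
        "n_females": ont.n_females,
        "dw_min": lo,
        "dw_max": hi,
        "breakpoint": bp,
        "slope_below": growth.slope_below,
        "slope_above": growth.slope_above,
        "clasper_noise_sd": growth.noise_sd,
        "male_maturation_effect_scale": ont.male_maturation_effect_scale,
        "female_effect_scale": ont.female_effect_scale,
        "allometry_scale": ont.allometry_scale,
        "digitizing_noise_sd": spec.digitizing_noise_sd,
        "seed": spec.seed,
    }
    for trait in spec.skeletal:
        truth[f"slope_f_{trait.name}"] = trait.slope_f
        truth[f"slope_m_{trait.name}"] = trait.slope_m
        truth[f"intercept_f_{trait.name}"] = trait.intercept_f
        truth[f"intercept_m_{trait.name}"] = trait.intercept_m

    sliders = spec.sliders()
    dataset = OntogenyDataset(
        configs=tuple(configs),
        records=tuple(records),
        skeletal=skeletal,
        sliders=sliders,
        truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tps(configs, outdir / "ontogeny.tps")
        write_sliders(sliders, outdir / "sliders.txt")
        write_metadata(records, outdir / "metadata.csv")
        skel_out = skeletal.copy()
        skel_out["disc_width_mm"] = skel_out["disc_width_mm"].map(
            lambda x: f"{x:.4f}"
        )
        for trait in spec.skeletal:
            skel_out[trait.name] = skel_out[trait.name].map(lambda x: f"{x:.6f}")
        skel_out.to_csv(outdir / "skeletal.csv", index=False)
        _write_truth(truth, outdir / "truth.txt")
    return dataset
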