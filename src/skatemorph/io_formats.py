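"""Readers and writers for the file formats the pipeline touches.

Landmark outlines travel as TPS records (the format emitted by the tpsDIG
family of digitizers), semilandmark slider definitions as three-column text,
specimen metadata as CSV, and phylogenies as newick with branch lengths.

Conventions
-----------
* Landmark indices are 1-based in every file and error message, 0-based in
  memory.
* y increases upward (mathematical convention).  Digitizers that use image
  coordinates can be accommodated with ``flip_y=True`` on the readers.
* All fin outlines are analysed facing right; left-side configurations are
  standardized with :func:`reflect_configuration`.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

METADATA_COLUMNS = (
    "specimen_id",
    "species",
    "sex",
    "disc_width_mm",
    "clasper_length_mm",
    "maturity",
)

VALID_SEXES = ("female", "male")
VALID_MATURITY = ("immature", "mature", "unknown")


class ParseError(ValueError):
    """A file violated its format; the message locates the offence."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's ordered 2-D outline landmarks.

    ``coords`` is a ``(k, 2)`` float array in mm (or pixels when no scale
    factor was recorded).  Landmark order is anatomically homologous across
    specimens: index 0 is the anterior propterygium tip and index k-1 the
    posterior fin insertion.
    """

    specimen_id: str
    coords: np.ndarray
    scale: float | None = None
    side: str = "right"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError(
                f"{self.specimen_id}: coords must be (k, 2), got {coords.shape}"
            )
        if coords.shape[0] < 1:
            raise ValueError(f"{self.specimen_id}: need at least 1 landmark")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinate")
        if self.side not in ("left", "right"):
            raise ValueError(f"{self.specimen_id}: side must be left|right")
        object.__setattr__(self, "coords", coords)

    @property
    def k(self) -> int:
        return int(self.coords.shape[0])


@dataclass(frozen=True)
class SliderDefinition:
    """Semilandmark slider triplets ``(before, slider, after)``, 1-based.

    Each slider appears exactly once as a middle element and slides along the
    chord between its flanking landmarks.  The two fixed curve endpoints never
    slide.
    """

    triplets: np.ndarray

    def __post_init__(self) -> None:
        trip = np.asarray(self.triplets, dtype=int)
        if trip.ndim != 2 or trip.shape[1] != 3:
            raise ValueError(f"slider triplets must be (m, 3), got {trip.shape}")
        mids = trip[:, 1]
        if len(set(mids.tolist())) != len(mids):
            dupes = sorted({int(m) for m in mids if (mids == m).sum() > 1})
            raise ValueError(f"slider landmarks repeated as middle element: {dupes}")
        for before, mid, after in trip:
            if len({int(before), int(mid), int(after)}) != 3:
                raise ValueError(f"degenerate slider triplet ({before},{mid},{after})")
        if trip.size and trip.min() < 1:
            raise ValueError("slider indices are 1-based; found index < 1")
        object.__setattr__(self, "triplets", trip)

    @property
    def n_sliders(self) -> int:
        return int(self.triplets.shape[0])

    def validate_for(self, k: int) -> None:
        """Check indices against a configuration of ``k`` landmarks."""
        trip = self.triplets
        if trip.size and trip.max() > k:
            raise ValueError(f"slider index {int(trip.max())} exceeds k={k}")
        endpoints = {1, k}
        bad = sorted(int(m) for m in trip[:, 1] if int(m) in endpoints)
        if bad:
            raise ValueError(
                f"fixed endpoint landmarks may not slide: {bad} (k={k})"
            )

    def zero_based(self) -> np.ndarray:
        return self.triplets - 1


@dataclass(frozen=True)
class SpecimenRecord:
    """Metadata for one specimen (sex, size, clasper, maturity)."""

    specimen_id: str
    species: str
    sex: str
    disc_width: float
    clasper_length: float | None = None
    maturity: str = "unknown"

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValueError(f"{self.specimen_id}: sex must be female|male")
        if not (self.disc_width > 0):
            raise ValueError(f"{self.specimen_id}: disc_width must be > 0")
        if self.clasper_length is not None and self.clasper_length < 0:
            raise ValueError(f"{self.specimen_id}: clasper_length must be >= 0")
        if self.sex == "female" and self.clasper_length is not None:
            raise ValueError(
                f"{self.specimen_id}: females carry no clasper measurement"
            )
        if self.maturity not in VALID_MATURITY:
            raise ValueError(f"{self.specimen_id}: bad maturity {self.maturity!r}")


class PhyloTree:
    """Rooted phylogeny with branch lengths, wrapping a dendropy tree.

    Provides the Brownian-motion covariance (shared root-to-ancestor path
    lengths) needed by phylogenetic regression.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels in tree")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError(
                    "newick tree lacks branch lengths (required for PGLS)"
                )
            if edge.length < 0:
                raise ValueError("negative branch length in tree")
        self.leaf_labels: tuple[str, ...] = tuple(sorted(labels))

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def root_to_tip_distances(self) -> dict[str, float]:
        dist = {}
        for leaf in self._tree.leaf_node_iter():
            dist[leaf.taxon.label] = leaf.distance_from_root()
        return dist

    def vcv(self, order: Sequence[str]) -> np.ndarray:
        """Brownian covariance: C[i, j] = shared path length from the root.

        Computed from root-to-tip times t and patristic distances d as
        C_ij = (t_i + t_j - d_ij) / 2, which equals the depth of the MRCA.
        """
        order = list(order)
        missing = sorted(set(order) - set(self.leaf_labels))
        if missing:
            raise ValueError(f"species not in tree: {missing}")
        t = self.root_to_tip_distances()
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa = {tax.label: tax for tax in self._tree.taxon_namespace}
        n = len(order)
        cov = np.empty((n, n))
        for i, a in enumerate(order):
            cov[i, i] = t[a]
            for j in range(i + 1, n):
                b = order[j]
                d = pdm.patristic_distance(taxa[a], taxa[b])
                cov[i, j] = cov[j, i] = 0.5 * (t[a] + t[b] - d)
        return cov

    def write_newick(self, path: str | Path) -> None:
        self._tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

_TPS_KEYS = ("LM=", "ID=", "SCALE=", "IMAGE=", "CURVES=", "POINTS=")


def read_tps(path: str | Path, flip_y: bool = False) -> list[LandmarkConfiguration]:
    """Parse a TPS landmark file into one configuration per record.

    Accepts ``LM=``, optional ``SCALE=``, ``ID=`` and ``IMAGE=`` lines;
    ``CURVES=``/``POINTS=`` blocks are skipped.  Coordinates are multiplied
    by the scale factor when one is present.  Records whose declared landmark
    count disagrees with the number of coordinate lines are rejected.
    """
    path = Path(path)
    configs: list[LandmarkConfiguration] = []
    current: dict | None = None
    in_curves = False

    def finalize(rec: dict) -> None:
        n_found = len(rec["coords"])
        if n_found != rec["lm"]:
            ident = rec["id"] if rec["id"] is not None else f"record {rec['index']}"
            raise ParseError(
                f"{path.name}: {ident} declares LM={rec['lm']} but has "
                f"{n_found} coordinate line(s) (record starts at line "
                f"{rec['start_line']})"
            )
        coords = np.array(rec["coords"], dtype=float).reshape(rec["lm"], 2)
        if flip_y:
            coords[:, 1] = -coords[:, 1]
        if rec["scale"] is not None:
            coords = coords * rec["scale"]
        specimen_id = rec["id"] if rec["id"] is not None else str(rec["index"])
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen_id, coords=coords, scale=rec["scale"]
            )
        )

    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                if current is not None:
                    finalize(current)
                try:
                    lm = int(upper.split("=", 1)[1])
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name}:{lineno}: malformed LM count {line!r}"
                    ) from exc
                if lm < 1:
                    raise ParseError(f"{path.name}:{lineno}: LM count must be >= 1")
                current = {
                    "lm": lm,
                    "coords": [],
                    "id": None,
                    "scale": None,
                    "index": len(configs) + 1,
                    "start_line": lineno,
                }
                in_curves = False
            elif upper.startswith("CURVES="):
                in_curves = True
            elif upper.startswith("POINTS="):
                pass  # inside a CURVES block; its coordinates are skipped
            elif upper.startswith(("ID=", "IMAGE=", "SCALE=")):
                if current is None:
                    raise ParseError(
                        f"{path.name}:{lineno}: {line!r} outside any record"
                    )
                in_curves = False
                value = line.split("=", 1)[1].strip()
                if upper.startswith("ID="):
                    current["id"] = value
                elif upper.startswith("SCALE="):
                    try:
                        current["scale"] = float(value)
                    except ValueError as exc:
                        raise ParseError(
                            f"{path.name}:{lineno}: non-numeric SCALE {value!r}"
                        ) from exc
            else:
                if current is None:
                    raise ParseError(
                        f"{path.name}:{lineno}: coordinate line before any LM= record"
                    )
                if in_curves:
                    continue
                if len(current["coords"]) >= current["lm"]:
                    raise ParseError(
                        f"{path.name}:{lineno}: extra coordinate line in record "
                        f"{current['index']}"
                    )
                parts = line.split()
                if len(parts) != 2:
                    raise ParseError(
                        f"{path.name}:{lineno}: expected 'x y', got {line!r}"
                    )
                try:
                    xy = (float(parts[0]), float(parts[1]))
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name}:{lineno}: non-numeric coordinate {line!r}"
                    ) from exc
                current["coords"].append(xy)
    if current is not None:
        finalize(current)
    return configs


def write_tps(
    configs: Sequence[LandmarkConfiguration],
    path: str | Path,
    decimals: int = 6,
) -> None:
    """Write configurations as TPS records (LM=, coordinates, ID=).

    All configurations must share the same landmark count.  SCALE lines are
    omitted: coordinates are written already in physical units.
    """
    configs = list(configs)
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise ValueError(f"heterogeneous landmark counts {sorted(ks)}")
    lines: list[str] = []
    for config in configs:
        lines.append(f"LM={config.k}")
        for x, y in config.coords:
            lines.append(f"{x:.{decimals}f} {y:.{decimals}f}")
        lines.append(f"ID={config.specimen_id}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def reflect_configuration(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Mirror a configuration across its vertical bilateral axis.

    x-coordinates are negated and the configuration re-centred so its
    centroid is unchanged; the side flag flips and landmark order (hence
    homology) is preserved.  Applying the function twice is the identity.
    """
    coords = config.coords.copy()
    cx = coords[:, 0].mean()
    coords[:, 0] = 2.0 * cx - coords[:, 0]
    new_side = "left" if config.side == "right" else "right"
    return replace(config, coords=coords, side=new_side)


# ---------------------------------------------------------------------------
# Metadata, sliders, newick
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> list[SpecimenRecord]:
    """Read the specimen metadata CSV into typed, validated records.

    Expected header: ``specimen_id,species,sex,disc_width_mm,
    clasper_length_mm,maturity``.  Blank maturity becomes ``unknown``;
    duplicate specimen ids are rejected.
    """
    frame = pd.read_csv(path, dtype={"specimen_id": str, "species": str})
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{Path(path).name}: missing columns {missing}")
    ids = frame["specimen_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"{Path(path).name}: duplicate specimen_id {dupes}")
    records = []
    for _, row in frame.iterrows():
        clasper = row["clasper_length_mm"]
        clasper = None if pd.isna(clasper) else float(clasper)
        maturity = row["maturity"]
        maturity = "unknown" if pd.isna(maturity) else str(maturity)
        records.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]),
                species=str(row["species"]),
                sex=str(row["sex"]),
                disc_width=float(row["disc_width_mm"]),
                clasper_length=clasper,
                maturity=maturity,
            )
        )
    return records


def write_metadata(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in records],
            "species": [r.species for r in records],
            "sex": [r.sex for r in records],
            "disc_width_mm": [f"{r.disc_width:.4f}" for r in records],
            "clasper_length_mm": [
                "" if r.clasper_length is None else f"{r.clasper_length:.4f}"
                for r in records
            ],
            "maturity": [r.maturity for r in records],
        }
    )
    frame.to_csv(path, index=False)


def read_sliders(path: str | Path, k: int | None = None) -> SliderDefinition:
    """Read a three-column whitespace-delimited slider file (1-based)."""
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ParseError(
                f"{Path(path).name}:{lineno}: expected 3 integers, got {line!r}"
            )
        try:
            rows.append([int(p) for p in parts])
        except ValueError as exc:
            raise ParseError(
                f"{Path(path).name}:{lineno}: non-integer slider index {line!r}"
            ) from exc
    sliders = SliderDefinition(np.array(rows, dtype=int).reshape(len(rows), 3))
    if k is not None:
        sliders.validate_for(k)
    return sliders


def write_sliders(sliders: SliderDefinition, path: str | Path) -> None:
    lines = [f"{b} {m} {a}" for b, m, a in sliders.triplets]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def default_outline_sliders(k: int) -> SliderDefinition:
    """Sliders for an open outline: every interior landmark slides along the
    chord between its neighbours; the two endpoints stay fixed."""
    trip = np.array([(i - 1, i, i + 1) for i in range(2, k)], dtype=int)
    return SliderDefinition(trip)


def read_newick(path: str | Path) -> PhyloTree:
    """Read a rooted newick tree with branch lengths."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return PhyloTree(tree)
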