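"""End-to-end orchestration of the two analysis designs.

``run_interspecific`` reproduces the cross-species design: pooled GPA of
one female + one male outline per species, tangent-space PCA, per-species
dimorphism vectors with lengths and angles to the PC 2 baseline, the
scaled-vector PCA, and PGLS of dimorphism magnitude on size-standardized
clasper length.

``run_ontogenetic`` reproduces the single-species case study: maturity
breakpoint from clasper growth (or a fixed threshold), maturity
classification, pooled GPA, the two permutation trajectory analyses
(immature->mature within sexes; female->male within maturity stages) and
per-trait allometric ANCOVAs.

Each analysis unit gets its own pooled superimposition — the vector
algebra requires a single common frame per analysis.  Configurations are
sorted by specimen id before alignment so reported statistics do not
depend on file order.  All report files are written with fixed numeric
formatting and no timestamps, so identical inputs and seed produce
byte-identical reports; the timestamped run log is the only
non-deterministic output.
"""
from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .comparative import (
    ancova,
    classify_maturity,
    maturity_breakpoint,
    pgls,
    size_standardize,
)
from .dimorphism import (
    angle_table,
    baseline_vector,
    dimorphism_vector,
    scaled_vector_pca,
)
from .io_formats import (
    PhyloTree,
    read_metadata,
    read_newick,
    read_sliders,
    read_tps,
    write_tps,
    LandmarkConfiguration,
)
from .superimposition import centroid_size, gpa, shape_pca
from .trajectory import permutation_test

logger = logging.getLogger("skatemorph")


@dataclass
class RunConfig:
    """Inputs and knobs for one pipeline run."""

    tps: Path
    sliders: Path
    metadata: Path
    outdir: Path
    tree: Path | None = None
    skeletal: Path | None = None
    analysis: str = "interspecific"
    n_permutations: int = 10000
    seed: int = 0
    alpha: float = 0.05
    threshold: float | None = None
    baseline_axis: int = 2
    flip_y: bool = False


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "run.log", mode="w"),
    ):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def _fmt(value: float) -> str:
    return f"{value:.10g}"


def _write_flat(path: Path, mapping: dict) -> None:
    lines = []
    for key, value in mapping.items():
        if isinstance(value, float):
            lines.append(f"{key}={_fmt(value)}")
        else:
            lines.append(f"{key}={value}")
    path.write_text("\n".join(lines) + "\n")


def _write_manifest(cfg: RunConfig, outputs: list[str]) -> None:
    manifest = {
        "skatemorph_version": __version__,
        "analysis": cfg.analysis,
        "tps": cfg.tps.name,
        "sliders": cfg.sliders.name,
        "metadata": cfg.metadata.name,
        "tree": cfg.tree.name if cfg.tree else "",
        "skeletal": cfg.skeletal.name if cfg.skeletal else "",
        "n_permutations": cfg.n_permutations,
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "threshold": "" if cfg.threshold is None else _fmt(cfg.threshold),
        "baseline_axis": cfg.baseline_axis,
        "flip_y": cfg.flip_y,
        "outputs": ",".join(outputs),
    }
    _write_flat(cfg.outdir / "manifest.txt", manifest)


def _load_common(cfg: RunConfig):
    configs = read_tps(cfg.tps, flip_y=cfg.flip_y)
    if not configs:
        raise ValueError(f"no landmark records in {cfg.tps}")
    sliders = read_sliders(cfg.sliders, k=configs[0].k)
    records = {r.specimen_id: r for r in read_metadata(cfg.metadata)}
    missing = [c.specimen_id for c in configs if c.specimen_id not in records]
    if missing:
        raise ValueError(f"specimens without metadata: {missing}")
    configs = sorted(configs, key=lambda c: c.specimen_id)
    return configs, sliders, records


def run_interspecific(cfg: RunConfig) -> dict[str, Path]:
    """Cross-species dimorphism analysis; returns the written report paths."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(cfg.outdir)
    configs, sliders, records = _load_common(cfg)
    if cfg.tree is None:
        raise ValueError("interspecific analysis requires a tree")
    tree = read_newick(cfg.tree)

    by_species: dict[str, dict[str, LandmarkConfiguration]] = {}
    for config in configs:
        rec = records[config.specimen_id]
        by_species.setdefault(rec.species, {})[rec.sex] = config
    bad = sorted(
        sp
        for sp, sexes in by_species.items()
        if set(sexes) != {"female", "male"}
    )
    if bad:
        raise ValueError(
            f"species lacking exactly one specimen per sex: {bad}"
        )
    species_names = sorted(by_species)
    logger.info("aligning %d shapes (%d species)", len(configs), len(species_names))
    aligned = gpa(configs, sliders=sliders)
    logger.info(
        "GPA converged=%s after %d iterations", aligned.converged, aligned.n_iterations
    )
    index = {sid: i for i, sid in enumerate(aligned.specimen_ids)}
    pca = shape_pca(aligned)
    baseline = baseline_vector(pca, axis=cfg.baseline_axis)
    vectors = [
        dimorphism_vector(
            aligned.shapes[index[by_species[sp]["female"].specimen_id]],
            aligned.shapes[index[by_species[sp]["male"].specimen_id]],
            species=sp,
        )
        for sp in species_names
    ]
    table, theta_range = angle_table(vectors, baseline)
    scaled = scaled_vector_pca(vectors)

    # PGLS of dimorphism magnitude on size-standardized clasper length
    with_clasper = [
        sp
        for sp in species_names
        if records[by_species[sp]["male"].specimen_id].clasper_length is not None
    ]
    dropped = sorted(set(species_names) - set(with_clasper))
    if dropped:
        logger.warning("species without clasper data dropped from PGLS: %s", dropped)
    log_cl = np.log(
        [records[by_species[sp]["male"].specimen_id].clasper_length for sp in with_clasper]
    )
    log_cs = np.log(
        [centroid_size(by_species[sp]["male"].coords) for sp in with_clasper]
    )
    resid = size_standardize(log_cl, log_cs)
    lengths = table.set_index("species")["L"]
    pruned_tree = tree
    if dropped:
        pruned = tree.tree.clone(depth=1)
        pruned.retain_taxa_with_labels(with_clasper)
        pruned_tree = PhyloTree(pruned)
    result = pgls(
        lengths.loc[with_clasper].to_numpy(), resid, pruned_tree, with_clasper
    )
    logger.info(
        "PGLS: F(%d,%d)=%.4g R2=%.4g p=%.4g",
        result.df[0],
        result.df[1],
        result.F_stat,
        result.R2,
        result.p_value,
    )

    out = cfg.outdir
    table_out = table.copy()
    for col in ("L", "theta_deg", "theta_supplement_deg"):
        table_out[col] = table_out[col].map(_fmt)
    table_out.to_csv(out / "dimorphism_vectors.csv", index=False)

    pca_frame = pd.DataFrame(
        {
            "axis": np.arange(1, pca.n_axes + 1),
            "eigenvalue": [_fmt(v) for v in pca.eigenvalues],
            "proportion_variance": [_fmt(v) for v in pca.proportion_variance],
        }
    )
    pca_frame.to_csv(out / "shape_pca.csv", index=False)
    scores = pd.DataFrame(
        pca.scores[:, : min(6, pca.n_axes)],
        columns=[f"PC{i + 1}" for i in range(min(6, pca.n_axes))],
    )
    scores.insert(0, "specimen_id", list(aligned.specimen_ids))
    for col in scores.columns[1:]:
        scores[col] = scores[col].map(_fmt)
    scores.to_csv(out / "shape_pca_scores.csv", index=False)

    sv_scores = pd.DataFrame(
        scaled.scores[:, : min(6, scaled.n_axes)],
        columns=[f"PC{i + 1}" for i in range(min(6, scaled.n_axes))],
    )
    sv_scores.insert(0, "species", species_names)
    for col in sv_scores.columns[1:]:
        sv_scores[col] = sv_scores[col].map(_fmt)
    sv_scores.to_csv(out / "scaled_vector_pca_scores.csv", index=False)

    _write_flat(out / "pgls.txt", result.as_flat_dict())
    lengths_arr = table["L"].to_numpy()
    summary = {
        "n_species": len(species_names),
        "n_shapes": aligned.n,
        "gpa_converged": aligned.converged,
        "gpa_iterations": aligned.n_iterations,
        "baseline_axis": cfg.baseline_axis,
        f"pc{cfg.baseline_axis}_proportion_variance": float(
            pca.proportion_variance[cfg.baseline_axis - 1]
        ),
        "theta_range_deg": theta_range,
        "theta_folded_range_deg": float(
            np.ptp(np.minimum(table["theta_deg"], table["theta_supplement_deg"]))
        ),
        "length_min": float(lengths_arr.min()),
        "length_max": float(lengths_arr.max()),
        "length_ratio_max_min": float(lengths_arr.max() / lengths_arr.min()),
        "pgls_n_species": result.n_species,
        "pgls_dropped": ",".join(dropped),
    }
    _write_flat(out / "summary.txt", summary)
    write_tps(
        [
            LandmarkConfiguration(specimen_id=sid, coords=aligned.shapes[i])
            for i, sid in enumerate(aligned.specimen_ids)
        ],
        out / "aligned.tps",
        decimals=8,
    )
    outputs = [
        "dimorphism_vectors.csv",
        "shape_pca.csv",
        "shape_pca_scores.csv",
        "scaled_vector_pca_scores.csv",
        "pgls.txt",
        "summary.txt",
        "aligned.tps",
    ]
    _write_manifest(cfg, outputs)
    return {name: cfg.outdir / name for name in outputs + ["manifest.txt"]}


def run_ontogenetic(cfg: RunConfig) -> dict[str, Path]:
    """Single-species ontogenetic analysis; returns written report paths."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(cfg.outdir)
    configs, sliders, records = _load_common(cfg)

    males = [r for r in records.values() if r.sex == "male" and r.clasper_length is not None]
    if cfg.threshold is not None:
        threshold = cfg.threshold
        bp_result = None
        logger.info("using fixed maturity threshold %.4g mm", threshold)
    else:
        dw = np.array([r.disc_width for r in males])
        cl = np.array([r.clasper_length for r in males])
        bp_result = maturity_breakpoint(dw, cl)
        threshold = bp_result.breakpoint_dw
        logger.info(
            "estimated maturity breakpoint %.4g mm (slopes %.4g -> %.4g)",
            threshold,
            bp_result.slope_below,
            bp_result.slope_above,
        )

    ordered = [records[c.specimen_id] for c in configs]
    sexes = np.array([r.sex for r in ordered])
    stages = np.array(
        [classify_maturity(r.disc_width, threshold) for r in ordered]
    )
    for sex in ("female", "male"):
        for stage in ("immature", "mature"):
            count = int(((sexes == sex) & (stages == stage)).sum())
            logger.info("cell %s/%s: n=%d", sex, stage, count)
            if count == 0:
                raise ValueError(f"empty cell (sex={sex}, stage={stage})")

    aligned = gpa(configs, sliders=sliders)
    logger.info(
        "GPA converged=%s after %d iterations", aligned.converged, aligned.n_iterations
    )
    shapes = aligned.flattened()
    seed_a, seed_b = (
        int(s.generate_state(1, dtype=np.uint32)[0]) % (2**31 - 1)
        for s in np.random.SeedSequence(cfg.seed).spawn(2)
    )
    # 1) ontogenetic shape change within each sex, compared across sexes
    traj_ontogeny = permutation_test(
        shapes, sexes, stages, n_perm=cfg.n_permutations, seed=seed_a
    )
    # 2) dimorphic shape change within each stage, compared across stages
    traj_dimorphism = permutation_test(
        shapes, stages, sexes, n_perm=cfg.n_permutations, seed=seed_b
    )
    for label, res in (
        ("ontogeny", traj_ontogeny),
        ("dimorphism", traj_dimorphism),
    ):
        logger.info(
            "trajectory %s: ratio_L=%.4g theta=%.4g p_dL=%.4g p_theta=%.4g",
            label,
            res.ratio_L,
            res.theta_deg,
            res.p_delta_L,
            res.p_theta,
        )

    ancova_rows = []
    if cfg.skeletal is not None:
        skeletal = pd.read_csv(cfg.skeletal, dtype={"specimen_id": str})
        meta_cols = {"specimen_id", "sex", "disc_width_mm"}
        trait_cols = [c for c in skeletal.columns if c not in meta_cols]
        log_dw = np.log(skeletal["disc_width_mm"].to_numpy(dtype=float))
        for trait in trait_cols:
            res = ancova(
                np.log(skeletal[trait].to_numpy(dtype=float)),
                log_dw,
                skeletal["sex"].to_numpy(),
                alpha=cfg.alpha,
                trait_name=trait,
            )
            ancova_rows.append(
                {
                    "trait": res.trait,
                    "slope_f": _fmt(res.slope_f),
                    "slope_m": _fmt(res.slope_m),
                    "intercept_f": _fmt(res.intercept_f),
                    "intercept_m": _fmt(res.intercept_m),
                    "p_interaction": _fmt(res.p_interaction),
                    "p_sex": "" if res.p_sex is None else _fmt(res.p_sex),
                    "n": res.n,
                }
            )
        logger.info("ANCOVA fitted for %d traits", len(ancova_rows))

    out = cfg.outdir
    bp_map: dict[str, object] = {"threshold_dw_mm": threshold}
    if bp_result is not None:
        bp_map.update(
            {
                "estimated": True,
                "slope_below": bp_result.slope_below,
                "slope_above": bp_result.slope_above,
                "sse": bp_result.sse,
                "n_males": bp_result.n,
            }
        )
    else:
        bp_map["estimated"] = False
    _write_flat(out / "breakpoint.txt", bp_map)
    _write_flat(out / "trajectory_ontogeny.txt", traj_ontogeny.as_flat_dict())
    _write_flat(out / "trajectory_dimorphism.txt", traj_dimorphism.as_flat_dict())
    outputs = ["breakpoint.txt", "trajectory_ontogeny.txt", "trajectory_dimorphism.txt"]
    if ancova_rows:
        pd.DataFrame(ancova_rows).to_csv(out / "ancova.csv", index=False)
        outputs.append("ancova.csv")
    _write_manifest(cfg, outputs)
    return {name: cfg.outdir / name for name in outputs + ["manifest.txt"]}
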