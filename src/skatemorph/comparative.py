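"""Comparative and allometric statistics.

Four pieces of machinery used by the interspecific and ontogenetic
analyses:

* :func:`size_standardize` — ordinary least-squares residuals of
  log-clasper length on log-body size (centroid size of the pectoral fin),
  removing overall size from clasper length before comparative tests.
* :func:`pgls` — phylogenetic generalized least squares under a Brownian
  motion covariance (shared root-to-ancestor path lengths), with the
  F-test of the slope against the intercept-only model.
* :func:`ancova` — per-trait allometric ANCOVA: does ln(trait) ~ ln(size)
  differ between sexes in slope (interaction term), and if not, in
  elevation (sex main effect)?  Model fits go through statsmodels OLS.
* :func:`maturity_breakpoint` — continuous two-segment ("hinge") least
  squares on clasper length versus disc width, locating the size at which
  clasper elongation accelerates; the selected breakpoint defines the
  maturity threshold used by :func:`classify_maturity` (strictly greater
  than the threshold counts as mature).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_formats import PhyloTree

__all__ = [
    "PGLSResult",
    "AllometryResult",
    "BreakpointResult",
    "size_standardize",
    "pgls",
    "ancova",
    "maturity_breakpoint",
    "classify_maturity",
]


def size_standardize(log_clasper, log_size) -> np.ndarray:
    """OLS residuals of log-clasper length on log-body size."""
    y = np.asarray(log_clasper, dtype=float)
    x = np.asarray(log_size, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("log_clasper and log_size must be equal-length 1-D")
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("log_size has zero variance")
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


@dataclass(frozen=True)
class PGLSResult:
    slope: float
    intercept: float
    F_stat: float
    df: tuple[int, int]
    R2: float
    p_value: float
    covariance_model: str
    n_species: int

    def as_flat_dict(self) -> dict[str, object]:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "F": self.F_stat,
            "df_num": self.df[0],
            "df_den": self.df[1],
            "R2": self.R2,
            "p_value": self.p_value,
            "covariance_model": self.covariance_model,
            "n_species": self.n_species,
        }


def pgls(
    y,
    x,
    tree: PhyloTree | None,
    species,
    covariance_model: str = "brownian",
) -> PGLSResult:
    """Phylogenetic regression of y on x across species.

    Under ``covariance_model="brownian"`` the error covariance between two
    species equals their shared path length from the root; ``"star"`` uses
    the identity (equivalent to OLS).  The slope is tested with an F-test
    against the GLS intercept-only model and R-squared is GLS-weighted.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    species = list(species)
    n = len(species)
    if not (y.shape == x.shape == (n,)):
        raise ValueError("y, x and species must have equal length")
    if n < 3:
        raise ValueError("PGLS needs at least 3 species")
    if len(set(species)) != n:
        raise ValueError("duplicate species in PGLS input")
    if covariance_model == "brownian":
        if tree is None:
            raise ValueError("brownian covariance requires a tree")
        extra = sorted(set(tree.leaf_labels) - set(species))
        missing = sorted(set(species) - set(tree.leaf_labels))
        if missing or extra:
            raise ValueError(
                f"species/tree mismatch: missing from tree {missing}, "
                f"unused leaves {extra}"
            )
        cov = tree.vcv(species)
    elif covariance_model == "star":
        cov = np.eye(n)
    else:
        raise ValueError("covariance_model must be 'brownian' or 'star'")

    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular phylogenetic covariance matrix (zero-length split "
            "between species?)"
        ) from exc
    # whiten: solve L z = v  =>  z has iid errors
    yw = np.linalg.solve(chol, y)
    design = np.column_stack([np.ones(n), x])
    dw = np.linalg.solve(chol, design)
    beta, *_ = np.linalg.lstsq(dw, yw, rcond=None)
    rss = float(((yw - dw @ beta) ** 2).sum())
    ones_w = np.linalg.solve(chol, np.ones(n))
    mu = float((ones_w @ yw) / (ones_w @ ones_w))
    tss = float(((yw - mu * ones_w) ** 2).sum())
    df_den = n - 2
    if rss <= 0:  # perfect fit: F unbounded, p at the floor
        f_stat = np.inf
        p_value = 0.0 if tss > 0 else 1.0
    else:
        f_stat = (tss - rss) / (rss / df_den)
        p_value = float(stats.f.sf(f_stat, 1, df_den))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return PGLSResult(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        F_stat=float(f_stat),
        df=(1, df_den),
        R2=float(max(r2, 0.0)),
        p_value=max(p_value, np.nextafter(0, 1)),
        covariance_model=covariance_model,
        n_species=n,
    )


@dataclass(frozen=True)
class AllometryResult:
    """Sex-specific allometry of one trait against log disc width.

    ``p_sex`` is reported only when the slope interaction is not significant
    at the chosen alpha; with a significant interaction the sexes differ in
    slope and a common-elevation test is not meaningful.
    """

    trait: str
    slope_f: float
    slope_m: float
    intercept_f: float
    intercept_m: float
    p_interaction: float
    p_sex: float | None
    alpha: float
    n: int


def ancova(trait, log_dw, sex, alpha: float = 0.05, trait_name: str = "trait") -> AllometryResult:
    """Allometric ANCOVA of one trait: slopes first, then elevations.

    Fits ``trait ~ sex + log_dw + sex:log_dw`` and F-tests the interaction;
    when the interaction is non-significant at ``alpha``, refits without it
    and reports the sex main-effect F-test.  Per-sex slopes and intercepts
    come from whichever fit was retained.
    """
    y = np.asarray(trait, dtype=float)
    x = np.asarray(log_dw, dtype=float)
    sex = np.asarray(sex)
    if not (y.shape == x.shape == sex.shape) or y.ndim != 1:
        raise ValueError("trait, log_dw, sex must be equal-length 1-D")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(x))):
        raise ValueError("non-finite values")
    levels = sorted(set(sex.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two sexes, got {levels}")
    is_m = (sex == levels[1]).astype(float)
    for label, mask in zip(levels, (is_m == 0, is_m == 1)):
        if mask.sum() < 3:
            raise ValueError(f"fewer than 3 specimens for sex {label!r}")

    full_design = np.column_stack([np.ones_like(x), is_m, x, is_m * x])
    add_design = full_design[:, :3]
    base_design = np.column_stack([np.ones_like(x), x])

    full = sm.OLS(y, full_design).fit()
    additive = sm.OLS(y, add_design).fit()
    f_int, p_int, _ = full.compare_f_test(additive)

    if p_int < alpha:
        b = full.params
        slope_f, slope_m = float(b[2]), float(b[2] + b[3])
        int_f, int_m = float(b[0]), float(b[0] + b[1])
        p_sex = None
    else:
        base = sm.OLS(y, base_design).fit()
        _, p_sex_val, _ = additive.compare_f_test(base)
        b = additive.params
        slope_f = slope_m = float(b[2])
        int_f, int_m = float(b[0]), float(b[0] + b[1])
        p_sex = float(p_sex_val)
    return AllometryResult(
        trait=trait_name,
        slope_f=slope_f,
        slope_m=slope_m,
        intercept_f=int_f,
        intercept_m=int_m,
        p_interaction=float(p_int),
        p_sex=p_sex,
        alpha=alpha,
        n=int(y.size),
    )


@dataclass(frozen=True)
class BreakpointResult:
    breakpoint_dw: float
    slope_below: float
    slope_above: float
    intercept: float
    sse: float
    n: int


def maturity_breakpoint(disc_widths, clasper_lengths, min_per_side: int = 3) -> BreakpointResult:
    """Continuous two-segment least squares for clasper growth.

    Candidate breakpoints are the unique observed disc widths together with
    the midpoints between consecutive sorted unique values (so a hinge
    located exactly at a sampled size is representable), restricted to
    candidates leaving at least ``min_per_side`` points strictly on each
    side; the SSE-minimizing candidate wins, ties going to the smaller
    breakpoint.  The hinge model nests the straight line, so its SSE never
    exceeds the single-line fit.
    """
    dw = np.asarray(disc_widths, dtype=float)
    cl = np.asarray(clasper_lengths, dtype=float)
    if dw.shape != cl.shape or dw.ndim != 1:
        raise ValueError("disc_widths and clasper_lengths must match")
    n = dw.size
    if n < 2 * min_per_side:
        raise ValueError(f"need at least {2 * min_per_side} males")
    uniq = np.unique(dw)
    if uniq.size < 2:
        raise ValueError("disc widths are all equal")
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    pool = np.sort(np.concatenate([uniq, mids]))
    candidates = [
        bp
        for bp in pool
        if (dw < bp).sum() >= min_per_side and (dw > bp).sum() >= min_per_side
    ]
    if not candidates:
        raise ValueError(
            f"no candidate breakpoint leaves {min_per_side} points per side"
        )
    best = None
    for bp in candidates:  # ascending, so strict improvement keeps first min
        design = np.column_stack(
            [np.ones(n), dw, np.maximum(dw - bp, 0.0)]
        )
        beta, *_ = np.linalg.lstsq(design, cl, rcond=None)
        sse = float(((cl - design @ beta) ** 2).sum())
        if best is None or sse < best[0] - 1e-12:
            best = (sse, float(bp), beta)
    sse, bp, beta = best
    return BreakpointResult(
        breakpoint_dw=bp,
        slope_below=float(beta[1]),
        slope_above=float(beta[1] + beta[2]),
        intercept=float(beta[0]),
        sse=sse,
        n=n,
    )


def classify_maturity(disc_width: float, threshold: float) -> str:
    """'mature' for disc widths strictly greater than the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if disc_width <= 0:
        raise ValueError("disc width must be positive")
    return "mature" if disc_width > threshold else "immature"
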