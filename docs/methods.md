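# Methods

This note documents the models, numerical choices and limitations of
`skatemorph`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Superimposition

Configurations are centred on their centroid, scaled to unit centroid size
(CS = √Σᵢ‖xᵢ − x̄‖², the size metric later used as "body size" in
allometric analyses) and rotated by the closed-form 2-D Kabsch solution
with the determinant constrained positive — reflections are never
introduced during alignment because all outlines are standardized to
right-facing beforehand (`reflect_configuration` mirrors left fins while
preserving landmark order, hence homology).

**GPA.** The consensus is seeded with the first configuration and the
sample iterates align-all / re-estimate-consensus until the consensus'
Procrustes change falls below `tol` (1e-8, `max_iter` 100). Convergence
failure sets a flag rather than raising.

**Sliding semilandmarks.** Each of the 33 interior outline points slides
along the chord between its flanking landmarks by the scalar that
minimizes its squared distance to the consensus (closed-form projection of
the residual onto the chord tangent; all sliders update simultaneously
from the pre-slide geometry). The criterion is minimized Procrustes
distance, chosen over bending energy because it is deterministic and
oracle-checkable in one dimension; a `criterion` extension point is
reserved but bending energy is out of scope.

Sliding is applied as a fixed, small number of passes (`slide_iter`, default
3) between two plain-GPA convergence phases, not inside the convergence
loop. The reason is a real pathology we measured during development:
iterating chord-tangent sliding against a moving consensus has a nearly
neutral mode in which semilandmarks collectively drift along the outline,
and because successive 1-D projections act along slowly rotating chord
directions, the iteration progressively contracts genuine shape
differences toward the consensus (roughly 1–2 % of a 0.08-Procrustes-unit
effect per pass, growing quadratically with effect size). Few passes are
also the convention of standard semilandmark tools.

**Canonical frame.** GPA fixes shapes only up to a global rotation, which
would make the consensus depend on input order. After convergence the
whole sample is rotated so the consensus lies on its principal axes
(major axis along x, det +1, 180° spin so the largest-magnitude consensus
coordinate is positive). Pipelines additionally sort specimens by id
before alignment, making every reported statistic independent of file
order.

**Tangent space.** Aligned shapes are used as-is (no orthogonal projection
onto the tangent plane); at the shape-variation scales simulated here the
difference is far below statistical tolerances. PCA loadings follow a
deterministic sign convention (largest-magnitude component positive, ties
to the lowest coordinate index); axis arguments are 1-based ("PC 2" =
`axis=2`).

## Dimorphism vectors

Vectors are oriented female→male throughout; the baseline runs from the
shape predicted at the minimum PC 2 score to the maximum. Both conventions
matter because θ and 180° − θ are interchanged by either flip, so the
supplement is always emitted alongside (`theta_supplement_deg`, and the
summary reports the angular range on both θ and the folded min(θ, 180−θ)
scale). With one specimen per sex and species no within-species test is
possible; lengths and angles are reported descriptively.

## Trajectory analysis

Trajectories are stage-mean paths per group in the flattened aligned
coordinates. The test statistics are ΔL = |L_A − L_B| and the angle θ
between direction vectors. The null is generated by residual
randomization: the reduced model with group and stage main effects but no
interaction is fitted per coordinate, specimen residual vectors are
permuted across the whole sample with a seeded generator and added back to
the fitted values, and both statistics are recomputed. p = (1 + #{stat* ≥
stat}) / (1 + n_perm), one-sided with large values extreme — never zero,
and bitwise reproducible given the seed. A `scheme="labels"` fallback
(group labels shuffled within stage on the raw shapes) exists for
sensitivity analysis. Monte-Carlo calibration in the acceptance suite
checks the size of the ΔL test ([0.02, 0.09] at α = 0.05 under a true
null), approximate uniformity of null p-values, power ≥ 0.9 for a
three-fold magnitude ratio at 20 specimens per cell, and ±10° recovery of
a constructed 90° trajectory separation.

## Comparative statistics

**Size standardization.** Clasper length is standardized as the ordinary
(non-phylogenetic) least-squares residual of log clasper length on log fin
centroid size; a phylogenetic variant is a possible extension but OLS is
the minimal reading of "residuals of a regression".

**PGLS.** Error covariance between species equals their shared
root-to-MRCA path length (pure Brownian motion; no Pagel's λ estimation —
again the minimal model). Estimation whitens by the Cholesky factor;
the slope is tested by F against the GLS intercept-only model with
df = (1, n − 2), and R² is GLS-weighted. A star covariance option
reproduces OLS to 1e-8 (asserted). Species with missing clasper data are
dropped with a logged warning, never imputed, and the tree is pruned to
match.

**Allometric ANCOVA.** For each trait, ln(trait) ~ sex + ln(DW) +
sex:ln(DW) is fitted (statsmodels OLS); the interaction is F-tested, and
only when p_int ≥ α (0.05) is the model refitted without the interaction
and the sex main effect reported as p_sex — reporting elevation
differences under heterogeneous slopes would be meaningless, so p_sex is
structurally absent otherwise. No multiple-testing correction is applied
across the nine traits (raw per-trait p-values are the convention for this
design).

**Maturity breakpoint.** Clasper length vs disc width is fitted by
continuous two-segment least squares (hinge model `a + b·DW +
c·max(DW − bp, 0)`). Candidates are the unique observed disc widths plus
midpoints between consecutive values, restricted to ≥ 3 points strictly on
each side; the SSE-minimizing candidate wins with ties to the smaller
value. Including observed values makes a hinge at a sampled size exactly
representable. The resulting threshold classifies maturity strictly:
DW > threshold ⇒ mature (so a specimen exactly at the threshold is
immature), and the same cutoff is applied to females, whose maturation
state is not otherwise observable in preserved material.

## Synthetic data

The generator's defaults are the study conditions: 35 landmarks (33
sliders), ~21 species for the interspecific design; 21 males + 22 females
spanning 50.6–109.5 mm disc width for the ontogenetic series; clasper
growth hinged at 84 mm with slopes 0.05 → 1.2 mm/mm and 0.5 mm noise; a
five-fold span of dimorphism magnitudes (d log-uniform in 0.03–0.15
Procrustes units); male maturation shape effect three times the female
one; nine skeletal traits of which three are slope-dimorphic, two
elevation-dimorphic and four monomorphic.

Design choices worth knowing:

* **Deformation fields.** The dimorphism field u is two Gaussian bumps
  along the outline's chord normals — an anterior concavity and a
  posterior lobe expansion, the two male-typical features — built inside
  the chord-normal subspace and orthogonalized (within that subspace)
  against the similarity-transform directions. This makes the injected
  effect invariant, to first order, under both superimposition and
  sliding, so generated magnitudes are recoverable. The shared ontogenetic
  allometry field v is a broad apex elongation, orthogonal to u. Exact
  bump shapes are arbitrary.
* **Species shape evolution** is Brownian on landmark coordinates over a
  unit-depth pure-birth tree (rate 4e-4 per coordinate), with increments
  smoothed along the outline (Gaussian kernel, sd 4 landmarks, rows
  L2-normalized so the per-coordinate marginal variance is preserved).
  Unsmoothed independent jitter at realistic rates exceeds inter-landmark
  spacing and folds the outline; smoothing makes displacement a coherent
  deformation of the margin. A brute-force segment-intersection check
  warns (listing species) if a draw still self-intersects. The pure-birth
  simulator stops at the n-th speciation, which would leave a zero-length
  cherry and a singular Brownian covariance; the memoryless Exp(nλ)
  waiting time to the next event is appended to every tip branch, keeping
  the tree ultrametric and the covariance positive definite.
* **Digitizing noise** is iid per coordinate (default sd 0.002 at unit
  centroid size — sub-pixel placement error relative to a typical source
  image). Per-species dimorphism directions disperse around u by a
  Gaussian angle (sd 15°), drawn within the sliding-invariant subspace.
* **Disc widths** are sampled uniformly per sex with counts on each side
  of the maturity threshold fixed at their expected value (≥ 1), so both
  maturity classes are always populated.
* **Reproducibility.** One RNG stream per output, spawned from the master
  seed; identical (spec, seed) yields byte-identical files. True
  parameters are persisted to a `truth.txt` manifest that recovery tests
  read back.

What the generator does *not* emulate: photographic/digitizing artefacts
beyond iid jitter, within-species variation in the interspecific design
(one specimen per sex, as in the real sampling), correlated measurement
error between skeletal traits, non-Brownian (selective) shape evolution,
and any direction change of the maturation deformation over ontogeny
(females share the male direction at a third the magnitude). Passing tests
therefore demonstrate correctness of the estimators under these stated
conditions, not robustness to every property of real specimen data.

## Known limitations

* **Sliding compresses large effects.** Chord-tangent sliding removes the
  component of a shape difference that is tangential to the *deformed*
  outline's chords. A deformation of magnitude d rotates chords in
  proportion to d, so recovered magnitudes shrink quadratically with d
  (≈1 % at d = 0.04, ≈15 % at d = 0.25 over the default three passes).
  Magnitude *ratios* are compressed toward 1 accordingly. This is a
  property of semilandmark analysis, not an implementation defect; the
  acceptance fixtures therefore work in the small-deformation regime.
* **Species spread adds multiplicative length noise.** Each species' mean
  shape rotates its chords relative to the consensus, making the sliding
  loss weakly species-random. At the full default interspecific
  conditions this costs a few points of rank concordance between
  estimated and generating magnitudes relative to the no-spread setting
  (the acceptance test isolates digitizing noise and directional
  dispersion, the perturbations the property is about).
* The simulation scales used throughout (20–50 species, ≤ 200 Monte-Carlo
  replicates, 999 permutations in calibration runs) were chosen so the
  whole suite completes in well under a minute of statistical computation
  while keeping binomial envelopes tight enough to detect miscalibration.
* Two identical aligned frames are assumed whenever vectors are compared;
  the pipelines enforce this by pooling each analysis unit (interspecific
  set, ontogenetic series) into its own single GPA.
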