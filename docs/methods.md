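# Methods

This note documents the models, numerical choices and limitations of
rostrumorph, in the package's own terms. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Landmark scheme and data model

A specimen is 22 ordered 3D landmarks in mm. Landmarks 1–10 are fixed
anatomical points: the apex, the ventral/dorsal and lateral outer walls and
the ventral/dorsal inner (alveolar) walls at the reference transversal
section, the protoconch, and the ventral/dorsal rim of the rostrum cavum
(truncated to 1/6 of the rostrum solidum length — the preparation rule
applied to the CT models). Landmarks 11–22 are curve-sliding
semilandmarks, split 11–16 (ventral) / 17–22 (dorsal); the split is a
package default and overridable, since only "ventral and dorsal flanks" is
anatomically fixed. Files are 1-based (TPS `LM3=22` blocks, long CSV,
JSON bundle); arrays are 0-based; the readers/writers are the only place
the shift occurs.

Specimens marked ontogenetically indeterminate load normally and are
excluded only from stage-stratified analyses.

## Superimposition

GPA iterates: centre, scale to unit centroid size, rotate each specimen
onto the current consensus (sign-corrected SVD; reflections disallowed
because specimens share handedness), optionally slide semilandmarks,
re-estimate the consensus (renormalised to unit size). Convergence is
`|ΔQ| < tol·(Q + tol)` on the summed squared Procrustes residuals Q, with
`tol = 1e-8`, `max_iter = 100`. The final frame is canonicalised to the
consensus's principal axes with signs fixed by projection skewness, so
results do not depend on the input orientation of any specimen.

**Bending energy.** The TPS bordered system uses the 3D radial kernel
U(r) = r; the upper-left block of its inverse is sign-oriented to the
positive-semidefinite convention (in 3D the PD Green's-function convention
is −r, and negating the kernel exactly negates the block). The form
annihilates affine maps of the reference (null space {1, x, y, z} per
coordinate, verified to machine tolerance) and is cross-checked against an
explicit interpolation-weight computation on small configurations.

**Sliding.** Each semilandmark moves only along the chord direction of its
two curve neighbours (endpoints use their single neighbour), by the exact
minimiser of the quadratic bending energy; the solve is iterated within a
call because tangents rotate as sliders move (each pass is non-increasing
in energy; flat directions receive the minimum-norm zero step). Sliding
runs during the first `slide_iterations = 3` outer GPA iterations only:
positions along straight outline stretches are bending-energy-flat, so
fully interleaved sliding against an evolving consensus drifts
indefinitely instead of converging. A few passes recover curve-homologous
positions; the subsequent plain GPA then converges normally. No
re-projection onto an original surface is performed (no meshes exist in
this pipeline); the Procrustes-distance sliding criterion is available as
an option but off by default.

## Ordination

Covariance PCA (no per-coordinate standardisation — Procrustes coordinates
are commensurate) of the flattened aligned shapes, tangent-projected at
the consensus by default (orthogonal projection; the raw-coordinate
variant is a flag and differs negligibly at small shape variance). Axis
signs follow two deterministic rules: each axis's largest-magnitude
loading is positive; PC1 is then oriented so that higher scores mean more
robust (higher width/length) shapes, using the per-specimen elongation
ratio of the aligned configurations. With contrasts ordered
earlier-sample-first this reproduces the reported sign conventions: an
increase in robustness through time prints as negative Hedges' g, and
allometric slopes are negative when smaller specimens are more robust.

## Statistics

* Hedges' g with J = 1 − 3/(4(n₁+n₂) − 9) (exact-gamma J behind a flag);
  ordering recorded in every result.
* Mann–Whitney U = #{aᵢ > bⱼ} + ½·ties; exact null enumeration when
  tie-free and n₁n₂ ≤ 400, else normal approximation with tie and
  continuity corrections (scipy backend; the exact path is verified
  against full enumeration for all small sample sizes).
* Mood's median test dichotomises strictly-above vs not-above the pooled
  grand median (ties fall in the lower cell), chi-squared without
  continuity correction; a two-group design with one group entirely at the
  grand median is reported degenerate with p = 1.
* Pairwise median tests run on consecutive subzones in stratigraphic
  order; the multiplicity adjustment defaults to "none" (consecutive
  contrasts are reported unadjusted), with Bonferroni and
  Benjamini–Hochberg selectable.
* MAD is unscaled (descriptive envelope); the 1.4826 factor is a flag.
* Significance tiers: significant < 0.05, marginal < 0.1, n.s. — the
  marginal tier exists because small palaeontological samples inflate
  type-II, not type-I, error.
* The size-proxy gate regresses centroid size on the geometric mean of the
  linear measurements and requires r² above a configurable threshold
  (default 0.9) before centroid size is interpreted as body size.

## Composition bootstrap

Overall relative abundances define selection probabilities; `draw_n`
defaults to the mean per-subzone sample size rounded half-up (29 for the
packaged 144-specimen table) and `reps` to 500. The envelope is the
min–max of simulated relative abundances (percentile envelopes behind a
flag); replicates are drawn sequentially from one seeded stream, so
extending `reps` under the same seed extends the replicate set and the
envelope widens monotonically. Classification flags a subzone when any
species' observed relative abundance falls strictly outside its envelope;
empty subzones are reported non-evaluable. A consequence of the literal
min–max frame worth knowing: a species abundant overall but absent from
one subzone is essentially always flagged, because 500 draws of 29 never
produce zero for a ~40%-abundant species.

## Environmental models

* Temperature split at δ¹⁸O = −0.9 ‰ (warm strictly below; the boundary
  value is cold — documented tie rule).
* Allometry is OLS of PC1 on centroid size per regime; the slope contrast
  is the regime×size interaction F-test in the pooled model, equivalent to
  the two-model ANOVA comparison.
* The ordinal stage model codes juvenile < neanic < adult by orthogonal
  polynomial contrasts (integer coding behind a flag) and compares against
  the intercept-only null by AICc = AIC + 2k(k+1)/(n−k−1), k counting the
  residual variance.
* Variation partitioning projects the morphospace scores (all retained
  PCs; PC1-only behind a flag) onto each subset of the predictor sets
  (δ¹⁸O, δ¹³C, δ¹¹B, lithology dummies), Ezekiel-adjusts each R², and
  reports unique fractions (adjR²(all) − adjR²(all∖i)), one lumped shared
  fraction, and the residual; the three sum to 1 exactly, and unique
  fractions may be slightly negative (adjustment artefact).
* GLS fits are maximum likelihood (not REML) so AICc is comparable across
  fixed-effect structures. The AR(1) coefficient over stratigraphic bed
  order is profiled out: conditional on φ, the whitened model is
  closed-form OLS; φ is found by bounded scalar minimisation on
  (−0.95, 0.95). With φ fixed at 0 the fit reproduces OLS exactly. The
  correlation structure is pluggable (independence / AR(1)) and recorded
  in the output; candidates are all 8 subsets of the isotope proxies with
  lithology always included, and a collinearity guard rejects |r| ≥ 0.99
  predictor pairs (a separate check reports the 0.7 screening threshold).
  The implementation is cross-checked in the test suite against OLS and
  against an external GLS reference (R nlme, ML, corAR1) on a fixture.

## Synthetic assemblages

The generator is the study-conditions model, not a fixture: a rostrum is a
piecewise sagittal outline (conical apex over 35% of the solidum length,
then parallel-sided to the cavum rim at solidum × 7/6), with two lateral
fixed landmarks on the reference transversal section so configurations are
genuinely 3D (an all-sagittal scheme would make the TPS system singular).
Semilandmarks are placed equidistantly in arc length; isotropic Gaussian
noise (default 0.3 mm, ≈1% of a typical 40 mm rostrum — digitisation-error
scale) perturbs every coordinate.

Defaults: four species spanning base robustness 0.15–0.26 at base sizes
35–45 mm; stage size factors juvenile 0.55, neanic 0.80, adult 1.05 (sd
0.07–0.08) of the species base; stage probabilities 0.40/0.35/0.25;
allometric slopes −0.004 (warm) and −0.002 (cold) ratio-units per mm, at
the magnitude scale of the reported slopes; robustness scatter sd 0.015.
Ten beds, two per subzone; δ¹⁸O steps from ≈−0.7 ‰ background to ≈−1.3 ‰
after the boundary so the −0.9 threshold bisects the series cleanly; δ¹³C
carries a short negative excursion and δ¹¹B a transient decline, with
per-bed structure chosen so pairwise proxy correlations stay well below
the 0.7 screening threshold. Lithology alternates marl / limestone /
marly limestone. The null and shifted composition presets share the
overall species vector; the shifted preset moves the dominant species'
probability mass to the most robust species in one subzone.

What the generator does **not** emulate — and hence what passing tests do
not show about real material: taphonomic fragmentation and preparation
artefacts, within-species geographic or bathymetric shape variation beyond
the single robustness factor, digitisation error that is anisotropic or
landmark-specific, uneven specimen numbers per bed, and any true
environmental dependence of shape other than the planted
allometry-by-regime effect. Recovery rates measured on the generator are
upper bounds for real data.

## Simulation scales and design choices in the checks

Test and acceptance simulations use: 100 seeds for allometric-slope CI
coverage (25 specimens per subzone; the slope is recovered by regressing
landmark-recomputed width/length ratios on true size, so the check
isolates the generator + measurement chain from PC1 scaling); 100–200
replicates for composition null coverage at draw 29 / reps 500; 500
replicates for the slope-ANOVA type-I rate (n = 60 per regime); and 100
replicates for GLS subset selection. Subset selection is simulated at
n = 24 — the smallest adequately sampled subzone in the packaged table —
with the independence residual structure matching the zero-autocorrelation
generating process: exact-subset recovery under AICc is bounded by the
spurious-inclusion probability ≈ 3·P(χ²₁ > penalty), and only at small n
does the small-sample correction push that bound high enough for a
reliable ≥80% recovery criterion; at n = 150 the asymptotic penalty caps
exact selection near 60%. The AR(1)-estimation path is validated
separately (φ recovery, external reference fit).

## Known limitations

* Sliding uses tangent lines without surface re-projection; heavily curved
  outlines between neighbours are linearised.
* The min–max composition frame hardens with `reps` (it can only widen),
  so its false-flag rate is conservative but its width is not a confidence
  interval; percentile envelopes are provided for calibrated use.
* The GLS AR(1) structure treats specimens as a single series ordered by
  bed; specimens within one bed are exchangeable and their within-bed
  correlation is not modelled separately.
* Variation partitioning reports a lumped shared fraction rather than the
  full 2⁴-cell inclusion–exclusion Venn decomposition.
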