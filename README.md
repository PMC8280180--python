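# rostrumorph

Geometric morphometrics of belemnite rostra across the
Pliensbachian–Toarcian boundary hyperthermal (~183 Ma): a tested, reusable
re-implementation of the full analysis chain used to ask whether rapid
ocean warming changed the *shape* of these extinct cephalopod predators as
well as their size, and whether different ontogenetic stages were affected
differently.

The package is aimed at palaeobiologists and morphometricians who want the
whole chain — superimposition, ordination, time-series statistics,
composition null models, and environmental model selection — as one
scriptable library, and at anyone who needs its components (3D Procrustes
alignment with sliding semilandmarks, a multinomial bootstrap composition
frame, ML-GLS/AICc selection) on their own data.

## What it computes

Each specimen is a configuration of 22 three-dimensional landmarks on a
rostrum (landmarks 1–10 fixed anatomical points; 11–22 curve-sliding
semilandmarks on the ventral and dorsal flanks; the hollow rostrum cavum is
truncated to 1/6 of the rostrum solidum length). The pipeline:

1. **Generalized Procrustes Analysis** — translate, scale to unit centroid
   size CS = √Σᵢ‖xᵢ − x̄‖², and rotate (no reflections) to an iteratively
   re-estimated consensus; semilandmarks slide along their outline tangents
   to minimise the thin-plate-spline bending energy
   tr(YᵀB Y) of the deformation from the consensus, where B is the
   bending-energy matrix of the bordered TPS system.
2. **Morphospace** — PCA of the (tangent-projected) aligned coordinates.
   PC1 captures the width/length proportion of the rostrum ("robustness";
   oriented so higher PC1 = more robust).
3. **Contrasts through time** — bias-corrected standardized mean
   differences (Hedges' g = J·d, J = 1 − 3/(4(n₁+n₂) − 9)) with
   Mann–Whitney U tests between consecutive ammonite subzones, Mood's
   median tests across ontogenetic stages, MAD dispersion envelopes.
4. **Composition null** — species names drawn 29× (the mean subzone sample
   size) with replacement from overall relative abundances, 500 replicates;
   the per-species min–max envelope is the frame within which abundance
   changes count as random sampling.
5. **Allometry × temperature** — OLS of PC1 on centroid size split at the
   δ¹⁸O = −0.9 ‰ threshold (warm: δ¹⁸O < −0.9), slope difference tested by
   the regime×size interaction F-test.
6. **Environmental models** — variation partitioning (RDA, Ezekiel-adjusted
   R²) of the morphospace over δ¹⁸O, δ¹³C, δ¹¹B and lithology, and ML-GLS
   with AR(1) residuals over stratigraphic order, AICc-ranked over all
   subsets of the isotope proxies with lithology always controlled.

The original CT-derived landmark coordinates are not publicly deposited, so
the package ships a first-class synthetic generator
(`rostrumorph.simulate`) producing belemnite-like assemblages with known
ground truth — species-specific robustness, stage-dependent size,
regime-dependent allometric slopes, Gaussian landmark noise, and a step
change in the proxy series at the boundary — so every stage is testable and
every recovery claim is checked against planted parameters. The occurrence
table of the 144 studied specimens is packaged and used directly.

## Worked example

```sh
python examples/02_superimposition_morphospace.py
```

prints (seed 1, 150 specimens):

```
GPA converged after 5 iterations (mean Procrustes distance 0.0757)
PC1 explains 70.5% of shape variance, PC2 2.2%
rank correlation of PC1 with the planted robustness ratio: 0.994
```

PC1 dominating the variance and correlating at ρ ≈ 0.99 with the planted
width/length ratios means the superimposition + ordination chain recovers
the generating shape factor almost perfectly at realistic landmark noise;
PC1 can then stand in for robustness in every downstream contrast.
`examples/` contains one short script per capability (assemblage
generation, alignment + morphospace, time-series contrasts, the composition
null on the packaged occurrence table, environmental models, and the full
pipeline); each prints the numbers it computes and what they mean.

The same pipeline runs from a shell:

```sh
rostrumorph make-assemblage --preset allometry --n 30 --seed 1 --out data/
rostrumorph run --config analysis.yaml
rostrumorph compose-null --occurrences data/occurrences.csv --seed 1 --out null/
```

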