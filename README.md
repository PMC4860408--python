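# ecomorph

Ecogeographic geometric morphometrics for 2-D landmark data, built around
the question of how climate and interspecific competition shape skull
morphology across a multi-species assemblage (the motivating system is the
South-American canid guild: eight species sampled across hundreds of
localities).

The package covers a complete analysis chain:

- **Superimposition & shape space** — generalized Procrustes analysis
  (GPA) removing position, scale and orientation; centroid size
  CS = √Σᵢ‖xᵢ − x̄‖²; the thin-plate-spline *weight matrix* of partial-warp
  and uniform-component scores (2k − 4 variables for k landmarks, so 54
  for a 29-landmark skull); relative warps (PCA of the weight matrix).
- **Group structure** — MANOVA (Pillai's trace) on selected relative
  warps, two-way ANOVA on lnCS, pairwise species tests.
- **Allometry** — multivariate regression of shape on lnCS with
  permutation inference, pooled within-group regression, and a
  Goodall-style interaction test for slope heterogeneity among species
  (residual randomization, default 9999 permutations).
- **Covariation with environment** — two-block partial least squares
  (singular warps) between shape (or lnCS) and 19 bioclimatic variables
  or a 3-column competition block; per-dimension permutation tests and
  variable loadings.
- **Competition scoring** — for each focal specimen, the fraction of
  co-occurring canids sharing its diet, sharing its habitat, and falling
  inside the interspecific-killing window of the body-size-difference
  index BSD = (Mbₗ − Mbₛ)/Mbₗ.
- **Variation partitioning** — pure and shared adjusted-R² components of
  shape or size variance across taxonomy / size / climate / competition
  blocks (redundancy analysis with the Ezekiel adjustment, components by
  inclusion–exclusion), globally and within genera.
- **Phylogenetic comparative tools** — squared-change-parsimony ancestral
  states, a tip-permutation test for phylogenetic signal ("tree length"),
  and Felsenstein's independent contrasts.
- **Synthetic studies** — a generator that plants known allometric,
  climatic, competitive and phylogenetic effects in a fully specified
  study (TPS landmarks, climate table, assemblages, traits, tree), so
  every stage has a recoverable ground truth.

## Worked example

```python
import numpy as np
from ecomorph import (StudyParams, generate_study, gpa, weight_matrix,
                      relative_warps, select_rws, multivariate_regression,
                      pls, vector_angle, competition_profile)
from ecomorph.pls import BIOCLIM_NAMES

study = generate_study(StudyParams(n_species=4, n_landmarks=10,
                                   n_localities=40,
                                   sample_sizes=(30, 30, 30, 30)), seed=42)
sample = gpa(study.specimens)
wm = weight_matrix(sample)
rw = relative_warps(wm)
print(f"aligned {sample.n} specimens, {wm.scores.shape[1]} shape variables")
print(f"RW1 explains {rw.percent_variance[0]:.2f}% of shape variance; "
      f"{select_rws(rw, 95)} axes reach 95%")

reg = multivariate_regression(wm.scores, sample.lnCS, n_perm=999, seed=1)
print(f"allometry: {reg.percent_variance:.2f}% of shape variance, "
      f"P = {reg.permutation_p:.4f}")

bio = study.specimen_climate().to_numpy(float)
res = pls(wm.scores, bio, n_perm=999, seed=2, right_names=BIOCLIM_NAMES)
print(f"PLS shape~climate: SW1 carries {res.percent_covariation[0]:.2f}% "
      f"of covariation, r = {res.score_correlations[0]:.3f}, "
      f"P = {res.permutation_p[0]:.4f}")

comp = study.specimen_competition().to_numpy(float)
res_c = pls(wm.scores, comp, n_perm=999, seed=3)
ang = vector_angle(res.left_vectors[:, 0], res_c.left_vectors[:, 0])
print(f"climate vs competition shape vectors: "
      f"angle = {ang.angle_degrees:.3f} deg, P = {ang.p:.2e}")

prof = competition_profile("Cerdocyon thous",
                           {"Lycalopex gymnocercus", "Speothos venaticus"})
print(f"competition profile: diet {prof.diet_overlap}, "
      f"habitat {prof.habitat_overlap}, killing {prof.killing}")
```

Output:

```
aligned 120 specimens, 16 shape variables
RW1 explains 40.20% of shape variance; 11 axes reach 95%
allometry: 8.22% of shape variance, P = 0.0010
PLS shape~climate: SW1 carries 98.84% of covariation, r = 0.680, P = 0.0010
climate vs competition shape vectors: angle = 42.674 deg, P = 7.71e-04
competition profile: diet 0.5, habitat 0.5, killing 0.0
```

Reading the numbers: 10 landmarks give 2·10 − 4 = 16 shape variables.
Size explains ~8 % of shape variance because the generator plants a
within-species allometric vector. The first singular-warp pair
concentrates nearly all shape–climate covariation (the generated climate
is latitude-driven and strongly inter-correlated, as real bioclim data
are), and the climate and competition shape vectors point in
significantly similar directions (angle well below the 90° expected for
unrelated directions) because locality assemblages also track latitude.
The competition profile is the classic case of a crab-eating fox sharing
a locality with a pampas fox (same diet and habitat, too similar in mass
to be a killing threat) and a bush dog (different diet and habitat):
half the co-occurring species overlap on diet, half on habitat, none
qualify for interspecific killing.

## Command line

```bash
ecomorph simulate --seed 1 --out study/          # synthetic study files
ecomorph all --tps study/landmarks.tps --metadata study/metadata.csv \
    --climate study/climate.csv --traits study/traits.csv \
    --presence study/presence.csv --tree study/tree.nwk \
    --out results/ --seed 1
```

`ecomorph all` writes CSV tables for every stage (relative warps,
allometry by species, PLS loadings, pairwise species matrices, variation
partitioning components, phylogenetic-signal statistics) plus a run log
with the seed and stage timings.

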