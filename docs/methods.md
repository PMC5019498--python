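# Methods

`landrefugia` models how climatically determined landcover categories shift
under future climate scenarios and where they stay put (climatic refuges).
This note documents the model, its assumptions, the parameters that matter,
and the choices made where the design was genuinely open.

## The modelling chain

1. **Grid and inputs.** The analysis unit is a 0.5° lat/lon cell carrying a
   19-component bioclimatic vector (bio1–bio19 semantics: temperature-like
   and precipitation-like summaries), a native landcover label, and the
   fraction of the cell under anthropogenic cover. Real rasters can be
   supplied (ESRI ASCII grids, WGS84, cell-registered, north-up); the
   synthetic generator produces the same structures with known ground truth.
   Cells whose landcover is anthropogenic (urban, agriculture) are removed
   before modelling: their distributions respond to policy, not climate.

2. **Climatic partition.** A CART classification tree (landcover ~ climate,
   Gini criterion, one variable per binary split) groups cells into leaves —
   climatically homogeneous clusters, each predicting the landcover category
   that best characterizes it. Unlike k-means or UPGMA, the tree needs no
   a-priori cluster count; repeated k-fold cross-validation over the
   cost-complexity path (1-SE rule) sets the number of subdivisions. A
   bagged random forest (bootstrap rows, random variable subsets per split)
   checks the classification via out-of-bag accuracy, and a sensitivity
   analysis tests whether cells with >50 % anthropogenic cover degrade it:
   accuracies with and without those cells, plus the slope of a logistic
   regression of per-cell OOB correctness on anthropogenic fraction with a
   bootstrap percentile interval.

3. **Distribution models.** Each leaf becomes a "pseudo-species": presences
   are its cells, absences the sampled cells of other leaves (true absences —
   the full distribution of the modelling unit is known, unlike for real
   species). Predictors are the climate variables the tree actually used.
   Nine methods in three families produce per-cell suitabilities in [0, 1]:

   - *envelope/distance*: BIOCLIM percentile envelope (score
     `1 − 2·max_j |pct_j − ½|`, 0 outside the min–max box); Gower
     (range-normalized mean absolute distance to the nearest presence,
     DOMAIN-style); Mahalanobis (distance to the presence centroid under the
     ridge-stabilized presence covariance, mapped through the χ² survival
     function).
   - *statistical*: GLM (logistic, linear+quadratic terms); a GAM analogue
     (additive logistic on a per-variable cubic-spline basis, 5 knots, ridge
     strength by 3-fold CV); MARS (hinge basis grown greedily to 21 terms,
     pruned backward by GCV with Friedman penalty 3, refitted with a
     logistic link).
   - *machine learning*: a MaxEnt-like penalized logistic on hinge+quadratic
     features against the full sampled background (simplified analogue); a
     GARP-like small genetic algorithm over conjunctive per-variable
     interval rules with training TSS as fitness (simplified analogue);
     random forest (bagged CART, suitability = presence vote fraction).

   The MaxEnt and GARP analogues are intentionally lightweight stand-ins for
   the published desktop tools and are labelled as such; they never gate the
   statistical-family path used for projection.

4. **Sampling design.** 25 % of cells are drawn once as the modelling
   sample; each of 10 replicates splits it 75/25 into calibration and
   validation. Suitabilities are replicate-averaged and binarized at the
   mean calibration prevalence (present iff suitability ≥ threshold; the
   boundary is inclusive by documented convention). Family ensembles are
   means of member suitabilities weighted by internal-validation TSS
   (negative TSS clamps to weight 0).

5. **Validation and selection.** The 75 % of cells never sampled form the
   holdout. Per method and leaf: sensitivity, specificity,
   TSS (= sens + spec − 1) and rank-based AUC against the tree's leaf map.
   A method is adequate iff *all four* metrics exceed 0.7 on its *worst*
   leaf (strict >; a per-method-mean alternative is exposed). Cells where
   more than one leaf is predicted present are reported as prediction
   uncertainty (only one landcover can occupy a cell).

6. **Projection, aggregation, consensus.** Adequate models are projected
   onto future climate without refitting; thresholds and ensemble weights
   carry over from calibration. Leaf presences aggregate to categories by
   cellwise union; the three GCMs combine by unanimity AND (majority rule
   behind a flag). The statistical ensemble is the default projection
   family.

7. **Refugia.** A refuge cell keeps its category under both current climate
   and the future consensus (cellwise AND). Per category and RCP the report
   gives areas (spherical band formula, R = 6371 km), percentages of the
   modelled domain, area-weighted centroids, and centroid displacement
   (haversine km + initial bearing). An extirpated range yields an explicit
   sentinel, not a number. Regional accounting assigns each cell to the
   polygon containing its center (bias below one cell at borders; no
   clipping).

## The synthetic world

The generator emulates the structure of a continental-scale analysis at desk
scale, with every downstream stage checkable against the generating rules:

- **Domain**: 40×40 cells of 0.5° spanning 20°S–0°, 70°W–50°W.
- **Climate**: temperature-like variables follow latitudinal linear
  gradients (bio1 = 28 °C at the equator, −0.6 °C per degree south, i.e.
  0.3 °C per cell row), precipitation-like variables longitudinal gradients
  (bio12 = 3000 mm in the west falling to 1000 mm, 50 mm per cell column),
  plus i.i.d. Gaussian noise. Default noise SD is a quarter of each
  variable's per-degree gradient (half an inter-cell step): spatial
  structure dominates but cells are jittered in climate space. A config
  flag smooths the noise field (Gaussian filter) to add spatial
  autocorrelation.
- **Landcover**: five categories from nested first-match-wins threshold
  rules on bio1 (22 °C) and bio12 (2000 and 1400 mm): closed vegetation
  (warm-wet), open vegetation (warm-dry), mosaic (cool-wet), closed
  deciduous forest (cool-intermediate), sparse vegetation (cool-driest).
  Labels are evaluated on the *noisy* climate, so landcover is a
  deterministic function of the observed climate vector — label noise is
  positional, not climatic.
- **Scenarios**: three pseudo-GCMs differing in warming/drying magnitude
  (RCP 4.5: +1.0 to +1.4 °C, −120 to −180 mm; RCP 8.5 doubles both;
  baselines have zero shift). Future stacks reuse the baseline noise
  realization, so scenario differences are exactly the shift fields (the
  delta/anomaly construction used with real GCM output).
- **Anthropogenic cover**: disc hotspots with configurable intensity,
  combined by maximum, optional jitter, clipped to [0, 1]; the native label
  is retained beside the fraction.

What the generator does **not** emulate: real South American climatology or
landcover frequencies, topographic and edaphic controls, anisotropic or
temporally autocorrelated climate change, fragmented (non-convex) category
geometries, and observation error in the landcover map. Passing tests
demonstrate that the pipeline recovers distributions generated by
climate-threshold rules at this grid resolution — not that any particular
real-world projection is correct.

## Numerical choices and edge cases

- **Tree determinism**: split ties break toward the smallest variable index,
  then the smallest threshold; thresholds are midpoints between adjacent
  distinct values; modal-class ties break toward the smallest class index.
  Minimum splittable node: 20 cells (min leaf = 20/3, the rpart
  convention). Single-category or constant-predictor input yields a
  root-only tree, not an error.
- **Pruning**: weakest-link cost-complexity path; CV evaluates the
  geometric-midpoint alpha of each subtree interval; relative error is
  scaled by the root (majority-class) risk; default 200 repetitions of
  10-fold CV (the estimand is identical at higher repetition counts, which
  remain available in config).
- **GAM ridge by accuracy, not log-loss**: downstream use is a prevalence
  threshold, so boundary placement matters and calibration of extreme
  probabilities does not; log-loss CV punished confident near-boundary
  errors so hard it chose heavily smoothed (range-inflating) envelopes.
- **Mahalanobis ridge**: covariance gets `ridge·tr(Σ)/p` added to the
  diagonal (default 1e-8); a still-singular covariance raises rather than
  silently pseudo-inverting.
- **Prevalence threshold** uses ≥ (documented; the boundary case is tested).
- **TSS weights** below 0 clamp to 0; an all-zero-weight ensemble is an
  error, not an empty map.
- **Consensus** is strict unanimity by default; "majority" is available.
- **Centroids** are area-weighted (a cell at 20°S is ~6 % smaller than at
  the equator; unweighted centroids would bias poleward). Domains are
  assumed far from the antimeridian.
- **Empty predicted ranges** are allowed and logged at binarization;
  extirpation propagates through centroid/displacement as a sentinel.

## Problem sizes

Defaults were chosen so a complete run (three GCMs, nine methods plus
ensembles, 10 replicates, 200 CV repetitions, 500-tree forest check) finishes
in minutes on one core: 1600 cells, ~5 leaves per GCM, ~1350 model fits.
All sizes are configuration, not code: the published-scale design (12 method
slots × 10 replicates × 38 leaves = 4560 fits, 456 averaged distributions)
is reproduced exactly by the job registry, and CV repetition counts in the
thousands are a config change.

## Known limitations

- The leaf partition is axis-aligned by construction (CART); real
  vegetation–climate boundaries that are oblique in climate space would be
  staircase-approximated.
- Prevalence thresholding of smooth suitabilities systematically inflates
  predicted ranges by a fraction of a cell around the true boundary; after
  the unanimity consensus this is the dominant error term for small
  categories.
- The GAM analogue's 5-knot basis bounds how sharp an envelope edge it can
  represent; MARS is consistently the sharpest statistical member.
- True absences are exact here because the synthetic distribution is known;
  with real data the "known distribution" premise inherits whatever error
  the landcover map and majority upscaling introduce (the anthropogenic
  sensitivity analysis quantifies one slice of that).
- The GARP/MaxEnt analogues are structural stand-ins; their scores should
  not be compared against published desktop-tool outputs.
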