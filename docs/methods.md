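# Methods

`rosaeval` implements two computational arms of fragrant-rose germplasm
research: a multi-criteria evaluation of accessions with the analytic
hierarchy process (AHP), and a stage-wise volatile-metabolomics analysis
(PCA, OPLS-DA with VIP, fold-change screening, trend clustering, pathway
over-representation). Because the underlying field and GC-MS raw data are
not publicly deposited, the package ships a synthetic-data generator that
emulates every input with the statistical structure the analysis assumes.
This note records the models, the defaults and why, the numerical choices,
and what the tests do and do not establish.

## AHP evaluation

**Model.** Experts compare evaluation characters pairwise on Saaty's 1–9
scale, producing positive reciprocal judgment matrices (`a_ii = 1`,
`a_ji = 1/a_ij`). Expert matrices are combined by the element-wise
geometric mean — the only aggregation that preserves reciprocity. Priority
weights are the principal right eigenvector of the combined matrix
(power iteration, convergence tolerance 1e-10, at most 10⁴ iterations),
normalized to sum to 1; normalized row geometric means are available as a
cross-check and coincide with the eigenvector exactly on consistent
matrices. Consistency is screened with `CI = (λmax − n)/(n − 1)` and
`CR = CI/RI(n)` using Saaty's random-index table (tabulated to n = 9);
`CR < 0.1` (strict) passes, and orders 1–2 pass by construction. For
reciprocal matrices `λmax ≥ n` with equality iff the matrix is consistent,
so `CI ≥ 0` always.

**Composition and grading.** The hierarchy is goal → criteria → index
leaves; a leaf's global weight is its local weight times its criterion's
weight, so global weights sum to 1. Field measurements are mapped to
integer band scores through a scoring standard (half-open bands
`[lo, hi)`, last band closed above so the declared range is covered
exactly once), and the final score is the global-weight-weighted sum.
Grades use fixed cutoffs: I ≥ 3.6 > II ≥ 3.1 > III ≥ 2.7 > IV, with each
band half-open below the next cutoff; the boundary convention matters only
for scores exactly at a cutoff and is asserted in tests.

The bundled example hierarchy carries the three published criterion
weights (quality 0.6370, vigor 0.2583, harvestability 0.1047) and the
published local weight 0.0645 of index F1, whose composed global weight is
0.0645 × 0.6370 = 0.0411. All other local weights are filled uniformly:
the underlying expert matrices are not published, so the example is a
template, not a reconstruction.

## Volatile-survey chemometrics

**Scaling and PCA.** Columns (compounds) are unit-variance scaled with the
sample sd (n − 1); zero-variance columns are flagged and zeroed rather
than divided by zero. PCA is computed by SVD of the centered matrix; the
contribution rate of component *a* is `100·λ_a/Σλ`, and rates over all
`min(n − 1, p)` components sum to 100%. The pooled-QC construction (the
mean of all samples) projects to the origin of the score space by
centering, which is the property QC mixes are meant to display.

**OPLS-DA.** The class label is coded −1/+1 and centered (PLS1). For each
orthogonal component: `w ∝ X'y` (unit norm), `t = Xw`, `p = X't/(t't)`,
`w_o ∝ p − (w'p/w'w)w` (unit norm), `t_o = Xw_o`, `p_o = X't_o/(t_o't_o)`,
and `X ← X − t_o p_o'`. One predictive component is then fitted on the
filtered matrix. `t` is orthogonal to every `t_o` by construction, and
with `n_orth = 0` the model is exactly the first PLS1 component (verified
against scikit-learn's PLS in tests). The default `n_orth = 1` is the
customary choice for two-group GC-MS panels with few replicates; no
cross-validated component selection is performed. If no orthogonal
variation remains (deflated weight vector numerically zero), extraction
stops early rather than fabricating a component.

**VIP.** By default VIP is computed on the predictive component only,
`VIP_j = √p · |w_j| / ‖w‖`, since that component carries the class
separation; `Σ_j VIP_j² = p` holds exactly (mean squared VIP is 1). A
`total` variant also weighs orthogonal weight vectors by their explained
X variation; the normalization identity is preserved because the weight
vectors have unit norm and the mixture weights are convex.

**S-plot.** Per variable, `p1 = cov(t, x_j)` and `pcorr1 = corr(t, x_j)`
(sample moments). Zero-variance variables get `pcorr1 = 0` with a
degeneracy flag. Covariance and correlation share signs wherever both are
nonzero.

**Fold change and the screen.** FC is the ratio of stage-mean
concentrations, oriented later/earlier. Undetected compounds are true
zeros (not missing); a zero group mean is replaced by half the smallest
positive group mean in the comparison, which keeps FC finite without
inventing detections, and compounds with both means zero are excluded as
undefined. A compound is differential when `VIP > 1` and `FC ≥ 2` (up) or
`FC ≤ 0.5` (down). Comparisons are the consecutive-stage pairs of each
cultivar (nine for three cultivars over four stages), and the total
differential set is the union of compound names over the comparisons.

## Clustering

Accession tables are clustered on Euclidean distances with Ward's
minimum-variance method via SciPy, using the Ward.D2 convention (merge
height = √(2·ΔSSE)); the merge sequence is verified in tests against an
exhaustive oracle that evaluates every candidate merge's exact increase in
within-cluster sum of squares for n ≤ 7. Mixed trait tables are
standardized before distances: continuous and ordinal characters are
z-scored, binary characters stay on their 0/1 scale — a pragmatic
convention, since no standardization is canonical for mixed phenotypes.

Trend classification standardizes each compound's four-stage mean profile
(z-score across stages; constant profiles become zero rows) and runs
K-means (Lloyd, best of 50 seeded restarts by SSE; deterministic given the
seed). The default k = 9 mirrors the nine trend shapes distinguishable
over four stages (rises, falls, single-stage peaks, plateaus, a valley);
it is a display convention, not an estimate, and is a config parameter.

## Enrichment

Over-representation uses the one-sided hypergeometric test — the standard
ORA for metabolite sets — through SciPy's log-gamma-based survival
function, verified against brute-force enumeration for all universes
N ≤ 12. The background is the set of compounds detected in the experiment
(detection-conditioned inference), not a full pathway database.
Benjamini–Hochberg FDR values are reported alongside raw p-values. The
bundled annotation map is a small curated table covering the monoterpenoid,
sesquiterpene/triterpene, terpenoid-backbone, phenylpropanoid and
aromatic-amino-acid routes; it is illustrative, not a database mirror. A
per-pathway trend report gives each member compound's standardized stage
profile and stage of maximum content per cultivar.

## Retention-index helper

`kovats_ri` implements the linear (temperature-programmed) convention:
`RI = 100n + 100(n′ − n)(rt − rt_n)/(rt_{n′} − rt_n)` over the bracketing
n-alkanes. Only the linear variant is provided; the isothermal logarithmic
variant is out of scope, and retention times outside the ladder span are
a range error rather than extrapolated.

## Synthetic-data generator

All generators are pure functions of (design, seed); a global seed feeds a
`SeedSequence` and each generator draws from its own spawned stream, so
the trait table is unchanged when only the panel model changes.

* **Germplasm collection** — default 27 rugosa + 43 hybrida + 7 species
  accessions. Continuous characters are group-conditional Gaussians
  truncated at 0, binary characters Bernoulli, ordinal characters
  categorical; defaults encode the field contrasts (hybrids: more and
  larger petals, longer pedicels; rugosa: thornier, shorter internodes).
* **Targeted panel** — 16 fragrance compounds; contents are zero-inflated
  log-normal (log-sd 0.5; zero probability 0.05/0.30/0.15 for
  rugosa/hybrida/species). The rugosa marginal means (zeros included) are
  anchored at the reported cohort values — phenethyl alcohol 11.76 µg/g,
  citronellol 3.76, nerol 1.77, farnesol 1.27 — with the remaining
  compounds at 0.5 µg/g; hybrida contents are scaled to one quarter and
  species to one half, reflecting rugosa's richer scent profile.
* **Volatile survey** — concentration = base × cultivar scale × stage
  archetype × planted effect × log-normal noise. Base levels are
  log-uniform over 1e3–1e6 µg/L (volatile panels span orders of
  magnitude, hence multiplicative noise); the default replicate noise sd
  is 0.1 on the log scale (≈10% CV, a typical GC-MS replicate precision);
  nine multiplicative stage archetypes (gradual rise/fall, steps,
  single-stage spikes, a plateau and a valley) are assigned at random,
  with a 10% flat fraction so that, as in real surveys, not every
  compound is differential. Planted effects multiply the later stage of a
  stated pair by the effect size (or its reciprocal for down-effects).
* **Expert panel** — `a_ij = (w_i/w_j)·exp(δ)`, `δ ~ N(0, σ²)` on the
  upper triangle, reciprocals below, so matrices are exactly reciprocal;
  σ = 0 yields consistent matrices that return the true weights to
  machine precision. Entries are not snapped to the discrete 1–9 scale by
  default because snapping floors the recovery error at small σ; an
  optional flag enables it.

**Calibration (verified by the test suite and the acceptance script).**
With a planted 4× effect (stage 3 vs 1, noise sd 0.1, 3 replicates) the
empirical FC lies in [2, 8] in ≥ 95% of 500 seeds and the screen flags the
compound "up" in ≥ 90% of 200 seeds with ≤ 10% false positives among null
compounds; σ = 0.05 judgment perturbation on 6 items gives mean absolute
weight error < 0.02 over 100 seeds with CR < 0.1 in ≥ 95%; the nine
archetypes are recovered by K-means at mean ARI ≥ 0.9 over 50 seeds.
Observed margins are wide (detection and ARI near 1.0, false positives
near 0).

**What the generator does not emulate:** compound–compound covariance,
retention-time drift and peak-shape artefacts, between-cultivar archetype
differences, and the discrete response styles of real experts. Passing
tests therefore demonstrate that the pipeline's statistics behave as
designed under their stated assumptions — not that any specific biological
conclusion about real cultivars is reproduced.

## Problem sizes

The default study sizes are the collection's (77 accessions, 16 panel
compounds, 3 cultivars × 4 stages × 3 replicates × 174 compounds). The
Monte-Carlo suites use 40 compounds (screening power) and 90 compounds
(trend recovery) per seed — large enough for stable rates while keeping
repeated fits cheap — with seed counts as stated above.

## Known limitations

* The published evaluation uses an unpublished scoring standard and expert
  matrices; scores and grades from the bundled example hierarchy are
  illustrative.
* VIP thresholds (`VIP > 1`) and FC gates are conventions, not error-rate
  guarantees; no permutation validation (Q², CV-ANOVA) is performed.
* Compound names are matched as strings; no identifier mapping to KEGG or
  PubChem is attempted.
* The consistency random-index table covers orders up to 9; larger
  matrices must be decomposed into sub-hierarchies.
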