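# Methods

`soildriver` implements a driver-attribution analysis for continental-scale
soil monitoring data: given per-site pesticide residue concentrations, soil
and climate covariates, an ecosystem-type factor and a set of soil
biodiversity metrics, it asks how much of the variation in each metric is
attributable to pesticides as opposed to environmental drivers, which
individual residues matter, and in which direction.

## The model

Each biodiversity metric `y` (richness, Shannon diversity, the
multidiversity index, functional-group relative abundance in %, or
functional-gene diversity in pmOG) is modelled with a Gaussian GLM with a
log link:

    E[y | X] = exp(b0 + sum_j b_j x_j),    y ~ Normal(mu, sigma^2)

The log link encodes a multiplicative mean structure while keeping additive
Gaussian errors on the response scale, which tolerates zero-valued
observations (the link applies to the mean, not to `y`); no offset is added
to zero responses by default.  One model family is used for every metric,
untransformed.

Model performance is summarized by r² (the squared Pearson correlation of
predicted vs observed values), MAE, MSE and RMSE.  AIC is computed as
`-2 logLik + 2 (p + 1)` with `sigma^2 = RSS/n`, counting the dispersion
parameter alongside the `p` regression coefficients — the convention used by
classical stepwise-GLM software, which matters for reproducible selection
paths.

## Two-stage scope-constrained selection

Pesticides can be collinear with the environments in which they are applied.
To prevent a residue from being selected merely because it tracks favourable
environmental conditions, selection proceeds in two stages:

1. **Environment stage.** Bidirectional AIC stepwise selection (additions
   and deletions, the move with the largest AIC decrease accepted, stopping
   when no move lowers AIC) over soil properties, climate variables and the
   ecosystem factor, starting from the intercept-only model (configurable to
   a full-model start).
2. **Pesticide stage.** A second stepwise run whose lower scope pins every
   stage-1 retained term into the model, and whose upper scope adds the
   candidate pesticide concentrations: a residue enters only if it lowers
   the AIC of the environmental model.

AIC ties between candidate moves are broken by preferring deletion over
addition, then lexicographic term name, making the selected set a
deterministic function of the data.  Candidate fits that fail to converge
are skipped with a warning, never silently accepted.  The ecosystem factor
is a single term expanded to reference-coded dummies; candidates are main
effects only.

Before stage 2, pesticide columns pass a near-zero-variance screen: a column
is dropped when the frequency ratio of its most common to second most common
value exceeds 95/5 = 19 **and** the percentage of distinct values among
sites is below 5% (constant columns always drop).  The two rules jointly
define a degenerate predictor; requiring both is essential for zero-inflated
continuous concentrations, where the most common value is always 0 and every
detected value is unique, so the ratio rule alone would remove everything.

## Attribution

**Variable importance.**  Each retained term is ranked by `|t| = |coef/SE|`,
annotated with the coefficient's sign; factor terms take the maximum
component `|t|` (a single rank per driver is needed for network-style
displays).

**Variation partitioning.**  The final model's terms are split by driver
group (pesticides, soil, climate, ecosystem; at most 4).  One GLM is fitted
per non-empty subset of groups — the union of their selected terms, with no
re-selection — and its r² recorded.  Treating each subset r² as the measure
of the union of the groups' "explained-variance regions", the exclusive
Venn-region fractions are recovered by inclusion–exclusion (intersection
measures from union measures, then Möbius inversion over the superset
lattice).  Unique fractions satisfy `unique(g) = r²(full) − r²(full − g)`
by construction; residual = `1 − r²(full)`; all regions plus the residual
sum to 1 to machine precision.  Two deliberate conventions: r² is the
squared predicted–observed correlation (not adjusted R² as in classical
`varpart`), and negative shared fractions are passed through unclipped —
they are diagnostic of suppressor structure, not errors.  Groups with no
selected terms contribute exactly 0 rather than being refit.

**Dual scope.**  The whole analysis runs on cropland sites only (annual +
permanent croplands) and on all ecosystems, with scope subsetting applied
*before* the near-zero-variance filter and any standardization, so each
scope legitimately retains its own pesticide set.

## Biodiversity metrics

- **SRS normalization**: counts are scaled to a common depth `c_min`
  (default: the minimum library size in the table), integer parts kept, and
  the remaining deficit distributed one unit each to taxa ranked by
  descending fractional part; ties break by descending original abundance,
  then stable input order (a seed switches to randomized tie-breaking).
  The deterministic default makes tests exact.  Every normalized site total
  equals `c_min` exactly.
- **Richness / Shannon**: taxa with positive counts; `−Σ p ln p` in nats
  (the base is a convention; nats are used throughout).  Computed on
  normalized counts by default, raw counts optionally.
- **Multidiversity**: the mean of per-group min–max standardized richness
  (`z_g ∈ [0,1]`) over the six organism groups (archaea, bacteria, fungi,
  protists, nematodes, arthropods).  Standardization is over the analyzed
  site set, recomputed per analysis scope.  A zero-range group contributes
  a constant 0.5, keeping the 1/6 weighting meaningful.
- **Functional-group relative abundance**: assigned-group reads over total
  reads × 100; unassigned taxa count in the denominator only.
- **pmOG**: orthologous gene groups per million functionally annotated
  reads, `og / reads × 1e6`.

## Pesticide preparation and risk

Concentrations strictly below their LOQ are set to exactly 0 (values equal
to the LOQ are retained); detection means concentration > 0.  pH is
negatively exponentially transformed (`exp(−pH)`) and electrical
conductivity log-transformed before modelling.  Risk quotients are
`conc / NOEC_min × 5` (assessment factor 5, regulatory convention);
pesticides without a reported NOEC_min are excluded from the cumulative sums
and listed in the run log.  Cumulative risk per site sums the quotients,
overall and per pesticide type (fungicide / herbicide / insecticide).

## Complementary statistics

For each pesticide retained in a final model, the environmental variables
selected in the same model are compared between presence and absence sites
with a Kruskal–Wallis test (the two-group case is the Wilcoxon rank-sum;
asymptotic chi-square p-values with tie correction; raw and BH-adjusted p
reported side by side, since whether the original analyses adjusted is
unstated).  Biodiversity metrics are screened against aggregated pesticide
metrics (detection counts per type, cumulative risks) with Spearman
correlations, BH-adjusted across the screen.  Per-site residue counts are
compared between all ecosystem pairs with two-sided rank-sum tests,
BH-adjusted, and summarized by a compact letter display (groups share a
letter iff their adjusted difference is not significant at α = 0.05).

## Synthetic data generator

No public generative model exists for these data, so the generator uses the
simplest structures matching their description:

- **Concentrations**: per pesticide and site, detected with probability
  `detect_prob` (default 0.3), detected values lognormal (median
  ~0.01 mg/kg, log-sd 1), then censored below the LOQ (default 0.001 mg/kg,
  the lower end of the reported 0.001–0.025 range).  One near-constant
  "rare" column (~2% detection, constant value) is always planted to give
  the near-zero-variance filter something to remove.
- **Environment**: 11 soil + 7 climate covariates from independent
  multivariate normal blocks with exchangeable within-block correlation
  (default 0.3); pH centred at 6.5, conductivity lognormal (strictly
  positive); a 5-level ecosystem factor with default proportions
  210/34/19/97/13 of 373, mirroring the emulated monitoring design.
- **Counts**: per organism group, a Dirichlet taxon profile
  (concentration 0.5, 150 taxa) and per-site multinomial draws with library
  sizes uniform on [5 000, 50 000]; gene summaries with known OG counts and
  read totals.
- **Responses**: `y = exp(b0 + Σ_g s_g z_g) + N(0, noise_sd²)` with `z_g`
  the unit-variance signal of driver group g (default two true predictors
  per group), `b0 = ln(100)` and `noise_sd = 5` by default.  The per-group
  scales `s_g` are calibrated so each group's *unique* explained-variance
  fraction matches the requested `group_r2`: a closed-form linear-
  approximation start followed by a deterministic fixed-point refinement
  against the realized design (analytic r² under a log link is
  intractable), converging to within 1e-3 on the expected-mean surface and
  raising a calibration error otherwise.  An `orthogonalize` switch
  Gram-Schmidt-orthogonalizes the true-predictor columns so unique fractions
  are unambiguous ground truth.
- A single global seed; all sub-generators derive child streams
  deterministically, so identical configs give bit-identical datasets.

What the generator does **not** emulate: spatial autocorrelation and maps,
pesticide co-application (mixture) dependence beyond optional correlation,
raw sequence reads, taxonomic structure, and real LOQ heterogeneity across
compounds (one LOQ per run by default, per-pesticide LOQs supported in the
catalog).  Passing tests therefore demonstrate the statistical machinery is
correct and well-calibrated under the stated generative assumptions — not
that real soil communities behave this way.

## Numerical choices and problem sizes

IRLS with at most 100 iterations and deviance tolerance 1e-8; failed fits
retry from OLS-on-log starting values before being flagged.  Exact
collinearity reports infinite (G)VIF and flags the model.  Partition
identities hold to 1e-10 by construction and are verified against a direct
linear-system solve of the Venn system.  Simulation studies in the test
suite and acceptance script use n = 200–300 sites with 50–100 replicates
and n = 5000 for asymptotic checks — sizes at which the Monte-Carlo error
of the checked quantities is well inside the stated tolerances.

## Known limitations

- Gaussian errors on the response scale can produce negative fitted-scale
  draws for strongly right-skewed metrics; the defaults keep the
  coefficient-of-variation small enough that this is rare.
- AIC stepwise admits noise terms at the known ~16% per-candidate rate;
  selected sets are supersets of the strong true predictors far more often
  than exact matches.  Downstream attribution is robust to this because
  extra terms carry near-zero unique variance.
- Variation-partitioning fractions based on squared correlations are not
  variance components; shared fractions can be negative and the
  decomposition is exact only as an accounting identity.
- No spatial structure: residual spatial autocorrelation testing is out of
  scope.
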