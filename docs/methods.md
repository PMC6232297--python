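# Methods

## Scope and data model

The package analyses a monthly two-reservoir survey design: an OTU count
table (samples × OTUs, nonnegative integers) with per-sample design metadata
(reservoir, site, month), an environmental table (samples × variables, real,
missing allowed), and an optional taxonomy map. Analyses are run per
reservoir block; samples present in only one of the two tables are dropped by
id intersection and the drops are reported, because published distance-based
model tables for such surveys often imply fewer samples than were collected
(a residual df of 21 for a single predictor implies n = 23 of 24 samples).

Two relative-abundance views feed the two halves of the pipeline:

* the **resemblance suite** uses square-root-transformed relative abundances
  of the *full* community (Bray–Curtis) and z-scored environmental variables
  (Euclidean);
* the **network suite** uses *unaltered* relative abundances of the abundant
  OTU subset: observed in at least max(5, ⌈0.2·n⌉) samples *and* reaching
  ≥1% in at least one sample. Both prevalence clauses are enforced via the
  max because they coincide only for n = 24. The filter is idempotent and
  never rescales retained values.

Diversity indices are computed on counts (optionally rarefied first —
rarefaction is exact multivariate-hypergeometric subsampling) because N
appears in Margalef's (S−1)/ln N. Whether resemblance analyses run on
rarefied or raw counts is the caller's choice; the default is un-rarefied.

## Resemblance statistics

Bray–Curtis is reported as PRIMER-style similarity on the 0–100 scale
(diagonal 100) and converted to dissimilarity internally. Euclidean distance
on environmental data handles missing values per pair with the classic
rescaling d = √(Σ_used diff² · k_total/k_used); a pair with no shared
observed variable is an error, not a guess.

nMDS minimizes Kruskal stress-1 by alternating isotonic regression of
configuration distances on the dissimilarity order with Guttman transforms;
one start comes from classical metric scaling, the rest (default 50; the
pipeline uses 20) are random, and the best configuration wins. Stress is
reported; metric triples embed exactly (stress 0).

PERMANOVA is the one-way pseudo-F from distance-partitioned sums of squares
(SS_total = Σ_{i<j} d²/n, SS_within summed per group); on Euclidean
distances of univariate data it reproduces the classical ANOVA F exactly,
which the suite tests property-style. ANOSIM uses
R = (mean between-group rank − mean within-group rank)/(M/2). Both use the
(count+1)/(n_perm+1) permutation convention with 9,999 permutations by
default; an enumeration mode computes exact p over all n! label
permutations for small fixtures. SIMPER averages per-OTU contributions
100·|x−y|/Σ(x+y) over all between-group pairs.

DistLM marginal tests Gower-centre the squared distances (G = −½JD²J) and
report SS = tr(HGH) for the centred single-predictor hat matrix,
pseudo-F = SS/((SS_total−SS)/(n−2)), proportion explained, and a permutation
p from permuting the raw predictor values (samples missing the tested
variable are dropped for that row, with the effective n recorded). A
perfectly fitting predictor reports F = ∞ rather than failing. The
`pseudo_f_from_prop` identity F = prop·df_res/(1−prop) audits printed tables
for internal consistency. Forward selection adds, at each step, the
candidate with the largest conditional SS if its permutation entry test
passes α = 0.05 (complete-case across variables); published step-wise
procedures do not state their entry criterion, so this simplest defensible
scheme is flagged in reports. RELATE is the Spearman correlation of the two
upper triangles with simultaneous row/column permutations; BEST/BIOENV
exhaustively searches subsets (feasible for ≤15 variables) of the z-scored
environmental table.

## Correlation networks

All unordered pairs over the pooled abundant-OTU + environmental variable
set are tested with Pearson r over pairwise-complete samples; p-values come
from t = r√(n−2)/√(1−r²) on n−2 df. Pairs with fewer than 5 complete samples
or a constant member are emitted with missing r and excluded from FDR.
Benjamini–Hochberg is the standard step-up (q_(i) = min_{j≥i} p_(j)·m/j);
significance is q < 0.05, combining the "p < 0.05" and "FDR below 5%"
conventions into one coherent criterion, with a raw-p mode behind a flag
(reports carry both counts, since published edge totals are ambiguous about
which rule produced them). Env–env and OTU–env pairs are first-class edges:
published module compositions contain multiple environmental nodes.

Positive significant correlations form the co-occurrence graph, negative
ones the co-exclusion graph; each graph keeps only incident nodes, and
significant = positive + negative edges holds by construction. Modules come
from Louvain greedy modularity maximization on |r| weights (seeded,
relabelled by decreasing size); Q is the weighted Newman modularity
Σ_c[W_c/W − (S_c/2W)²] and is verified against exhaustive partition search
on small two-clique fixtures. Betweenness is unnormalized shortest-path
betweenness on unweighted edges (a weighted mode exists behind a flag),
verified against a brute-force path-enumeration oracle. Network drawings of
this kind are usually described as circular layouts produced by a
force-directed algorithm — two different things — so the layout here is a
deterministic circular initialization refined by classic FR forces
(attraction d²/k, repulsion k²/d, linear cooling); it affects only
visualization, never statistics. Module percentages are rounded half-up to
two decimals, matching the style of published module tables (1/70 → 1.43%).

## Synthetic data

The generator emulates the survey design: n_reservoirs × n_sites × n_months
samples, 200 OTUs, 15 named environmental variables, mean sequencing depth
60,000 (per-sample depth Poisson, counts multinomial at the latent relative
abundances — the compositional mechanism the relative-abundance transform
assumes). Latent OTU abundances are lognormal: mean log abundance decays
linearly in rank (slope 0.05, giving a realistic rank-abundance curve in
which roughly 45–55 of 200 OTUs pass the 1% filter, matching the 58/85
abundant OTUs of the motivating survey) with log-SD 0.5 month-to-month
variability. Environmental variables are a sinusoidal seasonal driver
(amplitude 1, one phase per variable, period = the year) plus unit-variance
noise.

Dependence is a Gaussian copula across all OTU and environmental latents.
A planted edge's `target_r` is the Pearson correlation on the *latent
abundance* scale: the copula correlation is found by inverting the
bivariate-lognormal correlation map for OTU–OTU pairs, the
lognormal–normal map for OTU–env pairs, and by compensating environmental
variables for the variance their seasonal component adds. Targets outside
the achievable range — notably strong negative correlations between
lognormal abundances, which are bounded below by −1/(e^{σ²}−1) ≈ −0.78 at
σ = 0.5 — and planted sets whose implied matrix is not positive
semidefinite are rejected with an explicit error. Ground truth records each
planted edge's realized correlation on the latent values; identical config
and seed give byte-identical output.

What the generator does **not** emulate: phylogenetic or taxonomic
correlation structure, zero-inflation beyond what multinomial sampling
produces, seasonal structure in the OTUs themselves (seasonality enters only
through environmental variables, so ordination separation by season is not
expected of default synthetic data), sequencing error or chimeras. Passing
recovery tests therefore demonstrate the statistical machinery, not
robustness to those real-data features.

## Benchmarks

`reservoirnet.benchmarks` fixes two standing Monte-Carlo experiments, both
with seasonality disabled so the complement of the planted edges is a true
null (with seasonality on, env–env pairs sharing the sinusoid are genuinely
correlated and would be counted as false discoveries despite being correct
detections):

* **recovery** — 20 disjoint pairs planted at r = +0.8 among the 40 most
  abundant OTUs, one 24-sample reservoir block, 50 replicates through the
  full filter → Pearson → BH → network pipeline. Pairs are planted among
  reliably abundant OTUs because the tested-pair universe of the motivating
  survey is by construction the abundant filtered set; planting on OTUs the
  1% filter removes would measure the filter, not the detector. The target
  is positive because abundance-scale −0.8 is infeasible for lognormal
  abundances at σ = 0.5; co-exclusion recovery and sign accuracy are
  exercised separately at feasible negative targets (−0.7).
* **global null** — the same pipeline with nothing planted, measuring the
  raw p < 0.05 fraction (calibrated at 5%) and BH discovery counts.

Problem sizes throughout the suite (replicate counts, permutation counts in
tests, the 60-OTU null configuration) are chosen so the full suite runs in
well under a minute of the typical budget while keeping Monte-Carlo standard
errors small relative to the tested margins.

## Numerical conventions

All permutation p-values are seed-reproducible; every pipeline stage derives
its seed from one root seed by hashing the stage name. Floating output is
written with ≥6 significant digits; module percentages use decimal half-up
rounding; ties in BH use stable sorting; nMDS convergence tolerance is 1e-9
on stress; degenerate inputs (zero-total samples, constant variables,
all-zero sample pairs under Bray–Curtis, empty graphs) raise errors naming
the offender rather than propagating NaNs. The abundance filter warns (not
errors) when nothing passes, since an empty network is a legitimate result.
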