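# Methods

This note documents the models implemented in `hubwire`, the conventions
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Connectome topology

**Group connectome.** Edges are retained if present in at least a fraction
`consistency_min` (default 0.30) of subjects *and* ranked among the top
`round(τ · n(n−1)/2)` pairs by the cross-subject weight statistic (median
by default, computed over the subjects in which the edge is present).
Ties at the density boundary are broken by higher consistency, then lower
node-index pair, so output is deterministic. If the consistency filter
leaves fewer candidates than the density target, the function warns and
reports the achieved density rather than failing. Node degree — and hence
hub status — is always computed on the binary mask of the streamline-count
channel; the FA-like channel supplies edge weights for weight-based
analyses.

**Rich club.** φ(k) is the density of the subgraph of nodes with degree
strictly greater than k; it is undefined (NaN, not an exception) when
fewer than two nodes qualify, and curves carry those markers through. The
weighted coefficient divides the subgraph weight sum by the sum of the
equally many strongest weights anywhere in the network, so φʷ ∈ (0, 1].
Binary nulls rewire each edge 50 times on average via uniform double-edge
swaps that reject self-loops and duplicates (degree sequence preserved
exactly); weighted nulls permute the weight multiset on the fixed binary
topology, separating weight organization from wiring. Permutation
p-values use the add-one rule p = (1 + #{φ_rand ≥ φ})/(1 + n_null) and so
never reach zero. The default k grid runs over every integer from the
minimum to one below the maximum degree.

**Communicability** is the matrix exponential of the binary mask, or of
S^{−1/2} W S^{−1/2} for weights with S = diag(node strengths). Isolated
nodes in weighted mode keep only their identity contribution and trigger a
warning. `scipy.linalg.expm` does the work; tests pin the result to the
truncated path-count series Σ Aˡ/l! and to eigendecomposition closed
forms.

**Link-type curves.** At each k, edges are partitioned by the hub status
of their endpoints, and each class is compared against all remaining edges
with a one-sided Welch t-test (class mean greater). Classes with fewer
than two finite values are recorded with NaN statistics. Flags are
uncorrected p < 0.05 per k; no multiplicity correction is applied across
the k grid — the curves are read for their consistent ordering across k,
not as a family of independent tests, and this is a documented limitation.
When both samples are exactly constant the test is degenerate and reported
as t = 0, p = 0.5 (equal constants) or ±∞, p ∈ {0, 1}.

## Twin heritability

Phenotypic variance at each edge is decomposed into additive genetic (A),
twin non-specific common environmental (C), twin-specific common
environmental (T), and unique environmental (E) components. Families
contribute independent multivariate-normal likelihoods with covariance
(per unit variance) a²+c²+t²+e² on the diagonal, a²+c²+t² between MZ
co-twins, 0.5a²+c²+t² between DZ co-twins, and 0.5a²+c² between any twin
and the non-twin sibling.

Numerical choices:

* Nonnegativity is enforced by squared-path parameterization — the
  optimizer searches unconstrained path coefficients whose squares are the
  variances — so no boundary-constrained optimizer is needed and variance
  estimates are never negative.
* Age and sex enter the mean model as fixed effects (one global β per
  edge, raw units) and are profiled out by generalized least squares at
  every likelihood evaluation, leaving at most four free parameters for
  the quasi-Newton (L-BFGS-B) search; per-family-structure sufficient
  statistics (XX, XY, YY tensors) make each evaluation O(1) in the number
  of families. Closed-form 2×2/3×3 inverses avoid LAPACK overhead.
* Fits use one moment-informed start (Falconer-style estimates from the
  empirical MZ/DZ twin covariances) plus random Dirichlet restarts (3
  starts total by default); the E model is solved in closed form (OLS).
  Non-convergence after all starts yields a flagged fit with NaN
  components, excluded from selection.
* Outliers are removed per edge with the Tukey rule: keep w with
  Q1 − 1.5·IQR < w < Q3 + 1.5·IQR, strict inequalities, quartiles by
  linear interpolation of order statistics. When the IQR is zero the
  fences collapse onto the data and nothing is removed. Excluded or
  missing members reduce a family to its observed block, which contributes
  the marginal likelihood (standard full-information treatment).
* AIC = 2p − 2lnL with p counting variance plus mean parameters; ties
  break toward fewer parameters. h² is the standardized A of the AIC-best
  model; the full-ACTE h² channel is emitted alongside as a
  selection-free check.

Behavior worth knowing: at realistic cohort sizes (117 MZ pairs + 69
siblings, 60 DZ pairs + 48 siblings) the AE fit itself is unbiased, but
best-model h² is mildly shrunk toward zero (bias ≈ −0.04 to −0.09 across
true h² of 0.8 down to 0.2) because edges whose familial signal is too
weak to beat CE/E on AIC report h² = 0. This is a property of the
selection procedure, not the estimator. C and T are only separable when
sibling data are present; with twins alone only their sum is identified.

## Transcriptional coupling

Expression is normalized by two scaled-robust-sigmoid passes —
x ↦ 1/(1+exp(−(x−median)/(IQR/1.35))) then min–max to [0, 1], first per
sample across genes, then per gene across samples; multi-donor inputs are
normalized per donor and averaged per region. Zero-IQR features map to a
constant 0.5 and are flagged. CGE is the Pearson correlation of region
profiles across genes, pairwise-complete over missing values.

The exponential trend r(d) = A·e^{−d/n} + B is fitted by nonlinear least
squares with multiple starting length scales (10, 30, 90, 300 mm); the
best converged start wins, a nearly flat trend triggers a warning, and
residuals ĈGE = CGE − r(d) feed all downstream comparisons. Geodesic
surface distances can be supplied as the distance matrix; Euclidean
distances are the fallback.

Gene contribution scores use region profiles z-scored across genes with
the population (1/N) divisor — the unique convention under which
(1/N)Σₐ g̃ᵢᵃg̃ⱼᵃ equals the Pearson CGE exactly, making
mean-over-genes(GCS) ≡ ĈGE a machine-precision identity that the tests
enforce at 1e−10. A single-gene atlas is degenerate under this convention
and falls back to standardizing the gene across regions, with a warning.
Per-gene rich-vs-peripheral contrasts are Welch t-statistics, vectorized
over genes.

Gene-score-resampling enrichment summarizes a set by its mean score and
compares it against means of random same-size draws without replacement
(upper tail only — the score is directional), with the add-one rule
bounding Monte-Carlo error and BH-FDR across retained sets (size bounds
5–100 by default). n_iter is configurable; tests run at 10⁴.

## Microstructure

Depth profiles (16 surfaces, pial → white) are corrected for the
midsurface y-coordinate by per-depth linear regression, standardized per
depth, then correlated pairwise across depth while partialling out the
cortex-wide mean profile. Positive partial correlations map through
log(r/(1−r)) — monotone and finite on (0, 1); r = 1 is clipped at
1 − 1e−12 — and non-positive values floor at the minimum transformed value
so the matrix stays dense for curve code. Because the exact log variant
used by reference pipelines differs between implementations, the raw
partial-correlation matrix is returned alongside the transformed one.
Regions with vanishing residual profile variance get NaN rows/columns and
a warning.

## Generative models

Growth starts from the empty graph and adds one edge per iteration,
sampled with probability θᵢⱼ/Σθ over absent edges, where
θᵢⱼ = dᵢⱼ^η · (tᵢⱼ + ε)^γ and t is recomputed from the current adjacency
each iteration (13 rules: spatial, five clustering and five degree
combinations, neighbor count, and matching index; clustering is the
binary local coefficient, betweenness exact shortest-path). ε = 1e−5
prevents zero-probability lockout at the empty start. Exponent bounds:
the wiring-cost exponent η ∈ [−15, 0] (cost always penalized), the
topology exponent γ ∈ [−4, 4], λ ∈ [0, 200].

Genetic variants substitute/add a factor ĝᵢⱼ^λ, where ĝ is the residual
CGE min–max rescaled to [ε, 1] once over all candidate pairs at
initialization (kept static during growth): S = d^η, G = ĝ^λ,
SG = d^η·ĝ^λ, TG = (t+ε)^γ·ĝ^λ and ST = d^η·(t+ε)^γ, both with t the
average-degree rule. The functional form for λ is a package choice — it
respects the λ range, is monotone in CGE, and avoids overflow — and is
pluggable should a different weighting be preferred.

Fit quality is the maximum KS distance across the degree, clustering,
betweenness, and edge-length distributions (lower is better); hub
*topography* is scored separately by the Spearman correlation of degree
sequences with average-rank ties. Optimization samples the free exponents
uniformly in round 1, then draws candidates uniformly, assigns each to its
nearest evaluated point (a Voronoi cell, coordinates normalized by bound
widths), and importance-resamples with weight 1/rank of the cell's
objective — later rounds concentrate near the best cells. The preferential
sampling law is a package choice; the per-round best is tracked
cumulatively (elitist), and the sorted top-100 evaluations are reported.
Single-hemisphere fitting is done by passing the node-subset matrices;
degree terms then refer to within-subgraph degree.

## Synthetic data

The generators define the study conditions for all tests:

* **Connectome cohort** — nodes uniform in a 140×100×80 mm box, edge
  presence probability base_prob·e^{−d/decay_scale} (defaults 0.9 and
  60 mm, giving a consistent-edge density that supports 10–25% group
  thresholds), plus an additive boost with a hub-end factor (full between
  planted hubs, quarter for feeder edges) so the planted hubs are
  high-degree overall and strongly interconnected — high hub–hub density
  at moderate hub degree is what makes the club exceed its
  degree-preserving null. Hubs are placed by farthest-point sampling
  (spatially distributed). Streamline-count-like weights are lognormal
  with distance-decreasing location; FA-like weights are logistic-Gaussian
  in (0, 1); both are elevated on rich/feeder edges with the same factor.
* **Twin cohort** — defaults mirror a large twin imaging cohort (117 MZ
  pairs + 69 siblings, 60 DZ pairs + 48 siblings); MZ co-twins share the
  genetic draw fully, DZ co-twins and twin–sibling pairs with coefficient
  0.5; C is family-shared, T twin-shared (the sibling keeps an independent
  T draw so variances match); twins share age and sex (same-sex pairs);
  age and sex effects add to the mean. Implied covariances are exactly
  those of the fitted model, verified against closed forms in the tests.
* **Expression** — gene profiles drawn from a region-level latent
  correlation matrix whose off-diagonals follow A·e^{−d/n} + B (defaults
  0.64, −0.19, 90.4 mm), so the implied CGE is exact in expectation; the
  hub–hub boost is carried by a planted subset of genes (correlation
  boost/fraction within that subset). Non-positive-definite targets are
  repaired by minimal diagonal inflation with a warning, which attenuates
  the planted structure proportionally.
* **Profiles** — block-shared smooth cosine templates plus noise and a
  linear y trend injected at every depth.

What the generators do *not* emulate — tractography artifacts and
distance-dependent reconstruction error, donor/batch effects and spatial
sampling gaps of expression atlases, measurement-noise heteroscedasticity
across edges, realistic cortical geometry and geodesic distances, and
selection effects in cohort recruitment. Passing tests therefore show
that the estimators recover the effects they target under the assumed
statistical structure, with correct null calibration; they do not show
robustness to the artifacts of real acquisition pipelines.

## Problem sizes used in tests

The acceptance suite runs the heritability recovery at the full cohort
sizes above with 200 edges per h² level; rich-club detection on a
150-node, 10%-density network with 200 nulls and a 20-network
Erdős–Rényi control; generative self-recovery on a 100-node, 495-edge
target with 500 evaluations; enrichment calibration with 500 sets at 10⁴
resamples; and the end-to-end planted-effect checks on a 100-node
network with ~200 fitted edges. These sizes give Monte-Carlo error well
inside each asserted tolerance while keeping the whole suite to a few
minutes.

## Known limitations

* Best-AIC h² is shrunk toward zero at low true heritability (see above);
  the full-ACTE channel shows boundary bias in the other direction
  because nonnegative C/T absorb sampling noise. Bivariate/multivariate
  and sex-limitation models are out of scope.
* Uncorrected per-k significance flags on link-type curves.
* The enrichment null is exchangeable over genes and, like the standard
  tool it mirrors, is not constrained for spatial autocorrelation of the
  scores; spatially constrained nulls are out of scope.
* The λ weighting of CGE in genetic wiring rules and the preferential
  sampling law of the optimizer are package choices where the field has
  no single convention; both are isolated behind small functions.
* Cost-preserving (geometry-matched) rich-club nulls and
  betweenness-based hub definitions are not implemented.
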