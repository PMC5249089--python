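# Methods

## Pairwise control models and edge kernels

For a gene panel of size G, every unordered pair (i < j) gets a reference
model fitted on the control samples only (at least 3 required; counts per
pair are identical since the matrix is dense).

**Regression kernel.** OLS of m_j on m_i; the pair is unordered in the
graph but the residual definition is not symmetric, so the orientation is
fixed — the lower-indexed gene is always the predictor — and recorded in the
model. σ is the sample standard deviation of the control residuals
(divisor n−1; the residual mean is exactly 0, so this equals the root mean
squared residual up to the n−1 convention). Pairs with a constant predictor
or σ = 0 (exact collinearity) cannot be weighted; by default they are
dropped from the graph with a warning (`strict=True` raises), because real
beta-value panels contain near-constant genes and a single such gene should
not abort a run. All topology metrics operate on the surviving edge set.

**Mahalanobis kernel.** Per-pair control mean μ and 2×2 sample covariance S
(divisor n−1). The edge weight is the *squared* Mahalanobis distance — no
square root — matching the quadratic form as defined; `sqrt_distance`
exposes the square-root variant (off by default). When det S falls below a
relative tolerance of 1e−12 (constant or perfectly collinear genes),
ridge·I with ridge = 1e−8 (configurable) is added to the diagonal, making
every pair weightable; with ridge = 0 such pairs raise at weighting time.
A useful internal identity: the mean squared Mahalanobis distance of the n
fitting samples themselves is exactly 2(n−1)/n in two dimensions, which the
test suite uses as a fitting oracle.

Fitting is vectorized through the G×G covariance matrix; per-pair OLS
coefficients derived from it are algebraically identical to the
normal-equation solution. Models serialize to a NumPy `.npz` archive with an
embedded JSON header (kernel, panel, control ids, format version) and export
to a flat per-pair TSV. For panels well beyond ~3000 genes the dense G×G
weight matrix stops fitting in memory; `stream_pair_weights` yields
condensed weight chunks so edge lists and top-k selection still work
out-of-core. Panel size is never silently capped.

## Topology indices

Twelve per network, in fixed order: mean/variance/max of edge weights (over
present edges), mean/variance/max of weighted degree deg(v) = Σ_u w_vu,
mean/variance of pairwise shortest-path lengths (unordered pairs), diameter,
graph degree centrality, efficiency, and mean per-node betweenness.
"Variance" is always the sample variance (n−1) — not a coefficient of
variation.

*Distance semantics.* The default treats an edge's weight directly as its
length (distance = minimal total weight), the literal reading of a
weighted-graph distance; note this makes strongly abnormal edges *long*. The
competing intuition — heavier edges act as short-cuts and shrink the
diameter — corresponds to `length_mode="inverse"` (length = 1/w, capped at
1/ε for w ≤ ε = 1e−12). Both are first-class; every output is stamped with
the mode. The two readings are genuinely different models and produce
different path-based indices; choose one per study and keep it fixed.

*Graph degree centrality* uses the Freeman-style normalization
C_D(G) = H/H_max with C_D(v) = deg(v)/|V|, H = Σ_i |C_D(v*) − C_D(v_i)| and
H_max = (|V|−1)(|V|−2). With weighted degrees this caps the unit-weight star
at 1/n rather than 1, and because H_max is weight-independent the index
scales linearly under uniform edge-weight scaling; it is implemented exactly
in this normalized form, and both properties are asserted in the tests.
Graphs with fewer than 3 nodes have H_max = 0 and raise.

*Efficiency* is the mean inverse distance over ordered pairs; infinite
distances contribute 0, and distances below 1e−12 contribute the capped
value 1e12 (reachable only for samples lying exactly on a control
reference).

*Betweenness* follows Brandes' accumulation over a Dijkstra search in which
two path lengths count as tied when they differ by less than ε_path = 1e−9
(relative): weighted shortest-path counting is ill-posed under exact
floating-point comparison. The per-node scores sum fractions of tied
shortest paths through interior vertices over unordered pairs; the single
feature is the mean over nodes (the defining score is per-node, but the
feature vector needs a scalar; the per-node vector remains available).
The same tolerance-aware pass also yields the distance matrix, so zero-weight
edges are honest zero-length edges.

Feature extraction requires a connected graph; `largest_component=True`
restricts the path-based indices to the largest component instead (logged in
the feature metadata by the caller if used). Parenclitic graphs are complete
minus degenerate pairs, so disconnection is rare in practice.

## Degree distributions and power-law fits

The CCDF uses strict exceedance: P(deg > x). Group curves are pointwise
means of per-network CCDFs on a shared log-spaced grid (50 points spanning
the smallest positive to the largest observed degree); pooled-degree mode is
available as an alternative. The default fit is ordinary least squares of
log10 CCDF on log10 degree above x_min (default: the smallest
positive-mass degree value), reporting the CCDF-scale exponent (= density
exponent − 1), R² of the log-log line, and the Kolmogorov–Smirnov distance
between the empirical and fitted CCDF with the fitted curve capped at 1.
A continuous maximum-likelihood (Hill) estimator is provided as an
alternative; on discrete data with x_min near 1 it is biased and a larger
x_min should be chosen. The healthy-vs-disease comparison is reported as the
difference in fit quality (R², KS) between groups — a measurement, not a
hard-coded verdict.

## Two-step cross-validation

Outer folds partition the healthy samples (seeded shuffle, `array_split`);
each fold in turn is the control group, used only for model fitting, and the
remaining healthy samples join all disease samples as the classification
set — by construction no control sample is classified in its own fold. The
fold count follows the healthy-sample budget: 2 folds below 50 healthy
samples, else 4. The inner loop is stratified 10-fold CV (stratification is
mandatory: held-out healthy samples are scarce, often one or two per inner
fold). Confusion counts are pooled over all inner and outer folds rather
than averaging per-fold rates, because fold sizes are unequal; accuracy,
specificity (healthy correctly negative) and sensitivity (disease correctly
positive) derive from the pooled counts. Classifier defaults: Random Forest
with 500 trees, or an RBF SVM on standardized features; all hyperparameters
are recorded in the result. AUC is deliberately not a default output — with
one or two healthy samples per inner fold it is rarely well defined — and
every random draw descends deterministically from the single config seed.

## Synthetic cohorts

The generator works on the logit scale and squashes through the logistic
function, so values are genuinely bounded in (0, 1) and the correlation
structure stays smooth near the boundaries. Genes form disjoint pairs; a
fraction of pairs (default 0.5) is *linked* — bivariate normal with
correlation ρ (default 0.7) and marginal logit spread 0.25 — and per-gene
logit means are drawn uniformly in (−1.5, 1.5). Control and held-out healthy
samples share one distribution. Disease samples perturb every linked pair:

* **off_line** — the response gene shifts by δ⊥ control-residual standard
  deviations perpendicular to the pair's regression structure (default
  δ⊥ = 5), the geometry where regression residuals separate classes;
* **along_line** — the point shifts along the regression-line direction
  (1, ρ)/√(1+ρ²) by δ∥ marginal standard deviations, leaving regression
  residuals of the linked pair unchanged by construction while displacing
  the cluster away from the control cloud;
* **mixed** — both.

The default cohort is 60 control / 60 healthy / 120 disease samples over 50
genes — a desk-scale stand-in for a mid-sized methylation study. Shift signs
are fixed per pair (drawn once, recorded); ground truth (linked pairs,
signs, magnitudes, per-gene means) is returned and can be written as a
sidecar JSON so recovery tests never re-derive it. A probe-level expansion
(default 3 probes per gene, probe noise 0.01, configurable missingness and
detection-failure rates) exercises the preprocessing stage.

What the generator does **not** emulate: array chemistry artefacts (type
I/II probe bias, batch effects), genome-scale panels, gene–gene correlation
beyond disjoint pairs, and the heavy-tailed between-gene variability that
makes real healthy networks scale-free. Consequences: passing recovery tests
demonstrate the pipeline's statistical machinery, not performance on real
450k data; and group CCDFs of synthetic healthy networks are concentrated
rather than genuinely power-law — the degree-distribution contrast is
therefore assessed in a hub-sparse regime (20% of pairs perturbed at
δ⊥ = 8) where disease networks grow a few star hubs of strongly abnormal
genes and their CCDF visibly departs from a straight line on log-log axes,
while the kernel-advantage experiment uses the along-line geometry at
δ∥ = 3 with a 20-gene, 20/20/40 cohort, an effect size at which neither
kernel saturates. Marginal shifts leak into every cross pair involving a
perturbed gene (both kernels see them), so at large δ∥ the kernels converge;
the Mahalanobis advantage is a moderate-effect-size phenomenon, mirroring
its modest 1–3 percentage-point gain on real cohorts.

## Preprocessing

Probe filtering keeps probes that are annotated, not blacklisted (the
blacklist — SNP-overlapping, multi-mapping, sex-chromosome probes — is
caller-supplied rather than embedded, keeping the package data-free), and
observed in ≥ 95% of samples (configurable). Detection failures
(p > 0.05) are replaced by KNN imputation with k = 5: plain Euclidean
distance between probe rows over mutually observed entries, unweighted mean
of the k nearest rows' values at the failed sample. Flagged-but-measured
values still participate in distances and neighbour means (they are
unreliable, not absent), which keeps the rule defined even when an entire
row fails detection; remaining missing values are filled by the same rule so
the output is dense. Genes are the arithmetic mean of their probes;
rescaling to [0, 1] happens after gene averaging (the orders are
near-equivalent for in-range data) and is a no-op when values are already in
range, otherwise a global min–max by default (per-gene optional) so relative
gene differences survive; the applied mode is recorded in the matrix
metadata.

## Numerical conventions

| constant | value | role |
|---|---|---|
| ε_path | 1e−9 (relative) | shortest-path tie tolerance |
| ε_d | 1e−12 | distance floor in efficiency; inverse-length floor |
| ridge | 1e−8 | Mahalanobis covariance regularization |
| det tolerance | 1e−12 (relative) | singularity test before ridging |
| σ floor | 1e−15 | regression-pair degeneracy test |

Ties in top-k edge selection break by lexicographic gene-pair order. Matrix
I/O writes 17 significant digits so text round-trips are bit-exact. Test and
acceptance problem sizes (4–8-node graphs for the brute-force oracles, 50
genes / 240 samples for pipeline recovery, 20 genes / 80 samples for the
kernel contrast) were chosen so the exhaustive oracles stay exact and the
full suite runs comfortably on one CPU.

## Known limitations

* The per-pair models assume a dense, bounded matrix; no missingness
  downstream of preprocessing.
* The regression kernel's fixed predictor orientation is one of two equally
  defensible conventions (averaging both orientations is the other); results
  are reproducible but not orientation-agnostic.
* Log-log OLS on the CCDF is transparent but statistically crude compared to
  discrete MLE with KS-optimized x_min; it is the default because the fits
  feed a *contrast* between groups, not an absolute exponent claim.
* Betweenness is O(V·E + V² log V) per network with a dense-graph O(V³)
  implementation; fine up to a few hundred nodes per network, not tuned for
  genome-scale panels.
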