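# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## The psychometric model

The battery is modelled as a single-common-factor structure: standardized
test scores `x_ij = λ_j f_i + ε_ij`, with latent factor `f ~ N(0,1)` and
independent residuals. Under this model every pair of tests correlates
positively (`r_jk = λ_j λ_k`, the positive manifold), and the first factor
of an exploratory analysis is the general factor g.

**Adequacy.** KMO is the ratio `Σr² / (Σr² + Σq²)` over off-diagonal
entries, with anti-image partials `q_ij = −s_ij/√(s_ii s_jj)` from
`S = R⁻¹`; per-item MSA is the same ratio row-wise. Bartlett's sphericity
statistic is `χ² = −(n − 1 − (2p+5)/6)·ln|R|` on `p(p−1)/2` degrees of
freedom. A singular correlation matrix is rejected with the most collinear
pair named.

**Factor count.** Velicer's MAP partials the first m principal components
out of R for m = 0..p−2 and averages the squared (1976) or fourth-power
(2000) off-diagonal partial correlations; the minimizing m is returned. The
m = 0 term is the average over the raw correlations, so an identity-like
matrix correctly yields zero factors.

**Estimation.** Factoring is minres/ULS: uniquenesses ψ are optimized by
L-BFGS-B (bounds [0.005, 1]; starting values from squared multiple
correlations), and given ψ the loadings are the best rank-m spectral
approximation of R − diag(ψ). Minres was chosen over maximum likelihood
because it makes no normality assumption and is the common default in
exploratory practice. Heywood cases are handled by the 0.005 floor with a
warning rather than silently. A single factor is not rotated (sign fixed so
Σλ > 0); multi-factor solutions are rotated obliquely by quartimin/oblimin
through the gradient-projection algorithm. GPA is run from the identity
plus nine fixed pseudo-random starts (internal seed) because the identity
start is a saddle point for perfectly symmetric two-block patterns; the
lowest criterion value is kept, so rotation remains deterministic.

**Fit and scores.** RMSR is the root mean square off-diagonal residual.
The Tucker–Lewis index is computed from the ML discrepancy function
evaluated at the ULS solution (Bartlett-corrected scale factor), against
the independence model; it can slightly exceed 1 on near-exact fits.
Factor scores are Thurstone regression scores `W = R⁻¹ΛΦ`, standardized on
the combined sample (patients and controls together, matching how the
battery is administered and scored); score validity is
`√diag(ΦΛ′R⁻¹ΛΦ)` and the reported R² is its square — an algebraic
identity the tests assert on every fitted model.

## Group comparison

Cohen's d uses the pooled within-group SD and is reported as a magnitude
(with signed group means alongside), matching the convention of published
effect-size tables. Inference uses permutation tests on the difference in
group means: exact enumeration when the number of group assignments is at
most 20,000, otherwise Monte Carlo with the +1 correction (p can never be
zero). The discriminant is the classical two-class Fisher construction
`w ∝ S_pooled⁻¹(μ₁ − μ₀)` with no prior reweighting despite unequal group
sizes, scaled to unit pooled projected SD (so the projected separation
equals the Mahalanobis distance between group means) and signed so controls
score higher. Adjustment for g is residualization on the combined sample
(OLS with intercept) followed by re-testing; a measure that is exactly
proportional to g is exactly nulled. Covariate associations use Pearson or
Spearman correlation as declared per covariate, a two-sample t-test across
a two-level deprivation category, and χ² for categorical-categorical
contingency.

## Connectome graph theory

Connectivity is Fisher-z (`atanh`) of Pearson correlations with zero
diagonal. Negative z values are set to zero before graph construction
(config `negative_policy = zero | abs | error`): a 40% density ceiling is
conventionally chosen precisely so that retained edges are positive
associations, and negative functional couplings are not interpretable as
edge weights in these metrics.

**Thresholding.** The backbone is the maximum-weight spanning tree
(Kruskal on descending weight with lexicographic tie-breaking, so the tree
is deterministic; equivalently the minimum spanning tree under length
1/weight). A graph at density d keeps the backbone plus the strongest
remaining edges until exactly `round(d·N(N−1)/2)` edges are present,
weights retained. Every admissible density therefore yields a connected
graph — the point of the backbone. Densities below the spanning-tree floor,
or targets exceeding the pool of positive-weight pairs, raise errors rather
than silently delivering a different density.

**Metrics.** Global measures default to weighted variants on weights
rescaled to a per-subject maximum of 1; binary variants are available
(`mode="binary"`) since the published pipeline does not state which was
used. Transitivity is `trace(A³)/Σk_i(k_i−1)` in binary mode and the
Onnela geometric-mean generalization (cube-root weights) in weighted mode.
Global efficiency is the mean inverse shortest-path length (hops, or
lengths 1/weight). Modularity Q is optimized by Louvain with a configurable
number of seeded restarts (library default 100; tests and the acceptance
run use 3–5 because on the synthetic cohort sizes the partition is stable
after very few restarts). The participation coefficient uses weighted
strengths into each parcellation module; module-level participation is the
unweighted mean over member nodes.

**Null normalization.** Transitivity and efficiency are divided by their
means over degree-preserving Maslov–Sneppen rewired graphs. Rewiring
rejects self-loops, multi-edges and disconnecting swaps (connectivity is
enforced with an adaptive check window that undoes a window of swaps if it
ends disconnected); the original weight multiset is shuffled onto the
rewired edge list, so the degree sequence and the weight multiset are
preserved exactly. Saturated graphs (e.g. complete graphs, which admit no
legal swap) are returned unchanged with a warning.

**Group tests.** Global metrics are compared per density with permutation
tests and Bonferroni correction over densities within each metric family;
module-level participation is compared with Benjamini–Hochberg FDR across
modules at a chosen density (default the largest swept). Participation–g
associations are Spearman correlations per module, within each group
separately, with FDR across modules.

## Synthetic cohorts: what they emulate, and what they don't

The battery generator plants exactly the one-factor model above, with a
default patient deficit of 0.85 pooled SD on the latent factor — the
observed case-control effect size on g — 11 tests, and loadings of 0.7
(residual SDs √(1−λ²), so tests have unit variance and correlations λ²).
The connectome generator plants block-structured correlation matrices
(default 90 nodes in 6 equal modules, within/between correlations 0.5/0.1,
subject noise SD 0.06 on the off-diagonals followed by eigenvalue-clipping
PSD repair at 1e−8 and renormalization to unit diagonal) and reduces the
patient group's within-module correlation by 0.12 — a modular segregation
deficit, which is what lowers clustering and modularity and raises
participation. Covariates are linear in the true latent factor with unit
noise; neighbourhood deprivation is emitted as a two-level category split
at the latent median. Generators always return the latent truths (factor
values, module labels), because recovery of planted structure is the
package's validation surface.

What passing tests therefore show: the estimators recover the structures
they assume, at realistic effect sizes and sample sizes, and the corrected
tests are calibrated under the null. What they do not show: robustness to
features of real data the generators deliberately omit — non-Gaussian test
score distributions, missing data, fMRI temporal autocorrelation and
motion artefacts, scanner/site effects, unequal module sizes, and
hub-heterogeneous degree distributions. Published cohort-level values
(KMO = 0.84, RMSR = 0.08, TLI = 0.77, g–LDA r = 0.86, the clinical
correlation table, the specific surviving network) depend on the raw
cohort, which is not redistributable; the package recomputes these
quantities on any data given to it but makes no claim to reproduce those
numbers.

## Numerical choices and problem sizes

- Seeds: one user-facing integer; every stochastic component draws from a
  CRC-labelled `SeedSequence` child stream, so stages are independently
  reproducible and adding a stage does not shift another stage's stream.
- Degenerate inputs: constant vectors in permutation tests warn and return
  p = 1; zero pooled variance, singular correlation matrices, densities
  below the spanning-tree floor, and unparcellated nodes raise.
- Ties: MST edge ties break lexicographically; thresholding uses the same
  deterministic order.
- Default density grid for global metrics is 0.10–0.50 in steps of 0.02 in
  the config schema, with participation reported at 0.20/0.30/0.40; the
  test suite and acceptance script sweep {0.2, 0.3, 0.4}.
- Validation cohort sizes were chosen to make planted effects detectable
  while keeping the whole suite fast: batteries of 100–250 subjects per
  group, connectome cohorts of 12–50 subjects per group at 48–90 nodes,
  null ensembles of 2–5 rewired graphs with 3–5 swaps per edge, and 2000–
  5000 permutation draws. The null-calibration check uses 25 independent
  cohorts and bounds the family-wise false-positive rate by a three-sigma
  binomial envelope around the nominal α = 0.05.

## Known limitations

- The minres objective is optimized over uniquenesses only; with many
  factors and small p the spectral loading step can hit the zero-eigenvalue
  clip, in which case the reported fit is a boundary solution.
- The TLI uses an ML-discrepancy proxy at the ULS solution; it is not the
  likelihood-ratio TLI and can exceed 1 slightly on over-fitting solutions.
- Louvain is a heuristic: Q is a lower bound on the true maximum
  modularity (the tests verify it never exceeds the exhaustive optimum on
  small graphs, and equals it on planted two-clique fixtures).
- The rewiring null preserves degrees and the weight multiset but not the
  weight-degree correlation; for strongly weight-stratified networks a
  weighted rewiring null would be stricter.
- One matrix per subject is assumed; concatenation of multiple runs happens
  upstream.
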