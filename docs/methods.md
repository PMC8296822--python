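# Methods

This note documents the models, numerical conventions and design choices
behind `dcnet`, in the order the pipeline runs.

## Differential expression

The DEG caller operates on a log2 expression matrix; upstream preprocessing
(probe summarization, RNA-seq normalization, batch correction) is outside the
package's contract. Per gene, the pooled two-group variance s²_g on
d = n₁ + n₂ − 2 residual df is moderated under a scaled inverse-χ² prior
σ²_g ~ s₀²d₀/χ²_{d₀}. The prior parameters are fitted by moment matching on
z_g = log s²_g: with e_g = z_g − ψ(d/2) + log(d/2),

* Var(e) − ψ′(d/2) = ψ′(d₀/2) gives d₀ via a Newton inversion of the
  trigamma function (initialized at 0.5 + 1/x, converged to 1e−10 relative);
* s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)).

When the spread of log variances does not exceed the sampling spread
(Var(e) ≤ ψ′(d/2), e.g. all variances equal), d₀ = +∞ by convention and the
prior variance is the geometric mean of the observed variances; every
posterior variance then equals it. d₀ = 0 reduces exactly to the ordinary
pooled t (asserted to 1e−10 in the tests). The moderated statistic is
t_g = log2FC_g / √(s̃²_g(1/n₁ + 1/n₂)) referred to a t distribution on
d₀ + d df (normal when d₀ = ∞). Zero-variance fits are clipped so p ∈ (0, 1]
(smallest positive double, 5e−324).

DEG thresholds are strict (`p < 0.05`, `|log2FC| > 0.5`) on **raw** p-values;
a Benjamini–Hochberg q-value column is available but informational only —
the flag always uses the raw p. The fold-change sign convention is
disease − healthy. Welch's t (`method="welch"`) is a transparent fallback
with no cross-gene sharing.

## PPI filtering and the WDRN

Interaction confidence is an integer score in [0, 999]. "High confidence" is
score **strictly above** 900 by default; because score-threshold conventions
vary, the cutoff and its strictness are parameters (`min_score`, `strict`).
Gene identifiers are matched by exact string equality after one
normalization (strip whitespace, uppercase); no alias or ortholog resolution
is attempted, and users mixing identifier namespaces must map them upstream.

The WDRN keeps filtered edges with ≥ 1 DEG endpoint. Nodes arise only from
retained edges: a DEG with no retained incident interaction is absent, so
the construction is monotone in the DEG set and every node is within graph
distance 1 of a DEG.

DEG coverage is 100·n_deg_nodes/n_nodes **truncated** (not rounded) to two
decimals, computed as `(n_deg * 10000 // n_nodes) / 100` in exact integer
arithmetic. Truncation is deliberate: on composition counts such as 859 DEGs
among 5,195 nodes the exact value 16.5351…% truncates to 16.53 where
rounding gives 16.54, and only the truncation rule reproduces all published
coverage figures consistently.

## Differential correlation

Spearman's r_s is Pearson's correlation of average ranks (ties receive
average ranks); a constant vector makes r_s undefined (NaN marker, never
silently 0). Significance:

* **exact** — two-sided permutation test over all n! equally likely rank
  orderings; the count includes the observed ordering, so p > 0. With tied
  data the enumeration conditions on the observed tie pattern (permuting the
  observed rank multiset). Enumeration is vectorized and the untied null
  distribution cached per n; the practical limit is n ≤ 8 (40,320 orderings).
* **t_approx** — t = r_s√((n−2)/(1−r_s²)) on n−2 df, two-sided; |r_s| = 1
  maps to the smallest representable positive p.
* **auto** (default) — exact for n ≤ 8 without ties, t_approx otherwise.

The exact test is the default in the small-n regime because the t
approximation is anticonservative there; note the exact test's granularity:
at n = 3 the smallest achievable two-sided p is 1/3, so no 3-sample
condition can ever reach p < 0.05 exactly — analyses of 3-sample designs
implicitly rely on the approximation, which is why both modes exist.

An edge is *gained* when p_disease < α ≤ p_healthy, *lost* when
p_healthy < α ≤ p_disease, *none* otherwise (including undefined
correlations). "Uncorrelated or weakly correlated" is operationalized purely
as non-significance — no secondary |r_s| cutoff. No multiple-testing
correction is applied across edges (per-test α = 0.05 by design; an FDR mode
exists in the DEG stage only). The DN edge weight is the perturbation
r_s(disease) − r_s(healthy); its sign encodes gained (+) vs lost (−) and its
magnitude is the rendering width. Swapping the condition labels maps
gained ↔ lost and negates the perturbation exactly.

Because the per-condition tests are independent under the null, the expected
null fraction of differential edges is 2α*(1−α*) where α* is the **attained**
level of the discrete exact test (largest achievable p below α; 24/720 ≈
0.0333 at n = 6) — not the nominal 2α(1−α). The test suite computes α* from
the exact null distribution at run time rather than hard-coding it.

## Dense modules and hubs

Vertex weight = k × density of the highest k-core of the closed
neighborhood (the core-clustering coefficient). Seeds are processed in
decreasing weight (lexicographic tie-break) and expanded depth-first,
admitting unassigned vertices with weight > seed_weight × (1 − vwp),
vwp = 0.2. Every examined vertex is assigned to at most one module. Haircut
removes singly-connected members iteratively (the module's 2-core); fluff is
available but off by default (published tool defaults: vwp 0.2, haircut on,
fluff off). Module score = density × size; retention requires score
strictly > 3, and hub selection requires network degree strictly > 10, with
a fallback to the single maximum-degree module gene (lexicographic
tie-break) when no gene qualifies — the gene-level "score" is interpreted as
network degree, the only reading consistent with first-neighbor hub
renderings; the threshold is a parameter.

Merging per-tissue networks takes the node/edge union and annotates every
element with its contributing tissue set; DEG flags stay tissue-resolved.
The merged analysis defaults to merging WDRNs (`merge_on="wdrn"`), with DNs
as an option.

## Synthetic data

The generator emulates small-animal two-group designs: 6 samples per
condition by default (a 3+3 preset mirrors small public array sets), log2
intensities with baseline means uniform on [4, 12] and Gaussian noise
σ = 0.5 log2 units, a planted DEG fraction (default 0.2) with a ±1.0 log2
shift of random sign, and planted condition-specific correlated pairs
(default 5% of PPI edges) at target correlation ρ = 0.95.

The PPI is grown by preferential attachment (degree-weighted attachment of
each new node, then degree-weighted extra edges), giving a right-skewed
degree distribution; scores are integers from `score_range` with a
configurable fraction falling above the 900 filter threshold.

Correlation planting uses a shared latent factor: both genes of a pair get
x = μ + βz + ε with z ~ N(0,1) shared, ε ~ N(0, σ²), and
β = σ√(ρ/(1−ρ)), so the model Pearson correlation is exactly ρ in the
planted condition and 0 in the other. Planted pairs are drawn from edges
that carry a score above 900 **and** touch a planted DEG, so every planted
pair survives the default WDRN construction. Selection prefers a pairwise
disjoint edge set: a gene hosting k independent factors has per-pair
correlation β²/(kβ² + σ²) < ρ, so endpoint sharing is allowed only when
disjoint eligible edges run out, and any residual attenuation or cross-pair
correlation is inherent to the construction. Generation is fully
deterministic given the configuration (no timestamps in any output file).

What the generator does **not** emulate: count-level RNA-seq sampling
(negative binomial dispersion), probe effects, batch structure, correlated
background co-expression, or identifier mismatch between expression and PPI
namespaces. Passing tests therefore demonstrate correctness of the
algorithms under a clean Gaussian signal-plus-noise regime, not performance
on real tissue data.

## Problem sizes and test-design choices

The default study conditions (200 genes, 600 PPI edges, 6+6 samples) are
desk-scale: a full three-tissue pipeline run takes well under a second, and
the statistical checks (1,000 null genes; ≥ 2,000 null edges; 20 generator
seeds for recovery; 500 variances for moderation recovery) run in seconds.
Under these conditions the exact test's power against a planted ρ = 0.95
pair at n = 6 is ≈ 0.55 (the two-sided exact critical value at n = 6 is
r_s ≥ 31/35), which is what caps planted-pair recall near 0.55; precision is
high (≈ 0.8) because few null edges survive into the small WDRNs.

The cross-tissue housekeeping-DCG recovery check uses a deliberately
unbalanced strong-effect fixture (4 healthy vs 12 disease samples,
ρ = 0.99, planted direction gained): with n = 4 the smallest achievable
exact two-sided p is 2/24 ≈ 0.083 > α, so the scarce condition can never be
falsely significant and the check isolates disease-side power. Under a
balanced 6+6 design the three-tissue intersection would fail with
probability ≈ 1 − (1 − α*)³ ≈ 0.10 from healthy-side false positives alone,
making any high recovery bound ill-posed.

## Degenerate inputs and edge cases

* Empty filtered PPI, empty DEG set, or zero DCG edges propagate as empty
  networks; coverage of an empty network is reported as not available.
* Constant expression vectors yield undefined correlations and status
  'none', never an error; genes missing from a matrix skip their edges with
  a logged warning.
* A DEG caller run on pure noise still flags ~α of genes (raw-p design), so
  a zero-planted-signal pipeline run has small but nonempty WDRNs; the
  ground-truth tables are empty and all DN edges are false positives by
  construction.
* All orderings (module seeds, fallback hub ties, edge iteration, file rows)
  are lexicographic, making every stage reproducible bit-for-bit.

## Known limitations

* The exact permutation test is limited to n ≤ 8; beyond that only the
  (anticonservative for small n) t approximation is offered.
* Moderation assumes a common residual df across genes (complete matrices).
* Identifier normalization is uppercase/strip only.
* The merged-module stage does not attempt to reproduce any particular
  published module count; with undeposited source data such counts are not
  reproducible, and the merged analysis is validated structurally instead.
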