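# Methods

This note records the statistical models implemented in `evoisol`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real data.

## Mate-choice statistics

A multiple-choice assay yields a 2x2 table of mating-pair counts with
homotypic cells *a*, *d* and heterotypic cells *b*, *c*. Two association
indices are provided: Yule's Q = (ad − bc)/(ad + bc) and the coefficient
of colligation Y = (√ad − √bc)/(√ad + √bc). Y is the default reported
variant (it is the index conventionally written "Yule's Y"); Q is always
available, and |Y| ≤ |Q| for every nondegenerate table. Both are
undefined when ad + bc = 0, which is raised as a degenerate-table error.
Hypothesis testing uses Fisher's exact test (hypergeometric, both
margins conditioned); the reported odds ratio is the unconditional
sample OR ad/bc. Counts from the 8 cages per population combination are
pooled before testing, with per-cage tables retained by the caller if a
cage-level analysis is wanted; whether pooling or per-cage testing is
more faithful to any particular experiment is left to the user, since
assay protocols differ.

Chasing-time comparisons use Kruskal–Wallis with midrank tie handling
and a chi-square reference on k−1 df. The post-hoc display runs all
pairwise two-sided Mann–Whitney tests, BH-adjusts them at 0.05, and
builds a compact letter display by insert-and-absorb; two groups share a
letter iff their adjusted p exceeds 0.05. The post-hoc procedure is
packaging plumbing — no specific method is canonical for this design —
so it is deliberately the simplest defensible one.

## Compositional CHC analysis

Relative abundances carry only ratio information, so all multivariate
analysis happens after the centered log-ratio transform
clrᵢ = ln cᵢ − mean(ln c) (natural log; the base only rescales all
values). Zeros are handled by multiplicative replacement: each zero is
set to δ = 0.65 x the smallest positive fraction of that sample and the
vector re-closed; a strict mode raises instead. Compounds not detected
in every sample can be dropped first with `completeness_filter`, which
is how a "detected in all samples" compound panel is formed.

PCA is covariance PCA of the column-centered CLR matrix via SVD, with no
rescaling (CLR components are already on a common log scale). The sign
convention — the largest-magnitude loading entry of each component is
made positive — makes results deterministic. A constant matrix is
flagged degenerate rather than an error.

Per-compound two-way ANOVA uses type-II sums of squares by model
comparison (SS(sex|evolution), SS(evolution|sex),
SS(interaction|main effects)), F-tested against the residual mean square
of the full interaction model. ANOVA is run on CLR values by default for
compositional coherence; passing the raw percentage table gives the
raw-% analysis for comparison with conventions that use it. The type-II
implementation is hand-rolled with numpy design matrices so that
10,000-replicate null calibrations run in seconds; it is cross-checked
against `statsmodels.stats.anova_lm(typ=2)` in the test suite.

## Diallel-cross analysis

Progeny counts (possibly non-integer, being averages over two transfers)
from a full k×k diallel are summarized per cross type; the headline
contrast is the relative deficit (between − within)/within of pooled
means. Mid-parent expectations midparent(A,B) = (mean(AxA) +
mean(BxB))/2 are compared against each hybrid cross, reciprocals
reported separately and pooled.

The one-tailed Wilcoxon rank-sum test (H1: within-cross counts exceed
between-cross counts) uses complete enumeration over label assignments
of midranks when n₁+n₂ ≤ 12, which is exact under ties; larger samples
use the normal approximation with tie and continuity corrections. With
cross-type means as units (3 within vs 6 between), the smallest
attainable p is 1/84.

Dependence among crosses sharing a parental population is addressed by a
permutation test that shuffles the within/between labelling across cross
types while respecting the design (k within labels among k² types),
enumerated completely when C(k², k) permutations are feasible. This
plays the role a mixed-effects sanity check would play, without a
mixed-model dependency, and its null distribution is exact for the
statistic it permutes. Both the cross-type-mean and vial-level Wilcoxon
modes are available because the appropriate unit is design-dependent.

## Expression divergence

Counts are modeled as NB(μ, φ) with Var = μ + φμ². Genes are kept when
CPM = count/library-size x 10⁶ exceeds 0.1 in every sample.
Normalization is by library-size offsets only; compositional
normalizations such as TMM are deliberately out of scope, so strongly
asymmetric differential expression between groups would be absorbed
into fold-changes rather than corrected.

Only evolved male-type samples enter the divergence test (the design
this emulates lacks replicated female samples). The full model fits one
mean per evolved replicate with a log link and library-size offsets; the
null fits a single mean. Because the design is one-factor, the MLE
reduces to independent per-group scalar problems solved by a Newton
iteration vectorized across genes — there is no per-gene model object,
which is what makes 10,000-gene calibrations run in about a second. The
LRT statistic 2(ℓ₁−ℓ₀) is referred to χ²(k−1) and BH-corrected at FDR
0.05; non-converged genes get p = NA and are excluded from the FDR
family.

The common dispersion φ₀ maximizes a Cox–Reid adjusted profile
likelihood pooled over genes (profile likelihood minus half the
log-determinant of the mean-parameters' observed information). The
adjustment matters: the unadjusted plug-in underestimates φ (~0.19 for a
truth of 0.2 in our calibration runs) and inflates the LRT's type-I
error to ~0.064; the CR-adjusted estimate recovers 0.199 and calibrates
the test at ~0.05. Per-gene moment estimates (df-adjusted Pearson-style,
clipped at zero) are shrunk toward φ₀ with empirical-Bayes weights and a
prior df of 10 — a moderate default that stabilizes small designs
without overwhelming genuinely outlying genes.

**Per-replicate attribution.** "Gene g changed in replicate r" is not
standard edgeR output, so the rule is an explicit operationalization:
log2FC = log2((mean replicate CPM + c)/(mean ancestral CPM + c)) with
pseudo-count c = 0.5 CPM, and a call requires (i) |log2FC| > 1, (ii) a
significant 1-df replicate-vs-rest LRT among evolved samples,
BH-corrected over the genes x replicates family at 0.05, and (iii) a
replicate-specific deviation — log2FC minus the median log2FC of the
other replicates — exceeding the threshold with the same sign.
Condition (iii) exists because a strong shift in one replicate
contaminates any mean-based "rest" reference: without it, other
replicates inherit significant contrasts plus shared-response
fold-changes and the realized false-discovery rate against generator
truth rises from under 0.1 to about 0.25. The median reference is
robust to 1–2 genuinely shifted replicates, which is exactly the
sparsity the replicate-specific model assumes.

## Heterogeneity statistic

For a gene set, xᵢ is the vector of per-gene log2 fold-changes of
replicate i (ancestral-referenced; raw-expression vectors can be passed
instead where that convention is wanted). H = Σᵢ<ⱼ(1 − cor(xᵢ,xⱼ))/N
with Pearson correlation (Spearman available) and N = C(R,2) unordered
pairs; summing ordered pairs divides both numerator and denominator by
the same factor, so the value is identical and only the reported N
needs a convention. H ∈ [0,2]; pairs involving a zero-variance vector
are dropped with a warning and N reduced. H is invariant to affine
rescaling of any replicate's vector and to gene order.

A single gene set yields a single H, which is not a test. Significance
is constructed by (a) the empirical quantile of the focal H among
n_random size-matched sets drawn from the background without
replacement — the primary, correctly calibrated comparison — and (b)
Mann–Whitney tests between gene-bootstrap distributions of H, reported
as a secondary effect-size-style contrast (bootstrap draws are not
independent observations, so its p-value is heuristic and labelled as
such here).

Direction bias within a set counts every changed (gene, replicate) call,
tests the up-fraction against 0.5 with an exact binomial test, and
contrasts up/down splits between sets with Fisher's exact test.

## Enrichment

Over-representation is plain per-set Fisher (one-sided, greater) with BH
across the tested sets; graph-aware GO decorrelation (topGO-style) is
out of scope, so nested GO terms will partially duplicate signal and the
BH correction treats them as exchangeable tests. Annotation is read from
GMT-like files, keeping tests offline. Tissue-specific sets use the
strict rule expr(tissue) > 2 x expr(whole-body). Zero cells make the
sample OR infinite; a Haldane–Anscombe (+0.5) option is provided and
used where finite output matters (e.g. the acceptance report).

## Synthetic-data generator

All four modalities derive their randomness from one seed through
independent substreams, so runs are bit-reproducible.

- **Choice assay**: sequential pair formation without replacement; a
  free female is drawn uniformly, then a free male with weight
  `preference` (≥ 1) if homotypic, 1 otherwise; stops at `max_pairs`
  (default 25) or sex exhaustion; 50 flies per sex per population by
  default. Any exchangeable one-parameter scheme gives the same 2x2
  structure; this one is the simplest. preference = 1 is random mating
  (E[Q] ≈ 0); preference → ∞ gives Q = 1.
- **CHC profiles**: logistic-normal — closure(exp(base + sex shift +
  evolution shift + N(0, σ) noise)), 12 compounds, a ramped baseline so
  one compound dominates as in real fly profiles, orthogonal
  cosine/sine patterns for the sex (amplitude 1.2) and evolution
  (amplitude 0.45) shifts so the sex axis dominates PC1 and the
  evolution axis PC2, zero injected interaction, noise σ = 0.15.
- **Diallel**: progeny ~ Poisson(m(1+w)) within replicates,
  Poisson(m) between, m = 24, w = 0.09; the implied between-cross
  deficit is 1 − 1/(1+w) ≈ 8.3%.
- **Counts**: per-gene baselines are log-normal (log2 mean 6, sd 2);
  every gene gets a shared evolved shift log2FC ~ N(0, 0.5); genes in
  the reproduction set (10% of genes) additionally get
  replicate-specific shifts in 1 or 2 uniformly chosen replicates with
  magnitude `replicate_lfc_sd` x (1 + |N(0, 0.5)|) and sign positive
  with probability `up_bias` (default 0.9). The magnitude is bounded
  away from zero deliberately: a "replicate-specific change" of
  log2FC ≈ 0 is no change and would make recovery targets meaningless.
  The default scale 2 (typical ~4-fold shifts) represents pronounced
  replicate-specific evolution. Counts are gamma-Poisson draws
  (NB with φ = 0.2); library sizes are log-normal around 10⁶. Defaults
  use 10 evolved replicates with 5 samples each plus 5 ancestral
  samples.

What the generator does *not* emulate: batch effects, compositional
library biases (which is why TMM-free normalization suffices here),
gene-gene correlation beyond the injected set structure, mating-latency
or time-censoring dynamics in the choice assay (the 25-pair stopping
rule is modeled, the 2-hour clock is not), and vial-level environmental
covariance in the diallel. Passing recovery tests therefore shows the
estimators are correct under their assumed models, not that those models
absorb every artifact of real assays.

## Problem sizes and numerical choices

Calibration tests use 10,000 replicates per test (10,000 genes in one
design for the LRT); recovery tests use 1,000–2,000 genes, 1,000
size-matched random sets, and 1,500–2,500 choice-assay simulations —
sizes at which Monte-Carlo error is well below the asserted tolerances
while the whole suite stays fast. Newton fits clip steps to ±5 on the
log scale and flag non-convergence; zero-count groups take rate 0
exactly. Exact enumeration switches to normal approximation above
n₁+n₂ = 12 for the Wilcoxon and above the permutation budget for the
diallel labelling test. Midranks are used for all ties. The degenerate
cases (constant data, zero margins, empty sets, single-level factors)
return flagged results or informative errors rather than NaNs from
underlying libraries.

## Known limitations

- The NB LRT's χ² reference is asymptotic; with fewer than ~3 samples
  per replicate it runs anticonservative even with the CR-adjusted
  dispersion.
- The bootstrap Mann–Whitney contrast between gene sets is heuristic
  (see above); the random-set quantile is the calibrated quantity.
- Fisher-based enrichment inherits the usual dependence caveats when
  annotation sets overlap heavily.
- The per-replicate attribution rule is one reasonable
  operationalization among several; its FDR guarantee is empirical
  (against the generator), not distributional.
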