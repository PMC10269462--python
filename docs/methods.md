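# Methods

`rhizonet` re-implements, as a tested library, the network half of an
amplicon study of how a fungal seed inoculant (a *Trichoderma* genus)
restructures the rhizosphere microbiome of two crops: co-occurrence
network construction from OTU count tables, negative-edge topology,
natural-connectivity robustness, module eigengene–trait coupling, hub
identification, and an in-silico genus-knockout test of module
persistence. Because the analysis is exercised on synthetic data, this
note records both the statistical procedures and the generative model
they are validated against, with the reasoning behind every number
that had to be chosen.

## The analysis pipeline

**Normalization.** Counts are rarefied by multivariate hypergeometric
subsampling (without replacement) to a common depth, by default the
minimum sample total; alpha diversity is computed on rarefied counts.
Relative abundances (per-sample closure to 1) feed beta diversity and
all correlation work. Zero counts can never become positive under
rarefaction, and the expected rarefied count of taxon *i* is
`depth * count_i / total` — both are asserted in the test suite.

**Diversity.** Shannon entropy is reported in nats; Pielou evenness is
Shannon over `ln(richness)`, defined as 1 for a single-taxon sample;
Chao1 uses the bias-corrected form `S_obs + F1(F1-1) / (2(F2+1))`,
which stays finite without doubletons — the right variant for rarefied
data. Group comparisons use the two-sided independent-sample rank-sum
test: the design compares unpaired treatment groups, for which a
signed-rank test is undefined (a paired option exists for designs that
do pair). The exact null distribution is used up to 10 observations
per group, the tie-corrected normal approximation beyond. All p-value
families are Benjamini–Hochberg adjusted. Beta diversity is
Bray–Curtis with a one-way PERMANOVA: pseudo-F from the among/within
partition of squared distances, p from 999 random relabelings as
`(1 + #{F_perm >= F_obs}) / (1 + n_perm)`. The permutation loop is
vectorized in-house (the calibration suites need hundreds of full
PERMANOVAs); its statistic is cross-checked against scikit-bio's
implementation in the tests. One subtlety the tests document: a
relabeling that reproduces the observed block partition (e.g. the
complementary labeling with two equal groups) ties the observed F, so
the minimal attainable p exceeds `1/(n_perm+1)` for small balanced
designs.

**Networks.** Per sample group, taxa present in at least 3 samples
with mean relative abundance at least 1e-4 are screened (Spearman rank
correlation of near-constant vectors is meaningless); an edge joins
two taxa when |rho| is strictly above 0.8 and p strictly below 0.05
(raw p by default; a BH option exists). Rho uses average ranks
(tie-corrected). P-values come from the t approximation, except that
groups with at most 9 samples use the exact permutation null of the
rank-difference statistic for tie-free pairs (the exact null assumes
distinct ranks; tied pairs fall back to the approximation). The exact
null is enumerated once per sample size and cached. Edges carry the
correlation sign; the negative-edge ratio is the fraction of negative
edges and is undefined (NaN, with a warning) for an edgeless network.

**Modules.** Communities are detected by greedy modularity
maximization (Clauset–Newman–Moore, networkx) on the |rho|-weighted
edge set; the agglomeration is deterministic, and the recorded seed is
provenance for future stochastic detectors. Communities below
`min_module_size = 5` stay unlabeled: at the sample sizes of this kind
of study a 2–4 node "module" is indistinguishable from noise. Module
ids are ordinals assigned by content (size, then lexicographic first
member) and are stable only for identical inputs — modules should be
identified across analyses by membership, in particular "the module
containing the focal genus", never by number.

**Natural connectivity.** The robustness score of a graph is
`ln(mean_i exp(lambda_i))` over the eigenvalues of its *binary*
adjacency matrix (the robustness-literature convention; a |rho|-
weighted variant sits behind a flag), computed with `eigvalsh` plus a
log-sum-exp. It equals the log of the average closed-walk generating
function, so deleting an edge can never increase it — asserted on
random graphs, alongside equality with the independent
`ln(trace(expm(A))/N)` route to 1e-8. Robustness curves remove
`round(f*N)` uniformly random nodes (round half away from zero, making
curves bit-reproducible) for f on a grid from 0.01 to 0.60 and average
the recomputed natural connectivity of the induced subgraph — N in the
mean is always the current subgraph size.

**Eigengenes and traits.** A module's activity is its eigengene: the
first principal component (SVD) of the member taxa's standardized
relative-abundance profiles, oriented to correlate positively with the
module's mean standardized abundance, with the explained variance
fraction reported. Standardization makes the eigengene invariant to
rescaling any taxon. Eigengene–trait association uses Pearson
correlation (the convention of the eigengene framework; Spearman by
flag), pairwise deletion for missing trait values, and BH adjustment
across the full module-by-variable matrix with both raw and adjusted p
reported. Hubs are nodes in the top decile (configurable) of the
network by *both* degree and normalized betweenness; cutoffs are
computed among connected nodes — otherwise the betweenness cutoff of a
sparse network collapses to zero and the tie rule would flag every
leaf — and ties at the cutoff keep all tied nodes.

**Knockout.** `remove` drops every OTU of the genus; `reduce` scales
all of them in coated samples by one common factor (preserving
within-genus composition) chosen by root-finding so the genus's mean
relative abundance over coated samples matches the control mean after
rescaling — the naive ratio of means is wrong because sample totals
shrink with the genus. Scaled counts are rounded; zeros stay zero;
control samples are untouched. The network and partition are rebuilt
with identical parameters and seeds, and the original module (target
restricted to surviving nodes; in remove mode the genus's own OTUs
leave the denominator) is matched to the labeled rebuilt module
maximizing the shared-node proportion, ties to the smaller id; Jaccard
overlap and the count of recovered hub taxa are reported alongside.
The persistence verdict compares the proportion to a configurable
threshold, default 0.5 — the source analyses report a binary
similar/not-similar verdict without printing a cutoff, so the midpoint
is the least-informative honest default. Hub coincidence is reported
but deliberately not folded into the verdict.

## The synthetic community generator

Counts follow a log-normal–multinomial law. Per taxon, a baseline
log-abundance is drawn `N(0, 1.5^2)` across taxa; per sample, latent
factors and `N(0, 0.35^2)` idiosyncratic noise add on the log scale;
the log-abundance vector is closed to a composition and reads are
drawn multinomially at a Gamma-distributed depth (mean 20 000,
coefficient of variation 0.3). All draws descend from one seed through
named seed-sequence child streams, so every table is bit-reproducible.

**Planted structure.** A module is a set of taxa sharing a per-sample
standard-normal factor, each member scaled by `loading x factor_scale`
(default factor scale 1.5). With noise 0.35 this maps
loading 0.9 to a latent pairwise correlation of about 0.94 and an
observed count-level Spearman around 0.88–0.92 — comfortably above the
0.8 edge threshold, which is what "planted module" must mean for a
threshold-rule analysis. Negative ("competition") couplings are
antagonistic taxon pairs: a shared factor entering one taxon with a
positive and one with a negative sign; `competition_strength` scales
how many such pairs are active only under coating (10 per unit), on
top of positive association pairs and a few baseline negative pairs
present in all groups. Module members and pair taxa draw their
baselines from a narrower law, `N(1.0, 0.5^2)`: planted structure must
live in the moderately abundant range where rank correlations are
informative — neither drowned by count noise at a handful of reads nor
so abundant that it dominates the composition (see below).

**Marginal-preserving treatment contrasts.** Where a factor is active
only under coating (the focal module, the competition pairs), inactive
samples receive an *independent* draw of the same magnitude rather
than nothing: coating rewires the dependence structure of the
community without changing any taxon's marginal abundance law. This is
what makes the default scenario diversity-neutral by construction —
the emulated finding that coating leaves alpha diversity unchanged —
while still producing coated-specific modules and negative edges. The
one real marginal effect is the focal genus's enrichment factor
(default 5x) in coated samples, a single taxon at well under 1% of the
community.

**Compositional closure is the main enemy.** Because the analysis sees
relative abundances, any taxon or co-moving module that takes a large,
variable share of the reads warps every other taxon's rank order
through the denominator. Early design iterations with wilder log-scale
swings produced exactly this: occasional simulated communities where
one lucky taxon carried half the reads and all planted correlations
attenuated. The shipped defaults (factor scale 1.5, pinned focal
baseline, narrow member-baseline law) keep any planted taxon's typical
share in the low percents. This is a deliberate regime choice, not a
general solution; the generator makes no claim to emulate communities
with a dominant blooming taxon, and a compositional-aware inference
method (out of scope here) would be the right tool there.

**The focal module is small and star-like — necessarily.** Members of
a module are conditionally independent given its factor, so two
satellites correlating with the focal taxon at rho cannot correlate
with each other much below rho^2 (negatively correlated idiosyncratics
can push at most 1/(m-1) below that). A strict |rho| > 0.8 edge rule
therefore leaves any *large* keystone module a dense satellite cluster
(pairwise about 0.64–0.8, half the sample correlations above
threshold) that survives removal of its hub — hub knockout cannot
dissolve a big star module under this edge rule, as a short power
calculation over the satellite count shows. The default focal module
is consequently compact: the inoculant plus four satellites, exactly
`min_module_size`. Its satellites cohere only through the inoculant;
after removal at most four correlated members remain, too few to
constitute a labeled module, and the module dissolves — the regime in
which the knockout inference is actually decidable. The focal taxon
itself follows the colonization factor with loading 0.75 and strongly
reduced idiosyncratic noise (its abundance *is* the colonization
readout).

**Reduce mode on synthetic data.** Scaling a genus by a common factor
is invariant under ranks, so reduce-mode knockout leaves Spearman
networks essentially unchanged except through integer rounding at low
counts and the (small) compositional renormalization. On this
generator the focal module therefore persists under reduce mode even
though it dissolves under remove mode; a reduce-mode dissolution on
real data would have to come from detection-limit and depth effects
the generator deliberately does not model.

**Traits.** Each trait/enzyme variable is linear in one module's
factor plus Gaussian noise, `base + c*z + N(0, sd^2)`, giving a
generating correlation `c / sqrt(c^2 + sd^2)` with the factor (about
0.75 for the defaults; disease incidence uses a negative `c`). In
inactive groups the factor term is zero. Values are not clipped — the
bases sit far enough from zero that negative draws are vanishingly
rare, and a linear model keeps the generating correlation exact.

**Default design.** Four crop-by-treatment groups of 6 replicates (24
samples), 200 taxa, one focal module (5 members, satellite loading
0.95), one background module (8 members, loading 0.85), 15 positive
pairs, 3 baseline negative pairs, competition strength 1. The emulated
study reports 6 replicates per treatment; its stated total of 20
samples is internally inconsistent with that, and 6 per group is the
default here.

## Validation suites and their scenario sizes

The `validation` module runs the end-to-end checks that
`scripts/acceptance.py` and the acceptance tests execute; problem
sizes are part of each suite's definition:

* **Oracle equivalence** — natural connectivity vs
  `ln(trace(expm(A))/N)` on 200 random graphs (n <= 20); betweenness
  vs exhaustive simple-path enumeration on graphs with n <= 8;
  Spearman vs the rank-difference formula on 1000 tie-free vectors.
* **Null calibration** — 500 structure-free replicates at 12 samples
  per group, testing Bray–Curtis PERMANOVA (999 permutations) and the
  Shannon rank test at alpha 0.05. Twelve per group, not the study's
  six, because the exact rank test at n = 6 is so discrete that its
  attainable level (~0.04) makes a 500-replicate rate estimate
  unstable; at n = 12 the tie-corrected approximation operates near
  the nominal level.
* **Planted-module recovery** — a 15-member module at loading 0.9, 30
  samples per group, embedded with two background modules and coupled
  pairs so the planted module holds a minority of the network's edges.
  The background matters: a module containing nearly *all* edges of
  its graph is split by any modularity maximizer (the resolution
  degeneracy), which is a property of modularity, not of the data.
* **Module–trait recovery** — generating correlation 0.8 at n = 60,
  one 10-member module; recovered r within 0.15 and the disease sign.
* **Knockout specificity** — 50 replicates of the focal-nucleated
  scenario at 40 coated samples, removing the focal genus vs an
  abundance-matched random non-member genus. Forty samples per group
  is the regime where all four satellites reliably attach to the
  inoculant at the 0.8 threshold, so the intact analysis actually
  yields a labeled target module to knock out; replicates without one
  count as failures on both sides.
* **Negative-edge direction** — competition active only under coating,
  100 simulations at 20 samples per group. Twenty, because at n = 6
  the exact-test edge cutoff (|rho| >= 0.886) admits about 3% of null
  pairs, i.e. hundreds of random edges over ~20 000 screened pairs,
  drowning tens of planted ones: the threshold rule only has a
  controlled false-edge rate with adequate samples. This is also the
  honest caveat about the emulated study's regime — at six replicates
  per group these networks are noise-dominated, and the pipeline's
  own demo at n = 6 shows it (hundreds of edges, negative-edge ratios
  near 0.3 in *both* groups).
* **Diversity neutrality** — 200 default-scenario replicates; all
  three alpha indices compared between treatments within crop with BH
  adjustment, counting replicates with no significant comparison.

What passing these suites shows — and what it does not: the pipeline
recovers structure *that the generator plants*, under log-normal
margins, Gaussian copulas, and multinomial sampling. Real amplicon
data add compositional effects from dominant taxa, phylogenetic and
spatial correlation, chimeras and contamination, and far fewer
samples; none of those are modeled, so the suites certify the
statistical machinery, not field performance at n = 6.

## Numerical choices and degenerate inputs

Strict inequalities at both edge thresholds (a pair at exactly rho =
0.8 is not an edge). Constant taxa are excluded from correlation with
a warning; constant module members are dropped from eigengenes;
all-tied rank tests return p = 1 with a warning; an edgeless network
is returned with a warning, not an error, and its negative-edge ratio
is NaN. Natural connectivity of a single isolated node is 0. The
reduce-mode scaling factor is solved by bisection on [0, 1] and a
genus absent from controls is zeroed with a warning. Seeds: one
top-level seed per scenario or pipeline run, split into named child
streams (simulate, rarefy, permanova, modules, robustness, knockout);
identical configs reproduce byte-identical output tables.

## Known limitations

Correlation thresholding is compositionally naive by design (the
method under study); SparCC-style inference is a non-goal. Module
detection is a single deterministic greedy maximizer; consensus over
detectors is not attempted. The knockout verdict depends on
`min_module_size` and the 0.5 overlap threshold, both configurable and
reported, neither derivable from the source analyses. The generator's
regime choices (moderate factor scales, sub-dominant planted taxa) are
documented above; outside that regime the planted-structure guarantees
do not hold.
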