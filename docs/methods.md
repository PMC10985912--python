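# Methods

`snownet` implements a multi-threshold ensemble analysis of cross-kingdom
(fungal–bacterial) co-occurrence networks for paired amplicon datasets from
seasonally contrasted soils (snow-free vs snow-covered samples from several
locations).  This note records the models, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would want to know.

## Analysis model

### Occurrence filtering and the threshold grid

ASVs are filtered by *occurrence* (number of samples with count ≥ 1), never
by read abundance, because rare-but-recurrent taxa are the interesting
signal for association inference while singleton noise is not.  Each
kingdom has its own threshold vector — defaults 5, 7, 9, 11, 19 samples for
fungi and 10, 20, 31, 39, 46 for bacteria — and the Cartesian product gives
25 filtered table pairs.  Occurrence is computed once on the full
both-condition dataset, before the condition split: each condition's network
is then inferred from the same ASV panel, which makes between-condition
comparisons a comparison of structure, not of panel composition.  (Whether
to count occurrence before or after the split is genuinely open; the choice
is recorded in every network's sidecar metadata.)  `suggest_thresholds`
automates the usual shoulder heuristic — candidate thresholds at the largest
relative drops of the #ASVs-retained-vs-threshold curve — but is advisory
only.

### Network inference

Counts of the two kingdoms are concatenated and transformed with a single
centred log-ratio (CLR): x_i = ln(c_i + 1) − mean_j ln(c_j + 1) over the
joint feature vector, so both kingdoms share one geometric-mean reference
(a per-kingdom CLR is available behind `per_kingdom_clr=True`).  The
conditional-dependence graph is estimated by Meinshausen–Bühlmann
neighborhood selection: each CLR feature is lasso-regressed
(objective (1/2n)‖y − Xb‖² + λ‖b‖₁ on z-scored columns) on all others, and
an edge exists when either directional coefficient is non-zero (OR rule).

The penalty λ is chosen by StARS stability selection: 20 subsamples drawn
without replacement, per-pair selection frequencies θ̂, instability
D(λ) = mean over all feature pairs of 2θ̂(1−θ̂), and the smallest λ whose
running-supremum instability stays ≤ β = 0.05 is selected (the densest
sufficiently-stable graph).  The λ path has 20 log-spaced values from
λ_max (the largest absolute feature correlation) down to 0.01·λ_max.
Because the monotonized instability can only grow toward the dense end, the
solver walks the path stepwise with warm starts and stops one λ past the β
crossing; the dense end of the path is never solved, which is what keeps a
full 50-network grid run under a minute.

Subsample size is b = min(⌊n/2⌋, ⌊10√n⌋).  The classical ⌊10√n⌋ rate
exceeds n for n ≤ 100, and near-full subsamples make every subsample almost
identical, so instability collapses to zero and selection becomes
meaningless.  Half-sampling — the complementary-pairs convention of
stability selection — keeps subsamples maximally dissimilar at the small
per-condition sample sizes of a field study (34–45 here) and coincides with
⌊10√n⌋ at n = 400.

Edge weights: at the selected λ the neighborhoods are refitted on the full
data; the symmetrized coefficient is the larger-magnitude member of
{B_ij, B_ji} (configurable to the mean), the weight is that coefficient on
the refitted adjacency, and the sign is the weight's sign.  These are
penalized-regression coefficients — useful for sign and rough magnitude,
not comparable to correlation coefficients.  Orphan nodes are removed, but
the full post-filter node pool is retained in metadata because the null
models draw from it.

### Properties, paired comparison, null models

Per network we report node/edge counts by kingdom pairing (ff/fb/bb),
density (edges over possible node pairs), fb density (fb edges over
connected-fungi × connected-bacteria pairs), and "longest path", computed
as the unweighted diameter of the largest connected component — a true
longest simple path is NP-hard and the diameter is what standard graph
libraries provide; outputs label the quantity accordingly.  Snow-free vs
snow-covered properties are compared with the Wilcoxon signed-rank test on
the 25 per-filter-pair differences (zero differences dropped; an unpaired
Kruskal–Wallis variant is available).

Null models draw uniformly random graphs on the filtered dataset's node
pool with exactly the observed edge count, 999 replicates per network, and
record reference distributions for the ff/fb/bb edge-type fractions and —
drawing one random network per condition — for the number of shared edges.
The fb-restricted variant draws only fungal–bacterial pairs among each
network's connected nodes; its smaller candidate pool makes chance sharing
higher, answering whether fb partners are retained or swapped between
seasons.  Empirical p-values use the add-one rule (1 + #{rep ≥ obs})/(1 + R)
and are a convenience on top of the distributional comparison.

### Consensus, GLMs

An association is *frequent* in a condition when it appears in more than
five of that condition's 25 networks (≥ 6; counts are per condition, never
pooled).  Frequent fb associations are partitioned by condition
specificity, summarized at genus level (both partners annotated, genus
pairs supported by ≥ 2 ASV-level associations, majority consensus sign with
ties reported as "mixed"), and — on synthetic data — scored against the
planted truth.

Two GLMs close the analysis.  A binomial GLM (logit link) fits the
per-network (n_pos, n_neg) counts on condition, fitted across all 50
networks at once; its fitted values are the odds of a positive association
per season, and complete separation triggers a flagged Haldane–Anscombe
(+0.5) refit.  Per filter pair, a Poisson GLM (log link) models the number
of fb edges per fungal phylum and condition; the model is chosen by
bidirectional stepwise AIC from the main-effects model over the hierarchical
space {phylum, condition, phylum×condition}, stopping when no single move
lowers the AIC, with ties resolved toward the smaller model.  Phyla with
zero fb edges in both conditions of a pair are dropped (log-link
degeneracy).

### Community statistics

Richness counts detected ASVs; Shannon diversity uses the natural log (the
scale on which soil bacterial communities of ~1,000 ASVs land near 6).
Composition tests use Bray–Curtis dissimilarity and a single-factor
permutational ANOVA implemented on the distance decomposition
(R² = SS_between/SS_total, free label permutation, add-one p-value); the
two study factors are tested as separate single-factor runs because
marginal multi-factor behavior is not needed for the synthetic design.
Kruskal–Wallis omnibus tests are followed by Dunn's rank z-tests
(tie-corrected, Holm-adjusted) only when the omnibus is significant;
Dunn's test is implemented in-package since no installed library provides
it.

## Synthetic data generator

The generator emulates the structure of the motivating study design:

- **Design**: 79 samples in six location × condition groups
  (13/12, 19/14, 13/8), three locations, two snow-cover conditions.
- **Depths**: truncated-normal sequencing depth per sample, 6,500 ± 2,320
  reads (fungi) and 60,000 ± 16,000 (bacteria), floored at 100 so CLR rows
  never degenerate; row sums equal the drawn depths exactly.
- **Richness**: 150 fungal and 600 bacterial ASVs by default — scaled down
  ~10× and ~45× from real soil panels while preserving the fungi ≪ bacteria
  asymmetry, keeping a 50-network grid run at desk scale.
- **Occupancy**: per-ASV detection probability q ~ Beta(0.25, 1), so the
  median ASV occurs in ~6 of 79 samples (real core ASVs sit at median 8–9)
  and a minority of prevalent ASVs survives the strict thresholds.  Core
  ASVs (15 fungal, 60 bacterial) get q ≥ 0.35 and are forced to appear in
  at least one sample per location (by moving a single read within a
  sample when multinomial sampling would lose them, so depths stay exact).
- **Associations**: a latent Gaussian copula.  Every ASV has a standard
  normal latent; each planted edge sets correlation ±ρ between one fungal
  and one bacterial latent in the samples of its condition ("both" edges
  everywhere).  Latents map through log-normal abundance profiles
  (σ = 1, location-independent), are masked by occupancy, and counts are
  multinomial at the drawn depth.  The default truth plants 10 fb edges at
  ρ = 0.7 (4 season-independent, 3 snow-free-only, 3 snow-covered-only,
  7 positive / 3 negative) on always-present core taxa — real inferred
  associations are between prevalent ASVs, and any absence decouples a pair
  from its latent correlation.  A planted edge whose endpoints never
  co-occur in its active condition is annotated "weakly identifiable" with
  a warning.

The copula was chosen over Dirichlet-multinomial mixing because the
downstream estimator works on CLR-space partial correlations: latent
correlations give controllable, sign-preserving planted effects.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: spatial autocorrelation within plots, phylogenetic
signal in abundances, indirect association chains (all unplanted latents
are independent), seasonal shifts of overall composition, and sequencing
artifacts (chimeras, tag switching).  One consequence of the compositional
count model is worth stating explicitly: closure noise (the per-kingdom
random log-total) attenuates a planted latent ρ to a CLR-space correlation
of roughly 0.75ρ, so a ρ = 0.7 edge is observed at r ≈ 0.5–0.6.

## Validation results and a known limitation

On the default design the pipeline recovers planted edges well at the
ensemble level: recall of planted fb edges among frequent associations is
typically 0.7–1.0 per condition, recovered signs match the planted signs
essentially always, and condition-specific edges land in their correct
exclusivity partition in ~90% of edge × seed instances.

Precision against the planted truth is, by contrast, low (≈ 0.01–0.05) —
and this is a property of the sampling regime, not a fixable parameter.
With 34–45 samples per condition, spurious partial correlations among the
~10⁴ prevalent cross-kingdom pairs reach |r| ≈ 0.55, the same magnitude as
an attenuated ρ = 0.7 planted edge, so no penalty level separates signal
from noise: at the λ where a network keeps most planted edges it also keeps
hundreds of noise edges, and because all 25 networks of a condition share
the same samples, those noise edges recur across the grid and survive the
frequency filter.  Raising the StARS β would not help (the noise is stable,
not unstable), and lowering it far enough to exclude the noise also
excludes most planted edges while collapsing network density two orders of
magnitude below the empirically observed ~2% regime.  The package therefore
keeps the conventional β = 0.05 and reports precision honestly; frequent
associations from data of this size should be read as "reproducible across
filtering choices", not "likely real".

## Problem sizes and determinism

Default full runs (synthetic generation → 25-pair grid → 50 StARS networks
→ 999-replicate nulls → consensus → GLMs) take about a minute on one CPU;
the test suite exercises recovery on three full-design seeds and the
specificity partition on twenty, and the GLM operating characteristics on
fifty simulated ensembles.  All randomness flows from one master seed
through named per-stage streams (BLAKE2 hash of stage + network identity,
31-bit), so a rerun with the same configuration is bit-identical; the run
manifest records every output file's SHA-256 alongside the seeds used.

Numerical notes: the neighborhood lasso is an active-set coordinate descent
on the Gram matrix (numba-compiled, tolerance 1e-6 on coefficient changes,
KKT screening with warm starts along the path) and agrees with
scikit-learn's `lasso_path` to solver tolerance — the test suite asserts
the dual-route agreement.  Constant CLR columns are standardized to zero
and can never enter a neighborhood.  Zero-variance degenerate cases
(all-identical samples in PERMANOVA, empty networks in the nulls, phyla
with all-zero counts in the Poisson model) return defined values or named
errors rather than NaNs.
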