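# Methods

This note documents the statistical procedures, the defaults and why they were
chosen, the generative model behind the synthetic cohorts, and what the test
suite does and does not establish about real data.

## Data model and conventions

The substrate is a genus × sample matrix (`AbundanceTable`) in one of three
modes: raw `counts`, `relative` (columns sum to 1 ± 1e-9), or `scaled`
(arbitrary nonnegative values, e.g. total-sum-scaled to 10⁶). All abundance
thresholds are stored as fractions — 0.01 % is 1e-4, 1 % is 1e-2 — and only
rendered as percentages at the I/O boundary; this removes an entire class of
percent/fraction scale bugs in the screen. Group "content" is the arithmetic
mean of per-sample relative abundances over a stratum, not the pooled-count
fraction: the mean is robust to unequal sequencing depth, and a pooled mode
can be obtained by aggregating counts first. Unclassified taxa are retained
by default so compositions stay closed; dropping them renormalizes and is
opt-in.

## Alpha diversity

* **Shannon** uses the natural log by default (values for genus-level oral
  and nasal communities then fall in the familiar 2–4 range); base 2 is
  selectable.
* **Chao1** is the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), defined
  even when no doubletons exist; the classic F₁²/(2F₂) variant is selectable
  and errors when F₂ = 0.
* **ACE** uses the conventional rare cutoff of 10. When the coverage
  estimate degenerates (C_ace = 0 because every rare genus is a singleton,
  or N_rare ≤ 1) the bias-corrected Chao1 value is substituted and a flag is
  recorded (`ace_fallback`), rather than raising or returning infinity.
* Indices are computed on raw counts, with no rarefaction. Rarefying to the
  minimum depth mostly subtracts information at these sample sizes; the
  simulator draws equal depths anyway, so the suite would not distinguish
  the two choices.

Group contrasts use Welch's t for two groups and one-way ANOVA for three or
more, matching how two-group (children) and three-group (adolescent) designs
are conventionally tested. Identical constant groups are reported as
statistic 0, p = 1 rather than NaN.

## Beta diversity and ordination

Bray–Curtis dissimilarity d(j,k) = Σ|xᵢⱼ − xᵢₖ| / Σ(xᵢⱼ + xᵢₖ) is delegated
to scipy; PCoA is the Gower double-centring B = −½ J D² J followed by a
symmetric eigendecomposition. Axes come only from positive eigenvalues
(scaled by √λ, descending); negative eigenvalues — which Bray–Curtis matrices
can produce because they are not Euclidean — are discarded and their count
reported, with no Lingoes/Cailliez correction: the simplest defensible
default, and the count makes the information loss visible. Axis signs are
arbitrary, so tests compare only distances and magnitudes. Explained
proportions are taken over the positive spectrum and therefore sum to ≤ 1.

## Biomarker scan (Kruskal–Wallis + LDA effect size)

Samples of the two strata are total-sum-scaled to 10⁶; each genus is screened
with a Kruskal–Wallis test (average ranks, tie correction, p from χ² with
g−1 df) at α = 0.05, without multiple-testing correction — the screen is
deliberately the conventional raw rule. An exact-enumeration p (all label
assignments) is available for ≤ 12 observations, where the χ² approximation
is visibly off.

KW survivors are scored jointly with a bootstrapped two-class LDA effect
size: for each of 30 bootstraps, ⌈2n/3⌉ samples are drawn (redrawn up to 100
times if a class drops below 2), the pooled within-class covariance is shrunk
10 % toward its diagonal (plus a 1e-10-scale ridge, so the axis exists even
with degenerate variance), and feature f receives
e_b(f) = (|w_f · (w·(m₁−m₂))| + |m₁(f)−m₂(f)|)/2 for the unit-norm
discriminant axis w. The final score is log₁₀(1 + mean_b e_b(f)); a genus
passes at score > 2 and KW p < 0.05. These constants (30 bootstraps, 2/3
subsampling, 10⁶ scale, log₁₀(1+·)) reproduce the conventional "LDA score
2–6" magnitude that the threshold of 2 presupposes, and every one of them is
exposed in `LefseParams`. There is no subclass (within-group Wilcoxon) stage
because the study design has none; multi-group designs are run as all
pairwise two-group scans.

**A property worth knowing:** a score of 2 corresponds to an absolute
abundance difference of roughly 1e-4 on the fraction scale. Under realistic
between-subject variability (CV ≳ 10 %), any abundant genus that passes the
KW gate by chance will exceed that floor, so the score threshold does not by
itself control false positives for abundant taxa — an intrinsic property of
this class of procedure, not an implementation artifact. The two-group
fixture used to validate the scan (below) is therefore built with
within-group noise (CV 0.3 %) an order of magnitude below the effect floor,
so that its recovery and specificity checks exercise the decision rule
rather than this statistical ceiling. Conclusions about false-positive rates
on real cohorts should come from permutation analyses, not from the fixture.

## Translocation screen

The three conditions are evaluated on group-mean relative abundances, with
every intermediate quantity (the three means, c1/c2/c3 booleans) reported
per genus, and the selected set under the conjunctive reading of the rules
(`combination_mode="all"`; `"any"` exists for sensitivity analysis). The
module is fully deterministic.

Condition 1's "not found" admits two readings. The strict default takes a
detection floor of 0 — literal absence from the healthy target niche. A
relaxed mode raises the floor to the 0.01 % minor threshold, because for
genera present at trace level the strict reading of condition 1 conflicts
with condition 2's "< 0.01 %" (a genus at 0.005 % fails c1 but passes c2).
The pipeline reports both modes side by side. The oral reference list ships
as an editable text file containing twelve genera widely reported as
high-rate oral colonizers (Streptococcus, Gemella, Veillonella, Prevotella,
Alloprevotella, Neisseria, Rothia, Actinomyces, Haemophilus, Granulicatella,
Atopobium, Porphyromonas); a nasal counterpart backs the mirrored screen.

Useful monotonicities, enforced by tests: raising the dominance threshold or
shrinking the reference list can only shrink the selected set, and screening
oral→nasal equals screening nasal→oral on the same data with niche labels
swapped.

## Co-occurrence networks

Edges join genus pairs with Spearman |ρ| ≥ 0.6 and two-sided p < 0.05
(t approximation, n−2 df) on relative abundances within one stratum. The
absolute-value rule is used because negative edges are biologically and
visually meaningful; a signed-only mode is selectable. Genera must be
present in ≥ 20 % of the stratum's samples with nonzero variance — an added
filter (configurable) that removes all-tied rank vectors for which ρ is
undefined. No multiple-testing correction is applied to edge p-values.
Betweenness is computed on the unweighted kept-edge graph, normalized to
[0, 1]; hubs are ranked by betweenness then degree.

## Synthetic cohorts

The generator is a Dirichlet-multinomial: per sample, genus proportions are
drawn from a Dirichlet with mean equal to the stratum profile and total
concentration 200 (a genus at ~3 % abundance then has ~40 % CV between
subjects — realistic overdispersion for 16S genus tables), and counts from a
multinomial at 5,000 reads (typical pyrosequencing depth). Stratum sizes
default to the five-cohort paired design (10/10/10/5/10 subjects, one oral
and one nasal sample each).

Profiles encode the niche structure: oral communities are dominated by the
twelve reference oral colonizers (Streptococcus 15 % down to Porphyromonas
2 %), nasal communities by age-specific dominants (children:
Pseudomonas > Dolosigranulum > Moraxella; adolescents:
Pseudomonas > Serratia > Stenotrophomonas), with forty shared low-abundance
background genera closing each composition. Oral colonizers are exactly
absent from healthy nasal profiles, so the strict detection floor is
meaningful.

Case (CP and postoperative) nasal profiles add leakage λ × (oral mean) for
the seven planted translocators and renormalize. The default λ = 1
reflects a strong oronasal exchange — consistent with an oral dominant
becoming a top-3 nasal genus in unrepaired cases — and places the smallest
translocator at ~2.6 % expected case-nasal abundance, more than 3 standard
errors above the 1 % dominance threshold in the worst stratum (n = 5 CP
adolescents), so a default cohort recovers the planted set with
per-seed failure probability below 1 %. λ = 0 is the null: case and healthy
nasal distributions coincide and the screen must select nothing. A
`diversity_shift` fraction (default 0.05) additionally mixes case nasal
profiles toward the uniform distribution over nasal-resident genera, which
provably (by concavity of entropy) and empirically raises expected nasal
Shannon diversity, mirroring the richer case nasal communities. Optional
correlation blocks multiply a genus subset by a shared log-normal factor per
sample, planting positive rank correlations for network recovery tests.

`simulate_two_group` is the separate two-stratum biomarker fixture: 55
uniform background genera plus 5 planted features at 0.5 % abundance in the
enriched group and a 10-fold lower level in the control group, multiplicative
log-normal noise with CV 0.3 % (see the biomarker section for why the noise
is deliberately small), and `fold=1` as the exchangeable null.

What the generator does **not** emulate: taxonomic misclassification,
sequencing error, depth variation between samples, subject-level random
effects, zero-inflation beyond the multinomial, or compositional interactions
other than closure. Passing tests therefore demonstrate that the algorithms
recover planted structure under the stated model, not that the screen's
thresholds are optimal for any particular real cohort.

## Pipeline and reproducibility

`run_study` composes the stages over the hard-wired study comparisons
(children: healthy vs CP; adolescents: all three pairs; screens for CP
children, CP adolescents, postoperative adolescents), skipping any comparison
whose stratum is missing with a recorded warning. Every stochastic stage
(the LDA bootstrap) receives a seed derived from the run seed via
`numpy.random.SeedSequence` spawning, and the per-run seed is recorded in the
report. Outputs are pure functions of (inputs, parameters, seed); the
manifest stores input checksums so a run can be replayed byte for byte.

Problem sizes used throughout the suite and the acceptance script — 60-genus
tables, 90-sample cohorts, 20 repeated seeds per recovery estimate, 2,000
features for null calibration — were chosen as the smallest sizes at which
the planted-recovery margins computed above hold with comfortable
probability; they keep any single check under a couple of minutes on one
core.

## Known limitations

* The KW + LDA scan's false-positive behaviour for abundant taxa under
  realistic noise is an intrinsic ceiling (discussed above).
* PCoA reports, but does not correct, negative eigenvalues.
* The exact KW permutation p is exponential in sample count and restricted
  to ≤ 12 observations.
* The translocation screen applies thresholds to group means only;
  per-sample prevalence does not enter condition 1, and results can differ
  from a prevalence-based reading for small strata.
* Edge p-values use the t approximation; at n = 5–10 samples per stratum it
  is anti-conservative in the tails relative to the exact permutation null.
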