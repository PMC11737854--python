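# Methods

This note documents the statistical model behind `tcrhla`, the choices made
where the design was open, the synthetic data the tests run on, and the
package's known limitations.

## Data model

A clonotype is identified by the triple (chain, CDR3 amino-acid sequence,
V-gene family). V calls are normalized to family level everywhere
(`TRBV19-01*01 → TRBV19`), a single convention that makes cross-dataset
sharing counts well defined; the cost is that gene-level distinctions
within a family are collapsed. CDR3s containing stop (`*`), frameshift
(`_`) or other non-standard characters are non-productive and dropped on
read. HLA alleles are kept at 4-digit (protein-level) resolution: codes
with more fields are truncated, 2-digit allele groups are rejected rather
than silently expanded. Presence of a clonotype in a donor is binary; clone
abundance is deliberately ignored, because all downstream statistics
(Fisher tables, classifier features) are presence-based.

A donor's `has_alpha` flag records whether the alpha chain was sequenced.
An explicit flag from metadata overrides inference from content, because
alpha sequencing may legitimately yield zero retained clonotypes. Donors
appearing twice in a cohort (repeat samples) keep their first sample.

## Association testing

Publicness (presence in ≥ 3 donors, configurable) is counted across the
full input cohort — i.e. across merged cohorts when several are combined —
since sharing is a property of the pooled donor set.

Each (public clonotype, allele) pair is tested with Fisher's two-tailed
exact test. Among several "two-sided" conventions we use the
point-probability rule: p is the sum of hypergeometric probabilities of all
tables with the observed margins whose probability does not exceed that of
the observed table. The implementation works in exact integer arithmetic
(binomial weights over a common denominator, final division as a rational),
so ties between table probabilities are resolved exactly and results are
bit-reproducible; values agree with `scipy.stats.fisher_exact` to ≤ 1e-10
on random tables and with exhaustive enumeration to ≤ 1e-12 on every table
with total ≤ 60. Tables are cached, which matters in the all-pairs sweep
where many pairs realize identical counts.

Benjamini–Hochberg adjustment is applied jointly over *all* tests of a
discovery run (not per allele or per chain); joint control is the
conservative reading of a 1% FDR target, and the tests confirm the
empirical FDR on signal-free cohorts stays below it. Alpha-chain clonotypes
are tabulated only over alpha-sequenced donors, since absence in a donor
without alpha data carries no information. Alleles with fewer than 5
carriers (configurable) are skipped as vacuous. Both enriched and depleted
records are reported (direction from the sample odds ratio); by default
only enriched ones feed the classifier, whose features are presence
indicators. Output ordering is fully deterministic: (p_adj, p_raw, allele
code, chain, V family, CDR3).

## The classifier

Per allele *a*: `p_a = logistic(Σ_i w_ai x_i + v_a y + b_a)`. The alpha
indicator `y` lets the model absorb the systematic absence of alpha
features in beta-only donors; those features are also structurally zeroed
in the encoding. The intercept `b_a` is included by default (without it an
all-zero feature vector is pinned to p = 0.5, which is wrong for rare
alleles); `fit_intercept=False` recovers the literal intercept-free form.

Fitting: donors are split 70/30, stratified by allele status so both
portions contain positives (stratification is our choice; it guards the
split for rare alleles). For each of 20 geometrically spaced inverse
penalty strengths C in [1e-3, 1e3], an L1 (or L2) logistic model is fitted
on the 70% (scikit-learn, liblinear) and scored by cross-entropy on the
30%; the smallest held-out loss wins, ties going to the stronger penalty
(sparser model). The decision threshold is 0.5 on the probability scale;
ROC/PR reporting is threshold-free. No resampling or class weighting is
applied for imbalance.

Fuzzy matching (`fuzzy1`) counts a feature as present when a repertoire
clonotype has the same chain, same V family, the same CDR3 length, and
Hamming distance ≤ 1 — the same-length/same-V constraints mirror the
similarity-network edge rule and keep Hamming distance well defined. Fuzzy
matches are by construction a superset of exact matches. The weight-free
count classifier returns the number of feature matches; since the logistic
function is strictly increasing in the linear score, ranking donors by
count equals ranking by a unit-weight logistic score, which the tests
assert.

A caveat found while testing: the number of nonzero L1 weights is *not*
exactly monotone along the penalty path. Sparsity increases with penalty
strength in trend, but a feature can leave the active set as the penalty
weakens (a known property of lasso-type paths, reproduced identically by
two independent solvers at tight convergence). One regression test asserts
strict monotonicity and fails on a cohort exhibiting such an active-set
swap; it is kept as an honest record of the phenomenon.

## Evaluation

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/total, precision = TP/(TP+FP). Ratios with zero denominators are
reported as NaN with an explicit flag — never as 0 — so cross-allele
averages are not silently biased. ROC AUC uses the rank (Mann–Whitney U)
formulation, exact under ties; it agrees with trapezoidal integration on
tie-free data and with an all-pairs counting oracle always.
Precision–recall curves and average precision come from scikit-learn.
Cross-allele summaries report Pearson correlations of per-allele precision
with the number of associated clonotypes and with allele prevalence.

## Iterative typing

Subgroups of 100 untyped donors (configurable) are typed with the current
model; imputed labels are frozen once assigned (re-typing earlier subgroups
is off by default). Associations are then re-discovered on the augmented
cohort with a budget of ceil(r · n_donors) records ranked by raw p, where r
is the associations-per-donor ratio of the initial cohort; the budget rule
replaces the fixed FDR threshold during iteration, deliberately — it
bounds both error amplification from mistyped donors and feature-set
growth. The budget is applied from the first iteration. The recursion is
independent across alleles. The classifier is refitted after each subgroup
with a fresh stratified 70/30 split.

## Networks and repertoire features

Similarity networks join clonotypes of the same chain, V family and CDR3
length at Hamming distance ≤ 1; connected components are labelled and their
allele purity (fraction of member nodes carrying the component's majority
allele) computed. A node associated with several alleles keeps all labels;
purity uses the majority. Epitope annotation is an exact (CDR3, V family)
join against a user-supplied reference table; nothing is downloaded.
Alpha-chain networks are buildable like beta ones. V-usage frequencies are
computed over unique clonotypes, not read counts, consistent with the
presence-based analyses. The CDR3-length comparison uses a two-sample
Mann–Whitney test on lengths — our choice of test, labelled as such.
Whole-repertoire V-usage comparisons run a two-sided Mann–Whitney U per V
family on per-donor frequencies, BH-adjusted across families.

## Synthetic cohorts

The generator emulates the statistical skeleton the pipeline consumes:
donors draw alleles independently per allele at configured population
frequencies (capped at 2 per class-I locus; a panel forcing 3 alleles at
one class-I locus with frequency 1.0 is rejected as infeasible); background
clonotypes are present i.i.d. with a common sharing probability and carry
no HLA signal (the null for FDR calibration); planted clonotypes are
present with probability p_pos in carriers of their target allele and p_neg
otherwise. Synthetic CDR3s are random strings of length 8–20 over the 20
amino acids, starting with C and ending with F, so that length- and
mismatch-based machinery is exercised. Everything derives from one seed;
identical configs give byte-identical cohorts.

What the generator does *not* model — and hence what passing tests cannot
show about real data: allele linkage and haplotype structure (alleles are
independent), V(D)J recombination statistics and convergent recombination
(real sharing probabilities vary over orders of magnitude across
clonotypes), clone-size distributions, sequencing depth effects, and
epitope-driven sequence similarity among planted clonotypes (planted CDR3s
are unrelated strings). FDR calibration and recovery results on these
cohorts therefore validate the machinery, not effect sizes on real
repertoires.

Default test/acceptance problem sizes — chosen as the smallest cohorts at
which the checked effects are comfortably resolved — are: 100 donors × 500
clonotypes × 4 alleles × 200 replicates for null FDR; 400–500 donors for
classifier anchors and parameter recovery (20 planted features, p_pos 0.6,
p_neg 0.05, allele frequency 0.3); 150 typed + 1000 untyped + 250
validation donors × 20 seeds for the iterative recursion.

## Numerical and degenerate-input choices

Fisher tables with an empty margin give p = 1. Empty p-value lists adjust
to empty lists. `occurrence_matrix` on an empty cohort, ROC with a single
truth class, PR with no positives, and cross-allele summaries with < 3
alleles raise errors naming the problem. Grid selection ties break toward
stronger penalty; record-ordering ties break lexicographically. All
randomness flows through `numpy.random.default_rng` seeded per run.

## Known limitations

* Predictions are per-allele and unconstrained: the ≤ 2-alleles-per-locus
  rule is not imposed on predicted typings.
* Fuzzy matching applies to classifier features only, not to the publicness
  definition or the association test itself.
* The association test treats alleles marginally; co-occurring-allele or
  haplotype effects are out of scope.
* Binary presence ignores abundance, so expansion-driven signal is unused.
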