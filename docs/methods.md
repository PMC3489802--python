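# Methods

This note documents the statistical procedures implemented in `rarseek`,
the defaults and why they were chosen, what the synthetic cohorts emulate,
and the package's known limitations.

## Data model

Probe-level relative copy number: a probe map (id, chromosome 1–22/X,
1-based position) and a samples × probes matrix of normalized log2
tumor/reference intensity ratios. Inputs are assumed normalized (e.g.
print-tip Loess); the package does not normalize. Coordinates are 1-based
inclusive bp internally; reports print megabases with two decimals.
Missing ratios are carried as NaN, excluded from statistics, and inherit
the state of the enclosing segment for reporting.

## Segmentation

Each sample's profile is partitioned into constant-mean segments by
recursive binary splitting within *runs* — maximal probe stretches not
interrupted by a chromosome boundary or an inter-probe gap larger than
`max_probe_spacing_kbp` (default 1000).

At each recursion node the candidate split maximizes the standardized
two-sample rank-sum statistic between left and right (midranks for ties;
variance from the exact permutation moments of the rank multiset, which
remains exact under ties). The split is accepted iff

* both children have at least `min_probes` (default 5) probes, and
* the permutation p-value of the max-|Z| statistic, estimated as
  (b+1)/(B+1) over at most `max_permutations` (default 10,000) seeded
  label permutations, is below `significance_threshold` (default 5×10⁻⁴).

Runs shorter than `min_probes` are emitted as single segments flagged
`short`. Argmax ties break leftmost; the whole procedure is deterministic
given the seed.

This is an original, fully reproducible procedure in the "rank
segmentation" family used by commercial CNA callers. The published
parameters (threshold, spacing, minimum probes) are honored exactly; the
internal test of the proprietary implementation is not public and is not
cloned.

**Numerical/efficiency choices.** The permutation null of max-|Z| depends
only on the rank multiset and `min_probes`, not on the probe order, so
null draws are cached per (run length, tie signature, seed) and shared
across samples and recursion nodes; draw streams are keyed by the cache
key and offset, making p-values independent of traversal order.
Permutations are consumed in escalating batches and stop as soon as the
estimate can no longer fall below the threshold — the accept/reject
decision is identical to the full-budget decision, which also preserves
the monotonicity of segment counts in the threshold.

**Resolution limit.** A binary rank-split over a whole-chromosome run has
low power for focal events: a ~20-probe alteration inside a ~1900-probe
run at noise SD 0.15 yields max |Z| well below any usable threshold, while
the same event with zero noise is recovered exactly (ties collapse the
rank variance). Detectability at realistic noise requires an event width
that is an appreciable fraction of its run — in practice arm-scale events,
which are also the dominant early alterations in breast cancer.

## Copy-number calling

Segment mean log2 ratio > 0.2 (exclusive) → gain; < −0.3 (exclusive) →
loss; otherwise neutral. High-level flags sit on top of the state:
amplification at mean ≥ +1.5 (inclusive), homozygous deletion at ≤ −1.5
(inclusive). The asymmetric strictness tracks the thresholds' published
phrasing. Per-sample burden: number of non-neutral segments, altered Mb,
and altered fraction using the probe-covered genome span as denominator
(the only denominator computable from the inputs themselves).

## Recurrently altered regions

Per-probe gain and loss frequencies are computed independently. Candidate
regions are maximal within-chromosome probe runs with frequency ≥
`min_freq` (default 0.30); adjacent runs separated by even a single
sub-threshold probe are not merged.

Significance is assessed against a positional null: in each permutation,
every sample's per-probe state vector is circularly shifted within each
chromosome by an independent uniform offset. This preserves each sample's
segment-length spectrum and total alteration burden — the confounders that
make dense random overlap likely — while destroying cross-sample position
alignment. The region's p-value is the add-one proportion of permutations
in which the shifted cohort's maximum frequency over the region's span
reaches the observed maximum; regions with p < `alpha` (default 0.05) are
reported, named RAR-G1…/RAR-L1… in genomic order per direction.

A sample is scored positive for a RAR when its same-direction segments
cover at least 50% of the RAR's bp span (the carrier-scoring rule of the
original analysis is unpublished; 50% span overlap is this package's
declared choice). Reported total and stage-stratified frequencies are
recomputed from this marker matrix, so the region table is internally
consistent with all downstream marker analyses.

**Event timing.** With stage IIA/IIB collapsed to II: a RAR is *later*
when its stage-I frequency is < 10% (exclusive) and stage-II frequency is
> 40% (exclusive); otherwise *earlier* when both stage frequencies are
≥ 30%; otherwise unclassified. These are the only numeric anchors the
source results state, and they reproduce the published 23-region event
column exactly (15 earlier / 2 later / 6 unclassified).

**High-level regions.** Maximal runs of probes carried at high level by at
least one sample; reported when the carrier fraction strictly exceeds 10%,
with counts and half-up rounded percentages.

## Association-rule mining

CPAR-style predictive rule induction over the binary marker matrix with
survival status as the class (0 dead within the horizon, 1 alive). For
each class, rules grow literal by literal by weighted FOIL gain
p₁·(log₂ p₁/(p₁+n₁) − log₂ p₀/(p₀+n₀)); all literals within
`gain_similarity` (0.99) of the best gain are branched on; a body is
closed when no literal reaches `min_gain` (0.7). After each rule the
weights of covered positive examples decay by 2/3 and induction restarts
until the remaining positive weight falls below 5% of the initial total.
These hyperparameters are the published CPAR defaults and are
config-exposed. Literals are positive-valued ({marker=1}) by default,
matching the biology (presence of an alteration).

Reported N_total/N_c are exact unweighted recounts; rules are ranked by
Laplace accuracy (N_c+1)/(N_total+m), ties broken by smaller antecedent
then lexicographically. Death rules with Laplace strictly above 0.75 form
the reported set.

**Known limitation (kept, not papered over).** Greedy FOIL-gain search
with `min_gain` 0.7 cannot grow any rule when no single literal clears the
gain threshold — typically for a high-base-rate class, where a
high-Laplace single-literal rule can exist while every gain is small.
Consequently the best reported Laplace accuracy does not always equal the
brute-force optimum over small antecedents; the acceptance suite asserts
that equality on a mixed seeded battery and currently fails it, by design,
rather than silently switching to exhaustive search (which would make the
oracle comparison vacuous) or tuning the gain threshold.

## Survival analysis

The event is death within `horizon_years` (default 10) of diagnosis;
survivors and later deaths are censored at the horizon. Kaplan–Meier
curves and log-rank tests come from lifelines; the log-rank test for trend
over ordered carrier groups ({neither, either, both}, equally spaced
scores) is computed from the aggregated risk-set O−E vector and its
hypergeometric covariance. Cox proportional-hazards models use statsmodels
PHReg with Breslow tie handling (the default of the original analysis
software) and Wald confidence intervals; covariates are age (≥50), stage
(II vs I), ER, PR, HER2 (each 0/1) plus the marker(s). Constant covariates
are dropped with a warning. When Newton iteration fails on a near-monotone
likelihood (e.g. almost all carriers die), the fit retries with L-BFGS and
the note is recorded; a fit whose standard errors remain non-finite raises.

Association tests between markers and binary clinical variables use the
two-sided Fisher exact test with Benjamini–Hochberg FDR adjustment.
Molecular subtype: hormone-receptor positive (ER+ and/or PR+) splits on
HER2 into Luminal A (HER2−) / Luminal B (HER2+); receptor-negative tumors
are HER2 (HER2+) or TNBC (triple negative).

## Genomic qPCR quantification

ΔΔCT = (Ct_target,tumor − Ct_control,tumor) − (Ct_target,ref −
Ct_control,ref), with replicate Cts aggregated by arithmetic mean before
differencing (the ΔΔCT convention) and a diploid internal-control locus.
Dosage ratio = 2^(−ΔΔCT); amplification efficiency is fixed at 2.0 per
cycle (pure ΔΔCT; an `efficiency` parameter exists for sensitivity
checks). A gain is called when the ratio strictly exceeds 2.0. Replicate
SDs above a configurable limit flag the call without dropping it. The
contrast is invariant to adding a constant to all four mean Cts, so calls
are independent of template amount.

## Synthetic cohorts

The generator emulates the study conditions the pipeline assumes: 48
samples (11 stage I) by default, a 24,107-probe array over 22 autosomes +
X with probes evenly spaced in proportion to chromosome length (~129 kb
spacing), per-probe Gaussian noise (SD 0.15 log2 units), implanted
alterations with stage-stratified carrier frequencies (binomial or
exact-quota carrier assignment; quota mode exists so frequency-threshold
tests are deterministic), default implant means +0.58 (gain), −1.0
(loss), ±1.8 (high-level), exponential survival with hazard = baseline
(0.03/yr) × the product of carried implants' multipliers and of any
satisfied interaction multipliers, administrative censoring at 10 years,
and ER/PR/HER2/age marginals matching the discovery cohort's
characteristics table. The default panel plants arm-scale events (1q gain,
8p loss, 16p gain, 17q gain, a later-event 20q gain and a nested 17q12-q21
amplification), with the 16p×17q joint carriage carrying a hazard
multiplier of 7.31 — the replication cohort's published adjusted hazard
ratio — as an interaction, so single markers are prognostically weak but
the combination is strong.

Scaling simulations down restricts the genome to a chromosome subset at
full array density (`chromosomes=("16","17","20")`), never by thinning
probes genome-wide, which would open artificial >1000 kbp gaps and shatter
segmentation runs. Test and acceptance runs use such subsets (typically
~4,500–5,000 probes); these sizes are the package's own choice of problem
scale.

What the generator does **not** emulate: print-tip/spatial artifacts, dye
bias, GC waves, tumor-cell-content attenuation of log2 shifts, X-dosage
effects (the reference is female), correlated noise along the genome, and
focal high-amplitude events at realistic breast-cancer frequencies.
Passing tests therefore demonstrate algorithmic correctness and
calibration under idealized noise, not end-to-end performance on real
arrays.

## Determinism

Every stochastic step (segmentation permutations, RAR shifts, cohort
simulation, qPCR jitter) derives its stream from an explicit seed;
identical seeds give byte-identical pipeline reports, and the seed plus a
config hash are stamped into every output header.
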