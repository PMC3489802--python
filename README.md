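# rarseek

Recurrently altered region (RAR) discovery and prognosis analysis for
array-CGH copy-number profiles of tumor cohorts.

`rarseek` re-implements, as a tested and reusable pipeline, the analysis
used to find copy-number markers of poor prognosis in early-stage breast
cancer: per-sample segmentation of log2 tumor/reference ratios, categorical
copy-number calling, cohort-level delineation of recurrently altered
regions with a permutation null, stage-stratified classification of regions
as earlier or later progression events, predictive association-rule mining
of marker combinations against survival status, and Kaplan–Meier/log-rank/
Cox survival analysis of single and combined markers — plus ΔΔCT genomic
qPCR quantification for replication cohorts and a synthetic-cohort
generator so that every stage is testable without patient data.

## Who it is for

Cancer-genomics analysts working with probe-level relative copy-number data
(array-CGH or any log2-ratio platform) who want a transparent, seedable,
end-to-end reimplementation of the classic "segment → call → recurrent
region → prognostic marker" workflow, including its statistics.

## The methods in brief

- **Segmentation.** Within each run of probes (broken at chromosome
  boundaries and at gaps > 1000 kbp), recursive binary splitting on the
  two-sample Wilcoxon rank-sum statistic: the split maximizing the
  standardized rank sum |Z| is accepted iff its within-run permutation
  p-value (p = (b+1)/(B+1), B ≤ 10,000, seeded) is below 5×10⁻⁴ and both
  children keep ≥ 5 probes.
- **Calling.** Segment mean log2 ratio > 0.2 → gain, < −0.3 → loss;
  ≥ +1.5 → high-level amplification, ≤ −1.5 → homozygous deletion.
- **RARs.** Maximal probe runs where ≥ 30% of samples carry a
  same-direction CNA, kept at p < 0.05 under a null that circularly shifts
  each sample's call states within each chromosome (preserving its
  segment-length spectrum). A RAR is an *earlier* event when its carrier
  frequency is ≥ 30% in both stage I and stage II, a *later* event when
  < 10% in stage I but > 40% in stage II.
- **Rule mining.** CPAR-style greedy FOIL-gain rule induction over binary
  RAR markers vs survival status (0 dead / 1 alive), ranked by Laplace
  accuracy (N_c + 1)/(N_total + m); death rules with Laplace > 0.75 are
  reported.
- **Survival.** Kaplan–Meier curves, log-rank tests (including a test for
  trend over {neither, either, both} carrier groups), and Cox proportional-
  hazards regression (Breslow ties) adjusted for age, stage, ER, PR and
  HER2, with death within 10 years as the event.
- **qPCR replication.** ΔΔCT against a diploid internal-control locus;
  mean dosage ratio 2^(−ΔΔCT) strictly above 2 is called a gain.

## Worked example

Run the discovery pipeline on a simulated 48-sample cohort (chromosomes
16/17/20 at real array density; two planted prognostic gains on 16p and
17q whose joint carriage multiplies the death hazard by 7.31, and a
later-event 20q gain):

```python
from rarseek.pipeline import RunConfig, run_discovery

cfg = RunConfig(mode="discovery", seed=8,
                simulate={"defaults": True, "chromosomes": ["16", "17", "20"]},
                rar={"n_perm": 300})
report = run_discovery(cfg)
print(report.rar_table.to_string(index=False))
```

```
   RAR chromosome map_position_mb size_mb type  p_value  freq_total  freq_stageI  freq_stageII        event
RAR-G1         16      0.13-34.92   34.80 gain   0.0033      0.5000       0.3636        0.5405      earlier
RAR-G2         17     25.00-78.88   53.88 gain   0.0033      0.4167       0.2727        0.4595 unclassified
RAR-G3         20     30.00-61.88   31.88 gain   0.0033      0.3750       0.0909        0.4595        later
```

All three planted gains are recovered at probe resolution with significant
recurrence p-values; the 20q gain (9% of stage I, 46% of stage II) is
classified as a later progression event. The mined death rules and the
adjusted Cox fit surface the planted 16p×17q interaction:

```
                                      rule predicted_class  n_total  n_c  laplace
RAR-G1=1 AND RAR-G2=1 AND RAR-G3=1 => dead            dead        5    5   0.8571
             RAR-G1=1 AND RAR-G2=1 => dead            dead       10    9   0.8333

     analysis     covariate  hazard_ratio  ci_low  ci_high        p
RAR-G1*RAR-G2 RAR-G1*RAR-G2         25.35    5.66   113.62 0.000024
```

Every reported death rule contains both interacting markers, and the
double-positive marker is a strong independent predictor in the adjusted
Cox model (at n=48 the point estimate is noisy; the parameter-recovery
tests show the 95% CI covers the configured hazard ratio in ≥ 90% of
n=300 cohorts).

A command-line interface wraps the same stages:

```sh
rarseek simulate --out-dir cohort/ --seed 1
rarseek segment --ratios cohort/ratios.tsv --probes cohort/probes.tsv --out segs.seg
rarseek call --segs segs.seg --out calls.tsv
rarseek qpcr --ct ct.tsv --control-locus chr13q32.1 --out dosage.tsv
rarseek run-pipeline --config run.yaml
```

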