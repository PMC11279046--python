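# Methods

## The statistical procedure

`methmark` screens CpG probes in three stages, each strictly narrowing
the previous stage's output.

**Paired discovery.** With matched tumor/normal beta values
(β ∈ [0, 1]) for n patients, each probe is tested with a paired t test
on d = β_tumor − β_normal (sample SD, n−1 df, two-sided). Multiplicity
is controlled with the Benjamini–Hochberg step-up at FDR q (default
0.01); plain Bonferroni is available for sensitivity analysis. The
effect-size requirement is *complete separation*: the probe's tumor
values across all patients must lie strictly above (hyper) or below
(hypo) all of its normal values. Separation is defined group-wise —
disjoint value ranges, not merely consistent per-pair signs — which is
the strictest reading of "no overlap across patients"; exact boundary
ties count as overlap. Candidates must be both FDR-significant and
separated. Per probe, pairs with a missing value on either side are
dropped (complete-case); a probe needs at least 2 complete pairs.

**Survival validation.** Each candidate is fit with a univariate Cox
proportional-hazards model on an independent tumor-only cohort, with
the continuous beta value as sole covariate (lifelines; Breslow tie
handling; Wald two-sided p). Probes with p < α (default 0.01, raw —
this stage is a screen, not a confirmatory test) are mapped to genes
and tested for gene-set over-representation by the hypergeometric
upper tail, with population = all genes mappable from the full probe
annotation (analogous to a default array background), draws = the
query genes, and successes = the set intersected with the universe.
DAVID's EASE variant (overlap reduced by one) is available. A term is
"enriched" at p < 0.05 with overlap ≥ 2; no multiplicity correction is
applied across terms by default (a deliberate mirror of common ORA
practice at this stage; both thresholds are configuration values). A
user-supplied term blacklist can remove processes judged ubiquitous
across cell types — that judgment is the user's, not the package's.
Genes are then ranked by the number of enriched terms containing them
and the top-k (default 3, ties broken lexicographically and logged)
genes with their probes become the final candidates.

**Threshold search.** For each final probe the patients are
dichotomized at candidate thresholds — the midpoints of consecutive
distinct observed beta values, which guarantees the scan enumerates
every achievable partition — subject to a group-size constraint
max(min_group_abs, ⌈min_group_frac·n⌉) with defaults 2 and 0.01. The
defaults deliberately tolerate very small groups (reported real-data
thresholds of this design isolate risk groups with as few as 2–3
deaths). Among admissible thresholds the minimal two-group log-rank p
wins; ties go to the smallest threshold, deterministically, and the
full scan trace is retained on the result for audit. The reported p is
the raw minimal log-rank p, matching the procedure this package
reproduces; because a minimized p is optimistic, an opt-in permutation
correction re-runs the entire constrained scan on label-permuted data
and reports (1 + #{perm min-p ≤ observed}) / (B + 1). Patients missing
the probe's value are excluded per probe, with the count logged.

The log-rank statistic is computed in-package with the textbook
observed-minus-expected form (hypergeometric variance per distinct
event time, χ² on 1 df), vectorized over all candidate thresholds at
once; lifelines serves as an independent oracle in the tests rather
than as the implementation, keeping the scan fast (a full permutation
pass over ~60 patients runs in milliseconds).

## The synthetic world

`methmark.simulate` generates data with exactly the structure the
analysis assumes, plus a truth ledger for recovery testing. Defaults
mirror the targeted study design: 10 matched discovery pairs, 275
validation tumors, 40 planted separated probes, 4 prognostic probes on
3 genes (two probes share a gene, as CpGs on one promoter do) with
cutpoints 0.74 / 0.14 / 0.29 / 0.321 — the first with risk *below* the
cutpoint, the rest above — and log hazard ratio 1.5.

- **Null probes.** Per-probe Beta(a, b) baselines with mean ~ U(0.15,
  0.85) and concentration ~ U(20, 100), plus a shared per-patient
  shift on the logit scale (SD 0.4) applied to both tissues, so pairs
  are correlated while differences stay centered at zero. These are
  unimodal, moderately dispersed probes for which the paired t test's
  normality assumption is defensible; the strongly bimodal near-0/near-1
  probes of real 450K arrays are *not* emulated, so a green calibration
  test says nothing about t-test behavior on such probes.
- **Planted probes.** Normal and tumor values are drawn uniformly from
  disjoint intervals separated by at least `separation_gap` (default
  0.2 beta units), making separation exact by construction (re-asserted
  after generation). Prognostic probes get tumor intervals centered on
  their cutpoint so validation values straddle it.
- **Survival.** Event times are exponential with hazard
  h = baseline_hazard · exp(Σ log_hr · 1[risk side]); censoring is
  min(administrative horizon, U(0, 2·horizon)). `baseline_hazard`
  (1e-5/day) and `censor_time_max` (1200 days) were calibrated once to
  the targeted cohort's reported facts — ~27% deaths and median time
  to death ≈ 352 days. Median follow-up among the censored comes out
  near 1100 days, longer than the reported 527; this censoring family
  cannot match all three quantities at once and the event fraction and
  death timescale were prioritized. Because the planted effects
  multiply, experiment configurations with fewer planted markers use a
  proportionally higher baseline so the *cohort-level* event fraction
  stays at ~27% (3.5e-4 with no markers, 1.3e-4 with one).
- **Gene universe.** 500 genes; each probe maps to 0–2 of them,
  prognostic probes to exactly one planted gene each. Planted enriched
  sets each contain every prognostic gene plus disjoint fillers, so the
  frequency ranking puts the planted genes on top; 50 random background
  sets provide the null.
- **Determinism.** One root seed feeds four named SeedSequence streams
  (probe parameters, matched cohort, validation cohort, gene universe),
  so the matched and validation cohorts share per-probe baselines and
  every output is byte-identical under a fixed seed.

What a green recovery test establishes: the pipeline finds planted
effects of the stated size under this idealized world (independent
probes, exact interval separation, exponential hazards, no batch
effects, no tumor purity gradient). It does not establish performance
on real arrays with probe-type chemistry, correlated CpGs, or
non-proportional hazards.

## Numerical conventions

- Beta values are validated on read, never clamped; out-of-range cells
  are an error naming probe, sample and value.
- A zero-variance difference vector is detected up to rounding noise
  (sd ≤ |mean|·1e-12): non-zero mean → "infinite t", p reported as 0
  with a flag (capped at 320 in −log10 displays); all-zero differences
  → p = 1 with a flag.
- Constant Cox covariates are flagged with p = 1 by convention;
  non-convergent fits are flagged and excluded from selection.
- Log-rank variance terms with a single subject at risk are dropped;
  zero total events gives χ² = 0, p = 1 with a flag.
- Probe intersection (not union) across per-sample portal files; a
  patient with multiple samples of one tissue type is an error rather
  than a silent choice; sorted probe ids and first-appearance patient
  order make all outputs order-stable.
- The hypergeometric tail is exact (`scipy.stats.hypergeom.sf`), not a
  normal approximation.

## Known limitations

- The Cox screen is univariate by design; no adjustment for clinical
  covariates (extra clinical columns are carried but not modeled).
- Minimal-p thresholds are optimistic unless the permutation
  correction is enabled; the default mirrors the reproduced procedure
  and reports the raw p.
- Enrichment ignores the GO DAG (no parent–child or elim logic) and
  any dependency between terms.
- The generator does not model 450K probe-type chemistry, batch
  effects, or tumor purity; see above for what that implies about test
  coverage.
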