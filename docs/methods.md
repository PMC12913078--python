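# Methods

## The CAS-CAD composite

CAS-CAD scores one clinical visit as

```
total = c(clothing) · Σ_r  w_r · b_r · A(area_r) · S_r
```

* `S_r` — sum of four lesion-sign grades (erythema, papules/plaques,
  scaling, lichenification), each an ordinal 0–3 (none / mild / moderate /
  severe), so `S_r ∈ [0, 12]`.
* `A(·)` — affected-area score on the EASI convention: 0 for no
  involvement, then (0,10)%→1, [10,30)%→2, [30,50)%→3, [50,70)%→4,
  [70,90)%→5, [90,100]%→6. Half-open on the left so a region just reaching
  a decade boundary takes the higher score; 0 is reserved for literally no
  involvement.
* `b_r` — the region's fraction of body surface area; the shipped default
  is an eight-region partition (head/neck 0.09, anterior trunk 0.18,
  posterior trunk 0.18, dorsal hands+forearms 0.09, upper arms 0.09,
  thighs 0.18, lower legs 0.13, feet 0.06) with rule-of-nines-style
  shares summing to 1. The partition, shares and exposure flags are a
  YAML-editable config (`RegionMap.from_yaml`), because severity anchors
  and partitions legitimately differ between study protocols.
* `w_r` — photo-exposure weight: 2 for sun-exposed, 1 for covered skin.
  Head/neck and dorsal hands+forearms are exposed for everyone; the lower
  legs become exposed only in the Type-2 (shorts) stratum.
* `c` — clothing correction. Type 1 (long pants) is the reference, `c = 1`.
  For Type 2, `c` = (Type-1 exposed BSA) / (Type-2 exposed BSA) over the
  configured map (0.18 / 0.31 ≈ 0.58 on the default map). The direction is
  chosen so Type-2 totals are rescaled toward the Type-1 reference scale;
  since the map is configurable, so is the ratio.

Structural consequences, all enforced by property tests: the total is zero
iff every region has zero severity or zero area; it is monotone
non-decreasing in every severity grade and every area percent; it is
homogeneous of degree one in the weight vector; and Type-1 and Type-2
patients with identical findings score identically whenever their exposure
maps coincide.

Response tiers partition fractional improvement `(baseline − followup) /
baseline`: excellent > 0.75, good [0.50, 0.75], partial [0.25, 0.50), no
response below 0.25. The verbal tier definitions overlap at the
boundaries; exactly 0.50 and 0.75 are assigned to "good" and exactly 0.25
to "partial" (boundary goes to the tier whose label names the value), and
worsening (negative improvement) is "no response". Two-rater adjudication
averages the raters and escalates to a third rater when the absolute
disagreement exceeds 5 points, applied on each instrument's own scale.

Comparators: the standard adult EASI (0–72; region multipliers
0.1/0.3/0.2/0.4) is computed from the same region-level record by
BSA-weighted pooling of severity sums and area percents onto the four EASI
regions — an aggregation choice needed because the CAS-CAD map is finer
than EASI's. EQ-5D-3L utilities use a generic additive time-trade-off
tariff (constant minus per-dimension level decrements minus an optional
any-level-3 penalty); no national coefficient set is shipped, so a tariff
must be supplied explicitly.

## Efficacy statistics

Continuous summaries are mean ± sample SD (n−1) and median (IQR) with
quartiles by linear interpolation of order statistics (the convention that
reproduces published median/IQR values for this kind of table; the method
is numpy's `linear`). Paired comparisons are gated by a Shapiro–Wilk test
on the paired differences at α = 0.05: normal → paired *t*, otherwise
Wilcoxon signed-rank. The gate records its p-value, and the pipeline
report always carries both tests' p-values so the gate decision is
auditable. A zero-variance difference vector is degenerate for the gate
and falls through to the rank test with a warning.

The Wilcoxon signed-rank implementation drops zero differences
(Wilcoxon's original rule), mid-ranks tied magnitudes, and computes the
two-sided p exactly for up to 12 retained pairs by convolving the
distribution of the positive-rank sum over all 2ⁿ sign assignments of the
observed mid-ranks — so ties are handled exactly, which off-the-shelf
exact routines refuse. Two-sidedness is symmetric deviation from the null
mean n(n+1)/4. Beyond 12 pairs a normal approximation with the standard
tie correction and a 0.5 continuity correction is used; at the hand-over
the two regimes agree to well under 0.01 wherever p < 0.2.

## Inter-rater reliability

The ICC is computed from scratch via two-way ANOVA mean squares (subjects
random, raters fixed) in all four McGraw–Wong forms: consistency and
absolute agreement, single and average measures. Confidence intervals use
the exact F bounds for the consistency forms and Satterthwaite-approximate
F bounds for the agreement forms. The default is consistency/single
(ICC(3,1)), but `icc_report` always prints all four, since "two-way mixed
model" alone does not pin the form down. Interpretation bands: < 0.5 poor,
0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent, with boundary values
assigned upward. A residual mean square within floating-point noise of
zero (≤ 1e−12 · MSR) is treated as exactly zero so perfectly agreeing
raters yield ICC 1; zero between-subject variance leaves the ICC
undefined and is flagged degenerate rather than guessed.

## NPX differential expression

NPX is Olink's log2-scale relative abundance unit; vendor-side
normalization is assumed done, and only the per-sample QC pass/fail gate
is applied (subjects left without a complete timepoint set are flagged).
Per contrast (default A–B, A–C, B–C for baseline / week 1 / week 12), each
protein gets a paired *t*-test over subjects present in both groups,
complete-case per protein, requiring ≥ 2 complete pairs. Significance is
unadjusted p < 0.05 — the convention of small-panel exploratory
inflammation studies — with Benjamini–Hochberg adjusted p-values always
reported alongside rather than used for the call. Post-processing:
Spearman correlation (mid-rank ties; constant proteins reported missing)
among the DEPs per timepoint, degree ranking on a user-supplied
interaction edge list (degree is the default centrality; self-loops
rejected), and generic hypergeometric over-representation against a
user-supplied term table with the assay panel as background. No live
StringDB/GO/KEGG retrieval: edges and annotations are inputs.

## Synthetic-data generators

The generators emulate the study conditions the pipeline targets:

* **Cohort** — 16 patients, visits at weeks 0/1/4/12, baseline CAS-CAD
  targets Normal(23.65, 7.86²) drawn by stratified inverse-CDF sampling
  (one draw per equal-probability stratum, order shuffled), so even a
  16-patient cohort matches the target mean/SD closely while remaining
  fully seed-random. Follow-up targets are multiplicative: retention 0.65
  at week 1 (most patients in the partial tier), 0.35 at week 4, 0.102 at
  week 12 (tracing 23.65 → ≈ 2.4), each jittered by a lognormal factor
  (σ = 0.15, widened to 0.5 at the final visit so a minority of patients
  land in "good" rather than "excellent"). 25% of patients are Type 2.
  Scores are generated **bottom-up**: per-region area scores and severity
  sums are solved by greedy constrained rounding (regions visited in random
  order, each taking a jittered proportional share of the remaining
  target realised as the nearest feasible `w·b·A·S` product), then areas
  are sampled inside their bin (rounded to 4 dp, which cannot cross a bin
  edge) and severity sums randomly composed into four 0–3 grades. The
  emitted records are therefore scored by the real engine, and the
  ground-truth table stores both the intended and achieved totals
  (agreement is typically within ±0.5 points). NRS/IGA/EQ-5D responses are
  plausible monotone functions of the achieved total with noise — enough
  to exercise the comparator plumbing, with no claim of clinimetric
  realism. Infeasible targets (mean + SD beyond 90% of the attainable
  maximum) raise a generation error.
* **Ratings** — classical true-score model: subject scores
  Normal(μ, ρσ²), rater errors Normal(0, (1−ρ)σ²), so the population ICC
  is exactly ρ (default scale μ = 20, σ = 8, matching CAS-CAD magnitudes).
  Under this model the consistency-form F pivot is exact, which the CI
  coverage check (93–97% at n = 50) relies on.
* **NPX panel** — 6 subjects × 3 groups × 92 proteins: per-protein
  baselines Normal(5, 1.5²), per-(subject, protein) random intercepts
  (σ = 0.8) that cancel under pairing, Gaussian assay noise (σ = 0.4), and
  planted group shifts. The default plants −1.5 NPX at group C for the
  eight markers EN-RAGE, MCP-3, MCP-4, IL-13, FGF-21, TNFRSF9, OSM and
  CCL4, with OSM and TNFRSF9 already at −0.8 in group B, mirroring the
  early-vs-late response pattern such panels show. Optional correlation
  blocks add a shared per-sample latent factor. At these defaults the
  paired caller recovers ≥ 7/8 planted proteins in essentially every seed
  (effect size 1.5/(√2·0.4) ≈ 2.7 at n = 6) and holds its per-protein
  type-I error at 0.05 on null panels.

What the generators deliberately do **not** emulate: Olink plate
structure, LOD censoring, assay-specific dynamic ranges, non-Gaussian
noise, missing visits, or rater main effects. Passing closed-loop tests
therefore demonstrates correctness of the analysis chain under its own
model assumptions, not robustness to real-data pathologies.

## Numerical and scale choices

* All randomness flows through `numpy.random.default_rng(seed)`;
  identical seeds give byte-identical outputs.
* Scores are kept at full float precision internally; 3-decimal rounding
  is a reporting concern only.
* The paired *t* with zero-variance, nonzero-mean differences reports
  p = 1e−15 (a floor, not an estimate) with an infinite statistic; with a
  zero mean it reports t = 0, p = 1.
* Degenerate inputs fail loudly: all-zero differences for the rank test,
  all-failing QC, empty ratings variance, DEPs outside the ORA
  background, self-loops in edge lists.
* Simulation sizes in the calibration tests (200 replicates for ICC
  recovery, 1000 for CI coverage at n = 50, 200 seeds for DEP recovery,
  500 null panels) were chosen so Monte-Carlo error is a small fraction
  of each tolerance band while the whole suite stays fast.

## Known limitations

* The default region map, severity anchors and area bins are documented
  stand-ins for a protocol-specific partition; studies using a different
  partition should supply their own map (everything downstream adapts).
* The EQ-5D-3L evaluator is tariff-agnostic by design and useless without
  a supplied tariff.
* The agreement-form ICC confidence bounds are Satterthwaite
  approximations (as in standard software), not exact.
* The DE caller tests each protein marginally; no shrinkage or
  variance-moderation across the panel is attempted, matching the paired
  per-protein *t* convention rather than improving on it.
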