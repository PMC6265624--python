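# Methods

## Data model and effect-allele orientation

The unit of analysis is one case–control study of one biallelic SNP,
summarised by two genotype-count triples (RR, RW, WW) for cases and
controls. The effect allele R is defined positionally: it is the allele
of the first-listed homozygote column of the input table. This makes the
orientation an explicit property of the data file rather than of prose
conventions such as "A>G", which are ambiguous about which allele the
odds ratio is anchored to. For the packaged KLK3 table the effect
alleles are C (rs1058205) and G (rs2735839, rs266882); this orientation
reproduces the published pooled estimates.

## Count reconciliation

Published count tables sometimes contain cells inconsistent with their
printed row totals. `validate_study` handles an arm whose cells do not
sum to the reported total as follows, with `diff = total − sum(cells)`:

1. For each cell, the candidate repair is `cell + diff` (equivalently,
   `total − sum(other two cells)`); a candidate is admissible only if
   nonnegative. If **exactly one** cell admits a repair, the erroneous
   cell is unambiguous: it is replaced and a warning is recorded.
2. Otherwise, if `|diff| ≤ 5`, the printed cells are kept with a
   warning (a small bookkeeping discrepancy with no unique culprit).
3. Otherwise the record is rejected (two or more cells would need
   changing).

In the packaged table this rule repairs exactly one cell — the
largest study's reference-homozygote case count, printed with a stray
extra digit (161057 → 16057, forced by its row total) — and flags a
3-subject residual in the same study's control arm, which is kept as
printed. A `strict` policy that rejects any inconsistency is available
for clean data. Reported HWE p-values are carried for cross-checking
only and are never used in computation; censored entries ("<0.01") are
stored as missing.

## Genetic-model contrasts

`build_contrast` produces the five 2×2 tables listed in the README. The
allele contrast treats alleles as independent observations (2N per
group), the conventional allele-level OR; the heterozygote and
homozygote contrasts exclude the remaining genotype class from both
margins. A 0.5 continuity correction is added to all four cells of a
table only when that table has a zero cell, per contrast rather than per
study, so a sparse homozygote table does not perturb the allele contrast
of the same study. No contrast in the packaged table needs it.

## Hardy–Weinberg screening

Controls are tested with the Pearson chi-square against expected counts
N·p̂², 2N·p̂(1−p̂), N·(1−p̂)², where p̂ is the observed effect-allele
frequency; df = 1 (one estimated parameter), no Yates correction, no
exact test. This choice reproduces the fixture's published HWE column to
two decimals on every internally consistent row that was rounded rather
than truncated (one printed value, 0.68, is the truncation of 0.6858).
Studies violating HWE are flagged but retained in all pooled analyses,
matching how such studies are usually handled when sensitivity analysis
shows they do not drive the result. Monomorphic control groups return
χ² = 0, p = 1 with a warning.

## Pooling

Per-study effects are log ORs with Woolf SEs, √(1/a+1/b+1/c+1/d).
Cochran's Q uses inverse-variance weights; τ² is the DerSimonian–Laird
moment estimator max(0, (Q − df)/(Σw − Σw²/Σw)). Q and τ² are always
computed from IV weights, the standard DL construction, even when the
fixed-effects estimate is reported.

Model selection is the strict threshold rule: Q-test p > 0.10 → fixed
effects, otherwise random effects. The fixed-effects estimate is
Mantel–Haenszel, Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ), with the
Robins–Breslow–Greenland variance for its log; MH is preferred over
plain IV-fixed because it is the method named for this class of
analysis and is robust with sparse strata. The two agree closely but
not exactly on real tables (largest observed log-OR gap on the fixture
is ≈0.023, on a strongly heterogeneous contrast). The random-effects
estimate uses weights 1/(vᵢ + τ²). Confidence intervals are 95%
throughout (z = 1.959964) and computed on the log scale; the Z-test is
two-sided normal. k = 1 strata degenerate to the single study's
estimate, labelled fixed with p_het = 1 by convention. Rounding to the
reporting precision (default 2 dp, half-even) happens only in the
output layer; JSON output always carries full precision.

## Subgroups, sensitivity

`analyze` stratifies by ethnicity and control source (population-,
hospital-, family-based, each its own level), re-running selection per
stratum; `leave_one_out` re-pools with each study omitted, re-running
the fixed/random selection on the reduced set, so an omission that
removes the heterogeneity can legitimately flip the method.

## Publication bias

Egger's test is ordinary least squares of the standardized effect
(log OR/SE) on precision (1/SE); the intercept's t statistic is referred
to k−2 df. This unweighted standardized form is algebraically equivalent
to the classic weighted regression of log OR on SE. At least three
studies are required. Begg's test centres the log ORs on the IV-fixed
pooled value, standardises by √(vᵢ − 1/Σw), and correlates these
deviates with the variances using tie-corrected Kendall tau; z uses the
tie-corrected normal approximation without continuity correction (the
correction is a documented alternative but is off, as k is small and
the approximation is already conservative). When all variances are
equal the rank correlation is degenerate; the test warns and returns
tau = 0. Funnel coordinates plot log OR against SE (SE axis inverted by
convention) with pseudo-95% guide lines around the pooled estimate.

## Simulator

The generator mirrors the retrospective design of the consumed studies.
Controls are multinomial draws from HWE proportions at frequency p;
cases are drawn from the HWE distribution tilted by genotype odds
multipliers — (ψ², ψ, 1) multiplicative, (ψ, ψ, 1) dominant, (ψ, 1, 1)
recessive — and renormalised. This exact tilted-genotype sampling is
simpler than simulating a cohort with a logistic disease model and
matches the case–control likelihood directly; under multiplicative
inheritance the allele-contrast OR estimand equals ψ, under dominant
inheritance the dominant-model estimand equals ψ. Between-study
heterogeneity is a normal perturbation of log ψ with SD τ; per-study
allele frequencies and arm sizes may be drawn uniformly from ranges to
emulate the frequency spread across ethnic groups seen in real study
collections. Defaults (5 studies, 1000/arm, p = 0.3) are typical of the
candidate-gene literature the pipeline targets.

What the simulator does **not** model: linkage between SNPs,
covariates, population stratification within a study, genotyping error,
and selective publication. Passing calibration tests therefore
demonstrates correctness of the estimators under clean sampling, not
robustness to those artefacts.

Test/calibration problem sizes were chosen to give stable Monte-Carlo
checks at interactive runtimes: null CI coverage uses 500 replicates of
5 studies at 2000/arm (±3% binomial band), consistency uses 50
replicates at 10,000/arm, model-selection calibration uses 200
replicates of 10 studies at τ ∈ {0, 0.5}, and HWE-p uniformity uses 800
control draws of 5000 at a Kolmogorov–Smirnov screen.

## Known limitations

* Only the DL τ² estimator is provided (no REML/Paule–Mandel), and only
  MH/IV fixed effects (no Peto), matching the scope of the analyses the
  package reproduces.
* The Egger t statistic for the fixture's rs1058205 allele contrast is
  −0.93; see the test suite for how this and the other bias statistics
  are validated against independently published values where available.
* The reconciliation rule assumes at most one corrupted cell per arm;
  tables mangled more severely are rejected rather than guessed at.
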