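# Methods

## Disproportionality model

The unit of analysis is the spontaneous report: one record linking a set of
drugs to a set of MedDRA Preferred Terms (PTs) within a calendar quarter.
For a drug–category pair the database collapses to the 2×2 table
(a, b, c, d) with N = a+b+c+d, and the reporting odds ratio
ROR = (a·d)/(b·c) measures how much more often the pair is co-reported than
expected under independence *within the reporting database*. The comparator
is all other drugs and all other events in the same store; restricted
comparators are deliberately out of scope, as are PRR, Bayesian shrinkage
statistics (EBGM/IC) and any multiple-testing adjustment. Disproportionality
quantifies reporting association only — it is not a risk estimate and
supports no causal claim.

The 95% CI is the Woolf log-normal interval
exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)) with the conventional z = 1.96. Among
standard 2×2 interval choices this one reproduces the published aggregate
table from its printed marginal counts (56 of the 60 printed values to two
decimals; the remaining four printed values differ from their own printed
marginals by less than 0.006 at full precision, an internal inconsistency of
the published table that no interval choice can remove). No 0.5
continuity correction is applied by default because every cell of the study
tables is positive; `continuity_correction=True` enables the
Haldane–Anscombe correction for zero-cell tables. A zero b or c makes the
ROR undefined and raises; a zero a or d yields a 0 or infinite ROR with the
CI flagged unavailable. Reported values are rounded half-even to two
decimals; all internal computation is full precision.

**Signal rule.** A pair is a signal iff a > 3 and CI-low > 1, both strict.
The thresholds are exposed in configuration but the defaults are the rule
as stated.

## Vocabulary

Matching of PTs and of search terms is exact-string after case-folding and
whitespace collapsing; no stemming or fuzzy matching, because the category
definitions are literal PT lists. The narrow-scope SMQ categories ("drug
abuse and dependence", "drug withdrawal") are labels for proprietary
MedDRA PT sets; the packaged lists are explicit placeholders and the
vocabulary file format lets licence holders substitute the licensed
membership. Consequently, report-level counts computed with the placeholder
lists are not comparable to the published aggregate counts — which is why
the aggregate reproduction works from the marginal-count fixture, not from
raw reports. The brand spelling "kepra" is preserved as printed in the
source dictionary with "keppra" added as an alias; both normalise to
levetiracetam.

## Report cleaning

Deduplication keeps the first occurrence per report ID and, by default,
additionally collapses reports identical in (quarter, drugs, events) under
different IDs — the content-level rule is a config flag because upstream
cleaning pipelines differ and are not fully published. Reports outside the
window (default 2007Q1–2020Q2 inclusive, 54 quarters) are dropped; records
with blank drug or event fields are dropped at parse time. Every removal is
tallied in a cleaning log so N is auditable. Drug sets use set semantics: a
report naming brand and generic of the same drug counts once. Reports have
no role field; a drug "mention" counts regardless of suspect/concomitant
role, which is the conservative reading when roles are unavailable.

## Search-popularity emulation

The true ranking and normalisation pipeline of consumer search analytics is
closed; the module implements its operational contract: per period the top
related query (the plain drug-name query) scores 100, other queries scale
proportionally, and queries under a 1% share of total related searches are
reported as 0 and flagged suppressed. The suppression denominator is the
per-period total related volume for the drug (configurable). Monthly input
periods are averaged into quarters at ingest (configurable to sums).
Per-term-set scores are capped at 100 — the top query's own score — while
cumulative sums across term sets may exceed 100 by construction. The
normalisation is invariant under uniform rescaling of all volumes, so
synthetic "volumes" need no absolute calibration. A whole-drug volume floor
models big-data-only reporting: a drug whose total abuse-query volume over
the window falls below the floor yields no timeline, only an
insufficient-data flag (the behaviour observed for the low-volume negative
control). The euphoria event category pairs with the search term "high",
its colloquial search-domain counterpart.

## Cross-domain correlation

The report-domain series is, by default, the quarterly co-report count of
the primary category (quarterly RORs are available as an alternative; at
realistic quarterly cell sizes they are far noisier). The search-domain
series is the quarterly cumulative abuse SPS. Alignment is pairwise
complete over the intersection of quarters, with dropped quarters reported
so the effective n is visible. Spearman's rho uses average ranks for ties;
the two-sided p comes from the t approximation on n−2 degrees of freedom,
which is standard at n ≈ 54. An exact permutation p (full enumeration,
n ≤ 10) is provided for small samples; at n = 8 the t approximation agrees
with it to within 0.05 in the test suite. |rho| = 1 reports the smallest
positive float rather than p = 0.

## Synthetic-data generator

The generator provides the study's statistical structure with known ground
truth, not a facsimile of real pharmacovigilance data. Per quarter it draws
`n_reports_per_quarter` reports; study-drug mentions are independent
Bernoulli draws with configured marginal probabilities (defaults mirror the
observed per-drug report shares, e.g. 0.0145 for pregabalin), and a
category's event odds are background odds (defaults mirror the per-category
shares) times the latent trend, times the enrichment multiplier of each
study drug present. Enrichment on the odds scale makes the configured
multiplier equal the large-sample ROR exactly within a trend stratum.
Filler drugs and events populate the b/c/d cells; every report has at least
one drug and one event. The default enrichment config uses the published
aggregate RORs of the four study drugs as an illustrative setting.

The query log shares the reports' latent trend through a coupling
parameter: abuse-query log-volume adds coupling·z plus
√(1−coupling²)·matched-variance independent noise, where z is the
standardised log trend — so coupling interpolates between independent
domains and a fully shared monotone trend, and its sign is the expected
sign of the cross-domain rho. Decoy queries (a blocklisted collocation and
a no-abuse-term query) are emitted to exercise filtering. The default
latent trend is a monotone ramp from 0.5 to 2.0 over the window.

What the generator does *not* emulate: reporting demographics, stimulated
reporting waves, drug–drug report correlation, seasonality beyond the
latent trend, real query-text diversity, and the actual search-volume
dynamics of the study period. Passing calibration experiments therefore
demonstrates correctness of the estimators under the assumed structure, not
fidelity of the published external data streams, whose raw series are not
archived and are explicitly not reproduction targets.

## Calibration scenarios and problem sizes

Three named scenarios pin down the experiment conditions:

* `recovery_scenario` — one enriched pair (multiplier 3.0), 200,000 reports
  (4 quarters × 50,000), constant latent trend. The trend is held constant
  here because the crude odds ratio is noncollapsible: pooling strata with
  different baseline risks attenuates the crude OR slightly below the
  common stratum OR even without confounding, and the recovery experiment
  is meant to isolate the estimator. The 95% CI covers the configured
  multiplier in ≥90% of 50 seeded replicates.
* `null_signal_scenario` — the four study drugs at desk scale
  (400 reports/quarter × 54 quarters) with all enrichment at 1; the signal
  rule fires for ≤10% of drug–category pairs across 50 seeds (nominal
  one-sided 2.5% plus small-cell effects).
* `coupled_scenario` — one drug, 800 reports/quarter over 54 quarters,
  abuse share 0.3 of a 100k-volume top query. With coupling 1 the
  cross-domain rho is positive at p < 0.05 in ≥95% of 50 seeds; with
  coupling 0 the 5%-level rejection rate stays ≤10%.

These sizes keep each 50-replicate experiment to a few minutes on one core
while leaving the binomial cells large enough for the asymptotic intervals
to behave.

## Known limitations

* Aggregate reproduction depends entirely on the printed marginal counts;
  report-level recomputation of those aggregates would require the licensed
  SMQ membership and the original database extract.
* The quarterly series used for correlation in the original analysis are
  not published, so the correlation stage is validated by oracle
  equivalence, the printed (rho, p, n = 54) consistency checks, and
  synthetic recovery — not by re-deriving the published coefficients.
* Whether suppressed-SPS quarters were dropped from the published
  correlations is unstated; the implementation keeps them (suppressed = 0)
  and reports dropped quarters explicitly.
* The t-based p-value is approximate; for n < ~10 prefer the exact
  permutation method.
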