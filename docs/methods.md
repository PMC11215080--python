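# Methods

This note records the exact statistical definitions, data-handling
conventions, and synthetic-data models implemented by `icivig`, together with
the numerical choices made in the test suite.

## 1. Report ingestion and cleaning

FAERS-style tables are `'$'`-delimited text with one header line. Pre-2014
header variants are mapped onto the modern names (`isr` → `primaryid`,
`case` → `caseid`, `gndr_cod` → `sex`). Malformed lines (wrong field count,
unparseable mandatory fields) are skipped and counted; missing files or
missing mandatory columns are fatal.

Dates arrive as `YYYYMMDD`, `YYYYMM`, or `YYYY`. Partial dates are completed
to the first day of the period and flagged imprecise; imprecise dates are
excluded from time-to-onset arithmetic but kept for all other purposes. Ages
are converted to years by unit code: `DEC` ×10, `YR` ×1, `MON` ÷12, `WK`
÷52.18, `DY` ÷365.25, `HR` ÷8766.

## 2. Cohort construction

* **Deduplication** — among reports sharing a case identifier, keep the one
  with the latest FDA receipt date; ties are broken toward the larger
  numeric report identifier. The operation is idempotent and independent of
  input order.
* **Window and age filter** — FDA receipt date within 2012-01-01 to
  2022-12-31; reports with a known age under 18 years are dropped, unknown
  ages are retained.
* **Exposure** — only suspect-role drug entries (`PS`/`SS`) define ICI
  exposure. Drug names are matched after normalization against generic and
  brand-name synonyms of the eight agents.
* **Strategy** — anti-PD-1, anti-PD-L1, anti-CTLA-4 monotherapy classes, and
  combination therapy defined exclusively as anti-PD-1/L1 together with
  anti-CTLA-4. Reports with both an anti-PD-1 and an anti-PD-L1 agent but no
  anti-CTLA-4 are not assigned a strategy.
* **Case definition** — exact (casefold) match of the reaction preferred
  term, default "Immune thrombocytopenia".

## 3. Disproportionality statistics

For each strategy the 2×2 table is: a = strategy reports with the event,
b = strategy reports without, c = other reports with, d = other reports
without; N = a+b+c+d.

| Statistic | Definition | Signal threshold |
|---|---|---|
| ROR | ad/bc, CI95 = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)) | a ≥ 2 and CI lower bound > 1 |
| PRR | [a/(a+b)]/[c/(c+d)], χ² = (ad−bc)²N/((a+b)(c+d)(a+c)(b+d)) | a ≥ 2, PRR ≥ 2, χ² ≥ 4 |
| IC | log₂(aN/((a+c)(a+b))) | IC025 > 0 |
| EBGM | aN/((a+c)(a+b)), EBGM05 = exp(ln EBGM − 1.64·√(1/a+1/b+1/c+1/d)) | EBGM05 > 2 |

The χ² is the uncorrected Pearson statistic. The IC and EBGM here are the
unshrunk observed-to-expected forms, so the identity **IC = log₂(EBGM)**
holds exactly; the test suite uses it as a cross-check between the two
columns. IC025 is computed as exp(ln IC − 1.96·√(1/a+1/b+1/c+1/d)) — note
the unusual exponential-of-log-IC form, defined only for IC > 0; it is
implemented verbatim for comparability with the source convention rather
than as a posterior credible bound. A signal is **joint positive** only when
all four thresholds are met simultaneously; since each criterion is
necessary, the joint false-positive rate is bounded by the smallest
single-algorithm rate.

Undefined statistics (zero cells where a denominator or logarithm needs
positivity) are reported as missing and the corresponding flag is false.

## 4. Descriptive analysis

The characteristics table stratifies fatal (outcome code `DE`) against
non-fatal reports over gender, age group (<65, 65–85, >85), country
(Japan, US, France, Germany, Canada, China, other), reporter type,
reporting year, treatment strategy, indication organ (mapped from free-text
indication terms through an ordered keyword list), and outcome category
(most severe per report: death > life-threatening > hospitalization >
disability > other). Association p-values are uncorrected Pearson χ² tests
with missing categories excluded. Percentages are rounded half-up at the
reported precision.

## 5. Time to onset

TTO = event onset date − first ICI therapy start date, in days; reports with
missing or imprecise dates on either side, or non-positive differences, are
excluded with per-reason accounting. Onset bins are right-closed:
(0,30], (30,60], (60,90], (90,180], >180. Event-free curves use the
Kaplan–Meier product-limit estimator; with no censoring this equals
1 − ECDF, an identity the tests verify. Group comparisons use the log-rank
test (lifelines) and the Kruskal–Wallis test (scipy). Medians and quartiles
use the linear-interpolation (type-7) quantile definition.

## 6. Pan-cancer correlation

Within the ICI cohort, a per-cancer-type 2×2 table (that type vs all other
types) yields a per-type ROR. Expression data are scored per sample with a
rank-based single-sample enrichment statistic (weight exponent 0.25 on the
descending expression ranks, decrements 1/(N−m) outside the set, score =
sum of the running statistic, min–max normalized across samples), summarized
per type by the median, and correlated against the per-type RORs with
Spearman's rank correlation (midranks for ties, asymptotic p). At least
three shared types are required.

## 7. Synthetic data models

* **Cohort generator** — `n_background` reports with configurable ICI
  exposure probabilities per agent, baseline event probability, and
  plantable per-agent reporting-rate ratios (event probability multiplied by
  the ratio under exposure). Demographics, dates, outcomes and indications
  are drawn from fixed categorical distributions. A duplicate injector
  clones a fraction of reports under new report identifiers with later
  receipt dates, so deduplication is exercised realistically.
* **Reference case series** — a deterministic 345-report fixture whose
  marginal distributions (outcomes, strategies, gender, age groups,
  countries, reporters, years, indication organs) and onset/age quantiles
  are fixed by construction; 147 reports carry complete, precise date pairs
  with a planted onset distribution (median 42 days, IQR 17–135).
* **Expression generator** — 17 pseudo-cancer-types × 8 samples × 200 genes;
  a latent per-type activity shifts the 20 in-set genes by a configurable
  effect, and the per-type reporting ratio is a monotone function of a
  mixture of that activity and independent noise, giving a plantable
  population Spearman correlation (`planted_rho`); `planted_rho = 0` gives a
  constant-activity null.

## 8. Simulation sizes in the test suite

All simulation tests fix their seed ranges a priori (`range(n_seeds)`).

* **Null scan calibration** — 200 seeds of a no-signal cohort (n = 40,000,
  baseline event probability 0.005, expected overall a ≈ 6); the
  joint-positive rate across all strategy rows must be ≤ 1%. The cohort
  size was scaled down from larger designs to keep the expected event count
  ≥ 5 while fitting the suite's runtime budget; the joint rule's bound does
  not depend on N.
* **CI coverage** — 500 seeds with a planted ratio of 8 on a single agent
  (n = 10,000, exposure 0.2, baseline 0.0032, expected a ≈ 51); the ROR CI
  must cover the planted ratio in ≥ 90% of seeds (Wald coverage is expected
  near 95%).
* **Pan-cancer power** — 100 seeds at planted rho 0.8, n = 17 types; the
  estimated rho must be positive in ≥ 95% of seeds (empirical power is
  effectively 100%).
* **Pan-cancer null** — the criterion is |rho| < 0.5 in ≥ 95% of seeds. At
  n = 17 the permutation null of Spearman's rho gives
  P(|rho| ≥ 0.5) = 0.0432, so the per-seed pass probability (0.9568) sits
  only ~0.6 percentage points above the 95% threshold. The test therefore
  uses 10,000 seeds so that the Monte Carlo standard error of the observed
  proportion (~0.2%) is small relative to that margin; with a few hundred
  seeds the outcome is dominated by simulation noise rather than by the
  property under test. The measured pass rate over an independent 5,000-seed
  set was 95.5% (95% CI 95.0–96.1), consistent with the permutation-null
  value.

## 9. Limitations

Spontaneous-report disproportionality measures reporting associations, not
incidence or causality; there is no exposure denominator. The IC and EBGM
implementations are the unshrunk observed-to-expected forms without Bayesian
shrinkage, and the IC025/EBGM05 bounds are normal-approximation constructions
on the log scale; with small cell counts they are anti-conservative relative
to full posterior intervals. The enrichment scorer is a generic rank-based
single-sample statistic, not a re-implementation of any specific published
toolkit, and the pan-cancer stage demonstrates the correlation machinery on
synthetic expression panels rather than on real tumor expression data.
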