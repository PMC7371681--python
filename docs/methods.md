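# Methods

## Model and procedure

`prrscreen` performs frequentist disproportionality analysis on spontaneous
adverse-event reports. The counting unit is the report: within one stratum
of a report set, a report contributes at most once to each cell of the 2×2
table for a (drug entity, PT) pair, regardless of how many times the drug or
the event is listed on it. A drug entity is a set of canonical drug names; a
report is exposed when its drug set intersects the entity's members, so a
pooled class entity is exactly the union of its members and its a-cell
dominates each member's a-cell for the same PT and stratum.

The proportional reporting ratio is PRR = [a/(a+b)] / [c/(c+d)], the event's
reporting rate among exposed reports relative to the stratum's background
(all non-exposed reports *of the same stratum*: stratified analyses use
stratum-restricted backgrounds throughout, because the reporting mix of
events differs strongly by age). The chi-square is the Pearson statistic of
the table; a positive signal requires PRR ≥ 2, χ² ≥ 4 and a ≥ 3, all
inclusive. No multiple-testing adjustment is applied — the screen is
hypothesis-generating and reports every analysis at its nominal thresholds;
users who want error control can post-process the full results table, which
carries every statistic at full precision.

### Assumptions and their limits

Disproportionality measures reporting association, not risk: it inherits
every reporting bias of the source database (stimulated reporting,
confounding by indication, duplicates). The pipeline assumes reports are
already deduplicated and ages are expressed in years; the loader validates
ranges but performs no case-version reconciliation.

## Key parameters

| Parameter | Default | Meaning |
|---|---|---|
| `prr_min` | 2.0 | Evans PRR threshold (inclusive) |
| `chi2_min` | 4.0 | Evans chi-square threshold (inclusive) |
| `n_min` | 3 | minimum exposed cases (the a-cell) |
| `yates` | `True` | Yates continuity correction for χ² |
| strata | overall, 0–18, 19–39, 40–59, ≥60 y | female physiological phases |

The Yates choice matters near the χ² = 4 boundary; conventional statements
of the Evans criteria are associated with the corrected statistic, so the
correction is on by default, exposed as an explicit flag, and recorded in
every result row and run manifest.

## Numerical choices

- **Ages** are truncated to completed years before binning, so the closed
  printed intervals tile all fractional ages; unknown ages go to a dedicated
  bucket that participates in overall analyses only. Consequently the
  overall a-cell is ≥ the sum of the four stratum a-cells, with equality
  exactly when no age is missing.
- **Zero cells**: PRR is kept faithful to its definition — a = 0 gives 0,
  c = 0 with a > 0 gives +infinity (which can still satisfy the criteria),
  an empty background or an entity with no reports in the stratum is
  undefined. No Haldane 0.5 correction is applied.
- **Degenerate tables** (empty stratum, zero marginal, no exposed reports)
  become flagged non-signals with NaN statistics and one log line each, so a
  single empty cell can never abort a 15,320-analysis screen.
- **Ties** in the cross-drug comparison mark every maximal entity as
  strongest, listed in name order; all table output is deterministically
  ordered (entity, fixed category sequence, PT, stratum) and byte-identical
  across repeated runs on identical inputs.
- **Rounding**: PRR and χ² are printed to 2 decimals in the shaped tables
  and percentages to 2 decimals in the demography table; the tidy results
  file keeps full precision.

## PT vocabulary

PT classification is an exact case-folded lookup into a closed set of ten
ovary/uterus categories; no MedDRA hierarchy traversal (LLT→PT rollup) is
attempted. The bundled `ovary_uterus_pts.csv` is a partial, hand-assembled
working vocabulary (71 PTs covering all ten categories) sufficient for the
bundled examples and the synthetic benchmarks; a complete several-hundred-PT
dictionary should be supplied for production screens and is accepted as a
plain two-column file.

## Synthetic-data generator

The generator emulates the gross structure of a female spontaneous-report
extract: each report independently draws an age stratum (defaults shaped
like a large statin extract: 0.2% / 1.8% / 20% / 49% across the four bands
with 29% missing ages), a Bernoulli exposure per catalog drug, and a
Bernoulli occurrence per catalog PT. Injected signals multiply one PT's
occurrence probability (capped at 1, with a warning) in reports exposed to a
chosen drug within a chosen stratum. Reports that would come out empty
receive one catalog-weighted fill-in drug or PT, so every report mentions at
least one of each; per-report counts are therefore Poisson-binomial with a
minimum of one, and optional mean-count parameters rescale the catalogs.
Presets keep common background drugs and events frequent so the fill-in
stays a small correction.

Because PT occurrence is independent of exposure except through the
injected couplings, every non-injected pair has expected PRR exactly 1, and
an injected pair's expected PRR approaches its multiplier when the baseline
is rare. The truth ledger stores the *exact* expectation computed from the
configured probabilities, including the fill-in correction (for the default
benchmark: 9.47 for multiplier 10), so recovery tests do not rely on the
rare-event approximation. Two deliberate simplifications: cross-PT coupling
through one drug injected on several PTs is treated as independent in the
expectation (exact when each injected drug targets one PT), and the tiny
exposure inflation from the drug-side fill-in is ignored (it cancels in
PRR, which conditions on realized exposure).

What the generator does **not** emulate — duplicate and versioned cases,
stimulated-reporting waves, drug–drug and indication confounding, time
trends, male reports — bounds what green tests show: they validate the
counting, the statistics and the screen logic under a clean reporting model,
not robustness to real-world reporting artifacts.

Recovery scoring: sensitivity is the fraction of injected triples flagged;
the false-positive rate is computed over analyses not involving any
injected PT, because a strong planted signal legitimately propagates to the
pooled class entity and to the overall stratum.

## Problem sizes used by the test suite and acceptance script

Null calibration uses 200 seeds of 20,000 reports (≈1,080 analyses per
seed); signal recovery uses 100 seeds of 50,000 reports with the benchmark
injection (multiplier 10, exposure 0.1, baseline 0.002); the consistency
ladder uses n ∈ {2,000, 32,000} over four seeds. These sizes give stable
Monte-Carlo estimates (binomial standard error below 0.1 percentage points
for the null rate) while keeping a full run to a couple of minutes on one
CPU. Demography arithmetic runs on deterministic cohorts rebuilt from
published marginal counts (151,924 and 916 reports), so those percentages
are exact, not sampled.

## Open design choices made here

- The four Evans-criteria quantities are computed per (entity, PT, stratum)
  with stratum-restricted backgrounds; a whole-population background for
  stratified analyses is deliberately not offered.
- Unmapped drug names are retained verbatim (case-folded) rather than
  dropped, so the PRR background reflects the full extract.
- "Comparable" signal strengths across drugs are not formalized; the
  comparison table ranks by PRR and leaves near-ties visible numerically.
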