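# Methods

## The screening model

`pvscreen` treats a spontaneous-report database as a collection of
deduplicated case reports and screens each (drug, event term set) pair by
disproportionality. For a drug D and a PT term set S, every case falls in
exactly one cell of the 2×2 table

|            | event in S | no event in S |
|------------|-----------:|--------------:|
| **drug D** | a          | b             |
| **no D**   | c          | d             |

where "drug D" means the case carries D in an accepted role (default:
Primary Suspected only) and "event in S" means at least one *reported
event* PT lies in S's inclusion list (indication PTs are never counted as
events). The counting unit is the report: a case with several PTs from S
still contributes one count to `a`. The comparator is the whole
deduplicated database, the standard full-background design; restricting
the background to same-class reports is a different (and non-default)
design that the role filter and dictionary make easy to emulate but that
this package does not implement as a switch.

Two statistics are computed per table:

* **ROR** (reporting odds ratio) — (a·d)/(b·c), with a Woolf/Wald 95 %
  interval exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)). z is fixed at 1.96 by
  pharmacovigilance convention. With a zero cell and the continuity
  correction off, the point estimate is the raw ratio (0 or ∞) and the
  interval is the uninformative (0, ∞); with `continuity=True` the
  Haldane–Anscombe +0.5 is added to all four cells *only* when some cell
  is zero. The correction is off by default: the signal rule requires
  a ≥ 3 anyway, so zero-cell tables can never signal, and leaving raw
  tables untouched keeps the estimator exactly ad/(bc) wherever it is
  used for inference.
* **IC** (information component) — the shrinkage observed/expected form:
  E = (a+b)(a+c)/n, IC = log₂((a+0.5)/(E+0.5)), with closed-form 95 %
  credibility bounds IC − 3.3·(a+0.5)^−1/2 − 2·(a+0.5)^−3/2 and
  IC + 2.4·(a+0.5)^−1/2 − 0.5·(a+0.5)^−3/2. This deterministic
  approximation of the Bayesian shrinkage estimator was chosen over the
  original gamma-mixture BCPNN because it is closed-form and exactly
  testable; the computation sits behind a single function
  (`compute_ic`) so the gamma variant could be added without touching
  callers. The +0.5 shrinkage pulls rare-event estimates toward 0 and
  vanishes as a grows, so IC → log₂(observed/expected) asymptotically;
  IC is exactly 0 when a = E (both numerator and denominator gain 0.5).

A pair is a **signal** only if all four criteria hold strictly: a ≥ 3
(configurable `min_cases`), ROR lower bound > 1, IC > 0, IC lower bound
> 0. The conjunction suppresses single-case and small-count alarms at a
modest cost in sensitivity; under a null (λ = 1) simulation the flagged
fraction is ~1–2 %, well below the ~2.5 % that the ROR bound alone would
give.

## Case assembly and deduplication

Quarter files are `$`-separated ASCII with a header line (tab available
for fixtures); rows whose field count disagrees with the header go to a
rejects report and parsing continues — silently dropping or silently
repairing malformed rows both hide data problems. A report must have at
least one event PT and one drug entry to be a valid case; DEMO rows
failing either join are excluded and counted, as are DRUG/REAC/INDI rows
with no DEMO row.

One report per case identifier is retained: the highest receipt sequence
(`caseversion`) wins, ties broken by the lexicographically highest
`primaryid`, and output is sorted by case id — making deduplication
deterministic and idempotent. Follow-up versions are *replaced*, not
merged: merging event sets across versions can resurrect events that a
follow-up retracted.

Demographic decoding: sex F/M → female/male, else unknown; occupation
codes MD, PH, OT, HP → health professional, CN, LW → non-health
professional, else unknown; region from a shipped country→continent
lookup (unknown country → unknown). Ages are converted to years from the
(value, unit) pair — DEC as decades (×10), MON /12, WK /52, DY /365.25;
unparseable values, unknown units and results outside [0, 150) become
missing. Age bands are <18, 18–65 (18 ≤ age < 65), ≥65: the upper edge is
assigned to the older band, a convention the band labels themselves leave
ambiguous.

## Vocabularies

The drug dictionary maps verbatim names to ATC codes after case-folding,
whitespace collapsing and punctuation stripping — *exact* match only.
Fuzzy matching was deliberately excluded: edit-distance rules produce
irreproducible mappings and there is no principled threshold; unmapped
names simply stay unmapped and never enter a screen. The bundled
dictionary covers 65 distinct N06A codes (real, public WHO ATC codes)
plus common brand synonyms.

Term sets are candidate-PT lists minus explicit exclusion lists, the way
an SMQ is narrowed to drug-attributable events. Genuine MedDRA term lists
are licensed and cannot be redistributed, so the bundled seizure set and
confounder catalog are synthetic skeletons: placeholder `9xxxxxxx` codes
with the documented set sizes (84 − 43 = 41 seizure PTs; confounder
categories of 81, 30, 215, 115 and 181 PTs). The two excluded terms that
are publicly identifiable (post-stroke seizure 10076981, post-traumatic
epilepsy 10036312) keep their real codes. Loaders accept user TSVs of the
same shape for the real vocabularies.

## Confounder reanalysis

A report is *confounded* when any of its event **or** indication PTs
falls in a confounder category: a co-existing condition appears in
spontaneous reports either as a coded event or as the indication of a
prescribed drug, and consulting only one of the two misses half the
mechanism. Flagged reports are removed from the entire analysis — all
four cells — before rescreening; removing them only from `a` would leave
confounded reports inflating the background and bias d. Verdicts:
`robust_signal` (primary and adjusted both signal), `false_signal`
(primary signalled, adjusted does not), `no_primary_signal`. A drug that
loses all co-reports gets an explicit a = 0 adjusted table rather than
disappearing from the output.

## The synthetic generator

Per case: demographics are categorical draws; one PS drug is drawn from a
background frequency table; each background PT is an independent
Bernoulli draw, with term-set PT probabilities multiplied by λ(drug, set)
(p·λ > 1 is rejected at config validation); configured (drug, category)
pairs add, with probability q, a confounder-category indication PT *and*
a term-set event PT; with probability `duplicate_rate` the case also
emits an earlier version (lower ordinal, same content but only its first
event PT, so keeping the wrong version is detectable); a case that drew
no PT receives a fallback filler PT, keeping every report valid without
touching term-set probabilities. Everything derives from one root seed
and fixed draw order, so identical configs produce byte-identical quarter
files.

Because the draws are independent, the per-drug event probability is
closed-form: s_D = 1 − (1 − q_D)·∏_{t∈S}(1 − p_t·λ_D), giving expected
cells a = nπ_D s_D, etc., and an expected ROR — the oracle used by the
recovery tests. Note ROR(λ) ≠ λ: an odds ratio exceeds the rate ratio,
and planting λ on one drug contaminates the background of the others (at
the default mix, λ = 8 on bupropion implies an expected ROR ≈ 8.76 when
nothing else is planted).

Defaults are calibrated to the published seizure-cohort description:
stratum probabilities proportional to the 7,393-case Table-1 counts
(54.5 % female, 49.5 % aged 18–65, 70 % health-professional reporters,
67.1 % region unknown, …); drug backgrounds proportional to the eight
most-reported antidepressants' report totals; four emitted seizure PTs at
0.005 each, a ≈ 2 % per-case seizure marginal matching the null drugs'
printed constituent ratios; duplicate rate 0.1. What the generator does
**not** emulate: free-text drug-name noise, multi-drug reports (one PS
drug per case keeps the oracle closed-form; a multi-drug flag was
considered and deferred), dates and temporal reporting trends,
dose/formulation fields, and correlated demographics. Passing recovery
tests therefore demonstrate that the statistics and plumbing are correct
under a faithful independence model — not that real FAERS name-mapping or
multi-suspect attribution is solved.

## Descriptives

Percentages use half-up rounding (via `decimal`), which reproduces every
published stratum percentage of the 7,393-case table from its integer
counts — banker's rounding does not. One published per-drug constituent
ratio (bupropion, printed 6.78 %) is inconsistent with its own printed
counts (100·1757/25939 = 6.7736 → 6.77 under any standard rounding); the
package reports the count-derived value. Similarly, the published claim
that 7,393 is "1.29 %" of 336,566 reports is arithmetically wrong
(it is 2.20 %) and is not used anywhere.

## Problem sizes and test design

Golden descriptive tests are exact and instant. The ROR oracle test is
exhaustive over all 810,000 tables with cells 1..30 (relative error
< 1e−12 against direct vectorized arithmetic). Simulation studies use 20
seeded replicates each: null calibration and confounder demotion at
50,000 cases, λ-recovery at 200,000 cases per replicate with one planted
drug per config — sizes at which the smallest drug stratum still yields
hundreds of co-reports, chosen as the package's standard validation
conditions. Duplicate generation is disabled inside these three studies
(deduplication is validated separately and provably restores the
latest-version stream, so it cannot affect the statistics). Wald
intervals cover an analytic target in ≈ 95 % of replicates; the tests
require ≥ 18/20.

## Known limitations

* Single-quarter ingestion only; no multi-quarter delta or nullification
  handling, and no pre-2012Q4 schema variants.
* No stratified or regression-based adjustment (MGPS, propensity
  scores); the confounder mechanism is exclusion-based, as in the
  screening design it implements.
* The ROR/IC screen is signal *generation*: its outputs rank hypotheses
  and are not effect estimates or causal claims.
* With the full-database comparator convention, whether flagged
  confounded reports should also leave the background is a design choice;
  they do here (whole-table exclusion), which is conservative for d but
  keeps the adjusted table a true 2×2 partition of the analyzed set.
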