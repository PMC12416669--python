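# Methods

`faerspv` screens spontaneous adverse-event reports for drug–event
disproportionality, in the layout used by the public FAERS quarterly files.
This note records the model, the conventions, and the design choices that
were genuinely open.

## Report model and case definition

A *case* may be represented by several report versions sharing a CASEID;
versions differ in PRIMARYID and FDA receipt date (FDA_DT). Deduplication
keeps, per CASEID, the version with the maximum FDA_DT, breaking ties by
the maximum PRIMARYID. A missing FDA_DT sorts as the oldest possible date,
so a dated version always beats an undated one; a record with no CASEID is
retained as its own singleton (it cannot be linked to anything). The
operation is idempotent, and is verified against a brute-force
`(fda_dt, primaryid)`-max oracle.

A case belongs to the target event when at least one of its reactions
matches the target MedDRA Preferred Term — by PT code where both sides have
one, otherwise by case-insensitive exact name. The PT match itself is the
documentation of the event; no free-text narrative mining is attempted
(narratives are not part of the public quarterly files). Exposure is
defined by the Primary Suspect (PS) role only; SS/C/I mentions are
excluded. A report with *k* distinct PS drugs contributes one count to each
of the *k* drugs; this is a convention, not an identity — the alternative
(excluding multi-PS reports) is supported by filtering the exposure map
upstream.

Verbatim drug names are normalized by uppercasing, whitespace collapsing,
stripping trailing parentheticals and a documented list of dose-form/dose
tokens, then exact lookup in a user-supplied synonym table (two-column
delimited text, DrugBank/MeSH-style). There is deliberately no fuzzy
matching: a miss stays verbatim and flagged, so mapping-table coverage is
auditable. ATC classification is likewise an exact lookup from generic name
to ATC code; the code's first letter selects one of the 14 anatomical main
groups.

Ages are converted to years using DEC×10, YR×1, MON÷12, WK÷52.1775,
DY÷365.25, HR÷8766; results outside [0, 120] years are treated as unknown,
and a present age with a blank unit is assumed to be years (the common
FAERS pattern).

## Disproportionality statistics

For drug D and event E over N deduplicated reports, with cells
a (D∧E), b (D∧¬E), c (¬D∧E), d (¬D∧¬E):

**ROR** = (a·d)/(b·c), with the log-symmetric Wald interval
exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)). With any zero cell the ROR is
reported as undefined rather than silently corrected; an optional Haldane
correction (+0.5 to every cell) can be enabled explicitly. Every emitted
interval satisfies √(ci_low·ci_high) = ROR to 1e-6 relative (asserted
in-code); this identity also lets printed (ROR, CI) triples be checked for
internal consistency.

**BCPNN information component** IC = log₂ P(D,E)/(P(D)P(E)). The default is
the classical moment approximation of the posterior under conjugate priors
γ₁₁ = 1, α₁ = β₁ = 1, α = β = 2, with γ chosen data-dependently so the
prior IC expectation is 0 under independence:

    E[IC]  = log₂ ( (a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁)) )
    V[IC]  = (1/ln2)² [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                      + (N−a−b+α−α₁)/((a+b+α₁)(1+N+α))
                      + (N−a−c+β−β₁)/((a+c+β₁)(1+N+β)) ]
    IC025  = E[IC] − 2·√V[IC]

"IC025" follows the field's conventional label even though −2 SD has
≈97.7% one-sided normal coverage. A seeded Monte-Carlo alternative draws
the three probabilities from their independent conjugate Beta posteriors
and reports the literal 2.5th percentile of the IC draws. The two variants
agree within 0.15 bits once a ≥ 10; below that the posterior's left skew
pulls the exact percentile up to ~0.4 bits below the moment bound, so the
moment method is the *less* conservative of the two for very small counts.
Both are exposed; the moment method is the default because it is the
parameterization used across the FAERS disproportionality literature.

**Dual signal criterion.** A drug is flagged only when all three hold:
a ≥ 3, ROR lower 95% bound > 1, and IC025 > 0 (conjunction). No
multiple-testing adjustment is applied — the screen is a hypothesis
generator, not a confirmatory analysis. Screen output is ordered with
signals first, descending by ROR.

## Descriptive conventions

Percentages are computed on the total case count (unknowns included) and
rounded to one decimal, half-up — the rule that regenerates published
case-series tables from their raw counts. Age statistics use known ages
only; the median/IQR quantile rule is linear interpolation (the numpy
default), documented because published tables rarely name one. A report may
carry several outcome codes and increments each, which is why outcome
percentages need not sum to 100; "Unknown" means no outcome row at all.
Report year comes from FDA_DT (fallback: event date). Age-group histograms
use closed-open bins. Country uses the occurrence country with fallback to
the reporter country.

## Synthetic cohort generator

The generator emulates the features of a spontaneous-report stream that the
pipeline must survive, with a truth model simple enough to solve in closed
form:

- exactly one PS drug per report, drawn from a vocabulary of 30 drugs at 2%
  marginal each by default (the remaining mass is an implicit background
  pool). One PS drug keeps the 2×2 probability table analytic; multi-PS
  handling is a property of the real-data pipeline, not of the truth model.
- each vocabulary event is included independently with its background
  probability (1% for the target PT by default), multiplied by the planted
  rate ratio λ for the PS drug and capped at 1. The expected ROR follows
  from the implied cell probabilities; with all other drugs at background,
  λ = 10 on a 1% event gives (0.1/0.9)/(0.01/0.99) = 11.0.
- 8% of cases emit a second report version (same CASEID, higher PRIMARYID,
  non-decreasing FDA_DT, identical reactions), so deduplication correctness
  is observable and order-exchangeable with selection.
- 30% of drug mentions are written as brand-name variants, so name
  normalization has real work; the matching synonym table is generated
  alongside.
- demographics: sex F/M/missing at 0.46/0.36/0.18, ages normal(51, 19)
  years emitted in mixed units (YR/MON/DEC), 40% missing; reporter,
  country and outcome distributions follow the same published case-series
  profile. These defaults were fixed once when the generator was written.

What the generator does **not** model: drug co-prescription correlation,
masking/competition bias, reporting-rate drift over calendar time, and
event-term misspelling. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under a clean reporting model, not
robustness to those real-data pathologies.

## Problem sizes and determinism

The test suite and the acceptance script use cohorts of 5,000–50,000
reports, with CI-coverage runs at 100 replicates of 12,000 reports
(expected a ≈ 24 for the planted drug) and null-calibration runs at 10
replicates of 20,000 — sizes chosen so every binomial check has comfortable
power while a full run stays in tens of seconds. All randomness flows from
a single integer seed through `numpy.random.default_rng`; the same seed
yields byte-identical generated files and pipeline outputs.

## Known limitations

- The screen is case/non-case disproportionality only: no PRR, EBGM/MGPS,
  regression shrinkage, or time-to-onset statistics.
- Synonym and ATC tables are user inputs; the packaged tables cover only a
  demonstration vocabulary. Full-database results depend materially on
  mapping-table coverage.
- Label-warning status is an input annotation, not computed — FDA label
  text mining is out of scope.
- Quarantine policy for malformed rows (type failures are quarantined with
  reasons, orphan child rows dropped with counts) is this package's
  decision; public documentation of FAERS does not prescribe one.
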