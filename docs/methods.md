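# Methods

## Scope and model

`evita-score` encodes a deterministic scoring rubric for the early
appraisal of a new drug's additional therapeutic value in a single
approved indication. The unit of assessment is a drug–indication pair,
described by a dossier containing (a) the therapeutic context, (b) a list
of RCT records the assessor extracted from the literature, and (c) two
arm-level risk profiles. All judgement calls that require critical
appraisal — which trials exist, their Jadad items, the direction of each
result, the worst adverse-event frequency per CTCAE severity group — are
made by the assessor and recorded in the dossier; the package then applies
the rubric mechanically and reproducibly, with a complete audit trail.
Literature retrieval, SPC parsing, NNT computation from raw event tables
and meta-analytic pooling are deliberately out of scope.

## Eligibility and trial setting

A trial enters the evaluation when it has Jadad ≥ 3 (computed from the
five instrument items when given, clamped at 0; a precomputed integer is
also accepted) and an admissible comparator: pure placebo comparison is
rejected whenever the context lists any established therapy. Rules are
applied in a fixed order: assessor-recorded exclusions (free-text note,
e.g. GCP concerns) first, then the quality cut-off, then the comparator
rule, then duplicate-protocol collapse, then supersession of surrogate
trials by patient-relevant evidence. Ordering matters only for the reason
string attached to a doubly-ineligible trial and was chosen so the most
specific reason wins.

Duplicate collapse keeps the first record in dossier order; the trial
record carries no enrolment figure from which "larger evidence" could be
judged, and the canonical twin-protocol case involves identical trials.
Supersession removes surrogate trials from *efficiency counting* only —
their adverse-event data may still inform the dossier's risk profiles,
which are arm-level aggregates independent of the trial list.

The setting letter is A when any included trial addresses patient-relevant
outcomes, B otherwise; the digit is 1 when any trial at the tier-defining
outcome level is head-to-head, else 2. When designs are mixed,
head-to-head dominates, as the stronger design. An empty included list
yields N/A: no score is computed and the report renders a yield sign.
N/A is an assessment result, not an error (the CLI exits 0).

## Efficiency score

Directional evidence scores by count saturation at two trials:
superiority +5.0 (one trial) / +7.5 (two or more) with patient-relevant
outcomes, mirrored negatively for inferiority, halved for surrogate-only
evidence. Non-inferiority/equivalence trials score 0 in isolation and
otherwise pull the directional sum toward zero by 5/3 points (one trial)
or 2.5 (two or more), again halved for surrogates. The one-trial cells
are implemented as the exact fractions 5/3 and 5/6 (displayed rounded as
1.67/0.83) so that the patient-relevant = 2 × surrogate relation holds
identically on every cell. When superiority and inferiority evidence both
exist — a configuration the source tables do not address — both base
contributions apply and the equivalence adjustment follows the sign of
their sum, vanishing when they cancel; this preserves the "in the
presence of" semantics symmetrically and is noted in the result.

Trials that merely failed to show a significant difference (a failed
superiority trial without an equivalence claim) count toward none of the
three directions and contribute zero — they still define the trial
setting and can trigger supersession.

The strength-of-effect modifier multiplies the signed base sum. Its key
is the per-year NNT, obtained as NNT × duration-in-years under the
assumption that absolute risk reduction accrues linearly over the trial.
When several superiority trials carry an NNT, the smallest annualized
value is used (the most favorable pivotal evidence) and noted; when a
trial records ARR instead, NNT = 1/ARR (both given triggers a 5%
reciprocal-consistency check at load time); when the duration is absent
the NNT is taken as already per-year, with a note. Without any NNT the
modifier is absent and the sum stands — required to reproduce the
surrogate-endpoint cases, where no NNT is calculable. Band bounds are
half-open with the printed lower bound inclusive (treatment NNT exactly
10 → 1.0; prevention NNT exactly 1000 → 0.25).

## Risk score

Each arm's sum is the worst-single-AE penalty in each severity group plus
the interaction penalty, ranging from 0 to −10.0. Frequencies may be
recorded as exact percentages or as named SPC classes; classification is
half-open with inclusive lower bounds (0.1%, 1%, 10%) and exactly 0 is a
distinct class from "below 0.1%" (only grade 4+5 events are penalized at
sub-0.1% frequencies). The rubric's resolution is the frequency *class*:
arms whose worst AEs fall in the same class cancel exactly, regardless of
within-class differences — the only reading consistent with the published
worked results, where a "slightly less frequent" grade-3 difference
contributes nothing. No smoothing is applied at class boundaries (9.9% vs
10.1% score as different classes); assessors worried about boundary noise
should record classes, not percents. The net score is drug sum minus
comparator sum, antisymmetric by construction and positive when the
comparator's profile is worse.

## Combination, bounds, banding

The EVITA total is reported efficiency plus net risk. `score_bounds()`
re-derives the achievable envelope by brute force — every count
configuration (0/1/≥2 per direction), both outcome levels, every modifier
band plus the no-NNT case, and all 5×5×5×5 risk-class/interaction
combinations per arm — rather than hard-coding ±25; `combine` asserts
every computed total against it and raises an internal-consistency error
on violation (a table bug, never bad input).

The color band is presentation only. The published rubric defines the
bands qualitatively (green positive, yellow around zero, red negative);
this implementation uses a configurable yellow half-width defaulting to
2.0 points, which keeps the borderline worked cases (−1.0, −1.25) yellow.
The band never feeds back into any arithmetic.

Rounding of the efficiency score is configurable per dossier because the
published worked examples are inconsistent: one reports 3.75 rounded to
+4.0, another reports −1.25 unrounded. Modes are `none` (default) and
`half_up_integer` (decimal half-away-from-zero); each bundled fixture
pins the mode that reproduces its printed value.

## Synthetic dossiers

`generate_synthetic_dossier(seed, n_trials)` emits schema-valid dossiers
from a private seeded RNG: every enum literal of every field appears with
positive probability, Jadad items arrive both itemized and precomputed,
strength data as NNT (with or without duration) or ARR, and duplicate
keys and assessor exclusion notes occur occasionally. It emulates the
*structure* of real dossiers, not their joint distribution — result
directions are independent of comparator or outcome level, and
frequencies are uniform — so passing property tests demonstrate schema
closure, determinism and bound safety, not calibration against real
trial programmes. Sizes used in the shipped checks: 1000 seeds for enum
coverage, 100 for file round-trips, 10,000 for the bound sweep — all
desk-scale, finishing in seconds.

## Known limitations

- The rubric cannot weight trials by methodological quality beyond the
  Jadad cut-off, and saturates at two trials per direction.
- NNT annualization assumes linear risk accrual; for strongly
  time-varying hazards the per-year NNT is an approximation.
- The drug/comparator risk profiles are dossier-level aggregates; the
  package cannot verify that they derive from the same evidence base as
  the efficiency trials.
- Class-boundary effects in AE frequencies are intentionally sharp (see
  above).
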