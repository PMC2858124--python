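# evita-score

Early benefit/risk scoring of new drugs from randomized-controlled-trial
evidence.

New drugs routinely reach the market before their additional therapeutic
value over established therapy is clear: pivotal trials often use placebo
where an active comparator exists, or surrogate endpoints (HbA1c, scale
scores) where patient-relevant outcomes matter. `evita-score` implements
EVITA (EValuation of pharmaceutical Innovations with regard to Therapeutic
Advantage), a deterministic, fully transparent rubric that rates one drug
in one approved indication on a −25…+25 point scale — or returns an
explicit "not assessable" verdict when the available trials do not support
any calculation. It is a horizon-scanning / early-HTA screening instrument
for pharmacologists, drug-bulletin editors and HTA analysts, not a
replacement for a full health-technology assessment (in particular, it
performs no meta-analytic pooling and no study weighting).

## The rubric

Given an *assessment dossier* (one YAML/JSON document per drug–indication
pair) the pipeline runs:

1. **Eligibility.** Each RCT needs a Jadad quality score ≥ 3. Placebo as
   sole comparator is admissible only when no established therapy exists or
   in an add-on design; trials run under an identical protocol collapse
   into one logical trial; once patient-relevant evidence exists,
   surrogate-outcome trials are dropped from efficiency counting. Every
   exclusion is recorded with its reason.
2. **Trial setting.** A (patient-relevant outcomes) vs B (surrogate only);
   1 (head-to-head vs established therapy) vs 2 (placebo comparison);
   N/A when no trial survives — then the verdict is a yield sign and no
   score exists.
3. **Efficiency score.** Superiority in 1 / ≥2 patient-relevant RCTs earns
   +5.0 / +7.5 points, inferiority the negatives; non-inferiority or
   equivalence trials attenuate directional evidence by 5⁄3 (one trial) or
   2.5 (two or more) points toward zero; all magnitudes halve for
   surrogate-only evidence. The signed sum is multiplied by a modifier
   keyed on the annualized number needed to treat
   (NNT/year = NNT × duration in years): for treatment aims 2.0 / 1.5 /
   1.0 for NNT < 3 / 3–<10 / ≥10, for prevention eight bands from 2.0
   (NNT < 20) down to 0.25 (NNT ≥ 1000).
4. **Risk score.** Per arm, the worst single adverse event in each CTCAE
   severity group (grades 4+5, grade 3, grades 1+2) is penalized by SPC
   frequency class (e.g. grade 4+5 at ≥10% costs −4.0), plus an
   interaction penalty (0 to −2.0; "no information" costs −1.0). The net
   risk score opposes the drug arm's sum to the comparator's, so a cleaner
   profile than the comparator yields positive points.
5. **EVITA score** = efficiency + net risk, provably within [−25, +25],
   displayed as a color-coded bar: green (clearly positive), yellow
   (around zero, inconclusive), red (clearly negative). Therapeutic aim
   and disease-severity category annotate the report but never enter the
   arithmetic.

## Worked example

```sh
$ evita score src/evita/fixtures/lenalidomide_mm.yaml -o report.json
excluded MM-010: duplicate protocol
lenalidomide: setting A2, EVITA score +6 (green) -> report.json
```

The two twin-protocol trials collapse into one logical patient-relevant
superiority trial (+5.0); the NNT of 2.6 observed over 1.5 years is 3.9
per year, giving modifier 1.5 and an efficiency score of +7.5; identical
AE classes in both arms leave only the interaction difference (−1.5), so
the total is +6.0 — a likely innovative drug for this indication. The
JSON report carries every intermediate and the full exclusion audit trail.

Running all five bundled dossiers
(`python examples/score_worked_examples.py`) prints:

```
lenalidomide                 setting A2  efficiency +7.50  risk -1.50  EVITA +6.00 (green)
pioglitazone                 setting B2  efficiency +4.00  risk -1.00  EVITA +3.00 (green)
pioglitazone                 setting A2  efficiency +0.00  risk -1.00  EVITA -1.00 (yellow)
bupropion                    setting B1  efficiency -1.25  risk +0.00  EVITA -1.25 (yellow)
zoledronic acid (5 mg annually) setting N/A — not assessable (placebo despite established therapy)
```

The two pioglitazone lines show the same drug re-evaluated four years
apart: a large patient-relevant outcome trial that failed to show
superiority supersedes the earlier surrogate evidence and erases the
initially promising score. Other entry points: `evita synth --seed N`
writes a random valid dossier, `evita bounds` prints the enumerated score
envelope, and `examples/` holds short narrative scripts for building
dossiers in Python and probing the envelope.

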