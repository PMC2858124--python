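"""Score the five bundled worked-example dossiers and print the verdicts.

Each line shows the trial setting (A/B = patient-relevant/surrogate
outcomes, 1/2 = head-to-head/placebo comparison), the efficiency and net
risk components and the combined EVITA score with its traffic-light band.
An N/A verdict means no trial survived the eligibility filter, so no
score is computable — itself a telling assessment result.
"""

from evita import FIXTURE_NAMES, evaluate, fixture_path, load_dossier

for name in FIXTURE_NAMES:
    result = evaluate(load_dossier(fixture_path(name)))
    ctx = result.context
    if result.assessable:
        print(
            f"{ctx.drug_name:<28} setting {result.setting.value.value}  "
            f"efficiency {result.efficiency.reported_score:+5.2f}  "
            f"risk {result.risk.net_score:+5.2f}  "
            f"EVITA {result.total:+5.2f} ({result.band.value})"
        )
    else:
        excluded = ", ".join(e.reason for e in result.setting.excluded_trials[:1])
        print(f"{ctx.drug_name:<28} setting N/A — not assessable ({excluded})")
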