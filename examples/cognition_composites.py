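"""From raw neuropsychological scores to composite change scores.

Generates a small cohort in raw-score mode, derives speed-accuracy
trade-off (SAT) scores and Stroop interference, z-scores every test
against the baseline population, and averages them into the cognitive
index and three domain composites; change = follow-up minus baseline.
"""

import dataclasses

from svdnet import (
    CognitiveRecord,
    GeneratorConfig,
    baseline_stats_from_cohort,
    compose_domains,
    delta_scores,
    generate_cohort,
)

cohort = generate_cohort(GeneratorConfig(n_subjects=30, raw_scores=True), seed=7)
fields = {f.name for f in dataclasses.fields(CognitiveRecord)}
records = [
    CognitiveRecord(**{k: v for k, v in row.items() if k in fields})
    for row in cohort.cohort.to_dict("records")
]

# norms come from the baseline wave of the study population itself
stats = baseline_stats_from_cohort(records)

subject = records[0].subject_id
baseline = next(r for r in records if r.subject_id == subject and r.wave == "baseline")
followup = next(r for r in records if r.subject_id == subject and r.wave == "followup")

comp_b = compose_domains(baseline, stats)
comp_f = compose_domains(followup, stats)
delta = delta_scores(comp_f, comp_b)

print(f"subject {subject}")
for name in ("cognitive_index", "memory", "psychomotor_speed", "executive_function"):
    print(f"{name:20s} baseline {getattr(comp_b, name):+.3f}  "
          f"followup {getattr(comp_f, name):+.3f}  delta {getattr(delta, name):+.3f}")
# Composites are means of the constituent test z-scores (baseline-anchored,
# so ~0 is the cohort average at baseline); negative deltas mean decline.
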