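"""Demographic summary of the packaged 22-patient ADPKD reference cohort."""

import json

import sonotkv as sk

table = sk.reference_cohort()
summary = sk.summarize_cohort(table)
print(json.dumps(summary.display(), indent=2))
# pct_female, mean/median age and height, and the BMI band counts
# (normal / overweight / obese) summarise the study population.
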