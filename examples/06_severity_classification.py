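"""ADPKD severity classes (1A-1E) from age, height and total kidney volume.

Height-adjusted TKV is compared against age-dependent growth-band boundaries
150*(1+r)^age for r = 1.5, 3, 4.5, 6 %/yr; classes increase in severity.
"""

import pandas as pd

import sonotkv as sk
from sonotkv.classify import MayoInput, class_thresholds

for age, height, tkv in ((25, 1.60, 240.0), (45, 1.75, 1200.0),
                         (60, 1.68, 2600.0)):
    cls = sk.mayo_classify(MayoInput(age=age, height=height, tkv_mL=tkv))
    print(f"age {age}, height {height} m, TKV {tkv:7.1f} mL -> "
          f"htTKV {cls.httkv_mL_per_m:7.1f} mL/m -> class {cls.label}")

b = class_thresholds(45)
print("class boundaries at age 45 (mL/m):",
      [round(x, 1) for x in b])

# Cohort-level comparison of two measurement sources
demo = pd.DataFrame({"study_id": ["p1", "p2", "p3"],
                     "age": [40, 55, 62], "height_m": [1.70, 1.82, 1.60]})
us = pd.DataFrame({"patient_id": ["p1", "p2", "p3"],
                   "tkv_mL": [900.0, 1500.0, 800.0]})
mri = us.assign(tkv_mL=[870.0, 1620.0, 1150.0])
res = sk.classify_cohort({"us": us, "mri": mri}, demo)
print("US counts :", res["counts"]["us"])
print("MRI counts:", res["counts"]["mri"])
ag = res["agreement"]["mri_vs_us"]
print(f"agreement: {ag['n_agree']}/{ag['n']} patients; "
      f"discordant: {ag['discordant']}")
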