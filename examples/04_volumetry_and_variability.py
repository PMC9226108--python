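"""Patient-level TKV aggregation and interscan variability on worked numbers.

TKV per patient: left + right within each scan repetition, then the mean over
repetitions.  Interscan variability: mean absolute deviation of a kidney's
three repeated measurements from their own mean, averaged across kidneys.
"""

from sonotkv import interscan_variability, patient_tkv
from sonotkv.types import KidneyVolumeRecord as R

records = [R("PKD_X", "left", i + 1, v, "reader1")
           for i, v in enumerate((500.0, 510.0, 520.0))]
records += [R("PKD_X", "right", i + 1, v, "reader1")
            for i, v in enumerate((600.0, 590.0, 610.0))]

tkv = patient_tkv(records)
print(f"per-scan totals 1100, 1100, 1130 -> TKV {tkv.tkv_mL:.1f} mL "
      f"over {tkv.n_observations} observations")

one_kidney = [R("PKD_X", "left", i + 1, v, "reader1")
              for i, v in enumerate((100.0, 110.0, 120.0))]
print(f"kidney scanned (100, 110, 120) mL -> interscan variability "
      f"{interscan_variability(one_kidney):.3f} mL")
# deviations from the mean 110 are (10, 0, 10); their average is 6.667 mL.

two_kidneys = one_kidney + [R("PKD_X", "right", i + 1, 200.0, "reader1")
                            for i in range(3)]
print(f"adding a perfectly repeatable kidney halves it: "
      f"{interscan_variability(two_kidneys):.3f} mL")
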