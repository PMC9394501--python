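"""Construct cardiovascular phenotypes from raw measurements and records.

Shows the medication adjustments (+15/+10 mm Hg blood pressure, LDL/0.7 and
total cholesterol/0.8), iterative Tukey outlier removal, and the CAD
case/control/excluded algorithm driven by ICD/OPCS code lists.
"""

import numpy as np

from ykin import phenotypes as ph
from ykin.phenotypes import HealthRecord

# medication adjustments restore the untreated scale
sbp, dbp = ph.adjust_blood_pressure([120.0], [80.0], on_med=[True])
print(f"measured 120/80 on antihypertensives -> adjusted {sbp[0]:.0f}/{dbp[0]:.0f}")
lip = ph.adjust_lipids([5.6], [3.5], [1.4], [1.5], on_med=[True], apply_tukey=False)
print(f"LDL 3.5 on statins -> {lip['ldl'][0]:.1f}; total 5.6 -> {lip['total_chol'][0]:.1f}")

# iterative Tukey filter: the huge outlier is removed, quartiles recomputed,
# and the pass repeated until stable
vals = list(range(1, 10)) + [1000.0]
mask = ph.tukey_filter(vals)
print(f"Tukey filter keeps {int(mask.sum())} of {len(vals)} values "
      f"(removed: {[v for v, m in zip(vals, mask) if not m]})")

# CAD classification: MI/PCI/CABG/death codes are cases; angina or nitrate
# medication without a case code means exclusion; the rest are controls
print("I22 hospital record ->", ph.classify_cad([HealthRecord("hospital_icd10", "I22")]))
print("I20.0 angina only    ->", ph.classify_cad([HealthRecord("hospital_icd10", "I20.0")]))
print("no records           ->", ph.classify_cad([]))
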