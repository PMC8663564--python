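"""Load a raw long-format export and apply the e-SDMT dexterity correction.

The raw table has one row per test and metric.  The cognitive e-SDMT score
(correct symbol-digit responses in 60 s) has a motor component; dividing it
by the app's 15-second digit-tapping "baseline" step isolates information
processing speed.
"""

import tempfile
from pathlib import Path

import practicecurve as pc

raw = """floodlightOpenId,testName,handUsed,testStartedAt,testMetricName,testResultMetricValue,age
p1,e-SDMT,,2021-01-01,correctResponses,30,52
p1,e-SDMT,,2021-01-01,baselineCorrectResponses,60,52
p1,e-SDMT,,2021-01-08,correctResponses,36,52
p1,e-SDMT,,2021-01-08,baselineCorrectResponses,60,52
p1,e-SDMT,,2021-01-15,correctResponses,40,52
p1,e-SDMT,,2021-01-15,baselineCorrectResponses,64,52
p2,FingerPinching,left,2021-01-02,successfulPinches,18,47
p2,FingerPinching,right,2021-01-04,successfulPinches,21,47
"""

path = Path(tempfile.mkdtemp()) / "export.csv"
path.write_text(raw)

cohort = pc.load_cohort(path, cutoff_date="2021-07-31")
for unit in cohort.units:
    print(f"{unit.unit_id:10s} {unit.test:15s} {unit.n_reps} repetitions, "
          f"values {[float(v) for v in unit.values]}")

corrected = pc.correct_sdmt(cohort)
sdmt = [u for u in corrected.units if u.test == "e-SDMT"][0]
print("\ncorrected e-SDMT (main / baseline ratio, dimensionless):")
print([round(float(v), 3) for v in sdmt.values])
# A rising ratio means processing speed itself improves, not just tapping.
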