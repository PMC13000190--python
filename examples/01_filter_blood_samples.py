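"""Apply the blood-sample preparation rules to a small synthetic table.

Demonstrates detection-limit flooring and the between-sample independence
rules: the >56-day spacing rule, the 14-56-day exception for a >10 ug/dL
rise (a new exposure event), and the <14-day replacement rule (rising lead
from the same event).
"""

import pandas as pd

from condorlead import apply_detection_floor, select_independent_samples

samples = pd.DataFrame({
    "ID": ["C001"] * 5,
    "date": pd.to_datetime(["2015-01-01", "2015-01-08", "2015-02-05",
                            "2015-03-20", "2015-06-15"]),
    "value": [4.2, 33.0, 48.0, 12.0, 3.0],
})

floored = apply_detection_floor(samples)
print("After flooring (values <=5 ug/dL recorded as 2.5, censored flag):")
print(floored, "\n")

independent = select_independent_samples(floored)
print("Independent samples retained:")
print(independent)
print("""
Jan 8 replaces Jan 1 (a higher value <14 days later is the same exposure
event still rising); Feb 5 stays (28 days later and >10 ug/dL higher, a
new exposure); Mar 20 is dropped (43 days later but lower); Jun 15 stays
(>56 days since the last retained sample).""")
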