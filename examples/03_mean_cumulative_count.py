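"""Mean cumulative count of recurrent events with death as competing risk.

MCC(t) is the expected number of events per child by age t; each event
increment d(u)/n(u) is discounted by the Kaplan-Meier probability of
having escaped death before u.  With neither deaths nor censoring it is
exactly the running mean event count.
"""

import numpy as np

import regiscan as rs

# four children: one dies at age 1.5, one emigrates at 3
event_ages = [[0.5, 1.0], [2.0, 2.5, 4.0], [1.2], []]
death_ages = [np.nan, np.nan, 1.5, np.nan]
censor_ages = [5.0, 5.0, 5.0, 3.0]
# note child 2's event at 1.2 precedes their death at 1.5

curve = rs.mean_cumulative_count(event_ages, death_ages, censor_ages)
print(curve.to_frame().round(4).to_string(index=False))
for t in (1.0, 2.5, 5.0):
    print(f"MCC({t}) = {curve(t):.4f}")
# The age-2.0 step and later ones are scaled by S_D(u-) = 0.75 after the
# death, and by shrinking risk sets as children drop out.
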