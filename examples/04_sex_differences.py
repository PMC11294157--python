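"""Sex-stratified summary arithmetic on a metric table.

Builds a metric table whose per-sex group means equal published
drop-vertical-jump trunk-tilt ROM values and prints the male-minus-female
differences per tracking model.
"""
import pandas as pd

import trunktrack as tt

group_means = {  # model -> (female mean, male mean), DVJ tilt ROM in degrees
    "definition": (38.30, 52.81),
    "m-strn": (38.27, 51.83),
    "no-thorax": (42.98, 52.75),
    "no-sternum": (39.06, 53.37),
}
rows = []
for model, (f_mean, m_mean) in group_means.items():
    rows += [{"subject": f"F{i:02d}", "sex": "F", "model": model,
              "task": "dvj", "metric": "rom", "value": f_mean}
             for i in range(11)]
    rows += [{"subject": f"M{i:02d}", "sex": "M", "model": model,
              "task": "dvj", "metric": "rom", "value": m_mean}
             for i in range(7)]

out = tt.sex_difference_summary(pd.DataFrame(rows))
print(out.to_string(index=False))
print("\nMales flex the trunk substantially more than females during the "
      "jump; the\nNo-Thorax model (no T10 marker) understates that gap by "
      "several degrees because\nit inflates female ROM estimates.")
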