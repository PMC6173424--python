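"""Recompute kappa and agreement from published quintile cross-tabulations.

A pooled ten-country facility assessment (n = 9,238) reported, as row
percentages, how a 649-item readiness index cross-classifies against the WHO
service readiness index and against 50- and 100-item abbreviated indices.
Rebuilding the cell counts and recomputing the statistics checks this
package's agreement machinery against independently published numbers.
"""

import pandas as pd

from readix.published import check_reconstruction

pd.set_option("display.width", 140)
report = check_reconstruction()  # raises if any value disagrees
print(report.to_string(index=False))
print("\nEvery reconstructed kappa rounds to its printed value and every")
print("diagonal share matches the printed percent agreement.")
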