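"""Classify facilities into readiness quintiles and measure agreement.

On the packaged synthetic benchmark, facilities are ranked by the full
60-item index and by a 10-item expert-core stand-in; the cross-tabulation
shows how often the short index places a facility in the same quintile, and
Cohen's kappa corrects that agreement for chance.
"""

import readix as rx
from readix.agreement import crosstab_frame

matrix, truth = rx.benchmark_fixture()
domain_map = rx.benchmark_config().domain_map()

full_scores = rx.compute_index(
    matrix, rx.IndexDefinition(matrix.item_ids, domain_map)
)
core_scores = rx.compute_index(
    matrix, rx.IndexDefinition(rx.sri_like_items(), domain_map)
)

reference = rx.classify_quantiles(full_scores, q=5)
candidate = rx.classify_quantiles(core_scores, q=5)
cm = rx.confusion_matrix(reference, candidate)

print(crosstab_frame(cm).to_string())
print(f"\npercent agreement: {rx.percent_agreement(cm):.1f}%  "
      "(share of facilities on the diagonal)")
print(f"Cohen's kappa:     {rx.cohen_kappa(cm):.3f}  "
      "(agreement beyond chance; 1 = identical quintiles)")
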