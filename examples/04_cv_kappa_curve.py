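"""Estimate out-of-sample performance of M-item indices by 10-fold CV.

Items are re-selected within each training set (so the held-out facilities
never influence which items are chosen), held-out facilities are scored with
their fold's M-item index, and the pooled out-of-fold scores are classified
into quintiles and compared with the full-index reference. The curve shows
how much agreement survives as the index shrinks.
"""

import readix as rx

matrix, _ = rx.benchmark_fixture()
domain_map = rx.benchmark_config().domain_map()

curve = rx.cv_kappa_curve(matrix, domain_map, k=10, seed=7,
                          direction="backward")
print("cross-validated kappa by index length (backward selection):")
for m in (59, 40, 30, 20, 12, 6, 3, 1):
    print(f"  M = {m:>2}: {curve.kappa_at(m):.3f}")
print("\nA near-full index reproduces the reference almost perfectly;"
      "\nagreement decays as informative items are exhausted.")
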