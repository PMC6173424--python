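"""Compute a two-stage readiness index on a tiny hand-built item matrix.

Items are averaged within their domain, then the domain means are averaged,
so every domain counts equally regardless of size. Facility B has 3 of 5
items (flat mean 0.60) but scores 0.50: its complete amenities domain is
offset by the empty equipment domain.
"""

import numpy as np

import readix as rx

matrix = rx.ItemMatrix(
    facility_ids=np.array(["A", "B", "C"]),
    country=np.array(["north", "north", "south"]),
    facility_type=np.array(["hospital", "non-hospital", "non-hospital"]),
    weight=np.array([1.0, 2.0, 1.0]),
    item_ids=("water", "power", "gloves", "soap", "thermometer"),
    items=np.array(
        [
            [1, 1, 1, 1, 1],   # A: everything present
            [1, 1, 1, 0, 0],   # B: amenities complete, rest half/missing
            [0, 0, 1, 1, 0],   # C
        ],
        dtype=np.int8,
    ),
)
domain_map = rx.DomainMap(
    assignment={
        "water": "amenities", "power": "amenities",
        "gloves": "infection_prevention", "soap": "infection_prevention",
        "thermometer": "equipment",
    },
    domains=("amenities", "infection_prevention", "equipment"),
)

full = rx.IndexDefinition(matrix.item_ids, domain_map)
scores = rx.compute_index(matrix, full)
print("facility scores (mean of domain means):")
print(scores.to_string())
print(f"\nsurvey-weighted mean: {rx.weighted_mean(scores, matrix):.4f}"
      f"  (B's weight of 2 pulls it toward B's score)")
print(f"survey-weighted SD:   {rx.weighted_sd(scores, matrix):.4f}")
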