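"""Reading and writing the standard on-disk formats.

Item-matrix CSV: one header row; reserved columns ``facility_id``,
``country``, ``facility_type``, ``weight``; every other column is a binary
item parsed strictly as 0/1.

Domain-map / item-set config: YAML with a ``domains`` mapping (domain name ->
list of item ids, order significant) and an optional ``item_sets`` mapping of
named ordered item lists (e.g. ``sri``, ``full``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .core import RESERVED_COLUMNS, DomainMap, IndexDefinition, ItemMatrix

__all__ = [
    "read_item_matrix",
    "write_item_matrix",
    "read_domain_config",
    "write_domain_config",
]


def read_item_matrix(path) -> ItemMatrix:
    df = pd.read_csv(path)
    item_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    for c in item_cols:
        col = pd.to_numeric(df[c], errors="raise")
        bad = ~col.isin((0, 1))
        if bad.any():
            raise ValueError(
                f"item column {c!r} has non-binary values, e.g. "
                f"{col[bad].iloc[0]!r}"
            )
        df[c] = col.astype("int8")
    return ItemMatrix.from_dataframe(df)


def write_item_matrix(matrix: ItemMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path, index=False)


def read_domain_config(path):
    """Load (DomainMap, {set name: IndexDefinition}) from a YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    domains = cfg["domains"]
    assignment = {}
    for dom, items in domains.items():
        for item in items:
            if item in assignment:
                raise ValueError(f"item {item!r} listed under two domains")
            assignment[item] = dom
    dmap = DomainMap(assignment=assignment, domains=tuple(domains))
    sets = {
        name: IndexDefinition(tuple(items), dmap)
        for name, items in (cfg.get("item_sets") or {}).items()
    }
    return dmap, sets


def write_domain_config(path, domain_map: DomainMap, item_sets=None) -> None:
    cfg = {
        "domains": {d: domain_map.items_in(d) for d in domain_map.domains},
    }
    if item_sets:
        cfg["item_sets"] = {
            name: list(defn.item_ids) for name, defn in item_sets.items()
        }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
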