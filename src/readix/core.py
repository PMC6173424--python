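"""Facility item matrices and hierarchical (domain-averaged) readiness indices.

A readiness index is computed in two stages: binary items are averaged within
their domain, and the domain means are averaged to give the facility score in
[0, 1]. With unequal domain sizes this differs from the flat item mean: every
domain contributes equally regardless of how many items it holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemMatrix",
    "DomainMap",
    "IndexDefinition",
    "compute_index",
    "weighted_mean",
    "weighted_sd",
]

RESERVED_COLUMNS = ("facility_id", "country", "facility_type", "weight")


@dataclass(frozen=True)
class ItemMatrix:
    """Facility-by-item binary matrix with strata and sampling weights.

    Items are strictly 0/1: an item scored 1 was observed present (and
    functional where applicable); 0 means absent *or* not assessable, e.g.
    because the relevant service is not offered. Any missing raw value must be
    coded 0 before construction.
    """

    facility_ids: np.ndarray          # unique ids, shape (n,)
    country: np.ndarray               # stratum label per facility
    facility_type: np.ndarray         # e.g. hospital / non-hospital
    weight: np.ndarray                # positive sampling weight
    item_ids: tuple                   # unique item ids, length P
    items: np.ndarray                 # (n, P) int8 of 0/1

    _col_of: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        fid = np.asarray(self.facility_ids)
        items = np.asarray(self.items)
        if items.ndim != 2:
            raise ValueError("items must be a 2-D facility x item array")
        n, p = items.shape
        if n < 2 or p < 1:
            raise ValueError("need at least 2 facilities and 1 item")
        if fid.shape[0] != n:
            raise ValueError("facility_ids length does not match items")
        if len(np.unique(fid)) != n:
            raise ValueError("facility_ids must be unique")
        if len(set(self.item_ids)) != p or len(self.item_ids) != p:
            raise ValueError("item_ids must be unique and match items width")
        w = np.asarray(self.weight, dtype=float)
        if w.shape[0] != n or np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be positive and finite")
        vals = np.unique(items)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("item values must be 0 or 1")
        object.__setattr__(self, "items", items.astype(np.int8, copy=False))
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "weight", w)
        object.__setattr__(
            self, "_col_of", {iid: j for j, iid in enumerate(self.item_ids)}
        )

    @property
    def n_facilities(self) -> int:
        return self.items.shape[0]

    @property
    def n_items(self) -> int:
        return self.items.shape[1]

    def columns(self, item_ids: Iterable) -> np.ndarray:
        """Column indices of the given item ids (error on unknown ids)."""
        try:
            return np.array([self._col_of[i] for i in item_ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown item id: {e.args[0]!r}") from None

    def subset_facilities(self, mask: np.ndarray) -> "ItemMatrix":
        mask = np.asarray(mask)
        return ItemMatrix(
            facility_ids=self.facility_ids[mask],
            country=self.country[mask],
            facility_type=self.facility_type[mask],
            weight=self.weight[mask],
            item_ids=self.item_ids,
            items=self.items[mask],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "facility_id": self.facility_ids,
                "country": self.country,
                "facility_type": self.facility_type,
                "weight": self.weight,
            }
        )
        items = pd.DataFrame(self.items, columns=list(self.item_ids))
        return pd.concat([df, items], axis=1)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ItemMatrix":
        missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing reserved columns: {missing}")
        item_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
        items = df[item_cols].to_numpy()
        return cls(
            facility_ids=df["facility_id"].to_numpy(),
            country=df["country"].to_numpy(),
            facility_type=df["facility_type"].to_numpy(),
            weight=df["weight"].to_numpy(dtype=float),
            item_ids=tuple(item_cols),
            items=items,
        )


@dataclass(frozen=True)
class DomainMap:
    """Assignment of every item to exactly one domain.

    ``domains`` fixes the domain order used when averaging domain means, so
    scores are reproducible no matter how a definition lists its items.
    """

    assignment: Mapping  # item id -> domain name
    domains: tuple       # ordered domain names

    def __post_init__(self):
        object.__setattr__(self, "domains", tuple(self.domains))
        object.__setattr__(self, "assignment", dict(self.assignment))
        extra = set(self.assignment.values()) - set(self.domains)
        if extra:
            raise ValueError(f"items assigned to unlisted domains: {extra}")
        counts = {d: 0 for d in self.domains}
        for d in self.assignment.values():
            counts[d] += 1
        empty = [d for d, c in counts.items() if c == 0]
        if empty:
            raise ValueError(f"domains with no items in the map: {empty}")

    def domain_of(self, item_id) -> str:
        try:
            return self.assignment[item_id]
        except KeyError:
            raise KeyError(f"item {item_id!r} not in domain map") from None

    def domain_index(self, item_id) -> int:
        return self.domains.index(self.domain_of(item_id))

    def items_in(self, domain: str) -> list:
        return [i for i, d in self.assignment.items() if d == domain]


@dataclass(frozen=True)
class IndexDefinition:
    """An ordered item subset defining a readiness index of length M."""

    item_ids: tuple
    domain_map: DomainMap

    def __post_init__(self):
        ids = tuple(self.item_ids)
        if not ids:
            raise ValueError("an index needs at least one item")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids in index definition")
        unknown = [i for i in ids if i not in self.domain_map.assignment]
        if unknown:
            raise KeyError(f"items not in domain map: {unknown[:5]}")
        object.__setattr__(self, "item_ids", ids)

    def __len__(self) -> int:
        return len(self.item_ids)

    def restrict_to(self, matrix: ItemMatrix) -> "IndexDefinition":
        """Drop items absent from ``matrix`` (renormalized domain means).

        Survey waves differ in which items could be extracted; the convention
        here is to average each domain over the items actually available.
        """
        available = set(matrix.item_ids)
        kept = tuple(i for i in self.item_ids if i in available)
        return IndexDefinition(kept, self.domain_map)


def _domain_mean_matrix(
    matrix: ItemMatrix, cols: np.ndarray, dom_idx: np.ndarray, n_domains: int
):
    """Per-facility domain means for the selected columns.

    Returns (means, active): ``means`` is (n, n_active) in domain order over
    the domains with at least one selected item.
    """
    n = matrix.n_facilities
    sums = np.zeros((n, n_domains), dtype=np.int64)
    counts = np.zeros(n_domains, dtype=np.int64)
    for c, d in zip(cols, dom_idx):
        sums[:, d] += matrix.items[:, c]
        counts[d] += 1
    active = counts > 0
    means = sums[:, active] / counts[active]
    return means, active


def compute_index(matrix: ItemMatrix, definition: IndexDefinition) -> pd.Series:
    """Two-stage readiness index: mean over domains of within-domain means.

    Domains with no selected item are dropped from the outer average, which
    keeps the index defined for every subset down to a single item.
    """
    cols = matrix.columns(definition.item_ids)
    dmap = definition.domain_map
    dom_idx = np.array(
        [dmap.domains.index(dmap.assignment[i]) for i in definition.item_ids],
        dtype=np.intp,
    )
    means, _ = _domain_mean_matrix(matrix, cols, dom_idx, len(dmap.domains))
    scores = means.sum(axis=1) / means.shape[1]
    return pd.Series(scores, index=pd.Index(matrix.facility_ids, name="facility_id"),
                     name="score")


def weighted_mean(scores: pd.Series, matrix: ItemMatrix) -> float:
    """Survey-weighted mean of scores: sum(w*s) / sum(w)."""
    if len(scores) == 0:
        raise ValueError("empty scores")
    s = scores.reindex(matrix.facility_ids).to_numpy(dtype=float)
    w = matrix.weight
    return float(np.sum(w * s) / np.sum(w))


def weighted_sd(scores: pd.Series, matrix: ItemMatrix) -> float:
    """Survey-weighted standard deviation, sqrt(sum w (s - m)^2 / sum w)."""
    if len(scores) == 0:
        raise ValueError("empty scores")
    s = scores.reindex(matrix.facility_ids).to_numpy(dtype=float)
    w = matrix.weight
    m = np.sum(w * s) / np.sum(w)
    return float(np.sqrt(np.sum(w * (s - m) ** 2) / np.sum(w)))
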