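"""Greedy sequential item selection against a fixed reference classification.

Backward selection starts from the full item set and repeatedly drops the item
whose removal costs the least agreement (highest Cohen's kappa) between the
subset-index quantile classification and the reference classification.
Forward selection mirrors it, starting from the locked set (possibly empty)
and adding the item that gains the most agreement. Locked items are never
removed and are always included, which is how an expert-defined core set is
"enriched" with empirically chosen items.

The engine keeps per-facility, per-domain integer item sums and rebuilds the
candidate domain-mean matrix from them, so every candidate kappa equals the
one obtained by recomputing the index from scratch (binary items make the
cached sums exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agreement import (
    DegenerateClassificationError,
    QuantileClassification,
    _rank_groups,
    classify_quantiles,
    cohen_kappa,
    confusion_matrix,
)
from .core import DomainMap, IndexDefinition, ItemMatrix, compute_index

__all__ = [
    "SelectionTrace",
    "evaluate_subset",
    "backward_select",
    "forward_select",
    "index_at",
    "selection_order_report",
]


@dataclass(frozen=True)
class SelectionTrace:
    """Ordered record of one greedy selection path.

    ``steps`` holds (item_id, kappa_after_step): for a backward trace the item
    removed and the kappa of the surviving set; for a forward trace the item
    added and the kappa of the enlarged set.
    """

    direction: str                  # "backward" | "forward"
    steps: tuple                    # ((item_id, kappa), ...)
    locked: frozenset
    reference_q: int
    universe: tuple                 # matrix item ids, in column order
    domain_map: DomainMap = field(repr=False)

    def __post_init__(self):
        if self.direction not in ("backward", "forward"):
            raise ValueError("direction must be 'backward' or 'forward'")
        ids = [i for i, _ in self.steps]
        if len(set(ids)) != len(ids):
            raise ValueError("an item appears twice in the trace")
        if self.direction == "backward" and self.locked & set(ids):
            raise ValueError("locked items cannot be removed")

    @property
    def n_items(self) -> int:
        return len(self.universe)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(1, len(self.steps) + 1),
                "item_id": [i for i, _ in self.steps],
                "domain": [self.domain_map.domain_of(i) for i, _ in self.steps],
                "kappa": [k for _, k in self.steps],
            }
        )


def evaluate_subset(
    matrix: ItemMatrix,
    items,
    domain_map: DomainMap,
    reference: QuantileClassification,
) -> float:
    """Kappa of the subset index's quantile classification vs the reference.

    Pure composition of compute_index -> classify_quantiles -> cohen_kappa;
    raises DegenerateClassificationError when all subset scores are identical.
    """
    items = list(items)
    if not items:
        raise ValueError("empty item subset")
    cols = matrix.columns(items)  # validates ids
    ordered = [matrix.item_ids[c] for c in np.sort(cols)]
    scores = compute_index(matrix, IndexDefinition(tuple(ordered), domain_map))
    cand = classify_quantiles(scores, reference.q)
    return cohen_kappa(confusion_matrix(reference, cand))


class _GreedyEngine:
    """Cached domain sums + fast kappa for single-item add/remove moves."""

    def __init__(self, matrix, domain_map, reference, q):
        self.matrix = matrix
        self.items = matrix.items.astype(np.int64)
        self.n, self.p = self.items.shape
        self.domains = domain_map.domains
        self.d = len(self.domains)
        self.dom_idx = np.array(
            [self.domains.index(domain_map.domain_of(i)) for i in matrix.item_ids],
            dtype=np.intp,
        )
        ref = reference.as_series().reindex(matrix.facility_ids)
        if ref.isna().any():
            raise ValueError("reference does not cover all facilities")
        self.ref = ref.to_numpy(dtype=np.int64)
        self.q = q
        self.sums = np.zeros((self.n, self.d), dtype=np.int64)
        self.counts = np.zeros(self.d, dtype=np.int64)
        self.selected = np.zeros(self.p, dtype=bool)

    def add(self, j):
        self.sums[:, self.dom_idx[j]] += self.items[:, j]
        self.counts[self.dom_idx[j]] += 1
        self.selected[j] = True

    def remove(self, j):
        self.sums[:, self.dom_idx[j]] -= self.items[:, j]
        self.counts[self.dom_idx[j]] -= 1
        self.selected[j] = False

    def _scores(self, sums, counts):
        active = counts > 0
        means = sums[:, active] / counts[active]
        return means.sum(axis=1) / means.shape[1]

    def candidate_kappa(self, j, move):
        """Kappa after removing/adding column j, or None if degenerate."""
        d = self.dom_idx[j]
        counts = self.counts.copy()
        sums = self.sums.copy()
        if move == "remove":
            sums[:, d] -= self.items[:, j]
            counts[d] -= 1
        else:
            sums[:, d] += self.items[:, j]
            counts[d] += 1
        if not np.any(counts > 0):
            return None
        scores = self._scores(sums, counts)
        if np.all(scores == scores[0]):
            return None
        groups = _rank_groups(scores, self.q)
        flat = np.bincount(
            self.q * (self.ref - 1) + (groups - 1), minlength=self.q * self.q
        ).reshape(self.q, self.q)
        n = self.n
        p_o = np.trace(flat) / n
        p_e = float((flat.sum(axis=1) / n) @ (flat.sum(axis=0) / n))
        if p_e >= 1.0 - 1e-15:
            return 1.0 if p_o >= 1.0 - 1e-15 else None
        return float((p_o - p_e) / (1.0 - p_e))


def _prepare(matrix, domain_map, reference, locked, stop_size, direction):
    locked = frozenset(locked or ())
    unknown = locked - set(matrix.item_ids)
    if unknown:
        raise KeyError(f"locked items not in matrix: {sorted(unknown)[:5]}")
    p = matrix.n_items
    floor = max(1, len(locked))
    if stop_size is None:
        stop_size = floor if direction == "backward" else p
    if direction == "backward" and stop_size < floor:
        raise ValueError(f"stop_size must be >= {floor}")
    if direction == "forward" and stop_size < len(locked):
        raise ValueError("stop_size smaller than the locked set")
    if stop_size > p:
        raise ValueError(f"stop_size {stop_size} exceeds {p} items")
    return locked, stop_size


def _argmax_candidate(engine, candidates, move):
    """Best candidate by kappa; ties go to the smallest column index."""
    best_j, best_k = None, None
    for j in candidates:  # ascending column order
        k = engine.candidate_kappa(j, move)
        if k is None:
            continue
        if best_k is None or k > best_k:
            best_j, best_k = j, k
    return best_j, best_k


def backward_select(
    matrix: ItemMatrix,
    domain_map: DomainMap,
    reference: QuantileClassification,
    locked=(),
    stop_size: int | None = None,
) -> SelectionTrace:
    """Drop the least informative removable item until stop_size remain."""
    locked, stop_size = _prepare(
        matrix, domain_map, reference, locked, stop_size, "backward"
    )
    engine = _GreedyEngine(matrix, domain_map, reference, reference.q)
    for j in range(matrix.n_items):
        engine.add(j)
    locked_cols = set(matrix.columns(locked).tolist())
    steps = []
    n_selected = matrix.n_items
    while n_selected > stop_size:
        candidates = [
            j for j in range(matrix.n_items)
            if engine.selected[j] and j not in locked_cols
        ]
        j, kappa = _argmax_candidate(engine, candidates, "remove")
        if j is None:
            raise DegenerateClassificationError(
                f"every removal from the {n_selected}-item set collapses the "
                "index to a constant"
            )
        engine.remove(j)
        steps.append((matrix.item_ids[j], kappa))
        n_selected -= 1
    return SelectionTrace(
        direction="backward",
        steps=tuple(steps),
        locked=locked,
        reference_q=reference.q,
        universe=matrix.item_ids,
        domain_map=domain_map,
    )


def forward_select(
    matrix: ItemMatrix,
    domain_map: DomainMap,
    reference: QuantileClassification,
    locked=(),
    stop_size: int | None = None,
) -> SelectionTrace:
    """Add the most informative item until stop_size items are included."""
    locked, stop_size = _prepare(
        matrix, domain_map, reference, locked, stop_size, "forward"
    )
    engine = _GreedyEngine(matrix, domain_map, reference, reference.q)
    locked_cols = set(matrix.columns(locked).tolist())
    for j in sorted(locked_cols):
        engine.add(j)
    steps = []
    n_selected = len(locked)
    while n_selected < stop_size:
        candidates = [
            j for j in range(matrix.n_items) if not engine.selected[j]
        ]
        j, kappa = _argmax_candidate(engine, candidates, "add")
        if j is None:
            raise DegenerateClassificationError(
                f"every addition to the {n_selected}-item set leaves the "
                "index constant across facilities"
            )
        engine.add(j)
        steps.append((matrix.item_ids[j], kappa))
        n_selected += 1
    return SelectionTrace(
        direction="forward",
        steps=tuple(steps),
        locked=locked,
        reference_q=reference.q,
        universe=matrix.item_ids,
        domain_map=domain_map,
    )


def index_at(trace: SelectionTrace, m: int,
             domain_map: DomainMap | None = None) -> IndexDefinition:
    """The M-item index implied by a greedy path (nested across M).

    M counts all items including locked ones. For a backward trace this is
    the set surviving after P - M removals; for a forward trace the locked
    items plus the first M - |locked| additions.
    """
    dmap = domain_map or trace.domain_map
    p = trace.n_items
    n_locked = len(trace.locked)
    if trace.direction == "backward":
        lo = p - len(trace.steps)
        if not lo <= m <= p:
            raise ValueError(f"M={m} outside the trace range [{lo}, {p}]")
        removed = {i for i, _ in trace.steps[: p - m]}
        kept = tuple(i for i in trace.universe if i not in removed)
    else:
        hi = n_locked + len(trace.steps)
        if not max(1, n_locked) <= m <= hi:
            raise ValueError(
                f"M={m} outside the trace range [{max(1, n_locked)}, {hi}]"
            )
        locked_ordered = tuple(i for i in trace.universe if i in trace.locked)
        added = tuple(i for i, _ in trace.steps[: m - n_locked])
        kept = locked_ordered + added
    return IndexDefinition(kept, dmap)


def selection_order_report(trace: SelectionTrace) -> pd.DataFrame:
    """Item list with informativeness rank, most informative first.

    For a backward trace the last item discarded gets selection order 1 (it
    survived longest); locked items carry no order. Forward traces are
    numbered in addition order. Survivors of a backward trace stopped above
    the locked floor have no order either (they were never ranked).
    """
    rows = []
    n_steps = len(trace.steps)
    if trace.direction == "backward":
        order_of = {
            item: n_steps - t for t, (item, _) in enumerate(trace.steps)
        }
    else:
        order_of = {item: t + 1 for t, (item, _) in enumerate(trace.steps)}
    for item in trace.universe:
        rows.append(
            {
                "domain": trace.domain_map.domain_of(item),
                "item_id": item,
                "locked": int(item in trace.locked),
                "selection_order": order_of.get(item, np.nan),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["domain", "locked", "selection_order"],
        ascending=[True, False, True],
        kind="stable",
    ).reset_index(drop=True)
    return df
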