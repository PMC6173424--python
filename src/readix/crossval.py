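"""k-fold cross-validated evaluation of M-item indices.

For each fold, items are selected on the training facilities only (against a
reference classification recomputed on the training facilities, so the held
out fold never leaks into selection). One greedy path per fold yields every
M-item index at once because greedy paths are nested. Each facility's M-item
score is then taken from the fold that held it out, the pooled out-of-fold
scores are classified into q groups, and the curve point at M is the kappa of
that classification against the full-item reference computed once on all
facilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import (
    QuantileClassification,
    classify_quantiles,
    cohen_kappa,
    confusion_matrix,
)
from .core import DomainMap, IndexDefinition, ItemMatrix, compute_index
from .selection import SelectionTrace, backward_select, forward_select, index_at

__all__ = [
    "FoldAssignment",
    "KappaCurve",
    "make_folds",
    "cv_kappa_curve",
    "final_indices",
]


@dataclass(frozen=True)
class FoldAssignment:
    facility_ids: np.ndarray
    folds: np.ndarray  # int 1..k per facility
    k: int
    seed: int

    def __post_init__(self):
        sizes = np.bincount(self.folds, minlength=self.k + 1)[1:]
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most one")


@dataclass(frozen=True)
class KappaCurve:
    """Cross-validated kappa as a function of index length M."""

    m: np.ndarray
    kappa: np.ndarray
    direction: str
    locked: frozenset
    k: int
    seed: int
    q: int

    def kappa_at(self, m: int) -> float:
        pos = np.nonzero(self.m == m)[0]
        if len(pos) == 0:
            raise KeyError(f"M={m} not on the curve")
        return float(self.kappa[pos[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "M": self.m,
                "cv_kappa": self.kappa,
                "direction": self.direction,
                "k": self.k,
                "seed": self.seed,
                "q": self.q,
            }
        )


def make_folds(facility_ids, k: int, seed: int) -> FoldAssignment:
    """Random partition into k folds with sizes differing by at most one."""
    facility_ids = np.asarray(facility_ids)
    n = len(facility_ids)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of facilities ({n})")
    sizes = np.full(k, n // k, dtype=np.int64)
    sizes[: n % k] += 1
    labels = np.repeat(np.arange(1, k + 1), sizes)
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=np.int64)
    folds[rng.permutation(n)] = labels
    return FoldAssignment(facility_ids=facility_ids, folds=folds, k=k, seed=seed)


def _walk_scores(matrix, trace, m_values):
    """Scores of ``matrix`` facilities at every M along a greedy path.

    Replays the path once, updating per-domain integer sums, so the whole
    nested family costs O(n * P). Returns {M: scores array}.
    """
    dmap = trace.domain_map
    items = matrix.items.astype(np.int64)
    n = items.shape[0]
    d = len(dmap.domains)
    dom_idx = np.array(
        [dmap.domains.index(dmap.domain_of(i)) for i in matrix.item_ids],
        dtype=np.intp,
    )
    col_of = {iid: j for j, iid in enumerate(matrix.item_ids)}
    sums = np.zeros((n, d), dtype=np.int64)
    counts = np.zeros(d, dtype=np.int64)

    def score():
        active = counts > 0
        means = sums[:, active] / counts[active]
        return means.sum(axis=1) / means.shape[1]

    wanted = set(int(m) for m in m_values)
    out = {}
    if trace.direction == "backward":
        for j in range(len(matrix.item_ids)):
            sums[:, dom_idx[j]] += items[:, j]
            counts[dom_idx[j]] += 1
        m = trace.n_items
        if m in wanted:
            out[m] = score()
        for item, _ in trace.steps:
            j = col_of[item]
            sums[:, dom_idx[j]] -= items[:, j]
            counts[dom_idx[j]] -= 1
            m -= 1
            if m in wanted:
                out[m] = score()
    else:
        locked_cols = sorted(col_of[i] for i in trace.locked)
        for j in locked_cols:
            sums[:, dom_idx[j]] += items[:, j]
            counts[dom_idx[j]] += 1
        m = len(trace.locked)
        if m in wanted and m > 0:
            out[m] = score()
        for item, _ in trace.steps:
            j = col_of[item]
            sums[:, dom_idx[j]] += items[:, j]
            counts[dom_idx[j]] += 1
            m += 1
            if m in wanted:
                out[m] = score()
    missing = wanted - set(out)
    if missing:
        raise ValueError(f"path does not reach M values {sorted(missing)}")
    return out


def cv_kappa_curve(
    matrix: ItemMatrix,
    domain_map: DomainMap,
    k: int,
    seed: int,
    locked=(),
    direction: str = "backward",
    q: int = 5,
    m_values=None,
    pool: str = "pooled",
) -> KappaCurve:
    """Cross-validated kappa for every index length M.

    ``pool='pooled'`` classifies the assembled out-of-fold scores of all n
    facilities at once (default); ``pool='per_fold'`` classifies each held-out
    fold separately before the pooled kappa, for comparison.
    """
    if pool not in ("pooled", "per_fold"):
        raise ValueError("pool must be 'pooled' or 'per_fold'")
    locked = frozenset(locked or ())
    p = matrix.n_items
    lo = max(1, len(locked))
    if m_values is None:
        m_values = np.arange(lo, p)
    m_values = np.asarray(sorted(int(m) for m in m_values))
    if m_values.min() < lo or m_values.max() > p:
        raise ValueError(f"M values must lie in [{lo}, {p}]")

    full_def = IndexDefinition(matrix.item_ids, domain_map)
    reference = classify_quantiles(compute_index(matrix, full_def), q)
    assignment = make_folds(matrix.facility_ids, k, seed)

    n = matrix.n_facilities
    oof = {int(m): np.full(n, np.nan) for m in m_values}
    oof_groups = {int(m): np.zeros(n, dtype=np.int64) for m in m_values}
    stop = lo if direction == "backward" else int(m_values.max())
    for f in range(1, k + 1):
        val_mask = assignment.folds == f
        train = matrix.subset_facilities(~val_mask)
        val = matrix.subset_facilities(val_mask)
        train_ref = classify_quantiles(compute_index(train, full_def), q)
        if direction == "backward":
            trace = backward_select(train, domain_map, train_ref, locked, stop)
        else:
            trace = forward_select(train, domain_map, train_ref, locked, stop)
        fold_scores = _walk_scores(val, trace, m_values)
        for m, s in fold_scores.items():
            oof[m][val_mask] = s
            if pool == "per_fold":
                ids = pd.Index(matrix.facility_ids[val_mask])
                cls = classify_quantiles(pd.Series(s, index=ids), q)
                oof_groups[m][val_mask] = cls.groups

    kappas = np.empty(len(m_values))
    ids = pd.Index(matrix.facility_ids, name="facility_id")
    for i, m in enumerate(m_values):
        m = int(m)
        if pool == "pooled":
            cand = classify_quantiles(pd.Series(oof[m], index=ids), q)
        else:
            cand = QuantileClassification(
                facility_ids=matrix.facility_ids, groups=oof_groups[m], q=q
            )
        kappas[i] = cohen_kappa(confusion_matrix(reference, cand))
    return KappaCurve(
        m=m_values, kappa=kappas, direction=direction,
        locked=locked, k=k, seed=seed, q=q,
    )


def final_indices(
    matrix: ItemMatrix,
    domain_map: DomainMap,
    locked=(),
    direction: str = "backward",
    m_list=(),
    q: int = 5,
    return_trace: bool = False,
):
    """Final M-item indices chosen on the full data set (one greedy path)."""
    locked = frozenset(locked or ())
    m_list = [int(m) for m in m_list]
    if not m_list:
        raise ValueError("m_list must name at least one index length")
    p = matrix.n_items
    full_def = IndexDefinition(matrix.item_ids, domain_map)
    reference = classify_quantiles(compute_index(matrix, full_def), q)
    if direction == "backward":
        stop = max(1, len(locked))
        trace = backward_select(matrix, domain_map, reference, locked, stop)
    else:
        stop = min(p, max(m_list))
        trace = forward_select(matrix, domain_map, reference, locked, stop)
    defs = [index_at(trace, m) for m in m_list]
    return (defs, trace) if return_trace else defs
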