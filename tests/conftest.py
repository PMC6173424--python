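"""Shared fixtures and independent oracle implementations.

The oracle functions here deliberately re-implement the pipeline's math in
the plainest possible way (python loops over pandas frames) so the vectorized
production code is checked against independently written logic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import readix as rx

# ---------------------------------------------------------------------------
# independent oracles


def naive_index(df_items: pd.DataFrame, assignment: dict, domains) -> pd.Series:
    """Two-loop mean-of-domain-means, one facility at a time."""
    out = {}
    for fid, row in df_items.iterrows():
        dom_means = []
        for dom in domains:
            vals = [row[i] for i in df_items.columns if assignment[i] == dom]
            if vals:
                dom_means.append(sum(vals) / len(vals))
        out[fid] = sum(dom_means) / len(dom_means)
    return pd.Series(out)


def naive_quantile_groups(scores: np.ndarray, q: int) -> np.ndarray:
    """Rank-and-slice with stable ties, boundaries at ceil(k*n/q)."""
    n = len(scores)
    order = sorted(range(n), key=lambda i: (-scores[i], i))
    bounds = [int(np.ceil(k * n / q)) for k in range(1, q + 1)]
    groups = np.empty(n, dtype=int)
    for rank, i in enumerate(order):
        for g, b in enumerate(bounds, start=1):
            if rank < b:
                groups[i] = g
                break
    return groups


def naive_kappa(ref: np.ndarray, cand: np.ndarray, q: int) -> float:
    n = len(ref)
    cm = np.zeros((q, q))
    for r, c in zip(ref, cand):
        cm[r - 1, c - 1] += 1
    p_o = np.trace(cm) / n
    p_e = sum(cm[i].sum() * cm[:, i].sum() for i in range(q)) / n**2
    return (p_o - p_e) / (1 - p_e)


def naive_subset_kappa(matrix, items, assignment, domains, ref_groups, q):
    """evaluate_subset re-done with the naive pieces above."""
    df = pd.DataFrame(
        matrix.items, columns=list(matrix.item_ids),
        index=list(matrix.facility_ids),
    )[list(items)]
    scores = naive_index(df, assignment, domains)
    cand = naive_quantile_groups(scores.to_numpy(), q)
    return naive_kappa(ref_groups, cand, q)


# ---------------------------------------------------------------------------
# fixtures


def _random_matrix(n, item_spec, seed, p_one=0.5):
    """item_spec: {domain: n_items}; items ~ Bernoulli(p_one) iid."""
    rng = np.random.default_rng(seed)
    item_ids, assignment = [], {}
    for dom, cnt in item_spec.items():
        for i in range(cnt):
            iid = f"{dom}{i}"
            item_ids.append(iid)
            assignment[iid] = dom
    items = (rng.random((n, len(item_ids))) < p_one).astype(np.int8)
    matrix = rx.ItemMatrix(
        facility_ids=np.array([f"f{i:03d}" for i in range(n)]),
        country=np.array(["x"] * (n // 2) + ["y"] * (n - n // 2)),
        facility_type=np.array(["hospital", "non-hospital"] * (n // 2)
                               + ["hospital"] * (n % 2)),
        weight=rng.uniform(0.5, 2.0, n),
        item_ids=tuple(item_ids),
        items=items,
    )
    dmap = rx.DomainMap(assignment=assignment, domains=tuple(item_spec))
    return matrix, dmap


@pytest.fixture
def small_matrix():
    """20 facilities x 9 items in 3 domains of sizes 2/3/4."""
    return _random_matrix(20, {"A": 2, "B": 3, "C": 4}, seed=42)


@pytest.fixture
def oracle_matrix():
    """30 facilities x 8 items in 3 domains, for exhaustive greedy checks."""
    return _random_matrix(30, {"A": 3, "B": 3, "C": 2}, seed=11)


@pytest.fixture(scope="session")
def benchmark():
    matrix, truth = rx.benchmark_fixture()
    return matrix, truth, rx.benchmark_config().domain_map()


@pytest.fixture(scope="session")
def benchmark_reference(benchmark):
    matrix, _, dmap = benchmark
    scores = rx.compute_index(matrix, rx.IndexDefinition(matrix.item_ids, dmap))
    return scores, rx.classify_quantiles(scores, 5)


@pytest.fixture(scope="session")
def benchmark_backward_trace(benchmark, benchmark_reference):
    matrix, _, dmap = benchmark
    _, ref = benchmark_reference
    return rx.backward_select(matrix, dmap, ref, (), 1)


@pytest.fixture(scope="session")
def benchmark_cv_curves(benchmark):
    """Pooled 10-fold CV curves for both greedy directions (fold seed 7)."""
    matrix, _, dmap = benchmark
    curves = {}
    for direction in ("backward", "forward"):
        curves[direction] = rx.cv_kappa_curve(
            matrix, dmap, k=10, seed=7, direction=direction
        )
    return curves


def make_random_matrix(n, item_spec, seed, p_one=0.5):
    return _random_matrix(n, item_spec, seed, p_one)
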