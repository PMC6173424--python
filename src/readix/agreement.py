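"""Quantile classification of index scores and agreement statistics.

Facilities are ranked by descending score (group 1 = most ready) and the rank
order is cut into q contiguous groups with boundaries at ceil(k*n/q), the
convention that reproduces published quintile sizes such as
1848/1848/1847/1848/1847 for n = 9238. Ties are broken by the stable input
order, so classification is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QuantileClassification",
    "ConfusionMatrix",
    "DegenerateClassificationError",
    "classify_quantiles",
    "group_sizes",
    "confusion_matrix",
    "cohen_kappa",
    "percent_agreement",
    "matrix_from_row_percentages",
    "crosstab_frame",
]


class DegenerateClassificationError(ValueError):
    """All scores identical: a rank-based classification is meaningless."""


@dataclass(frozen=True)
class QuantileClassification:
    facility_ids: np.ndarray
    groups: np.ndarray  # int 1..q per facility, 1 = highest scores
    q: int

    def __post_init__(self):
        g = np.asarray(self.groups)
        if g.min() < 1 or g.max() > self.q:
            raise ValueError("group labels must lie in 1..q")

    @property
    def n(self) -> int:
        return len(self.groups)

    def as_series(self) -> pd.Series:
        return pd.Series(self.groups,
                         index=pd.Index(self.facility_ids, name="facility_id"),
                         name="group")


@dataclass(frozen=True)
class ConfusionMatrix:
    """q x q cross-tabulation; rows = reference groups, columns = candidate.

    ``counts`` may be real-valued when reconstructed from printed row
    percentages (rounding to integers twice would distort the kappa).
    """

    counts: np.ndarray
    q: int

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (self.q, self.q):
            raise ValueError("counts must be q x q")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def group_sizes(n: int, q: int) -> np.ndarray:
    """Group sizes implied by rank boundaries at ceil(k*n/q)."""
    bounds = np.ceil(np.arange(1, q + 1) * n / q).astype(np.int64)
    return np.diff(np.concatenate([[0], bounds]))


def _rank_groups(scores: np.ndarray, q: int) -> np.ndarray:
    """Groups 1..q in input order; descending score, stable ties."""
    n = scores.shape[0]
    order = np.lexsort((np.arange(n), -scores))
    bounds = np.ceil(np.arange(1, q + 1) * n / q).astype(np.int64)
    ranks_group = np.searchsorted(bounds, np.arange(n), side="right") + 1
    groups = np.empty(n, dtype=np.int64)
    groups[order] = ranks_group
    return groups


def classify_quantiles(scores: pd.Series, q: int) -> QuantileClassification:
    """Cut facilities into q near-equal groups by descending score.

    Raises DegenerateClassificationError when every score is identical and
    ValueError when q is out of range.
    """
    values = np.asarray(scores.to_numpy(), dtype=float)
    n = values.shape[0]
    if q < 2:
        raise ValueError("q must be at least 2")
    if q > n:
        raise ValueError(f"q={q} exceeds the number of facilities ({n})")
    if np.all(values == values[0]):
        raise DegenerateClassificationError(
            "all scores identical; quantile groups are undefined"
        )
    groups = _rank_groups(values, q)
    return QuantileClassification(
        facility_ids=np.asarray(scores.index.to_numpy()), groups=groups, q=q
    )


def confusion_matrix(
    ref: QuantileClassification, cand: QuantileClassification
) -> ConfusionMatrix:
    if ref.q != cand.q:
        raise ValueError("classifications use different numbers of groups")
    if ref.n != cand.n or not np.array_equal(
        np.sort(ref.facility_ids), np.sort(cand.facility_ids)
    ):
        raise ValueError("classifications cover different facility sets")
    cand_groups = cand.as_series().reindex(ref.facility_ids).to_numpy()
    q = ref.q
    flat = np.bincount(
        q * (ref.groups - 1) + (cand_groups - 1), minlength=q * q
    )
    return ConfusionMatrix(counts=flat.reshape(q, q).astype(float), q=q)


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Unweighted Cohen's kappa, (p_o - p_e) / (1 - p_e)."""
    c = cm.counts
    n = c.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(c) / n
    p_e = float((c.sum(axis=1) / n) @ (c.sum(axis=0) / n))
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("degenerate single-cell marginals: kappa undefined")
    return float((p_o - p_e) / (1.0 - p_e))


def percent_agreement(cm: ConfusionMatrix) -> float:
    """Diagonal share of the cross-tabulation, in percent."""
    n = cm.counts.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    return float(100.0 * np.trace(cm.counts) / n)


def matrix_from_row_percentages(row_ns, row_pcts, slack: float = 0.5
                                ) -> ConfusionMatrix:
    """Rebuild a cross-tabulation from printed row Ns and row percentages.

    Cells are kept real-valued (row_n * pct / 100) so agreement statistics
    are not distorted by rounding the counts a second time.
    """
    row_ns = np.asarray(row_ns, dtype=float)
    pcts = np.asarray(row_pcts, dtype=float)
    q = len(row_ns)
    if pcts.shape != (q, q):
        raise ValueError("row_pcts must be square with one row per row N")
    sums = pcts.sum(axis=1)
    bad = np.abs(sums - 100.0) > slack
    if np.any(bad):
        r = int(np.nonzero(bad)[0][0])
        raise ValueError(
            f"row {r + 1} percentages sum to {sums[r]:.2f}, outside "
            f"100 +/- {slack}"
        )
    counts = row_ns[:, None] * pcts / 100.0
    return ConfusionMatrix(counts=counts, q=q)


def crosstab_frame(cm: ConfusionMatrix) -> pd.DataFrame:
    """Report-ready cross-tab: counts plus row percentages per group."""
    q = cm.q
    labels = [f"group_{i}" for i in range(1, q + 1)]
    counts = pd.DataFrame(cm.counts, index=labels, columns=labels)
    row_tot = counts.sum(axis=1)
    pct = counts.div(row_tot, axis=0) * 100.0
    out = pd.concat(
        {"count": counts, "row_pct": pct.round(1)}, axis=1
    )
    out.insert(0, ("", "N"), row_tot)
    out.index.name = "reference"
    return out
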