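"""Hypervolume-under-the-manifold (HUM) objective functions.

For a coefficient vector ``beta`` and ``M`` ordered groups with scores
``beta^T X``, the empirical HUM (EHUM) is the fraction of cross-group
M-tuples whose scores are *strictly* increasing with category order:

    D_E(beta) = (1 / prod_j n_j) * sum I(s_M > s_{M-1} > ... > s_1)

For ``M = 2`` this is the Mann-Whitney AUC estimate; for ``M = 3`` the
volume under the ROC surface. The upper-and-lower-bound (ULBA) surrogates
are built from adjacent pairwise exceedance probabilities
``P(beta^T X_{j+1} > beta^T X_j)``: ``P_A`` is their mean (a lower-bound
surrogate up to an affine map) and ``P_M`` their minimum (an upper bound):

    max{0, (M-1) P_A - (M-2)}  <=  D  <=  P_M.

Ties contribute zero to every indicator (strict inequalities), so tied
data can make the objectives non-smooth on measure-zero sets of ``beta``.
All evaluators accept raw (non-unit) coefficient vectors: every objective
here is invariant to positive rescaling of ``beta``.
"""

from __future__ import annotations

import enum
import itertools
import math
from typing import Callable, NamedTuple

import numpy as np

from .data import OrderedBiomarkerData

__all__ = [
    "ObjectiveKind",
    "ObjectiveValue",
    "combination_scores",
    "ehum",
    "ehum_bruteforce",
    "pairwise_exceedance",
    "ulba_pa",
    "ulba_pm",
    "individual_ehum",
    "evaluate",
    "make_objective",
]


class ObjectiveKind(str, enum.Enum):
    EHUM = "ehum"
    ULBA_PA = "ulba_pa"
    ULBA_PM = "ulba_pm"


class ObjectiveValue(NamedTuple):
    value: float
    kind: ObjectiveKind


def _as_beta(beta, d: int) -> np.ndarray:
    b = np.asarray(beta, dtype=float).ravel()
    if b.size != d:
        raise ValueError(f"coefficient vector has length {b.size}, data has d={d}")
    return b


def combination_scores(beta, data: OrderedBiomarkerData) -> list[np.ndarray]:
    """Per-group linear combination scores ``beta^T X``."""
    b = _as_beta(beta, data.n_markers)
    return [g @ b for g in data.groups]


def _ehum_from_scores(scores: list[np.ndarray]) -> float:
    # DP over categories: w_j(x) = number of strictly increasing chains
    # through groups 1..j ending at score x; prefix sums over the sorted
    # previous group give each update in O(n log n).
    w = np.ones_like(scores[0])
    for prev, cur in zip(scores, scores[1:]):
        order = np.argsort(prev, kind="stable")
        sorted_prev = prev[order]
        cum = np.cumsum(w[order])
        idx = np.searchsorted(sorted_prev, cur, side="left")
        w = np.where(idx > 0, cum[np.maximum(idx - 1, 0)], 0.0)
    total = math.prod(s.size for s in scores)
    return float(w.sum() / total)


def ehum(beta, data: OrderedBiomarkerData) -> float:
    """Empirical HUM: fraction of strictly ordered cross-group M-tuples."""
    return _ehum_from_scores(combination_scores(beta, data))


def ehum_bruteforce(beta, data: OrderedBiomarkerData) -> float:
    """Direct enumeration over all ``prod n_j`` M-tuples (test oracle)."""
    scores = combination_scores(beta, data)
    count = 0
    for tup in itertools.product(*scores):
        if all(a < b for a, b in zip(tup, tup[1:])):
            count += 1
    return count / math.prod(s.size for s in scores)


def pairwise_exceedance(beta, data: OrderedBiomarkerData, j: int) -> float:
    """Empirical ``P(beta^T X_{j+1} > beta^T X_j)`` for adjacent categories.

    ``j`` is 1-based: ``1 <= j <= M-1`` compares group ``j`` with group
    ``j+1`` in category order.
    """
    if not 1 <= j <= data.n_categories - 1:
        raise ValueError(f"adjacent pair index must be in 1..{data.n_categories - 1}")
    scores = combination_scores(beta, data)
    return _exceedance(scores[j - 1], scores[j])


def _exceedance(lo: np.ndarray, hi: np.ndarray) -> float:
    sorted_lo = np.sort(lo)
    wins = np.searchsorted(sorted_lo, hi, side="left").sum()
    return float(wins / (lo.size * hi.size))


def ulba_pa(beta, data: OrderedBiomarkerData) -> float:
    """ULBA ``P_A``: mean of the M-1 adjacent pairwise exceedances."""
    scores = combination_scores(beta, data)
    vals = [_exceedance(a, b) for a, b in zip(scores, scores[1:])]
    return float(np.mean(vals))


def ulba_pm(beta, data: OrderedBiomarkerData) -> float:
    """ULBA ``P_M``: minimum of the adjacent pairwise exceedances."""
    scores = combination_scores(beta, data)
    vals = [_exceedance(a, b) for a, b in zip(scores, scores[1:])]
    return float(min(vals))


def individual_ehum(data: OrderedBiomarkerData, k: int) -> tuple[int, float]:
    """Best sign and EHUM of marker ``k`` alone (1-based index).

    Evaluates the EHUM at ``+e_k`` and ``-e_k`` and returns
    ``(sign, value)`` for the better orientation, ties broken toward +1.
    """
    if not 1 <= k <= data.n_markers:
        raise ValueError(f"marker index must be in 1..{data.n_markers}")
    cols = [g[:, k - 1] for g in data.groups]
    plus = _ehum_from_scores(cols)
    minus = _ehum_from_scores([-c for c in cols])
    if minus > plus:
        return -1, minus
    return +1, plus


_FUNCS: dict[ObjectiveKind, Callable] = {
    ObjectiveKind.EHUM: ehum,
    ObjectiveKind.ULBA_PA: ulba_pa,
    ObjectiveKind.ULBA_PM: ulba_pm,
}


def evaluate(kind: ObjectiveKind | str, beta, data: OrderedBiomarkerData) -> ObjectiveValue:
    kind = ObjectiveKind(kind)
    return ObjectiveValue(_FUNCS[kind](beta, data), kind)


def make_objective(kind: ObjectiveKind | str, data: OrderedBiomarkerData) -> Callable[[np.ndarray], float]:
    """Bind an objective kind to a dataset as ``f(beta) -> float``.

    The returned callable is what the optimizers maximize; it accepts raw
    coefficient vectors (scale invariance makes normalization optional).
    """
    kind = ObjectiveKind(kind)
    groups = data.groups
    if kind is ObjectiveKind.EHUM:
        def f(beta: np.ndarray) -> float:
            return _ehum_from_scores([g @ beta for g in groups])
    elif kind is ObjectiveKind.ULBA_PA:
        def f(beta: np.ndarray) -> float:
            scores = [g @ beta for g in groups]
            return float(np.mean([_exceedance(a, b) for a, b in zip(scores, scores[1:])]))
    else:
        def f(beta: np.ndarray) -> float:
            scores = [g @ beta for g in groups]
            return float(min(_exceedance(a, b) for a, b in zip(scores, scores[1:])))
    return f
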