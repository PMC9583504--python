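"""Clinical post-processing: screening, cut-points, bootstrap uncertainty.

Utilities surrounding a fitted combination score in an applied analysis:
greedy correlation screening of redundant predictors, Youden-index
cut-points turning the continuous score into ordinal predictions,
ordered-grade collapsing, and stratified bootstrap confidence intervals
for the HUM and the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import OrderedBiomarkerData

__all__ = ["CutPointSet", "BootstrapResult", "greedy_correlation_filter",
           "youden_cutpoints", "bootstrap_ci", "collapse_categories"]


@dataclass
class CutPointSet:
    """M-1 score thresholds separating adjacent category splits.

    For each adjacent split (categories <= j vs > j) the threshold
    maximizes Youden's J = sensitivity + specificity - 1 over the
    midpoints of sorted unique scores; ``youden`` is the mean of the
    per-split maxima (the per-split values are exposed as well since the
    multi-class aggregation is a convention, not a standard).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden_per_split: np.ndarray

    @property
    def youden(self) -> float:
        return float(np.mean(self.youden_per_split))


@dataclass
class BootstrapResult:
    estimate: float | np.ndarray
    se: float | np.ndarray
    lower: float | np.ndarray
    upper: float | np.ndarray
    n_replicates: int
    alpha: float


def greedy_correlation_filter(markers, threshold: float = 0.8) -> list[int]:
    """Iteratively drop the most redundant marker until all |r| < threshold.

    At each pass the marker with the highest mean absolute pairwise
    correlation (among those still retained) is removed; ties remove the
    earliest column. Returns retained column indices (or column names if
    a DataFrame was given). Constant columns are rejected: their
    correlation is undefined.
    """
    if isinstance(markers, pd.DataFrame):
        names = list(markers.columns)
        x = markers.to_numpy(dtype=float)
    else:
        x = np.asarray(markers, dtype=float)
        names = None
    if x.shape[1] < 2:
        raise ValueError("need at least two markers to screen")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if np.any(np.std(x, axis=0) == 0):
        raise ValueError("constant marker column: correlation undefined")
    keep = list(range(x.shape[1]))
    while len(keep) > 1:
        corr = np.abs(np.corrcoef(x[:, keep], rowvar=False))
        np.fill_diagonal(corr, 0.0)
        if corr.max() < threshold:
            break
        mean_corr = corr.mean(axis=1)
        drop = int(np.argmax(mean_corr))  # argmax takes the earliest tie
        keep.pop(drop)
    return [names[k] for k in keep] if names is not None else keep


def _binary_youden(scores_neg: np.ndarray, scores_pos: np.ndarray) -> tuple[float, float, float]:
    """Best (threshold, sensitivity, specificity) for one adjacent split."""
    pooled = np.sort(np.unique(np.concatenate([scores_neg, scores_pos])))
    if pooled.size < 2:
        return float(pooled[0]), float(np.mean(scores_pos > pooled[0])), float(np.mean(scores_neg <= pooled[0]))
    cands = 0.5 * (pooled[:-1] + pooled[1:])
    sens = np.array([(scores_pos > c).mean() for c in cands])
    spec = np.array([(scores_neg <= c).mean() for c in cands])
    j = sens + spec - 1.0
    b = int(np.argmax(j))
    return float(cands[b]), float(sens[b]), float(spec[b])


def youden_cutpoints(scores: np.ndarray, labels: np.ndarray,
                     category_order=None) -> CutPointSet:
    """Youden-index cut-points categorizing a continuous score.

    ``labels`` are ordinal; for each of the M-1 adjacent splits the
    subjects with category above the split are "positive". Predicting
    positive means score strictly above the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    levels = list(category_order) if category_order is not None else sorted(np.unique(labels).tolist())
    if len(levels) < 2:
        raise ValueError("need at least two categories present")
    rank = np.array([levels.index(l) for l in labels])
    thr, sens, spec = [], [], []
    for split in range(len(levels) - 1):
        neg = scores[rank <= split]
        pos = scores[rank > split]
        t, sn, sp = _binary_youden(neg, pos)
        thr.append(t)
        sens.append(sn)
        spec.append(sp)
    thr, sens, spec = map(np.array, (thr, sens, spec))
    return CutPointSet(thr, sens, spec, sens + spec - 1.0)


def bootstrap_ci(data: OrderedBiomarkerData, estimator, B: int = 200,
                 alpha: float = 0.05,
                 rng: np.random.Generator | int | None = None) -> tuple[BootstrapResult, BootstrapResult]:
    """Stratified bootstrap for the HUM estimate and the coefficients.

    ``estimator(data) -> (beta, hum)``. Resampling is with replacement
    *within* each outcome category, preserving the ordered-group design
    (no category can empty out). Coefficient replicates are flipped into
    the point estimate's halfspace before the standard error is taken,
    and intervals are the normal-theory ``estimate +/- z_{alpha/2} se_B``.

    Returns ``(hum_result, beta_result)``.
    """
    if B < 2:
        raise ValueError("need at least two bootstrap replicates")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    beta_hat, hum_hat = estimator(data)
    beta_hat = np.asarray(beta_hat, dtype=float)
    hums = np.empty(B)
    betas = np.empty((B, beta_hat.size))
    for b in range(B):
        groups = tuple(g[rng.integers(0, g.shape[0], size=g.shape[0])] for g in data.groups)
        boot = OrderedBiomarkerData(groups, data.category_labels)
        bb, hh = estimator(boot)
        bb = np.asarray(bb, dtype=float)
        if bb @ beta_hat < 0:
            bb = -bb
        betas[b] = bb
        hums[b] = hh
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    se_hum = float(np.std(hums, ddof=1))
    se_beta = np.std(betas, axis=0, ddof=1)
    hum_res = BootstrapResult(float(hum_hat), se_hum,
                              float(hum_hat) - z * se_hum, float(hum_hat) + z * se_hum, B, alpha)
    beta_res = BootstrapResult(beta_hat, se_beta,
                               beta_hat - z * se_beta, beta_hat + z * se_beta, B, alpha)
    return hum_res, beta_res


def collapse_categories(labels, grouping_map: dict) -> tuple[np.ndarray, dict]:
    """Merge ordinal grades into coarser ordered classes.

    ``grouping_map`` sends each original grade to its new class; the map
    must preserve order (e.g. grades {2,3,4} -> 2 is valid, {0,2} -> 0
    with 1 -> 1 is not). Returns the relabeled array and the class sizes.
    """
    labels = np.asarray(labels)
    levels = sorted(np.unique(labels).tolist())
    for lev in levels:
        if lev not in grouping_map:
            raise ValueError(f"grade {lev!r} missing from the grouping map")
    mapped = [grouping_map[lev] for lev in levels]
    if any(b < a for a, b in zip(mapped, mapped[1:])):
        raise ValueError("grouping map must be monotone in the grade order")
    out = np.array([grouping_map[l] for l in labels])
    sizes = {lev: int(np.sum(out == lev)) for lev in sorted(set(mapped))}
    return out, sizes
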