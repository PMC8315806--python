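"""dpGBC feature selection: deviation maps, dot-product index, step-down loop.

A subject's ΔGBC map is their GBC minus a group-mean GBC per parcel; the
dpGBC index is the dot product of that deviation with a reference
coefficient map over a parcel subset — a signed, unbounded similarity that
is maximized against symptom variation instead of map magnitude.  The
step-down loop ranks parcels by coefficient magnitude in the full-sample
map, removes the weakest parcel per iteration and evaluates a strict
leave-one-subject-out regression at each retained set, tracing two
criterion curves:

* metric A — correlation between the subjects' symptom scores and their
  leave-one-out observed dpGBC values (the symptom-association criterion);
* metric B — correlation between observed and leave-one-out predicted
  dpGBC values (the prediction criterion; the prediction is the scalar
  regression of dpGBC on the symptom score applied to the held-out
  subject).

The returned best subset maximizes metric A; metric B's argmax is reported
alongside.  Leave-one-out is strict: for subject i both the coefficient map
and the group mean are computed from the other N-1 subjects, so the index
is never inflated by self-similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import GBCMatrix

__all__ = ["DeltaGBC", "SelectionResult", "delta_gbc", "dpgbc",
           "loo_dpgbc_eval", "stepdown_select"]


@dataclass
class DeltaGBC:
    """Subjects x parcels deviation-from-group-mean GBC."""

    values: np.ndarray
    parcel_ids: list
    subject_ids: list


@dataclass
class SelectionResult:
    """Trace of one step-down elimination run.

    ``elimination_order`` lists parcel indices from first-removed to last;
    the metric curves have one entry per retained-count from P down to 1
    (NaN where the decimated evaluation grid skipped a count).
    """

    elimination_order: np.ndarray
    retained_counts: np.ndarray
    metric_a_curve: np.ndarray
    metric_b_curve: np.ndarray
    best_subset: np.ndarray
    best_count: int
    best_count_metric_b: int
    dpgbc_obs: np.ndarray
    dpgbc_pred: np.ndarray


def delta_gbc(gbc: GBCMatrix, reference_mean: np.ndarray | None = None) -> DeltaGBC:
    """Row-wise deviation of each subject's GBC from a group-mean map.

    With ``reference_mean=None`` the within-sample column mean is used
    (columns then sum to zero); an external reference group's mean map may
    be supplied instead, as when scoring a replication sample against a
    discovery cohort.
    """
    values = gbc.values
    if reference_mean is None:
        reference_mean = values.mean(axis=0)
    else:
        reference_mean = np.asarray(reference_mean, float)
        if reference_mean.shape != (values.shape[1],):
            raise ValueError("reference_mean length does not match parcel count")
    return DeltaGBC(values - reference_mean, list(gbc.parcel_ids), list(gbc.subject_ids))


def dpgbc(delta_row: np.ndarray, beta_map: np.ndarray, subset) -> float:
    """Dot product of a deviation map with a coefficient map over a subset.

    Signed and unbounded; linear in the deviation map.
    """
    subset = np.asarray(subset, int)
    if subset.size == 0:
        raise ValueError("empty parcel subset")
    d = np.asarray(delta_row, float)
    b = np.asarray(beta_map, float)
    return float(d[subset] @ b[subset])


def _loo_slopes_and_means(scores: np.ndarray, g: np.ndarray):
    """Leave-one-out per-parcel OLS slopes and group means, vectorized.

    For each held-out subject i, returns the slope of each parcel's GBC on
    the score fit on the other N-1 subjects (intercept included) and the
    N-1 group mean, via rank-one downdates of the full-sample sums.
    """
    n, p = g.shape
    s = scores
    sum_s, sum_ss = s.sum(), s @ s
    sum_g = g.sum(axis=0)            # (p,)
    sum_sg = s @ g                   # (p,)
    s_i = s[:, None]
    loo_n = n - 1
    mean_s = (sum_s - s_i) / loo_n                    # (n,1)
    mean_g = (sum_g[None, :] - g) / loo_n             # (n,p)
    sxx = (sum_ss - s_i**2) - loo_n * mean_s**2       # (n,1)
    sxy = (sum_sg[None, :] - s_i * g) - loo_n * mean_s * mean_g
    if np.any(sxx <= 0):
        raise ValueError("scores are constant after leaving one subject out")
    return sxy / sxx, mean_g


def loo_dpgbc_eval(gbc: GBCMatrix, scores: np.ndarray, subset):
    """Strict leave-one-out dpGBC evaluation on one parcel subset.

    Per held-out subject i: the coefficient map and group mean come from
    the other N-1 subjects; ``dpgbc_obs[i]`` is the dot product of i's
    deviation map with that map; the scalar regression of dpGBC on the
    symptom score (intercept included), fit on the others, gives
    ``dpgbc_pred[i]`` from i's score alone.

    Returns ``(dpgbc_obs, dpgbc_pred, metric_a, metric_b)`` where
    ``metric_a = corr(scores, dpgbc_obs)`` and
    ``metric_b = corr(dpgbc_obs, dpgbc_pred)``.
    """
    scores = np.asarray(scores, float)
    n = gbc.n_subjects
    if n < 10:
        raise ValueError("need at least 10 subjects for leave-one-out evaluation")
    if np.ptp(scores) == 0:
        raise ValueError("constant score vector; regression is degenerate")
    subset = np.asarray(subset, int)
    if subset.size == 0:
        raise ValueError("empty parcel subset")
    g = gbc.values[:, subset]
    slopes, means = _loo_slopes_and_means(scores, g)
    obs = ((g - means) * slopes).sum(axis=1)

    # leave-one-out scalar regression obs = alpha * score + intercept
    sum_s, sum_ss = scores.sum(), scores @ scores
    sum_o, sum_so = obs.sum(), scores @ obs
    loo_n = n - 1
    mean_s = (sum_s - scores) / loo_n
    mean_o = (sum_o - obs) / loo_n
    sxx = (sum_ss - scores**2) - loo_n * mean_s**2
    sxy = (sum_so - scores * obs) - loo_n * mean_s * mean_o
    alpha = sxy / sxx
    pred = mean_o + alpha * (scores - mean_s)

    metric_a = float(np.corrcoef(obs, scores)[0, 1])
    metric_b = float(np.corrcoef(obs, pred)[0, 1])
    return obs, pred, metric_a, metric_b


def _evaluation_counts(p: int, dense_below: int = 100, stride: int = 5) -> np.ndarray:
    """Decimated retained-count grid: every count up to ``dense_below``,
    every ``stride``-th above, always including P."""
    counts = set(range(1, min(p, dense_below) + 1))
    counts.update(range(dense_below + stride, p + 1, stride))
    counts.add(p)
    return np.array(sorted(counts))


def stepdown_select(gbc: GBCMatrix, scores: np.ndarray,
                    rerank_each_step: bool = False,
                    dense_below: int = 100, stride: int = 5) -> SelectionResult:
    """Step-down parcel elimination maximizing the dpGBC criteria.

    The full-sample coefficient map is computed once and parcels are
    eliminated in ascending |coefficient| order (ties broken by parcel
    index); ``rerank_each_step`` recomputes the map on the retained set at
    every iteration instead (sensitivity analysis).  The leave-one-out
    evaluation runs on a decimated retained-count grid (every count for the
    last ``dense_below`` parcels, every ``stride``-th before), then exactly
    around the provisional peak.  ``best_subset`` maximizes metric A.
    """
    from .univariate import map_symptom_to_gbc

    scores = np.asarray(scores, float)
    p = gbc.n_parcels

    if rerank_each_step:
        retained = list(range(p))
        elimination = []
        while len(retained) > 1:
            sub = np.asarray(retained, int)
            beta = map_symptom_to_gbc(scores, GBCMatrix(
                gbc.values[:, sub], [gbc.parcel_ids[i] for i in sub],
                list(gbc.subject_ids))).coefficients
            weakest = np.lexsort((sub, np.abs(beta)))[0]
            elimination.append(retained.pop(weakest))
        elimination.extend(retained)
        elimination = np.asarray(elimination, int)
    else:
        beta = map_symptom_to_gbc(scores, gbc).coefficients
        elimination = np.lexsort((np.arange(p), np.abs(beta)))

    # retained set at count c = last c parcels of the elimination order
    metric_a = np.full(p, np.nan)
    metric_b = np.full(p, np.nan)
    cache: dict[int, tuple] = {}

    def evaluate(count: int):
        if count in cache:
            return
        subset = elimination[p - count:]
        obs, pred, a, b = loo_dpgbc_eval(gbc, scores, subset)
        cache[count] = (obs, pred)
        metric_a[count - 1] = a
        metric_b[count - 1] = b

    for count in _evaluation_counts(p, dense_below, stride):
        evaluate(int(count))
    # refine exactly around the provisional metric-A peak
    provisional = int(np.nanargmax(metric_a)) + 1
    for count in range(max(1, provisional - stride), min(p, provisional + stride) + 1):
        evaluate(count)

    best_count = int(np.nanargmax(metric_a)) + 1
    best_count_b = int(np.nanargmax(metric_b)) + 1
    best_subset = np.sort(elimination[p - best_count:])
    obs, pred = cache[best_count]
    return SelectionResult(
        elimination_order=elimination,
        retained_counts=np.arange(1, p + 1),
        metric_a_curve=metric_a,
        metric_b_curve=metric_b,
        best_subset=best_subset,
        best_count=best_count,
        best_count_metric_b=best_count_b,
        dpgbc_obs=obs,
        dpgbc_pred=pred,
    )
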