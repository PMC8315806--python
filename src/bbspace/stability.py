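"""Generic resampling harness: leave-site-out, k-fold, split-half, leave-one-out.

Any estimator exposing ``fit(indices)`` (returning a fit with a
``components`` matrix of features x k and, for score prediction, a
``project(indices)`` method) can be pushed through the same machinery:

* ``predicted_vs_observed`` — fit on the retained subjects, project the
  held-out subjects, correlate their predicted scores with the scores
  observed under the full-sample fit;
* ``split_half_replication`` — independent fits on two disjoint stratified
  halves, compared by matched-column correlation of loadings/maps.

Component order and sign are arbitrary across refits, so comparisons match
columns greedily by maximum absolute correlation and sign-align before
correlating.  Folds are stratified by default (diagnosis proportions
preserved within +-1 subject per fold); a run containing a failed fold is
excluded from the aggregate statistics and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .symptom_pca import SymptomMatrix, fit_pca, project_scores

__all__ = ["ResamplingPlan", "StabilityReport", "make_folds",
           "predicted_vs_observed", "split_half_replication", "PCAEstimator"]

_SCHEMES = ("kfold", "leave_site_out", "split_half", "leave_one_out")


@dataclass
class ResamplingPlan:
    scheme: str = "kfold"
    k: int = 5
    n_runs: int = 1
    stratify_by: str | None = "diagnosis"
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {_SCHEMES}")
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")


@dataclass
class StabilityReport:
    """Per-run similarity statistics with means and standard errors."""

    scheme: str
    per_run: np.ndarray          # runs x components
    mean: np.ndarray
    sem: np.ndarray
    n_failed_runs: int = 0
    failures: list = field(default_factory=list)


def _resolve(labels, key):
    if labels is None:
        return None
    if isinstance(labels, dict):
        return np.asarray(labels[key]) if key in labels else None
    return np.asarray(labels)


def _n_subjects(labels):
    if isinstance(labels, int):
        return labels
    if isinstance(labels, dict):
        return len(next(iter(labels.values())))
    return len(labels)


def _stratified_folds(n, k, strata, rng):
    folds = [[] for _ in range(k)]
    strata = np.zeros(n, int) if strata is None else strata
    offset = 0
    for value in np.unique(strata):
        idx = rng.permutation(np.flatnonzero(strata == value))
        if len(idx) < k and k > 2:
            raise ValueError(
                f"stratum {value!r} has {len(idx)} subjects, fewer than k={k}"
            )
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(i)
        offset += len(idx) % k
    return [np.sort(np.array(f, int)) for f in folds]


def make_folds(labels, plan: ResamplingPlan, run: int = 0):
    """Disjoint, exhaustive (train, test) index pairs for one run.

    ``labels`` is an int (subject count, unstratified), a label array, or a
    dict of label arrays keyed by name (``plan.stratify_by`` selects the
    stratification labels; leave-site-out requires a ``"site"`` entry or a
    plain array).  Deterministic given ``plan.seed`` and ``run``.
    """
    n = _n_subjects(labels)
    rng = np.random.default_rng(np.random.SeedSequence((plan.seed, run)).generate_state(1)[0])
    everyone = np.arange(n)
    if plan.scheme == "leave_one_out":
        return [(np.delete(everyone, i), np.array([i])) for i in range(n)]
    if plan.scheme == "leave_site_out":
        site = _resolve(labels, "site")
        if site is None:
            raise ValueError("leave_site_out requires site labels")
        folds = [np.flatnonzero(site == s) for s in np.unique(site)]
    else:
        k = 2 if plan.scheme == "split_half" else plan.k
        if k > n:
            raise ValueError(f"k={k} exceeds the number of subjects ({n})")
        strata = None if plan.stratify_by is None else _resolve(labels, plan.stratify_by)
        folds = _stratified_folds(n, k, strata, rng)
    return [(np.setdiff1d(everyone, test), test) for test in folds]


class PCAEstimator:
    """Adapter exposing the symptom PCA to the resampling harness."""

    def __init__(self, data: SymptomMatrix, n_components: int | None = None):
        self.data = data
        self.n_components = n_components

    def fit(self, idx):
        solution = fit_pca(self.data.subset(idx))
        k = self.n_components or solution.n_components
        est, data = self, self.data

        class _Fit:
            components = solution.loadings[:, :k]

            @staticmethod
            def project(idx2):
                return project_scores(solution, data.subset(idx2))[:, :k]

        return _Fit()


def _match_and_correlate(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Greedy |corr| matching of columns, then per-matched-pair correlation."""
    k = ref.shape[1]
    c = np.corrcoef(ref.T, other.T)[:k, k:]
    c = np.nan_to_num(c)
    out = np.empty(k)
    assigned = np.zeros(k, bool)
    taken = np.zeros(other.shape[1], bool)
    for _ in range(k):
        masked = np.where(assigned[:, None] | taken[None, :], -np.inf, np.abs(c))
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        out[i] = abs(c[i, j])
        assigned[i] = True
        taken[j] = True
    return out


def _align_to(ref: np.ndarray, other: np.ndarray):
    """Permutation and signs aligning ``other``'s columns to ``ref``'s."""
    k = ref.shape[1]
    c = np.nan_to_num(np.corrcoef(ref.T, other.T)[:k, k:])
    perm = np.full(k, -1)
    signs = np.ones(k)
    taken = np.zeros(other.shape[1], bool)
    for _ in range(k):
        masked = np.where((perm != -1)[:, None] | taken[None, :], -np.inf, np.abs(c))
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        perm[i] = j
        signs[i] = 1.0 if c[i, j] >= 0 else -1.0
        taken[j] = True
    return perm, signs


def predicted_vs_observed(estimator, labels, plan: ResamplingPlan) -> StabilityReport:
    """Held-out score prediction versus full-sample observed scores.

    Per fold: fit on the retained subjects, align the fold fit's components
    to the full-sample fit (absolute-correlation matching + sign), project
    the held-out subjects, and correlate predicted with observed scores per
    component.  Singleton test sets (leave-one-out) are pooled across folds
    before correlating.  Rows of the report are fold-level (or pooled
    run-level) correlation vectors.
    """
    full = estimator.fit(np.arange(_n_subjects(labels)))
    k = full.components.shape[1]
    rows, failures = [], []
    n_failed = 0
    for run in range(plan.n_runs):
        folds = make_folds(labels, plan, run=run)
        run_rows = []
        pooled_pred, pooled_obs = [], []
        failed = False
        for fold_no, (train, test) in enumerate(folds):
            try:
                fit = estimator.fit(train)
                perm, signs = _align_to(full.components, fit.components)
                pred = fit.project(test)[:, perm] * signs
                obs = full.project(test)
            except Exception as exc:  # noqa: BLE001 - diagnostics, not control flow
                failures.append((run, fold_no, repr(exc)))
                failed = True
                break
            if len(test) == 1:
                pooled_pred.append(pred)
                pooled_obs.append(obs)
            else:
                run_rows.append([np.corrcoef(pred[:, j], obs[:, j])[0, 1] for j in range(k)])
        if failed:
            n_failed += 1
            continue
        if pooled_pred:
            pred = np.vstack(pooled_pred)
            obs = np.vstack(pooled_obs)
            run_rows.append([np.corrcoef(pred[:, j], obs[:, j])[0, 1] for j in range(k)])
        rows.extend(run_rows)
    per_run = np.asarray(rows, float) if rows else np.empty((0, k))
    return _report(plan.scheme, per_run, n_failed, failures)


def split_half_replication(estimator, labels, plan: ResamplingPlan) -> StabilityReport:
    """Independent fits on disjoint stratified halves, compared by matched
    absolute correlation of component columns."""
    half_plan = ResamplingPlan("split_half", n_runs=plan.n_runs,
                               stratify_by=plan.stratify_by, seed=plan.seed)
    rows, failures = [], []
    n_failed = 0
    for run in range(plan.n_runs):
        (_, h1), (_, h2) = make_folds(labels, half_plan, run=run)
        try:
            fit1 = estimator.fit(h1)
            fit2 = estimator.fit(h2)
        except Exception as exc:  # noqa: BLE001
            failures.append((run, None, repr(exc)))
            n_failed += 1
            continue
        rows.append(_match_and_correlate(fit1.components, fit2.components))
    k = rows[0].shape[0] if rows else 0
    per_run = np.asarray(rows, float) if rows else np.empty((0, k))
    return _report("split_half", per_run, n_failed, failures)


def _report(scheme, per_run, n_failed, failures) -> StabilityReport:
    if per_run.size:
        mean = per_run.mean(axis=0)
        sem = per_run.std(axis=0, ddof=1) / np.sqrt(per_run.shape[0]) \
            if per_run.shape[0] > 1 else np.zeros(per_run.shape[1])
    else:
        mean = sem = np.array([])
    return StabilityReport(scheme, per_run, mean, sem, n_failed, failures)
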