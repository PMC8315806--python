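"""Unit-variance PCA of clinical symptom batteries with permutation tests.

The decomposition operates on the item correlation matrix (each item scaled
to unit variance across subjects before the fit), so components are axes of
shared symptom variation rather than raw-score magnitude.  Component
significance follows the permutation logic of Horn-style parallel analysis:
each item column is shuffled independently across subjects, the PCA is
refit, and component k is compared against the null distribution of the
rank-k variance fraction.

Signs of principal axes are arbitrary; here each loading column is oriented
so its largest-magnitude element is positive, and any cross-fit comparison
elsewhere in the package matches components by absolute correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SymptomMatrix", "PCASolution", "fit_pca", "permutation_significance", "project_scores"]


@dataclass
class SymptomMatrix:
    """Subjects x items clinical scores with diagnosis and site labels."""

    values: np.ndarray
    item_ids: list = field(default_factory=list)
    subject_ids: list = field(default_factory=list)
    diagnosis: np.ndarray | None = None
    site: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("values must be subjects x items")
        n, p = self.values.shape
        if not self.item_ids:
            self.item_ids = [f"item{i}" for i in range(p)]
        if not self.subject_ids:
            self.subject_ids = [f"s{i}" for i in range(n)]
        if len(self.item_ids) != p or len(self.subject_ids) != n:
            raise ValueError("label lengths do not match value dimensions")
        if not np.isfinite(self.values).all():
            raise ValueError("symptom matrix contains missing or non-finite values")
        for name in ("diagnosis", "site"):
            lab = getattr(self, name)
            if lab is not None:
                lab = np.asarray(lab)
                if len(lab) != n:
                    raise ValueError(f"{name} labels do not match subject count")
                setattr(self, name, lab)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def subset(self, idx) -> "SymptomMatrix":
        idx = np.asarray(idx)
        return SymptomMatrix(
            self.values[idx],
            list(self.item_ids),
            [self.subject_ids[i] for i in idx],
            None if self.diagnosis is None else self.diagnosis[idx],
            None if self.site is None else self.site[idx],
        )


@dataclass
class PCASolution:
    """Loadings, scores and per-component variance of a symptom PCA.

    ``loadings`` columns are unit-norm eigenvectors of the item correlation
    matrix ordered by decreasing ``variance_fraction``; ``scores`` are the
    standardized data projected on them.  ``item_means`` / ``item_sds`` store
    the standardization used at fit time so held-out subjects can be
    projected without refitting.
    """

    loadings: np.ndarray
    scores: np.ndarray
    variance_fraction: np.ndarray
    item_means: np.ndarray
    item_sds: np.ndarray
    item_ids: list
    pvalues: np.ndarray | None = None
    significant: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _standardize(values: np.ndarray, item_ids) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = item_ids[int(np.argmax(sds == 0))]
        raise ValueError(f"item {bad!r} has zero variance; cannot standardize")
    return (values - means) / sds, means, sds


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Orient each column so its largest-magnitude element is positive."""
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return loadings * flip


def _eig_fractions(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    corr = (z.T @ z) / (z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    return eigval / eigval.sum(), eigvec[:, order]


def fit_pca(data: SymptomMatrix) -> PCASolution:
    """Eigendecomposition of the item correlation matrix.

    Returns all ``n_items`` components (trailing ones carry ~zero variance
    when the data are rank-deficient).  Deterministic up to the documented
    sign convention.
    """
    z, means, sds = _standardize(data.values, data.item_ids)
    frac, vec = _eig_fractions(z)
    loadings = _fix_signs(vec)
    return PCASolution(
        loadings=loadings,
        scores=z @ loadings,
        variance_fraction=frac,
        item_means=means,
        item_sds=sds,
        item_ids=list(data.item_ids),
    )


def permutation_significance(
    data: SymptomMatrix,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PCASolution:
    """Fit the PCA and attach per-component permutation p-values.

    Null model: each item column is independently shuffled across subjects
    (destroying inter-item correlation while preserving marginals) and the
    PCA refit; component k is compared against the null distribution of the
    rank-k variance fraction.  p-values use the add-one estimator
    ``(1 + #{null >= obs}) / (1 + n_perm)`` so they are never zero.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    solution = fit_pca(data)
    rng = np.random.default_rng(seed)
    n, p = data.values.shape
    exceed = np.zeros(p)
    for _ in range(n_perm):
        perm = rng.permuted(data.values, axis=0)
        z, _, _ = _standardize(perm, data.item_ids)
        frac, _ = _eig_fractions(z)
        exceed += frac >= solution.variance_fraction
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    solution.pvalues = pvals
    solution.significant = pvals < alpha
    return solution


def project_scores(solution: PCASolution, new_data: SymptomMatrix) -> np.ndarray:
    """Project new subjects through an existing PCA solution.

    Standardizes with the solution's stored item means/SDs, then applies the
    loadings.  Training data projected through its own solution reproduces
    the stored scores exactly.
    """
    if list(new_data.item_ids) != list(solution.item_ids):
        raise ValueError("item_ids of new data do not match the fitted solution")
    z = (new_data.values - solution.item_means) / solution.item_sds
    return z @ solution.loadings
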