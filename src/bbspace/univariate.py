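"""Mass-univariate symptom-neural mapping at parcel resolution.

Each parcel's GBC is regressed on a single symptom score (simple OLS with
intercept); the resulting coefficient map is Z-scored across parcels so
maps are comparable across predictors.  Family-wise error control over
parcels uses the max-statistic permutation procedure: the predictor is
shuffled across subjects, all parcel |t| statistics recomputed, and each
parcel's corrected p-value is the add-one tail probability of its observed
|t| under the permutation distribution of the maximum.  Shuffling the
predictor (not the brain data) preserves the spatial covariance of GBC,
giving strong FWE control at parcellated resolution.

A PCA of the GBC matrix itself ("neural PCA") exposes the large shared
variance components that are common across subjects irrespective of
symptoms; ``partial_out_neural_pcs`` reconstructs a GBC matrix with the
leading shared components removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import GBCMatrix
from .symptom_pca import PCASolution, _fix_signs

__all__ = ["BetaMap", "map_symptom_to_gbc", "permutation_fwe",
           "fit_neural_pca", "project_neural_scores", "partial_out_neural_pcs"]


@dataclass
class BetaMap:
    """Per-parcel regression slopes of GBC on one symptom score."""

    coefficients: np.ndarray
    zscores: np.ndarray
    tvalues: np.ndarray
    parcel_ids: list
    predictor_id: str = ""
    pvalues: np.ndarray | None = None  # FWE-corrected, when computed


def _slopes_t(scores: np.ndarray, gbc_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-parcel OLS slope and t statistic (intercept included)."""
    n = scores.shape[0]
    x = scores - scores.mean()
    sxx = x @ x
    y = gbc_values - gbc_values.mean(axis=0)
    slopes = (x @ y) / sxx
    resid_ss = (y * y).sum(axis=0) - slopes**2 * sxx
    dof = n - 2
    se = np.sqrt(np.maximum(resid_ss, 0.0) / (dof * sxx))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slopes / se, np.inf * np.sign(slopes))
    return slopes, t


def map_symptom_to_gbc(scores: np.ndarray, gbc: GBCMatrix, predictor_id: str = "",
                       covariates: np.ndarray | None = None) -> BetaMap:
    """Regress every parcel's GBC on one symptom score vector.

    ``covariates`` (subjects x k), when given, are residualized out of both
    the score and the GBC matrix before the per-parcel simple regressions.
    The coefficient map is Z-scored across parcels (map mean 0, SD 1).
    """
    scores = np.asarray(scores, float)
    values = gbc.values
    if scores.ndim != 1 or scores.shape[0] != values.shape[0]:
        raise ValueError("scores length must equal number of subjects")
    if not np.isfinite(scores).all():
        raise ValueError("scores contain non-finite values")
    if np.ptp(scores) == 0:
        raise ValueError("constant score vector; regression is degenerate")
    if covariates is not None:
        design = np.column_stack([np.ones(values.shape[0]), np.asarray(covariates, float)])
        scores = scores - design @ np.linalg.lstsq(design, scores, rcond=None)[0]
        values = values - design @ np.linalg.lstsq(design, values, rcond=None)[0]
        if np.ptp(scores) == 0:
            raise ValueError("score vector is collinear with the covariates")
    slopes, t = _slopes_t(scores, values)
    sd = slopes.std()
    if sd == 0:
        raise ValueError("degenerate coefficient map: zero variance across parcels")
    z = (slopes - slopes.mean()) / sd
    return BetaMap(slopes, z, t, list(gbc.parcel_ids), predictor_id)


def permutation_fwe(scores: np.ndarray, gbc: GBCMatrix, n_perm: int = 2000,
                    seed: int = 0) -> np.ndarray:
    """Max-statistic FWE-corrected p-value per parcel.

    Per permutation the score vector is shuffled across subjects and the
    maximum |t| over parcels recorded; corrected p-values use the add-one
    estimator against that max-null distribution.
    """
    if n_perm < 500:
        raise ValueError("n_perm must be at least 500 for FWE calibration")
    scores = np.asarray(scores, float)
    obs = np.abs(_slopes_t(scores, gbc.values)[1])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(gbc.n_parcels)
    for _ in range(n_perm):
        perm = rng.permutation(scores)
        max_t = np.abs(_slopes_t(perm, gbc.values)[1]).max()
        exceed += max_t >= obs
    return (1.0 + exceed) / (1.0 + n_perm)


def fit_neural_pca(gbc: GBCMatrix, n_perm: int = 0, alpha: float = 0.05,
                   seed: int = 0) -> PCASolution:
    """PCA of the subjects x parcels GBC matrix (unit-variance parcels).

    Same algebra as the symptom PCA but computed through an economy SVD
    (the parcel count typically exceeds the subject count, so at most
    ``n_subjects - 1`` components carry variance; only those are kept).
    The optional permutation significance variant shuffles parcels within
    subject, breaking topography while preserving each subject's value
    distribution.
    """
    x = gbc.values
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = gbc.parcel_ids[int(np.argmax(sds == 0))]
        raise ValueError(f"parcel {bad!r} has zero variance; cannot standardize")
    z = (x - means) / sds

    def _svd_fractions(zm):
        u, s, vt = np.linalg.svd(zm, full_matrices=False)
        rank = min(zm.shape[0] - 1, zm.shape[1])
        ev = s[:rank] ** 2
        return ev / (zm.shape[1] * (zm.shape[0] - 1)), vt[:rank].T

    frac, vec = _svd_fractions(z)
    loadings = _fix_signs(vec)
    solution = PCASolution(
        loadings=loadings,
        scores=z @ loadings,
        variance_fraction=frac,
        item_means=means,
        item_sds=sds,
        item_ids=list(gbc.parcel_ids),
    )
    if n_perm:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(frac))
        for _ in range(n_perm):
            perm = rng.permuted(x, axis=1)  # shuffle parcels within subject
            psd = perm.std(axis=0, ddof=1)
            psd[psd == 0] = 1.0
            zp = (perm - perm.mean(axis=0)) / psd
            exceed += _svd_fractions(zp)[0] >= frac
        pvals = (1.0 + exceed) / (1.0 + n_perm)
        solution.pvalues = pvals
        solution.significant = pvals < alpha
    return solution


def project_neural_scores(solution: PCASolution, gbc: GBCMatrix) -> np.ndarray:
    if list(gbc.parcel_ids) != list(solution.item_ids):
        raise ValueError("parcel_ids do not match the fitted neural PCA")
    return ((gbc.values - solution.item_means) / solution.item_sds) @ solution.loadings


def partial_out_neural_pcs(gbc_patients: GBCMatrix, neural_solution: PCASolution,
                           drop_k: int) -> GBCMatrix:
    """Reconstruct a GBC matrix with the first ``drop_k`` neural PCs removed.

    Patients are projected through the (possibly combined-group) solution;
    the contribution of the dropped leading components is subtracted in
    standardized space and the original parcel scaling restored.  The
    residual standardized matrix is orthogonal to the dropped components.
    """
    if drop_k < 0 or drop_k > neural_solution.n_components:
        raise ValueError("drop_k must lie in [0, n_components]")
    z = (gbc_patients.values - neural_solution.item_means) / neural_solution.item_sds
    if drop_k > 0:
        lead = neural_solution.loadings[:, :drop_k]
        z = z - (z @ lead) @ lead.T
    values = z * neural_solution.item_sds + neural_solution.item_means
    return GBCMatrix(values, list(gbc_patients.parcel_ids), list(gbc_patients.subject_ids))
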