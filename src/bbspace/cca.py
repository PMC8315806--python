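"""Canonical correlation analysis between neural and symptom feature sets.

``fit_cca`` standardizes both feature blocks and solves the CCA through the
singular value decomposition of the whitened cross-covariance: with
standardized blocks X (n x p) and Y (n x q), economy SVDs X = Ux Sx Vx' and
Y = Uy Sy Vy' give orthonormal score bases, and the SVD of Ux' Uy yields the
canonical correlations and, after back-transformation, the weight matrices.
Latent variates are scaled to unit variance; correlations are non-increasing
over modes and the k-th pair of variates correlates exactly at the k-th
canonical correlation.

Mode significance uses a permutation null (symptom-side subject shuffling,
rank-matched across modes) with Benjamini-Hochberg FDR across modes.

The module also carries the generative power analysis: a joint Gaussian
model over p + q features encoding exactly one true canonical mode at a
specified correlation, Monte-Carlo estimation of detection power and of
four estimation-error metrics, and a bisection search for the smallest
sample size meeting power/error targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["CCASolution", "PowerQuery", "fit_cca", "mode_significance",
           "variance_explained", "project_item_loadings", "loo_latent_prediction",
           "CCAPowerModel", "required_sample_size"]

_RIDGE = 1e-10  # relative cutoff for rank decisions in whitening


@dataclass
class CCASolution:
    """Paired transformations and latent variates of one CCA fit.

    ``psi`` (symptom features x modes) and ``theta`` (neural features x
    modes) map standardized feature blocks to the unit-variance latent
    variates ``u_scores`` / ``v_scores``.  Feature means/SDs from the fit
    are stored so held-out subjects can be projected.
    """

    psi: np.ndarray
    theta: np.ndarray
    u_scores: np.ndarray
    v_scores: np.ndarray
    canonical_correlations: np.ndarray
    neural_means: np.ndarray
    neural_sds: np.ndarray
    symptom_means: np.ndarray
    symptom_sds: np.ndarray
    mode_pvalues: np.ndarray | None = None
    fdr_significant: np.ndarray | None = None

    @property
    def n_modes(self) -> int:
        return len(self.canonical_correlations)


def _standardize_block(x: np.ndarray, name: str):
    x = np.asarray(x, float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    if (sds == 0).any():
        raise ValueError(f"{name} feature {int(np.argmax(sds == 0))} has zero variance")
    return (x - means) / sds, means, sds


def _whiten(z: np.ndarray):
    """Economy SVD whitening; raises on rank deficiency."""
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if s[-1] <= _RIDGE * s[0]:
        raise ValueError(
            "feature block is rank deficient; reduce the feature space "
            "(e.g. parcel symmetrization or a preliminary PCA) before CCA"
        )
    return u, s, vt


def fit_cca(neural: np.ndarray, symptoms: np.ndarray) -> CCASolution:
    """Fit a CCA between standardized neural and symptom feature blocks.

    Requires more subjects than total features (otherwise the solution is
    degenerate with all correlations 1).  Returns ``min(p, q)`` modes with
    the deterministic sign convention: each psi column's largest-magnitude
    element is positive, and theta is flipped jointly so canonical
    correlations stay non-negative.
    """
    x, xm, xs = _standardize_block(neural, "neural")
    y, ym, ys = _standardize_block(symptoms, "symptom")
    n, p = x.shape
    q = y.shape[1]
    if x.shape[0] != y.shape[0]:
        raise ValueError("neural and symptom blocks have different subject counts")
    if n <= p + q:
        raise ValueError(
            f"CCA needs more subjects than total features (n={n}, p+q={p + q}); "
            "reduce the feature space first"
        )
    ux, sx, vxt = _whiten(x)
    uy, sy, vyt = _whiten(y)
    a, d, bt = np.linalg.svd(ux.T @ uy, full_matrices=False)
    k = min(p, q)
    a, d, b = a[:, :k], np.clip(d[:k], 0.0, 1.0), bt.T[:, :k]
    # weights on standardized features giving unit-variance variates
    theta = vxt.T @ (a / sx[:, None]) * np.sqrt(n - 1)
    psi = vyt.T @ (b / sy[:, None]) * np.sqrt(n - 1)
    # sign convention on the symptom side; neural side follows
    flip = np.sign(psi[np.abs(psi).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    psi *= flip
    theta *= flip
    return CCASolution(psi, theta, y @ psi, x @ theta, d, xm, xs, ym, ys)


def _null_correlations(ux, uy, rng, n_perm, k):
    null = np.empty((n_perm, k))
    n = ux.shape[0]
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = np.linalg.svd(ux.T @ uy[perm], compute_uv=False)[:k]
    return null


def mode_significance(neural, symptoms, n_perm: int = 5000, alpha: float = 0.05,
                      seed: int = 0) -> CCASolution:
    """Fit the CCA and attach permutation p-values with BH-FDR flags.

    Symptom-side subjects are shuffled per permutation; each mode is
    compared against the permutation distribution of the same-rank
    canonical correlation (add-one p-values).
    """
    if n_perm < 500:
        raise ValueError("n_perm must be at least 500")
    solution = fit_cca(neural, symptoms)
    x, _, _ = _standardize_block(neural, "neural")
    y, _, _ = _standardize_block(symptoms, "symptom")
    ux = _whiten(x)[0]
    uy = _whiten(y)[0]
    k = solution.n_modes
    null = _null_correlations(ux, uy, np.random.default_rng(seed), n_perm, k)
    obs = solution.canonical_correlations
    pvals = (1.0 + (null >= obs).sum(axis=0)) / (1.0 + n_perm)
    solution.mode_pvalues = pvals
    solution.fdr_significant = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    return solution


def variance_explained(solution: CCASolution, symptoms: np.ndarray) -> tuple[np.ndarray, float]:
    """Symptom variance explained by each latent neural variate.

    For neural variate V_k the proportion is the variance-weighted mean of
    squared correlations between V_k and each symptom feature; the total is
    the sum over modes.  With orthogonal variates this is the R^2 of the
    symptom block on the latent neural scores.
    """
    y = np.asarray(symptoms, float)
    yc = y - y.mean(axis=0)
    var = yc.var(axis=0, ddof=1)
    v = solution.v_scores
    props = np.empty(solution.n_modes)
    for k in range(solution.n_modes):
        vk = v[:, k] - v[:, k].mean()
        denom = vk @ vk
        with np.errstate(invalid="ignore"):
            r2 = np.where(
                var > 0,
                (yc.T @ vk) ** 2 / (denom * (yc * yc).sum(axis=0)),
                0.0,
            )
        props[k] = (r2 * var).sum() / var.sum()
    return props, float(props.sum())


def project_item_loadings(cca_psi: np.ndarray, pca_loadings: np.ndarray) -> np.ndarray:
    """Original-item loadings per canonical variate.

    When the CCA was computed on PCA component scores, multiplying the PCA
    loadings (items x PCs) with the CCA symptom transformation (PCs x
    modes) expresses each canonical variate in the original item basis.
    """
    psi = np.asarray(cca_psi, float)
    load = np.asarray(pca_loadings, float)
    if load.shape[1] != psi.shape[0]:
        raise ValueError(
            f"inner dimensions disagree: pca_loadings is {load.shape}, cca_psi is {psi.shape}"
        )
    return load @ psi


def _match_columns(reference: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy max-|correlation| column matching; returns (perm, signs)."""
    k = reference.shape[1]
    c = np.corrcoef(reference.T, other.T)[:k, k:]
    c = np.nan_to_num(c)
    perm = np.full(k, -1)
    signs = np.ones(k)
    taken = np.zeros(other.shape[1], bool)
    for _ in range(k):
        masked = np.where(taken[None, :] | (perm != -1)[:, None], -np.inf, np.abs(c))
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        perm[i] = j
        signs[i] = 1.0 if c[i, j] >= 0 else -1.0
        taken[j] = True
    return perm, signs


def loo_latent_prediction(neural: np.ndarray, symptoms: np.ndarray,
                          seed: int = 0) -> np.ndarray:
    """Leave-one-subject-out prediction of latent variates.

    For each held-out subject the CCA is refit on the remaining subjects,
    the refit solution's modes aligned to the full-sample solution (greedy
    absolute-correlation matching of psi columns, sign-aligned), and the
    held-out subject's latent scores computed from the refit weights.  The
    assembled predicted U-hat / V-hat columns are correlated with each
    other across subjects; with a stable solution these correlations are
    comparable to the in-sample canonical correlations, while an overfit
    solution collapses toward zero.
    """
    x = np.asarray(neural, float)
    y = np.asarray(symptoms, float)
    n = x.shape[0]
    full = fit_cca(x, y)
    k = full.n_modes
    u_hat = np.empty((n, k))
    v_hat = np.empty((n, k))
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        fit = fit_cca(x[mask], y[mask])
        perm, signs = _match_columns(full.psi, fit.psi[:, :k])
        xi = (x[i] - fit.neural_means) / fit.neural_sds
        yi = (y[i] - fit.symptom_means) / fit.symptom_sds
        u_hat[i] = signs * (yi @ fit.psi[:, perm])
        v_hat[i] = signs * (xi @ fit.theta[:, perm])
    return np.array([np.corrcoef(u_hat[:, j], v_hat[:, j])[0, 1] for j in range(k)])


# ---------------------------------------------------------------------------
# Generative power analysis
# ---------------------------------------------------------------------------

@dataclass
class PowerQuery:
    """Specification of a CCA power question.

    ``true_r`` is the single planted canonical correlation; power is the
    probability of detecting a nonzero association at alpha = 0.05 via the
    rank-1 permutation test, and the four error metrics (association
    strength, weights, scores, loadings — relative error for the strength,
    1 - |cosine| or 1 - |correlation| for the vector quantities) must all
    fall to ``target_error`` on average.
    """

    n_features_x: int
    n_features_y: int
    true_r: float
    target_power: float = 0.9
    target_error: float = 0.1
    n_reps: int = 100
    n_perm: int = 100
    spectrum_decay: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.true_r < 1):
            raise ValueError("true_r must lie in (0, 1)")
        if self.n_features_x < 2 or self.n_features_y < 2:
            raise ValueError("each feature set needs at least 2 features")


class CCAPowerModel:
    """Joint Gaussian generative model with one planted canonical mode.

    Within-set covariance has a power-law eigenvalue spectrum
    ``lambda_i ~ i**-spectrum_decay`` (decay 0 gives the identity) in a
    random orthogonal basis, trace-normalized to the feature count.  True
    weight vectors are random directions normalized to unit score variance;
    the cross-covariance is the rank-one ``true_r * (Sx wx)(Sy wy)'``, so
    the population canonical correlation equals ``true_r`` exactly and true
    weights, scores and loadings are known in closed form.
    """

    def __init__(self, p: int, q: int, true_r: float, spectrum_decay: float = 1.0,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.p, self.q, self.true_r = p, q, true_r
        sx = self._within(p, spectrum_decay, rng)
        sy = self._within(q, spectrum_decay, rng)
        self.wx = self._weight(sx, rng)
        self.wy = self._weight(sy, rng)
        cross = true_r * np.outer(sx @ self.wx, sy @ self.wy)
        joint = np.block([[sx, cross], [cross.T, sy]])
        # planted mode has unit score variance, so the joint matrix is PSD
        self.chol = np.linalg.cholesky(joint + 1e-12 * np.eye(p + q))
        self.sigma_x, self.sigma_y = sx, sy
        self.true_loadings_x = (sx @ self.wx) / np.sqrt(np.diag(sx))
        self.true_loadings_y = (sy @ self.wy) / np.sqrt(np.diag(sy))

    @staticmethod
    def _within(d: int, decay: float, rng) -> np.ndarray:
        lam = np.arange(1, d + 1, dtype=float) ** -decay
        lam *= d / lam.sum()
        if decay == 0:
            return np.eye(d)
        basis = np.linalg.qr(rng.standard_normal((d, d)))[0]
        return basis @ np.diag(lam) @ basis.T

    @staticmethod
    def _weight(sigma: np.ndarray, rng) -> np.ndarray:
        w = rng.standard_normal(sigma.shape[0])
        return w / np.sqrt(w @ sigma @ w)

    def sample(self, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
        z = rng.standard_normal((n, self.p + self.q))
        data = z @ self.chol.T
        return data[:, :self.p], data[:, self.p:]

    def evaluate(self, n: int, n_reps: int, n_perm: int, rng,
                 alpha: float = 0.05) -> dict:
        """Monte-Carlo power and mean error metrics at sample size n.

        The CCA is solved from the feature covariance blocks (inverse
        square roots by eigendecomposition), avoiding any n x p
        factorization.  The permutation detection threshold — the
        ``1 - alpha`` quantile of the leading canonical correlation under
        symptom-side subject shuffling — is calibrated once per sample size
        on the first replicate and reused across replicates; under the null
        of no association that distribution depends on the block dimensions,
        not the draw.
        """
        detect = 0
        errs = np.zeros(4)  # association, weights, scores, loadings
        thresh = None
        wx_t = self.wx * np.sqrt(np.diag(self.sigma_x))
        wy_t = self.wy * np.sqrt(np.diag(self.sigma_y))
        for rep in range(n_reps):
            x, y = self.sample(n, rng)
            xz, _, _ = _standardize_block(x, "x")
            yz, _, _ = _standardize_block(y, "y")
            wxx = _inv_sqrt(xz.T @ xz / (n - 1))
            wyy = _inv_sqrt(yz.T @ yz / (n - 1))
            cxy = xz.T @ yz / (n - 1)
            a, d, bt = np.linalg.svd(wxx @ cxy @ wyy)
            r1 = min(d[0], 1.0)
            wx_hat = wxx @ a[:, 0]
            wy_hat = wyy @ bt[0]
            if rep == 0:
                null = np.empty(n_perm)
                for j in range(n_perm):
                    perm = rng.permutation(n)
                    null[j] = np.linalg.svd(
                        wxx @ (xz.T @ yz[perm] / (n - 1)) @ wyy, compute_uv=False
                    )[0]
                thresh = np.quantile(null, 1.0 - alpha)
            detect += r1 > thresh
            errs[0] += abs(r1 - self.true_r) / self.true_r
            errs[1] += max(1 - _abs_cos(wx_hat, wx_t), 1 - _abs_cos(wy_hat, wy_t))
            tx = x @ self.wx
            ty = y @ self.wy
            errs[2] += max(1 - _abs_corr(xz @ wx_hat, tx), 1 - _abs_corr(yz @ wy_hat, ty))
            lx_hat = _col_corrs(xz, xz @ wx_hat)
            ly_hat = _col_corrs(yz, yz @ wy_hat)
            errs[3] += max(1 - _abs_cos(lx_hat, self.true_loadings_x),
                           1 - _abs_cos(ly_hat, self.true_loadings_y))
        errs /= n_reps
        return {
            "power": detect / n_reps,
            "error_association": errs[0],
            "error_weights": errs[1],
            "error_scores": errs[2],
            "error_loadings": errs[3],
        }


def _inv_sqrt(c: np.ndarray) -> np.ndarray:
    eigval, eigvec = np.linalg.eigh(c)
    if eigval[0] <= _RIDGE * eigval[-1]:
        raise ValueError("covariance block is rank deficient; reduce the feature space")
    return eigvec @ ((1.0 / np.sqrt(eigval))[:, None] * eigvec.T)


def _abs_cos(a, b) -> float:
    return abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))


def _abs_corr(a, b) -> float:
    return abs(np.corrcoef(a, b)[0, 1])


def _col_corrs(z: np.ndarray, score: np.ndarray) -> np.ndarray:
    s = score - score.mean()
    return (z.T @ s) / (np.sqrt((z * z).sum(axis=0)) * np.linalg.norm(s))


def required_sample_size(query: PowerQuery, n_min: int | None = None,
                         n_max: int = 65536, grid_factor: float = 1.25,
                         return_details: bool = False):
    """Smallest n meeting the power and error targets, by grid bisection.

    A geometric grid of candidate sample sizes (ratio ``grid_factor``) is
    searched by bisection under the monotonicity assumption that power
    rises and errors fall with n.  Each grid point is evaluated with
    ``query.n_reps`` Monte-Carlo replicates (seeded per point, so repeated
    evaluations are reproducible).  Raises if even the largest grid point
    fails the targets.
    """
    model = CCAPowerModel(query.n_features_x, query.n_features_y, query.true_r,
                          query.spectrum_decay, seed=query.seed)
    lo_n = n_min if n_min is not None else max(4 * (query.n_features_x + query.n_features_y), 32)
    grid = [lo_n]
    while grid[-1] < n_max:
        grid.append(int(np.ceil(grid[-1] * grid_factor)))
    details = {}

    def passes(idx: int) -> bool:
        n = grid[idx]
        rng = np.random.default_rng(np.random.SeedSequence((query.seed, n)).generate_state(1)[0])
        res = model.evaluate(n, query.n_reps, query.n_perm, rng)
        details[n] = res
        return (res["power"] >= query.target_power
                and res["error_association"] <= query.target_error
                and res["error_weights"] <= query.target_error
                and res["error_scores"] <= query.target_error
                and res["error_loadings"] <= query.target_error)

    # coarse upward scan (every 6th grid point, ~3.8x steps) to bracket the
    # transition, then bisection inside the bracket
    stride = 6
    lo, hi = 0, None
    for idx in range(0, len(grid), stride):
        if passes(idx):
            hi = idx
            break
        lo = idx
    if hi is None:
        if lo < len(grid) - 1 and passes(len(grid) - 1):
            hi = len(grid) - 1
        else:
            raise RuntimeError(
                f"targets not met within the search bracket [{grid[0]}, {grid[-1]}]"
            )
    if hi == 0:
        n_req = grid[0]
    else:
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if passes(mid):
                hi = mid
            else:
                lo = mid
        n_req = grid[hi]
    return (n_req, details) if return_details else n_req
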