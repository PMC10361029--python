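"""Kernel machinery: RBF Gram matrices, EasyMKL weights, and the SVM dual.

Each feature *source* (a (valence, ROI, band) block of the feature table)
induces one RBF kernel.  EasyMKL learns a nonnegative weight per kernel by
solving a single convex quadratic program over the bi-class probability
simplex: with L = diag(labels) and the averaged kernel
K̄ = Σ_p K_p / N_p,

    min_{γ ∈ Ξ}  (1 − λ) γᵀ L K̄ L γ + λ ‖γ‖²,

where Ξ constrains γ to be a probability distribution over each class
separately.  The minimizer locates the two nearest points of the class
convex hulls in the combined feature space; the weight of source p is then
η_p ∝ γᵀ L K_p L γ (clipped at zero, normalized to unit norm), so a larger
η_p marks a source along which the hulls are further apart — i.e. a more
relevant source.  A kernel SVM trained on the combined Gram matrix
Σ_p η_p K_p yields the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.spatial.distance import cdist

__all__ = [
    "KernelSet", "MKLModel", "rbf_kernel", "sigma_heuristic",
    "easymkl_fit", "combine_kernels", "svm_fit", "svm_decision", "predict",
]


@dataclass
class KernelSet:
    """Ordered per-source Gram matrices over a common sample set.

    Training sets hold square (train x train) matrices; test sets hold
    rectangular (test x train) blocks in the same source order.
    """

    source_ids: list
    matrices: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.source_ids) != len(self.matrices):
            raise ValueError("source_ids and matrices must have equal length")
        if not self.matrices:
            raise ValueError("empty kernel set")
        shape = self.matrices[0].shape
        for K in self.matrices:
            if K.shape != shape:
                raise ValueError("all Gram matrices must have the same shape")

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def n_samples(self) -> int:
        return self.matrices[0].shape[0]

    def validate(self, atol: float = 1e-8, eig_tol: float = -1e-10) -> None:
        """Check symmetry and positive semidefiniteness of every matrix."""
        for sid, K in zip(self.source_ids, self.matrices):
            if not np.allclose(K, K.T, atol=atol):
                raise ValueError(f"kernel {sid}: not symmetric")
            w = np.linalg.eigvalsh((K + K.T) / 2)
            if w.min() < eig_tol:
                raise ValueError(f"kernel {sid}: min eigenvalue {w.min():.3e} < {eig_tol}")


@dataclass
class MKLModel:
    """Learned MKL + SVM parameters.

    ``eta`` are the per-source kernel weights (nonnegative, unit norm);
    ``gamma_solution`` is the bi-class simplex minimizer; ``alpha`` and
    ``b`` are the SVM dual coefficients and offset for the combined
    kernel.
    """

    eta: np.ndarray | None = None
    gamma_solution: np.ndarray | None = None
    lam: float = 0.2
    alpha: np.ndarray | None = None
    b: float = 0.0
    C: float = 1.0
    labels: np.ndarray | None = None
    source_ids: list = field(default_factory=list)
    weight_norm: str = "L2"

    def to_dict(self) -> dict:
        return {
            "eta": None if self.eta is None else self.eta.tolist(),
            "gamma_solution": None if self.gamma_solution is None else self.gamma_solution.tolist(),
            "lambda": self.lam,
            "alpha": None if self.alpha is None else self.alpha.tolist(),
            "b": self.b,
            "C": self.C,
            "labels": None if self.labels is None else self.labels.tolist(),
            "source_ids": [list(s) if isinstance(s, tuple) else s for s in self.source_ids],
            "weight_norm": self.weight_norm,
        }


def rbf_kernel(X: np.ndarray, Z: np.ndarray, sigma: float) -> np.ndarray:
    """RBF Gram matrix ``exp(-sigma * ||x - z||^2)``.

    ``sigma`` here multiplies the squared distance directly (the width
    heuristics below produce it on that scale).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not (np.isfinite(X).all() and np.isfinite(Z).all()):
        raise ValueError("non-finite feature values")
    if X.shape[1] != Z.shape[1]:
        raise ValueError("feature dimensions differ")
    d2 = cdist(X, Z, metric="sqeuclidean")
    return np.exp(-sigma * d2)


def sigma_heuristic(X_train: np.ndarray) -> float:
    """Width heuristic for single-kernel SVMs: sigma = 1 / (d * var).

    ``d`` is the number of features in the source block and ``var`` the
    population variance of all training feature values pooled together.
    For z-scored blocks this gives 1/d, so typical squared distances
    (around 2d) map into the kernel's sensitive range.
    """
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    d = X.shape[1]
    var = float(X.var())
    if var <= 0:
        raise ValueError(
            "pooled training variance is zero; jitter the features or drop "
            "the constant source"
        )
    return 1.0 / (d * var)


def _class_masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=float)
    pos, neg = labels > 0, labels < 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    return pos, neg


def easymkl_fit(
    kernels: KernelSet,
    labels: np.ndarray,
    lam: float = 0.2,
    weight_norm: str = "L2",
    tol: float = 1e-12,
) -> MKLModel:
    """Learn EasyMKL kernel weights.

    Solves the convex QP ``min_{γ∈Ξ} (1-λ) γᵀL K̄ Lγ + λ‖γ‖²`` over the
    bi-class simplex (γ sums to one over each class, γ ≥ 0) with the
    averaged kernel K̄, then scores each source as η_p ∝ γᵀ L K_p L γ,
    clipped at zero and normalized to unit L2 (or L1) norm.
    """
    if not 0 <= lam <= 1:
        raise ValueError("lambda must lie in [0, 1]")
    y = np.asarray(labels, dtype=float)
    n = kernels.n_samples
    if y.shape != (n,):
        raise ValueError("labels length must match kernel size")
    pos, neg = _class_masks(y)

    Kbar = sum(kernels.matrices) / len(kernels)
    Q = (1 - lam) * (y[:, None] * y[None, :]) * Kbar + lam * np.eye(n)
    Q = (Q + Q.T) / 2

    def fun(g):
        return float(g @ Q @ g)

    def jac(g):
        return 2.0 * (Q @ g)

    g0 = np.where(pos, 1.0 / pos.sum(), 1.0 / neg.sum())
    constraints = [
        {"type": "eq", "fun": lambda g: g[pos].sum() - 1.0,
         "jac": lambda g: pos.astype(float)},
        {"type": "eq", "fun": lambda g: g[neg].sum() - 1.0,
         "jac": lambda g: neg.astype(float)},
    ]
    res = optimize.minimize(
        fun, g0, jac=jac, method="SLSQP",
        bounds=[(0.0, None)] * n, constraints=constraints,
        options={"maxiter": 1000, "ftol": tol},
    )
    if not res.success:
        raise RuntimeError(f"EasyMKL QP did not converge: {res.message}")
    gamma = np.clip(res.x, 0.0, None)
    gamma[pos] /= gamma[pos].sum()
    gamma[neg] /= gamma[neg].sum()

    Lg = y * gamma
    raw = np.array([float(Lg @ K @ Lg) for K in kernels.matrices])
    raw[raw < 1e-12] = 0.0
    if weight_norm == "L2":
        norm = np.linalg.norm(raw)
    elif weight_norm == "L1":
        norm = raw.sum()
    else:
        raise ValueError("weight_norm must be 'L2' or 'L1'")
    if norm == 0:
        raise RuntimeError("all source scores are zero; cannot normalize weights")
    eta = raw / norm
    return MKLModel(eta=eta, gamma_solution=gamma, lam=lam, labels=y.astype(int),
                    source_ids=list(kernels.source_ids), weight_norm=weight_norm)


def combine_kernels(kernels: KernelSet, eta: np.ndarray) -> np.ndarray:
    """Weighted sum ``Σ_p η_p K_p`` (PSD for nonnegative weights)."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (len(kernels),):
        raise ValueError("eta length must equal the number of kernels")
    if (eta < 0).any():
        raise ValueError("kernel weights must be nonnegative")
    out = np.zeros_like(kernels.matrices[0])
    for w, K in zip(eta, kernels.matrices):
        out += w * K
    return out


def _smo(K: np.ndarray, y: np.ndarray, C: float,
         tol: float = 1e-8, max_iter: int = 500000) -> np.ndarray:
    """SMO solver for max Σα − ½ αᵀ(yyᵀ∘K)α, 0 ≤ α ≤ C, Σ α_i y_i = 0.

    Maximal-violating-pair working-set selection with exact second-order
    steps clipped to the box; stops when the KKT violation gap drops below
    ``tol``.  The step direction (α_i += y_i t, α_j −= y_j t) preserves the
    equality constraint exactly.
    """
    n = y.size
    alpha = np.zeros(n)
    Q = (y[:, None] * y[None, :]) * K
    grad = -np.ones(n)  # gradient of ½αᵀQα − Σα
    eps = 1e-14
    for _ in range(max_iter):
        yg = -y * grad
        i_ok = ((y > 0) & (alpha < C - eps)) | ((y < 0) & (alpha > eps))
        j_ok = ((y > 0) & (alpha > eps)) | ((y < 0) & (alpha < C - eps))
        if not i_ok.any() or not j_ok.any():
            break
        ii = np.flatnonzero(i_ok)
        jj = np.flatnonzero(j_ok)
        i = ii[np.argmax(yg[ii])]
        j = jj[np.argmin(yg[jj])]
        if yg[i] - yg[j] < tol:
            break
        quad = max(K[i, i] + K[j, j] - 2 * K[i, j], 1e-12)
        t = (yg[i] - yg[j]) / quad
        t = min(t, C - alpha[i] if y[i] > 0 else alpha[i])
        t = min(t, alpha[j] if y[j] > 0 else C - alpha[j])
        if t <= 0:
            break
        di = y[i] * t
        dj = -y[j] * t
        alpha[i] += di
        alpha[j] += dj
        grad += Q[:, i] * di + Q[:, j] * dj
    return alpha


def svm_fit(
    K: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    model: MKLModel | None = None,
    tol: float = 1e-8,
) -> MKLModel:
    """Train a kernel SVM from a precomputed Gram matrix (dual problem).

    The offset ``b`` is the average KKT residual over unbounded support
    vectors (0 < α < C), falling back to the midpoint of the feasible
    interval when every support vector sits on the box boundary.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(labels, dtype=float)
    if K.shape != (y.size, y.size):
        raise ValueError("Gram matrix and labels are inconsistent")
    _class_masks(y)
    if C <= 0:
        raise ValueError("C must be positive")
    alpha = _smo(K, y, C, tol=tol)
    if not np.isfinite(alpha).all():
        raise RuntimeError("SVM solver produced non-finite coefficients")

    f = K @ (alpha * y)  # decision values without offset
    margin = (alpha > 1e-8 * C) & (alpha < C * (1 - 1e-8))
    if margin.any():
        b = float(np.mean(y[margin] - f[margin]))
    else:
        # feasible interval endpoints from the box KKT conditions
        upper_set = ((alpha <= 1e-8 * C) & (y > 0)) | ((alpha >= C * (1 - 1e-8)) & (y < 0))
        lower_set = ((alpha <= 1e-8 * C) & (y < 0)) | ((alpha >= C * (1 - 1e-8)) & (y > 0))
        hi = np.min(y[upper_set] - f[upper_set]) if upper_set.any() else 0.0
        lo = np.max(y[lower_set] - f[lower_set]) if lower_set.any() else 0.0
        b = float((hi + lo) / 2)

    out = model if model is not None else MKLModel()
    out.alpha = alpha
    out.b = b
    out.C = C
    out.labels = y.astype(int)
    return out


def svm_decision(model: MKLModel, K_test: np.ndarray) -> np.ndarray:
    """Decision values for test rows of a (test x train) Gram matrix."""
    if model.alpha is None:
        raise ValueError("model has no trained SVM coefficients")
    K_test = np.atleast_2d(np.asarray(K_test, dtype=float))
    if K_test.shape[1] != model.alpha.size:
        raise ValueError("test Gram block does not match training size")
    return K_test @ (model.alpha * model.labels) + model.b


def predict(model: MKLModel, kernels_test: KernelSet | list[np.ndarray]) -> np.ndarray:
    """Predict labels from per-source (test x train) Gram blocks.

    Blocks must be ordered as the training sources; they are combined with
    the model's η before the SVM decision rule.  ``sign(0)`` maps to +1.
    """
    if isinstance(kernels_test, KernelSet):
        if model.source_ids and list(kernels_test.source_ids) != list(model.source_ids):
            raise ValueError("test sources do not match training sources")
        blocks = kernels_test.matrices
    else:
        blocks = list(kernels_test)
    eta = model.eta if model.eta is not None else np.ones(len(blocks)) / len(blocks)
    if len(blocks) != eta.size:
        raise ValueError("number of test blocks does not match eta")
    K = sum(w * np.atleast_2d(B) for w, B in zip(eta, blocks))
    dec = svm_decision(model, K)
    return np.where(dec >= 0, 1, -1)
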