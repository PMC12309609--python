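"""Linear classifiers in the projected space: soft-margin SVM and the
joint binary/continuous objective (MLVO), plus back-projection of weights
to per-(position, residue) betas and per-position contributions.

The joint objective trains one linear score f(x) = w.x + b against both
label types:

    lambda * ||w||^2
      + (1/n_bin)  sum_i c_i * hinge(y_i * f(x_i))
      + (mu/n_cont) sum_j (f(x_j) - y_j)^2

With mu = 0 (or no continuous labels) and lambda = 1/(2 * n_bin * C) the
minimizer coincides with the C-parameterized soft-margin SVM, so the model
reduces exactly to the SVM baseline. The shared score enforces the
monotone link between continuous affinity and binary class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from sklearn.svm import SVC

DEFAULT_C = 0.01

#: the 11 shipped prediction tasks
MODEL_IDS = (
    "overall_binder",
    "high_vs_low",
    "001",
    "002",
    "004",
    "005",
    "008",
    "009",
    "015",
    "020",
    "029",
)


@dataclass
class LinearModel:
    """A fitted linear score in projected space with back-projected betas."""

    model_id: str
    w: np.ndarray
    b: float
    betas: Optional[np.ndarray] = None
    intercept: Optional[float] = None  # intercept on the raw feature scale
    feature_labels: list = field(default_factory=list)
    kernel: str = "linear"
    metadata: dict = field(default_factory=dict)
    _estimator: object = None  # kept only for polynomial kernels

    def decision(self, X: np.ndarray) -> np.ndarray:
        return score(self, X)


@dataclass
class MLVOProblem:
    """Inputs for the joint binary/continuous fit.

    ``y_bin`` holds +/-1 with NaN for unlabeled samples; ``y_cont`` holds
    real (log-binding scale) values with NaN for unlabeled samples. Every
    sample must carry at least one label.
    """

    X: np.ndarray
    y_bin: np.ndarray
    y_cont: np.ndarray
    lam: Optional[float] = None  # defaults to 1/(2 * n_bin * C)
    mu: float = 1.0
    C: float = DEFAULT_C
    class_weight: Optional[str] = "balanced"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y_bin = np.asarray(self.y_bin, dtype=float)
        self.y_cont = np.asarray(self.y_cont, dtype=float)
        n = self.X.shape[0]
        if self.y_bin.shape != (n,) or self.y_cont.shape != (n,):
            raise ValueError("label arrays must match the number of rows")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        has_label = ~np.isnan(self.y_bin) | ~np.isnan(self.y_cont)
        if not has_label.all():
            raise ValueError("every sample needs at least one label")
        if not has_label.any():
            raise ValueError("no labels at all")


def _balanced_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample weights inversely proportional to class size (mean 1)."""
    classes, counts = np.unique(y, return_counts=True)
    w = {cls: len(y) / (len(classes) * cnt) for cls, cnt in zip(classes, counts)}
    return np.array([w[v] for v in y])


def fit_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = DEFAULT_C,
    kernel: str = "linear",
    class_weight: Optional[str] = "balanced",
    tol: float = 1e-8,
    model_id: str = "svm",
) -> LinearModel:
    """Soft-margin SVM (libsvm) with the box constraint C.

    ``class_weight="balanced"`` scales each class's box constraint
    inversely to its size. Decision scores are continuous.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if kernel not in ("linear", "poly", "polynomial"):
        raise ValueError(f"unsupported kernel {kernel!r}")
    sk_kernel = "poly" if kernel in ("poly", "polynomial") else "linear"
    est = SVC(C=C, kernel=sk_kernel, class_weight=class_weight, tol=tol)
    est.fit(X, y)
    if sk_kernel == "linear":
        w = est.coef_.ravel().copy()
        b = float(est.intercept_[0])
    else:
        w, b = None, float(est.intercept_[0])
    return LinearModel(
        model_id=model_id,
        w=w,
        b=b,
        kernel=sk_kernel,
        metadata={"method": "svm", "C": C, "class_weight": class_weight},
        _estimator=est,
    )


def svm_primal_objective(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float,
    C: float = DEFAULT_C, class_weight: Optional[str] = "balanced",
) -> float:
    """Primal objective 0.5||w||^2 + C * sum_i c_i * hinge_i."""
    c = _balanced_weights(y) if class_weight == "balanced" else np.ones(len(y))
    margins = y * (X @ w + b)
    return float(0.5 * w @ w + C * np.sum(c * np.maximum(0.0, 1.0 - margins)))


def _smoothed_hinge(z: np.ndarray, eps: float) -> tuple[np.ndarray, np.ndarray]:
    """Huber-smoothed hinge h(z) ~= max(0, 1-z); returns (value, dh/dz)."""
    val = np.zeros_like(z)
    grad = np.zeros_like(z)
    mid = (z < 1.0) & (z > 1.0 - eps)
    lo = z <= 1.0 - eps
    val[mid] = (1.0 - z[mid]) ** 2 / (2.0 * eps)
    grad[mid] = -(1.0 - z[mid]) / eps
    val[lo] = 1.0 - z[lo] - eps / 2.0
    grad[lo] = -1.0
    return val, grad


def mlvo_objective(p: MLVOProblem, w: np.ndarray, b: float) -> float:
    """The exact (non-smoothed) joint objective value."""
    f = p.X @ w + b
    lam = p.lam if p.lam is not None else _default_lam(p)
    obj = lam * float(w @ w)
    bin_mask = ~np.isnan(p.y_bin)
    if bin_mask.any():
        yb = p.y_bin[bin_mask]
        c = _balanced_weights(yb) if p.class_weight == "balanced" else np.ones(len(yb))
        hinge = np.maximum(0.0, 1.0 - yb * f[bin_mask])
        obj += float(np.sum(c * hinge)) / bin_mask.sum()
    cont_mask = ~np.isnan(p.y_cont)
    if p.mu > 0 and cont_mask.any():
        resid = f[cont_mask] - p.y_cont[cont_mask]
        obj += p.mu * float(resid @ resid) / cont_mask.sum()
    return obj


def _default_lam(p: MLVOProblem) -> float:
    n_bin = int((~np.isnan(p.y_bin)).sum())
    n = n_bin if n_bin else p.X.shape[0]
    return 1.0 / (2.0 * n * p.C)


def _solve_hinge_qp(Xb, yb, c, lam, mu, Xc, yc, theta0, maxiter=3000, gtol=1e-12):
    """Exact QP: min lam||w||^2 + (1/n) c.xi + (mu/m)||Xc w + b - yc||^2
    s.t. xi_i >= 1 - y_i (w.x_i + b), xi >= 0."""
    from scipy.optimize import LinearConstraint

    n, k = Xb.shape
    use_cont = Xc is not None

    def fg(t):
        w, b, xi = t[:k], t[k], t[k + 1:]
        obj = lam * (w @ w) + (c @ xi) / n
        gw = 2.0 * lam * w
        gb = 0.0
        gxi = c / n
        if use_cont:
            r = Xc @ w + b - yc
            m = len(yc)
            obj += mu * (r @ r) / m
            co = (2.0 * mu / m) * r
            gw = gw + Xc.T @ co
            gb = float(co.sum())
        return obj, np.concatenate([gw, [gb], gxi])

    margin_rows = np.hstack([yb[:, None] * Xb, yb[:, None], np.eye(n)])
    slack_rows = np.hstack([np.zeros((n, k + 1)), np.eye(n)])
    constraints = [
        LinearConstraint(margin_rows, 1.0, np.inf),
        LinearConstraint(slack_rows, 0.0, np.inf),
    ]
    w0, b0 = theta0[:k], theta0[k]
    xi0 = np.maximum(0.0, 1.0 - yb * (Xb @ w0 + b0)) + 1e-6
    start = np.concatenate([w0, [b0], xi0])
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="delta_grad == 0.0")
        res = minimize(
            fg, start, jac=True, method="trust-constr", constraints=constraints,
            options={"gtol": gtol, "xtol": 1e-14, "maxiter": maxiter},
        )
    return res.x[: k + 1]


def fit_mlvo(
    p: MLVOProblem, model_id: str = "mlvo", tol: float = 1e-10, polish: str = "exact"
) -> LinearModel:
    """Minimize the joint objective over (w, b).

    Continuous-only problems reduce to ridge regression and are solved in
    closed form; otherwise a smoothed-hinge continuation with L-BFGS is
    warm-started into an exact slack-variable QP solve (the objective is
    convex, so restarts agree in objective). ``polish="fast"`` trades the
    final QP accuracy for speed in bulk cross-validation runs.
    """
    lam = p.lam if p.lam is not None else _default_lam(p)
    X = p.X
    n, k = X.shape
    bin_mask = ~np.isnan(p.y_bin)
    cont_mask = ~np.isnan(p.y_cont)
    n_bin, n_cont = int(bin_mask.sum()), int(cont_mask.sum())
    use_cont = p.mu > 0 and n_cont > 0

    if n_bin == 0 and not use_cont:
        raise ValueError("no effective labels (no binary labels and mu * n_cont = 0)")

    if n_bin == 0:
        # ridge: lam*||w||^2 + (mu/n_cont) * ||Xc w + b - y||^2
        Xc = X[cont_mask]
        yc = p.y_cont[cont_mask]
        A = np.hstack([Xc, np.ones((n_cont, 1))])
        reg = np.eye(k + 1) * (lam * n_cont / p.mu)
        reg[-1, -1] = 0.0  # intercept unpenalized
        theta = np.linalg.solve(A.T @ A + reg, A.T @ yc)
        w, b = theta[:k], float(theta[k])
    else:
        yb = p.y_bin[bin_mask]
        if len(np.unique(yb)) < 2 and not use_cont:
            raise ValueError("binary labels contain a single class")
        c = _balanced_weights(yb) if p.class_weight == "balanced" else np.ones(n_bin)
        Xb = X[bin_mask]
        Xc = X[cont_mask] if use_cont else None
        yc = p.y_cont[cont_mask] if use_cont else None

        def make_fun(eps: float):
            def fun(theta: np.ndarray):
                w, b = theta[:k], theta[k]
                obj = lam * (w @ w)
                grad_w = 2.0 * lam * w
                grad_b = 0.0
                z = yb * (Xb @ w + b)
                hval, hgrad = _smoothed_hinge(z, eps)
                obj += float(c @ hval) / n_bin
                coeff = (c * hgrad * yb) / n_bin
                grad_w += Xb.T @ coeff
                grad_b += float(coeff.sum())
                if use_cont:
                    resid = Xc @ w + b - yc
                    obj += p.mu * float(resid @ resid) / n_cont
                    coeff2 = (2.0 * p.mu / n_cont) * resid
                    grad_w += Xc.T @ coeff2
                    grad_b += float(coeff2.sum())
                return obj, np.concatenate([grad_w, [grad_b]])

            return fun

        theta = np.zeros(k + 1)
        for eps in (1e-1, 1e-3, 1e-5, 1e-7):
            res = minimize(
                make_fun(eps),
                theta,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 20000, "ftol": 1e-14, "gtol": 1e-12},
            )
            theta = res.x
        # polish on the exact slack-variable QP (hinge is non-smooth, so the
        # smoothed warm start is refined by a constrained convex solve)
        if polish == "exact":
            theta = _solve_hinge_qp(Xb, yb, c, lam, p.mu, Xc, yc, theta)
        elif polish == "fast":
            theta = _solve_hinge_qp(
                Xb, yb, c, lam, p.mu, Xc, yc, theta, maxiter=150, gtol=1e-8
            )
        elif polish != "none":
            raise ValueError(f"unknown polish mode {polish!r}")
        w, b = theta[:k], float(theta[k])

    return LinearModel(
        model_id=model_id,
        w=w,
        b=b,
        kernel="linear",
        metadata={
            "method": "mlvo",
            "lam": lam,
            "mu": p.mu,
            "C": p.C,
            "class_weight": p.class_weight,
            "n_binary": n_bin,
            "n_continuous": n_cont,
        },
    )


def score(model: LinearModel, X: np.ndarray) -> np.ndarray:
    """Continuous decision scores w.x + b per row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.kernel != "linear":
        return model._estimator.decision_function(X)
    if X.shape[1] != model.w.shape[0]:
        raise ValueError(
            f"dimension mismatch: {X.shape[1]} columns vs weight size {model.w.shape[0]}"
        )
    return X @ model.w + model.b


def score_features(model: LinearModel, X_features: np.ndarray) -> np.ndarray:
    """Score raw one-hot rows through the back-projected betas."""
    if model.betas is None:
        raise ValueError("model has no back-projected betas")
    X_features = np.atleast_2d(np.asarray(X_features, dtype=float))
    return X_features @ model.betas + model.intercept


def back_project(model: LinearModel, projection=None) -> LinearModel:
    """Attach per-feature betas such that scoring raw one-hot rows through
    them equals projecting then applying (w, b).

    With ``projection=None`` the model is assumed to act on the raw
    features (identity projection), so betas = w. Polynomial kernels have
    no exact linear back-projection and are refused.
    """
    if model.kernel != "linear":
        raise ValueError("no exact linear back-projection for a polynomial kernel")
    if projection is None:
        model.betas = model.w.copy()
        model.intercept = float(model.b)
        return model
    if projection.method == "mca":
        raise ValueError(
            "MCA projection is not affine in the raw features; "
            "betas are only exported for PCA or identity projections"
        )
    model.betas = projection.components.T @ model.w
    model.intercept = float(model.b - model.w @ (projection.components @ projection.center))
    model.feature_labels = list(projection.feature_labels)
    return model


def position_contributions(
    betas: np.ndarray, feature_labels: list[tuple[int, str]]
) -> dict[int, float]:
    """Per-position sum of |beta| over residues, min-max scaled to [0, 1]."""
    sums: dict[int, float] = {}
    for beta, (pos, _res) in zip(betas, feature_labels):
        sums[pos] = sums.get(pos, 0.0) + abs(float(beta))
    values = np.array(list(sums.values()))
    lo, hi = values.min(), values.max()
    if hi == lo:
        return {pos: 0.0 for pos in sums}
    return {pos: (v - lo) / (hi - lo) for pos, v in sums.items()}
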