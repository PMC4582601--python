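"""Binary logistic regression fitted by maximum likelihood over all genes.

The posterior probability that gene i carries label 1 is the logistic
sigmoid of a linear score w'phi_i of its feature vector.  The weights w
maximize the log-likelihood

    ln L(w) = sum_i [ x_i * w'phi_i - ln(1 + exp(w'phi_i)) ]

over the *whole* universe — known genes with their fixed labels and unknown
genes with their sampled prior labels — starting from w = 0.  The negated
log-likelihood is convex, so the optimum is unique whenever the data are not
separable.  Optimization uses damped Newton steps with the analytic d x d
Hessian (d is at most 2l+1, so each step is essentially free) and a
backtracking line search; on (quasi-)separable data the weights diverge, and
the iterate is rescaled onto the infinity-norm cap and reported with a
:class:`~netlogit.exceptions.SeparationWarning`.

An optional ridge penalty exists as a clearly-labeled extension and is off
by default: the exact likelihood above is the method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.special import expit

from .containers import GeneUniverse
from .exceptions import NumericalError, SeparationWarning
from .features import FeatureMatrix

logger = logging.getLogger("netlogit")

__all__ = [
    "ModelWeights",
    "log_likelihood",
    "gradient",
    "fit_weights",
    "posterior",
    "score_unknown_genes",
]


@dataclass(frozen=True)
class ModelWeights:
    """Fitted coefficient vector plus convergence diagnostics."""

    w: np.ndarray
    log_likelihood: float
    grad_norm: float
    converged: bool
    n_iter: int
    separable: bool = False

    @property
    def d(self) -> int:
        return self.w.size


def _linear_scores(w: np.ndarray, features) -> np.ndarray:
    phi = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    w = np.asarray(w, dtype=float)
    if phi.ndim != 2 or phi.shape[1] != w.size:
        raise ValueError(
            f"dimension mismatch: features are {phi.shape}, w has length {w.size}"
        )
    return phi @ w


def log_likelihood(w: np.ndarray, features, labels: np.ndarray) -> float:
    """Exact log-likelihood, overflow-safe via ``logaddexp``."""
    t = _linear_scores(w, features)
    x = np.asarray(labels, dtype=float)
    if x.shape != t.shape:
        raise ValueError("label vector length does not match feature rows")
    return float(x @ t - np.logaddexp(0.0, t).sum())


def gradient(w: np.ndarray, features, labels: np.ndarray) -> np.ndarray:
    """Analytic gradient of the log-likelihood: Phi'(x - sigmoid(Phi w))."""
    phi = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    t = _linear_scores(w, features)
    x = np.asarray(labels, dtype=float)
    return phi.T @ (x - expit(t))


def fit_weights(
    features,
    labels: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    weight_cap: float = 50.0,
    ridge: float = 0.0,
) -> ModelWeights:
    """Maximize the log-likelihood from w = 0 by damped Newton iteration.

    Parameters
    ----------
    features
        :class:`FeatureMatrix` or plain N x d array with intercept column.
    labels
        Binary configuration of length N (the regression's dependent
        variable).
    tol
        Convergence threshold on the Euclidean gradient norm.
    max_iter
        Iteration cap; reaching it clears the ``converged`` flag.
    weight_cap
        Infinity-norm bound; when the iterate exceeds it the data are
        treated as separable, the iterate is rescaled onto the cap and a
        :class:`SeparationWarning` is emitted.
    ridge
        Optional L2 penalty coefficient (extension; 0 = exact method).
    """
    phi = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    x = np.asarray(labels, dtype=float)
    if x.shape != (phi.shape[0],):
        raise ValueError("label vector length does not match feature rows")
    n1 = int(x.sum())
    if n1 == 0 or n1 == x.size:
        warnings.warn(
            "all training labels identical; likelihood is maximized on the "
            "boundary (separation)",
            SeparationWarning,
            stacklevel=2,
        )

    d = phi.shape[1]
    w = np.zeros(d)

    def objective(wv: np.ndarray) -> float:
        t = phi @ wv
        val = float(x @ t - np.logaddexp(0.0, t).sum())
        if ridge:
            val -= 0.5 * ridge * float(wv @ wv)
        return val

    ll = objective(w)
    separable = False
    converged = False
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        t = phi @ w
        p = expit(t)
        g = phi.T @ (x - p)
        if ridge:
            g -= ridge * w
        grad_norm = float(np.linalg.norm(g))
        if grad_norm < tol:
            converged = True
            # a vanishing gradient with likelihood at its supremum (0) means
            # every gene is fitted with probability ~1: perfect separation,
            # the maximizer lies at infinity
            if ll > -1e-6 and not separable:
                separable = True
                warnings.warn(
                    "likelihood reached its supremum (perfect separation); "
                    "weights are a finite surrogate for a boundary maximizer",
                    SeparationWarning,
                    stacklevel=2,
                )
            break
        s = p * (1.0 - p)
        hess = (phi * s[:, None]).T @ phi
        if ridge:
            hess = hess + ridge * np.eye(d)
        with warnings.catch_warnings():
            # ill-conditioning near separation is expected and handled below
            warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
            try:
                step = scipy.linalg.solve(hess, g, assume_a="pos")
            except (scipy.linalg.LinAlgError, ValueError):
                # near-separable: Hessian is singular; damp it
                damped = hess + 1e-8 * max(1.0, float(np.trace(hess))) * np.eye(d)
                try:
                    step = scipy.linalg.solve(damped, g, assume_a="pos")
                except (scipy.linalg.LinAlgError, ValueError) as exc:
                    raise NumericalError(
                        "Newton step failed on a singular Hessian"
                    ) from exc
        # backtracking line search on the ascent direction
        alpha = 1.0
        for _ in range(60):
            candidate = w + alpha * step
            if objective(candidate) >= ll - 1e-12:
                break
            alpha *= 0.5
        w = w + alpha * step
        ll = objective(w)
        w_inf = float(np.max(np.abs(w)))
        if w_inf > weight_cap:
            w = w * (weight_cap / w_inf)
            ll = objective(w)
            separable = True
            warnings.warn(
                "weights exceeded the cap (separable likelihood); returning "
                "the capped solution",
                SeparationWarning,
                stacklevel=2,
            )
            g = phi.T @ (x - expit(phi @ w))
            if ridge:
                g -= ridge * w
            grad_norm = float(np.linalg.norm(g))
            break
    if not converged and not separable and it >= max_iter:
        logger.warning(
            "fit_weights: gradient norm %.3g after %d iterations (tol %.1g)",
            grad_norm, max_iter, tol,
        )
    return ModelWeights(
        w=w,
        log_likelihood=float(ll),
        grad_norm=grad_norm,
        converged=converged,
        n_iter=it,
        separable=separable,
    )


def posterior(w: np.ndarray, phi: np.ndarray) -> np.ndarray | float:
    """Posterior probability of label 1: the stable sigmoid of w'phi.

    Accepts a single feature row or a 2-D stack of rows; the label-0
    probability is exactly ``1 - posterior`` by construction of ``expit``.
    """
    phi_arr = np.asarray(phi, dtype=float)
    t = phi_arr @ np.asarray(w, dtype=float)
    out = expit(t)
    return float(out) if np.isscalar(t) or t.ndim == 0 else out


def score_unknown_genes(
    weights: ModelWeights, features, universe: GeneUniverse
) -> np.ndarray:
    """Posterior for every unknown gene (first n rows in canonical order)."""
    phi = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if phi.shape[0] != universe.N:
        raise ValueError("feature rows do not match universe size")
    return np.asarray(posterior(weights.w, phi[: universe.n]))
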