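"""Gaussian-process surrogate with spatio-temporal covariance functions.

The surrogate regresses the stimulation objective over a periodic 1-D
parameter space (stimulation phase) while optionally discounting or
periodically re-weighting past samples through a temporal covariance factor:

* spatial kernel  K_s(x, x') = exp(-2 sin^2(pi |x-x'| / T_x) / l_x^2)
* temporal kernels over optimization-step indices t, t':
    - ``static``               K_t = 1 (time-invariant surrogate)
    - ``forgetting``           K_t = (1 - eps)^(|t-t'| / 2)
    - ``periodic``             K_t = exp(-2 sin^2(pi |t-t'| / T_t) / l_tp^2)
    - ``forgetting_periodic``  product of the previous two
* combined kernel  K~ = K_s * K_t (Hadamard product), which is PSD as a
  product of PSD kernels.

Posterior inference is exact (zero prior mean, Gaussian noise sigma_n^2),
solved through a Cholesky factorization with adaptive jitter.

Two half-life utilities interpret the forgetting factor: ``eps = ln2 /
t_half`` and the relative weight ``2**(-lag / t_half)``.  Note these printed
conventions imply a decay of exp(-eps*lag), whereas the forgetting kernel
itself decays as exp(-eps*lag/2) for small eps; both are provided verbatim
and never silently reconciled (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "SampleRecord",
    "GPHyperparams",
    "PosteriorEstimate",
    "spatial_kernel",
    "temporal_kernel",
    "spatiotemporal_kernel",
    "gp_posterior",
    "half_life_to_epsilon",
    "half_life_weight",
    "TimeVaryingGPRegressor",
]

KERNEL_KINDS = ("static", "forgetting", "periodic", "forgetting_periodic")

VAR_TOL = 1e-10  # posterior variances above -VAR_TOL are clamped to zero


@dataclass(frozen=True)
class SampleRecord:
    """One optimization sample: tested phase x at step t with outcome y."""

    x: float
    t: int
    y: float = 0.0


@dataclass(frozen=True)
class GPHyperparams:
    l_x: float = 1.0
    T_x: float = 2.0 * np.pi
    epsilon: float = 0.0
    T_t: float = 100.0
    l_tp: float = 1.0
    sigma_n2: float = 1e-2
    kernel_kind: str = "static"
    window: int | None = 500
    normalize_y: bool = True

    def __post_init__(self):
        if self.l_x <= 0 or self.T_x <= 0 or self.T_t <= 0 or self.l_tp <= 0:
            raise ValueError("lengthscales and periods must be > 0")
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must be in [0, 1)")
        if self.sigma_n2 < 0:
            raise ValueError("sigma_n2 must be >= 0")
        if self.kernel_kind not in KERNEL_KINDS:
            raise ValueError(f"kernel_kind must be one of {KERNEL_KINDS}")


@dataclass(frozen=True)
class PosteriorEstimate:
    mu: np.ndarray
    var: np.ndarray

    @property
    def std(self) -> np.ndarray:
        return np.sqrt(self.var)


def _as_xt(rec):
    if isinstance(rec, SampleRecord):
        return rec.x, rec.t
    return rec  # (x, t) pair


def spatial_kernel(x, x2, hp: GPHyperparams):
    """Exponential-sine-squared covariance over the periodic phase space."""
    d = np.abs(np.asarray(x, dtype=float) - np.asarray(x2, dtype=float))
    out = np.exp(-2.0 * np.sin(np.pi * d / hp.T_x) ** 2 / hp.l_x**2)
    return out if out.ndim else float(out)


def temporal_kernel(t, t2, hp: GPHyperparams):
    """Temporal covariance between optimization-step indices, per ``kernel_kind``."""
    lag = np.abs(np.asarray(t, dtype=float) - np.asarray(t2, dtype=float))
    if hp.kernel_kind == "static":
        out = np.ones_like(lag)
    elif hp.kernel_kind == "forgetting":
        out = (1.0 - hp.epsilon) ** (lag / 2.0)
    elif hp.kernel_kind == "periodic":
        out = np.exp(-2.0 * np.sin(np.pi * lag / hp.T_t) ** 2 / hp.l_tp**2)
    elif hp.kernel_kind == "forgetting_periodic":
        out = (1.0 - hp.epsilon) ** (lag / 2.0) * np.exp(
            -2.0 * np.sin(np.pi * lag / hp.T_t) ** 2 / hp.l_tp**2
        )
    else:  # pragma: no cover - guarded by GPHyperparams
        raise ValueError(hp.kernel_kind)
    return out if out.ndim else float(out)


def spatiotemporal_kernel(a, b, hp: GPHyperparams):
    """Hadamard product K_s(a.x, b.x) * K_t(a.t, b.t)."""
    ax, at = _as_xt(a)
    bx, bt = _as_xt(b)
    return spatial_kernel(ax, bx, hp) * temporal_kernel(at, bt, hp)


def half_life_to_epsilon(t_half: float) -> float:
    """Forgetting factor from a data half-life in samples: eps = ln2 / t_half."""
    if t_half <= 0:
        raise ValueError("t_half must be > 0")
    return math.log(2.0) / t_half


def half_life_weight(lag: float, t_half: float) -> float:
    """Relative sample weight after ``lag`` samples: 2**(-lag / t_half)."""
    if t_half <= 0:
        raise ValueError("t_half must be > 0")
    if lag < 0:
        raise ValueError("lag must be >= 0")
    return 2.0 ** (-lag / t_half)


def _kernel_matrix(xa, ta, xb, tb, hp: GPHyperparams):
    ks = spatial_kernel(xa[:, None], xb[None, :], hp)
    kt = temporal_kernel(ta[:, None], tb[None, :], hp)
    return ks * kt


def _solve_with_jitter(K_noisy, start=1e-10, stop=1e-6):
    """Cholesky-factor K_noisy, adding doubling jitter if needed."""
    try:
        return cho_factor(K_noisy, lower=True)
    except np.linalg.LinAlgError:
        pass
    jitter = start
    eye = np.eye(K_noisy.shape[0])
    while jitter <= stop:
        try:
            return cho_factor(K_noisy + jitter * eye, lower=True)
        except np.linalg.LinAlgError:
            jitter *= 2.0
    raise np.linalg.LinAlgError(
        f"Gram matrix not factorizable even with jitter up to {stop:g}"
    )


def _posterior(xs, ts, ys, qx, qt, hp: GPHyperparams) -> PosteriorEstimate:
    qx = np.asarray(qx, dtype=float)
    qt = np.asarray(qt, dtype=float)
    prior_var = np.ones_like(qx)  # every kernel has unit variance on the diagonal
    if len(xs) == 0:
        return PosteriorEstimate(np.zeros_like(qx), prior_var)
    K = _kernel_matrix(xs, ts, xs, ts, hp)
    c_and_lower = _solve_with_jitter(K + hp.sigma_n2 * np.eye(len(xs)))
    k_star = _kernel_matrix(qx, qt, xs, ts, hp)  # (n_query, n_train)
    alpha = cho_solve(c_and_lower, ys)
    mu = k_star @ alpha
    v = cho_solve(c_and_lower, k_star.T)
    var = prior_var - np.einsum("ij,ji->i", k_star, v)
    if np.any(var < -VAR_TOL):
        raise FloatingPointError("posterior variance below numerical tolerance")
    return PosteriorEstimate(mu, np.maximum(var, 0.0))


def gp_posterior(history, queries, hp: GPHyperparams) -> PosteriorEstimate:
    """Exact posterior mean/variance at ``queries`` given sampled ``history``.

    ``history`` is a sequence of :class:`SampleRecord` (or ``(x, t, y)``
    triples); ``queries`` a sequence of ``(x, t)`` pairs.  With
    ``kernel_kind="static"`` this is ordinary time-invariant GP regression;
    otherwise the spatio-temporal kernel ages samples by their step index.
    A finite ``hp.window`` keeps only the most recent samples.
    """
    if len(queries) == 0:
        raise ValueError("queries must be non-empty")
    hist = [(r.x, r.t, r.y) if isinstance(r, SampleRecord) else tuple(r) for r in history]
    if hp.window is not None and len(hist) > hp.window:
        hist = sorted(hist, key=lambda r: r[1])[-hp.window:]
    xs = np.array([h[0] for h in hist], dtype=float)
    ts = np.array([h[1] for h in hist], dtype=float)
    ys = np.array([h[2] for h in hist], dtype=float)
    q = np.asarray(queries, dtype=float)
    return _posterior(xs, ts, ys, q[:, 0], q[:, 1], hp)


class TimeVaryingGPRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style GP regressor over (phase, step-index) inputs.

    Parameters mirror :class:`GPHyperparams`.  ``X`` is ``(n_samples, 2)``
    with columns ``[phase, step]``; a single column is accepted and treated
    as all-same-time (pure spatial regression).

    Examples
    --------
    >>> import numpy as np
    >>> X = np.array([[0.0, 0], [1.5, 1]])
    >>> gpr = TimeVaryingGPRegressor(kernel_kind="forgetting", epsilon=0.1)
    >>> gpr.fit(X, np.array([0.2, -0.4]))
    TimeVaryingGPRegressor(epsilon=0.1, kernel_kind='forgetting')
    >>> mu, std = gpr.predict(X, return_std=True)
    """

    def __init__(
        self,
        kernel_kind: str = "static",
        l_x: float = 1.0,
        T_x: float = 2.0 * np.pi,
        epsilon: float = 0.0,
        T_t: float = 100.0,
        l_tp: float = 1.0,
        sigma_n2: float = 1e-2,
        window: int | None = 500,
        normalize_y: bool = False,
    ):
        self.kernel_kind = kernel_kind
        self.l_x = l_x
        self.T_x = T_x
        self.epsilon = epsilon
        self.T_t = T_t
        self.l_tp = l_tp
        self.sigma_n2 = sigma_n2
        self.window = window
        self.normalize_y = normalize_y

    def _hp(self) -> GPHyperparams:
        return GPHyperparams(
            l_x=self.l_x, T_x=self.T_x, epsilon=self.epsilon, T_t=self.T_t,
            l_tp=self.l_tp, sigma_n2=self.sigma_n2, kernel_kind=self.kernel_kind,
            window=self.window,
        )

    @staticmethod
    def _split(X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] not in (1, 2):
            raise ValueError("X must be (n_samples, 2) [phase, step] or (n_samples, 1)")
        t = X[:, 1] if X.shape[1] == 2 else np.zeros(len(X))
        return X[:, 0], t

    def fit(self, X, y):
        hp = self._hp()  # validates parameters
        x, t = self._split(X)
        y = np.asarray(y, dtype=float)
        if y.shape != x.shape:
            raise ValueError("y must be one value per sample")
        if hp.window is not None and len(x) > hp.window:
            keep = np.argsort(t, kind="stable")[-hp.window:]
            x, t, y = x[keep], t[keep], y[keep]
        self.X_train_ = np.column_stack([x, t])
        self.y_train_ = y
        self.n_features_in_ = 2
        if self.normalize_y and len(y):
            self.y_train_mean_ = float(y.mean())
            std = float(y.std())
            self.y_train_std_ = std if std > 0 else 1.0
        else:
            self.y_train_mean_, self.y_train_std_ = 0.0, 1.0
        y_fit = (y - self.y_train_mean_) / self.y_train_std_
        if len(x):
            K = _kernel_matrix(x, t, x, t, hp)
            self._factor_ = _solve_with_jitter(K + hp.sigma_n2 * np.eye(len(x)))
            self.alpha_ = cho_solve(self._factor_, y_fit)
        else:
            self._factor_ = None
            self.alpha_ = np.zeros(0)
        return self

    def predict(self, X, return_std: bool = False):
        if not hasattr(self, "X_train_"):
            raise AttributeError("TimeVaryingGPRegressor is not fitted yet")
        hp = self._hp()
        qx, qt = self._split(X)
        if self._factor_ is None:
            mu, var = np.zeros_like(qx), np.ones_like(qx)
        else:
            xs, ts = self.X_train_[:, 0], self.X_train_[:, 1]
            k_star = _kernel_matrix(qx, qt, xs, ts, hp)
            mu = k_star @ self.alpha_
            v = cho_solve(self._factor_, k_star.T)
            var = 1.0 - np.einsum("ij,ji->i", k_star, v)
            if np.any(var < -VAR_TOL):
                raise FloatingPointError("posterior variance below numerical tolerance")
            var = np.maximum(var, 0.0)
        mu = self.y_train_mean_ + self.y_train_std_ * mu
        std = self.y_train_std_ * np.sqrt(var)
        return (mu, std) if return_std else mu
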