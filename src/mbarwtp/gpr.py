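"""Gaussian-process smoothing of noisy free-energy surfaces.

A zero-mean GP with a squared-exponential covariance

    k(x, x') = sigma_f^2 exp(-|x - x'|^2 / (2 l^2)) + alpha sigma_n^2(x) delta(x, x')

is fitted to the per-bin surface values; the Kronecker-delta noise term is
heteroscedastic, with the per-observation level ``sigma_n^2`` taken from the
reweighting entropy as ``e^(-S)`` and a single learnable scale ``alpha``.
Hyperparameters ``{l, sigma_f, alpha}`` maximize the log marginal likelihood
(multi-start L-BFGS on log-parameters). Observations are centered before
fitting (the GP prior mean is zero) and the mean is restored on prediction.

Both the posterior mean and variance are exposed; a single isotropic length
scale is shared by the two RC dimensions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.optimize import minimize

from .data_model import Grid2D, Surface2D

logger = logging.getLogger(__name__)

BOUNDS_L = (0.01, 10.0)        # length scale, Å
BOUNDS_SF = (1e-3, 1e3)        # signal std, kcal/mol
BOUNDS_ALPHA = (1e-6, 1e3)     # noise scale, unitless


def _sqdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def _chol_with_jitter(k: np.ndarray):
    """Cholesky factor of k, adding diagonal jitter 1e-10..1e-6 only on failure."""
    jitter = 0.0
    while True:
        try:
            kj = k if jitter == 0.0 else k + jitter * np.eye(len(k))
            return cholesky(kj, lower=True), jitter
        except np.linalg.LinAlgError:
            if jitter >= 1e-6:
                raise
            jitter = 1e-10 if jitter == 0.0 else jitter * 10.0


@dataclass
class GPRModel:
    """Fitted GP: hyperparameters, training set, and the cached kernel solve."""

    length_scale: float
    signal_variance: float
    noise_scale: float
    per_obs_noise: np.ndarray
    x_train: np.ndarray
    y_train: np.ndarray
    y_mean: float = 0.0
    _chol: np.ndarray | None = field(default=None, repr=False)
    _coef: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if min(self.length_scale, self.signal_variance, self.noise_scale) <= 0:
            raise ValueError("hyperparameters must be strictly positive")
        self.per_obs_noise = np.asarray(self.per_obs_noise, dtype=float)
        if np.any(self.per_obs_noise < 0):
            raise ValueError("per-observation noise must be >= 0")
        self.x_train = np.asarray(self.x_train, dtype=float).reshape(-1, 2)
        self.y_train = np.asarray(self.y_train, dtype=float)
        if self._chol is None:
            k = kernel_matrix(self)
            low, jitter = _chol_with_jitter(k)
            if jitter > 1e-10:
                logger.debug("GPR: Cholesky needed jitter %.1e", jitter)
            self._chol = low
            self._coef = cho_solve((low, True), self.y_train - self.y_mean)

    @property
    def n_train(self) -> int:
        return len(self.y_train)

    def log_marginal_likelihood(self) -> float:
        r = self.y_train - self.y_mean
        return float(
            -0.5 * r @ self._coef
            - np.log(np.diag(self._chol)).sum()
            - 0.5 * self.n_train * np.log(2 * np.pi)
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "length_scale": self.length_scale,
                "signal_variance": self.signal_variance,
                "noise_scale": self.noise_scale,
                "per_obs_noise": self.per_obs_noise.tolist(),
                "x_train": self.x_train.tolist(),
                "y_train": self.y_train.tolist(),
                "y_mean": self.y_mean,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GPRModel":
        d = json.loads(text)
        return cls(
            d["length_scale"],
            d["signal_variance"],
            d["noise_scale"],
            np.array(d["per_obs_noise"]),
            np.array(d["x_train"]),
            np.array(d["y_train"]),
            y_mean=d["y_mean"],
        )

    def __call__(self, query: np.ndarray) -> np.ndarray:
        """Posterior-mean surface value(s) at 2D query point(s)."""
        mean, _ = predict(self, query)
        return mean


def kernel(x1, x2, model: GPRModel, same_index: bool = False) -> float:
    """Covariance between two RC points under ``model``.

    The noise term contributes only when both arguments refer to the *same
    training observation* (``same_index=True``); distinct points, however
    close, share only the squared-exponential part.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    d2 = float(((x1 - x2) ** 2).sum())
    val = model.signal_variance * np.exp(-d2 / (2.0 * model.length_scale**2))
    if same_index:
        idx = np.flatnonzero(np.all(np.isclose(model.x_train, x1), axis=1))
        noise = model.per_obs_noise[idx[0]] if len(idx) else 0.0
        val += model.noise_scale * noise
    return float(val)


def kernel_matrix(model: GPRModel) -> np.ndarray:
    """Training covariance matrix K: SE part plus per-point noise on the diagonal."""
    d2 = _sqdist(model.x_train, model.x_train)
    k = model.signal_variance * np.exp(-d2 / (2.0 * model.length_scale**2))
    k[np.diag_indices_from(k)] += model.noise_scale * model.per_obs_noise
    return k


def predict(model: GPRModel, query) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance at query point(s).

    Mean ``k*^T K^{-1} f`` (plus the restored centering constant); variance
    ``k(x*, x*) - k*^T K^{-1} k*``, clipped at zero (values below -1e-8
    trigger a warning before clipping).
    """
    q = np.atleast_2d(np.asarray(query, dtype=float))
    d2 = _sqdist(q, model.x_train)
    kstar = model.signal_variance * np.exp(-d2 / (2.0 * model.length_scale**2))
    mean = kstar @ model._coef + model.y_mean
    v = cho_solve((model._chol, True), kstar.T)
    var = model.signal_variance - np.einsum("ij,ji->i", kstar, v)
    if np.any(var < -1e-8):
        logger.warning("GPR predictive variance dipped to %.3e; clipping at 0", var.min())
    var = np.clip(var, 0.0, None)
    if np.ndim(query) == 1:
        return float(mean[0]), float(var[0])
    return mean, var


def _neg_lml_and_grad(theta, x, r, sn2):
    """Negative log marginal likelihood and gradient wrt log-parameters."""
    l, sf, alpha = np.exp(theta)
    d2 = _sqdist(x, x)
    rbf = sf**2 * np.exp(-d2 / (2.0 * l**2))
    k = rbf + np.diag(alpha * sn2)
    try:
        low, _ = _chol_with_jitter(k)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros(3)
    coef = cho_solve((low, True), r)
    n = len(r)
    lml = -0.5 * r @ coef - np.log(np.diag(low)).sum() - 0.5 * n * np.log(2 * np.pi)
    kinv = cho_solve((low, True), np.eye(n))
    outer = np.outer(coef, coef) - kinv
    grads = np.empty(3)
    grads[0] = 0.5 * np.einsum("ij,ji->", outer, rbf * (d2 / l**2))
    grads[1] = 0.5 * np.einsum("ij,ji->", outer, 2.0 * rbf)
    grads[2] = 0.5 * float(np.diag(outer) @ (alpha * sn2))
    return -lml, -grads


def fit(
    x,
    y,
    per_obs_noise=None,
    n_starts: int = 8,
    seed: int = 0,
    center: bool = True,
) -> GPRModel:
    """Fit GP hyperparameters by multi-start maximum marginal likelihood.

    Parameters
    ----------
    x, y
        Training inputs (n, 2) and values (n,); n >= 2 distinct inputs.
    per_obs_noise
        Per-observation noise levels ``sigma_n^2`` (e.g. ``e^(-S)`` from the
        reweighting entropy); zeros give a noise-free interpolant. Default 0.
    n_starts
        Number of L-BFGS starts: one heuristic start (median pairwise
        distance / value spread) plus seeded log-uniform restarts.
    seed
        Seed for the restart sampler; the fit is deterministic given it.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 2)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.unique(x, axis=0).shape[0] < 2:
        raise ValueError("degenerate inputs: all training points identical")
    sn2 = np.zeros(n) if per_obs_noise is None else np.asarray(per_obs_noise, dtype=float)
    y_mean = float(y.mean()) if center else 0.0
    r = y - y_mean

    d2 = _sqdist(x, x)
    med = np.sqrt(np.median(d2[d2 > 0]))
    l0 = float(np.clip(med, *BOUNDS_L))
    sf0 = float(np.clip(max(r.std(), 1e-3), *BOUNDS_SF))
    rng = np.random.default_rng(seed)
    starts = [np.log([l0, sf0, 1.0])]
    log_bounds = np.log(np.array([BOUNDS_L, BOUNDS_SF, BOUNDS_ALPHA]))
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(log_bounds[:, 0], log_bounds[:, 1]))

    best = None
    for t0 in starts:
        res = minimize(
            _neg_lml_and_grad,
            t0,
            args=(x, r, sn2),
            jac=True,
            method="L-BFGS-B",
            bounds=log_bounds.tolist(),
        )
        if best is None or res.fun < best.fun:
            best = res
    l, sf, alpha = np.exp(best.x)
    model = GPRModel(
        length_scale=float(l),
        signal_variance=float(sf**2),
        noise_scale=float(alpha),
        per_obs_noise=sn2,
        x_train=x,
        y_train=y,
        y_mean=y_mean,
    )
    logger.info(
        "GPR fit: l=%.4g Å, sigma_f=%.4g kcal/mol, alpha=%.4g, LML=%.4g",
        l, sf, alpha, model.log_marginal_likelihood(),
    )
    return model


def smooth_surface(
    surface: Surface2D,
    entropy: np.ndarray | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[GPRModel, Surface2D]:
    """Smooth a per-bin surface; returns the fitted model and the smoothed grid.

    Occupied bins become training points; the per-observation noise is
    ``e^(-S)`` from the supplied (or surface-attached) reweighting entropy,
    zero if no entropy is available. The smoothed surface carries the GP
    predictive variance.
    """
    occ = surface.occupied
    if entropy is None:
        entropy = surface.entropy
    centers = surface.grid.centers().reshape(*surface.grid.shape, 2)
    x = centers[occ]
    y = surface.value[occ]
    sn2 = None
    if entropy is not None:
        s = np.asarray(entropy, dtype=float)[occ]
        sn2 = np.where(np.isfinite(s), np.exp(-s), 1.0)
    model = fit(x, y, per_obs_noise=sn2, n_starts=n_starts, seed=seed)
    mean, var = predict(model, surface.grid.centers())
    smoothed = Surface2D(
        surface.grid,
        mean.reshape(surface.grid.shape),
        variance=var.reshape(surface.grid.shape),
        count=surface.count,
        entropy=surface.entropy,
        occupied=np.ones(surface.grid.shape, dtype=bool),
    )
    return model, smoothed
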