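"""Gaussian-process surrogate over the normalized reaction space.

The surrogate is a single-output GP regression on the unit-hypercube
encoding produced by :meth:`ReactionSpace.normalize`:

* kernel: signal variance × anisotropic Matérn-5/2 (one lengthscale per
  normalized coordinate) + white noise;
* one-hot categorical columns are scaled by 1/sqrt(2) before entering the
  kernel, so two candidates differing only in a categorical level sit at
  Euclidean distance 1 — a categorical switch counts like a full-range move
  along a continuous axis;
* observed yields (percent) are standardized to zero mean / unit variance
  before fitting; predictions are mapped back to yield units;
* hyperparameters maximize the log marginal likelihood with seeded
  multi-restart L-BFGS; fitting is deterministic for a given seed.

Implementation detail: the heavy lifting is delegated to
``sklearn.gaussian_process.GaussianProcessRegressor``; this module owns the
kernel configuration, output scaling, categorical distance convention and
serialization, which together define the surrogate's contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    ConstantKernel,
    Matern,
    WhiteKernel,
)

LATENT_STD = True  # acquisition sees latent-function std (noise excluded)
JITTER = 1e-10  # added to the covariance diagonal for factorization stability
CAT_SCALE = 1.0 / np.sqrt(2.0)  # one-hot scaling: inter-category distance 1
LS_BOUNDS = (1e-2, 2e1)
CAT_LS_BOUNDS = (0.5, 3.0)  # one-hot columns may not be switched off
NOISE_BOUNDS = (1e-6, 1.0)
SIGNAL_BOUNDS = (1e-3, 1e3)
SIGNAL_BOUNDS_DEGENERATE = (1e-8, 1.0)  # constant outputs: no signal to explain


class GPError(ValueError):
    pass


@dataclass
class GPModel:
    """Fitted GP surrogate; see :func:`fit`."""

    gpr: GaussianProcessRegressor
    X: np.ndarray  # normalized training inputs (unscaled)
    y: np.ndarray  # raw training yields (percent)
    y_mean: float
    y_std: float
    cat_mask: np.ndarray | None = None
    seed: int = 0
    noise: float | str = "fit"

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    @property
    def theta(self) -> np.ndarray:
        """Fitted log-hyperparameters (signal, lengthscales, [noise])."""
        return self.gpr.kernel_.theta.copy()

    def _scale_inputs(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.cat_mask is not None and self.cat_mask.any():
            X = X.copy()
            X[:, self.cat_mask] *= CAT_SCALE
        return X

    def predict(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and std of the latent yield surface, in
        yield-percent units (measurement noise is not added back; it is the
        instrument's, not the surface's).

        Accepts a single vector or a 2-D batch; returns arrays of matching
        leading shape.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.dim:
            raise GPError(f"expected dim {self.dim}, got {X.shape[1]}")
        m, s = self.standardized_predict(X)
        return m * self.y_std + self.y_mean, s * self.y_std

    @property
    def noise_variance(self) -> float:
        """Fitted (or pinned) measurement-noise variance on standardized
        outputs; 0 when the model is noise-free."""
        if self.noise == "fit" or (
            not isinstance(self.noise, str) and float(self.noise) > 0
        ):
            return float(self.gpr.kernel_.k2.noise_level)
        return 0.0

    def standardized_predict(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and *latent-function* std on the standardized
        scale used by the acquisition function.

        The white-noise term belongs to the measurement, not to the yield
        surface: leaving it in the predictive std lets expected improvement
        re-sample noisy incumbents forever, so it is subtracted here.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m, s = self.gpr.predict(self._scale_inputs(X), return_std=True)
        if LATENT_STD:
            s = np.sqrt(np.clip(s**2 - self.noise_variance, 0.0, None))
        return m, s

    def standardized_mean(self, X) -> np.ndarray:
        """Posterior mean only (cheaper than :meth:`standardized_predict`
        for large batches: no O(n²) variance solve)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.gpr.predict(self._scale_inputs(X), return_std=False)

    def standardize_y(self, y) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_std

    def log_marginal_likelihood(self, theta: np.ndarray | None = None) -> float:
        """LML of the standardized outputs at ``theta`` (default: fitted)."""
        if theta is None:
            return float(self.gpr.log_marginal_likelihood_value_)
        return float(self.gpr.log_marginal_likelihood(np.asarray(theta, dtype=float)))

    def to_dict(self) -> dict:
        return {
            "X": self.X.tolist(),
            "y": self.y.tolist(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "cat_mask": None if self.cat_mask is None else self.cat_mask.tolist(),
            "seed": self.seed,
            "noise": self.noise,
            "theta": self.theta.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GPModel":
        model = fit(
            np.asarray(payload["X"], dtype=float),
            np.asarray(payload["y"], dtype=float),
            seed=payload["seed"],
            cat_mask=None
            if payload["cat_mask"] is None
            else np.asarray(payload["cat_mask"], dtype=bool),
            noise=payload["noise"],
            theta=np.asarray(payload["theta"], dtype=float),
            optimize=False,
        )
        return model


def _make_kernel(
    dim: int,
    noise: float | str,
    init_lengthscale: np.ndarray | None = None,
    init_signal: float = 1.0,
    init_noise: float = 0.05,
    degenerate: bool = False,
    cat_dims: np.ndarray | None = None,
):
    ls = (
        np.full(dim, 0.5)
        if init_lengthscale is None
        else np.asarray(init_lengthscale, dtype=float)
    )
    ls_bounds = LS_BOUNDS
    if cat_dims is not None and cat_dims.any():
        # One-hot levels (including the transfer task variable) start with a
        # long lengthscale — levels and tasks are presumed similar until the
        # data identifies otherwise — and their lengthscales are bounded
        # away from "irrelevant": an ARD scale of 20 on a single level
        # column would erase that level's evidence entirely, which is how a
        # surrogate quietly discards, say, everything it knows about one
        # solvent.
        if init_lengthscale is None:
            ls[cat_dims] = 2.0
        ls_bounds = [
            CAT_LS_BOUNDS if is_cat else LS_BOUNDS for is_cat in cat_dims
        ]
    # constant outputs carry no signal: the variance is allowed to collapse
    # to the noise floor instead of inventing structure
    sig_bounds = SIGNAL_BOUNDS_DEGENERATE if degenerate else SIGNAL_BOUNDS
    init_signal = min(max(init_signal, sig_bounds[0]), sig_bounds[1])
    kernel = ConstantKernel(init_signal, sig_bounds) * Matern(
        length_scale=ls, length_scale_bounds=ls_bounds, nu=2.5
    )
    if noise == "fit":
        kernel = kernel + WhiteKernel(init_noise, NOISE_BOUNDS)
    elif float(noise) > 0.0:
        kernel = kernel + WhiteKernel(float(noise), "fixed")
    return kernel


def fit(
    X,
    y,
    seed: int = 0,
    cat_mask: np.ndarray | None = None,
    noise: float | str = "fit",
    n_restarts: int = 5,
    theta: np.ndarray | None = None,
    optimize: bool = True,
    maxiter: int = 80,
) -> GPModel:
    """Fit the GP surrogate to observed (normalized candidate, yield) pairs.

    Parameters
    ----------
    X, y:
        Normalized inputs (n × d, in [0,1] up to one-hot blocks) and yields
        in percent.
    seed:
        Seeds the restart draws; refitting with the same arguments is
        bit-reproducible.
    cat_mask:
        Boolean mask marking one-hot columns (scaled to the inter-category
        distance convention before the kernel).
    noise:
        ``"fit"`` to estimate the noise variance (bounds ``NOISE_BOUNDS`` on
        standardized outputs), or a fixed non-negative variance (0 pins the
        model to jitter-level noise, i.e. near-interpolation).
    n_restarts:
        Extra seeded restarts for the marginal-likelihood maximization.
    theta, optimize:
        Advanced: start from / freeze a known hyperparameter vector.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise GPError("X and y length mismatch")
    if X.shape[0] < 1:
        raise GPError("need at least one observation")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise GPError("non-finite training data")

    # output standardization; skipped when fewer than 2 distinct values
    degenerate = np.unique(y).size < 2
    if not degenerate:
        y_mean, y_std = float(np.mean(y)), float(np.std(y))
    else:
        y_mean, y_std = float(y[0]), 1.0
    ys = (y - y_mean) / y_std

    kernel = _make_kernel(
        X.shape[1],
        noise,
        degenerate=degenerate,
        cat_dims=None if cat_mask is None else np.asarray(cat_mask, dtype=bool),
    )

    def _lbfgs(obj_func, initial_theta, bounds):
        from scipy.optimize import minimize as _minimize

        res = _minimize(
            obj_func,
            initial_theta,
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"maxiter": maxiter},
        )
        return res.x, res.fun

    gpr = GaussianProcessRegressor(
        kernel=kernel,
        alpha=JITTER,
        normalize_y=False,
        optimizer=_lbfgs if optimize else None,
        n_restarts_optimizer=n_restarts if optimize else 0,
        random_state=seed,
    )
    model = GPModel(
        gpr=gpr,
        X=X,
        y=y,
        y_mean=y_mean,
        y_std=y_std,
        cat_mask=None if cat_mask is None else np.asarray(cat_mask, dtype=bool),
        seed=seed,
        noise=noise,
    )
    Xs = model._scale_inputs(X)
    if theta is not None:
        gpr.kernel = gpr.kernel.clone_with_theta(np.asarray(theta, dtype=float))
    with warnings.catch_warnings():
        # hyperparameters legitimately sit at their bounds (e.g. an
        # irrelevant dimension pushed to the lengthscale ceiling)
        warnings.simplefilter("ignore", ConvergenceWarning)
        gpr.fit(Xs, ys)
    return model
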