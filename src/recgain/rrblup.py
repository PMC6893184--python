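"""Ridge-regression BLUP of marker effects (RR-BLUP) via spectral REML.

Mixed model ``y = X b + Z u + e`` with ``X`` a column of ones, ``Z`` the
``{-1, 0, +1}``-coded marker matrix, ``u ~ N(0, Vu I)`` and
``e ~ N(0, Ve I)``.  The variance ratio ``delta = Ve / Vu`` is estimated by
restricted maximum likelihood using the spectral decomposition of the
projected kernel ``S K S`` with ``K = Z Z'`` and ``S`` the residual-forming
matrix of ``X`` — a one-dimensional optimization over ``log delta``.  The
BLUE of ``b`` and BLUP of ``u`` follow from the mixed-model equations at the
REML ratio.

The API follows the Model / Results convention: build a :class:`MarkerRidge`
from data, call :meth:`~MarkerRidge.fit`, inspect the returned
:class:`MarkerRidgeResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize_scalar

from .errors import DegenerateFitError

__all__ = ["MarkerRidge", "MarkerRidgeResults"]

_LOG_DELTA_RANGE = (-10.0, 10.0)


class MarkerRidge:
    """RR-BLUP mixed model for a vector of phenotypes and a marker matrix.

    Parameters
    ----------
    y : (n,) phenotypes.
    Z : (n, m) marker genotypes coded -1 / 0 / +1 (monomorphic columns are
        permitted; their effects shrink to zero).
    """

    def __init__(self, y: np.ndarray, Z: np.ndarray):
        y = np.asarray(y, dtype=float)
        Z = np.asarray(Z)
        if y.ndim != 1 or Z.ndim != 2 or Z.shape[0] != y.shape[0]:
            raise ValueError("y must be (n,), Z must be (n, m)")
        if y.shape[0] < 2:
            raise DegenerateFitError("need at least 2 observations")
        if np.ptp(y) == 0:
            raise DegenerateFitError("constant phenotypes cannot be fitted")
        self.y = y
        self.Z = Z
        self.nobs, self.nmarkers = Z.shape

    def fit(self, tol: float = 1e-8) -> "MarkerRidgeResults":
        """Estimate delta by REML and solve the mixed-model equations."""
        y, Z = self.y, self.Z
        n = self.nobs
        Zf = Z.astype(np.float32, copy=False)
        K = (Zf @ Zf.T).astype(float)
        # restrict to the orthogonal complement of the intercept and
        # eigendecompose the projected kernel there
        Q, _ = np.linalg.qr(np.ones((n, 1)), mode="complete")
        T = Q[:, 1:]  # (n, n-1) orthonormal basis of 1-perp
        theta, V = eigh(T.T @ K @ T)
        theta = np.maximum(theta, 0.0)
        eta2 = (V.T @ (T.T @ y)) ** 2

        def neg_restricted_ll(log_delta: float) -> float:
            d = np.exp(log_delta)
            w = theta + d
            return (n - 1) * np.log(np.sum(eta2 / w)) + np.sum(np.log(w))

        res = minimize_scalar(
            neg_restricted_ll,
            bounds=_LOG_DELTA_RANGE,
            method="bounded",
            options={"xatol": tol},
        )
        delta = float(np.exp(res.x))
        w = theta + delta
        var_u = float(np.sum(eta2 / w) / (n - 1))
        var_e = delta * var_u
        # BLUE / BLUP at the REML ratio
        c, low = cho_factor(K + delta * np.eye(n))
        hinv_y = cho_solve((c, low), y)
        hinv_1 = cho_solve((c, low), np.ones(n))
        beta = float(hinv_y.sum() / hinv_1.sum())
        resid = cho_solve((c, low), y - beta)
        u = Z.T.astype(float) @ resid
        ll = -0.5 * (
            neg_restricted_ll(res.x)
            + (n - 1) * (1.0 + np.log(2.0 * np.pi / (n - 1)))
        )
        return MarkerRidgeResults(
            model=self, beta=beta, u=u, var_u=var_u, var_e=var_e,
            delta=delta, restricted_loglik=ll,
        )


@dataclass
class MarkerRidgeResults:
    """REML estimates and BLUP marker effects of a fitted :class:`MarkerRidge`."""

    model: MarkerRidge
    beta: float  # population-mean intercept
    u: np.ndarray  # (m,) marker effects
    var_u: float  # per-marker effect variance
    var_e: float  # residual variance
    delta: float  # var_e / var_u
    restricted_loglik: float

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.Z)

    def predict(self, Znew: np.ndarray) -> np.ndarray:
        """Genomic estimated breeding values ``beta + Znew @ u``."""
        Znew = np.asarray(Znew)
        if Znew.ndim != 2 or Znew.shape[1] != self.model.nmarkers:
            raise ValueError(f"Znew must have {self.model.nmarkers} marker columns")
        return self.beta + Znew.astype(float) @ self.u

    def summary(self) -> str:
        m = self.model
        h2_hat = self.var_u * np.trace(m.Z.astype(float).T @ m.Z.astype(float)) / m.nobs
        h2_hat = h2_hat / (h2_hat + self.var_e) if (h2_hat + self.var_e) > 0 else np.nan
        lines = [
            "RR-BLUP mixed model (REML)",
            "=" * 42,
            f"{'observations':<28}{m.nobs:>14d}",
            f"{'markers':<28}{m.nmarkers:>14d}",
            f"{'intercept (beta)':<28}{self.beta:>14.4f}",
            f"{'marker-effect var (Vu)':<28}{self.var_u:>14.6g}",
            f"{'residual var (Ve)':<28}{self.var_e:>14.6g}",
            f"{'delta = Ve/Vu':<28}{self.delta:>14.6g}",
            f"{'genomic h2 (approx.)':<28}{h2_hat:>14.4f}",
            f"{'restricted log-lik':<28}{self.restricted_loglik:>14.4f}",
            "=" * 42,
        ]
        return "\n".join(lines)
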