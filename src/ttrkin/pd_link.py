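"""Phenomenological link between stabiliser concentration and TTR stability.

Subunit-exchange assays performed in full plasma measure the *net* tetramer
dissociation rate as a function of the stabiliser concentration added —
regardless of how much drug is albumin-bound, T4-displaced or otherwise
sequestered.  The dependence is captured by a single Arrhenius-like decay

    kd(c1) = kd0 · exp(−λ·c1)

with kd0 the drug-free dissociation rate (h⁻¹) and λ (μM⁻¹) the only
fitted constant.  Reference values for tafamidis at physiological
temperature: kd0 = 0.0024 h⁻¹, λ = 0.112 μM⁻¹.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DomainError, FitError

__all__ = [
    "StabiliserRelation",
    "kd_of_concentration",
    "StabiliserResponseModel",
    "StabiliserResponseResults",
    "fit_lambda",
]


@dataclass(frozen=True)
class StabiliserRelation:
    """Exponential concentration→dissociation-rate relation (kd0, λ)."""

    kd0: float
    lam: float

    def __post_init__(self) -> None:
        if self.kd0 <= 0:
            raise DomainError(f"kd0 must be > 0, got {self.kd0}")
        if self.lam < 0:
            raise DomainError(f"lam must be >= 0, got {self.lam}")

    @classmethod
    def reference(cls) -> "StabiliserRelation":
        """Tafamidis in plasma at physiological temperature."""
        return cls(kd0=0.0024, lam=0.112)

    def __call__(self, c1):
        return kd_of_concentration(self, c1)

    def replace(self, **changes) -> "StabiliserRelation":
        return replace(self, **changes)


def kd_of_concentration(rel: StabiliserRelation, c1):
    """Effective dissociation rate kd0·exp(−λ·c1) at plasma level c1 (μM).

    Accepts scalars or arrays; strictly decreasing in c1 when λ > 0.
    """
    c = np.asarray(c1, dtype=float)
    if np.any(c < 0):
        raise DomainError("stabiliser concentration must be >= 0")
    out = rel.kd0 * np.exp(-rel.lam * c)
    return float(out) if np.isscalar(c1) else out


class StabiliserResponseModel:
    """Estimate λ (and optionally kd0) from (concentration, kd) pairs.

    By default the fit is a linear regression of log(kd) on c1 (slope −λ):
    exact on noiseless data and variance-stabilising for the multiplicative
    error typical of exchange assays.  ``log_space=False`` switches to
    untransformed least squares on kd.

    kd0 handling: fixed to a supplied value; otherwise, if a measurement
    at c1 = 0 exists it is used as the fixed drug-free rate; otherwise
    kd0 is co-estimated.
    """

    def __init__(self, c1, kd_measured, *, kd0: Optional[float] = None,
                 log_space: bool = True):
        c = np.asarray(c1, dtype=float)
        k = np.asarray(kd_measured, dtype=float)
        if c.shape != k.shape or c.ndim != 1:
            raise ValueError("c1 and kd_measured must be 1-D of equal length")
        if len(c) < 2 or len(np.unique(c)) < 2:
            raise FitError("need measurements at >= 2 distinct concentrations")
        if np.any(k <= 0):
            raise DomainError("measured kd values must be > 0")
        if np.any(c < 0):
            raise DomainError("concentrations must be >= 0")
        self.c = c
        self.k = k
        self.log_space = log_space
        if kd0 is not None:
            self.kd0_fixed: Optional[float] = float(kd0)
        elif np.any(c == 0):
            self.kd0_fixed = float(np.exp(np.mean(np.log(k[c == 0]))))
        else:
            self.kd0_fixed = None

    @classmethod
    def from_csv(cls, path, **kwargs) -> "StabiliserResponseModel":
        df = pd.read_csv(path)
        return cls(df["c1_uM"], df["kd_per_h"], **kwargs)

    def fit(self) -> "StabiliserResponseResults":
        if self.log_space:
            return self._fit_log()
        return self._fit_linear()

    def _fit_log(self) -> "StabiliserResponseResults":
        y = np.log(self.k)
        if self.kd0_fixed is not None:
            # slope-only regression through log(kd0)
            x = self.c
            yy = y - np.log(self.kd0_fixed)
            lam = -float(x @ yy / (x @ x))
            resid = yy + lam * x
            dof = max(len(x) - 1, 1)
            se = float(np.sqrt((resid @ resid) / dof / (x @ x)))
            rel = StabiliserRelation(self.kd0_fixed, max(lam, 0.0))
        else:
            A = np.column_stack([np.ones_like(self.c), -self.c])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ coef
            dof = max(len(self.c) - 2, 1)
            cov = (resid @ resid) / dof * np.linalg.inv(A.T @ A)
            se = float(np.sqrt(cov[1, 1]))
            rel = StabiliserRelation(float(np.exp(coef[0])), max(float(coef[1]), 0.0))
        if rel.lam == 0.0 and se == 0.0:
            warnings.warn("fitted λ is exactly 0: no concentration dependence",
                          RuntimeWarning)
        return StabiliserResponseResults(model=self, relation=rel,
                                         se_lambda=se, resid=resid,
                                         rss=float(resid @ resid))

    def _fit_linear(self) -> "StabiliserResponseResults":
        free_kd0 = self.kd0_fixed is None
        x0 = np.array([np.log(self.k.max()), 0.05] if free_kd0 else [0.05])
        scale = self.k.max()  # kd values are ~1e-3; rescale for the optimizer

        def resid(x):
            kd0 = np.exp(x[0]) if free_kd0 else self.kd0_fixed
            lam = x[-1]
            return (kd0 * np.exp(-lam * self.c) - self.k) / scale

        sol = least_squares(resid, x0, xtol=3e-16, ftol=3e-16, gtol=3e-16,
                            x_scale="jac")
        if not sol.success:
            raise FitError(f"λ fit did not converge: {sol.message}")
        kd0 = float(np.exp(sol.x[0])) if free_kd0 else self.kd0_fixed
        lam = float(sol.x[-1])
        dof = max(len(self.c) - len(sol.x), 1)
        jac = sol.jac * scale
        s2 = 2 * sol.cost * scale ** 2 / dof
        try:
            cov = s2 * np.linalg.inv(jac.T @ jac)
            se = float(np.sqrt(cov[-1, -1]))
        except np.linalg.LinAlgError:
            se = float("nan")
        rel = StabiliserRelation(kd0, max(lam, 0.0))
        raw = sol.fun * scale
        return StabiliserResponseResults(model=self, relation=rel,
                                         se_lambda=se, resid=raw,
                                         rss=float(raw @ raw))


@dataclass
class StabiliserResponseResults:
    """Fitted (kd0, λ) with residuals; λ standard error from the regression."""

    model: StabiliserResponseModel
    relation: StabiliserRelation
    se_lambda: float
    resid: np.ndarray
    rss: float

    def summary(self) -> str:
        kd0_src = "fixed" if self.model.kd0_fixed is not None else "estimated"
        return "\n".join([
            "Stabiliser concentration–kd fit  (kd = kd0·exp(−λ·c1))",
            "=" * 54,
            f"n obs      {len(self.model.c):>8d}     objective  "
            f"{'log(kd)' if self.model.log_space else 'kd'}",
            f"kd0        {self.relation.kd0:>12.5g} 1/h   ({kd0_src})",
            f"lambda     {self.relation.lam:>12.5g} 1/uM  "
            f"(se {self.se_lambda:.3g})",
            f"RSS        {self.rss:>12.4e}",
            "=" * 54,
        ])

    def to_json(self) -> str:
        return json.dumps({"kd0": self.relation.kd0,
                           "lambda": self.relation.lam,
                           "se_lambda": self.se_lambda,
                           "rss": self.rss})

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(self.model.c, self.model.k, "o", color="tab:red",
                    label="measured kd")
        grid = np.linspace(0, self.model.c.max() * 1.05, 200)
        ax.semilogy(grid, kd_of_concentration(self.relation, grid), "-",
                    color="tab:blue", label="kd0·exp(−λc)")
        ax.set_xlabel("stabiliser concentration (μM)")
        ax.set_ylabel("kd (1/h)")
        ax.legend()
        return ax


def fit_lambda(pairs, kd0: Optional[float] = None, *, log_space: bool = True
               ) -> tuple[StabiliserRelation, StabiliserResponseResults]:
    """Functional wrapper: ``pairs`` is a sequence of (c1_uM, kd_per_h)."""
    arr = np.asarray(pairs, dtype=float)
    res = StabiliserResponseModel(arr[:, 0], arr[:, 1], kd0=kd0,
                                  log_space=log_space).fit()
    return res.relation, res
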