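"""General parameters defined by estimating equations under two-phase designs.

A population parameter xi_0 solves the population-averaged estimating
equation N^{-1} sum_i s(y_i; xi) = 0.  The phase-II estimator xi_II solves
the pi*-weighted Hajek analogue.  Its limiting law keeps the three-component
mixture structure of the mean case with s_i(xi_0) in place of y_i, a
projection coefficient B_0 of s on x in place of beta_0, and an
inverse-Jacobian sandwich.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import optimize, stats

from .designs import PhaseSample
from .estimators import _sample_values
from .variance import (
    EstimateResult,
    MixtureBasis,
    VarianceComponents,
    confidence_interval,
    pairwise_components,
)
from .asymptotics import v_p_gamma
from .designs import phase_design_cov

__all__ = ["EstimatingFunction", "builtin_ee", "solve_ee", "ee_variance"]


@dataclass
class EstimatingFunction:
    """An estimating function s(y; xi) with optional analytic derivative.

    ``evaluate(y, xi)`` returns an (n, q) array; ``derivative(y, xi)`` the
    (n, q, q) array of partials when the function is smooth in xi.
    ``derivative_mode`` selects how the Jacobian Gamma_s is estimated:
    ``analytic`` for the smooth built-ins, ``kernel_density`` for the
    quantile kind (the Jacobian is the outcome density at the quantile).
    """

    kind: str
    dim_q: int
    evaluate: Callable[[np.ndarray, np.ndarray], np.ndarray]
    derivative: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None
    derivative_mode: str = "analytic"
    smooth: bool = True
    params: dict = None


def builtin_ee(kind: str, c: Optional[float] = None, tau: Optional[float] = None
               ) -> EstimatingFunction:
    """Built-in estimating functions.

    ``mean``: s = y - xi; ``proportion``: s = I(y < c) - xi;
    ``variance_pair``: s = (y - xi1, (y - xi1)^2 - xi2);
    ``quantile``: s = I(y <= xi) - tau (nonsmooth; solved by generalized
    inverse).
    """
    if kind == "mean":
        return EstimatingFunction(
            kind="mean", dim_q=1,
            evaluate=lambda y, xi: (y - xi[0])[:, None],
            derivative=lambda y, xi: np.full((y.size, 1, 1), -1.0),
            params={},
        )
    if kind == "proportion":
        if c is None:
            raise ValueError("proportion kind needs the cutoff c")
        return EstimatingFunction(
            kind="proportion", dim_q=1,
            evaluate=lambda y, xi: ((y < c).astype(float) - xi[0])[:, None],
            derivative=lambda y, xi: np.full((y.size, 1, 1), -1.0),
            params={"c": c},
        )
    if kind == "variance_pair":
        def ev(y, xi):
            return np.column_stack([y - xi[0], (y - xi[0]) ** 2 - xi[1]])

        def dv(y, xi):
            d = np.zeros((y.size, 2, 2))
            d[:, 0, 0] = -1.0
            d[:, 1, 0] = -2.0 * (y - xi[0])
            d[:, 1, 1] = -1.0
            return d

        return EstimatingFunction(kind="variance_pair", dim_q=2, evaluate=ev,
                                  derivative=dv, params={})
    if kind == "quantile":
        if tau is None or not 0 < tau < 1:
            raise ValueError("quantile kind needs tau in (0, 1)")
        return EstimatingFunction(
            kind="quantile", dim_q=1,
            evaluate=lambda y, xi: ((y <= xi[0]).astype(float) - tau)[:, None],
            derivative=None, derivative_mode="kernel_density", smooth=False,
            params={"tau": tau},
        )
    raise ValueError(f"unknown estimating-function kind {kind!r}")


def solve_ee(sampleII: PhaseSample, y, ee: EstimatingFunction) -> np.ndarray:
    """Solve the pi*-weighted phase-II estimating equation.

    Smooth kinds use their closed-form weighted-moment roots (verified
    against the equation) or bracketed root finding; the quantile kind uses
    the exact generalized inverse inf{xi : sbar_II(xi) >= 0} on the sorted
    phase-II support.
    """
    if sampleII.n == 0:
        raise ValueError("empty sample")
    Y = _sample_values(sampleII, y).ravel()
    w = sampleII.weights()
    w = w / w.sum()
    if ee.kind == "mean":
        return np.array([w @ Y])
    if ee.kind == "proportion":
        return np.array([w @ (Y < ee.params["c"]).astype(float)])
    if ee.kind == "variance_pair":
        m = w @ Y
        return np.array([m, w @ (Y - m) ** 2])
    if ee.kind == "quantile":
        tau = ee.params["tau"]
        order = np.argsort(Y, kind="stable")
        cw = np.cumsum(w[order])
        k = int(np.searchsorted(cw, tau, side="left"))
        return np.array([Y[order][min(k, Y.size - 1)]])
    # generic smooth scalar: bracketed root finding on the weighted equation
    if ee.dim_q != 1:
        raise ValueError("generic root finding supports scalar xi only")

    def sbar(xi):
        return float(w @ ee.evaluate(Y, np.array([xi])).ravel())

    lo, hi = Y.min() - 1.0, Y.max() + 1.0
    span = hi - lo
    for _ in range(60):
        if sbar(lo) * sbar(hi) <= 0:
            break
        lo -= span
        hi += span
        span *= 2
    else:
        raise ValueError("no sign change found for the estimating equation")
    return np.array([optimize.brentq(sbar, lo, hi, xtol=1e-12, rtol=1e-12)])


def _jacobian_hat(sampleII: PhaseSample, Y: np.ndarray, ee: EstimatingFunction,
                  xi_bar: np.ndarray) -> np.ndarray:
    w = sampleII.weights()
    w = w / w.sum()
    if ee.smooth and ee.derivative is not None:
        d = ee.derivative(Y, xi_bar)
        return np.tensordot(w, d, axes=(0, 0))
    if ee.kind == "quantile":
        # Jacobian of E I(y <= xi) is the outcome density at xi; estimate with
        # a pi*-weighted Gaussian kernel and Silverman's rule-of-thumb
        # bandwidth 0.9 min(sd, IQR/1.34) n_eff^{-1/5} (robust scale matters
        # for skewed outcomes)
        n_eff = 1.0 / np.sum(w**2)  # Kish effective sample size
        mu = w @ Y
        sd = np.sqrt(w @ (Y - mu) ** 2)
        order = np.argsort(Y)
        cw = np.cumsum(w[order])
        q25, q75 = np.interp([0.25, 0.75], cw, Y[order])
        scale = min(sd, (q75 - q25) / 1.34)
        bw = 0.9 * max(scale, 1e-12) * n_eff ** (-0.2)
        kde = stats.gaussian_kde(Y, bw_method=bw / sd, weights=w)
        return np.array([[float(kde(xi_bar[0])[0])]])
    raise ValueError("no derivative available for this estimating function")


def ee_variance(sampleI: PhaseSample, sampleII: PhaseSample, x, y,
                ee: EstimatingFunction, xi_bar: np.ndarray, gamma2: float,
                p: Optional[int] = None, form: str = "ht", alpha: float = 0.05,
                basis: Optional[MixtureBasis] = None,
                mc_draws: int = 200_000) -> EstimateResult:
    """Variance components and confidence interval for an estimating-equation root.

    Builds the three components with s_i(xi_bar) in place of y:
    V1 = n_II B_hat^T V_xx,I B_hat where B_hat is the pi*-weighted phase-II
    projection of s on x; V2 uses the projection residuals e^s_i = s_i -
    x_i^T B_hat; V3 uses s_i itself.  The variance is the inverse-Jacobian
    sandwich n_II^{-1} Gamma^{-T} (V1 v_{p,gamma^2} + V2 + V3) Gamma^{-1},
    with Gamma the Jacobian of the limiting estimating function (the outcome
    density at the quantile for the quantile kind).  The first component of
    xi gets a mixture-law interval; reported variance is the [0,0] entry.
    """
    pop = sampleII.population
    popN = pop.N
    xsel = "x" if x is None else x
    X = pop.values(xsel)
    XII = _sample_values(sampleII, xsel)
    Y = _sample_values(sampleII, y).ravel()
    if p is None:
        p = XII.shape[1]
    xi_bar = np.asarray(xi_bar, float).ravel()
    S = ee.evaluate(Y, xi_bar)  # (n, q)
    q = S.shape[1]
    # pi*-weighted projection of s on x (plug-in analogue of the population B0)
    w = sampleII.weights()
    xbar = w @ XII / w.sum()
    sbar = w @ S / w.sum()
    Xc = XII - xbar
    A = (Xc * w[:, None]).T @ Xc
    B_hat = np.linalg.solve(A, (Xc * w[:, None]).T @ (S - sbar))  # (p, q)
    Vxx_I = phase_design_cov(sampleII, X[sampleI.selected], popN=popN)
    nII = sampleII.n
    V1 = nII * B_hat.T @ Vxx_I @ B_hat
    es = S - XII @ B_hat
    V2, V3 = pairwise_components(sampleI, sampleII, es, S, popN, form=form)
    Gamma = _jacobian_hat(sampleII, Y, ee, xi_bar)
    if np.linalg.cond(Gamma) > 1e12:
        raise np.linalg.LinAlgError("singular estimating-equation Jacobian")
    Ginv = np.linalg.inv(Gamma)
    v = v_p_gamma(p, gamma2)
    total = Ginv.T @ (V1 * v + V2 + V3) @ Ginv / nII
    # sandwich-transformed components for the mixture interval (first coord)
    V1t = float((Ginv.T @ V1 @ Ginv)[0, 0])
    V2t = float((Ginv.T @ V2 @ Ginv)[0, 0])
    V3t = float((Ginv.T @ V3 @ Ginv)[0, 0])
    comps = VarianceComponents(
        V1_hat=V1t, V2_hat=V2t, V3_hat=V3t, form=form,
        meta={"nII": nII, "nI": sampleI.n, "N": popN, "gamma2": gamma2, "p": p},
    )
    res = confidence_interval(float(xi_bar[0]), comps, alpha=alpha,
                              estimator_kind="mean", path="general",
                              basis=basis, mc_draws=mc_draws)
    res.variance = float(total[0, 0])
    res.method = f"ee/{ee.kind}/{form}"
    return res
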