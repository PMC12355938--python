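"""Design-consistent variance estimators and confidence intervals.

Two routes exist and the dispatcher never falls back silently between them:

* the SRS route (equal-probability two-phase simple random sampling), with
  closed-form variance expressions driven by the phase-II sample covariance,
  the df-adjusted residual variance and the plug-in squared correlation; and
* the general route, with the three Horvitz-Thompson (or Sen-Yates-Grundy)
  components V1 (balanced auxiliary term, shrunk by v_{p,gamma^2} under
  rejection), V2 (phase-II residual term) and V3 (phase-I term), built from
  second-order inclusion probabilities.

All components are scaled as components of n_II * var(estimator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .asymptotics import MixtureBasis, v_p_gamma
from .designs import PhaseSample, pair_inclusion_matrix, phase_design_cov
from .estimators import _sample_values, regression_coefficient

__all__ = [
    "VarianceComponents",
    "EstimateResult",
    "sample_cov_hat",
    "residual_variance_hat",
    "var_hat_srs",
    "ht_components",
    "syg_components",
    "confidence_interval",
]


class NegativeVarianceError(ValueError):
    """A Horvitz-Thompson plug-in variance came out negative; use the SYG form."""


@dataclass
class VarianceComponents:
    """Components of n_II * var for a two-phase estimator.

    The SRS route fills ``Vee_hat/Vyy_hat/R2_hat``; the general route fills
    ``V1_hat/V2_hat/V3_hat``.  ``meta`` carries the design facts (n_II, n_I,
    N, gamma2, p) needed to rebuild the mixture law for interval estimation.
    """

    V1_hat: float = np.nan
    V2_hat: float = np.nan
    V3_hat: float = np.nan
    form: str = "ht"
    Vee_hat: float = np.nan
    Vyy_hat: float = np.nan
    R2_hat: float = np.nan
    meta: dict = field(default_factory=dict)


@dataclass
class EstimateResult:
    point: float
    variance: float
    components: VarianceComponents
    ci: Tuple[float, float]
    alpha: float
    method: str
    acceptance: Optional[object] = None


def sample_cov_hat(sampleII: PhaseSample, u, v=None) -> np.ndarray:
    """Phase-II sample covariance of u and v with divisor n_II - 1."""
    if sampleII.n < 2:
        raise ValueError("need n_II >= 2 for a sample covariance")
    U = _sample_values(sampleII, u)
    V = U if v is None else _sample_values(sampleII, v)
    Uc = U - U.mean(axis=0)
    Vc = V - V.mean(axis=0)
    return Uc.T @ Vc / (sampleII.n - 1)


def residual_variance_hat(sampleII: PhaseSample, x=None, y="y",
                          beta_hat: Optional[np.ndarray] = None):
    """Residual variance, reconstructed total variance and plug-in R^2.

    V_ee is the variance of the phase-II regression residuals with divisor
    n_II - p - 1 (degrees of freedom spent estimating the slope), V_yy is
    rebuilt from the decomposition beta^T V_xx beta + V_ee, and R^2 is the
    ratio of raw (divisor n_II - 1) cross moments, clipped to [0, 1 - 1e-10].

    Returns ``(Vee_hat, Vyy_hat, R2_hat)``.
    """
    xsel = "x" if x is None else x
    X = _sample_values(sampleII, xsel)
    Y = _sample_values(sampleII, y).ravel()
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"insufficient degrees of freedom: n_II={n} <= p+1={p + 1}")
    if beta_hat is None:
        beta_hat = regression_coefficient(sampleII, xsel, y, "unweighted").beta_hat
    beta_hat = np.asarray(beta_hat, float).ravel()
    resid = (Y - Y.mean()) - (X - X.mean(axis=0)) @ beta_hat
    Vee = float(resid @ resid / (n - p - 1))
    Vxx = sample_cov_hat(sampleII, xsel)
    Vyy = float(beta_hat @ Vxx @ beta_hat + Vee)
    Vxy = sample_cov_hat(sampleII, xsel, y).ravel()
    Vyy_raw = float(sample_cov_hat(sampleII, y, y)[0, 0])
    R2 = float(Vxy @ np.linalg.solve(np.atleast_2d(Vxx), Vxy) / Vyy_raw)
    R2 = min(max(R2, 0.0), 1.0 - 1e-10)
    return Vee, Vyy, R2


def var_hat_srs(sampleI: PhaseSample, sampleII: PhaseSample, popN: int,
                gamma2: float, p: Optional[int] = None, which: str = "mean",
                x=None, y="y"):
    """Plug-in variance estimator under two-phase SRS (with or without rejection).

    ``which="mean"`` gives

        n_II^{-1} [ (1 - n_II/n_I) {1 - (1 - v_{p,gamma^2}) R^2_hat}
                    + (n_II/n_I)(1 - n_I/N) ] V_yy_hat,

    and ``which="regression"`` the residual form

        n_II^{-1} { (n_II/n_I)(1 - n_I/N) V_yy_hat + (1 - n_II/n_I) V_ee_hat }.

    Returns ``(components, variance)``.
    """
    if sampleI.design_kind != "srs" or sampleII.design_kind != "srs":
        raise ValueError("var_hat_srs requires SRS phases; use the general route")
    xsel = "x" if x is None else x
    nII, nI = sampleII.n, sampleI.n
    if p is None:
        p = _sample_values(sampleII, xsel).shape[1]
    Vee, Vyy, R2 = residual_variance_hat(sampleII, xsel, y)
    fII = nII / nI
    fI = nI / popN
    comps = VarianceComponents(
        form="srs", Vee_hat=Vee, Vyy_hat=Vyy, R2_hat=R2,
        meta={"nII": nII, "nI": nI, "N": popN, "gamma2": gamma2, "p": p},
    )
    if which == "mean":
        v = v_p_gamma(p, gamma2)
        var = ((1 - fII) * (1 - (1 - v) * R2) + fII * (1 - fI)) * Vyy / nII
    elif which == "regression":
        var = (fII * (1 - fI) * Vyy + (1 - fII) * Vee) / nII
    else:
        raise ValueError(f"unknown estimator kind {which!r}")
    return comps, float(var)


# --------------------------------------------------------------------------
# general-route pairwise components


def _hajek_center(sample: PhaseSample, values: np.ndarray) -> np.ndarray:
    w = sample.weights()
    return values - w @ values / w.sum()


def _pair_weight_matrices(sampleI: PhaseSample, sampleII: PhaseSample):
    ids = sampleII.selected
    piII = pair_inclusion_matrix(sampleII, ids)
    piI = pair_inclusion_matrix(sampleI, ids)
    return piI, piII


def pairwise_components(sampleI: PhaseSample, sampleII: PhaseSample,
                        resid: np.ndarray, vals: np.ndarray, popN: int,
                        form: str = "ht") -> Tuple[np.ndarray, np.ndarray]:
    """V2 and V3 matrices for arbitrary (vector-valued) residuals and values.

    ``resid`` feeds the phase-II component V2 (regression residuals for the
    mean pipeline, estimating-function residuals in the general-parameter
    pipeline); ``vals`` feeds the phase-I component V3.  Both are arrays over
    the phase-II units, shape (n_II, q).  Estimating a phase-I (or
    population) double sum from the phase-II sample requires lifting each
    pair term by its selection probability, so V2 divides by pi_IIij|A and V3
    by pi_Iij * pi_IIij|A; this applies to the Sen-Yates-Grundy forms as well.
    """
    nII = sampleII.n
    piI, piII = _pair_weight_matrices(sampleI, sampleII)
    piI_i = np.diag(piI)
    piII_i = np.diag(piII)
    pistar = sampleII.cum_pistar
    R = np.atleast_2d(np.asarray(resid, float).T).T
    Yv = np.atleast_2d(np.asarray(vals, float).T).T
    Rc = _hajek_center(sampleII, R)
    Yc = _hajek_center(sampleII, Yv)
    scale = nII / popN**2
    if form == "ht":
        W2 = (piII - np.outer(piII_i, piII_i)) / (np.outer(pistar, pistar) * piII)
        V2 = scale * (Rc.T @ W2 @ Rc)
        W3 = (piI - np.outer(piI_i, piI_i)) / (np.outer(piI_i, piI_i) * piI * piII)
        V3 = scale * (Yc.T @ W3 @ Yc)
        return V2, V3
    if form == "syg":
        if sampleI.design_kind == "poisson" or sampleII.design_kind == "poisson":
            raise ValueError("Sen-Yates-Grundy form requires fixed-size phases")
        W2 = (piII - np.outer(piII_i, piII_i)) / piII
        D2 = Rc / pistar[:, None]
        V2 = -0.5 * scale * _syg_quadratic(W2, D2)
        W3 = (piI - np.outer(piI_i, piI_i)) / (piI * piII)
        D3 = Yc / piI_i[:, None]
        V3 = -0.5 * scale * _syg_quadratic(W3, D3)
        return V2, V3
    raise ValueError(f"unknown form {form!r}")


def _syg_quadratic(W: np.ndarray, D: np.ndarray) -> np.ndarray:
    """sum_{i,j} W_ij (D_i - D_j)(D_i - D_j)^T for symmetric W."""
    s = W.sum(axis=1)
    return 2.0 * (D * s[:, None]).T @ D - 2.0 * (D.T @ W @ D)


def ht_components(sampleI: PhaseSample, sampleII: PhaseSample, x=None, y="y",
                  beta_hat: Optional[np.ndarray] = None, popN: Optional[int] = None,
                  gamma2: float = np.inf, form: str = "ht") -> VarianceComponents:
    """The three general-route variance components for the phase-II mean.

    V1 = n_II beta_hat^T V_xx,I beta_hat with V_xx,I the conditional design
    covariance of the phase-II auxiliary mean over the phase-I sample; V2 and
    V3 are the pairwise residual and phase-I terms.  ``form="syg"`` switches
    V2/V3 to the nonnegative Sen-Yates-Grundy variants.
    """
    pop = sampleII.population
    if popN is None:
        popN = pop.N
    xsel = "x" if x is None else x
    X = pop.values(xsel)
    if beta_hat is None:
        beta_hat = regression_coefficient(sampleII, xsel, y, "pistar").beta_hat
    beta_hat = np.asarray(beta_hat, float).ravel()
    Vxx_I = phase_design_cov(sampleII, X[sampleI.selected], popN=popN)
    nII = sampleII.n
    V1 = float(nII * beta_hat @ Vxx_I @ beta_hat)
    XII = _sample_values(sampleII, xsel)
    Y = _sample_values(sampleII, y).ravel()
    ehat = Y - XII @ beta_hat
    V2, V3 = pairwise_components(sampleI, sampleII, ehat, Y, popN, form=form)
    p = XII.shape[1]
    return VarianceComponents(
        V1_hat=V1, V2_hat=float(V2[0, 0]), V3_hat=float(V3[0, 0]), form=form,
        meta={"nII": nII, "nI": sampleI.n, "N": popN, "gamma2": gamma2, "p": p},
    )


def syg_components(sampleI: PhaseSample, sampleII: PhaseSample, x=None, y="y",
                   beta_hat: Optional[np.ndarray] = None, popN: Optional[int] = None,
                   gamma2: float = np.inf) -> VarianceComponents:
    """Sen-Yates-Grundy variant of :func:`ht_components` (fixed-size phases only)."""
    return ht_components(sampleI, sampleII, x, y, beta_hat, popN, gamma2, form="syg")


def components_variance(comps: VarianceComponents, which: str = "mean") -> float:
    """n_II^{-1} (V1 v_{p,gamma^2} + V2 + V3) for the mean, n_II^{-1}(V2+V3) for regression."""
    m = comps.meta
    v = v_p_gamma(m["p"], m["gamma2"])
    if which == "mean":
        total = comps.V1_hat * v + comps.V2_hat + comps.V3_hat
    else:
        total = comps.V2_hat + comps.V3_hat
    return float(total / m["nII"])


def confidence_interval(point: float, components: VarianceComponents, alpha: float = 0.05,
                        estimator_kind: str = "mean", path: str = "srs",
                        basis: Optional[MixtureBasis] = None,
                        mc_draws: int = 200_000,
                        acceptance=None) -> EstimateResult:
    """Confidence interval for the population mean from plug-in components.

    The sample-mean interval uses quantiles nu_alpha of the non-normal
    mixture law with plug-in components (R^2_hat on the SRS route,
    V1/V2/V3-hat on the general route):

        ( point - n_II^{-1/2} nu_{1-alpha/2},  point - n_II^{-1/2} nu_{alpha/2} ).

    The regression-estimator interval is normal-based.
    """
    m = components.meta
    nII, nI, N, gamma2, p = m["nII"], m["nI"], m["N"], m["gamma2"], m["p"]
    if path == "srs":
        Vyy, Vee, R2 = components.Vyy_hat, components.Vee_hat, components.R2_hat
        fII, fI = nII / nI, nI / N
        if estimator_kind == "mean":
            a = np.sqrt((1 - fII) * R2)
            b = np.sqrt((1 - fII) * (1 - R2))
            c = np.sqrt(fII * (1 - fI))
            if basis is None:
                basis = MixtureBasis(p, gamma2, n_draws=mc_draws)
            qlo, qhi = basis.quantile(a, b, c, [alpha / 2, 1 - alpha / 2])
            half = np.sqrt(Vyy / nII)
            ci = (point - qhi * half, point - qlo * half)
            var = ((1 - fII) * (1 - (1 - v_p_gamma(p, gamma2)) * R2)
                   + fII * (1 - fI)) * Vyy / nII
        elif estimator_kind == "regression":
            var = (fII * (1 - fI) * Vyy + (1 - fII) * Vee) / nII
            z = stats.norm.ppf(1 - alpha / 2)
            ci = (point - z * np.sqrt(var), point + z * np.sqrt(var))
        else:
            raise ValueError(f"unknown estimator kind {estimator_kind!r}")
    elif path == "general":
        V1, V2, V3 = components.V1_hat, components.V2_hat, components.V3_hat
        if min(V2, V3) < 0 or (estimator_kind == "mean" and V1 < 0):
            raise NegativeVarianceError(
                "negative plug-in variance component; use the Sen-Yates-Grundy form"
            )
        if estimator_kind == "mean":
            if basis is None:
                basis = MixtureBasis(p, gamma2, n_draws=mc_draws)
            qlo, qhi = basis.quantile(np.sqrt(V1), np.sqrt(V2), np.sqrt(V3),
                                      [alpha / 2, 1 - alpha / 2])
            root_n = np.sqrt(nII)
            ci = (point - qhi / root_n, point - qlo / root_n)
            var = components_variance(components, "mean")
        elif estimator_kind == "regression":
            var = (V2 + V3) / nII
            z = stats.norm.ppf(1 - alpha / 2)
            ci = (point - z * np.sqrt(var), point + z * np.sqrt(var))
        else:
            raise ValueError(f"unknown estimator kind {estimator_kind!r}")
    else:
        raise ValueError(f"unknown path {path!r}")
    return EstimateResult(
        point=float(point), variance=float(var), components=components,
        ci=(float(ci[0]), float(ci[1])), alpha=alpha,
        method=f"{estimator_kind}/{path}/{components.form}", acceptance=acceptance,
    )
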