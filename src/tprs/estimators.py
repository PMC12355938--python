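"""Point estimators for two-phase designs.

Covers the Hajek phase means, the double-expansion (pi*) estimator, the
reweighted expansion estimator (REE) for stratified second phases, and the
two-phase regression estimator with its weight representation.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .designs import PhaseSample

__all__ = [
    "RegressionFit",
    "hajek_mean",
    "pistar_mean",
    "ree_mean",
    "regression_coefficient",
    "regression_estimate",
    "regression_weights",
]

_RCOND_MIN = 1e-12


class SingularDesignMatrixError(np.linalg.LinAlgError):
    pass


def _check_invertible(M: np.ndarray) -> None:
    M = np.atleast_2d(M)
    if M.size == 0 or np.linalg.cond(M) > 1.0 / _RCOND_MIN:
        w, v = np.linalg.eigh((M + M.T) / 2)
        null = v[:, int(np.argmin(np.abs(w)))]
        raise SingularDesignMatrixError(
            f"collinear design matrix; null direction approx {np.round(null, 6).tolist()}"
        )


def _sample_values(sample: PhaseSample, values) -> np.ndarray:
    """Resolve ``values`` to an (n, k) array over the sample's units.

    ``values`` may be a selector string ("x"/"y"/"z"), an array over the whole
    population (subset by the sample's unit ids), or an array already aligned
    with the sample.
    """
    if isinstance(values, str):
        return sample.values(values)
    arr = np.asarray(values, dtype=float)
    arr2 = arr[:, None] if arr.ndim == 1 else arr
    if arr2.shape[0] == sample.population.N:
        return arr2[sample.selected]
    if arr2.shape[0] == sample.n:
        return arr2
    raise ValueError(
        f"values length {arr2.shape[0]} matches neither population N nor sample n"
    )


def hajek_mean(sample: PhaseSample, values) -> np.ndarray:
    """Inverse-probability-weighted mean normalized by the weight sum.

    Weights are 1/pi* (the cumulative conditional inclusion probability), so
    for a phase-I sample this is the classical Hajek estimator and for later
    phases the Hajek form of the double-expansion estimator.  Returns a
    scalar for 1-column values.
    """
    if sample.n == 0:
        raise ValueError("empty sample")
    U = _sample_values(sample, values)
    w = sample.weights()
    total = w.sum()
    if total <= 0:
        raise ValueError("zero weight sum")
    out = w @ U / total
    return float(out[0]) if U.shape[1] == 1 else out


def pistar_mean(sampleII: PhaseSample, values):
    """Hajek-normalized double-expansion estimator (weights 1/pi*).

    Under two-phase SRS the weights are equal and the estimator reduces to
    the unweighted phase-II sample mean.
    """
    if sampleII.phase_index < 2:
        raise ValueError("pistar_mean requires a phase >= 2 sample")
    return hajek_mean(sampleII, values)


def ree_mean(sampleI: PhaseSample, sampleII: PhaseSample, stratum_labels, values) -> float:
    """Reweighted expansion estimator for a stratified second phase.

    For each stratum h the phase-I expanded stratum count is combined with
    the pi*-weighted phase-II stratum mean:

        N^{-1} sum_h ( sum_{i in A, h} 1/pi_Ii )
                     ( sum_{i in B, h} y_i/pi*_i ) / ( sum_{i in B, h} 1/pi*_i ).
    """
    pop = sampleII.population
    lab = np.asarray(stratum_labels)
    y = np.asarray(pop.values(values), float).ravel()
    labI = lab[sampleI.selected]
    labII = lab[sampleII.selected]
    wI = 1.0 / sampleI.cum_pistar
    wII = sampleII.weights()
    yII = y[sampleII.selected]
    total = 0.0
    for h in np.unique(labI):
        Nh_hat = wI[labI == h].sum()
        mask = labII == h
        if Nh_hat > 0 and not mask.any():
            raise ZeroDivisionError(
                f"stratum {h!r}: empty phase-II stratum with positive phase-I weight"
            )
        denom = wII[mask].sum()
        total += Nh_hat * (wII[mask] @ yII[mask]) / denom
    return total / pop.N


@dataclass
class RegressionFit:
    beta_hat: np.ndarray
    weights_used: np.ndarray
    xbar_used: np.ndarray
    ybar_used: float


def regression_coefficient(sample: PhaseSample, x=None, y="y",
                           weighting: str = "unweighted") -> RegressionFit:
    """Weighted least-squares slope of y on x within a sample (no intercept after centering).

    beta_hat = { sum w_i (x_i - xbar)(x_i - xbar)^T }^{-1}
               sum w_i (x_i - xbar)(y_i - ybar)

    with w = 1 (``unweighted``) or w = 1/pi* (``pistar``); the centering means
    match the weighting.
    """
    X = _sample_values(sample, "x" if x is None else x)
    Y = np.asarray(_sample_values(sample, y), float).ravel()
    if weighting == "unweighted":
        w = np.ones(sample.n)
    elif weighting == "pistar":
        w = sample.weights()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    xbar = w @ X / w.sum()
    ybar = w @ Y / w.sum()
    Xc = X - xbar
    A = (Xc * w[:, None]).T @ Xc
    _check_invertible(A)
    b = (Xc * w[:, None]).T @ (Y - ybar)
    beta = np.linalg.solve(A, b)
    return RegressionFit(beta_hat=beta, weights_used=w, xbar_used=xbar, ybar_used=float(ybar))


def _phase_mean(sample, values, weighting: str):
    U = _sample_values(sample, values)
    if weighting == "unweighted":
        return U.mean(axis=0)
    w = sample.weights()
    return w @ U / w.sum()


def regression_estimate(sampleI: PhaseSample, sampleII: PhaseSample, x=None, y="y",
                        weighting: str = "unweighted") -> float:
    """Two-phase regression estimator ybar_II - (xbar_II - xbar_I)^T beta_hat_II.

    Phase means and the slope use matching weighting: unweighted for
    equal-probability SRS phases, pi*-weighted Hajek means otherwise.
    """
    xsel = "x" if x is None else x
    fit = regression_coefficient(sampleII, xsel, y, weighting)
    xbarI = _phase_mean(sampleI, xsel, weighting)
    xbarII = _phase_mean(sampleII, xsel, weighting)
    ybarII = _phase_mean(sampleII, y, weighting)
    return float(ybarII[0] - (xbarII - xbarI) @ fit.beta_hat)


def regression_weights(sampleI: PhaseSample, sampleII: PhaseSample, x=None):
    """Per-unit regression weights omega for the SRS two-phase regression estimator.

    omega_i = 1 + (xbar_I - xbar_II)^T { n_II^{-1} sum_B (x_i - xbar_II)^{x2} }^{-1}
                  (x_i - xbar_II),

    so that n_II^{-1} sum_B omega_i y_i equals the regression estimate
    exactly (the inner matrix is the average cross-product; with the raw sum
    the weighted average would miss the adjustment by a factor n_II).
    Returns ``(omega, n_negative)``; negative weights flag influential
    auxiliary values, which rejective sampling makes less frequent.
    """
    xsel = "x" if x is None else x
    XI = _sample_values(sampleI, xsel)
    XII = _sample_values(sampleII, xsel)
    xbarI = XI.mean(axis=0)
    xbarII = XII.mean(axis=0)
    Xc = XII - xbarII
    A = Xc.T @ Xc / XII.shape[0]
    _check_invertible(A)
    omega = 1.0 + Xc @ np.linalg.solve(A, xbarI - xbarII)
    return omega, int(np.sum(omega < 0))
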