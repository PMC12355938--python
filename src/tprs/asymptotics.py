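"""The truncated balance limit law and closed-form asymptotic variances.

Under rejective sampling the balanced error component converges to

    L_{p,gamma^2} = chi_{p,gamma} * S * Gamma_p^{1/2},

the product of a chi_p variable conditioned on chi^2_p <= gamma^2, a random
sign, and the first coordinate of a uniform point on the unit sphere in R^p
(Gamma_p ~ Beta(1/2, (p-1)/2); for p = 1 the sphere is {-1, +1} so Gamma_1 is
the point mass at 1 and L is a standard normal truncated to (-gamma, gamma)).
Its variance is the chi-square CDF ratio

    v_{p,gamma^2} = P(chi^2_{p+2} <= gamma^2) / P(chi^2_p <= gamma^2) <= 1.

The full limiting law of the sample-mean error is a mixture
a*L + b*Z1 + c*Z2 with independent standard normals Z1, Z2; its quantiles are
computed by Monte Carlo with a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "v_p_gamma",
    "sample_L",
    "MixtureLaw",
    "mixture_quantile",
    "theoretical_reduction",
    "asymptotic_variance_srs",
]

_DEFAULT_MC_DRAWS = 2_000_000
_DEFAULT_MC_SEED = 20_230_915  # fixed so reported quantiles are reproducible


def v_p_gamma(p: int, gamma2: float) -> float:
    """Variance of L_{p,gamma^2}: P(chi^2_{p+2} <= gamma^2) / P(chi^2_p <= gamma^2).

    Returns 1 for gamma^2 = inf (no truncation).  The value lies in (0, 1].
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if not gamma2 > 0:
        raise ValueError("gamma2 must be positive")
    if np.isinf(gamma2):
        return 1.0
    num = stats.chi2.cdf(gamma2, df=p + 2)
    den = stats.chi2.cdf(gamma2, df=p)
    return float(num / den)


def sample_L(p: int, gamma2: float, n_draws: int, seed) -> np.ndarray:
    """Draws of L_{p,gamma^2} by inverse-CDF truncation.

    chi_{p,gamma} is drawn by mapping a uniform on (0, F_{chi^2_p}(gamma^2))
    through the chi-square quantile function; the sign S is uniform on
    {-1, +1}; Gamma_p ~ Beta(1/2, (p-1)/2), degenerate at 1 when p = 1.
    Stream consumption order: n uniforms (radius), n uniforms (sign), then n
    beta draws if p > 1.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    rng = np.random.default_rng(seed)
    cap = stats.chi2.cdf(gamma2, df=p) if np.isfinite(gamma2) else 1.0
    u = rng.random(n_draws) * cap
    chi = np.sqrt(stats.chi2.ppf(u, df=p))
    s = np.where(rng.random(n_draws) < 0.5, -1.0, 1.0)
    if p == 1:
        gam = 1.0
    else:
        gam = rng.beta(0.5, (p - 1) / 2.0, size=n_draws)
    return chi * s * np.sqrt(gam)


@dataclass
class MixtureLaw:
    """The law of a*L_{p,gamma^2} + b*Z1 + c*Z2 with quantiles by Monte Carlo.

    ``coeffs = (a, b, c)`` are the nonnegative scales of the truncated
    component and the two independent standard normals.  Draws are generated
    once per instance with ``mc_seed`` and cached; quantiles interpolate
    linearly between order statistics.
    """

    p: int
    gamma2: float
    coeffs: Tuple[float, float, float]
    mc_draws: int = _DEFAULT_MC_DRAWS
    mc_seed: int = _DEFAULT_MC_SEED
    _cache: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        a, b, c = self.coeffs
        if a < 0 or b < 0 or c < 0:
            raise ValueError("mixture coefficients must be nonnegative")
        if a == 0 and b == 0 and c == 0:
            raise ValueError("degenerate law: all mixture coefficients are zero")

    def draws(self) -> np.ndarray:
        if self._cache is None:
            a, b, c = self.coeffs
            rng = np.random.default_rng(self.mc_seed)
            out = np.zeros(self.mc_draws)
            if a > 0:
                out += a * sample_L(self.p, self.gamma2, self.mc_draws, rng)
            if b > 0:
                out += b * rng.standard_normal(self.mc_draws)
            if c > 0:
                out += c * rng.standard_normal(self.mc_draws)
            self._cache = out
        return self._cache

    def quantile(self, alpha) -> np.ndarray:
        if np.any((np.asarray(alpha) <= 0) | (np.asarray(alpha) >= 1)):
            raise ValueError("alpha must be in (0, 1)")
        return np.quantile(self.draws(), alpha)


def mixture_quantile(law: MixtureLaw, alpha):
    """100*alpha-th quantile of the mixture law (Monte Carlo)."""
    q = law.quantile(alpha)
    return float(q) if np.isscalar(alpha) else q


class MixtureBasis:
    """Cached (L, Z1, Z2) draws reused across many coefficient triples.

    Confidence intervals plug estimated variance components into the mixture
    law, so replication studies need its quantiles for thousands of slightly
    different coefficients.  Sharing one set of base draws (common random
    numbers) makes those quantiles a cheap vectorized combination instead of
    a fresh simulation each time.
    """

    def __init__(self, p: int, gamma2: float, n_draws: int = 200_000,
                 seed: int = _DEFAULT_MC_SEED):
        rng = np.random.default_rng(seed)
        self.p = p
        self.gamma2 = gamma2
        self.L = sample_L(p, gamma2, n_draws, rng)
        self.Z1 = rng.standard_normal(n_draws)
        self.Z2 = rng.standard_normal(n_draws)

    def quantile(self, a: float, b: float, c: float, alpha):
        return np.quantile(a * self.L + b * self.Z1 + c * self.Z2, alpha)


def theoretical_reduction(p: int, gamma2: float, R2: float,
                          fII_I: float, fI_0: float) -> float:
    """Percentage reduction in asymptotic design variance of the phase-II mean.

    100 * (1 - f_II,I) / (1 - f_II,I * f_I,0) * (1 - v_{p,gamma^2}) * R^2,
    zero in the census case f_II,I * f_I,0 = 1.
    """
    if not 0 <= R2 <= 1:
        raise ValueError("R2 must be in [0, 1]")
    for f in (fII_I, fI_0):
        if not 0 <= f <= 1:
            raise ValueError("sampling fractions must be in [0, 1]")
    if fII_I * fI_0 == 1:
        return 0.0
    v = v_p_gamma(p, gamma2)
    return float(100.0 * (1 - fII_I) / (1 - fII_I * fI_0) * (1 - v) * R2)


def asymptotic_variance_srs(p: int, gamma2: float, R2: float, Vyy: float,
                            fII_I: float, fI_0: float) -> Tuple[float, float]:
    """Asymptotic variances of the sqrt(n_II)-scaled estimators under two-phase SRS.

    Returns ``(var_yII, var_yreg)`` where

        var_yII  = [ (1 - f_II,I) {1 - (1 - v_{p,gamma^2}) R^2}
                     + f_II,I (1 - f_I,0) ] V_yy
        var_yreg = f_II,I (1 - f_I,0) V_yy + (1 - f_II,I) V_ee,

    with V_ee = V_yy (1 - R^2).  The regression variance does not depend on
    gamma^2; as gamma^2 -> 0 the sample-mean variance approaches it.
    """
    if not 0 <= R2 <= 1:
        raise ValueError("R2 must be in [0, 1]")
    v = v_p_gamma(p, gamma2)
    var_yII = ((1 - fII_I) * (1 - (1 - v) * R2) + fII_I * (1 - fI_0)) * Vyy
    Vee = Vyy * (1 - R2)
    var_yreg = fII_I * (1 - fI_0) * Vyy + (1 - fII_I) * Vee
    return float(var_yII), float(var_yreg)
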