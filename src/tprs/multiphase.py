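"""Three-phase rejective sampling with block-orthogonalized auxiliaries.

The design measures a cheap auxiliary x on a large phase-I SRS, draws the
phase-II sample by Poisson sampling proportional to x with rejection on
x-balance, then measures the second-tier auxiliaries z on phase II,
residualizes them on x (block Gram-Schmidt: a_i = z_i - zbar_II -
(x_i - xbar_II)^T beta_zx,II), and draws the phase-III sample by Poisson
sampling with rejection on the balance of the residualized block a.
Balancing a alone at phase III is the default because x is already balanced
at phase II; joint (x, a) balancing is available by flag.

Analytic three-phase variance estimators are out of scope; the replication
harness provides Monte Carlo calibration for three-phase uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .designs import (
    PhaseSample,
    Poisson,
    RejectionRule,
    SRS,
    rejective_draw,
)
from .estimators import _sample_values, hajek_mean
from .population import FinitePopulation

__all__ = ["ThreePhasePlan", "residualize", "draw_three_phase", "three_phase_estimates"]


@dataclass
class ThreePhasePlan:
    """Sizes, thresholds and options for a three-phase rejective design."""

    nI: int
    expected_nII: float
    expected_nIII: float
    gamma1_2: float = np.inf
    gamma2_2: float = np.inf
    balance_mode: str = "residual"  # or "joint" to balance (x, a) at phase III
    max_draws: int = 1_000_000

    def __post_init__(self) -> None:
        if not (self.gamma1_2 > 0 and self.gamma2_2 > 0):
            raise ValueError("thresholds must be positive (or inf)")
        if self.balance_mode not in ("residual", "joint"):
            raise ValueError("balance_mode must be 'residual' or 'joint'")


def residualize(sampleII: PhaseSample, z="z", x="x") -> Tuple[np.ndarray, np.ndarray, dict]:
    """Residualize z on x within the phase-II sample (pi*-weighted).

    Returns ``(a, beta_zx, centers)`` where ``a_i = z_i - zbar_II -
    (x_i - xbar_II)^T beta_zx`` for i in phase II; the pi*-weighted mean of a
    is zero and a is pi*-weighted-orthogonal to x by construction.
    ``centers`` holds the weighted means so that a can be evaluated for any
    subset of phase-II units later.
    """
    Z = _sample_values(sampleII, z)
    X = _sample_values(sampleII, x)
    w = sampleII.weights()
    w = w / w.sum()
    zbar = w @ Z
    xbar = w @ X
    Xc = X - xbar
    A = (Xc * w[:, None]).T @ Xc
    if np.linalg.cond(A) > 1e12:
        raise np.linalg.LinAlgError("singular x cross-moment matrix in residualize")
    beta_zx = np.linalg.solve(A, (Xc * w[:, None]).T @ (Z - zbar))  # (p, q2)
    a = (Z - zbar) - Xc @ beta_zx
    return a, beta_zx, {"zbar": zbar, "xbar": xbar}


def _residual_values(pop: FinitePopulation, beta_zx, centers) -> np.ndarray:
    """Evaluate the phase-II residualization rule at every population unit."""
    Z = pop.values("z")
    X = pop.values("x")
    return (Z - centers["zbar"]) - (X - centers["xbar"]) @ beta_zx


def _feasible_size(size: np.ndarray, parent_ids: np.ndarray, expected_n: float,
                   cap: float = 0.999) -> Tuple[np.ndarray, float]:
    """Shift a size measure so every pps inclusion probability stays <= cap.

    pi_i = expected_n * s_i / sum(s) over the parent; adding a constant
    flattens the measure toward equal probabilities, which is always feasible
    when the expected size is below the parent size.  Returns the adjusted
    full-length measure and the shift applied (0 when none is needed).
    """
    s = size[parent_ids]
    M = s.size
    if expected_n > cap * M:
        raise ValueError("expected size exceeds parent size")
    need = expected_n * s.max() - cap * s.sum()
    if need <= 0:
        return size, 0.0
    delta = need / (cap * M - expected_n)
    return size + delta, float(delta)


def draw_three_phase(pop: FinitePopulation, plan: ThreePhasePlan, seed):
    """Execute the three-phase rejective design.

    Returns ``(sampleI, sampleII, sampleIII, info)`` where ``info`` carries
    the balance results of both rejective phases, the residualization rule,
    and any positivity shift applied to the phase-III size measure.
    """
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = ss.spawn(3)
    sampleI = SRS(plan.nI).draw(pop, np.random.default_rng(s1))

    ruleII = RejectionRule(gamma2=plan.gamma1_2, balance_columns="x",
                           variance_mode="general", max_draws=plan.max_draws)
    sizeII, shiftII = _feasible_size(pop.x[:, 0], sampleI.selected, plan.expected_nII)
    try:
        sampleII, balII = rejective_draw(
            sampleI, Poisson(plan.expected_nII, sizeII), ruleII, s2)
    except RuntimeError as err:
        raise RuntimeError(f"phase II acceptance failure: {err}") from err

    a_II, beta_zx, centers = residualize(sampleII)
    a_pop = _residual_values(pop, beta_zx, centers)

    # phase-III size measure: row sums of z, shifted positive if needed and
    # flattened so every inclusion probability is feasible
    size = pop.z.sum(axis=1).astype(float)
    shift = 0.0
    smin = size[sampleII.selected].min()
    if smin <= 0:
        shift = -smin + 1e-3 * max(1.0, np.abs(size[sampleII.selected]).max())
        size = size + shift
    size, shiftIII = _feasible_size(size, sampleII.selected, plan.expected_nIII)
    shift += shiftIII

    if plan.balance_mode == "residual":
        bal_cols = a_pop
    else:
        bal_cols = np.column_stack([pop.x, a_pop])
    ruleIII = RejectionRule(gamma2=plan.gamma2_2, balance_columns=bal_cols,
                            variance_mode="general", max_draws=plan.max_draws)
    try:
        sampleIII, balIII = rejective_draw(
            sampleII, Poisson(plan.expected_nIII, size), ruleIII, s3)
    except RuntimeError as err:
        raise RuntimeError(f"phase III acceptance failure: {err}") from err

    info = {
        "balance_II": balII,
        "balance_III": balIII,
        "beta_zx": beta_zx,
        "centers": centers,
        "size_shift": shift,
        "sizeII_shift": shiftII,
    }
    return sampleI, sampleII, sampleIII, info


def three_phase_estimates(samples, x="x", z="z", y="y",
                          info: Optional[dict] = None) -> Tuple[float, float]:
    """Triple-expansion and regression estimators from a three-phase sample.

    ``y_III`` is the Hajek mean with weights 1/pi*** (product of the three
    conditional inclusion probabilities).  ``y_III_reg`` adjusts it by both
    auxiliary blocks:

        y_III - (xbar_III - xbar_I)^T b_x - (abar_III - abar_II)^T b_a,

    with (b_x, b_a) from one pi***-weighted regression of y on the
    orthogonalized blocks (x, a) in phase III.
    """
    sampleI, sampleII, sampleIII = samples
    if sampleIII.n == 0:
        raise ValueError("empty phase-III sample")
    pop = sampleIII.population
    if info is not None:
        beta_zx, centers = info["beta_zx"], info["centers"]
    else:
        _, beta_zx, centers = residualize(sampleII, z, x)
    a_pop = _residual_values(pop, beta_zx, centers)

    y_III = hajek_mean(sampleIII, y)

    X3 = _sample_values(sampleIII, x)
    A3 = a_pop[sampleIII.selected]
    Y3 = _sample_values(sampleIII, y).ravel()
    w3 = sampleIII.weights()
    w3 = w3 / w3.sum()
    G = np.column_stack([X3, A3])
    gbar = w3 @ G
    Gc = G - gbar
    M = (Gc * w3[:, None]).T @ Gc
    if np.linalg.cond(M) > 1e12:
        raise np.linalg.LinAlgError("singular (x, a) cross-moment matrix")
    coef = np.linalg.solve(M, (Gc * w3[:, None]).T @ (Y3 - w3 @ Y3))
    p = X3.shape[1]
    b_x, b_a = coef[:p], coef[p:]

    xbar_I = hajek_mean(sampleI, x)
    xbar_I = np.atleast_1d(xbar_I)
    xbar_III = w3 @ X3
    wII = sampleII.weights()
    a_II = a_pop[sampleII.selected]
    abar_II = wII @ a_II / wII.sum()
    abar_III = w3 @ A3

    y_reg = y_III - (xbar_III - xbar_I) @ b_x - (abar_III - abar_II) @ b_a
    return float(y_III), float(y_reg)
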