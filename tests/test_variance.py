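from itertools import combinations
from math import comb

import numpy as np
import pytest

import tprs
from tprs.designs import RejectionRule, SRS, rejective_draw
from tprs.variance import (
    components_variance,
    confidence_interval,
    ht_components,
    residual_variance_hat,
    sample_cov_hat,
    syg_components,
    var_hat_srs,
)

from conftest import manual_phase2


def test_sample_cov_hat_hand_cases(two_phase_srs, pop_beta2):
    _, sII = two_phase_srs
    const = np.full(pop_beta2.N, 2.0)
    assert sample_cov_hat(sII, const)[0, 0] == 0.0

    pop = tprs.FinitePopulation(unit_id=np.arange(3), x=np.zeros(3), y=[1.0, 2.0, 3.0])
    census = tprs.draw_srs(tprs.draw_srs(pop, 3, seed=0), 3, seed=0)
    assert sample_cov_hat(census, "y")[0, 0] == pytest.approx(1.0)

    # matches a direct divisor-(n-1) recomputation
    y = pop_beta2.y[sII.selected]
    assert sample_cov_hat(sII, "y")[0, 0] == pytest.approx(
        ((y - y.mean()) ** 2).sum() / (sII.n - 1), rel=1e-12
    )


def test_residual_variance_hat(two_phase_srs, pop_beta2):
    sI, sII = two_phase_srs
    # exact linear y: zero residual variance, R^2 at the clip boundary
    yl = 0.5 + 2.0 * pop_beta2.x[:, 0]
    Vee, Vyy, R2 = residual_variance_hat(sII, "x", yl)
    assert Vee == pytest.approx(0.0, abs=1e-20)
    assert R2 == pytest.approx(1.0, abs=1e-9)

    # 5-point toy vs an independent least-squares residual computation
    pop = tprs.FinitePopulation(
        unit_id=np.arange(5), x=np.array([0.0, 1.0, 2.0, 3.0, 4.0]),
        y=np.array([1.0, 1.5, 3.5, 3.0, 5.5]),
    )
    census = tprs.draw_srs(tprs.draw_srs(pop, 5, seed=0), 5, seed=0)
    Vee5, Vyy5, R25 = residual_variance_hat(census, "x", "y")
    slope, intercept = np.polyfit(pop.x[:, 0], pop.y, 1)
    rss = ((pop.y - intercept - slope * pop.x[:, 0]) ** 2).sum()
    assert Vee5 == pytest.approx(rss / (5 - 1 - 1), rel=1e-10)
    Vxx = np.var(pop.x[:, 0], ddof=1)
    assert Vyy5 == pytest.approx(slope**2 * Vxx + rss / 3, rel=1e-10)
    r2_direct = np.corrcoef(pop.x[:, 0], pop.y)[0, 1] ** 2
    assert R25 == pytest.approx(r2_direct, rel=1e-10)

    with pytest.raises(ValueError, match="degrees of freedom"):
        tiny = manual_phase2(tprs.draw_srs(pop, 5, seed=0), [0, 1])
        residual_variance_hat(tiny, "x", "y")


def test_var_hat_srs_structural_limits(pop_beta2):
    # census phase I: the regression variance reduces to (1-f) Vee / nII
    sI = tprs.draw_srs(pop_beta2, pop_beta2.N, seed=0)
    sII = tprs.draw_srs(sI, 200, seed=1)
    comps, var_reg = var_hat_srs(sI, sII, pop_beta2.N, np.inf, which="regression")
    f = 200 / pop_beta2.N
    assert var_reg == pytest.approx((1 - f) * comps.Vee_hat / 200, rel=1e-12)

    # gamma^2 = inf: the mean variance drops the R^2 term entirely
    sIb = tprs.draw_srs(pop_beta2, 1000, seed=2)
    sIIb = tprs.draw_srs(sIb, 200, seed=3)
    compsb, var_mean = var_hat_srs(sIb, sIIb, pop_beta2.N, np.inf, which="mean")
    fII, fI = 200 / 1000, 1000 / pop_beta2.N
    expected = ((1 - fII) + fII * (1 - fI)) * compsb.Vyy_hat / 200
    assert var_mean == pytest.approx(expected, rel=1e-12)


def test_ht_components_match_srs_closed_form(pop_beta2):
    """n_II^{-1}(V2+V3) agrees with the closed-form regression variance."""
    sI = tprs.draw_srs(pop_beta2, 1000, seed=5)
    sII = tprs.draw_srs(sI, 200, seed=6)
    comps = ht_components(sI, sII, popN=pop_beta2.N)
    _, var13 = var_hat_srs(sI, sII, pop_beta2.N, np.inf, which="regression")
    assert components_variance(comps, "regression") == pytest.approx(var13, rel=0.10)
    # beta_hat = 0 gives V1 = 0
    comps0 = ht_components(sI, sII, beta_hat=np.zeros(1), popN=pop_beta2.N)
    assert comps0.V1_hat == 0.0


def test_ht_double_sum_unbiased_by_enumeration():
    """E over all two-phase draws of the lifted pairwise sums recovers the
    exact design variance of the phase-I mean (known-mean centering)."""
    rng = np.random.default_rng(3)
    N, nI, nII = 6, 4, 2
    pop = tprs.FinitePopulation(
        unit_id=np.arange(N), x=rng.normal(size=N), y=rng.normal(size=N)
    )
    ybar0 = pop.y.mean()
    # exact design variance of the phase-I sample mean under SRS
    Vyy0 = np.var(pop.y, ddof=1)
    exact = (1 / nI - 1 / N) * Vyy0

    total = 0.0
    pA = 1 / comb(N, nI)
    pB = 1 / comb(nI, nII)
    for A in combinations(range(N), nI):
        sI = manual_phase2(
            tprs.draw_srs(pop, N, seed=0), np.array(A),
        )
        for B in combinations(A, nII):
            sII = manual_phase2(sI, np.array(B))
            # the phase-I double sum with known-mean centering is exactly
            # design-unbiased; this validates the pair-probability plumbing
            yc = pop.y - ybar0
            from tprs.designs import pair_inclusion_matrix

            piI = pair_inclusion_matrix(sI, sII.selected)
            piII = pair_inclusion_matrix(sII, sII.selected)
            piI_i = np.diag(piI)
            W3 = (piI - np.outer(piI_i, piI_i)) / (np.outer(piI_i, piI_i) * piI * piII)
            z = yc[sII.selected]
            raw = nII / N**2 * z @ W3 @ z
            total += pA * pB * raw / nII
    assert total == pytest.approx(exact, rel=1e-10)


def test_syg_components_nonnegative_and_close_to_ht(pop_beta2):
    sI = tprs.draw_srs(pop_beta2, 1000, seed=9)
    rng_seeds = range(40)
    for r in rng_seeds:
        sII = tprs.draw_srs(sI, 100, seed=100 + r)
        syg = syg_components(sI, sII, popN=pop_beta2.N)
        assert syg.V2_hat >= 0 and syg.V3_hat >= 0
    sII = tprs.draw_srs(sI, 200, seed=999)
    ht = ht_components(sI, sII, popN=pop_beta2.N)
    syg = syg_components(sI, sII, popN=pop_beta2.N)
    assert syg.V2_hat == pytest.approx(ht.V2_hat, rel=0.15)
    assert syg.V3_hat == pytest.approx(ht.V3_hat, rel=0.15)

    # constant residuals: V2 = 0 (exactly linear outcome)
    yl = 1.0 + 2.0 * pop_beta2.x[:, 0]
    syg0 = syg_components(sI, sII, "x", yl, popN=pop_beta2.N)
    assert syg0.V2_hat == pytest.approx(0.0, abs=1e-18)


def test_syg_rejects_poisson_phase(pop_beta2):
    sI = tprs.draw_srs(pop_beta2, 500, seed=0)
    sII = tprs.draw_poisson(sI, 50, np.ones(pop_beta2.N), seed=1)
    with pytest.raises(ValueError, match="fixed-size"):
        syg_components(sI, sII, popN=pop_beta2.N)


def test_confidence_interval_normal_limit(pop_beta2):
    """R^2=0, gamma^2=inf: the mean interval equals the normal interval."""
    sI = tprs.draw_srs(pop_beta2, 1000, seed=11)
    sII = tprs.draw_srs(sI, 200, seed=12)
    comps, var = var_hat_srs(sI, sII, pop_beta2.N, np.inf, which="mean")
    comps.R2_hat = 0.0
    point = float(pop_beta2.y[sII.selected].mean())
    res = confidence_interval(point, comps, 0.05, "mean", "srs", mc_draws=400_000)
    fII, fI = 200 / 1000, 1000 / pop_beta2.N
    sd = np.sqrt(((1 - fII) + fII * (1 - fI)) * comps.Vyy_hat / 200)
    assert res.ci[0] == pytest.approx(point - 1.959964 * sd, abs=0.02 * sd)
    assert res.ci[1] == pytest.approx(point + 1.959964 * sd, abs=0.02 * sd)
    assert res.ci[0] <= res.point <= res.ci[1]


def test_confidence_interval_alpha_half_degenerates_to_point(pop_beta2):
    sI = tprs.draw_srs(pop_beta2, 1000, seed=13)
    sII = tprs.draw_srs(sI, 200, seed=14)
    comps, _ = var_hat_srs(sI, sII, pop_beta2.N, 0.01, which="mean")
    point = float(pop_beta2.y[sII.selected].mean())
    res = confidence_interval(point, comps, alpha=0.5, estimator_kind="mean",
                              path="srs", mc_draws=200_000)
    # q(0.25) and q(0.75) are symmetric; the interval straddles the point
    width = res.ci[1] - res.ci[0]
    assert res.ci[0] <= point <= res.ci[1]
    assert width < 2 * np.sqrt(res.variance)


def test_variance_estimator_tracks_monte_carlo_variance():
    """Mean of the variance estimates matches the empirical estimator variance."""
    pop = tprs.make_simulation_population(20_000, 1.0, seed=51)
    points, ves = [], []
    for r in range(600):
        sI = tprs.draw_srs(pop, 1000, seed=80_000 + r)
        sII, _ = rejective_draw(sI, SRS(100), RejectionRule(gamma2=0.01), seed=r)
        points.append(pop.y[sII.selected].mean())
        _, v = var_hat_srs(sI, sII, pop.N, 0.01, which="mean")
        ves.append(v)
    mc_var = np.var(points, ddof=1)
    assert np.mean(ves) == pytest.approx(mc_var, rel=0.25)
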