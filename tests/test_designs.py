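from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats

import tprs
from tprs.designs import (
    InfeasibleDesignError,
    Poisson,
    RejectionRule,
    SRS,
    SingularBalanceMetricError,
    balance_statistic,
    gamma_from_acceptance,
    joint_inclusion,
    pair_inclusion_matrix,
    phase_design_cov,
    rejective_draw,
)
from tprs.harness import enumerate_phase2_given

from conftest import manual_phase2


# --------------------------------------------------------------------------
# basic samplers


def test_srs_census_and_closed_form_probabilities(pop_tiny):
    census = tprs.draw_srs(pop_tiny, 8, seed=0)
    assert np.all(census.cond_pi == 1.0)
    assert np.array_equal(np.sort(census.selected), np.arange(8))

    pop = tprs.make_simulation_population(10, 1.0, seed=0)
    s = tprs.draw_srs(pop, 4, seed=1)
    assert np.all(s.cond_pi == pytest.approx(0.4))
    assert s.n == 4

    with pytest.raises(InfeasibleDesignError):
        tprs.draw_srs(pop, 11, seed=0)


def test_srs_selection_frequencies_uniform():
    """Per-unit selection frequency over many replicates matches n/N."""
    pop = tprs.make_simulation_population(30, 1.0, seed=0)
    n, reps = 6, 20_000
    rng = np.random.default_rng(5)
    counts = np.zeros(30)
    sampler = SRS(n)
    for _ in range(reps):
        counts[sampler.draw(pop, rng).selected] += 1
    freq = counts / reps
    se = np.sqrt(0.2 * 0.8 / reps)
    assert np.all(np.abs(freq - n / 30) < 5 * se)


def test_poisson_probabilities_and_realized_size():
    pop = tprs.make_simulation_population(200, 1.0, seed=0)
    # equal size measures: pi_i = m / parent size
    s = tprs.draw_poisson(pop, 40, np.ones(200), seed=3)
    assert np.all(s.cond_pi == pytest.approx(0.2))

    rng = np.random.default_rng(9)
    sampler = Poisson(40, np.ones(200))
    sizes = np.array([sampler.draw(pop, rng).n for _ in range(4000)])
    se = np.sqrt(200 * 0.2 * 0.8 / 4000)
    assert abs(sizes.mean() - 40) < 5 * se

    # a unit with pi > 1 is an infeasible design, not a silent clip
    measure = np.ones(200)
    measure[0] = 50.0
    with pytest.raises(InfeasibleDesignError):
        tprs.draw_poisson(pop, 40, measure, seed=0)


def test_stratified_probabilities_and_enumeration():
    pop = tprs.make_simulation_population(5, 1.0, seed=0)
    labels = np.array([0, 0, 0, 1, 1])
    s = tprs.draw_stratified(pop, labels, {0: 2, 1: 1}, seed=2)
    got = dict(zip(s.selected.tolist(), s.cond_pi.tolist()))
    for uid, pi in got.items():
        assert pi == pytest.approx(2 / 3 if labels[uid] == 0 else 1 / 2)

    # every within-stratum subset is equiprobable: chi-square GOF on
    # exhaustively enumerated outcomes
    from tprs.designs import Stratified

    sampler = Stratified(labels, {0: 2, 1: 1})
    rng = np.random.default_rng(17)
    reps = 6000
    keys = {}
    for _ in range(reps):
        draw = sampler.draw(pop, rng)
        keys[tuple(draw.selected)] = keys.get(tuple(draw.selected), 0) + 1
    n_outcomes = comb(3, 2) * comb(2, 1)
    assert len(keys) == n_outcomes
    observed = np.array(list(keys.values()))
    _, pval = stats.chisquare(observed)
    assert pval > 0.001


# --------------------------------------------------------------------------
# second-order inclusion probabilities


def test_joint_inclusion_closed_forms(pop_tiny):
    sI = tprs.draw_srs(pop_tiny, 4, seed=0)
    i, j = sI.selected[0], sI.selected[1]
    assert joint_inclusion(sI, i, j) == pytest.approx(4 * 3 / (8 * 7))
    assert joint_inclusion(sI, i, i) == pytest.approx(0.5)

    pop = tprs.make_simulation_population(10, 1.0, seed=0)
    sp = tprs.draw_poisson(pop, 3, np.arange(1.0, 11.0), seed=4)
    if sp.n >= 2:
        a, b = sp.selected[0], sp.selected[1]
        assert joint_inclusion(sp, a, b) == pytest.approx(
            joint_inclusion(sp, a, a) * joint_inclusion(sp, b, b)
        )


def test_srs_pair_probability_sum_identity_by_enumeration():
    """sum_{j != i} pi_ij = (n-1) pi_i, exactly, via full enumeration (M=6, n=3)."""
    M, n = 6, 3
    pop = tprs.make_simulation_population(M, 1.0, seed=0)
    s = tprs.draw_srs(pop, n, seed=1)
    # enumeration oracle for pi_ij
    count_pair = np.zeros((M, M))
    for subset in combinations(range(M), n):
        for a in subset:
            for b in subset:
                count_pair[a, b] += 1
    pi_enum = count_pair / comb(M, n)
    for i in range(M):
        row = sum(joint_inclusion(s, i, j) for j in range(M) if j != i)
        assert row == pytest.approx((n - 1) * (n / M), abs=1e-12)
        for j in range(M):
            assert joint_inclusion(s, i, j) == pytest.approx(pi_enum[i, j], abs=1e-12)
    mat = pair_inclusion_matrix(s, np.arange(M))
    np.testing.assert_allclose(mat, pi_enum, atol=1e-12)


def test_phase_design_cov_matches_brute_force_double_sum(pop_tiny):
    """The linear-cost Eq-style covariance equals the explicit pairwise sum."""
    sI = tprs.draw_srs(pop_tiny, 6, seed=3)
    sII = tprs.draw_srs(sI, 3, seed=4)
    X = pop_tiny.x[sI.selected]
    got = phase_design_cov(sII, X)
    # brute force over all parent pairs
    ids = sI.selected
    pimat = pair_inclusion_matrix(sII, ids)
    pi = np.diag(pimat)
    pistar = sI.cum_pistar * pi
    w = 1.0 / sI.cum_pistar
    xc = (X - w @ X / w.sum()).ravel()
    brute = 0.0
    for a in range(ids.size):
        for b in range(ids.size):
            delta = pimat[a, b] - pi[a] * pi[b]
            brute += delta / (pistar[a] * pistar[b]) * xc[a] * xc[b]
    brute /= pop_tiny.N**2
    assert got[0, 0] == pytest.approx(brute, rel=1e-12)


# --------------------------------------------------------------------------
# balance statistic


def test_balance_statistic_hand_value(pop_tiny):
    pop = tprs.FinitePopulation(
        unit_id=np.arange(4), x=np.array([1.0, 2.0, 3.0, 5.0]), y=np.zeros(4)
    )
    sI = tprs.draw_srs(pop, 4, seed=0)
    sII = manual_phase2(sI, [0, 1])
    res = balance_statistic(sII, sI, RejectionRule(gamma2=np.inf))
    # xbar_I=2.75, xbar_II=1.5, V_xx,I=35/12, factor (1/2 - 1/4)
    assert res.Q == pytest.approx(1.5625 / (0.25 * 35 / 12), rel=1e-12)

    # exact balance gives Q = 0
    pop2 = tprs.FinitePopulation(
        unit_id=np.arange(4), x=np.array([1.0, 3.0, 1.0, 3.0]), y=np.zeros(4)
    )
    sI2 = tprs.draw_srs(pop2, 4, seed=0)
    sII2 = manual_phase2(sI2, [0, 1])
    assert balance_statistic(sII2, sI2, RejectionRule(gamma2=np.inf)).Q == pytest.approx(0.0)


def test_balance_statistic_singular_metric_is_hard_error():
    pop = tprs.FinitePopulation(
        unit_id=np.arange(4), x=np.full(4, 2.0), y=np.zeros(4)
    )
    sI = tprs.draw_srs(pop, 4, seed=0)
    sII = manual_phase2(sI, [0, 1])
    with pytest.raises(SingularBalanceMetricError):
        balance_statistic(sII, sI, RejectionRule(gamma2=np.inf))


def test_balance_statistic_null_distribution_chisq(pop_beta2):
    """Without rejection, Q over phase-II draws is asymptotically chi^2_1 (KS)."""
    sI = tprs.draw_srs(pop_beta2, 5000, seed=3)
    rng = np.random.default_rng(12)
    sampler = SRS(200)
    rule = RejectionRule(gamma2=np.inf)
    Q = np.array(
        [balance_statistic(sampler.draw(sI, rng), sI, rule).Q for _ in range(2000)]
    )
    _, pval = stats.kstest(Q, stats.chi2(df=1).cdf)
    assert pval > 0.001


# --------------------------------------------------------------------------
# rejective draw


def test_rejective_draw_accepts_immediately_at_infinite_threshold(pop_beta2):
    sI = tprs.draw_srs(pop_beta2, 500, seed=1)
    _, bal = rejective_draw(sI, SRS(50), RejectionRule(gamma2=np.inf), seed=2)
    assert bal.draws_used == 1 and bal.accepted


def test_rejective_draw_mean_draw_count_matches_chisq_rate(pop_beta2):
    """Mean draws at gamma^2=0.01 is near 1/P(chi^2_1 <= 0.01) ~ 12.6."""
    sI = tprs.draw_srs(pop_beta2, 2000, seed=1)
    rule = RejectionRule(gamma2=0.01)
    draws = []
    for r in range(500):
        _, bal = rejective_draw(sI, SRS(100), rule, seed=1000 + r)
        draws.append(bal.draws_used)
    draws = np.asarray(draws)
    expected = 1.0 / stats.chi2.cdf(0.01, df=1)
    # geometric draw count: sd ~ expected; 5-SE band over 500 replicates
    assert abs(draws.mean() - expected) < 5 * draws.std(ddof=1) / np.sqrt(500)


def test_rejective_draw_matches_enumerated_conditional_law(pop_tiny):
    """Accepted-sample frequencies match the exact conditional law (chi^2 GOF)."""
    sI = tprs.draw_srs(pop_tiny, 5, seed=6)
    gamma2 = 1.0
    oracle = enumerate_phase2_given(pop_tiny, sI.selected, 2, gamma2)
    probs = {tuple(b): p for b, p in zip(oracle.B, oracle.prob_cond) if p > 0}
    rule = RejectionRule(gamma2=gamma2)
    counts = {k: 0 for k in probs}
    reps = 10_000
    for r in range(reps):
        sample, _ = rejective_draw(sI, SRS(2), rule, seed=50_000 + r)
        counts[tuple(sample.selected)] += 1
    keys = list(probs)
    observed = np.array([counts[k] for k in keys])
    expected = reps * np.array([probs[k] for k in keys])
    _, pval = stats.chisquare(observed, expected)
    assert pval > 0.001


def test_rejection_reduces_phase2_mean_variance(pop_beta2):
    """Monte Carlo variance of xbar_II (and ybar_II) drops under rejection."""
    sI = tprs.draw_srs(pop_beta2, 1000, seed=21)
    plain, rej = [], []
    for r in range(400):
        s0, _ = rejective_draw(sI, SRS(100), RejectionRule(gamma2=np.inf), seed=3000 + r)
        s1, _ = rejective_draw(sI, SRS(100), RejectionRule(gamma2=0.01), seed=3000 + r)
        plain.append(pop_beta2.y[s0.selected].mean())
        rej.append(pop_beta2.y[s1.selected].mean())
    vp, vr = np.var(plain, ddof=1), np.var(rej, ddof=1)
    assert vr < vp  # R^2=0.8: reduction is large, far beyond MC noise


def test_gamma_from_acceptance():
    assert gamma_from_acceptance(1, 0.5) == pytest.approx(0.454936, abs=1e-4)
    assert gamma_from_acceptance(1, 0.999) > gamma_from_acceptance(1, 0.5)
    # recommended default acceptance rate 0.001
    assert gamma_from_acceptance(1, 0.001) == pytest.approx(
        stats.chi2.ppf(0.001, 1), rel=1e-12
    )
    with pytest.raises(ValueError):
        gamma_from_acceptance(1, 1.5)
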