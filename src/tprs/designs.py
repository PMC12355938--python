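"""Sampling designs, inclusion probabilities, balance statistics and rejection.

A multi-phase sample is a chain of :class:`PhaseSample` objects.  Each phase
records the conditional first-order inclusion probability of its units given
the previous phase, and the cumulative product pi* of those conditional
probabilities, which is the weight base for double-expansion estimation.

Rejective sampling redraws the candidate phase until the Mahalanobis balance
statistic

    Q = (xbar_later - xbar_earlier)^T  V^{-1}  (xbar_later - xbar_earlier)

falls strictly below a threshold gamma^2, where V is the conditional design
variance of the mean difference.  The accepted sample is distributed as the
candidate design conditioned on the balance event {Q < gamma^2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats

from .population import FinitePopulation

__all__ = [
    "PhaseSample",
    "RejectionRule",
    "BalanceResult",
    "SRS",
    "Poisson",
    "Stratified",
    "draw_srs",
    "draw_poisson",
    "draw_stratified",
    "joint_inclusion",
    "pair_inclusion_matrix",
    "phase_design_cov",
    "balance_statistic",
    "rejective_draw",
    "gamma_from_acceptance",
]


class InfeasibleDesignError(ValueError):
    """A requested design has inclusion probabilities outside (0, 1]."""


class SingularBalanceMetricError(np.linalg.LinAlgError):
    """The balance covariance matrix is numerically singular."""


class AcceptanceFailureError(RuntimeError):
    """The rejection loop exhausted its draw budget."""

    def __init__(self, draws: int, accept_rate: float):
        self.draws = draws
        self.accept_rate = accept_rate
        super().__init__(
            f"no candidate accepted in {draws} draws "
            f"(running acceptance rate {accept_rate:.3g}); "
            "consider increasing gamma^2 or max_draws"
        )


# --------------------------------------------------------------------------
# phase samples


@dataclass
class PhaseSample:
    """One phase of a multi-phase sample.

    ``selected`` holds population unit ids (a subset of the parent's ids).
    ``cond_pi`` is the per-unit conditional inclusion probability for this
    phase; ``cum_pistar`` is the elementwise product of conditional
    probabilities across all phases so far (pi*), aligned with ``selected``.
    """

    selected: np.ndarray
    cond_pi: np.ndarray
    cum_pistar: np.ndarray
    design_kind: str
    parent: Union[FinitePopulation, "PhaseSample"]
    phase_index: int
    design_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=np.int64)
        self.cond_pi = np.asarray(self.cond_pi, dtype=float)
        self.cum_pistar = np.asarray(self.cum_pistar, dtype=float)
        if np.any(self.cond_pi <= 0) or np.any(self.cond_pi > 1):
            raise InfeasibleDesignError("cond_pi must lie in (0, 1]")

    @property
    def n(self) -> int:
        return int(self.selected.size)

    @property
    def population(self) -> FinitePopulation:
        node = self.parent
        while isinstance(node, PhaseSample):
            node = node.parent
        return node

    def values(self, which) -> np.ndarray:
        """Population values of the selected units, as an (n, k) array."""
        return self.population.values(which)[self.selected]

    def weights(self) -> np.ndarray:
        """Design weights 1/pi* aligned with ``selected``."""
        return 1.0 / self.cum_pistar


def _parent_ids(parent) -> np.ndarray:
    if isinstance(parent, PhaseSample):
        return parent.selected
    return parent.unit_id


def _parent_pistar(parent) -> np.ndarray:
    if isinstance(parent, PhaseSample):
        return parent.cum_pistar
    return np.ones(parent.N)


def _parent_phase(parent) -> int:
    return parent.phase_index if isinstance(parent, PhaseSample) else 0


# --------------------------------------------------------------------------
# sampler specifications


@dataclass
class SRS:
    """Simple random sampling without replacement of fixed size n."""

    n: int

    def draw(self, parent, rng: np.random.Generator) -> PhaseSample:
        ids = _parent_ids(parent)
        M = ids.size
        if not 1 <= self.n <= M:
            raise InfeasibleDesignError(f"SRS size {self.n} out of range 1..{M}")
        pos = rng.permutation(M)[: self.n]
        pos.sort()
        pi = self.n / M
        cond = np.full(self.n, pi)
        return PhaseSample(
            selected=ids[pos],
            cond_pi=cond,
            cum_pistar=_parent_pistar(parent)[pos] * cond,
            design_kind="srs",
            parent=parent,
            phase_index=_parent_phase(parent) + 1,
            design_info={"n": self.n, "M": M},
        )


@dataclass
class Poisson:
    """Poisson sampling with expected size and a positive size measure.

    Inclusion probabilities are pi_i = expected_n * s_i / sum(s), evaluated
    over the parent units; each unit enters independently.  The realized size
    is random and may be zero (the rejective loop treats an empty candidate
    as rejected).
    """

    expected_n: float
    size_measure: Optional[np.ndarray] = None  # aligned with population ids

    def probabilities(self, parent) -> np.ndarray:
        ids = _parent_ids(parent)
        if self.size_measure is None:
            s = np.ones(ids.size)
        else:
            s = np.asarray(self.size_measure, dtype=float)[ids]
        if np.any(s <= 0):
            raise InfeasibleDesignError("size measure must be strictly positive")
        pi = self.expected_n * s / s.sum()
        if np.any(pi > 1):
            bad = ids[pi > 1]
            raise InfeasibleDesignError(
                f"poisson inclusion probability exceeds 1 for units {bad[:10].tolist()}"
            )
        return pi

    def draw(self, parent, rng: np.random.Generator) -> PhaseSample:
        ids = _parent_ids(parent)
        pi = self.probabilities(parent)
        keep = rng.random(ids.size) < pi
        return PhaseSample(
            selected=ids[keep],
            cond_pi=pi[keep],
            cum_pistar=_parent_pistar(parent)[keep] * pi[keep],
            design_kind="poisson",
            parent=parent,
            phase_index=_parent_phase(parent) + 1,
            design_info={"pi_parent": pi, "M": ids.size},
        ) if keep.any() else PhaseSample(
            selected=ids[:0],
            cond_pi=pi[:0],
            cum_pistar=pi[:0],
            design_kind="poisson",
            parent=parent,
            phase_index=_parent_phase(parent) + 1,
            design_info={"pi_parent": pi, "M": ids.size, "empty": True},
        )


@dataclass
class Stratified:
    """Independent SRS within strata.

    ``labels`` assigns a stratum to every population unit; ``n_per_stratum``
    maps stratum label -> within-stratum sample size.
    """

    labels: np.ndarray  # aligned with population ids
    n_per_stratum: dict

    def draw(self, parent, rng: np.random.Generator) -> PhaseSample:
        ids = _parent_ids(parent)
        lab = np.asarray(self.labels)[ids]
        pistar_parent = _parent_pistar(parent)
        sel_pos, cond = [], []
        m_h, r_h = {}, {}
        for h, r in self.n_per_stratum.items():
            pos_h = np.flatnonzero(lab == h)
            if r > pos_h.size:
                raise InfeasibleDesignError(
                    f"stratum {h!r}: requested {r} > stratum size {pos_h.size}"
                )
            if r < 1:
                raise InfeasibleDesignError(f"stratum {h!r}: requested size < 1")
            take = pos_h[rng.permutation(pos_h.size)[:r]]
            sel_pos.append(take)
            cond.append(np.full(r, r / pos_h.size))
            m_h[h], r_h[h] = int(pos_h.size), int(r)
        pos = np.concatenate(sel_pos)
        order = np.argsort(pos)
        pos, cond = pos[order], np.concatenate(cond)[order]
        return PhaseSample(
            selected=ids[pos],
            cond_pi=cond,
            cum_pistar=pistar_parent[pos] * cond,
            design_kind="stratified",
            parent=parent,
            phase_index=_parent_phase(parent) + 1,
            design_info={"labels": np.asarray(self.labels), "m_h": m_h, "r_h": r_h,
                         "M": ids.size},
        )


def draw_srs(parent, n: int, seed) -> PhaseSample:
    return SRS(n).draw(parent, np.random.default_rng(seed))


def draw_poisson(parent, expected_n: float, size_measure, seed) -> PhaseSample:
    return Poisson(expected_n, size_measure).draw(parent, np.random.default_rng(seed))


def draw_stratified(parent, stratum_labels, per_stratum_n: dict, seed) -> PhaseSample:
    return Stratified(stratum_labels, per_stratum_n).draw(
        parent, np.random.default_rng(seed)
    )


# --------------------------------------------------------------------------
# second-order inclusion probabilities


def joint_inclusion(sample: PhaseSample, i: int, j: int) -> float:
    """Conditional second-order inclusion probability of units i, j for this phase.

    Closed forms: SRS pi_ij = n(n-1)/(M(M-1)) for i != j and n/M on the
    diagonal; Poisson pi_ij = pi_i pi_j (independence); stratified SRS is the
    within-stratum SRS form and the product across strata.
    """
    info = sample.design_info
    kind = sample.design_kind
    if kind == "srs":
        n, M = info["n"], info["M"]
        return n / M if i == j else n * (n - 1) / (M * (M - 1))
    if kind == "poisson":
        pid = {int(u): p for u, p in zip(_parent_ids(sample.parent), info["pi_parent"])}
        return pid[int(i)] if i == j else pid[int(i)] * pid[int(j)]
    if kind == "stratified":
        lab = info["labels"]
        hi, hj = lab[int(i)], lab[int(j)]
        ri, mi = info["r_h"][hi], info["m_h"][hi]
        if i == j:
            return ri / mi
        if hi == hj:
            return ri * (ri - 1) / (mi * (mi - 1))
        rj, mj = info["r_h"][hj], info["m_h"][hj]
        return (ri / mi) * (rj / mj)
    raise ValueError(f"unsupported design kind {kind!r}")


def pair_inclusion_matrix(sample: PhaseSample, ids: np.ndarray) -> np.ndarray:
    """Matrix of conditional pair probabilities pi_ij for the given unit ids.

    The diagonal holds the first-order probabilities.  ``ids`` must be a
    subset of the phase's parent units.
    """
    ids = np.asarray(ids, dtype=np.int64)
    k = ids.size
    info = sample.design_info
    kind = sample.design_kind
    if kind == "srs":
        n, M = info["n"], info["M"]
        out = np.full((k, k), n * (n - 1) / (M * (M - 1)))
        np.fill_diagonal(out, n / M)
        return out
    if kind == "poisson":
        parent_ids = _parent_ids(sample.parent)
        lookup = np.full(int(parent_ids.max()) + 1, np.nan)
        lookup[parent_ids] = info["pi_parent"]
        pi = lookup[ids]
        out = np.outer(pi, pi)
        np.fill_diagonal(out, pi)
        return out
    if kind == "stratified":
        lab = info["labels"][ids]
        r = np.array([info["r_h"][h] for h in lab], dtype=float)
        m = np.array([info["m_h"][h] for h in lab], dtype=float)
        fi = r / m
        out = np.outer(fi, fi)
        same = lab[:, None] == lab[None, :]
        # within-stratum pair probability r(r-1)/(m(m-1)); product across strata
        rr = r[:, None]
        mm = m[:, None]
        out = np.where(same, rr * (rr - 1) / (mm * (mm - 1)), out)
        np.fill_diagonal(out, fi)
        return out
    raise ValueError(f"unsupported design kind {kind!r}")


# --------------------------------------------------------------------------
# conditional design covariance of Hajek phase means (general designs)


def phase_design_cov(sample: PhaseSample, U: np.ndarray, V: Optional[np.ndarray] = None,
                     popN: Optional[int] = None) -> np.ndarray:
    """Conditional design covariance of the phase Hajek means of U and V.

    Computes, over the phase's parent units,

        N^{-2} sum_{i,j} (pi_ij - pi_i pi_j) / (pi*_i pi*_j)
                         (U_i - Ubar)(V_j - Vbar)^T

    with pi the conditional probabilities of this phase, pi* the cumulative
    probability through this phase, and means centered at the parent-phase
    Hajek mean.  Uses the closed-form pair-probability structure of each
    design kind, so the cost is linear in the parent size.

    ``U`` (and ``V``) are arrays over the *parent* units, shape (M, k).
    """
    parent = sample.parent
    ids = _parent_ids(parent)
    M = ids.size
    U = np.atleast_2d(np.asarray(U, float))
    if U.shape[0] != M:
        U = U.T
    V = U if V is None else np.atleast_2d(np.asarray(V, float))
    if V.shape[0] != M:
        V = V.T
    if popN is None:
        popN = sample.population.N
    wpar = 1.0 / _parent_pistar(parent)
    ubar = wpar @ U / wpar.sum()
    vbar = wpar @ V / wpar.sum()
    Uc = U - ubar
    Vc = V - vbar
    info = sample.design_info
    kind = sample.design_kind
    pistar_parent = _parent_pistar(parent)

    if kind == "poisson":
        pi = info["pi_parent"]
        w2 = pi * (1 - pi) / (pistar_parent * pi) ** 2
        cov = (Uc * w2[:, None]).T @ Vc
        return cov / popN**2
    if kind == "srs":
        n = info["n"]
        pi = n / M
        d_off = n * (n - 1) / (M * (M - 1)) - pi**2 if M > 1 else 0.0
        d_diag = pi * (1 - pi)
        A = Uc / (pistar_parent * pi)[:, None]
        B = Vc / (pistar_parent * pi)[:, None]
        sa, sb = A.sum(axis=0), B.sum(axis=0)
        cov = d_off * np.outer(sa, sb) + (d_diag - d_off) * (A.T @ B)
        return cov / popN**2
    if kind == "stratified":
        lab = info["labels"][ids]
        cov = np.zeros((U.shape[1], V.shape[1]))
        for h, m in info["m_h"].items():
            r = info["r_h"][h]
            mask = lab == h
            pi = r / m
            d_off = r * (r - 1) / (m * (m - 1)) - pi**2 if m > 1 else 0.0
            d_diag = pi * (1 - pi)
            A = Uc[mask] / (pistar_parent[mask] * pi)[:, None]
            B = Vc[mask] / (pistar_parent[mask] * pi)[:, None]
            sa, sb = A.sum(axis=0), B.sum(axis=0)
            cov += d_off * np.outer(sa, sb) + (d_diag - d_off) * (A.T @ B)
        return cov / popN**2
    raise ValueError(f"unsupported design kind {kind!r}")


# --------------------------------------------------------------------------
# balance statistic and rejection


@dataclass
class RejectionRule:
    """Acceptance rule for a rejective phase.

    gamma2 : strict upper threshold for the balance statistic (may be inf).
    balance_columns : columns of the population x used for balancing
        (``None`` = all of x); any (N, k) array is also accepted.
    variance_mode : ``"srs_closed_form"`` for the equal-probability two-phase
        statistic, ``"general"`` for the Hajek/general-design statistic.
    """

    gamma2: float
    balance_columns: Optional[object] = None
    variance_mode: str = "srs_closed_form"
    max_draws: int = 1_000_000
    record_draws: bool = False

    def __post_init__(self) -> None:
        if not self.gamma2 > 0:
            raise ValueError("gamma2 must be positive")
        if self.max_draws < 1:
            raise ValueError("max_draws must be >= 1")


@dataclass
class BalanceResult:
    Q: float
    accepted: bool
    draws_used: int = 1


_COND_MAX = 1e12


def _balance_values(pop: FinitePopulation, rule: RejectionRule) -> np.ndarray:
    if rule.balance_columns is None:
        return pop.x
    return pop.values(rule.balance_columns)


def _solve_spd(Vmat: np.ndarray, d: np.ndarray) -> float:
    """Quadratic form d^T Vmat^{-1} d with a hard singularity check."""
    Vmat = np.atleast_2d(Vmat)
    if np.linalg.cond(Vmat) > _COND_MAX:
        raise SingularBalanceMetricError(
            "balance covariance matrix is numerically singular "
            f"(condition number > {_COND_MAX:.0e})"
        )
    return float(d @ np.linalg.solve(Vmat, d))


def balance_statistic(sampleII: PhaseSample, sampleI, rule: RejectionRule) -> BalanceResult:
    """Mahalanobis balance statistic Q of the later phase against the earlier one.

    In ``srs_closed_form`` mode (equal-probability two-phase SRS), Q uses the
    unweighted phase means and the closed-form conditional variance
    (1/n_II - 1/n_I) V_xx,I with V_xx,I the phase-I sample covariance
    (divisor n_I - 1).  In ``general`` mode the phase means are Hajek means
    and the variance is the general conditional design covariance of the mean
    difference computed from second-order inclusion probabilities.
    """
    pop = sampleII.population
    X = _balance_values(pop, rule)
    idsI = _parent_ids(sampleI) if not isinstance(sampleI, PhaseSample) else sampleI.selected
    XI = X[idsI]
    XII = X[sampleII.selected]
    if sampleII.n == 0:
        return BalanceResult(Q=np.inf, accepted=False)
    if rule.variance_mode == "srs_closed_form":
        nI, nII = XI.shape[0], XII.shape[0]
        if nII >= nI:
            raise ValueError("srs_closed_form balance needs n_II < n_I")
        d = XII.mean(axis=0) - XI.mean(axis=0)
        Vxx = np.cov(XI, rowvar=False, ddof=1)
        Q = _solve_spd((1.0 / nII - 1.0 / nI) * np.atleast_2d(Vxx), d)
    elif rule.variance_mode == "general":
        wI = (1.0 / sampleI.cum_pistar if isinstance(sampleI, PhaseSample)
              else np.ones(XI.shape[0]))
        xbarI = wI @ XI / wI.sum()
        wII = sampleII.weights()
        xbarII = wII @ XII / wII.sum()
        d = xbarII - xbarI
        Vxx = phase_design_cov(sampleII, X[_parent_ids(sampleII.parent)])
        Q = _solve_spd(Vxx, d)
    else:
        raise ValueError(f"unknown variance_mode {rule.variance_mode!r}")
    return BalanceResult(Q=Q, accepted=bool(Q < rule.gamma2))


def rejective_draw(parent, sampler, rule: RejectionRule, seed):
    """Draw candidate phases until the balance statistic is accepted.

    ``sampler`` is an :class:`SRS`, :class:`Poisson` or :class:`Stratified`
    specification.  One seeded generator is consumed sequentially across
    candidate draws, so the draw count is reproducible.  Returns the accepted
    sample and a :class:`BalanceResult` carrying ``draws_used``.  An empty
    Poisson candidate counts as a rejected draw.
    """
    rng = np.random.default_rng(seed)
    sampleI = parent  # the earlier phase the balance is taken against
    for k in range(1, rule.max_draws + 1):
        cand = sampler.draw(parent, rng)
        if cand.n == 0:
            continue
        if np.isinf(rule.gamma2):
            return cand, BalanceResult(Q=np.nan, accepted=True, draws_used=k)
        res = balance_statistic(cand, sampleI, rule)
        if res.accepted:
            res.draws_used = k
            return cand, res
    raise AcceptanceFailureError(rule.max_draws, 0.0)


def gamma_from_acceptance(p: int, accept_prob: float) -> float:
    """Threshold gamma^2 giving an asymptotic acceptance rate ``accept_prob``.

    Q converges to chi^2_p without rejection, so the threshold is the
    accept_prob quantile of chi^2_p.  The recommended default acceptance rate
    is 0.001.
    """
    if not 0 < accept_prob < 1:
        raise ValueError("accept_prob must be in (0, 1)")
    if p < 1:
        raise ValueError("p must be >= 1")
    return float(stats.chi2.ppf(accept_prob, df=p))
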