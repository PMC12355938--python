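"""Finite-population container, exact population moments, and synthetic populations.

Design-based inference treats the finite population as fixed: every unit i
carries a p-dimensional auxiliary vector x_i, a study variable y_i and
optionally a second-tier auxiliary vector z_i.  All randomness in the rest of
the package comes from the sampling design, never from these values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "FinitePopulation",
    "population_moments",
    "make_simulation_population",
    "make_threephase_population",
    "read_population",
    "write_population",
]


class PopulationFormatError(ValueError):
    """Raised when a population table violates the CSV schema."""


@dataclass
class FinitePopulation:
    """A fixed finite population of N units.

    Attributes
    ----------
    unit_id : (N,) int array of unique, stable unit identifiers (0-based).
    x : (N, p) float array of auxiliary variables.
    y : (N,) float array, the study variable.
    z : optional (N, q2) float array of second-tier auxiliaries used by
        three-phase designs.
    """

    unit_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: Optional[np.ndarray] = None
    N: int = field(init=False)

    def __post_init__(self) -> None:
        self.unit_id = np.asarray(self.unit_id, dtype=np.int64)
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if self.x.shape[0] == 1 and self.unit_id.size > 1:
            self.x = self.x.T
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.z is not None:
            self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
            if self.z.shape[0] == 1 and self.unit_id.size > 1:
                self.z = self.z.T
        self.N = int(self.unit_id.size)
        if self.x.shape[0] != self.N or self.y.size != self.N:
            raise PopulationFormatError(
                f"inconsistent row counts: ids={self.N}, x={self.x.shape[0]}, y={self.y.size}"
            )
        if self.z is not None and self.z.shape[0] != self.N:
            raise PopulationFormatError("z row count differs from N")
        if np.unique(self.unit_id).size != self.N:
            raise PopulationFormatError("unit_id values are not unique")
        for name, arr in (("x", self.x), ("y", self.y)) + (
            (("z", self.z),) if self.z is not None else ()
        ):
            if not np.all(np.isfinite(arr)):
                raise PopulationFormatError(f"non-finite values in column block '{name}'")

    @property
    def p(self) -> int:
        return self.x.shape[1]

    def values(self, which: Union[str, Sequence[int], np.ndarray]) -> np.ndarray:
        """Resolve a variable selector into an (N, k) array.

        ``which`` may be ``"y"``, ``"x"``, ``"z"``, an integer column list into
        x, or a raw array of length N.
        """
        if isinstance(which, str):
            if which == "y":
                return self.y[:, None]
            if which == "x":
                return self.x
            if which == "z":
                if self.z is None:
                    raise PopulationFormatError("population has no z block")
                return self.z
            raise PopulationFormatError(f"unknown variable selector {which!r}")
        arr = np.asarray(which)
        if arr.ndim == 1 and arr.size == self.N:
            return np.asarray(arr, dtype=float)[:, None]
        if arr.ndim == 2 and arr.shape[0] == self.N:
            return np.asarray(arr, dtype=float)
        # otherwise treat as column indices into x
        return self.x[:, np.asarray(arr, dtype=int).ravel()]


def population_moments(pop: FinitePopulation, which_u="y", which_v=None):
    """Exact finite-population mean and covariance.

    Returns ``(ubar0, V_uv0)`` where ``ubar0 = N^{-1} sum_i u_i`` and the
    covariance uses divisor N - 1.  ``which_v`` defaults to ``which_u``.
    """
    if pop.N < 2:
        raise ValueError("degenerate population: N < 2")
    U = pop.values(which_u)
    V = U if which_v is None else pop.values(which_v)
    ubar = U.mean(axis=0)
    vbar = V.mean(axis=0)
    cov = (U - ubar).T @ (V - vbar) / (pop.N - 1)
    return ubar, cov


def make_simulation_population(N: int, beta: float, seed) -> FinitePopulation:
    """Generate the benchmark simulation population.

    x_i ~ sqrt(0.5) * (chi^2_1 - 1), e_i ~ N(0, 1), y_i = 1 + beta * x_i + e_i.
    Under the superpopulation, var(x) = 1, var(e) = 1 and the squared
    correlation between x and y is R^2 = beta^2 / (beta^2 + 1).

    Stream consumption order: N chi-square draws for x, then N normal draws
    for e, from one ``numpy`` generator seeded with ``seed``.
    """
    if N < 2:
        raise ValueError("degenerate population: N < 2")
    rng = np.random.default_rng(seed)
    x = np.sqrt(0.5) * (rng.chisquare(1, size=N) - 1.0)
    e = rng.standard_normal(N)
    y = 1.0 + beta * x + e
    return FinitePopulation(unit_id=np.arange(N), x=x[:, None], y=y)


def make_threephase_population(
    N: int = 6194,
    beta_x: float = 1.0,
    beta_z: Sequence[float] = (0.6, 0.4, 0.3),
    z_loading: float = 0.7,
    seed=0,
) -> FinitePopulation:
    """Synthetic analogue of a school-performance population for three-phase designs.

    One strictly positive auxiliary x (a shifted gamma, so sampling with
    probability proportional to x is valid), a 3-vector z correlated with x,
    and y linearly related to both.  This is a synthetic stand-in with the
    same broad structure (positive size measure, correlated second-tier
    auxiliaries), not a replication of any real survey file.

    Stream consumption order: N gamma draws for x, N x q2 normal draws for the
    z innovations, N normal draws for the y error.
    """
    if N < 2:
        raise ValueError("degenerate population: N < 2")
    beta_z = np.asarray(beta_z, dtype=float)
    q2 = beta_z.size
    rng = np.random.default_rng(seed)
    # shifted gamma: strictly positive by construction, right-skewed like size
    # measures in practice
    x = rng.gamma(shape=4.0, scale=0.5, size=N) + 0.5
    z = z_loading * (x - x.mean())[:, None] + rng.standard_normal((N, q2))
    e = rng.standard_normal(N)
    y = 1.0 + beta_x * x + z @ beta_z + e
    if np.min(x) <= 0:  # unreachable for the shifted gamma; guard regardless
        x = x - np.min(x) + 0.5
    return FinitePopulation(unit_id=np.arange(N), x=x[:, None], y=y, z=z)


def write_population(pop: FinitePopulation, path) -> None:
    """Write a population as CSV with header unit_id,x1..xp,y[,z1..zq2]."""
    cols = {"unit_id": pop.unit_id}
    for j in range(pop.p):
        cols[f"x{j + 1}"] = pop.x[:, j]
    cols["y"] = pop.y
    if pop.z is not None:
        for j in range(pop.z.shape[1]):
            cols[f"z{j + 1}"] = pop.z[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_population(path) -> FinitePopulation:
    """Read a population CSV written by :func:`write_population`."""
    df = pd.read_csv(path)
    if "unit_id" not in df.columns:
        raise PopulationFormatError("missing required column 'unit_id'")
    if "y" not in df.columns:
        raise PopulationFormatError("missing required column 'y'")
    xcols = sorted(
        (c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    zcols = sorted(
        (c for c in df.columns if c.startswith("z") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not xcols:
        raise PopulationFormatError("no auxiliary columns x1..xp found")
    for c in xcols + zcols + ["y"]:
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()]
            row = int(bad[0]) if len(bad) else -1
            raise PopulationFormatError(f"non-numeric cell in column '{c}', row {row}")
    if df["unit_id"].duplicated().any():
        dup = int(df["unit_id"][df["unit_id"].duplicated()].iloc[0])
        raise PopulationFormatError(f"duplicate unit_id {dup}")
    z = df[zcols].to_numpy(float) if zcols else None
    return FinitePopulation(
        unit_id=df["unit_id"].to_numpy(np.int64),
        x=df[xcols].to_numpy(float),
        y=df["y"].to_numpy(float),
        z=z,
    )
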