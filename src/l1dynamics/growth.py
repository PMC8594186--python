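"""Asymptotic L1 growth dynamics.

The fitted BiSSE rates define a linear system for the expected numbers
x = (n_low, n_high) of low- and high-activity L1 insertions:

    dx/dt = [[lambda0 - mu0 - q01,  q10                ],
             [q01,                  lambda1 - mu1 - q10]] x

with t in substitutions/site.  The dominant eigenvalue is the asymptotic
rate of increase of L1 insertions per nucleotide substitution; its
eigenvector gives the equilibrium mix of low- and high-activity copies.
Multiplying by the substitution rate per generation converts to a
per-generation growth rate, and ln 2 over that rate is the doubling time
of the genomic L1 count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .bisse import BisseParams
from .treeio import UnitConversion

__all__ = [
    "DynamicsMatrix",
    "DynamicsResult",
    "Trajectory",
    "build_matrix",
    "asymptotic_growth",
    "doubling_time",
    "forward_integrate",
    "format_report",
]


@dataclass(frozen=True)
class DynamicsMatrix:
    """The 2x2 rate matrix of the L1 abundance dynamics (per substitution/site)."""

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (2, 2):
            raise ValueError("dynamics matrix must be 2x2")
        if m[0, 1] < 0 or m[1, 0] < 0:
            raise ValueError("off-diagonal entries (transition rates) must be >= 0")
        object.__setattr__(self, "m", m)


def build_matrix(params: BisseParams) -> DynamicsMatrix:
    """Assemble [[l0-m0-q01, q10], [q01, l1-m1-q10]] from the six rates."""
    p = params
    return DynamicsMatrix(
        np.array(
            [
                [p.lambda0 - p.mu0 - p.q01, p.q10],
                [p.q01, p.lambda1 - p.mu1 - p.q10],
            ]
        )
    )


@dataclass(frozen=True)
class DynamicsResult:
    """Growth rate and equilibrium composition implied by a dynamics matrix."""

    r_sub: float  # insertions per nucleotide substitution
    fraction_high: float
    fraction_low: float
    r_gen: float  # per generation
    doubling_time: float  # generations; inf when not growing


def doubling_time(r_gen: float) -> float:
    """ln 2 over a per-generation growth rate (inf for r_gen <= 0)."""
    return math.log(2.0) / r_gen if r_gen > 0 else math.inf


def asymptotic_growth(
    m: DynamicsMatrix, conv: UnitConversion = UnitConversion()
) -> DynamicsResult:
    """Dominant eigenvalue/eigenvector of the dynamics, in closed form.

    With non-negative off-diagonals the 2x2 spectrum is real (the
    discriminant (a-d)^2 + 4bc is non-negative), so the quadratic is
    solved directly rather than through a generic eigensolver.  The
    dominant eigenvector is taken non-negative and normalized to sum 1 so
    its second entry is the equilibrium fraction of high-activity L1s.
    """
    a, b = float(m.m[0, 0]), float(m.m[0, 1])
    c, d = float(m.m[1, 0]), float(m.m[1, 1])
    disc = (a - d) ** 2 + 4.0 * b * c
    assert disc >= -1e-12 * max(1.0, a * a + d * d), "complex dominant pair"
    disc = max(disc, 0.0)
    r = 0.5 * ((a + d) + math.sqrt(disc))
    if b > 0:
        v = np.array([b, r - a])
    elif c > 0:
        v = np.array([r - d, c])
    else:  # diagonal matrix: the dominant state takes everything
        if a > d:
            v = np.array([1.0, 0.0])
        elif d > a:
            v = np.array([0.0, 1.0])
        else:
            v = np.array([0.5, 0.5])
    v = np.clip(v, 0.0, None)
    v = v / v.sum()
    r_gen = r * conv.subst_rate
    return DynamicsResult(
        r_sub=r,
        fraction_high=float(v[1]),
        fraction_low=float(v[0]),
        r_gen=r_gen,
        doubling_time=doubling_time(r_gen),
    )


@dataclass(frozen=True)
class Trajectory:
    """Forward solution of dx/dt = M x, stored as composition + log size."""

    times: np.ndarray
    log_total: np.ndarray  # log(x0_total) + integral of growth
    fractions: np.ndarray  # shape (n_times, 2), rows sum to 1

    def growth_rate(self) -> float:
        """Slope of log total abundance over the second half of the run."""
        half = self.times.shape[0] // 2
        t, y = self.times[half:], self.log_total[half:]
        return float(np.polyfit(t, y, 1)[0])

    def final_fractions(self) -> np.ndarray:
        return self.fractions[-1]


def forward_integrate(
    m: DynamicsMatrix,
    x0: np.ndarray,
    t: float,
    n_points: int = 201,
) -> Trajectory:
    """Integrate the linear dynamics to time ``t`` (an oracle for the eigenanalysis).

    Overflow at large t is avoided by propagating the composition
    y = x / |x|_1 and the log of the total separately:
    d log N / dt = 1' M y, dy/dt = M y - (1' M y) y.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (2,) or np.any(x0 < 0) or x0.sum() <= 0:
        raise ValueError("x0 must be a non-negative 2-vector with positive total")
    A = m.m
    y0 = np.array([x0[0] / x0.sum(), x0[1] / x0.sum(), math.log(x0.sum())])

    def rhs(_t, y):
        frac = y[:2]
        Af = A @ frac
        g = Af.sum()
        return np.array([Af[0] - g * frac[0], Af[1] - g * frac[1], g])

    times = np.linspace(0.0, t, n_points)
    sol = solve_ivp(
        rhs, (0.0, t), y0, t_eval=times, method="LSODA", rtol=1e-10, atol=1e-12
    )
    if not sol.success:
        raise ArithmeticError(f"forward integration failed: {sol.message}")
    fractions = sol.y[:2].T
    return Trajectory(times=times, log_total=sol.y[2], fractions=fractions)


def _round_sig(x: float, sig: int) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def format_report(res: DynamicsResult) -> str:
    """Human-readable summary with conventional rounding (machine output stays full precision)."""
    lines = [
        f"asymptotic growth rate: {round(res.r_sub):d} insertions per nucleotide substitution",
        f"per-generation growth rate: {_round_sig(res.r_gen, 2):.2g} per generation",
        (
            f"doubling time: {_round_sig(res.doubling_time, 2):.2g} generations"
            if math.isfinite(res.doubling_time)
            else "doubling time: undefined (not growing)"
        ),
        f"equilibrium fraction of high-activity L1: {res.fraction_high:.1%}",
    ]
    return "\n".join(lines)
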