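"""Relaxation kinetics of tetramer dissociation after a dilution jump.

The mass-action scheme 4M ⇌ T with rates k_on (M^-3 h^-1) and k_off (h^-1)
obeys

    d[T]/dt = k_on [M]^4 - k_off [T],    [M] = c_total - 4[T].

After a small perturbation about equilibrium the tetramer fraction relaxes
exponentially with

    1/τ = k_off + 16 k_on [M]_eq^3 = k_off (1 + 16 [M]_eq^3 / K).

Following common practice, the primary estimator is a bare exponential fit of
the observed tetramer fraction; the ODE model is a simulator and oracle for
that fit, because observed "rate constants" are often reported without a
stated definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np
from scipy.integrate import solve_ivp

from .equilibrium import DissociationConstant, solve_speciation

__all__ = [
    "TimeCourse",
    "RelaxationFit",
    "RateConstants",
    "simulate_relaxation",
    "fit_relaxation",
    "k_off_from_tau",
    "linearized_tau",
    "dilution_jump",
]


@dataclass(frozen=True)
class RateConstants:
    """Mass-action rate constants; implied K = k_off / k_on (1 M standard state)."""

    k_off: float  # h^-1
    k_on: float  # M^-3 h^-1

    def __post_init__(self) -> None:
        if self.k_off <= 0 or self.k_on <= 0:
            raise ValueError("rate constants must be > 0")

    @property
    def k_eq(self) -> float:
        return self.k_off / self.k_on


@dataclass(frozen=True)
class TimeCourse:
    """Tetramer mass fraction sampled at strictly increasing times (h)."""

    times: np.ndarray
    f_tet: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.f_tet, dtype=float)
        if t.size != f.size:
            raise ValueError("times and f_tet must have equal length")
        if t.size and (t[0] < 0 or not np.all(np.diff(t) > 0)):
            raise ValueError("times must be non-negative and strictly increasing")
        if f.size and (np.min(f) < -1e-9 or np.max(f) > 1 + 1e-9):
            raise ValueError("f_tet must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "f_tet", np.clip(f, 0.0, 1.0))


@dataclass(frozen=True)
class RelaxationFit:
    f0: float  # fitted initial tetramer fraction
    f_eq: float  # fitted equilibrium tetramer fraction
    tau: float  # relaxation time, h
    rms_residual: float
    success: bool = True
    message: str = ""
    monotonic: bool = True  # False flags non-monotonicity beyond noise

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        for name in ("f0", "f_eq"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.f_eq + (self.f0 - self.f_eq) * np.exp(-t / self.tau)


def simulate_relaxation(
    rates: RateConstants,
    c_total: float,
    f_tet_initial: float,
    times: Sequence[float],
) -> TimeCourse:
    """Integrate the mass-action ODE from a given initial tetramer fraction.

    Adaptive LSODA (implicit-capable) integration at rtol 1e-9 and
    atol 1e-12·c_total; monomer-equivalent conservation holds at every output
    time by construction ([M] is eliminated as c_total - 4[T]).
    """
    if c_total <= 0:
        raise ValueError("c_total must be > 0")
    if not (0.0 <= f_tet_initial <= 1.0):
        raise ValueError("f_tet_initial must lie in [0, 1]")
    t_grid = np.asarray(times, dtype=float)
    t0_conc = f_tet_initial * c_total / 4.0  # [T] in M

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        tet = y[0]
        m = c_total - 4.0 * tet
        return [rates.k_on * m**4 - rates.k_off * tet]

    span = (min(0.0, t_grid[0]), t_grid[-1]) if t_grid.size else (0.0, 0.0)
    sol = solve_ivp(
        rhs,
        span,
        [t0_conc],
        t_eval=t_grid,
        method="LSODA",
        rtol=1e-9,
        atol=1e-12 * c_total,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed: {sol.message} "
            f"(k_off={rates.k_off}, k_on={rates.k_on}, c_total={c_total})"
        )
    tet = np.clip(sol.y[0], 0.0, c_total / 4.0)
    return TimeCourse(times=t_grid, f_tet=4.0 * tet / c_total)


def fit_relaxation(tc: TimeCourse) -> RelaxationFit:
    """Least-squares fit of f(t) = f_eq + (f0 - f_eq) exp(-t/τ).

    f0 and f_eq are constrained to [0, 1].  Needs >= 5 points; a span shorter
    than one fitted relaxation time or non-monotone data beyond the residual
    noise is flagged, not fatal.
    """
    t, f = tc.times, tc.f_tet
    if t.size < 5:
        raise ValueError(f"fit_relaxation needs >= 5 points, got {t.size}")

    f0_init = float(f[0])
    feq_init = float(f[-1])
    # crude tau guess: time to cover 63% of the observed span
    gap = f - feq_init
    if abs(gap[0]) > 1e-12:
        frac = np.abs(gap / gap[0])
        below = np.nonzero(frac < math.exp(-1.0))[0]
        tau_init = float(t[below[0]]) if below.size else float(t[-1] / 2.0)
    else:
        tau_init = float(t[-1] / 2.0)
    tau_init = max(tau_init, float(np.min(np.diff(t))))

    pars = lmfit.Parameters()
    pars.add("f0", value=min(max(f0_init, 0.0), 1.0), min=0.0, max=1.0)
    pars.add("f_eq", value=min(max(feq_init, 0.0), 1.0), min=0.0, max=1.0)
    pars.add("tau", value=tau_init, min=1e-12)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return f - (p["f_eq"].value + (p["f0"].value - p["f_eq"].value) * np.exp(-t / p["tau"].value))

    out = lmfit.minimize(residual, pars, method="leastsq", xtol=1e-13, ftol=1e-13,
                         max_nfev=20_000)
    resid = residual(out.params)
    rms = float(np.sqrt(np.mean(resid**2)))
    # monotonicity beyond noise: successive increments against the fitted trend
    direction = np.sign(out.params["f_eq"].value - out.params["f0"].value)
    steps = np.diff(f)
    tol = 3.0 * rms + 1e-12
    monotonic = bool(np.all(direction * steps >= -tol)) if direction != 0 else True
    return RelaxationFit(
        f0=float(out.params["f0"].value),
        f_eq=float(out.params["f_eq"].value),
        tau=float(out.params["tau"].value),
        rms_residual=rms,
        success=bool(out.success),
        message=str(out.message),
        monotonic=monotonic,
    )


def linearized_tau(rates: RateConstants, c_total: float) -> float:
    """Relaxation time of the mass-action system linearized about equilibrium."""
    m_eq = solve_speciation(rates.k_eq, c_total).m_conc
    return 1.0 / (rates.k_off + 16.0 * rates.k_on * m_eq**3)


def k_off_from_tau(
    tau: float, k: DissociationConstant | float, c_total: float
) -> RateConstants:
    """Rate constants from an observed relaxation time.

    Inverts the near-equilibrium linearization: with [M]_eq from the
    speciation solve, k_off = 1 / (τ (1 + 16 [M]_eq^3 / K)) and
    k_on = k_off / K.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    kval = k.value if isinstance(k, DissociationConstant) else float(k)
    m_eq = solve_speciation(kval, c_total).m_conc
    k_off = 1.0 / (tau * (1.0 + 16.0 * m_eq**3 / kval))
    return RateConstants(k_off=k_off, k_on=k_off / kval)


def dilution_jump(
    rates: RateConstants,
    c_stock: float,
    dilution_factor: float,
    times: Sequence[float],
) -> TimeCourse:
    """Equilibrate at c_stock, dilute instantaneously, then relax.

    Mirrors the standard protocol of diluting a concentrated equilibrated
    stock (e.g. 300 µM diluted 50-fold) and following the tetramer fraction.
    """
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    f_tet0 = solve_speciation(rates.k_eq, c_stock).f_tet
    return simulate_relaxation(rates, c_stock / dilution_factor, f_tet0, times)
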