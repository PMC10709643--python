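"""Algebra of the tetramer ⇌ 4-monomer equilibrium.

An antibody light chain (or its isolated variable domain) partitions between
free monomer M and a non-covalent tetramer T,

    T ⇌ 4 M,   K_D = [M]^4 / [T],

with K_D referenced to a 1 M standard state so it is stored dimensionless but
numerically equal to the conventional value in M^3.  SEC peak areas report
monomer-equivalent *mass* fractions (A280 per unit mass is identical for
monomer and tetramer of the same chain), so for a total concentration
``c_total`` in monomer-equivalent molar units,

    [M] = f_mono * c_total,     [T] = (1 - f_mono) * c_total / 4.

This module converts observed fractions to dissociation constants and solves
the inverse problem (speciation at a given K_D and total concentration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SpeciationState",
    "DissociationConstant",
    "kd_from_ratio",
    "solve_speciation",
    "read_equilibrium_table",
    "write_equilibrium_table",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
]

_CONSERVATION_RTOL = 1e-9


def celsius_to_kelvin(t_celsius: float) -> float:
    return float(t_celsius) + 273.15


def kelvin_to_celsius(t_kelvin: float) -> float:
    return float(t_kelvin) - 273.15


@dataclass(frozen=True)
class DissociationConstant:
    """Equilibrium constant of T ⇌ 4M at a given temperature.

    ``value`` is dimensionless against a 1 M standard state and numerically
    equal to the conventional K_D in M^3.
    """

    value: float
    temperature: float  # K

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise ValueError(f"dissociation constant must be > 0, got {self.value}")
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")


@dataclass(frozen=True)
class SpeciationState:
    """Monomer/tetramer speciation at one total concentration.

    c_total is in monomer-equivalent molar units; f_mono and f_tet are mass
    fractions and sum to 1; conservation [M] + 4[T] = c_total holds to 1e-9
    relative.
    """

    c_total: float  # M, monomer-equivalent
    m_conc: float  # M
    t_conc: float  # M
    f_mono: float
    f_tet: float

    def __post_init__(self) -> None:
        if self.c_total <= 0:
            raise ValueError(f"c_total must be > 0, got {self.c_total}")
        if self.m_conc < 0 or self.t_conc < 0:
            raise ValueError("concentrations must be non-negative")
        total = self.m_conc + 4.0 * self.t_conc
        if not math.isclose(total, self.c_total, rel_tol=_CONSERVATION_RTOL):
            raise ValueError(
                f"mass conservation violated: [M] + 4[T] = {total!r} != c_total = {self.c_total!r}"
            )
        if not math.isclose(self.f_mono + self.f_tet, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("f_mono + f_tet must equal 1")

    @classmethod
    def from_monomer(cls, m_conc: float, c_total: float) -> "SpeciationState":
        t_conc = (c_total - m_conc) / 4.0
        f_mono = m_conc / c_total
        return cls(
            c_total=c_total,
            m_conc=m_conc,
            t_conc=t_conc,
            f_mono=f_mono,
            f_tet=1.0 - f_mono,
        )


def kd_from_ratio(
    f_mono: float, c_total: float, temperature: float = 298.15
) -> DissociationConstant:
    """Dissociation constant from an observed monomer mass fraction.

    Parameters
    ----------
    f_mono : monomer mass fraction from SEC relative peak areas, strictly
        between 0 and 1.
    c_total : total protein concentration in monomer-equivalent M.
    temperature : absolute temperature in K.

    Returns
    -------
    DissociationConstant with value [M]^4/[T] where [M] = f_mono*c_total and
    [T] = (1-f_mono)*c_total/4.
    """
    if not (0.0 < f_mono < 1.0):
        raise ValueError(
            f"f_mono must lie strictly in (0, 1); got {f_mono} "
            "(a pure-monomer or pure-tetramer sample leaves K undefined)"
        )
    if c_total <= 0:
        raise ValueError(f"c_total must be > 0, got {c_total}")
    m = f_mono * c_total
    t = (1.0 - f_mono) * c_total / 4.0
    return DissociationConstant(value=m**4 / t, temperature=temperature)


def _speciation_residual(m: float, k: float, c_total: float) -> float:
    # g([M]) = [M] + 4[M]^4/K - c_total, strictly increasing on [0, c_total]
    return m + 4.0 * m**4 / k - c_total


def solve_speciation(k: DissociationConstant | float, c_total: float) -> SpeciationState:
    """Unique speciation at a given dissociation constant and total concentration.

    Solves g([M]) = [M] + 4[M]^4/K - c_total = 0 on (0, c_total]; g is strictly
    increasing so the root is unique.  Bracketing root finder followed by a
    Newton polish; no dependence on an initial guess.
    """
    kval = k.value if isinstance(k, DissociationConstant) else float(k)
    if kval <= 0:
        raise ValueError(f"dissociation constant must be > 0, got {kval}")
    if c_total <= 0:
        raise ValueError(f"c_total must be > 0, got {c_total}")

    if _speciation_residual(c_total, kval, c_total) <= 0:
        # 4 c^4 / K underflows: effectively fully dissociated
        m = c_total
    else:
        m = brentq(
            _speciation_residual,
            0.0,
            c_total,
            args=(kval, c_total),
            xtol=1e-300,
            rtol=8.9e-16,
            maxiter=200,
        )
        # one Newton step to polish against the analytic derivative
        for _ in range(3):
            g = _speciation_residual(m, kval, c_total)
            dg = 1.0 + 16.0 * m**3 / kval
            step = g / dg
            if m - step <= 0 or m - step > c_total:
                break
            m -= step
            if abs(step) <= 1e-14 * m:
                break
    m = min(m, c_total)
    return SpeciationState.from_monomer(m, c_total)


# ---------------------------------------------------------------------------
# measurement-table I/O

_TABLE_COLUMNS = ["temperature_C", "c_total_uM", "f_mono", "f_tet"]


def read_equilibrium_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV of SEC-derived speciation measurements.

    Expected columns: temperature_C, c_total_uM, f_mono, f_tet.  Lines
    starting with '#' are comments.  f_mono must lie in [0, 1) and f_tet in
    (0, 1]; the two must sum to 1 within 1e-6.
    """
    df = pd.read_csv(path, comment="#", encoding="utf-8")
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"equilibrium table {path} is missing columns: {missing}")
    if (df["f_mono"] < 0).any() or (df["f_mono"] >= 1).any():
        raise ValueError("f_mono values must lie in [0, 1)")
    if (df["f_tet"] <= 0).any() or (df["f_tet"] > 1).any():
        raise ValueError("f_tet values must lie in (0, 1]")
    if not np.allclose(df["f_mono"] + df["f_tet"], 1.0, atol=1e-6):
        raise ValueError("f_mono + f_tet must equal 1 for every row")
    return df[_TABLE_COLUMNS].copy()


def write_equilibrium_table(df: pd.DataFrame, path: str | Path) -> None:
    df[_TABLE_COLUMNS].to_csv(path, index=False, encoding="utf-8")
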