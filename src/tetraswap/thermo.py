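"""Constant-ΔC°p thermodynamic model of tetramer dissociation.

The standard free energy of dissociation, ΔG°(T) = -RT ln K, is
parameterized by a temperature-independent heat-capacity change ΔC°p and two
characteristic temperatures: T_h where ΔH° crosses zero and T_s where ΔS°
crosses zero.  With ΔC°p constant the integrals close to

    ΔH°(T) = ΔC°p (T - T_h)
    ΔS°(T) = ΔC°p ln(T / T_s)
    ΔG°(T) = ΔC°p (1 + ln T_s) T - ΔC°p T ln T - ΔC°p T_h

ΔG° is per mole of tetramer for T ⇌ 4M, matching K = [M]^4/[T].  Energies
are in kcal/mol throughout; R = 1.9872e-3 kcal/mol/K.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

from .equilibrium import DissociationConstant, kelvin_to_celsius

__all__ = [
    "R_KCAL",
    "ThermoParams",
    "ThermoPoint",
    "ThermoFitResult",
    "delta_g_from_k",
    "k_from_delta_g",
    "delta_h",
    "delta_s",
    "delta_g_model",
    "fit_thermo",
    "read_thermo_table",
    "write_fit_json",
]

R_KCAL = 1.9872e-3  # gas constant, kcal mol^-1 K^-1

_BOUNDS_DCP = (1e-12, 100.0)  # kcal/mol/K; strictly positive
_BOUNDS_T = (200.0, 400.0)  # K, sensible for protein oligomers in water


@dataclass(frozen=True)
class ThermoParams:
    """Model parameters: ΔC°p (kcal/mol/K), T_h (K), T_s (K)."""

    delta_cp: float
    t_h: float
    t_s: float

    def __post_init__(self) -> None:
        if not (self.t_h > 0 and self.t_s > 0):
            raise ValueError("characteristic temperatures must be positive (K)")
        if not math.isfinite(self.delta_cp):
            raise ValueError("delta_cp must be finite")


@dataclass(frozen=True)
class ThermoPoint:
    """One (T, ΔG°) observation, optionally with a standard uncertainty."""

    temperature: float  # K
    delta_g: float  # kcal/mol (per mole of tetramer)
    sigma: float | None = None  # kcal/mol

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 K")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma, if given, must be > 0")


@dataclass(frozen=True)
class ThermoFitResult:
    params: ThermoParams
    stderr: dict = field(default_factory=dict)  # per-parameter standard errors
    rss: float = 0.0  # residual sum of squares, kcal^2/mol^2
    n_points: int = 0
    success: bool = True
    message: str = ""


def delta_g_from_k(k: DissociationConstant) -> float:
    """ΔG° = -RT ln K, in kcal per mole of tetramer."""
    return -R_KCAL * k.temperature * math.log(k.value)


def k_from_delta_g(delta_g: float, temperature: float) -> DissociationConstant:
    """Inverse of ``delta_g_from_k``: K = exp(-ΔG°/(RT))."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    return DissociationConstant(
        value=math.exp(-delta_g / (R_KCAL * temperature)), temperature=temperature
    )


def delta_h(params: ThermoParams, temperature) -> float:
    """ΔH°(T) = ΔC°p (T - T_h)."""
    return params.delta_cp * (np.asarray(temperature, dtype=float) - params.t_h)


def delta_s(params: ThermoParams, temperature) -> float:
    """ΔS°(T) = ΔC°p ln(T / T_s), kcal/mol/K."""
    return params.delta_cp * np.log(np.asarray(temperature, dtype=float) / params.t_s)


def delta_g_model(params: ThermoParams, temperature) -> float:
    """ΔG°(T) from the closed form; equals ΔH°(T) - T ΔS°(T) identically."""
    t = np.asarray(temperature, dtype=float)
    return (
        params.delta_cp * (1.0 + math.log(params.t_s)) * t
        - params.delta_cp * t * np.log(t)
        - params.delta_cp * params.t_h
    )


def _initial_guess(t: np.ndarray, g: np.ndarray) -> ThermoParams:
    # T_s: location of the observed ΔG° maximum (model is maximal at T = T_s)
    t_s0 = float(t[np.argmax(g)])
    # ΔC°p from the curvature of a quadratic pre-fit: ΔG'' = -ΔC°p / T
    coeffs = np.polyfit(t, g, 2)
    t_mid = 0.5 * (t.min() + t.max())
    dcp0 = -2.0 * coeffs[0] * t_mid
    if not np.isfinite(dcp0) or dcp0 <= 0:
        dcp0 = 1.0
    dcp0 = float(np.clip(dcp0, 1e-6, _BOUNDS_DCP[1]))
    # T_h from ΔG°(T_s) = ΔC°p (T_s - T_h)
    g_at_ts = float(g[np.argmax(g)])
    t_h0 = t_s0 - g_at_ts / dcp0
    t_s0 = float(np.clip(t_s0, *_BOUNDS_T))
    t_h0 = float(np.clip(t_h0, *_BOUNDS_T))
    return ThermoParams(delta_cp=dcp0, t_h=t_h0, t_s=t_s0)


def fit_thermo(points: Sequence[ThermoPoint]) -> ThermoFitResult:
    """Weighted least-squares fit of the ΔG°(T) model.

    Minimizes Σ wᵢ (ΔGᵢ - model(Tᵢ))² with wᵢ = 1/σᵢ² when uncertainties are
    present (all points must then carry one), else wᵢ = 1.  Initialization is
    closed-form from the data (see ``_initial_guess``); parameters are bounded
    to ΔC°p ∈ (0, 100] kcal/mol/K and T_h, T_s ∈ [200, 400] K.

    Raises ValueError for fewer than 3 distinct temperatures.  Non-convergence
    is reported through ``success=False``, never as silent garbage.
    """
    pts = list(points)
    t = np.array([p.temperature for p in pts], dtype=float)
    g = np.array([p.delta_g for p in pts], dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError(
            f"fit_thermo needs >= 3 distinct temperatures, got {len(np.unique(t))}"
        )
    sigmas = [p.sigma for p in pts]
    if any(s is not None for s in sigmas):
        if any(s is None for s in sigmas):
            raise ValueError("either all points carry sigma or none do")
        weights = 1.0 / np.array(sigmas, dtype=float)
    else:
        weights = np.ones_like(t)

    init = _initial_guess(t, g)
    pars = lmfit.Parameters()
    pars.add("delta_cp", value=init.delta_cp, min=_BOUNDS_DCP[0], max=_BOUNDS_DCP[1])
    pars.add("t_h", value=init.t_h, min=_BOUNDS_T[0], max=_BOUNDS_T[1])
    pars.add("t_s", value=init.t_s, min=_BOUNDS_T[0], max=_BOUNDS_T[1])

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = ThermoParams(p["delta_cp"].value, p["t_h"].value, p["t_s"].value)
        return weights * (g - delta_g_model(model, t))

    out = lmfit.minimize(
        residual, pars, method="leastsq", xtol=1e-12, ftol=1e-12, max_nfev=10_000
    )
    fitted = ThermoParams(
        delta_cp=out.params["delta_cp"].value,
        t_h=out.params["t_h"].value,
        t_s=out.params["t_s"].value,
    )
    resid = g - delta_g_model(fitted, t)
    stderr = {
        name: (out.params[name].stderr if out.params[name].stderr is not None else float("nan"))
        for name in ("delta_cp", "t_h", "t_s")
    }
    return ThermoFitResult(
        params=fitted,
        stderr=stderr,
        rss=float(np.sum(resid**2)),
        n_points=len(pts),
        success=bool(out.success),
        message=str(out.message),
    )


# ---------------------------------------------------------------------------
# I/O

def read_thermo_table(path: str | Path) -> list[ThermoPoint]:
    """Read (temperature_C, kd_M3) or (temperature_C, delta_g_kcal_mol) CSV.

    Temperatures are user-facing °C and converted to K on read.  An optional
    sigma_kcal_mol column supplies per-point uncertainties.
    """
    df = pd.read_csv(path, comment="#", encoding="utf-8")
    if "temperature_C" not in df.columns:
        raise ValueError(f"{path}: missing temperature_C column")
    t_K = df["temperature_C"].to_numpy(dtype=float) + 273.15
    if "delta_g_kcal_mol" in df.columns:
        g = df["delta_g_kcal_mol"].to_numpy(dtype=float)
    elif "kd_M3" in df.columns:
        g = np.array(
            [
                delta_g_from_k(DissociationConstant(value=k, temperature=tk))
                for k, tk in zip(df["kd_M3"], t_K)
            ]
        )
    else:
        raise ValueError(f"{path}: need a kd_M3 or delta_g_kcal_mol column")
    sig = df["sigma_kcal_mol"].to_numpy(dtype=float) if "sigma_kcal_mol" in df.columns else None
    return [
        ThermoPoint(temperature=tk, delta_g=gv, sigma=(None if sig is None else float(sig[i])))
        for i, (tk, gv) in enumerate(zip(t_K, g))
    ]


def write_fit_json(result: ThermoFitResult, path: str | Path) -> None:
    """Serialize a fit with parameters reported in both K and °C."""
    payload = {
        "delta_cp_kcal_mol_K": result.params.delta_cp,
        "t_h_K": result.params.t_h,
        "t_s_K": result.params.t_s,
        "t_h_C": kelvin_to_celsius(result.params.t_h),
        "t_s_C": kelvin_to_celsius(result.params.t_s),
        "stderr": result.stderr,
        "rss": result.rss,
        "n_points": result.n_points,
        "success": result.success,
        "message": result.message,
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
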