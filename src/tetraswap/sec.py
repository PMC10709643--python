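"""SEC chromatogram simulation, Gaussian peak deconvolution, CD unmixing.

SEC separates the tetramer (eluting first, smaller volume) from the monomer
(eluting later).  Peak areas from a Gaussian decomposition of the A280 trace
give monomer:tetramer mass ratios; because extinction per unit mass is equal
for the two species, the relative area of the latest-eluting peak is the
monomer mass fraction f_mono.

Two-state CD spectral unmixing recovers pure monomer and tetramer basis
spectra from two mixed spectra of known composition by a per-wavelength 2x2
linear solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "Chromatogram",
    "GaussianPeak",
    "PeakFitResult",
    "Spectrum",
    "simulate_chromatogram",
    "fit_peaks",
    "unmix_two_state_spectra",
    "read_chromatogram",
    "write_chromatogram",
    "read_spectrum",
    "write_peak_fit",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class GaussianPeak:
    center: float  # mL
    sigma: float  # mL
    amplitude: float  # AU at the apex

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * SQRT_2PI

    def __call__(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        return self.amplitude * np.exp(-0.5 * ((v - self.center) / self.sigma) ** 2)


@dataclass(frozen=True)
class Chromatogram:
    """An (elution volume, A280) trace on a strictly increasing grid."""

    volumes: np.ndarray  # mL
    absorbance: np.ndarray  # AU

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if v.size != a.size:
            raise ValueError("volumes and absorbance must have equal length")
        if v.size == 0:
            raise ValueError("empty chromatogram")
        if not np.all(np.diff(v) > 0):
            raise ValueError("volumes must be strictly increasing")
        if not (np.all(np.isfinite(v)) and np.all(np.isfinite(a))):
            raise ValueError("non-finite values in chromatogram")
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "absorbance", a)


@dataclass(frozen=True)
class PeakFitResult:
    peaks: tuple  # GaussianPeak, ordered by center
    baseline: tuple  # (intercept, slope)
    rms_residual: float
    f_mono: float  # relative area of the latest-eluting peak
    success: bool = True
    message: str = ""
    crowded: bool = False  # n_peaks exceeded the resolvable local maxima

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_mono <= 1.0):
            raise ValueError("f_mono must lie in [0, 1]")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")


@dataclass(frozen=True)
class Spectrum:
    wavelengths: np.ndarray  # nm, strictly increasing
    signal: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if w.size != s.size:
            raise ValueError("wavelengths and signal must have equal length")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "signal", s)


def simulate_chromatogram(
    peaks: Sequence[GaussianPeak],
    baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    volume_grid: np.ndarray | None = None,
) -> Chromatogram:
    """Forward model: sum of Gaussians + linear baseline + i.i.d. normal noise.

    Identical seeds give bitwise-identical traces.
    """
    if volume_grid is None:
        volume_grid = np.linspace(8.0, 24.0, 1601)
    v = np.asarray(volume_grid, dtype=float)
    if v.size == 0:
        raise ValueError("empty volume grid")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    signal = baseline[0] + baseline[1] * v
    for p in peaks:
        signal = signal + p(v)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=v.size)
    return Chromatogram(volumes=v, absorbance=signal)


def _smooth(y: np.ndarray, window: int = 5) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")


def _find_initial_peaks(chrom: Chromatogram, n_peaks: int) -> tuple[list[GaussianPeak], bool]:
    """Deterministic initial guesses: n largest local maxima after smoothing,
    sigmas from half-width at half-maximum."""
    v, y = chrom.volumes, _smooth(chrom.absorbance, 5)
    y0 = y - np.median(y)
    interior = np.arange(1, v.size - 1)
    is_max = (y0[interior] >= y0[interior - 1]) & (y0[interior] > y0[interior + 1])
    candidates = interior[is_max]
    candidates = candidates[np.argsort(y0[candidates])[::-1]]
    # accept maxima tallest-first, suppressing any candidate inside the
    # half-maximum region of an already-accepted peak (noise on a broad peak
    # produces many spurious local maxima that all belong to the same peak)
    chosen: list[int] = []
    excluded: list[tuple[int, int]] = []
    for idx in candidates:
        if any(lo <= idx <= hi for lo, hi in excluded):
            continue
        chosen.append(int(idx))
        half = y0[idx] / 2.0
        lo = idx
        while lo > 0 and y0[lo] > half:
            lo -= 1
        hi = idx
        while hi < v.size - 1 and y0[hi] > half:
            hi += 1
        excluded.append((lo, hi))
        if len(chosen) == n_peaks:
            break
    crowded = len(chosen) < n_peaks
    while len(chosen) < n_peaks:  # fall back to grid quantiles
        q = (len(chosen) + 1) / (n_peaks + 1)
        chosen.append(int(q * (v.size - 1)))
    guesses = []
    for idx in sorted(chosen):
        amp = max(y0[idx], 1e-12)
        half = amp / 2.0
        left = idx
        while left > 0 and y0[left] > half:
            left -= 1
        right = idx
        while right < v.size - 1 and y0[right] > half:
            right += 1
        hwhm = max((v[right] - v[left]) / 2.0, (v[1] - v[0]))
        sigma = hwhm / math.sqrt(2.0 * math.log(2.0))
        guesses.append(GaussianPeak(center=float(v[idx]), sigma=float(sigma), amplitude=float(amp)))
    return guesses, crowded


def fit_peaks(
    chrom: Chromatogram,
    n_peaks: int,
    init: Sequence[GaussianPeak] | None = None,
) -> PeakFitResult:
    """Least-squares Gaussian decomposition with a jointly fitted linear baseline.

    Peaks are reported in increasing elution-volume order; f_mono is the
    relative area of the latest-eluting peak (the monomer elutes after the
    tetramer on SEC).
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    n_params = 3 * n_peaks + 2
    if chrom.volumes.size <= 5 * n_params:
        raise ValueError(
            f"chromatogram too short: need more than {5 * n_params} samples for "
            f"{n_peaks} peaks, got {chrom.volumes.size}"
        )
    crowded = False
    if init is None:
        init_list, crowded = _find_initial_peaks(chrom, n_peaks)
    else:
        init_list = list(init)
        if len(init_list) != n_peaks:
            raise ValueError("init must supply one guess per peak")
        centers = [p.center for p in init_list]
        if len(set(centers)) != len(centers):
            raise ValueError("coincident peak centers in initial guesses")

    v, y = chrom.volumes, chrom.absorbance
    span = v[-1] - v[0]
    pars = lmfit.Parameters()
    for i, p in enumerate(init_list):
        pars.add(f"c{i}", value=p.center, min=v[0] - span, max=v[-1] + span)
        pars.add(f"s{i}", value=p.sigma, min=(v[1] - v[0]) / 10.0, max=span)
        pars.add(f"a{i}", value=max(p.amplitude, 1e-12), min=0.0)
    pars.add("b0", value=float(np.median(y)))
    pars.add("b1", value=0.0)

    def model(p: lmfit.Parameters) -> np.ndarray:
        out = p["b0"].value + p["b1"].value * v
        for i in range(n_peaks):
            out = out + GaussianPeak(p[f"c{i}"].value, p[f"s{i}"].value, p[f"a{i}"].value)(v)
        return out

    result = lmfit.minimize(
        lambda p: y - model(p), pars, method="leastsq", xtol=1e-12, ftol=1e-12,
        max_nfev=20_000,
    )
    fitted = sorted(
        (
            GaussianPeak(
                center=result.params[f"c{i}"].value,
                sigma=result.params[f"s{i}"].value,
                amplitude=result.params[f"a{i}"].value,
            )
            for i in range(n_peaks)
        ),
        key=lambda p: p.center,
    )
    resid = y - model(result.params)
    total_area = sum(p.area for p in fitted)
    f_mono = fitted[-1].area / total_area if total_area > 0 else 0.0
    return PeakFitResult(
        peaks=tuple(fitted),
        baseline=(result.params["b0"].value, result.params["b1"].value),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        f_mono=float(f_mono),
        success=bool(result.success),
        message=str(result.message),
        crowded=crowded,
    )


def unmix_two_state_spectra(
    spec_a: Spectrum,
    f_mono_a: float,
    spec_b: Spectrum,
    f_mono_b: float,
) -> tuple[Spectrum, Spectrum]:
    """Recover pure monomer/tetramer basis spectra from two known mixtures.

    Each observed spectrum is modelled as S = f·B_mono + (1-f)·B_tet; with two
    mixtures of distinct composition the pair (B_mono, B_tet) follows from a
    2x2 solve at every wavelength.
    """
    if spec_a.wavelengths.shape != spec_b.wavelengths.shape or not np.allclose(
        spec_a.wavelengths, spec_b.wavelengths
    ):
        raise ValueError("spectra must share an identical wavelength grid")
    if abs(f_mono_a - f_mono_b) <= 0.05:
        raise ValueError(
            f"mixing fractions too close to unmix (|{f_mono_a} - {f_mono_b}| <= 0.05): "
            "the 2x2 system is singular or ill-conditioned"
        )
    mix = np.array([[f_mono_a, 1.0 - f_mono_a], [f_mono_b, 1.0 - f_mono_b]])
    stacked = np.vstack([spec_a.signal, spec_b.signal])  # 2 x n_wavelengths
    bases = np.linalg.solve(mix, stacked)
    w = spec_a.wavelengths
    return Spectrum(w, bases[0]), Spectrum(w, bases[1])


# ---------------------------------------------------------------------------
# I/O

def read_chromatogram(path: str | Path) -> Chromatogram:
    df = pd.read_csv(path, comment="#", encoding="utf-8")
    for col in ("volume_mL", "a280"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return Chromatogram(
        volumes=df["volume_mL"].to_numpy(dtype=float),
        absorbance=df["a280"].to_numpy(dtype=float),
    )


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    pd.DataFrame({"volume_mL": chrom.volumes, "a280": chrom.absorbance}).to_csv(
        path, index=False, encoding="utf-8"
    )


def read_spectrum(path: str | Path) -> Spectrum:
    df = pd.read_csv(path, comment="#", encoding="utf-8")
    for col in ("wavelength_nm", "signal"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return Spectrum(
        wavelengths=df["wavelength_nm"].to_numpy(dtype=float),
        signal=df["signal"].to_numpy(dtype=float),
    )


def write_peak_fit(chrom: Chromatogram, fit: PeakFitResult, path: str | Path) -> None:
    """Emit data alongside the fitted curve and per-peak components."""
    v = chrom.volumes
    base = fit.baseline[0] + fit.baseline[1] * v
    out = {"volume_mL": v, "a280": chrom.absorbance, "baseline": base}
    total = base.copy()
    for i, p in enumerate(fit.peaks):
        comp = p(v)
        out[f"peak{i + 1}"] = comp
        total = total + comp
    out["fitted"] = total
    pd.DataFrame(out).to_csv(path, index=False, encoding="utf-8")
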