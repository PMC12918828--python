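"""Spectral data model and photometric analyses.

The central object is :class:`Spectrum`, a wavelength-indexed series tagged
with what it measures (absorbance, emission, reflectance, transmittance).
On top of it sit the photometric analyses used throughout the
biliverdin-binding-serpin (BBS) work: peak location with sub-grid
refinement, extinction coefficients from dilution series (Beer–Lambert),
relative fluorescence quantum yield against a reference standard, Q-band
enhancement ratios, chemical-denaturation metrics (Q-band fold-decrease and
hypsochromic Soret shift), and the red-edge position of whole-animal
reflectance spectra.

All wavelengths are in nm, molar extinction coefficients in M^-1 cm^-1 and
concentrations in molar units unless stated otherwise.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SpectrumKind",
    "Spectrum",
    "GaussianBand",
    "BandModel",
    "ExtinctionFit",
    "QuantumYieldResult",
    "PeakResult",
    "DenaturationMetrics",
    "RedEdgeResult",
    "find_peak",
    "fit_extinction",
    "q_band_enhancement",
    "relative_quantum_yield",
    "denaturation_metrics",
    "red_edge_position",
]

# fractional slack tolerated above 1.0 for measured reflectance/transmittance
_RT_TOL = 0.02

# absorbance validity range for the gradient quantum-yield method
QY_ABSORBANCE_RANGE = (0.005, 0.12)


class SpectrumKind(str, enum.Enum):
    ABSORBANCE = "absorbance"
    EMISSION = "emission"
    REFLECTANCE = "reflectance"
    TRANSMITTANCE = "transmittance"


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed measurement series.

    Parameters
    ----------
    wavelengths:
        Strictly increasing grid in nm.
    values:
        Dimensionless values (absorbance AU, relative intensity, or
        fractional reflectance/transmittance).
    kind:
        What the values measure.
    label:
        Free-text label (species, condition, ...).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: SpectrumKind
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "kind", SpectrumKind(self.kind))
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D of equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(vals))):
            raise ValueError("spectrum contains non-finite entries")
        if self.kind in (SpectrumKind.REFLECTANCE, SpectrumKind.TRANSMITTANCE):
            if vals.min() < 0 or vals.max() > 1.0 + _RT_TOL:
                raise ValueError(
                    f"{self.kind.value} values must lie in [0, {1 + _RT_TOL}]"
                )

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def interp(self, wavelength) -> np.ndarray | float:
        """Linear interpolation of the spectrum at arbitrary wavelengths."""
        return np.interp(wavelength, self.wavelengths, self.values)

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        return (self.wavelengths >= lo) & (self.wavelengths <= hi)

    def covers(self, window: tuple[float, float]) -> bool:
        lo, hi = self.support
        return lo <= window[0] and hi >= window[1]


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian band: center (nm), sigma (nm), peak amplitude."""

    center: float
    sigma: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("band sigma must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")

    def __call__(self, wavelength) -> np.ndarray | float:
        wl = np.asarray(wavelength, dtype=float)
        out = self.amplitude * np.exp(-0.5 * ((wl - self.center) / self.sigma) ** 2)
        return out if out.ndim else float(out)


class BandKind(str, enum.Enum):
    ABSORPTION = "absorption"
    EMISSION = "emission"


@dataclass(frozen=True)
class BandModel:
    """Gaussian band mixture for a chromophore's eps(lambda) or emission.

    For absorption models the amplitudes are molar extinction coefficients
    (M^-1 cm^-1); for emission they are dimensionless relative intensities.
    Evaluation is the sum of the bands and is always >= 0.
    """

    bands: tuple[GaussianBand, ...]
    kind: BandKind = BandKind.ABSORPTION

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "kind", BandKind(self.kind))
        if not self.bands:
            raise ValueError("BandModel needs at least one band")

    def __call__(self, wavelength) -> np.ndarray | float:
        wl = np.asarray(wavelength, dtype=float)
        out = np.zeros_like(wl, dtype=float)
        for b in self.bands:
            out += b.amplitude * np.exp(-0.5 * ((wl - b.center) / b.sigma) ** 2)
        return out if out.ndim else float(out)

    def as_spectrum(
        self,
        wavelengths: np.ndarray,
        kind: SpectrumKind | None = None,
        label: str = "",
    ) -> Spectrum:
        if kind is None:
            kind = (
                SpectrumKind.ABSORBANCE
                if self.kind is BandKind.ABSORPTION
                else SpectrumKind.EMISSION
            )
        return Spectrum(np.asarray(wavelengths, float), self(wavelengths), kind, label)


@dataclass(frozen=True)
class ExtinctionFit:
    """Slope-based molar extinction coefficient from a dilution series."""

    epsilon: float  # M^-1 cm^-1
    intercept: float  # AU
    stderr_epsilon: float  # M^-1 cm^-1
    r_squared: float
    wavelength: float  # nm
    negative_slope: bool = False


@dataclass(frozen=True)
class QuantumYieldResult:
    """Relative quantum yield via the gradient (dilution-series) method."""

    qy: float
    gradient_sample: float
    gradient_reference: float
    qy_reference: float
    refractive_ratio_sq: float


@dataclass(frozen=True)
class PeakResult:
    wavelength: float
    value: float
    flat: bool = False


@dataclass(frozen=True)
class DenaturationMetrics:
    q_fold_decrease: float
    soret_shift: float  # nm, native minus denatured peak position


@dataclass(frozen=True)
class RedEdgeResult:
    wavelength: float
    flat: bool = False


def _parabolic_vertex(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Vertex of the parabola through three (x, y) points (non-uniform ok)."""
    a, b, c = np.polyfit(x, y, 2)
    if a == 0.0:  # degenerate: collinear points
        return float(x[1]), float(y[1])
    xv = -b / (2.0 * a)
    yv = a * xv * xv + b * xv + c
    return float(xv), float(yv)


def find_peak(spectrum: Spectrum, window: tuple[float, float]) -> PeakResult:
    """Locate the maximum of ``spectrum`` within ``window``.

    The grid argmax is refined by a 3-point parabolic interpolation so the
    reported position is robust to the sampling grid. A window in which all
    values are equal has no unique maximum: the window midpoint is returned
    with ``flat=True``.

    Raises
    ------
    ValueError
        If the window does not overlap the spectrum support or holds fewer
        than 3 samples.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window outside spectrum: empty window")
    mask = spectrum.window_mask(window)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("window outside spectrum")
    if n < 3:
        raise ValueError("window outside spectrum: fewer than 3 samples inside")
    wl = spectrum.wavelengths[mask]
    vals = spectrum.values[mask]
    if np.ptp(vals) == 0.0:
        return PeakResult(0.5 * (lo + hi), float(vals[0]), flat=True)
    i = int(np.argmax(vals))
    if i == 0 or i == n - 1:
        return PeakResult(float(wl[i]), float(vals[i]))
    xv, yv = _parabolic_vertex(wl[i - 1 : i + 2], vals[i - 1 : i + 2])
    # keep the refined position inside the window and between the neighbours
    xv = min(max(xv, float(wl[i - 1])), float(wl[i + 1]))
    xv = min(max(xv, lo), hi)
    return PeakResult(xv, max(yv, float(vals[i])))


def fit_extinction(
    concentrations: Sequence[float],
    absorbances: Sequence[float],
    wavelength: float,
    path_cm: float = 1.0,
) -> ExtinctionFit:
    """Molar extinction coefficient from the slope of A vs concentration.

    Ordinary least squares with a free intercept (a baseline offset is
    tolerated but only the slope is reported); ``epsilon = slope / path_cm``.
    A negative slope is physically suspect for a pure chromophore and is
    flagged but reported as-is.
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size != a.size or c.size < 3:
        raise ValueError("need >= 3 paired (concentration, absorbance) points")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if np.ptp(c) == 0.0:
        raise ValueError("rank-deficient design: all concentrations equal")
    if path_cm <= 0:
        raise ValueError("path length must be positive")

    n = c.size
    X = np.column_stack([c, np.ones(n)])
    coef, *_ = np.linalg.lstsq(X, a, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = a - X @ coef
    ssr = float(resid @ resid)
    sst = float(((a - a.mean()) ** 2).sum())
    if sst == 0.0:
        r2 = 1.0 if ssr < 1e-30 else 0.0
    else:
        r2 = float(np.clip(1.0 - ssr / sst, 0.0, 1.0))
    sxx = float(((c - c.mean()) ** 2).sum())
    sigma2 = ssr / (n - 2) if n > 2 else 0.0
    stderr = math.sqrt(sigma2 / sxx) if sxx > 0 else float("inf")

    negative = slope < 0
    if negative:
        warnings.warn(
            "negative absorbance-vs-concentration slope; epsilon reported as-is",
            stacklevel=2,
        )
    return ExtinctionFit(
        epsilon=slope / path_cm,
        intercept=intercept,
        stderr_epsilon=stderr / path_cm,
        r_squared=r2,
        wavelength=float(wavelength),
        negative_slope=negative,
    )


def q_band_enhancement(epsilon_holo_q: float, epsilon_free_q: float) -> float:
    """Fold-increase of Q-band absorption of protein-bound vs free biliverdin."""
    if epsilon_free_q <= 0:
        raise ValueError("free-chromophore Q-band epsilon must be > 0")
    if epsilon_holo_q <= 0:
        raise ValueError("holo Q-band epsilon must be > 0")
    return epsilon_holo_q / epsilon_free_q


def _zero_intercept_slope(x: np.ndarray, y: np.ndarray) -> float:
    return float((x @ y) / (x @ x))


def relative_quantum_yield(
    sample_series: Sequence[tuple[float, float]],
    reference_series: Sequence[tuple[float, float]],
    qy_reference: float,
    n_sample: float = 1.333,
    n_reference: float = 1.333,
    absorbance_range: tuple[float, float] = QY_ABSORBANCE_RANGE,
) -> QuantumYieldResult:
    """Relative quantum yield by the gradient method.

    Each series holds (absorbance at the excitation wavelength, integrated
    emission) pairs for a dilution ladder kept optically thin. Gradients are
    zero-intercept least-squares slopes of integrated emission vs
    absorbance, and

        qy = qy_reference * (grad_sample / grad_reference) * (n_s / n_ref)^2
    """
    s = np.asarray(sample_series, dtype=float)
    r = np.asarray(reference_series, dtype=float)
    for name, arr in (("sample", s), ("reference", r)):
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
            raise ValueError(f"{name} series needs >= 3 (absorbance, emission) pairs")
        if np.any(arr[:, 0] <= 0):
            raise ValueError(f"{name} series has non-positive absorbances")
        lo, hi = absorbance_range
        if np.any((arr[:, 0] < lo) | (arr[:, 0] > hi)):
            warnings.warn(
                f"{name} series has absorbances outside the validity range "
                f"[{lo}, {hi}]; inner-filter bias possible",
                stacklevel=2,
            )
    grad_s = _zero_intercept_slope(s[:, 0], s[:, 1])
    grad_r = _zero_intercept_slope(r[:, 0], r[:, 1])
    if grad_s <= 0 or grad_r <= 0:
        raise ValueError("non-positive emission-vs-absorbance gradient")
    ratio_sq = (n_sample / n_reference) ** 2
    qy = qy_reference * (grad_s / grad_r) * ratio_sq
    return QuantumYieldResult(
        qy=qy,
        gradient_sample=grad_s,
        gradient_reference=grad_r,
        qy_reference=qy_reference,
        refractive_ratio_sq=ratio_sq,
    )


def denaturation_metrics(
    native: Spectrum,
    denatured: Spectrum,
    q_window: tuple[float, float] = (600.0, 720.0),
    soret_window: tuple[float, float] = (350.0, 430.0),
) -> DenaturationMetrics:
    """Chemical-denaturation metrics from native vs denatured absorbance.

    Unfolding releases biliverdin, collapsing the enhanced Q band and
    shifting the Soret band hypsochromically (e.g. 390 -> 376 nm), so the
    fold-decrease is native-peak / denatured-peak in the Q window and the
    shift is native minus denatured Soret peak position (positive for a
    blue shift on denaturation).
    """
    for name, sp in (("native", native), ("denatured", denatured)):
        if sp.kind is not SpectrumKind.ABSORBANCE:
            raise ValueError(f"{name} spectrum must be absorbance kind")
        for win in (q_window, soret_window):
            if not sp.covers(win):
                raise ValueError(f"{name} spectrum does not cover window {win}")
    q_nat = find_peak(native, q_window)
    q_den = find_peak(denatured, q_window)
    if q_den.value <= 0:
        raise ValueError("denatured Q-band peak is non-positive")
    s_nat = find_peak(native, soret_window)
    s_den = find_peak(denatured, soret_window)
    return DenaturationMetrics(
        q_fold_decrease=q_nat.value / q_den.value,
        soret_shift=s_nat.wavelength - s_den.wavelength,
    )


def red_edge_position(
    reflectance: Spectrum,
    window: tuple[float, float] = (650.0, 800.0),
    smooth_window: int | None = None,
) -> RedEdgeResult:
    """Wavelength of the steepest reflectance rise (the red edge).

    Computes the first derivative by central differences on the native grid
    (optionally after a moving-average smooth) and returns the location of
    its maximum, refined parabolically. A constant derivative (linear ramp)
    has no unique edge: the window midpoint is returned with ``flat=True``.
    """
    if reflectance.kind is not SpectrumKind.REFLECTANCE:
        raise ValueError("red_edge_position expects a reflectance spectrum")
    mask = reflectance.window_mask(window)
    if int(mask.sum()) < 5:
        raise ValueError("window holds fewer than 5 samples")
    wl = reflectance.wavelengths[mask]
    vals = reflectance.values[mask]
    def _moving_average(arr: np.ndarray, win: int) -> np.ndarray:
        kernel = np.ones(win) / win
        return np.convolve(np.pad(arr, win // 2, mode="edge"), kernel, mode="valid")

    if smooth_window is not None:
        if smooth_window < 1 or smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")
        if smooth_window > 1:
            vals = _moving_average(vals, smooth_window)
    deriv = np.gradient(vals, wl)
    if smooth_window is not None and smooth_window > 1:
        # the derivative amplifies residual noise; smooth it with the same
        # kernel so the edge position reflects the broad rise, not a spike
        deriv = _moving_average(deriv, smooth_window)
    if np.ptp(deriv) < 1e-12 * max(1.0, float(np.abs(deriv).max())):
        return RedEdgeResult(0.5 * (window[0] + window[1]), flat=True)
    i = int(np.argmax(deriv))
    if i == 0 or i == deriv.size - 1:
        return RedEdgeResult(float(wl[i]))
    xv, _ = _parabolic_vertex(wl[i - 1 : i + 2], deriv[i - 1 : i + 2])
    xv = min(max(xv, float(wl[i - 1])), float(wl[i + 1]))
    return RedEdgeResult(xv)
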