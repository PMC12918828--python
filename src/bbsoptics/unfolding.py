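"""Two-state thermal unfolding of the A390/A376 absorbance ratio.

Holo-BBS absorbs at 390 nm; on unfolding the released biliverdin reverts
to its free form absorbing at 376 nm, so the A390/A376 ratio falls through
a sigmoid as temperature rises. The midpoint Tm is read as the peak of the
first derivative |d(ratio)/dT|; a hyperstable protein whose ratio never
moves (relaxed-conformation serpins) yields a ``no_transition`` result.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "MeltStatus",
    "MeltCurve",
    "MeltResult",
    "two_state_fraction",
    "simulate_melt",
    "melting_temperature",
]

GAS_CONSTANT_KJ = 8.314462618e-3  # kJ mol^-1 K^-1
_T0_K = 273.15


class MeltStatus(str, enum.Enum):
    TRANSITION = "transition"
    NO_TRANSITION = "no_transition"


@dataclass(frozen=True)
class MeltCurve:
    """Temperature series (deg C, strictly increasing) of the A390/A376 ratio."""

    temperatures: np.ndarray
    ratio: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        r = np.asarray(self.ratio, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "ratio", r)
        if t.size != r.size or t.size < 10:
            raise ValueError("melt curve needs >= 10 paired samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(r <= 0):
            raise ValueError("A390/A376 ratio must be > 0")
        if t[-1] - t[0] < 10.0:
            raise ValueError("temperature span must be >= 10 degC")


@dataclass(frozen=True)
class MeltResult:
    tm: float | None  # deg C; absent when no transition
    transition_amplitude: float
    derivative_curve: np.ndarray  # d(ratio)/dT on the curve's grid
    status: MeltStatus

    def __post_init__(self) -> None:
        if self.status is MeltStatus.NO_TRANSITION and self.tm is not None:
            raise ValueError("no_transition result cannot carry a tm")
        if self.transition_amplitude < 0:
            raise ValueError("transition amplitude must be >= 0")


def two_state_fraction(temperature, tm: float, dh_vh: float):
    """Fraction unfolded under the van't Hoff two-state model.

    f(T) = 1 / (1 + exp((dH_vH/R) (1/T - 1/Tm))) with absolute temperatures;
    ``dh_vh`` in kJ/mol sets the transition sharpness. f(Tm) = 0.5 by
    construction and the dh_vh -> inf limit is a step at Tm.
    """
    if dh_vh <= 0:
        raise ValueError("van't Hoff enthalpy must be > 0")
    t_k = np.asarray(temperature, dtype=float) + _T0_K
    tm_k = tm + _T0_K
    arg = (dh_vh / GAS_CONSTANT_KJ) * (1.0 / t_k - 1.0 / tm_k)
    # exp overflow -> fraction 0; underflow -> 1
    with np.errstate(over="ignore"):
        f = 1.0 / (1.0 + np.exp(np.clip(arg, -700.0, 700.0)))
    return float(f) if f.ndim == 0 else f


def simulate_melt(
    tm: float,
    dh_vh: float,
    ratio_native: float,
    ratio_unfolded: float,
    grid,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> MeltCurve:
    """Synthesize a two-state melt of the A390/A376 ratio.

    ratio(T) = ratio_native + (ratio_unfolded - ratio_native) f(T) + noise,
    with seeded Gaussian noise of standard deviation ``noise_sd`` (absolute
    ratio units). Unfolding releases biliverdin so the native ratio must
    exceed the unfolded one.
    """
    t = np.asarray(grid, dtype=float)
    if t.size < 10 or not np.all(np.diff(t) > 0):
        raise ValueError("grid must be strictly increasing with >= 10 points")
    if not ratio_native > ratio_unfolded > 0:
        raise ValueError("require ratio_native > ratio_unfolded > 0")
    f = two_state_fraction(t, tm, dh_vh)
    ratio = ratio_native + (ratio_unfolded - ratio_native) * f
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ratio = ratio + rng.normal(0.0, noise_sd, size=t.size)
        ratio = np.maximum(ratio, 1e-9)
    return MeltCurve(t, ratio)


def melting_temperature(
    curve: MeltCurve,
    smooth_window: int = 7,
    min_amplitude_frac: float = 0.05,
) -> MeltResult:
    """Tm as the first-derivative peak of the (smoothed) melt curve.

    The ratio is smoothed with a moving polynomial (Savitzky-Golay) filter,
    differentiated by central differences, and the extremum of |dA/dT| is
    refined by a 3-point parabola. If the smoothed ratio moves by less than
    ``min_amplitude_frac`` of its starting value over the whole ramp, the
    protein is declared thermostable over the window (``no_transition``).
    """
    t, r = curve.temperatures, curve.ratio
    if smooth_window >= t.size:
        raise ValueError("smooth_window must be smaller than the series length")
    if smooth_window < 3 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd integer >= 3")
    smoothed = savgol_filter(r, smooth_window, polyorder=2)
    deriv = np.gradient(smoothed, t)
    amplitude = float(np.ptp(smoothed))
    if amplitude / abs(float(smoothed[0])) < min_amplitude_frac:
        return MeltResult(
            tm=None,
            transition_amplitude=amplitude,
            derivative_curve=deriv,
            status=MeltStatus.NO_TRANSITION,
        )
    mag = np.abs(deriv)
    i = int(np.argmax(mag))
    if 0 < i < t.size - 1:
        x = t[i - 1 : i + 2]
        y = mag[i - 1 : i + 2]
        a, b, _ = np.polyfit(x, y, 2)
        tm = float(-b / (2.0 * a)) if a != 0 else float(t[i])
        tm = min(max(tm, float(x[0])), float(x[2]))
    else:
        tm = float(t[i])
    return MeltResult(
        tm=tm,
        transition_amplitude=amplitude,
        derivative_curve=deriv,
        status=MeltStatus.TRANSITION,
    )
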