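"""1:1 equilibrium binding: isotherms, dose-response fits, regime diagnosis.

Fluorescence titrations of a fixed, limiting amount of biliverdin with
increasing apoprotein report the bound fraction through the NIR emission
that appears on binding. Two fitting models are supported:

* ``logistic4`` — the standard 4-parameter logistic (sigmoidal
  dose-response) on log10 concentration; its EC50 is the *apparent* Kd.
* ``exact_isotherm`` — the exact 1:1 mass-action solution
  (quadratic in the complex concentration), which can recover the true Kd
  when the experiment is in the binding regime.

When the limiting ligand concentration L greatly exceeds Kd the titration
is stoichiometric and any dose-response midpoint sits at ~L/2 regardless of
the true affinity (the titration-regime artefact); ``classify_regime``
makes that diagnosis explicit.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Regime",
    "BindingModel",
    "TitrationSeries",
    "BindingFit",
    "EquilibrationResult",
    "fraction_ligand_bound",
    "classify_regime",
    "equilibration_time",
    "fit_apparent_kd",
]


class Regime(str, enum.Enum):
    TITRATION = "titration"
    INTERMEDIATE = "intermediate"
    BINDING = "binding"


class BindingModel(str, enum.Enum):
    LOGISTIC4 = "logistic4"
    EXACT_ISOTHERM = "exact_isotherm"


@dataclass(frozen=True)
class TitrationSeries:
    """A titration of fixed limiting ligand with varying protein.

    ``fluorescence`` is either 1-D (one equilibrium scan, same length as
    ``protein_concentrations``) or 2-D with shape (n_concentrations,
    n_timepoints) for hourly kinetic reads.
    All concentrations are molar; timepoints in hours.
    """

    protein_concentrations: np.ndarray
    ligand_total: float
    fluorescence: np.ndarray
    timepoints: np.ndarray | None = None
    emission_wavelength: float | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.protein_concentrations, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "protein_concentrations", p)
        object.__setattr__(self, "fluorescence", f)
        if np.any(p < 0):
            raise ValueError("protein concentrations must be >= 0")
        if np.unique(p).size < 5:
            raise ValueError("need at least 5 distinct protein concentrations")
        if self.ligand_total <= 0:
            raise ValueError("ligand_total must be > 0")
        if not np.all(np.isfinite(f)):
            raise ValueError("fluorescence contains non-finite values")
        if f.ndim == 1:
            if f.size != p.size:
                raise ValueError("fluorescence length must match concentrations")
        elif f.ndim == 2:
            if f.shape[0] != p.size:
                raise ValueError("fluorescence rows must match concentrations")
            if self.timepoints is None:
                raise ValueError("2-D fluorescence requires timepoints")
            t = np.asarray(self.timepoints, dtype=float)
            object.__setattr__(self, "timepoints", t)
            if t.size != f.shape[1]:
                raise ValueError("timepoints length must match fluorescence columns")
        else:
            raise ValueError("fluorescence must be 1-D or 2-D")


@dataclass(frozen=True)
class EquilibrationResult:
    time_h: float
    index: int
    equilibrated: bool


@dataclass(frozen=True)
class BindingFit:
    """Result of a dose-response fit.

    ``kd_apparent`` is the EC50 for the logistic model and equals
    ``kd_exact`` for the exact isotherm. ``regime`` classifies the
    experiment from (ligand_total, kd_apparent).
    """

    kd_apparent: float
    kd_exact: float | None
    hill: float
    top: float
    bottom: float
    regime: Regime
    residual_norm: float
    model: BindingModel
    equilibration_time_h: float | None = None

    def __post_init__(self) -> None:
        if self.kd_apparent <= 0:
            raise ValueError("kd_apparent must be > 0")


def fraction_ligand_bound(p_total, l_total, kd):
    """Fraction of the (limiting) ligand bound at 1:1 mass-action equilibrium.

    Solves [PL]^2 - (P+L+Kd)[PL] + PL = 0 for the complex and returns
    [PL]/L. Uses the numerically stable quadratic branch
    ``[PL] = 2PL / (b + sqrt(b^2 - 4PL))`` with ``b = P + L + Kd``, which
    does not cancel when Kd << P, L.
    """
    p = np.asarray(p_total, dtype=float)
    l = np.asarray(l_total, dtype=float)
    k = np.asarray(kd, dtype=float)
    if np.any(p < 0) or np.any(l < 0) or np.any(k < 0):
        raise ValueError("p_total, l_total and kd must all be >= 0")
    b = p + l + k
    disc = b * b - 4.0 * p * l
    disc = np.maximum(disc, 0.0)  # guard round-off
    denom = b + np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        complex_ = np.where(denom > 0, 2.0 * p * l / denom, 0.0)
        frac = np.where(l > 0, complex_ / np.where(l > 0, l, 1.0), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    return float(frac) if frac.ndim == 0 else frac


def classify_regime(ligand_total: float, kd: float) -> Regime:
    """Titration if L >= 10 Kd, binding if L <= Kd, else intermediate.

    In the titration regime the dose-response midpoint reflects ~L/2, not
    the affinity; only the binding regime resolves Kd itself. The 10x / 1x
    thresholds make the half-limiting-reagent artefact detectable.
    """
    if ligand_total <= 0 or kd <= 0:
        raise ValueError("ligand_total and kd must be > 0")
    if ligand_total >= 10.0 * kd:
        return Regime.TITRATION
    if ligand_total <= kd:
        return Regime.BINDING
    return Regime.INTERMEDIATE


def equilibration_time(
    series: TitrationSeries, rel_tol: float = 0.02
) -> EquilibrationResult:
    """Earliest timepoint after which every well has stopped drifting.

    A well is settled at step k if |F_k - F_{k-1}| / max(|F_{k-1}|, tiny)
    < ``rel_tol``. Returns the earliest timepoint from which every later
    step of every well is settled; if the series never settles, the last
    timepoint is returned with ``equilibrated=False``.
    """
    f = series.fluorescence
    if f.ndim != 2 or series.timepoints is None:
        raise ValueError("equilibration_time requires a per-timepoint series")
    t = series.timepoints
    if t.size < 3:
        raise ValueError("need at least 3 timepoints")
    prev = np.abs(f[:, :-1])
    denom = np.where(prev > 0, prev, np.finfo(float).tiny)
    with np.errstate(over="ignore", divide="ignore"):
        rel = np.abs(np.diff(f, axis=1)) / denom
    unsettled = np.any(rel >= rel_tol, axis=0)  # step k: scan k -> scan k+1
    if not unsettled.any():
        return EquilibrationResult(float(t[0]), 0, True)
    last_bad = int(np.max(np.nonzero(unsettled)[0]))
    # the first settled scan: endpoint of the step after the last unsettled one
    idx = last_bad + 2
    if idx > t.size - 1:
        return EquilibrationResult(float(t[-1]), int(t.size - 1), False)
    return EquilibrationResult(float(t[idx]), idx, True)


def _pseudo_log_concentrations(conc: np.ndarray) -> np.ndarray:
    """log10 concentrations with zeros floored a decade below the min nonzero."""
    c = conc.copy()
    nz = c[c > 0]
    if nz.size == 0:
        raise ValueError("all concentrations are zero")
    floor = nz.min() / 10.0
    c[c == 0] = floor
    return np.log10(c)


def _logistic4(logc: np.ndarray, log_ec50: float, hill: float, bottom: float, top: float):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logc) * hill))


def fit_apparent_kd(
    series: TitrationSeries,
    model: BindingModel | str = BindingModel.LOGISTIC4,
    rel_tol: float = 0.02,
    n_starts: int = 8,
) -> BindingFit:
    """Fit a titration and report the apparent (and, if asked, exact) Kd.

    For kinetic (2-D) series the scan at the equilibration timepoint is
    used. Fitting is trust-region nonlinear least squares from ``n_starts``
    Kd seeds log-spaced across the concentration range; ties in residual
    norm are broken toward the smaller Kd.
    """
    model = BindingModel(model)
    conc = series.protein_concentrations
    if np.unique(conc).size < 5:
        raise ValueError("need at least 5 distinct concentrations")

    eq_time: float | None = None
    if series.fluorescence.ndim == 2:
        eq = equilibration_time(series, rel_tol=rel_tol)
        f = series.fluorescence[:, eq.index]
        eq_time = eq.time_h
    else:
        f = series.fluorescence

    nz = conc[conc > 0]
    lo, hi = nz.min(), nz.max()
    kd_seeds = np.geomspace(lo / 10.0, hi * 10.0, n_starts)
    fmin, fmax = float(f.min()), float(f.max())
    span = max(fmax - fmin, 1e-12)

    candidates: list[tuple[float, np.ndarray]] = []
    failures: list[str] = []

    if model is BindingModel.LOGISTIC4:
        logc = _pseudo_log_concentrations(conc)

        def resid(p):
            return _logistic4(logc, *p) - f

        bounds = (
            [logc.min() - 3.0, 0.05, fmin - 10 * span, fmin - 10 * span],
            [logc.max() + 3.0, 20.0, fmax + 10 * span, fmax + 10 * span],
        )
        for kd0 in kd_seeds:
            x0 = [math.log10(kd0), 1.0, fmin, fmax]
            try:
                sol = least_squares(resid, x0, bounds=bounds, method="trf")
            except Exception as exc:  # pragma: no cover - scipy internal
                failures.append(str(exc))
                continue
            if np.all(np.isfinite(sol.x)):
                candidates.append((float(np.linalg.norm(sol.fun)), sol.x))
    else:
        L = series.ligand_total

        def resid(p):
            kd, f0, df = 10.0 ** p[0], p[1], p[2]
            return f0 + df * fraction_ligand_bound(conc, L, kd) - f

        bounds = (
            [math.log10(lo) - 6.0, fmin - 10 * span, -20 * span],
            [math.log10(hi) + 6.0, fmax + 10 * span, 20 * span],
        )
        for kd0 in kd_seeds:
            x0 = [math.log10(kd0), fmin, span]
            try:
                sol = least_squares(resid, x0, bounds=bounds, method="trf")
            except Exception as exc:  # pragma: no cover
                failures.append(str(exc))
                continue
            if np.all(np.isfinite(sol.x)):
                candidates.append((float(np.linalg.norm(sol.fun)), sol.x))

    if not candidates:
        raise RuntimeError(
            "dose-response fit did not converge from any start: "
            + "; ".join(failures[:3])
        )
    best_norm = min(c[0] for c in candidates)
    tol = max(1e-9 * max(best_norm, 1e-30), 1e-30)
    near = [c for c in candidates if c[0] <= best_norm + tol]
    near.sort(key=lambda c: c[1][0])  # smaller log-Kd wins ties
    norm, x = near[0]

    if model is BindingModel.LOGISTIC4:
        ec50 = 10.0 ** x[0]
        bottom, top = float(min(x[2], x[3])), float(max(x[2], x[3]))
        fit = BindingFit(
            kd_apparent=ec50,
            kd_exact=None,
            hill=float(x[1]),
            top=top,
            bottom=bottom,
            regime=classify_regime(series.ligand_total, ec50),
            residual_norm=norm,
            model=model,
            equilibration_time_h=eq_time,
        )
    else:
        kd = 10.0 ** x[0]
        f0, df = float(x[1]), float(x[2])
        fit = BindingFit(
            kd_apparent=kd,
            kd_exact=kd,
            hill=1.0,
            top=f0 + max(df, 0.0),
            bottom=f0 + min(df, 0.0),
            regime=classify_regime(series.ligand_total, kd),
            residual_norm=norm,
            model=model,
            equilibration_time_h=eq_time,
        )
    return fit
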