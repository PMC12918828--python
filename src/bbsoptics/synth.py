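"""Seeded generators for every input the analysis pipeline consumes.

The defaults carry the measured photophysics of the three characterized
biliverdin-binding serpins (TpBBS from *Teratohyla pulverata*, BpBBS from
*Boana punctata*, SlBBS from *Sphaenorhynchus lacteus*) and of free
biliverdin in PBS: peak extinction coefficients, band positions, quantum
yields and dissociation constants. Band *widths* are not measured
quantities; the documented defaults (Soret sigma 18 nm, Q 15 nm, blue
shoulder 25 nm, emission 17 nm) are the dominant free choice and are
exposed as overrides.

Every generator is a pure function of (parameters, seed); a noiseless call
returns the exact generating model, which closes the recovery loop for
each analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import adding_doubling, binding, unfolding
from .spectra import BandKind, BandModel, GaussianBand

__all__ = [
    "BbsPhotophysics",
    "SPECIES",
    "make_bbs",
    "make_titration",
    "make_melt",
    "make_dilution_series",
    "make_slab_rt",
    "make_qy_series",
]

# default Gaussian band widths (nm) — a modelling choice, not a measurement
SIGMA_SORET = 18.0
SIGMA_Q = 15.0
SIGMA_SHOULDER = 25.0
SIGMA_EMISSION = 17.0
Q_SHOULDER_RELATIVE_AMPLITUDE = 0.35


@dataclass(frozen=True)
class BbsPhotophysics:
    """Absorption/emission band models plus the intrinsic quantum yield."""

    absorption: BandModel
    emission: BandModel
    intrinsic_qy: float
    name: str
    kd_nM: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.intrinsic_qy < 1.0:
            raise ValueError("intrinsic_qy must lie in (0, 1)")
        wl = np.arange(650.0, 751.0)
        peak = wl[np.argmax(self.emission(wl))]
        if not 650.0 <= peak <= 750.0:
            raise ValueError("emission peak must lie within 650-750 nm")


def _species_table() -> dict[str, dict]:
    # peak molar extinction coefficients (M^-1 cm^-1) and band centers (nm)
    return {
        "TpBBS": dict(
            soret=(390.0, 52_809.0),
            q=(673.0, 36_449.0),
            shoulder=620.0,
            emission=697.0,
            qy=0.0124,
            kd_nM=5.0,
        ),
        "BpBBS": dict(
            soret=(391.0, 32_072.0),
            q=(666.0, 28_034.0),
            shoulder=615.0,
            emission=710.0,
            qy=0.0139,
            kd_nM=7.5,
        ),
        "SlBBS": dict(
            soret=(390.0, 38_393.0),
            q=(666.0, 26_229.0),
            shoulder=615.0,
            emission=707.0,
            qy=0.0058,
            kd_nM=5.0,
        ),
        "free_biliverdin": dict(
            soret=(376.0, 39_900.0),
            q=(672.0, 11_200.0),
            shoulder=None,
            emission=695.0,
            # free biliverdin in buffer is almost dark; order-of-magnitude
            # literature-typical placeholder, never asserted against data
            qy=1e-4,
            kd_nM=None,
        ),
    }


SPECIES = tuple(_species_table())


def make_bbs(
    name: str,
    sigma_soret: float = SIGMA_SORET,
    sigma_q: float = SIGMA_Q,
    sigma_shoulder: float = SIGMA_SHOULDER,
    sigma_emission: float = SIGMA_EMISSION,
    emission_center: float | None = None,
    intrinsic_qy: float | None = None,
) -> BbsPhotophysics:
    """Band-model photophysics for one species (or free biliverdin).

    Peak extinction amplitudes equal the measured values for that species;
    the protein Q band carries a blue shoulder at 0.35 relative amplitude.
    Overrides shift the documented default band shapes.
    """
    table = _species_table()
    if name not in table:
        raise ValueError(f"unknown species {name!r}; choose from {SPECIES}")
    p = table[name]
    soret_c, soret_eps = p["soret"]
    q_c, q_eps = p["q"]
    bands = [
        GaussianBand(soret_c, sigma_soret, soret_eps),
        GaussianBand(q_c, sigma_q, q_eps),
    ]
    if p["shoulder"] is not None:
        bands.append(
            GaussianBand(
                p["shoulder"], sigma_shoulder, Q_SHOULDER_RELATIVE_AMPLITUDE * q_eps
            )
        )
    absorption = BandModel(tuple(bands), BandKind.ABSORPTION)
    center = emission_center if emission_center is not None else p["emission"]
    emission = BandModel(
        (GaussianBand(center, sigma_emission, 1.0),), BandKind.EMISSION
    )
    return BbsPhotophysics(
        absorption=absorption,
        emission=emission,
        intrinsic_qy=intrinsic_qy if intrinsic_qy is not None else p["qy"],
        name=name,
        kd_nM=p["kd_nM"],
    )


def default_titration_concentrations(n_wells: int = 8, top_nM: float = 30.0) -> np.ndarray:
    """Apoprotein ladder spanning ~0.2-30 nM (molar units).

    A 2-fold serial dilution from the top concentration — the standard
    plate design for this span (30, 15, ..., 0.23 nM with 8 wells).
    """
    return np.sort(top_nM * 1e-9 / 2.0 ** np.arange(n_wells))


def make_titration(
    kd: float,
    ligand_total: float,
    concentrations: Sequence[float] | None = None,
    f0: float = 100.0,
    df: float = 900.0,
    noise_sd_frac: float = 0.0,
    seed: int | None = None,
    timepoints: Sequence[float] | None = None,
    tau_h: float = 1.0,
    emission_wavelength: float = 697.0,
) -> binding.TitrationSeries:
    """Synthetic fluorescence titration at fixed limiting ligand.

    F(c) = f0 + df * fraction_bound(c, L, Kd) * (1 + eps) with
    multiplicative Gaussian noise eps ~ N(0, noise_sd_frac), seeded. With
    ``timepoints`` the bound signal approaches equilibrium exponentially
    with time constant ``tau_h`` hours, emulating hourly kinetic reads.
    """
    if kd < 0 or ligand_total <= 0:
        raise ValueError("kd must be >= 0 and ligand_total > 0")
    conc = (
        np.asarray(concentrations, dtype=float)
        if concentrations is not None
        else default_titration_concentrations()
    )
    frac = binding.fraction_ligand_bound(conc, ligand_total, kd)
    rng = np.random.default_rng(seed)
    if timepoints is None:
        signal = df * frac
        if noise_sd_frac > 0:
            signal = signal * (1.0 + rng.normal(0.0, noise_sd_frac, size=conc.size))
        return binding.TitrationSeries(
            conc, ligand_total, f0 + signal, emission_wavelength=emission_wavelength
        )
    t = np.asarray(timepoints, dtype=float)
    approach = 1.0 - np.exp(-t / tau_h)
    signal = df * frac[:, None] * approach[None, :]
    if noise_sd_frac > 0:
        signal = signal * (1.0 + rng.normal(0.0, noise_sd_frac, size=signal.shape))
    return binding.TitrationSeries(
        conc,
        ligand_total,
        f0 + signal,
        timepoints=t,
        emission_wavelength=emission_wavelength,
    )


def make_melt(
    tm: float,
    dh_vh: float = 400.0,
    ratio_native: float = 1.6,
    ratio_unfolded: float = 0.8,
    grid: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> unfolding.MeltCurve:
    """Two-state A390/A376 melt on a 20-90 degC ramp (0.5 degC default grid)."""
    g = np.asarray(grid, float) if grid is not None else np.arange(20.0, 90.25, 0.5)
    return unfolding.simulate_melt(
        tm, dh_vh, ratio_native, ratio_unfolded, g, noise_sd=noise_sd, seed=seed
    )


def make_flat_melt(
    ratio: float = 1.6,
    grid: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> unfolding.MeltCurve:
    """Thermostable (no-transition) melt curve: constant ratio plus noise."""
    g = np.asarray(grid, float) if grid is not None else np.arange(20.0, 90.25, 0.5)
    r = np.full(g.size, float(ratio))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = np.maximum(r + rng.normal(0.0, noise_sd, size=g.size), 1e-9)
    return unfolding.MeltCurve(g, r)


def make_dilution_series(
    epsilon: float,
    concentrations: Sequence[float] | None = None,
    intercept: float = 0.0,
    noise_sd_frac: float = 0.0,
    seed: int | None = None,
    path_cm: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Beer-Lambert dilution series A = eps * c * path + intercept.

    Noise is multiplicative Gaussian (fractional sd ``noise_sd_frac``) on
    the absorbance. Returns (concentrations [M], absorbances [AU]).
    """
    c = (
        np.asarray(concentrations, dtype=float)
        if concentrations is not None
        else np.linspace(0.0, 10e-6, 6)
    )
    a = epsilon * c * path_cm + intercept
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        a = a * (1.0 + rng.normal(0.0, noise_sd_frac, size=c.size))
    return c, a


def make_slab_rt(
    mua: float,
    mus: float,
    slab: adding_doubling.SlabSample,
    wavelengths: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    quadrature_order: int = 8,
) -> list[adding_doubling.RTMeasurement]:
    """Forward slab R/T (optionally per wavelength) plus seeded noise."""
    wl = np.asarray(wavelengths, float) if wavelengths is not None else np.array([np.nan])
    rng = np.random.default_rng(seed)
    out = []
    for lam in wl:
        m = adding_doubling.forward_rt(mua, mus, slab, quadrature_order, float(lam))
        r, t = m.reflectance, m.transmittance
        if noise_sd > 0:
            r = max(r + rng.normal(0.0, noise_sd), 0.0)
            t = max(t + rng.normal(0.0, noise_sd), 0.0)
        out.append(adding_doubling.RTMeasurement(r, t, float(lam)))
    return out


def make_qy_series(
    intrinsic_qy: float,
    qy_reference: float = 0.28,
    reference_gradient: float = 1.0e6,
    absorbances: Sequence[float] | None = None,
    noise_sd_frac: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (sample, reference) dilution series for the gradient QY method.

    The reference ladder has integrated emission ``reference_gradient * A``;
    the sample's gradient is scaled by ``intrinsic_qy / qy_reference`` so a
    noiseless analysis recovers ``intrinsic_qy`` exactly. Returns two
    (n, 2) arrays of (absorbance, integrated emission) pairs.
    """
    a = (
        np.asarray(absorbances, dtype=float)
        if absorbances is not None
        else np.linspace(0.01, 0.1, 5)
    )
    ref = reference_gradient * a
    sam = reference_gradient * (intrinsic_qy / qy_reference) * a
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        ref = ref * (1.0 + rng.normal(0.0, noise_sd_frac, size=a.size))
        sam = sam * (1.0 + rng.normal(0.0, noise_sd_frac, size=a.size))
    return np.column_stack([a, sam]), np.column_stack([a, ref])
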