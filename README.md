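# bbsoptics

Quantitative machinery behind the biophysics of **biliverdin-binding
serpins (BBSs)** — the proteins that let hylid and centrolenid treefrogs
and glassfrogs retain the blood pigment biliverdin at high concentration,
producing leaf-like green camouflage and near-infrared (NIR) fluorescence.
The package implements, as tested reusable code, every quantitative step
of that analysis:

* **Spectral photometry** (`bbsoptics.spectra`) — peak location with
  parabolic sub-grid refinement, molar extinction coefficients from
  Beer–Lambert dilution series (ε from the slope of *A* vs *c*), Q-band
  enhancement ratios, relative fluorescence quantum yield by the gradient
  method (Φ = Φ_ref · (m_s/m_ref) · (n_s/n_ref)²), chemical-denaturation
  metrics, and the red-edge position of reflectance spectra.
* **Ligand binding** (`bbsoptics.binding`) — the exact 1:1 mass-action
  isotherm ([PL] from the quadratic in the stable branch), 4-parameter
  logistic dose–response fits on log₁₀ concentration, and the
  **titration-vs-binding regime** diagnosis: when the limiting ligand L
  far exceeds K_d, any dose–response midpoint reads ≈ L/2 rather than the
  affinity.
* **Thermal unfolding** (`bbsoptics.unfolding`) — two-state van 't Hoff
  melts of the A390/A376 absorbance ratio,
  f(T) = 1/(1 + exp((ΔH_vH/R)(1/T − 1/T_m))), with T_m read from the peak
  of |dA/dT| and a no-transition verdict for hyperstable (relaxed-serpin)
  proteins.
* **Tissue Monte Carlo** (`bbsoptics.tissue_mc`) — weighted-packet photon
  transport through the three-layer in vivo geometry (skin / BBS-filled
  lymph / ideal specular reflector, air above) on a 300×300 pixel grid,
  with Henyey–Greenstein scattering, Fresnel/total-internal-reflection at
  the air interface, Russian roulette with an exactly closing energy
  ledger, and per-wavelength runs that simulate the concentration-dependent
  reabsorption red shift of the escaping fluorescence.
* **Adding–doubling slab optics** (`bbsoptics.adding_doubling`) — forward
  total reflectance/transmittance of a homogeneous slab by repeated
  doubling from a thin starting layer on a Gauss–Radau quadrature, and the
  inverse (IAD) recovery of (µ_a, µ_s) from a measured (R, T) pair at
  fixed g and n.
* **Synthetic data** (`bbsoptics.synth`) — seeded generators for every
  input the pipeline consumes, calibrated to the measured photophysics of
  TpBBS, BpBBS, SlBBS and free biliverdin (band positions, extinction
  coefficients, quantum yields), so the full analysis runs with no
  external data.

A thin `bbsoptics` command-line interface wraps each stage
(`fit-kd`, `melt`, `extinction`, `qy`, `denat`, `rededge`, `iad`,
`mc-emission`, and `synth …` generators); the numbered scripts under
`analysis/` run the full narrative and write tables to `results/`.

## Worked example

```python
import numpy as np
from bbsoptics import binding, synth, tissue_mc as mc, unfolding

# titration-regime artefact: 15 nM limiting biliverdin, picomolar-Kd binder
series = synth.make_titration(kd=0.1e-9, ligand_total=15e-9)
fit = binding.fit_apparent_kd(series, "logistic4")
print(f"apparent Kd = {fit.kd_apparent * 1e9:.2f} nM ({fit.regime.value})")

# derivative-peak melting point of a two-state A390/A376 melt
res = unfolding.melting_temperature(synth.make_melt(tm=67.0))
print(f"Tm = {res.tm:.2f} C")

# reabsorption red shift at 500 uM BBS in skin and lymph
tp = synth.make_bbs("TpBBS")
cfg = mc.FluorSimConfig(wavelengths=np.arange(650.0, 821.0, 5.0),
                        photons_per_wavelength=20_000, seed=17)
esc = mc.simulate_bbs_emission(tp.absorption,
                               tp.emission.as_spectrum(np.arange(600.0, 901.0)),
                               500e-6, cfg)
print(f"escaping peak = {mc.red_shift(esc).peak_out:.1f} nm")
```

prints

```
apparent Kd = 7.79 nM (intermediate)
Tm = 66.93 C
escaping peak = 711.2 nm
```

The first line is the stoichiometric artefact (≈ half the 15 nM ligand,
four orders of magnitude above the true 0.1 nM affinity), the second the
derivative-peak readout of a melt generated at 67 °C, and the third the
reabsorption-shifted NIR emission peak — the intrinsic 697 nm emission
moves past 710 nm at in-vivo BBS concentrations.

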