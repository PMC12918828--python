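# Methods

This note documents the models implemented in `bbsoptics`, the defaults
they carry, the numerical choices behind them, and what the synthetic-data
generators do and do not emulate.

## Spectral model and photometry

Spectra are wavelength-indexed series (strictly increasing nm grid) tagged
as absorbance, emission, reflectance or transmittance; fractional
reflectance/transmittance may exceed 1 by up to 0.02 to absorb calibration
slack in real measurements. Chromophores are modelled as Gaussian band
mixtures. Band **positions and peak amplitudes** are the measured values
for each species (e.g. TpBBS: Soret 52,809 M⁻¹cm⁻¹ at 390 nm, Q band
36,449 M⁻¹cm⁻¹ at 673 nm with a blue shoulder at 620 nm at 0.35 relative
amplitude; free biliverdin: 39,900 at 376 nm, 11,200 at 672 nm). Band
**widths** are not measured quantities; the defaults (σ: Soret 18 nm,
Q 15 nm, shoulder 25 nm, emission 17 nm) were chosen once to give the
printed peak positions with plausible tetrapyrrole band shapes, and they
are the dominant free choice affecting the simulated reabsorption red
shift — all are exposed as overrides. Emission is a single Gaussian; real
BBS emission is broader and asymmetric with a red tail, so simulated
red-shift magnitudes should be read as model results, not instrument
predictions.

Peak finding takes the window argmax refined by a three-point parabola
(grid-robust to ~0.5 grid steps; verified against dense brute-force
evaluation); a flat window returns the midpoint with a flatness flag.
Default search windows — Q band 600–720 nm, Soret 350–430 nm — bracket all
reported peak positions and are configurable. Extinction fitting is
ordinary least squares of A on c with a **free intercept** (baseline
offsets tolerated, slope-only reported), path length 1 cm by default.
Quantum-yield gradients use **zero-intercept** regression of integrated
emission on absorbance (standard practice for the relative method, where
zero absorbance emits nothing), with a validity warning outside
A ∈ [0.005, 0.12]. The red-edge estimator differentiates by central
differences after an optional moving-average smooth and applies the same
smooth to the derivative before locating its maximum — without the second
smooth the estimator tracks single-pixel noise spikes; its single-spectrum
precision at noise sd 0.002 and window 7 is ~1.5 nm (tested as a
10-replicate mean against the analytic inflection).

## Binding model and regime diagnostics

The 1:1 isotherm solves the mass-action quadratic for the complex in the
cancellation-free branch [PL] = 2PL / (b + √(b² − 4PL)), b = P + L + K_d,
stable down to K_d twelve orders below the concentrations. Dose–response
fitting offers the 4-parameter logistic on log₁₀ c (free Hill slope,
start 1.0; zero-concentration wells are floored one decade below the
smallest nonzero concentration) and the exact isotherm
F = F₀ + ΔF·f_bound(c; L, K_d). Both use trust-region least squares from
8 K_d starts log-spaced across the concentration range, ties broken by
residual norm then smaller K_d. Kinetic (hourly) series are reduced to the
scan at the equilibration timepoint — the first scan from which every
well's scan-to-scan change stays below 2% (relative), with a
non-equilibrated flag when the ramp never settles.

Regime classification: titration if L ≥ 10 K_d, binding if L ≤ K_d,
intermediate otherwise. The thresholds are a package choice (sharp enough
to make the ½L artefact detectable) and configurable. A caveat the tests
document: a free-endpoint 4PL on a hard-saturating stoichiometric curve
biases the parameter EC50 high by ~4% even without noise, because the
logistic approaches its top asymptotically while the data saturate
sharply; the raw half-signal crossing sits within 2% of the true
half-saturation point. Recovery property (200 seeded 1%-noise titrations,
K_d ∈ [1, 100] nM, L = K_d/10, 10-point ladders spanning K_d/20–20K_d):
median relative K_d error well under 10%.

The synthetic titration ladder defaults to a 2-fold serial dilution from
30 nM down to 0.23 nM (8 wells) — the canonical plate design for a
0.2–30 nM span.

## Thermal unfolding

Melts follow the two-state van 't Hoff form on absolute temperature with a
default ΔH_vH of 400 kJ/mol (typical protein-unfolding sharpness; the
melt data themselves carry no slope information), baselines 1.6 → 0.8 in
the A390/A376 ratio, and a 20–90 °C ramp sampled at 0.5 °C. T_m extraction
smooths with a Savitzky–Golay filter (window 7, order 2), differentiates
by central differences, and parabolically refines the extremum of |dA/dT|
(the absolute value makes the result independent of baseline direction
conventions). If the smoothed ratio moves by less than 5% of its starting
value across the ramp, the result is `no_transition` with no T_m — the
behaviour of a relaxed-conformation (cleaved) serpin that never releases
its chromophore below 90 °C. Noiseless recovery is within 0.1 °C across
T_m 45–85 °C and ΔH_vH 200–600 kJ/mol; at 1% noise the median error over
50 seeded replicates stays within 1.5 °C.

## Layered-tissue Monte Carlo

Geometry: air above; skin 0.1 mm; BBS lymph 0.1 mm; a transparent spacer
representing the reflector layer 0.1 mm; an ideal specular mirror below —
on a 300×300 grid of ~3.3 µm pixels (1 mm² domain). Both skin and lymph
carry BBS at the same concentration unless overridden; µ_a comes from the
band model via µ_a = ln10 · ε(λ) · c / 10 (mm⁻¹). Scattering is
wavelength-independent with defaults µ_s = 10 mm⁻¹ (skin), 1 mm⁻¹
(lymph), g = 0.9, n = 1.4 in every layer. An isotropic point source sits
at the center of the lymph layer; the detector is the full top boundary
(a literal point detector collects no weight in finite runs; the
acceptance segment is configurable).

Transport bookkeeping: step lengths s = −ln ξ/(µ_a+µ_s) truncated at
boundaries (the exponential's memorylessness makes fresh re-draws at
interfaces unbiased); each interaction deposits w·µ_a/(µ_a+µ_s) into the
pixel map; the top interface applies unpolarized Fresnel splitting with
total internal reflection past the critical angle; the mirror flips the
vertical direction losslessly. Russian roulette (threshold 10⁻⁴, survival
0.1) keeps a signed net balance inside the loss ledger — killed weight is
added, survival amplification subtracted — so
detected + absorbed + lost = 1 holds **per realized run** to ~10⁻¹²,
not merely in expectation. An optional path gate (max_path_mm ≈ 1.07 mm
emulates a 5 ps integration window at n = 1.4) truncates long paths;
default is CW (no gate).

Two direction spaces are supported. `slab` (default) propagates 3D unit
vectors over the 2D grid with the lateral axis untracked — an infinite
slab, which is how voxel Monte Carlo packages realize a "2D" simulation —
and therefore carries the physical TIR escape cone (~15% of solid angle at
n = 1.4). `planar` keeps directions strictly on the unit circle with the
2D Henyey–Greenstein phase function p(θ) ∝ (1−g²)/(1+g²−2g cos θ),
sampled by its exact inverse CDF (verified against numerical CDF
integration to sup-distance < 0.002); its isotropic and ballistic limits
are exactly testable, but its wide escape cone (~51% of directions)
shortens waveguided paths about five-fold. The distinction is physically
decisive for the reabsorption red shift: trapped light bouncing between
the subcutaneous mirror and the TIR-confining skin/air interface is what
accumulates absorbing path; with strictly 2D directions the 500 µM
escaping peak stalls near 704 nm for any plausible scattering, while slab
transport reproduces the in-vivo 697 → ≥710 nm shift with the default
optical properties.

Side boundaries: generic stacks default to absorbing walls, but the
in-vivo three-layer builder (`bbs_layer_stack`) defaults to **reflecting
(laterally periodic) sides**, because the 1 mm domain is a representative
patch of laterally extended skin and lymph — absorbing walls would kill
every waveguided photon within the domain width and cap the effective
reabsorption path at ~0.4 mm. Per-wavelength seeds derive from
SeedSequence(config seed, wavelength), so wavelength loops are
reproducible independent of execution order.

Problem sizes: the emission scans run 650–820 nm; the acceptance script
uses a 5 nm grid at 10⁵ photon packets per wavelength (the full in-vivo
study scale of 1 nm × 5·10⁷ is configurable), the analysis driver 2·10⁴
for quick tables. At zero concentration the periodic, conservative cavity
detects all launched weight at every wavelength, so the escaping spectrum
equals the source spectrum and the 697 nm endpoint is exact.

## Adding–doubling and inversion

Operators live in the flux representation (matrix entry = fraction of
flux from incidence ordinate j leaving in ordinate i), so layers compose
by plain matrix products and conservation is a column-sum identity. The
quadrature is Gauss–Radau on (0, 1] with an **exact node at µ = 1**, so
normal collimated incidence and the unscattered (Beer–Lambert) component
need no interpolation; with an index mismatch the quadrature splits at
the critical-angle cosine (Gauss–Legendre below, Radau above). The
Henyey–Greenstein redistribution matrix comes from the Legendre expansion
h(µᵢ,µⱼ) = Σ (2k+1) gᵏ Pₖ(µᵢ)Pₖ(µⱼ) truncated at gᵏ < 10⁻¹⁵, then
renormalized by a symmetric (Sinkhorn-style) iteration so the discrete
phase function scatters unit energy from every ordinate — this is what
makes a conservative slab return R + T = 1 to ~10⁻¹² after doubling.

Initialization is the first-order thin layer at τ₀ = τ/2^k with
k = max(1, ⌈log₂(τ/10⁻⁵)⌉); because k increments exactly when τ doubles,
a slab of thickness 2d and the sum of two slabs of thickness d start from
the *same* thin layer and agree to machine precision (the 10⁻⁸
self-consistency property holds by construction). Boundary Fresnel
interfaces are diagonal operators added via the general two-sided adding
equations — the intermediate slab-plus-one-boundary composite is
asymmetric, and using the symmetric shortcut there produces a spuriously
trapped (singular) mode.

Accuracy: at g = 0.9 the default order-8 quadrature under-resolves the
forward peak (R ~20% low); order 16 is within ~2% and order 32 within
0.1% of the converged value, which itself matches an independent
Monte Carlo slab run within statistical error (R 0.2498 vs
0.2502 ± 0.0007 at µ_a = 0.1, µ_s = 10 mm⁻¹, d = 1 mm). Accuracy-sensitive
work should pass `quadrature_order=16` or higher; the analysis driver
does. The strictly-2D (planar) transport differs from 1D slab theory by
~10% in R and ~0.5% in T for the same medium — a geometry gap, not an
implementation error, and the bound the planar cross-check test asserts.

Inversion (IAD) minimizes the summed squared **relative** errors of (R, T)
(so small transmittances are not swamped) over (µ_a, µ_s) at fixed g and
n, seeded from a 12×12 log-spaced grid in optical thickness
(τ_a ∈ [10⁻³, 10], τ_s ∈ [10⁻², 10²]) and refined by Nelder–Mead on the
log parameters; convergence requires relative residual < 10⁻³. R + T ≥ 1
(a conservative pair) is rejected as non-invertible — there is no
absorption to recover. Only normal collimated incidence is modelled;
integrating-sphere port geometry and lost-light corrections are out of
scope, a systematic (not statistical) limitation when applying the
inversion to sphere data.

## Synthetic data: what passing tests show

Every generator is a pure function of (parameters, seed), and each
noiseless generator output is exactly the corresponding analyzer's model,
closing the recovery loop stage by stage. Noise models are Gaussian —
multiplicative on titration signals, dilution absorbances and QY
emissions, additive on melt ratios and slab R/T. Real data deviate in
ways the generators do not emulate: correlated baseline drift, instrument
spectral response, inner-filter effects at high absorbance, asymmetric
emission bands, and protein aggregation near the melt. Passing recovery
tests therefore demonstrate the **estimators are correct and unbiased
under the stated noise model at the stated conditions**, not that real
measurements reach the same precision.

## Degenerate inputs and tie-breaks

Flat spectra return midpoints with flatness flags rather than arbitrary
argmaxes; rank-deficient extinction designs and non-positive QY gradients
raise; multistart fit ties are broken toward smaller K_d; the melt
no-transition threshold (5% of the starting ratio) is configurable; the
Monte Carlo guards non-terminating photons (transparent mirrored cavities
with no exit) with an explicit error and a generous per-photon step cap.
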