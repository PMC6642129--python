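# Methods

## Model overview

`phytotherm` treats ambient temperature as a radiometric quantity. Any body
above absolute zero emits thermal radiation with a Planck spectrum, and leaf
surfaces in thermal equilibrium with their surroundings behave very nearly as
black bodies (emissivity ≈ 1, fixed at exactly 1 here). The pipeline has
three stages:

1. **Radiometry.** Planck spectral energy density
   ρ_T(λ) = 8πhc/λ⁵ · 1/(e^{hc/λk_BT} − 1); plane irradiance
   E_d(λ) = (c/4)ρ_T(λ) = 2πhc²/λ⁵ · 1/(e^{hc/λk_BT} − 1) under the
   isotropic assumption; sunlight is the same expression at T_sun = 5778 K
   diluted by (R_sun/R_orbit)². Physiological temperatures (4–37 °C) peak
   near 10 μm (thermal IR, inside the 8–14 μm atmospheric window), while the
   solar spectrum peaks at 501 nm. The monochromatic photon flux
   N = E·λ/(hc) at a nominal band wavelength (660 nm red, 10 μm IR) is the
   quantity the kinetics consumes; a band-integrated flux is deliberately not
   offered, since every ratio the pipeline uses is taken at fixed wavelength
   and the band factor would cancel.
2. **Phytochrome kinetics.** The two-form photoreceptor model
   d[Pfr]/dt = N_Rσ_R[Pr] − N_FRσ_FR[Pfr] − N_IRk_IR[Pfr], where
   σ = 2.3·ε·φ is a photoconversion cross-section and the third term models
   dark reversion as an IR-driven photoconversion. In darkness the equation
   integrates to [Pfr](t) = [Pfr]₀e^{−N_IRk_IRt}, giving
   t_1/2 = ln2/(N_IRk_IR) and Pr/Pfr = e^{N_IRk_IRt} − 1 (the closed Pr/Pfr
   form assumes an all-Pfr start, the natural initial condition after red
   illumination).
3. **Regression.** (a) log₂ of the relative half-life against temperature in
   °C over {4, 12, 16, 22, 28, 37} °C, which is almost perfectly linear
   (slope ≈ −0.0243 per °C, R² ≈ 0.9988); (b) per-genotype hypocotyl length
   against the relative R:IR ratio r(T) = N_IR(22 °C)/N_IR(T), fitted by OLS
   on per-temperature means (per-seedling fitting is available), with a
   sensitivity ranking by |slope|.

## Parameters and units

| parameter | default | unit | rationale |
|---|---|---|---|
| h, c, k_B | 6.626e-34, 2.998e8, 1.381e-23 | SI | rounded values the reference irradiance table was computed with; overridable via a YAML/JSON constants block (CODATA precision changes the golden values by more than their printed rounding) |
| R_sun, R_orbit, T_sun | 6.95e8 m, 1.50e11 m, 5778 K | SI | solar dilution geometry |
| °C → K | +273.15 exactly | — | so 22 °C is exactly 295.15 K |
| IR wavelength | 10 μm | m | environmental Planck peak; monochromatic proxy for the thermal band |
| reference temperature | 22 °C | — | anchors r = 1 and relative t_1/2 = 1 |
| k_IR | ln2 / N_IR(22 °C) | per (photon flux × time) | only the product N_IR·k_IR is identifiable; this calibration makes the 22 °C dark half-life exactly 1 relative time unit. Time is therefore in relative units throughout; no absolute rate constant is claimed. |
| noise σ | 0.5 mm | mm | replicate scatter of the synthetic generator (see below) |
| n per condition | 15 | seedlings | matches standard hypocotyl assays |
| truncation floor | 0.1 mm | mm | prevents non-physical lengths |
| sensitivity cutoff | 0.5 × reference slope | — | reporting convention for the "reduced sensitivity" flag; configurable. At 0.5 the phyABCDE and YHB archetypes are flagged against a wild-type reference; hy1 (0.554 × reference) is flagged only at cutoffs above that. |

## Numerical choices

* **Planck evaluation** uses `expm1` for small exponents and switches to the
  Wien approximation e^{−x} for x > 500, flushing to exactly zero past the
  double-precision underflow point, so UV irradiances at leaf temperatures
  (values ~1e-65) neither overflow nor raise.
* **Peak wavelength** solves the Wien condition x·eˣ/(eˣ−1) = 5 by bracketed
  root finding (tolerance 1e-12), so λ_max·T is constant to machine
  precision; a dense grid argmax serves only as a test oracle.
* **Band integration** is adaptive quadrature (relative tolerance 1e-10) over
  10 nm – 1 mm with break points at multiples of the Planck peak; the result
  matches σT⁴ (σ = 2π⁵k_B⁴/15h³c² with the same constants) to well within
  0.1% from 277 K to 5778 K.
* **ODE integration** is fixed-step classic RK4 with step ≤ t_1/2/100,
  integrating [Pfr] only and recovering [Pr] from conservation (so
  [Pfr]+[Pr] is exact along trajectories). For a constant dark environment
  the closed-form exponential is used directly; the RK4 path agrees with it
  to better than 1e-6 of [Pfr]₀ over five half-lives.
* **OLS** is `scipy.stats.linregress`; R² is the squared Pearson correlation.
  A constant predictor raises a degenerate-fit error; a constant response
  returns slope 0 with R² defined as 0 and a warning. Slope standard errors
  use the classic OLS formula; no p-value or multiple-testing machinery is
  attached, as single fits per genotype do not call for it.
* **log base**: the half-life difference identity is base-free; reporting
  uses log₂ (the scale the half-life regression is quoted on), with the
  natural-log series one transform away.

## The synthetic generator and its validity window

The generator emulates the statistical structure the regression stage
assumes — a genotype-specific linear mean response
length = intercept + slope·r plus i.i.d. Gaussian replicate noise
(σ = 0.5 mm, a value giving plausible scatter on 1–20 mm hypocotyls and a
non-trivial recovery problem) — with a seeded `numpy` Generator whose seed is
recorded in the dataset and its CSV output. It does **not** simulate growth
dynamics over days, photoperiod, seedling-level covariance, or any
physiology; passing recovery tests therefore demonstrates correctness of the
generator→fit round trip, not fidelity to real seedling data (which the
printed per-genotype fit equations summarize but whose raw measurements are
not available).

One structural caveat is inherent to the presets: the steep wild-type-like
archetypes (slope ≈ −15 to −16 mm per unit r) extrapolate to *negative* mean
lengths at the coldest conditions (e.g. 18.662 − 14.853·1.375 ≈ −1.8 mm at
4 °C), where the 0.1 mm truncation floor dominates and any fitted slope is
necessarily biased toward zero. Recovery is therefore assessed over the warm
window {16, 22, 28, 37} °C, in which every archetype's mean clears the floor
comfortably (worst case: the near-flat YHB archetype at 16 °C, where ~1.3%
of draws are floored, biasing the mean slope by ~+0.007 — an order of
magnitude below the 2-SEM resolution of the 200-seed recovery check).
Datasets generated at the full six temperatures remain available and valid
as *data*; only unbiased parameter recovery is confined to the window.

## Known limitations

* Atmospheric transmission is not modelled; the 8–14 μm window is an
  assumption, not a computation. Emissivity is fixed at 1.
* The kinetics is a single well-mixed phytochrome pool: no phyA–E species
  resolution, dimerization, photobodies, or photocycle intermediates.
* Absolute time and absolute Pfr amounts are not identifiable from the model
  inputs; all kinetic outputs are relative.
* Four visible-range rows of the reference irradiance table are internally
  inconsistent with the stated plane-irradiance formula (UV-B/B/FR thermal
  cells low by a consistent factor ≈1.6, the red thermal row by ~7%, the
  730 nm solar cell by ~2%); they are carried as unverified values and a test
  measures, rather than "fixes", the deviation.
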