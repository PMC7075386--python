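# Methods

## Physical model and assumptions

The predictor is a single-Compton-scatter sightline model of photon
skyshine. A vertical beam of field area `F0` (cm² at the isocenter, 1 m
from the target) passes through the roof with transmission `B_xs`; each
air slab of thickness `dz` above the roof scatters photons toward a
ground-level observer at horizontal distance `d_s` from the isocenter.
Assumptions, in decreasing order of importance:

* **Single scattering from the beam axis.** Multiple scatter and the
  finite beam radius are neglected; this is the likely cause of the
  20–25% misfit published measurements show in the sidewall "shadow"
  (smallest distances).
* **Opaque sidewall.** The wall stops all scattered photons, so only
  scattering angles above `θ_m = π/2 + arctan(h/(d_s − d_w))` contribute.
  The observer is evaluated at isocenter height; no correction to
  ground or detector height is applied anywhere.
* **Large-angle, high-energy Compton cross section**
  dσ/dΩ ≈ [α(1 − cos θ)]⁻¹ with α = E_γ/0.511 MeV and the mean
  bremsstrahlung energy taken as (nominal MV)/3. The full Klein–Nishina
  form is deliberately not used; the approximation is marginal at 6 MV
  but its error is absorbed by the fitted constant.
* **No attenuation of either beam or scattered photons in air.** The
  2 MeV mean free path in air is ~189 m; the scattered photons
  (0.25–0.51 MeV) have a ~72 m mean free path, so predictions beyond
  100 m trigger a warning and should be read as upper bounds.

Carrying out the angular integral ∫_{θ_m}^{π} (1 − cos θ)⁻² dθ with the
antiderivative −(1/2)(cot(θ/2) + cot³(θ/2)/3) and
cot(θ_m/2) = √(1+x²) − x yields (1/3)·S(x),

    S(x) = 2(1 + x²)^{3/2} − x(2x² + 3),  x = h/(d_s − d_w),

and the dose rate

    Ḣ [nSv/s] = k (F0/400)(Ḋ0/400) B_xs S(x)/d_s.

The overall distance dependence is 1/d_s — the scattering column acts
like a line source — with S carrying the geometry: S(0) = 2 far from
the wall, S → 3/(4x) → 0 approaching it, producing a single interior
maximum at d_s − d_w ≈ 1.8–2 h. The 1/3 from the integral and every
physical prefactor (r_e², air electron density, α⁻², energy-absorption
coefficient ratios, the scattered/incident energy ratio) are absorbed
into the single empirical constant k.

## Parameters

| symbol | meaning | units | default |
|---|---|---|---|
| `d_w` | isocenter → outer sidewall surface | m | — |
| `h` | isocenter → roof top | m | — |
| `d_i` | target → 2 m above roof (empirical formula only) | m | `h + 3` |
| `F0` | field area at isocenter | cm² | — |
| `Ḋ0` | dose rate at isocenter | cGy/min | — |
| `B_xs` | roof photon transmission | — | — (always user input) |
| `k` | model constant | nSv/s | 312 / 200 / 160 for 6/10/18 MV |
| `W, U, T` | weekly workload, use factor, occupancy | Gy/wk, —, — | — |
| `W_h` | busiest-hour workload | cGy | 800 |
| `P` | sidewall weekly design goal (ALARA) | μSv/wk | 10 |

The default k values are fits to published facility measurements; their
accuracy is limited mainly by how well each facility's `B_xs` was known
(the 18 MV value especially). Roof-thickness design is out of scope:
`B_xs` is always an input, never derived from attenuation tables. The
uncontrolled-area weekly goal used in audit interpretation is
20 μSv/week, overridable.

## Numerical choices

* **Closed form vs quadrature.** `scatter_shape_numeric` integrates the
  angular kernel with `scipy.integrate.quad` at absolute tolerance
  1e-10 and is the independent oracle; the model itself always uses the
  closed form. Their equivalence (|S − 3·quad| ≤ 1e-8 over
  x ∈ [10⁻³, 10³]) is asserted in the test suite and re-checked at
  every CLI run (logged to stderr).
* **Stable evaluation of S.** The polynomial form of S loses ~1e-7
  absolute accuracy by x ≈ 10³ to catastrophic cancellation; S is
  evaluated as the algebraically identical (2u + x)/(u + x)²,
  u = √(1+x²), accurate to machine precision at all x ≥ 0.
* **Dose-maximum search.** `find_dmax` maximizes S(x)/d_s — pure
  geometry — on a 2001-point grid over (d_w, d_w + 20h], then refines
  with bounded scalar minimization to well below 0.01 m. The profile is
  provably monotone declining long before d_w + 20h for realistic
  vaults; the bracket is asserted in tests.
* **Solid angle.** The empirical comparison formula uses the exact
  square-field solid angle 4·arcsin(a²/(a² + 4d²)) by default, since
  the published comparisons do not state which form they used; the
  (a/d)² small-field form (high by ~4% at a/d = 0.4) is a flag away.
* **Units.** Photon radiation weighting factor 1 throughout, so
  1 cGy ↔ 1000 mrem ↔ 10 mSv; all conversions live in `skyshine.units`.
  The weekly constant 1.5×10⁻² is a pure unit conversion
  (H_w = Ḣ · 6000·W·U·T/(1000·Ḋ0), independent of Ḋ0); a property test
  over random parameter draws pins it rather than trusting the
  hard-coded literal.
* **Calibration.** The model is linear in k, so both losses are closed
  form. The default log-space least squares,
  ln k̂ = mean(ln y_i − ln model_i(k=1)), treats survey noise as
  multiplicative, which matches the percentage-style residuals of the
  published fits; linear-space (optionally 1/σ²-weighted) least squares
  is available. Points at d_s ≤ d_w are hard-rejected — the model is
  undefined there — and non-positive readings are excluded with a
  warning (erroring below 3 usable points). Power-law exponents come
  from OLS of ln y on ln d_s with standard errors from the residual
  variance; the estimator behind published exponent uncertainties is
  unstated, so plain OLS errors are reported as such.

## Synthetic data

`synthesize_profile` draws value_i = model(d_i)·exp(ε_i),
ε_i ~ N(0, σ_rel) i.i.d. from a seeded generator (a seed is mandatory
whenever σ_rel > 0). It emulates the one noise feature calibration
must be robust to — multiplicative, percentage-scale instrument
scatter (default σ_rel = 0.05, matching the <10% residuals of the
published mid-range fits) — and none of the systematic features of
real surveys: distance-correlated misfit near the wall, attenuation
steepening beyond ~50 m, uncertain B_xs, detector energy response.
Passing parameter-recovery tests therefore demonstrates the estimator
is correct and unbiased under the stated noise model, not that k can
be recovered this accurately from a real survey, where the error
budget is dominated by B_xs.

Parameter-recovery test sizes (30-point profiles on 6–50 m, 200 seeded
replicates for the distribution check) were chosen to keep the whole
suite fast while giving the ±2σ/√n recovery band a comfortable margin.

## Known limitations

* Neutron skyshine is out of scope entirely; for 18 MV facilities it
  can exceed the photon component and needs separate evaluation.
* No TVL/attenuation tables: the package cannot convert a roof
  thickness into B_xs or vice versa.
* Published 18 MV profiles fall off as ~d_s^−1.5 beyond 19 m, steeper
  than the model's ~d_s^−1; the model's own mid-range (19–50 m)
  exponent for a typical vault is ≈ 0.77. Beyond d_max the model tends
  to overpredict measured rates.
* Side scatter into adjacent multistory structures is not modeled.
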