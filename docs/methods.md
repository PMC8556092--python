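# Methods

This note records the models implemented in `peffkit`, their assumptions,
the places where the published formulation is ambiguous and what this
package chose, and what the synthetic-data tests do and do not demonstrate.

## Water-equivalent thickness (module `chambers`)

A chamber wall/window is an ordered stack of homogeneous layers; the WET of
a stack is the sum of per-layer WETs (additive, order-independent):

* PMMA: `t × 1.16` (the standard PMMA-to-water path-length factor; the
  published worked calculations use it without a density term),
* graphite: `t × ρ × (1.16/1.19)` — the PMMA factor rescaled by the layer
  density relative to PMMA's 1.19 g/cm³,
* lacquer, water: `t × 1.0`.

These per-material constants are inferred from the two published worked
sums they must reproduce: 2.0648 mm for the plane-parallel reference
chamber (PTW 34080, (0.62 + 1.16) mm PMMA × 1.16) and 4.022 mm for the
in-field chamber (PTW 34070, 3.35 PMMA + 0.02 graphite + 0.1 lacquer).
Both are reproduced exactly at the printed precision; the factors sit in
`WET_FACTORS` so another protocol can override them. Two published
inconsistencies are handled as follows:

* the 34080 worked sum absorbs its graphite coat into "1.16 mm electrode
  PMMA" while the 34070 sum scales graphite separately; each bundled record
  uses the stack the published number was computed from, per chamber;
* the sentence assigning 4.022 mm also to the Farmer 30013 *wall* is
  treated as a transcription error — its layers (0.335 mm PMMA + 0.09 mm
  graphite) sum to 0.5509 mm, which is what the bundled record ships.

## The Dutreix cavity integral (module `dutreix`)

Assumptions: a parallel, uniform, forward-directed fluence; the full chord
2*y* at entry angle θ contributes; entrance weighting cos θ; no electron
transport. Under these the shift is the pure geometry factor 8/(3π)
≈ 0.84883 of the cavity radius — independent of *r* and of any constant
fluence weight. Both the closed form and a Gauss–Legendre quadrature of the
integrand are provided; the quadrature is spectral (|error| < 1e-12 by 64
nodes) and exists to validate the tilted variants below.

## The scatter ("barrier") decomposition (module `barrier`)

The carbon-ion generalization tilts the entering fluence by the beam
spreading angle φ and splits the shift into

* vertical: `y_eff,v/r = (4/π)(8cos²φ/15 − cosφ·sinφ/5)` — the closed form
  of the printed integrand `2r³cos⁴θ·cosφ·cos(θ+φ)` over the Dutreix
  denominator; reproduces the published "Vertical shift" row;
* horizontal: `y_eff,h/r = (4/π)(2cos²φ/15 + 2cosφ·sinφ/15)` — closed form
  of the printed side-scatter integrand. This does **not** reproduce the
  published "Horizontal shift" row, whose derivation the source defers to
  an appendix it does not contain; the horizontal row is therefore exposed
  as bilinear interpolation over the published ten-condition grid, and the
  literal value always carries a warning flag.

Angle conventions: φ is the spreading angle of the normally incident beam,
`sin φ = +√(1−cos²φ)`, and `cos(90−θ−φ)` / `sin(90−θ−φ)` are expanded as
`sin(θ+φ)` / `cos(θ+φ)`.

### Literal vs calibrated mode

The published parameter chain ε(E, FS) → α → cos φ does not evaluate to the
published table under any operator-precedence reading tried (the literal
cos φ formula with α = 0.84, R_L = −0.6 gives 1.41, outside [0, 1]). Every
entry point therefore runs in one of two modes, always recorded in the
report:

* `literal`: the formulas exactly as typeset (ε = 1.6·exp(ln E_c·√FS);
  α = ε·exp(−1.1·Z − 0.68·E_c) as the documented precedence guess;
  cos φ = 1 − 2αR_L/(1+α−R_L)), flagged as not reproducing the table;
* `calibrated`: anchored to the published table — α = C(FS)/E_c with C
  least-squares fitted to the ten printed α cells (C(3 cm) = 100.9 MeV/u,
  C(10 cm) = 22.95 MeV/u; all ten cells reproduced at two decimals; ln C
  interpolated linearly in ln FS between fitted sizes), cos φ and the
  horizontal shift by grid interpolation.

### Reproduction status of the published table

Recomputing the four trigonometric term rows from the ten *printed* cos φ
values matches 37 of 40 cells after two-decimal rounding. The three
mismatching cells (both scatter terms with sin φ in the 120 MeV/u 10×10
column; the 8cos²φ/15 term in the 330 MeV/u 3×3 column) are all
simultaneously consistent with unrounded cos φ ≈ 0.885 and ≈ 0.835 — i.e.
the printed cos φ row is itself rounded and the table was computed from
more digits, which the printed values cannot recover. The vertical-shift
quadrature matches the printed row within 0.015 in 9 of 10 columns; the
400 MeV/u 3×3 cell (printed 0.34, computed 0.39) deviates by ≈ 0.05 and is
treated as a suspected misprint (documented, not asserted). "Total" equals
horizontal + vertical exactly in all ten columns.

Sign convention: shifts are stored as positive magnitudes; serialized
reports add a signed field with a leading minus meaning "upstream toward
the source". Report rounding is two decimals (round-half-to-even),
deviations one decimal, matching the published precision.

## Curve analysis (module `curves`)

* Peak definition: vertex of a least-squares parabola over samples within
  ±2 mm (configurable) of the maximum sample, ties broken toward smaller
  depth. This is exact for any symmetric peak sampled symmetrically and is
  the only peak definition used (distal-80% or spline fits are out of
  scope, since only maximum-peak positions enter the shift). A maximum at
  the boundary of the scanned range is an error, not a value.
* Depth coordinate: 0 at the phantom entrance-window inner surface; all
  WET corrections are additive. Setup chains (tank wall, clearances,
  chamber windows) are user-supplied config because the published
  item-by-item decompositions behind the corrected depths 195.782 mm and
  198.06 mm are not enumerated; the example chains in the tests reproduce
  those totals but their per-item values are illustrative.
* Shift ratio uncertainty: sample standard deviation over replicate pairs
  (undefined, reported as NaN, for a single replicate).
* Monotone (PCHIP) resampling exists for overlay plotting only and is
  never used in peak finding.

## Synthetic beams (module `synthbeam`)

The generator is phenomenological, not a transport model: a pristine curve
is a Gaussian peak of width σ (default 0.01·R) on a pedestal that rises
linearly from the entrance plateau (default 25 % of peak) into the peak,
holds constant through the near-peak region, and cosine-tapers to zero
between R+3σ and R+5σ (a crude fragment tail). The range follows
R = a·E^p with p = 1.7 and a solved so that R(330 MeV/u) = 195.78 mm, the
published water-equivalent peak depth at that energy; p = 1.7 is the
familiar range–energy power-law exponent for ions in water and puts
120 MeV/u at ≈ 35 mm. Noise is multiplicative Gaussian, seeded.

The pedestal is deliberately *locally constant* around the peak so that
both the parabola fit and the symmetric chord kernel see an unbiased peak;
this is what makes injected-shift recovery exact to ≈ 2×10⁻⁴ noise-free.
The cavity response is a chord-length-weighted average
(w(u) = 2√(r²−u²), normalized) followed by relabeling the depth axis
downstream by the injected `peff_ratio·r` — a chamber whose effective point
is upstream of its centre sees the curve arrive late in centre coordinates.

What passing tests therefore show: the *extraction pipeline* (peak fit,
WET chains, ratio bookkeeping) is unbiased and noise-robust at the stated
grid and noise levels. What they do not show: anything about real detector
perturbations — fluence-spectrum changes inside the cavity, fragmentation
tails, lateral scatter, recombination or quenching are all outside the
generator.

## Dose conversion (module `doseconv`)

`K(E) = D_meas·A/(S·MU)` is the only dimensionally consistent arrangement
of the monitor-calibration quantities; with D in Gy (J/kg), A in cm² and S
in MeV·cm²/g the particle count uses 1 MeV = 1.602176634e-13 J *and* the
g→kg factor, i.e. D[Gy] = 1.602×10⁻¹⁰·Φ[cm⁻²]·S[MeV·cm²/g]. The
air-density correction k_TP uses the standard (273.2+T)/(273.2+T₀)·(P₀/P)
with configurable reference conditions (20 °C, 1013.25 hPa); it is exposed
as an explicit factor of `absorbed_dose_peff` because protocols differ on
whether the reported charge already includes it (pass 1.0 if it does). All
w/e values and stopping-power ratios entering K_Q are user inputs; the
package bundles no physics constants presented as authoritative.

## Numerical choices

* Quadrature: Gauss–Legendre, 128 nodes default, on θ ∈ [0, π/2]; constant
  fluence weights cancel analytically and are not carried.
* Grid interpolation over the published table: bilinear (linear in field
  size at each tabulated energy, then linear in energy); exact at grid
  points; extrapolation is opt-in.
* Parabola fit degeneracies: a non-concave fit window falls back to the
  maximum sample; the vertex is clipped to the fit window.
* The curve reader rejects non-monotone or duplicate depths, negative
  readings and files with fewer than five rows, naming the offending row.

## Known limitations

* The calibrated barrier mode interpolates the published grid; outside
  120–400 MeV/u or 3–10 cm it extrapolates only on request and flags it.
* The literal formula chain is preserved for inspection but cannot
  reproduce the published table (see above); R_L has no published meaning
  beyond "a parameter describing a Gaussian distribution" and no admissible
  range.
* Plane-parallel chambers are treated as ideal reference detectors; no
  perturbation corrections (k_s, k_pol, humidity) anywhere.
* Square fields only; SOBP composition, lateral profiles and film
  dosimetry are out of scope.
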