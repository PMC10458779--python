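# Methods

## Model

The package treats tuber growth as carbon accounting. Starch synthesis is
represented by four lumped reaction stages: light capture
(chlorophyll + photon energy → ATP), carbon fixation
(6 CO₂ + 6 H₂O + ATP → C₆H₁₂O₆ + 6 O₂), glucose respiration in the tuber
(C₆H₁₂O₆ + 6 O₂ → 6 CO₂ + 6 H₂O + ATP), and polymerisation
(C₆H₁₂O₆ + ATP → C₆H₁₀O₅ + H₂O). Eliminating glucose and the tuber-side
ATP — two fixation stages feed one respiration and one polymerisation —
gives the net reaction 6 CO₂ + 5 H₂O + 2 ATP → C₆H₁₀O₅ + 6 O₂: one starch
monomer per six CO₂ molecules. Reaction algebra uses exact rational
coefficients so cancellation is exact; ATP and the photon-energy term are
opaque tokens excluded from the elemental ledger (they are written without
structural formulas, and the light stage is qualitative only — no energy
budget is modelled). Atomic weights are a bundled IUPAC table (3 d.p.),
giving m₁ = 2.6924×10⁻²⁵ kg for the monomer and 7.308×10⁻²⁶ kg for CO₂.

Assumptions: the chamber is well mixed; temperature and pressure are
constant per chamber spec and CO₂ behaves ideally
(n = x·10⁻⁶·P/(k_B·T)); every absorbed CO₂ molecule that the active
stoichiometric mode credits ends up as tuber starch, diluted to fresh mass
by the starch fraction η_starch; all environmental influence (light,
temperature, humidity) enters only through the measured CO₂ dynamics.

## Stoichiometric modes

The published derivation of the drawdown formula places the factor of six on
the monomer side (six monomers per CO₂), contradicting the balanced net
reaction (six CO₂ per monomer); its integral form further applies 6/η
directly to a CO₂ *mass*. Rather than silently correcting or silently
reproducing, the estimator carries an explicit mode:

- `mass_balance` (default): f = m₁/(6η) per molecule. Elementally
  conserving; starch gained = (162.14/264.06) × CO₂ mass absorbed.
- `as_published_eq13`: f = 6m₁/η, the drawdown formula as printed
  (36× the conserving value).
- `as_published_eq14`: 6/η applied to CO₂ mass, i.e. f = 6m_CO₂/η per
  molecule (≈9.8× the conserving value).

For any input the predictions order eq13 ≥ eq14 ≥ mass_balance. A warning
is raised whenever an as_published mode runs. Whether a published
calculated yield used the eq13 or eq14 factor cannot be settled without
the original flux tabulation, so neither mode is claimed to reproduce any
particular printed mass; both are available for literature-faithful runs.

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| η_starch | – | 0.20 | varietal range 0.10–0.25; warning outside it |
| m_tubers(0) | kg | 0 | seed tuber mass at planting; measured, never corrected |
| partition ratio ρ | – | 1.0 (off) | total biomass / tuber biomass; 1.46 at 20–24 °C bundled as a named constant; divides the predicted mass *increment* only, since m_tubers(0) is a measurement, not a prediction |
| V, T, P | m³, K, Pa | –, 293.15, 101325 | chamber state, constant per run |
| leak coefficient k | 1/s | 0 | first-order relaxation toward ambient; user input, optionally fitted from a plant-free decay trace (log-linear regression) |
| injections | molecules at times | none | instantaneous impulses (well-mixed); ramps can be expressed as several impulses |

## Numerical choices

- Quadrature is composite trapezoid on the native sample grid (flux
  integral and leak integral); exact for piecewise-linear integrands,
  second-order for smooth ones; no resampling unless the caller does it.
- Negative drawdown (concentration rising, e.g. nighttime respiration) is
  retained as a signed estimate; a clamped-at-zero view is offered and
  flagged, since the estimator itself is silent on non-monotone traces.
- The inverse design helper `required_drawdown` is the exact algebraic
  inverse of the sealed estimator, including the partition correction.
- Comparison ratios are reported at 2 decimals by default, matching the
  precision such verification figures are usually quoted at.
- All internal units are SI (kg, m, s, K, Pa); the report layer also shows
  g, mol, days and ppm.

## Synthetic experiments

The simulator emulates the sealed-room thought experiment the estimators
invert: whole-plant uptake A(t) = A_max · logistic canopy growth ·
photoperiod square wave, with dark hours flipping uptake to respiration at
a fixed fraction of A_max. Defaults (40 m³ chamber, 1000 ppm start,
A_max = 10¹⁸ molecules/s, canopy half-grown at day 8 with a 2-day time
scale, 16 h photoperiod, 10 % dark respiration, 2 ppm Gaussian sensor
noise, 20 days at 60 s steps) produce a realistic day/night sawtooth
drawing the chamber down by roughly 650 ppm over the run.

The state steps explicitly at the scenario step; the absorption term is
taken at the step start, while the leak term is accounted trapezoidally
within the step (Crank–Nicolson in n). The trapezoidal leak form was
chosen over pure explicit Euler because the ground-truth bookkeeping must
be second-order consistent with the trapezoid quadrature the recovery
estimator applies — with a first-order leak tally the forward/inverse
round trip carries an O(dt) bias that never converges away. Absorption
saturates at the CO₂ actually available, so simulated concentration never
goes negative. The truth series tallies exactly what the discrete system
removed, which makes the sealed noise-free round trip exact to rounding;
an `oversample` knob refines the internal step (output grid unchanged) for
convergence studies against the continuous dynamics. Sensor noise is
additive i.i.d. Gaussian in ppm from a seeded generator; the seed is
recorded in simulation provenance output.

What the generator does *not* emulate: mechanistic photosynthesis
(light/CO₂/temperature response), stomatal behaviour, humidity, imperfect
mixing, sensor drift or calibration error, and pressure-driven advective
exchange. Passing round-trip tests therefore demonstrates that the
estimators correctly invert the chamber mass balance they assume — not
that a real chamber satisfies that balance; on real data the leak law and
the well-mixed assumption are the components most likely to bite.

A bundled 20-day hump-shaped flux profile (sin² envelope, peak
8×10⁻⁷ kg m⁻² s⁻¹, leaf area 0.38 m²) is a synthetic stand-in for measured
leaf gas-exchange curves and exists so the flux-integral estimator has a
self-contained input; it is generated by code, not digitised from any
measurement.

## Known limitations

- The partition correction is a single constant ratio; real partitioning
  varies over the season and with temperature.
- k must be known or fitted from a plant-free period; it is not jointly
  estimated with absorption from a single trace (the two are confounded
  without extra information).
- The sealed estimator uses only the endpoints of the drawdown, so a few
  ppm of sensor noise on a several-hundred-ppm drawdown is negligible, but
  short windows with small drawdown are noise-limited.
- Problem sizes in the test suite (20-day scenarios at 60 s steps, 100
  random traces for the invariants) were chosen as the smallest runs that
  exercise day/night cycling and canopy growth while keeping the suite
  quick to run.
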