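# Methods

This note documents the models implemented in `coreflow`, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical conventions that matter for reproducibility.

## Virtual-core filtration

The instrument measures every particle in the open sample stream, but only
particles near the stream centre are in the optical system's focal volume.
Membership is decided from the two position detectors (d1, d2) and forward
scatter (fsc), all log₁₀-transformed:

- **alignment**: |log₁₀ d1 − log₁₀ d2| ≤ tol, with tol set to the 97.5th
  percentile of the bead log-ratio distribution (self-calibrating and
  dimensionless);
- **focus**: log₁₀ d1 and log₁₀ d2 each at or below a boundary line
  evaluated at the particle's log₁₀ fsc.  The boundary is two line segments
  meeting *exactly* at the anchor — the per-channel median of the gated
  1-µm bead population — with slopes fit separately below and above the
  anchor.

Slopes are anchored quantile regressions: the slope through a fixed anchor
minimizing the pinball loss at level τ is the weighted τ-quantile (weights
|x−x₀|) of the point slopes, with the (1−τ) flip on the left segment and
ties broken toward the smaller slope.  Quantiles 2.5/50/97.5% give nested
acceptance regions; monotonicity of the slopes in τ is enforced per segment
so the nesting is structural, not statistical.  Filtration parameters are
fit once per cruise on beads pooled over all files — bead statistics per
file are too small for stable slope extrapolation several decades from the
anchor — and are identified by a deterministic hash (`filtration_id`).

Boundary-inclusive comparisons (≤) are used, so a particle exactly at the
anchor is accepted at every quantile.

## Classification

Gates are applied sequentially in the fixed order beads → synecho → croco →
prochloro (density mode) → picoeuk → unknown; the first containing polygon
wins and gated particles leave the pool.  Polygons live in log₁₀ raw
channel space: gating precedes bead normalization because the beads
themselves are identified by the first gate.  Polygon validity (simple, ≥3
vertices) is checked with shapely at construction; point-in-polygon tests
use matplotlib's path code.

The *Prochlorococcus* step finds the dominant density mode of the remaining
pool in (log fsc, log red): a 128×128 binned KDE (Gaussian smoothing,
per-axis Silverman bandwidth), watershed segmentation around local maxima,
then a merge of basins whose separating saddle exceeds half the lower of
the two peak densities.  The saddle merge is what makes the step robust:
defocus elongates each population into a ridge along the scatter axis, and
sampling noise otherwise fragments the ridge into several shallow maxima.
The most populated merged basin is labelled (ties toward lower scatter).
The full basin is labelled by default (`contour_mass = 1.0`); a smaller
mass fraction trims the basin to its densest contour when a conservative
core of the population is wanted, at a proportional cost in recall.  The
procedure involves no random draws, so identical inputs give identical
labels; a `seed` argument exists for interface stability.

## Mie sizing

Forward scatter of a homogeneous sphere of diameter d and refractive index
n in seawater (n_m = 1.34) is modelled by the Mie series (size parameter
x = π d n_m / λ, λ = 457 nm from the instrument's forward-scatter bandpass,
relative index m = n/n_m, truncation N = ⌈x + 4x^⅓ + 2⌉, logarithmic-
derivative downward recurrence).  The detector is an annular cone with two
free half-angles; collected power is the unpolarized phase function
integrated over the annulus by 96-node Gauss–Legendre quadrature.  All
responses are normalized by the same quantity for a 1-µm, n = 1.60 sphere,
so the bead anchor is exactly 1 by construction.

The two half-angles are fit to the bead calibration table (n = 1.60,
diameters 0.3, 0.5, 0.75, 1, 1.83, 3.1, 5.7 µm) by Nelder–Mead on the sum
of squared log₁₀ residuals, with a positivity/ordering transform
(inner = e^p₀, outer = inner + e^p₁).  Self-generated bead tables recover
known angles to well under a degree.  Defaults (3°, 45°) were chosen
because a small inner angle captures the forward lobe and keeps the
response curve monotone over the working range for all three cell indices;
wide-annulus geometries (inner ≳ 10°) produce interference ripple large
enough to make inversion ambiguous at the lowest contrast (n = 1.35).

Inversion uses a 2,000-point log-spaced diameter grid over [0.2, 6.0] µm,
isotonic (least-squares monotone non-decreasing) regression of log response,
and linear interpolation in (log scatter, log diameter); plateau ties
resolve toward the smaller diameter, and out-of-range scatter clamps to the
grid endpoints with a flag.  ESD is reported at n = 1.35, 1.38 and 1.41,
bracketing marine phytoplankton; for fixed scatter ESD decreases with
index.  Carbon quota is Qc = 0.261 · V^0.860 (fgC, V in µm³) with
V = (π/6)·ESD³.

## Quantification and errors

Sample volume is flow rate × duration (µL); core volume is the OPP/EVT
ratio times sample volume.  Abundance = count / core volume.  The reported
`abundance_se` propagates only the flow-rate calibration uncertainty (delta
method — the relative SE passes through unchanged), matching the
instrument's stated error model; Poisson counting error √n / core volume
is computed and stored in `abundance_se_count` but never folded in.  When a
metadata file lacks `flow_rate_se`, 5% of the flow rate is assumed.

Because the OPP ratio is measured on the same stream that is counted, any
position-dependent acceptance probability that is *common across
populations* cancels between numerator and denominator, which is why
abundance recovery in simulation is unbiased even though the 50%-quantile
filter accepts well under half of all events.

## Quality control

Instrument flags are strict inequalities: pressure deviation > 5% of the
cruise mean (mean over non-null pressures; all-null ⇒ not evaluable) or
event rate > 18,000 s⁻¹.  The Chauvenet screen is the classical single-pass
rule — flag x when N · 2Φ̄(|x−x̄|/s) < ½, with the sample sd (ddof = 1) —
applied per cruise and population to abundance, median ESD and median
carbon quota (at n = 1.38).  Groups with fewer than 4 finite values are not
evaluable; bead rows are calibration material and are never screened.
Flags are tri-state (`pass`/`fail`/`na`) and flagged records are retained
in the output for the user to filter.

## The simulator

`coreflow.synthetic` draws Poisson particle arrivals at rate
(Σ concentration × flow), assigns populations multinomially, and gives each
particle a lognormal diameter, lognormal fluorescence, and two lateral
coordinates: u on the position-detector axis (the virtual core is
|u| ≤ 0.25) and v, a focal offset.  Forward scatter is the package's own
Mie detector response attenuated by exp(−3.4·|v|) with 0.05-decade
lognormal noise; the position detectors respond to observed forward scatter
through a log-linear gain curve plus an even position boost 4.5·|u| shared
by both detectors and an opposing odd term ±0.5·u.

Two structural choices are deliberate.  (i) Focus (v) and lateral position
(u) are independent coordinates: if a single coordinate drove both the
scatter attenuation and the position-detector boost, the anchored bead
regression would absorb the entire position dependence into its slope and
the OPP test would degenerate into a brightness cut.  (ii) The |u| and |v|
profiles are linear, so with uniform positions the residuals around the
gain curve are symmetric; skewed profiles (e.g. quadratic) measurably bias
the anchored quantile slopes and make acceptance population-dependent at
the several-percent level when the boundary is extrapolated two decades
from the anchor.

Default study conditions: 5 files of 180 s at 0.5 mL min⁻¹ (1.5 mL each),
concentrations 3.0 / 0.8 / 0.25 / 0.06 cells µL⁻¹ for *Prochlorococcus* /
*Synechococcus* / picoeukaryotes / *Crocosphaera* plus 1.5 beads µL⁻¹,
diameters 0.55 / 1.0 / 1.7 / 2.2 µm at n = 1.38, fluorescence centroids
separated by ≥ 1 decade in at least one gating channel.  These are scaled
to give per-file OPP counts of order 10²–10³ per population (the regime of
the real three-minute files) while keeping a simulated cruise fast enough
to iterate on; the concentration *ratios* follow the oligotrophic surface
ocean ordering.  The matched gating spec uses ±0.55-decade boxes (3.7σ at
the default 0.15-decade fluorescence spread), elongated along the scatter
axis to cover the defocus tail.  A `hard_config` preset overlaps
*Prochlorococcus* with a debris population near the noise floor to exercise
the density clusterer beyond its comfortable regime.

What the simulator does **not** emulate: correlated drift in gains or flow
rate within a cruise, non-spherical or structured cells (all particles are
homogeneous Mie spheres, so sizing errors are purely inversion errors),
coincidence at high event rates, fluorescence spillover between channels,
and position-dependent fluorescence collection.  Passing recovery tests
therefore demonstrates the correctness of the processing chain under its
own measurement model, not the accuracy of Mie sizing for real cells.

## Numerical conventions

- Quantiles in summaries: linear interpolation between order statistics
  (type 7, numpy default).
- Quantile-regression ties: smallest minimizing slope.
- Isotonic plateaus invert to the smallest diameter.
- All hashes (`filtration_id`, `gating_id`) are SHA-1 over rounded
  parameter values, truncated to 12 hex digits.
- Empty populations are omitted from summaries; `unknown` is kept by
  default and can be excluded by configuration, in which case per-file
  population counts sum to |OPP| minus unknowns.
- Missing metadata propagate as nulls, never zeros.
- Determinism: a single `numpy` `default_rng(seed)` drives each simulated
  cruise; the processing chain itself is deterministic, so identical inputs
  and seed reproduce the curated CSV byte for byte.

## Known limitations

- The two-piece boundary is extrapolated beyond the bead cloud; populations
  scattering far outside the bead calibration range (≳ 1 decade above the
  1-µm bead) approach the acceptance edge and would need a second, larger
  bead size for reliable filtration.
- ESD medians for strongly defocused particles are biased low (defocus
  attenuates scatter but does not change size); the curated medians are
  dominated by in-focus particles, keeping the bias small but nonzero.
- The Chauvenet screen assumes approximate normality within a cruise ×
  population group; strong real trends along a cruise track would inflate
  its flag rate.
- The red/orange channel labels follow pigment roles (red = chlorophyll,
  orange = phycoerythrin); the instrument's printed filter-to-channel
  wavelength mapping is recorded in configuration without asserting which
  published variant is authoritative.
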