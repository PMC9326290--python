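# Methods

## Model overview

`thermopmi` estimates the postmortem interval (PMI) by coupling a
thermodynamic finite-difference (TFD) forward model of body cooling to a
surrogate-model-based search over the two parameters that are usually
unknown in casework: the perimortem body temperature T_peri and the
ambient temperature T_amb.

### Geometry

A body-surface point cloud is embedded in a cubic grid (default cube
size 0.01 m; 0-based indices; cube *i* occupies the half-open interval
[origin + i·Δx, origin + (i+1)·Δx) per axis, with a 1e-9-cube tolerance
against floating-point jitter for points on cell boundaries). Cubes
containing at least one surface point are surface cubes; the solid
interior is recovered by flood-filling the 6-connected complement from
the domain boundary — cubes unreachable from outside become body. If the
interior leaks to the boundary the cloud is not watertight at that
resolution and voxelization fails with a diagnostic rather than
guessing. A substrate slab (default 0.05 m, wood-like) spans the domain
beneath the body's lowest extent; the outermost cube layer is always
clamped to ambient. An optional one-cube clothing shell exists in the
material table but is off by default. Analytic phantoms (ellipsoid,
capped cylinder) provide deterministic test bodies with logger sites at
chosen angular positions; an optional adipose shell is assigned to body
cubes within a given distance of the surface (Euclidean distance
transform). How adipose tissue was distributed in the original study
bodies is unknown; the shell is a plain stand-in.

Voxel volumes over-count the true solid by ≈ area·Δx/2 (surface cubes
are counted whole), about 10 % for the default ellipsoid at 1 cm and
shrinking linearly with Δx — relevant when validating against analytic
volumes, irrelevant for cooling curves.

Logger positions snap to the nearest surface body cube (Euclidean
distance between cube centres; ties toward the lexicographically
smaller index; positions farther than 0.05 m from any surface cube are
rejected — skin markers with sub-centimetre photogrammetric noise never
are).

### Thermal model

Explicit finite differences on the labelled grid:

    T_i ← T_i + Δt/(ρ_i c_i Δx²) · Σ_{j∈N6(i)} k_ij (T_j − T_i)

with k_ij = 2 k_i k_j/(k_i + k_j), the harmonic mean — the conservative
choice for discontinuous conductivity. Updates are Jacobi-style in
double precision; on insulated domains the scheme conserves
Σ ρ_i c_i Δx³ T_i to ~1e-13 relative per 1e4 steps, and under constant
ambient it obeys the discrete maximum principle. The time step defaults
to half the explicit stability bound min_i ρ_i c_i Δx²/Σ_j k_ij and is
rounded down so the output interval (default 5 min) is a whole number of
steps. Body cubes start at T_peri, everything else at T_amb(0).
Clamped-ambient cubes — the outermost layer plus all air farther than
the free-air shell (default 0.05 m) from the body — are reset to
T_amb(t) after every step, so step or periodic ambient histories apply
exactly at the step boundary. No metabolic heat, no explicit radiation,
no humidity-dependent evaporation, no body cavities.

**Effective air conductivity.** The model transports heat through air by
conduction only. Molecular still air (k = 0.026 W m⁻¹ K⁻¹) across the
resolved ~5 cm boundary layer gives a surface exchange of ~0.5 W m⁻² K⁻¹
— an order of magnitude below the free-convection-plus-radiation range
(≈5–9 W m⁻² K⁻¹) for a body indoors — and produces skin that cools only
~1 °C in 5 h, which both contradicts observed postmortem cooling and
renders (T_peri, T_amb, PMI) practically unidentifiable from short
logger records. The default air entry therefore uses an *effective*
conductivity of 0.25 W m⁻¹ K⁻¹, the standard effective-medium treatment
of unresolved convective and radiative transport; it delivers
h ≈ 4–5 W m⁻² K⁻¹ through the resolved air layer and realistic ~6–7 °C
skin drops over 5 h at 20 °C ambient. Truly still air is available by
overriding the material table. Other defaults (tissue 0.5/1050/3600,
adipose 0.21/920/2350, substrate 0.2/700/1700, clothing 0.06/250/1300 in
k / ρ / c SI units) are rounded literature figures and configurable per
case.

Verification: a homogeneous tissue sphere with its surface held at
ambient matches the separation-of-variables series for the centre
temperature within 0.5 °C at 1 h and 3 h at Δx = R/30. Boundary-layer
discretization converges first-order in Δx; between 2 cm and 1 cm grids
a probe at fixed 2 cm depth moves by ≲1.1 °C over 6 h, which sets the
scale of resolution-dependent model error.

### Curve matching

The measured logger series (≥5 samples, relative times from the first
sample; values outside 0–45 °C are flagged) is compared against the
simulated curve of its co-registered voxel. The unknown PMI enters as a
time offset τ, profiled out inside the cost by a 1-D grid search
(default step = the simulation output interval, bounds 0 to
horizon − span): cost(τ) = Σ_k (sim(τ + t_k) − meas(t_k))², with the
simulated curve linearly interpolated in time and measured samples never
interpolated. Ties go to the smaller τ. The offset of the
lowest-cost evaluation point is the reported PMI at the first
measurement. Locations are matched and optimized independently (an
optional joint mode sums costs over a shared offset).

### Surrogate optimization

The surrogate of the cost function (SCF) is a cubic radial-basis-function
interpolant with a linear polynomial tail over parameters scaled to the
unit square — parameter-free and exact at every evaluated point
(verified to 1e-8 relative after every refit). The search protocol:

- 20 initial points uniform over 36–38 °C × 15–25 °C, resampled to keep
  pairwise scaled distance above the exclusion radius (1e-3);
- per iteration, 2000 fresh uniform candidates (candidates inside the
  exclusion radius of history are discarded); S(x) = (s − s_min)/(s_max −
  s_min) and D(x) = (d_max − d)/(d_max − d_min) are scaled over the
  candidate set, with the degenerate all-equal cases mapped to 0;
- the candidate minimizing w·S + (1 − w)·D wins (first in draw order on
  ties), with w cycling 0.3, 0.5, 0.8, 0.95 per iteration;
- termination after 200 evaluations total.

Design/candidate randomness comes from two streams spawned from one
seeded generator recorded in the report. On analytic test costs
(quadratic bowl, two-basin) the best value lands within 1 % of a 201×201
exhaustive-grid minimum for every seed tried, at ~1/200th of the grid's
evaluation count.

The convexity check fits a global quadratic s ≈ a + bᵀx + ½xᵀHx in
scaled space and requires both eigenvalues of H to be non-negative (to
1e-6 of the largest magnitude). Convexity over the compact search
rectangle guarantees the minimum exists (possibly at a bound, as for
chest locations where the simplified anatomy biases the best-fit ambient
downward); requiring an interior stationary point was tried and
abandoned — the fitted stationary point along the quasi-flat T_peri
direction of these trough-shaped surfaces is numerically unstable and
misflags convex fits. `success` is advisory: unsuccessful locations are
still reported, flagged, and excluded from the aggregate mean ± s.d.

With a constant ambient temperature the discrete update is affine in
(T_peri, T_amb), so the per-case cost oracle derives every candidate's
curves from a single unit-response run (body = 1, environment = 0) via
T(t) = T_amb + (T_peri − T_amb)·u(t); this is exact for the scheme
(≈1e-13 °C vs direct runs, verified in tests), and reduces a full
four-location 20/200 search on the 2 cm phantom to ~10 s on one CPU.
Time-varying ambient histories fall back to direct simulation memoized
on (T_peri, T_amb) quantized to 0.01 °C.

## Synthetic fixtures: what they do and do not show

`generate_fixture_case` runs the forward model at known truth, samples
each logger curve over [PMI, PMI + span] at the logger cadence, and adds
independent zero-mean Gaussian noise. Defaults mirror the validation
setting the method targets: true PMI 5 h (within the 2.8–7.4 h range of
morgue arrivals), T_peri 37 °C, T_amb 20 °C, spans of tens of minutes to
a few hours (emulating 41–290 min logger records), 5 min cadence, 0.1 °C
logger-grade noise. Because fixture and estimator share the forward
model, round trips test the *inverse machinery* — co-registration,
matching, search — under ideal model conditions (a deliberate inverse
crime). They do not test model error against real bodies: real tissue is
heterogeneous, posture and cavities matter, and ambient conditions
drift. Passing fixtures therefore bounds algorithmic error, not total
field error.

Measured desk-scale behaviour (2 cm phantom, full 20/200 protocol):
mean absolute PMI error across the four locations is 0.1–0.8 h over
seeds at the 2 h-span/0.1 °C-noise condition — inside the ±2.8 h
best-case envelope of the standard method with a wide margin. Parameter
identifiability is anisotropic: T_amb is well determined by the late-time
level, while T_peri trades against the time offset along a quasi-flat
cost trough; at zero noise the 200-evaluation protocol resolves T_peri
to ~0.2–0.6 °C depending on seed (spans ≲2 h degrade this sharply, which
is why round-trip validation uses a 4 h span). Aggregate parameter
errors are *not* monotone in injected noise at 0–0.3 °C — search
stochasticity dominates — whereas the attained residual cost rises with
the noise floor n·σ² by orders of magnitude, and is the monotone
diagnostic.

## Numerical and design choices

- Offset grid = output interval (5 min) by default; refining it never
  increases the minimal cost.
- Exclusion radius 1e-3 (scaled) keeps the RBF system nonsingular;
  violating candidates are resampled (design) or discarded (search).
- Weight cycling is per proposal iteration; whether the original
  protocol cycled per iteration or per block is unknown.
- Degenerate inputs fail loudly: empty/sparse clouds, non-watertight
  surfaces, non-positive material properties, time steps beyond the
  stability bound, spans exceeding the horizon, <4 records for the SCF,
  <6 for the convexity check.
- Per-location failures are recorded in the report and do not abort
  other locations; the aggregate exists only if ≥1 location succeeds.

## Known limitations

- Conduction-only air with an effective conductivity is a scalar stand-in
  for convection and radiation; it cannot reproduce posture-dependent
  plumes or enclosure effects.
- No body cavities or tissue heterogeneity beyond the optional adipose
  shell; chest-like locations are expected to bias the fitted ambient
  temperature low.
- Humidity and evaporative cooling are not modelled.
- The explicit scheme's step is limited by the most diffusive (air)
  cubes; very fine grids get expensive quickly (Δt ∝ Δx²).
- The PMI is read from a finite offset grid; its resolution bounds the
  achievable PMI precision.
- Validated for the two-parameter (T_peri, T_amb) case only; the
  architecture accepts N-dimensional parameter points but nothing beyond
  2-D is exercised.
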