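# Methods

## Scope and design

`rbesim` estimates the dose-dependent RBE of ²²⁵Ac relative to ¹⁷⁷Lu with
the number of DNA double-strand breaks (DSBs) in the nucleus of a central
target cell as the biological endpoint. Event-by-event track-structure
Monte Carlo (and with it water radiolysis, an explicit DNA geometry and a
mechanistic repair code) is deliberately replaced by a *surrogate* that
reproduces the statistical structure the downstream analysis consumes —
the linearity/curvature of the dose–effect curves, their stochastic
spread, and the spatial character of the damage — at desk scale. The
surrogate is calibrated, not predictive: absolute DSB yields are inputs,
and everything the RBE calculus needs is carried by the *shape* of
N_DSB(D) per condition.

## Cell and cluster geometry

Cells are ellipsoids of equal volume (≈ 4189 µm³) with a 10 nm membrane
and a concentric spherical nucleus of radius 4.65 µm (a fibroblast-like
G0/G1 nucleus). Five catalog shapes are shipped, from a 10 µm sphere to a
5 × 40 × 5 µm rod. Clusters tile cells on a rectangular grid with pitch
2·HL per axis around the central cell; the per-axis cell count is

    n_i = 2 ⌈((range + R_nucleus)/HL_i − 1)/2⌉ + 1 ,

clamped below at 1, which is always odd so a central cell exists. The
particle range is 280 µm for the beta emitter in monolayers, 140 µm (half)
in 3-D lattices to keep cell counts tractable — legitimate because the
cross-dose decays roughly exponentially with distance — and 86.53 µm (the
CSDA range of the most energetic chain alpha, 8.5 MeV) for the alpha
emitter. Monolayers span the plane of the two largest half-lengths; this
is the unique choice that reproduces all twenty catalog cluster sizes.
Membrane-bound sources are sampled uniformly per unit area on the outer
ellipsoid surface (gradient-norm rejection from the unit-sphere
parameterization, which is exact); internalized sources uniformly per
unit volume in the cytoplasm (bounding-box rejection). At these problem
sizes exactness was preferred over clever sampling.

## Source planning

A cell's decay budget over therapy is N = A·T½/ln 2 per GBq injected,
taken from SPECT-normalized activity concentrations; no excretion, every
source point decays exactly once (for ²²⁵Ac, one full chain). The
¹⁷⁷Lu→²²⁵Ac count scaling is (7400 MBq · 6.647 d)/(8 MBq · 9.92 d) ≈ 619.8.
Note the ¹⁷⁷Lu half-life enters here as 6.647 d (it is elsewhere quoted as
6.67 d); 6.647 d reproduces the conventional 619.8 factor and is the
package default. The per-cell source grids are fixed at
{100, 300, 500, 700, 900, 1000, 2000, 3000, 4000, 5000} (¹⁷⁷Lu) and
{1, …, 10} (²²⁵Ac). The synthetic lesion cohort draws normalized activity
concentrations log-uniform over the interval whose per-cell counts span
100–5000 — by construction, since the underlying patient SPECT data are
not publicly deposited. It emulates only that derived count range, not the
shape of any real cohort's concentration distribution.

## Damage surrogate

**Alpha emitter.** Each source point emits the five chain alphas (5.8,
6.3, 7.1, 5.9, 8.4 MeV) isotropically from the decay site; the recoiling
daughters travel nanometres, so all chain decays are treated as local.
Alphas follow straight chords; the range–energy relation is a power law
R(E) = k·E^p fitted to two CSDA anchors, R(8.5 MeV) = 86.53 µm and
R(5.8 MeV) = 46 µm (midpoint of the 43–49 µm interval). The energy
deposited in the central nucleus is E(s_in) − E(s_out) along the
intranuclear chord (all residual energy if the track stops inside), and
the dose is that energy over the 4.211·10⁻¹³ kg water mass of the nucleus
(0.380 Gy/MeV). DSBs are a Poisson process along the chord with linear
density η·LET(s); choosing η = y_Ac · (Gy/MeV) makes the expected DSB
count exactly y_Ac per Gy (default 165/Gy, the mean of the reference
initial-damage slopes). Track-end clustering (a Bragg-peak-like LET rise)
emerges from the range law. All alpha-track DSBs are labelled complex.
The chain's three beta emissions are omitted by default (config flag to
add a crude kernel-based term); their local dose contribution is small
next to the alphas.

**Beta emitter.** Electron transport is condensed into a cross-dose
kernel: the expected nucleus dose per decay is K₀ inside the nucleus and
K₀·exp(−(r − R_nuc)/r₀) beyond it. r₀ = 30 µm was fixed a priori so that
the kernel is negligible (< 10⁻³) at the 280 µm electron range. K₀ is the
one calibrated constant: it pins the reference configuration (spherical
cells, 29 × 29 monolayer, fully internalized, 5000 sources per cell) to a
mean nucleus dose of 2.084 Gy, giving K₀ = 2.55207·10⁻⁵ Gy/decay, frozen
in the package. The cluster-wide kernel sum is a deterministic geometry
integral; it is evaluated once per (cluster, scenario) by Monte Carlo
with a fixed internal seed (default 500 position samples per cell, an
unbiased estimator with sub-percent error) and cached. Run-to-run
stochasticity enters as a unit-mean gamma factor on the dose (shape 1111,
≈ 3% relative SD, matching the spread of the reference configuration) and
as Poisson DSB counts, N ~ Poisson(y_Lu·D) with y_Lu = 77/Gy. DSB
positions are uniform over the nucleus. Breaks are simple except for an
intrinsic complex fraction (below) and spatial pairs closer than 0.1 µm.

## Repair kinetics

Each DSB contributes two co-located free ends. Ends of simple breaks
initiate joining at λ_f = 2.07 h⁻¹ per break (λ_f/2 per end), complex at
λ_s = 0.259 h⁻¹, over a 24 h window; the loop is an exact event-driven
(Gillespie) simulation, which makes the kinetic closed form exp(−λt)
recoverable in the σ → 0 limit and is why a fixed-time-step scheme was
rejected. A firing end picks its partner among all free repair-competent
ends with weight exp(−d²/2σ²); the sibling end (d = 0) is always a
candidate. A break is *correct* if its ends rejoined each other,
*misrepaired* if both ends joined and at least one joint is wrong, and
*residual* if any end is still free at 24 h — this counting convention is
the package's own, stated because mechanistic repair codes differ here.
Additionally, each complex break is unrepairable outright with probability
p_u (modelling irreversibly complex lesions); such breaks are residual and
their ends are excluded from the partner pool.

Three knobs were calibrated once and frozen: σ = 0.19 µm, p_u = 0.86, and
an intrinsic complex fraction of 0.23 for low-LET DSBs. The last is a
deliberate extension beyond "all beta-emitter breaks are simple": isolated
simple breaks rejoin correctly with near certainty at these rates, so a
dose-independent ~21% surviving fraction — the observed ratio of
post-repair to initial slope for the beta emitter — cannot arise from
proximity misrepair alone, which scales with dose. A ~20–30% complex
fraction for low-LET damage is also what track-structure studies
themselves report. With these defaults the surrogate yields, for the
reference 3-D condition, post-repair damage within 25% of
16.31·D + 1.21·D² over 1–5 Gy (upward curvature from density-driven
misrepair) and an alpha-emitter post/initial slope ratio ≈ 0.92 that
stays linear, because track-clustered complex damage is mostly blocked
and its misrepair is dose-independent per track.

## Fitting and RBE calculus

Dose–effect curves are fitted unweighted through the origin with
`scipy.optimize.curve_fit`: N = b·D for the alpha emitter (both stages)
and the beta emitter's initial damage; N = a·D² + b·D for the beta
emitter's post-repair damage. The quadratic coefficient is bounded below
by zero by default (near-linear data otherwise produce sign-flipping
outliers); a flag disables the bound. Parameter σ are 1-sigma values from
the estimator covariance; R² uses the total sum of squares about the data
mean — one of several conventions for through-origin models, reported for
comparability only and never used downstream.

The RBE closed forms, their shared zero-dose limit b_Ac/b_Lu, the
isoeffect dose conversions and the crossover dose (b_Ac − b_Lu)/a_Lu are
evaluated exactly. Uncertainties are first-order delta-method propagation
treating the fit parameters as independent (a full covariance can be
supplied); independence reproduces the reference uncertainty spans
(0.018–0.022 for the 3-D initial conditions) and gives a crossover
uncertainty of ±11 Gy for the reference post-repair condition. The delta
method is first-order: for the crossover dose, whose 1/a nonlinearity is
driven by a ~10% relative σ_a, a full parameter Monte Carlo shows a ~4%
larger spread — a known, accepted limitation.

## Statistics design and scale

The full grid mirrors the study design: 2 radionuclides × 5 geometries ×
2 arrangements × 2 internalizations × 10 source levels = 400 setups, 10
seeds each (4000 damage simulations), 10 repair repetitions per damage
pattern, and 100-point dose–effect datasets per condition and stage. The
default **desk profile** runs one geometry/arrangement/scenario with 10
levels × 3 seeds × 3 repetitions and finishes in seconds; the paper-scale
grid sits behind `--profile paper` with a runtime warning. Seeds derive
hierarchically (master → condition → level → run → repetition) via
`numpy.random.SeedSequence`, so all outputs are reproducible from the
master seed.

## Degenerate inputs and numerical choices

Zero source points yield zero dose and no DSBs; empty damage repairs to
(0, 0, 0). Tangent rays give zero-length chords; rays with the sphere
behind the origin miss. DSB positions are clipped to the nucleus sphere
against floating-point overshoot at the chord boundary. Fits require ≥ 3
points and a non-degenerate dose spread. A vanishing misjoin σ is treated
exactly (only co-located partners are reachable). Crossover with a_Lu = 0
is signalled as a dedicated no-crossover error rather than returning
infinity.

## What passing tests do and do not show

The geometry, source-planning, fitting and RBE layers are exact
implementations and are tested against independent oracles (triangulated
surface sampling, rejection-volume fractions, ray-march chords, parameter
Monte Carlo) and against the packaged reference tables. The damage and
repair layers are surrogates: their tests pin *structure* — linearity of
the alpha emitter's dose–effect, convexity of the beta emitter's
post-repair curve, end-state conservation, kinetic limits, the calibrated
anchor dose — not track-structure-exact values. Agreement of the
surrogate's fitted slopes with the reference tables is built in by
calibration and therefore evidence of internal consistency, not of
predictive physics. Real-data features the surrogate does not carry:
electron energy-spectrum changes across geometries, Auger/conversion
electron microdosimetry, daughter-nuclide relocation, concurrent
induction-and-repair during week-long irradiation, and cell-cycle
heterogeneity.
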