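# Methods

## Model and assumptions

All analyses assume a bimolecular two-state equilibrium between two
non-identical complementary strands and their duplex, A + B ⇌ AB, with
both strands supplied equimolar. `Ct` is everywhere the **total**
single-strand concentration (each strand at Ct/2), which is what makes
K(Tm) = 4/Ct and the ln(Ct/4) form of the melting-temperature equation
correct. Self-complementary sequences obey a different molecularity
(K(Tm) = 1/Ct) and are rejected at sequence validation rather than
silently mishandled. ΔH° and ΔS° are treated as temperature-independent
(ΔCp = 0), the standard assumption for short oligomers; all extrapolations
to 37 °C inherit it.

Units: ΔH° and ΔG° in kcal·mol⁻¹, ΔS° in cal·mol⁻¹·K⁻¹ (factor 1000
between them), temperatures Kelvin internally and °C at file/CLI
boundaries, R = 1.987 cal·mol⁻¹·K⁻¹. `ThermoParams` stores (ΔH°, ΔS°) and
*derives* ΔG°(T), so a parameter triple can never be internally
inconsistent. The literature factor "2.303" is implemented as ln 10
exactly.

The mass-action quadratic for the duplex fraction is evaluated in the
rationalized form f = a/(a + 1 + √(2a+1)), a = K·Ct, which is exact and
avoids catastrophic cancellation of the textbook root at small a.

## Curve fitting

Each melting curve is fitted by trust-region nonlinear least squares to
the six-parameter model (ΔH°, Tm, b_ds, m_ds, b_ss, m_ss); ΔS° is derived
from (ΔH°, Tm, Ct) through the closed form. Fitting (ΔH°, Tm) instead of
(ΔH°, ΔS°) decorrelates the transition parameters — ΔH° and ΔS° are
nearly collinear over a narrow transition, while Tm is pinned by the data.

Initialization: Tm₀ from the smoothed-derivative peak, ΔH°₀ = −80
kcal·mol⁻¹, baselines from straight-line fits to the lowest and highest
15% of the temperature range. Convergence: relative SSE change below
1e-10 within 500 iterations per parameter; non-convergence is *reported*
(`converged=False`), never raised, so batch runs complete. A curve whose
absorbance span does not exceed 3× a robust noise estimate (MAD of first
differences) carries no transition and raises `NoTransitionError` instead
of returning a meaningless fit.

The derivative-based transition temperature uses a centered 5-point moving
average of dA/dT, ties broken toward the lowest temperature, and requires
the peak to stand 3 robust standard deviations above the median derivative
level. Note a physical caveat: for a **bimolecular** transition the
steepest point of the curve falls at duplex fraction ≈ 0.42, about
R·Tm²/|ΔH°| ≈ 1 K *above* the f = ½ temperature. The estimator is
therefore used for initialization and for model-free condition
comparisons (e.g. long duplexes), not as a thermodynamic Tm.

## Van't Hoff analysis and consolidation

The concentration plot regresses Tm⁻¹ on log₁₀(Ct/4) by ordinary least
squares; ΔH° = 2.303·R/slope and ΔS° = 1000·intercept·ΔH°. For any duplex
that melts, the slope is negative (ΔH° < 0); a non-negative slope is
rejected as not a melting series. At least three distinct concentrations
are required; the recommended design spans ≥ 1.5 decades.

Consolidated parameters are the unweighted mean of the converged-curve-fit
mean and the van't Hoff estimate, with ΔG°₃₇ recomputed from the averaged
(ΔH°, ΔS°) rather than averaged directly — the difference is below
reporting precision for two-state data, and recomputation keeps the triple
consistent. The two-state indicator requires the two |ΔH°| routes to agree
within 15% (relative to their mean), the community rule of thumb;
configurable because no sharper published criterion exists. Non-converged
fits never enter any average.

## Salt dependence and counterion uptake

Duplex stability is regressed on log₁₀ of the cation concentration by
unweighted OLS over its linear range (≥ 3 concentrations); the intercept
is the stability extrapolated to 1 M. Slopes convert to ion-uptake
numbers by Δn = slope/(2.303·α·R·T) with T = 310.15 K (the temperature of
the ΔG° values) and α = 0.9 for NaCl, 0.88 for MgCl₂; Mg²⁺ uses the
identical formalism with its own α, no extra valence correction. The
alternative Tm⁻¹-based estimator Δn = δ(Tm⁻¹)/δlog[M]·ΔH°/(2.303·α·R)
assumes ΔH° constant over the salt range; the two estimators agree
identically on data generated under that assumption, and their agreement
on real data is itself a consistency check. Δn is reported rounded to one
decimal (conventional presentation) with full precision retained in
machine output.

## Nearest-neighbor model

The embedded tables are the published unified Watson-Crick DNA/DNA set
(10 steps + per-terminus initiation; SantaLucia 1998) and the internal
G·T wobble set (11 steps; Allawi & SantaLucia 1997). Only (ΔH°, ΔS°) are
transcribed; ΔG°₃₇ is recomputed, so every table entry is exactly
self-consistent (published ΔG columns round-trip to within their printed
precision). Each step is stored under both strand-orientation spellings
with identical values.

A prediction is initiation (both termini) plus all dinucleotide steps.
Supported: Watson-Crick duplexes with at most one internal G·T wobble and
Watson-Crick termini. I- and D-containing duplexes are representable (for
labeling, simulation, discrimination) but prediction rejects them — no
published parameters, none invented.

The trinucleotide-core decomposition attributes a whole-duplex value to a
central pair and its two flanking stacks: subtract initiation and every
step *not* touching the central position; the remainder is the two central
steps. For a predicted input this returns exactly the two-step sum (e.g.
CGC/GTG: −ΔH° 8.5 kcal·mol⁻¹, −ΔS° 24.0 cal·mol⁻¹·K⁻¹, −ΔG°₃₇ 1.06
kcal·mol⁻¹); for a measured input it isolates the experimental core
contribution, valid because the flanking sequence is identical across
variants of one template. No initiation share is assigned to the core.
Positions are 0-based (top strand) in machine output, 1-based in
human-readable reports.

## Synthetic data generator

The generator is the analysis model run forward, which is exactly what
parameter-recovery testing requires. It emulates: linear sloping duplex
and single-strand baselines (defaults b_ds = 0.60, m_ds = 2×10⁻⁴/°C,
b_ss = 0.75, m_ss = 3×10⁻⁴/°C — 15–25% hyperchromicity, typical at
260 nm); i.i.d. Gaussian absorbance noise (default σ = 0.002 AU, a
realistic photometric scale; instruments do not publish this figure, so it
is a fixture choice); a 0–95 °C grid at 0.5 °C; strand-concentration
series (default 2 µM–200 µM total, 2 decades); and salt series with
−ΔG°₃₇ linear in log₁₀[M] and ΔH° salt-independent, ΔS° absorbing the
change. Study-scale fixtures use the reported six-variant settings:
1 M −ΔG°₃₇ of 12.5/11.2/11.2/10.4/9.15/8.83 kcal·mol⁻¹, the reported
per-condition salt slopes, and representative enthalpies −85…−105
kcal·mol⁻¹ ordered with stability.

What passing tests show — and do not. The generator shares its functional
form with the fitter, so round-trip tests verify estimator correctness,
noise sensitivity and the internal consistency of the whole chain; they
cannot detect model misspecification present in real data (curved
baselines, partial intermediates, evaporation or pH drift, correlated
photometric error). Those failure modes surface in real use through the
two-state flag and fit diagnostics, not through these tests.

Randomness: a single integer seed drives `numpy.random.default_rng`;
series members draw from seeds spawned off the master `SeedSequence`, so
curves are independent but jointly reproducible, and seeds are recorded in
output metadata.

## Problem sizes and numerical choices

Statistical guarantees are validated at desk scale: 50-seed recovery
studies for noisy fits, 100-draw oracle comparisons for the closed-form
Tm (bisection to <0.01 K), 100-seed coverage runs for salt-slope
confidence intervals (using the exact t(3 dof) interval for 5-point
series), and a full 6-duplex × 4-salt × 4-Ct study for the end-to-end
test. These sizes give stable medians and orderings while keeping the
default test run fast.

Degenerate inputs are rejected with named errors rather than propagated as
NaN: flat curves, monotone baselines, non-increasing temperature grids,
duplicate concentrations, unmeltable parameter signs, unrecognized base
pairs, parallel-orientation strands, α outside (0, 1].

## Known limitations

- Two states only; three-state or intermediate transitions are out of
  scope and will trip (not silently pass) the two-state agreement flag.
- ΔCp = 0; long extrapolations from Tm to 37 °C carry the usual bias.
- Linear baselines only.
- No Poisson-Boltzmann or counterion-condensation modeling; the α-factor
  mass-action treatment is deliberately the simplest defensible model.
- Single-salt solutions; mixed Na⁺/Mg²⁺ competition is not modeled.
- The wobble parameter set covers one internal G·T; tandem wobbles and
  terminal mismatches are rejected.
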