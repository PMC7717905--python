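# Methods

## Models

### Four-state binary-elements model

The channel is two interacting binary elements: a pore, closed (C) or open
(O), and a calcium sensor, unbound (U) or bound (B).  With the closed/apo
state as the energy reference, the four state weights are `θ_UC`,
`L0·θ_UO`, `K·x·θ_BC` and `L0·K·x·θ_BO` (`x` calcium in molar, `K` the
association constant in M⁻¹, `L0` the intrinsic pore-opening constant, and
the four θ's state-dependent sensor–pore coupling factors).  All six
parameters must be strictly positive.  The Hill-transformed open
probability ln(Po/(1−Po)) = ln(Z_O/Z_C) runs between the asymptotes
χ− = ln(L0·θ_UO/θ_UC) at zero calcium and χ+ = ln(L0·θ_BO/θ_BC) at
saturation; Δχ = χ+ − χ− = ln(θ_BO·θ_UC/(θ_BC·θ_UO)) is independent of `K`
and `L0` and is the quantity the linkage analysis estimates from data.

The model is algebraically equivalent to the classical single-coupling
form: dividing Z by θ_UC gives apparent constants L0′ = L0·θ_UO/θ_UC,
K′ = K·θ_BC/θ_UC and net cooperativity θ = θ_UC·θ_BO/(θ_UO·θ_BC)
(`normalize()`).  The equivalence is exact, and the suite verifies
pointwise Po agreement to 1e-12 over random parameter draws.  A corollary
used by the tests: the four-state Po(x) is exactly a Hill curve with
n = 1, so the Hill fit is unbiased for data generated by this model.

Any constant may be given a van't Hoff temperature dependence
`exp(−(ΔH − TΔS)/RT)` with R = 8.314 J/(mol·K); temperatures are kelvin
internally, °C only at file boundaries.  Coupling energies are reported as
RT·Δχ with R = 1.987×10⁻³ kcal/(mol·K) (and 8.314×10⁻³ kJ/(mol·K)).

### Discrete-thermosensor model

`SensorModel` adds a third binary element with activation constant `M0`
(normally van't Hoff) coupled to the pore by factor `C` and to the ligand
site by `E`; the single pore–site coupling is `D`.  Its asymptotes are
χ− = ln[L0(1+M0·C)/(1+M0)] and χ+ = ln[L0·D(1+M0·C·E)/(1+M0·E)], and the
analytic temperature derivatives are implemented in closed form
(`sensor_chi_derivatives`), validated against central finite differences at
1e-6 relative tolerance.  Two structural facts fall out of the algebra and
are asserted in the tests: with C = 1 (thermosensor uncoupled from the
pore) all three derivatives vanish, and with E = 1 (uncoupled from the
ligand site) dΔχ/dT vanishes while dχ−/dT = dχ+/dT.  A thermosensor
therefore reproduces a temperature-dependent Δχ only when it is coupled to
*both* the pore and the ligand-binding module.  `SensorModel` carries an
optional binding constant `K` (default 2×10⁴ M⁻¹) used only for full
dose–response simulation; the χ values do not depend on it.

### Generalized N-site model

`GeneralizedModel` has N binding sites with per-site affinities `K_i`,
per-site couplings θ⁽ⁱ⁾_XY and pairwise site–site factors
α[i, j, state_i, state_j] (default 1, symmetry α[i,j,a,b] = α[j,i,b,a]
enforced).  It is evaluated by explicit enumeration of all 2^N occupancy
patterns per pore state rather than transfer-matrix factorization: N is
small in practice (capped at 12 by the 2^(N+1) state count) and the
enumeration doubles as its own oracle.  The closed forms
χ− = ln(L0·Πθ_UO/Πθ_UC), χ+ = ln(L0·Πθ_BO/Πθ_BC) and
Δχ = Σ ln(θ_BO·θ_UC/(θ_BC·θ_UO)) are checked against the numeric
ln(Z_O/Z_C) limits and against an independent brute-force enumeration; the
invariance of Δχ to `K_i`, `L0` and all α terms is checked by
randomization.

## Shipped MthK parameter set

`thermolink/data/mthk_ir_default.json` carries the default four-state
parameters for MthK gating (L0 = 0.1, K = 2×10⁴ M⁻¹, θ_UC = 150,
θ_UO = 18, θ_BC = 8, θ_BO = 8; Δχ = 2.12 at any temperature while all
couplings are static) plus per-coupling van't Hoff (ΔH, ΔS) pairs.
Published listings of this set are partially ambiguous — the static θ_BC
entry in particular — so the file documents these values as configuration
choices.  `default_mthk_model(vant_hoff=("theta_UC",))` promotes a
coupling to van't Hoff form; by default the substitution is *anchored*:
ΔH is kept as the temperature sensitivity and ΔS is re-derived so the
coupling equals its static value at 294.15 K (21 °C).  The raw (ΔH, ΔS)
pairs are mutually inconsistent with the static values (e.g. they give
θ_UC ≈ 13 rather than 150 at 21 °C), which would silently change the
reference-temperature behavior; anchoring makes the temperature-dependent
and static models agree at 21 °C by construction.  `anchor_T_K=None`
disables this and uses the raw pairs.

## Linkage analysis of dose–response data

Po(x) at one temperature is fitted with the four-parameter Hill equation
Po = A + (B−A)xⁿ/(Kⁿ+xⁿ) by bounded least squares (`scipy.optimize.
curve_fit`), weighted 1/sem² when every point carries a SEM and unweighted
otherwise; replicate counts are not used as weights.  Initialization is
A = min Po, B = max Po, K = geometric mean of the calcium grid, with a
deterministic multistart over n ∈ {1, 2, 4, 8} (best residual wins, ties
to the smaller n) because steep cooperative curves have local minima in n.
Bounds: A, B ∈ (10⁻⁶, 1−10⁻⁶), n ∈ (0.1, 10).  The asymptotes are taken
from the fitted plateaus — χ− = logit A, χ+ = logit B — not from the raw
extreme Po points, since the plateaus are what the Hill fit constrains.
When a fitted plateau extrapolates more than 2× (in logit units) beyond
the observed Po range, the fit carries an identifiability warning, and
every two-temperature comparison carries the one-sided caveat that a
low-temperature Δχ is an underestimate whenever the lowest attainable
calcium has not reached the χ− plateau.  Uncertainty on Δχ is available by
bootstrap over points (`bootstrap_delta_chi`); profile-likelihood
intervals are out of scope.

## Single-channel statistics

Traces are filtered with a zero-phase Gaussian kernel whose −3 dB point is
the requested cutoff (σ_t = √(ln 2)/(2π·fc)); circular boundary handling
makes the filter exactly mean-preserving.  Idealization is half-amplitude
threshold assignment to the level ladder (nearest level of
closed + k·(open−closed), k = 0..n_channels), followed by merging of
excursions shorter than the dead time (default 0.04 ms), shortest first,
into the enclosing level.  This emulates conventional threshold-based
event detection; hidden-Markov idealization is deliberately not
implemented.  A warning (not an error) is attached when the level
separation is under 3× the baseline noise SD.

nPo = Σ i·P_i over conductance levels and Po = nPo/n; the channel count n
is supplied by the user (conventionally the maximal simultaneous opening
count at high activity).  The mean closed time is derived as
mean_open/Po − mean_open.  Q10 = (A₂/A₁)^(10/(T₂−T₁)) with sample 1 at the
lower temperature; `max_q10` scans adjacent pairs of a temperature series
because steeply thermosensitive channels concentrate their sensitivity in
a sub-interval.  Dwell-time distributions are fitted as exponential
mixtures by maximum likelihood (EM; the k = 1 MLE is the sample mean in
closed form), adding components only while the likelihood-ratio statistic
exceeds the χ²(2 df) critical value at 95% confidence (k ≤ 4).  Fitting
the raw-dwell likelihood is equivalent to fitting the standard
log-transformed density Σ P_i·exp[(ln t − ln τ_i) − e^(ln t − ln τ_i)] to a
log-binned histogram, so the conventional square-root/log-axis display
corresponds to the same MLE.  Both the mixture mean Σ P_i·τ_i and the
arithmetic mean of detected dwells are reported, since published "mean
open time" values may be either.

nPo uncertainty uses a moving-block bootstrap over the event sequence:
blocks span ~1% of the recording (at least 10 events; both choices are
package defaults, stated here because no standard exists), are resampled
with replacement to the original duration, and the SEM is the SD of the
replicate nPo values.  Blocks preserve the serial correlation of gating
that an i.i.d. event bootstrap would destroy.

## Synthetic data

The equilibrium models say nothing about kinetics, so simulation uses a
kinetic embedding: forward rates are user choices (defaults: pore opening
100 s⁻¹ and calcium on-rate 10⁷ M⁻¹s⁻¹, putting dwells on the millisecond
scale typical of large-conductance channel records) and every backward
rate follows from detailed balance against the Boltzmann weights.  Because
the weights derive from state energies, cycle products close exactly and
*any* such embedding reproduces all equilibrium observables; the
acceptance properties only concern equilibrium quantities, so the base-rate
choice is not load-bearing.  Simulation is exact (Gillespie), initialized
from the stationary distribution, with the final sojourn truncated at the
recording end.  For dose–response generation only the open-class occupancy
is needed, and a compiled (numba) inner loop makes 300 s recordings at
millimolar calcium — where binding events dominate the event count —
cheap; a pure-Python loop with identical logic is the fallback.  Traces
map open-class states to a fixed current, add white Gaussian noise, and
apply the Gaussian low-pass (defaults 25 kHz sampling, kHz-range
filtering, 10 pA openings, 1 pA noise).  Dose–response datasets simulate
`n_patches` independent 300 s recordings per condition (mirroring 5-minute
continuous experimental recordings and 3+ patches per condition), report
the patch mean and SD/√n, and omit the SEM for a single patch.  All seeds
derive deterministically from one user seed.

What the generator does *not* emulate: inactivation and rundown (the
experimental construct removes inactivation), leak currents, baseline
drift, temperature gradients within a recording, and open-channel noise
exceeding baseline noise.  Passing round-trip tests therefore shows the
estimators are correct for the assumed data-generating process, not that
they are robust to every artifact of real recordings.

## Problem sizes and numerical choices

Test and acceptance runs use 300 s recordings, 3 patches, 7-point calcium
grids (0.1–10 mM), 5000-dwell MLE studies and 200–1000 bootstrap
replicates — sizes at which Monte-Carlo error is comfortably inside the
asserted tolerances (e.g. Δχ recovery is asserted within 0.3 natural-log
units while the realized errors are ~0.05–0.2).  Exponential-mixture EM
stops at a 1e-10 relative log-likelihood increment; τ components are
ordered ascending; degenerate fractions below 1e-12 are dropped.  Hill
fits treat a decreasing dose–response (possible when Δχ < 0) by swapping
plateaus to keep A < B, so Δχ estimated from data is reported as a
magnitude in that edge case.  `hill_transform` refuses Po ∈ {0, 1} and
asks the caller to report a limiting bound instead.

## Known limitations

- Equilibrium only: no rate-level (kinetic) fitting of models to data.
- Threshold idealization misses events shorter than the dead time by
  construction; dwell-time mixtures are fitted to detected events without
  missed-event correction.
- Multi-channel records are treated as independent identical channels.
- Δχ from data inherits the finite-concentration-range bias discussed
  above; the package surfaces it as a caveat rather than modeling it.
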