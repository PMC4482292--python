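# Methods

## The model template and its assumptions

Every candidate model shares one mass-balance template for two membrane
proteins, Rab5 and Rab7, each present in a passive GDP-bound form (`r5`,
`r7`) and an active GTP-bound form (`R5`, `R7`).  Membrane association and
dissociation via GDI contribute a constant influx `K_i` and a first-order
efflux `k_i·r_i` acting on the passive pools; activation (GDP→GTP exchange,
"GEF") converts passive to active at rate `GEF_i(R5,R7)·r_i` and hydrolysis
("GAP") converts back at rate `GAP_i(R5,R7)·R_i`.  Summing each protein's
two equations shows the structural identity

    d(r_i + R_i)/dt = K_i − k_i·r_i,

i.e. the observable total changes only through GDI exchange — the
regulatory terms cancel.  This identity is used throughout the tests as an
integration oracle: the finite difference of a simulated total must match
`K − k·r` along any successful trajectory.

Assumptions inherited with the template: mass-action GDI kinetics with
constant rates, regulatory rates depending only on the *active*
concentrations, spatially homogeneous pools (the aggregated intensity data
average over many endosomes), and noise entering only through observation.

## Candidate space

Each of the four regulatory slots draws from a small library of kinetic
forms (see `src/rabswitch/library.yaml`):

| slot | alternatives |
|------|--------------|
| GEF5 | MM auto-catalysis by R5; sigmoidal auto-catalysis by R5; exchange inhibition by R7 |
| GAP5 | intrinsic; MM catalysis by R7; sigmoidal catalysis by R7 |
| GEF7 | cross-activation by R5 ∈ {MM, sigmoidal} × auto-activation by R7 ∈ {none, MM, sigmoidal}, plus linear cross-activation |
| GAP7 | intrinsic; MM catalysis by R5 |

The Cartesian product has 3·3·7·2 = 126 members, enumerated in
lexicographic order of the slot indices; that order defines the canonical
structure index used for every tie-break.  The sigmoidal (Hill) exponent is
fixed at h = 3 rather than estimated: the data constrain at most the
steepness class of a response, and a free exponent would aggravate the
identifiability problems documented below.  Both the exponent and all box
bounds are configurable through the library document.

Model complexity `C(m)` counts leaf processes: four fixed GDI processes
(association and dissociation per protein) plus one per chosen kinetic
component, so a GEF7 alternative with both cross and auto components
contributes two.  The library spans C ∈ {8, 9}; the parsimony criteria use
the normalised value `(C − Cmin)/(Cmax − Cmin)` by default so that the
complexity term shares the [0, 1] scale of the fit terms (a raw-count mode
is available).

## Selection criteria

All criteria are minimised.  `E` is the average relative RMSE over the two
observed channels, normalised per channel by the deviation from the channel
mean, so `E = 1` for the mean predictor and `E = 0` for a perfect fit.  `R`
penalises hidden active states that fail to correlate positively with their
observed totals; each channel term is `min(1 − r, 1)`, clamping
anti-correlated fits at the maximal penalty, and a constant (zero-variance)
hidden state is assigned `r := 0` — a flat active state cannot explain a
switching total, so it receives the full term without an extra penalty.
`X` is the absolute distance between the measured and simulated dominance
switch times divided by the window length; a simulation with no detected
switch scores `X = 1`.  Switch times (measured and simulated alike) are the
earliest time at which the Rab7 channel reaches the Rab5 channel and stays
at or above it for a 5 s persistence window; if the channels are equal from
the start, the first sample is the switch.

The combined criteria are the convex combinations `ER = αE + (1−α)R`,
`EX = αE + (1−α)X`, `ERX = αE + (1−α)·½(R+X)` and, with complexity,
`EC = βE + (1−β)C`, `ERC = β·ER + (1−β)C`, `EXC`, `ERXC`.  Setting `α = 1`
collapses every domain-dependent criterion to `E`; `β = 1` removes the
complexity term.  Default trade-offs are `α = β = 0.5`; both are plain
configuration values.

## Parameter estimation

Differential Evolution, strategy rand/1/bin: mutant `x_r1 + F·(x_r2 −
x_r3)` over three distinct members, binomial crossover with at least one
mutant coordinate, greedy one-to-one replacement.  Control settings follow
the values established for this estimation task — population 81,
F = 0.942, Cr = 0.915 — with an evaluation budget of 20,000 objective
evaluations per free parameter at full scale.  Design choices the strategy
leaves open:

- **Bound handling** — mutant vectors are clipped to the box; the simplest
  reproducible repair.
- **Initialisation** — uniform within bounds, except the intensity scale
  `K`, which spans two decades and is sampled log-uniformly.
- **Budget accounting** — every objective call counts, including the
  initial population and failed simulations.
- **Failure penalty** — a simulation that diverges or stalls returns an
  objective value of 10⁶; a candidate that merely lacks a dominance switch
  is *not* penalised this way (it receives `X = 1` inside the criterion).
- **Determinism** — per-structure seeds are spawned from (master seed,
  canonical structure index), making sweep results bitwise independent of
  worker count and structure order.

A property worth knowing when budgeting runs: with F ≈ 0.94 the population
contracts slowly by design (the setting favours exploration over
refinement).  On a 19-dimensional sphere benchmark this configuration —
ours and an independent implementation of the same strategy alike — still
sits near 0.4 after 20,000 evaluations, while it reaches ≤ 1e−3 at up to
8 dimensions.  Full-template candidates carry 15–20 parameters, so
desk-scale budgets (a few hundred evaluations per parameter) yield
*partially converged* fits: informative for ranking experiments, far from
the E → 0 attainable on noiseless self-generated data.  Matching the
behaviour of a generating structure to E ≤ 0.05 was not reached below
roughly 2×10⁵ evaluations in our experiments; this is a property of the
prescribed optimiser settings, not of the model space.

## Synthetic data

The generator emulates the statistical shape of aggregated endosome
fluorescence measurements: two dense channels that are scaled sums of a
hidden active and passive state, one Rab5→Rab7 dominance switch inside the
window, near-constant passive concentrations, and proportional Gaussian
observation noise (`sd = noise_level·|value|`, independent per sample).  It
does **not** emulate the raw multi-track imaging data, the manual
scaling/averaging that aggregates such tracks, autocorrelated or
heteroscedastic-beyond-proportional noise, or measurement dropout — so
passing recovery tests says nothing about those complications.

The default scenario uses the structure with sigmoidal GEF5 auto-catalysis,
sigmoidal GAP5 catalysed by R7, Michaelis–Menten GEF7 with both cross- and
auto-activation, and intrinsic GAP7 (canonical index 72), parameterised as
a *cut-out switch*: active Rab5 ramps up through near-saturated
auto-catalysis, cross-activates GEF7, and the rising active Rab7 drives
GAP5 to shut Rab5 off.  Parameters were chosen once, in smooth operating
regimes (saturated or quasi-linear segments of the response curves) so that
the switch timing depends polynomially — not exponentially — on the rate
constants: GDI fluxes `K_i = k_i = 0.5 /s` pin the passive states near 1;
`gef5: V = 0.004, Km = 0.1` (saturated, quasi-linear R5 ramp);
`gap5: V = 0.05, Km = 1.6`; `gef7 cross: V = 0.012, Km = 2.0` (quasi-linear
in R5); `gef7 auto: V = 0.01, Km = 0.5`; `gap7: k = 0.005`; initial state
`(r5, R5, r7, R7) = (1, 0.6, 1, 0.05)`; `K = 10⁴`; `td = 30 s`.  On the
default 2,001-point grid over [0, 300] s (a ~10⁴-point grid matching the
real data's density is one flag away) the noiseless truth switches at
128.4 s, passive CVs are below 0.01 and active/total correlations exceed
0.999.  Desk-scale analyses use 300–500-point grids; those sizes keep a
full objective evaluation near 2 ms.

## Bootstrap identifiability

Each replicate perturbs every measured value with independent zero-mean
Gaussian noise of standard deviation `noise_level·|value|` (default 0.1),
re-detects the switch time on the perturbed channels (falling back to the
original if noise destroys the switch), refits with a replicate-specific
optimiser seed, and records the estimate.  Defaults: 100 replicates at full
scale, 20 with a reduced budget for desk-scale runs.  Summaries: percentile
95 % confidence intervals, CI-length-to-mean ratios, the Pearson
correlation matrix of the estimates (degenerate constant columns contribute
0 off-diagonal, 1 on the diagonal), high-|r| pairs sorted descending, and a
bound-pile-up flag raised when at least 50 % of a parameter's estimates lie
within 1 % of the box range of either bound.  For the zero-noise control
the replicate fits can share one seed (`vary_fit_seeds=False`), in which
case all replicates are identical by construction and every CI has length
zero — the degenerate baseline of the procedure.

## Numerical choices

- Integration: LSODA (stiff-capable, adaptive) with rtol 1e−6, atol 1e−8;
  outputs reported exactly at the measurement times, no resampling.
  Internal time starts at 0 and maps to measurement time via
  `τ = (t − t₀) + td`, treating `td` as a global onset offset.
  Regulator concentrations are clamped at 0 inside the rate forms to guard
  against solver micro-undershoot; rational forms define 0/0 := 0.
- Integration failures (non-finite states, step-size collapse) return a
  flagged failure trajectory, never an exception, so sweeps continue.
- Plateau detection measures the jump relative to the earlier (smaller)
  value and uses signed differences; profiles are sorted, so the two
  readings coincide except for exact ties.
- Ranking is a stable sort; all ties fall back to the canonical structure
  index.
- CSV output uses 6 significant digits; JSON keeps full precision.

## Known limitations

- The library is hard-wired to the two-protein Rab template; there is no
  generic process-modeling language.
- COT/IP/NOBS bistability classes are consumed as an optional annotation
  file; the package performs no stability or bifurcation analysis.
- At desk-scale budgets the optimiser noise dominates structure ranking:
  wrong structures routinely fit as well as the generating one, so plateau
  composition — not rank-1 identity — is the meaningful output.  This
  mirrors the indistinguishability the method is designed to expose, but it
  means small sweeps should not be read as structure recovery.
- Proportional Gaussian noise is an idealisation of fluorescence error;
  no background, bleaching or autocorrelation model is included.
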