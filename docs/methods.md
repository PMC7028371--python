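# Methods

## Scope and data model

The package analyzes frame-discretized presence intervals from multi-channel
single-molecule colocalization recordings and lag-domain FCS autocorrelation
curves. Conventions used everywhere: frames are 0-based and intervals
half-open `[start, end)`; times are seconds; concentrations are molar (the
YAML config accepts `_nM` suffixes); channels are named `rnap` (labeled
polymerase), `greb` (labeled secondary channel factor) and `probe`
(transcript hybridization probe). Recordings travel as plain TSV with
`#frame_interval_s` / `#n_frames` headers; FCS curves as 2–3 column text;
all fit reports as JSON carrying estimate, SE, N and log-likelihood.

## Two-closed-complex scheme

States: unbound → RP1 (association k₁[R], second order) with RP1 ⇄ RP2
(k₂, k₋₂) and dissociation only from RP1 (k₋₁), per the scheme's topology in
which the promoter complex leaves through the state it entered. The dwell
(entry into RP1 until unbinding) is phase-type with survival
S(t) = a·e^{−λ₁t} + (1−a)·e^{−λ₂t}, where

- λ₁ + λ₂ = k₋₁ + k₂ + k₋₂, λ₁λ₂ = k₋₁k₋₂ (λ₁ > λ₂),
- a = k₋₁(λ₁ − k₋₂) / (λ₁(λ₁ − λ₂)),
- mean dwell a·τ₁ + (1−a)·τ₂ = (1/k₋₁)(1 + k₂/k₋₂).

The inverse map is closed form: k₋₁ = a·λ₁ + (1−a)·λ₂, k₋₂ = λ₁λ₂/k₋₁,
k₂ = λ₁ + λ₂ − k₋₁ − k₋₂. On the open region a ∈ (0,1), τ₁ < τ₂ the inverse
always yields non-negative rates (AM–GM argument: m + λ₁λ₂/m ≤ λ₁ + λ₂ for m
between the eigenvalues), so forward and inverse maps are a bijection there;
the test suite verifies round trips to 10⁻⁶ relative error and checks the
forward map against a matrix-exponential oracle and against Gillespie
simulation (Kolmogorov–Smirnov at the 1 % critical value on 10⁵ draws).
`assemble_scheme` copies k₁ from the first-binding fit and propagates dwell
parameter SEs through the inversion by parametric (Gaussian) bootstrap,
discarding infeasible draws.

Inverting published dwell-fit values reproduces the corresponding published
rate constants only to within one to two standard errors; the package's
correctness criterion for the inversion is therefore the round-trip and
simulation oracles, not numeric identity with any printed rate table.

## Dwell-time maximum likelihood

Observed durations are whole frames. The likelihood treats a recorded
duration d as interval-censored: the true dwell lies in
(d − Δ + off, d + off], with Δ the frame interval and `off` a per-sample
discretization offset — 0 for the bundled dwell generator (which rounds up
to whole frames and discards sub-frame draws, so detection requires t ≥ Δ)
and Δ/2 for recordings discretized by the ≥50 %-overlap detection rule.
Detection imposes left truncation at the window's lower edge for the
smallest qualifying duration; the window is clipped at the truncation point
so no probability mass below the detection threshold can enter a numerator.
Dwells still in progress at the recording end contribute survival terms.

Parameters are estimated by Nelder–Mead on transformed coordinates
(logit a, log τ₁, log(τ₂ − τ₁)), which keeps a ∈ [0,1] and 0 < τ₁ ≤ τ₂ by
parameterization rather than clipping, from three moment-based starts (ties
broken by likelihood). A nested single-exponential fit provides a
likelihood-ratio check: when the second phase buys less than LR = 4 the fit
is flagged `single_exponential_adequate`/`tau2_unidentifiable` (near-equal
time constants sit on a flat likelihood ridge where the amplitude is
arbitrary). Standard errors come from a 1,000-resample bootstrap (default)
over molecules when location identities are available — molecules, not
individual dwells, are the independent unit — and over dwells otherwise.

## Time-to-first-binding and initiation

Per location, the first qualifying event time (or right-censoring at the
recording end). Joint maximum likelihood over the two location classes:

- control: F(t) = 1 − e^{−k_bkgnd·C·t};
- DNA: F(t) = A_f·(1 − e^{−(k_a+k_bkgnd)·C·t}) + (1−A_f)·(1 − e^{−k_bkgnd·C·t}).

The background rate multiplies inside the active branch (an active location
is hit by whichever process fires first); with C = 1 the same model yields
first-order probe rates, i.e. the background-corrected initiation rate
k_init with the ≥5 s probe-duration filter. The active fraction can be
pinned to a reference condition's value. Transformed-coordinate Nelder–Mead
(log rates, logit A_f), three starts, bootstrap SEs over locations.
Per-condition summaries average replicate k_init without weighting; fold
inhibition is the ratio of condition averages with relative errors combined
in quadrature.

Count-based rates are exact arithmetic: k = n/(T·C) with Poisson SE √n/(T·C);
the kinetic dissociation constant is K_D = (k_on·τ₁)⁻¹. The photobleaching
control fits a censoring-aware exponential disappearance rate to a dye-only
recording and calls bleaching negligible iff k_bl < 0.1/τ₂ (i.e. it shortens
the slow phase by <10 %).

## Coincidence statistics

Arrivals and departures are interval start/end frames; "simultaneous" means
|Δframe| ≤ w with w = 1 frame by default (inclusive, the literal reading of
a ±1-frame window). Co-departure is evaluated on the co-arrived subset, with
nearest-start matching and each partner interval used at most once. The
randomized control pools absolute departure times and pairs them across
locations with a seeded derangement-style shuffle (self- and same-location
pairs repaired by swaps); pairing absolute times, not dwell durations, is
what makes the null represent chance coincidence in a shared time base.
Recruitment onto preformed complexes counts visitor arrivals strictly inside
target intervals, excluding the co-arrival window, over summed target-bound
time. The co-arrival/lone dwell split is exhaustive and disjoint by
construction.

## FCS

The multi-component 3-D Gaussian model with an additive baseline offset
(standard practice for curves that do not decay exactly to zero; no
triplet/blinking term). Concentration units fixed at 1 nM = 0.6022
molecules/μm³. Fits are weighted least squares (lmfit) from five log-spaced
starts, lowest residual sum wins. Calibration fits (ω₀, S) with the
reference-dye D fixed — the model constrains only D/ω₀², so calibrated ω₀
scales as √D_ref, and D_ref is an explicit parameter rather than a committed
value. Sample fits hold (ω₀, S) fixed; the free-species fit returns (⟨C⟩, D);
the two-component fit fixes D_free, bounds the complex's D in [1, 100] μm²/s
by default, and flags f_bound pinned at 0 or 1. Titration analysis follows
the published procedure exactly — R_bound = C·f_bound, R_free = R_T − R_bound,
1/SE²-weighted Langmuir — while the synthetic generator uses the exact 1:1
quadratic with depletion for ground truth; the two coincide because the
quadratic solution satisfies the isotherm in R_free identically.

## Synthetic-data generator

Defaults reproduce the reference colocalization condition: 0.5 s/frame,
2,684 frames (1,342 s), 227 DNA and 227 control locations, active fraction
0.95, 1 nM RNAP, 10 nM GreB with K_D = 10 nM (50 % occupancy) and 93 %
labeling; rate sets from inverting the fitted dwell spectra of the GreB-free
(a=0.91, τ₁=2.6 s, τ₂=29.7 s, k₁=2.2×10⁶ M⁻¹s⁻¹) and GreB-bound (a=0.90,
τ₁=3.4 s, τ₂=44.6 s, k₁=2.4×10⁶ M⁻¹s⁻¹) populations; nonspecific surface
association 0.037×10⁶ (RNAP) and 1.4×10⁴ M⁻¹s⁻¹ (GreB) with exponential
background dwells of mean 5 s (the experiments characterize background only
by an association rate; 5 s makes background events detectable yet clearly
shorter-lived than specific binding).

Arrivals at an active location are a renewal process: exponential waiting at
the occupancy-weighted total association rate, blocked while the promoter is
occupied (at these rates occupancy is ~1 %, so arrival counts are Poisson to
within sampling error, which a dispersion test checks). Each arrival carries
GreB with the equilibrium occupancy probability; unlabeled GreB (7 %) is
invisible in the observable channels but recorded in the truth sidecar.
GreB-free visits may commit to initiation with a single first-order rate
acting over the whole visit; commitment truncates the polymerase interval
and spawns a probe interval with its own exponential dwell (mean 60 s).
GreB-bound visits never initiate. Note the configured commitment rate is a
per-visit hazard: the *measured* initiation rate is approximately
(arrival rate) × P(commit | visit) × P(probe ≥ 5 s), with
P(commit | visit) = 1 − [a·λ₁/(λ₁+k) + (1−a)·λ₂/(λ₂+k)].

Detection: an event registers in a frame iff it overlaps ≥50 % of that
frame; overlapping events merge at the frame level; optional per-frame false
negatives split runs (an event straddling an undetected frame counts as two
events), and optional per-channel photobleaching truncates true durations.
All randomness flows from a single seed through per-location spawned
substreams, so recordings are bit-reproducible and parallel-safe.

What the generator does not emulate: spatial drift and registration error,
intensity noise and spot-detection thresholds (it starts from ideal
presence/absence), dye blinking, non-exponential background, multiple
simultaneous occupancy of one location in the same channel, and open-complex
or elongation kinetics (initiation is a single committed step). Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated kinetic model, not robustness to upstream image-analysis
artifacts.

## Numerical choices and edge cases

- Degenerate eigenvalues (λ₁ ≈ λ₂) collapse to a single exponential; the
  inversion requires a strictly inside (0,1) and τ₁ < τ₂.
- Likelihood terms are floored at 1e-300 before logs; truncation
  normalizations likewise.
- The Langmuir fit seeds K_D from midpoint interpolation and rejects any
  titration point whose bound amount exceeds its total.
- Randomized pairing requires ≥2 locations; the swap-repair loop is bounded
  (200 passes) and seeded.
- Bootstraps skip degenerate resamples (e.g. all-censored) rather than fail;
  SEs are reported as 0 when fewer than 10 resamples survive.

## Problem sizes used in tests and the acceptance script

Simulation-heavy checks run at the experiments' own scales (227–1,600
locations, 1,342–3,600 s recordings, 2,576-dwell samples, 10 curves per
titration point at 1 % rms noise, 10⁵ Gillespie draws for distributional
tests), with bootstrap resamples reduced to 60–200 in tests; the acceptance
script reports point estimates. The slow dwell time constant estimated from
a single 2,576-dwell sample carries an intrinsic sampling SE of ≈6 % (only
~9 % of dwells populate the slow phase), which bounds how tightly any single
seeded run can be expected to match its ground truth.
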