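# smkinetics

Single-molecule and FCS kinetic analysis of secondary-channel-factor
regulation of transcription initiation.

Bacterial RNA polymerase (RNAP) carries a "secondary channel" through which
regulators such as GreB and DksA reach the active site. At ribosomal-RNA
promoters these secondary channel factors (SCFs) repress initiation, and
single-molecule experiments show they do so by a *delayed inhibition*
mechanism: the SCF binds free σ⁷⁰RNAP holoenzyme in solution, rides along to
the promoter, leaves only when the polymerase leaves, and the SCF-bound
polymerase never initiates — while initial promoter binding and closed-complex
lifetimes are unchanged. This package implements the quantitative analyses
behind that picture, for two kinds of data:

- **CoSMoS interval records** (colocalization single-molecule spectroscopy):
  per-location, per-channel presence intervals of fluorescently labeled
  RNAP, SCF and transcript probe at surface-tethered promoter DNA;
- **FCS autocorrelation curves** (fluorescence correlation spectroscopy):
  lag-time vs G(τ) tables from solution binding titrations.

A bundled stochastic simulator generates both with known ground truth, so
every estimator in the package is exercised by parameter-recovery tests.

## The models

**FCS binding titration.** For a mixture of species diffusing through a 3-D
Gaussian confocal volume,

    G(τ) = [π^{3/2} ω₀³ S ⟨C⟩]⁻¹ Σᵢ fᵢ (1 + 4Dᵢτ/ω₀²)⁻¹ (1 + 4Dᵢτ/(S²ω₀²))^{-1/2}

with beam radius ω₀, aspect ratio S = z₀/ω₀, mean concentration ⟨C⟩,
fractions fᵢ and diffusion coefficients Dᵢ. Beam geometry is calibrated on a
reference dye, the free-ligand D from a single-component fit, then
two-component fits with D_free fixed yield the bound fraction at each titration
point. R_bound = C·f_bound and R_free = R_T − R_bound feed a 1/SE²-weighted
Langmuir fit f_bound = R_free/(R_free + K_D).

**Dwell and first-binding kinetics.** Polymerase dwells on the promoter
follow a biexponential survival S(t) = a·e^{−t/τ₁} + (1−a)·e^{−t/τ₂}, fit by
maximum likelihood with frame quantization (interval censoring), left
truncation at the detection threshold and right censoring at the recording
end. Time-to-first-binding curves are fit jointly over DNA and DNA-free
control locations: controls bind at the nonspecific rate k_bkgnd·C; a
fraction A_f of DNA locations additionally binds specifically at k_a·C.
The same model with first-order rates gives background-corrected initiation
rates k_init from transcript-probe arrivals (events ≥ 5 s).

**Coincidence statistics.** Co-arrival and co-departure of SCF and RNAP are
scored within ±1 frame; the chance-coincidence null pairs absolute departure
times from different locations (a seeded derangement). The equilibrium
prediction for the co-arriving fraction is label_eff·[SCF]/([SCF]+K_D).

**Two-closed-complex scheme.** Promoter-bound polymerase interconverts
between closed complexes RP1 ⇄ RP2 (rates k₂, k₋₂) and dissociates only from
RP1 (k₋₁). The dwell spectrum follows from the eigenvalues
λ₁λ₂ = k₋₁k₋₂, λ₁+λ₂ = k₋₁+k₂+k₋₂ with fast-phase amplitude
a = k₋₁(λ₁−k₋₂)/(λ₁(λ₁−λ₂)); the package provides the exact closed-form
inverse (a, τ₁, τ₂) → (k₋₁, k₂, k₋₂) and assembles full rate sets with k₁
taken from the first-binding fit, separately for SCF-free and SCF-bound
polymerase.

## Worked example

Simulate the reference experiment (1,342 s at 0.5 s/frame, 227 promoter-DNA
plus 227 control locations, 1 nM labeled RNAP, 10 nM labeled GreB at
K_D = 10 nM, 93 % dye labeling) and run the full analysis:

```python
import smkinetics as smk

cfg = smk.SimConfig(seed=42)
rec, truth = smk.simulate_cosmos_recording(cfg)

fb = smk.first_binding_times(rec, "rnap")
fit = smk.fit_first_binding(fb["dna"], fb["control"], conc_M=1e-9,
                            n_boot=200, seed=0)
bi = smk.fit_biexponential(smk.extract_dwells(rec, "rnap"),
                           n_boot=200, seed=0)
arr = smk.coarrival_fraction(rec, "rnap", "greb")
rates = smk.assemble_scheme(fit, bi, seed=0)
```

which prints (formatted):

```
k_a = 2.08 +/- 0.21 x10^6 M-1 s-1   A_f = 0.97 +/- 0.02   (N = 227)
a = 0.88 +/- 0.02   tau1 = 3.3 +/- 0.2 s   tau2 = 37.3 +/- 6.7 s   (N = 616)
co-arrival fraction = 0.494 +/- 0.020   predicted = 0.465
co-departure = 100%   randomized control = 0.51%
k1 = 2.08e6 M-1 s-1   k-1 = 0.270 s-1   k2 = 0.0290 s-1   k-2 = 0.0300 s-1
```

Reading this: the promoter association rate constant k_a and active fraction
A_f recover the simulation's ground truth (2.2×10⁶ M⁻¹s⁻¹, 0.95) within
error; the polymerase dwell distribution is biexponential (the fitted values
mix the GreB-free and GreB-bound subpopulations — `split_dwells_by_coarrival`
separates them); half of polymerase arrivals carry labeled GreB, as the
equilibrium occupancy at K_D times the 93 % labeling efficiency predicts;
departures are simultaneous, while randomly re-paired departures almost
never are; and inverting the dwell spectrum returns the closed-complex rate
constants.

The same analyses are scriptable from the shell via the `smki` CLI
(`smki simulate cosmos`, `smki dwells fit`, `smki first-binding fit`,
`smki coloc arrivals|departures|control|predict`, `smki fcs
calibrate|fit-free|fit-bound|titrate`, `smki scheme forward|invert|assemble`,
`smki init rate|summarize`, `smki run --config`).

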