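# Methods

This note documents the models implemented in `pi3knet`, the choices made
where the design was genuinely open, and what the packaged tests do and do
not demonstrate.

## Network model

The signaling network is a deterministic ODE system over ~60 state
variables (protein forms, the PIP2/PIP3 lipid pair, cyclin–CDK complexes)
in arbitrary normalized units, with time in minutes. Ligands (IGF-1,
insulin, HRG, in nM) are boundary inputs, not state variables; the
composite "growth-medium" stimulus drives all three at basal
concentrations (IGF-1 1 nM, insulin 10 nM, HRG 0.1 nM — a plausible
serum/insulin-supplemented culture condition).

Kinetic laws follow standard usage: Michaelis–Menten for enzyme-catalyzed
(de)phosphorylation, mass action for binding/complex formation and
first-order deactivation, Hill induction (n = 1) for transcription, and
zeroth-order synthesis with first-order degradation for expression-level
species (SGK3, NDRG1, ERα, cMyc, cyclin D1, cyclin E, E2F, p21). Modifier
species enter a flux multiplicatively as saturating activators x/(K+x),
saturating inhibitors 1/(1+x/K), linear enzymes, or linear boosts (1+x/K)
used where a regulator enhances but is not required for a flux (e.g., p21
promoting cyclin D1–CDK4/6 assembly).

Every feedback/crosstalk edge of the underlying biology is realized by at
least one reaction or modifier: hyper-phosphorylated Rb suppressing mTORC2,
cyclin D1–CDK4/6 inactivating TSC2, the S6K1→IRS negative feedback,
PIP3-dependent GAB recruitment into PI3K activation, the
P-Rex1/Rac1/p110β positive loop and Rac1→MEK, the nested ERK feedbacks
onto Ras and ErbB, AKT/SGK1 inactivation of FOXO3 and FOXO3-driven ERα
expression, ERα induction of cMyc and SGK3, ERK activation of ERα,
NDRG1 inhibition of ErbB with SGK1/3-primed NDRG1 degradation, Ras→PI3Kα,
AKT⊣Raf, ERK⊣GAB, mTORC1-gated translation of cMyc and cyclin D1,
sequential Rb phosphorylation by cyclin D1–CDK4/6 then cyclin E–CDK2, E2F
auto-activation and Myc-boosted cyclin E induction, ERK-driven p21
expression, AKT-mediated p21 stabilization, and p21's dual role (assembly
factor for cyclin D1–CDK4/6, inhibitor of cyclin E–CDK2 activity).

AKT is modeled with two phosphorylation sites: PDK1 phosphorylates T308,
mTORC2 phosphorylates S473 on the T308 form; the "pAKT" observable is the
sum of both phospho-forms, "pAKT-S473" the doubly phosphorylated form
alone. PDK1's substrates (AKT-T308, SGK1, SGK3) engage at high affinity
(small activator K), which buffers them against partial PIP3 loss but makes
them collapse under direct PDK1 inhibition — the kinetic basis of the
full-pathway co-inhibition synergy discussed below.

### Simulation

The right-hand side is generated as Python source from the reaction list
and compiled once per model; integration uses LSODA (stiff-capable,
adaptive) at rtol 1e−8 / atol 1e−10 for reported trajectories (1e−6/1e−9
inside the fitting objective, where thousands of solves occur and residuals
are far above solver error). Tiny negative excursions are clipped at the
absolute tolerance; larger ones abort with diagnostics. Pre-equilibration
integrates up to 1e5 min under the basal stimulus and requires
max |dy/dt| < 1e−8.

Drugs scale the *effective concentration of the target node's active forms
wherever they appear in catalytic (modifier) positions*: 1/(1 + dose/K_I)
in dose mode, (1 − f) in fractional mode, composable multiplicatively.
BYL719 is dose-mode on PI3Kα with K_I = 0.05 µM, chosen so the standard
1 µM treatment leaves ~5% activity and suppresses AKT phosphorylation as
observed. Abstract screen co-targets use fractional mode at f = 0.9.

### The demo parameterization

The builtin preset's default rate constants are a hand-calibrated demo
parameterization: fast signaling steps (k ≈ 0.3–3 min⁻¹, K_m ≈ 0.3),
expression dynamics on the hour scale (synthesis ~1e−3–5e−3, degradation
0.01–0.03 min⁻¹), tuned so that basal activities sit mid-range under
growth medium and the model reproduces the qualitative behaviors it is
used to demonstrate: BYL719 collapses pAKT-S473 and reduces cyclin D1/pRb;
ERK is spared; the resistant variant retains higher pS6/pRb/cyclin D1; the
p21 sweep is monotone; PDK1-class co-inhibition is strongly synergistic.
It is a demonstration vehicle, not a fit to any dataset — full-data
calibration uses the GA machinery, and the cluster-scale "replication"
preset (population 2000 × 100 generations × 77 starts) is exposed but not
run in the test suite. The packaged demo *ensemble* is a deterministic
log-normal jitter (σ = 0.03–0.05 on log₁₀ parameters) around the demo
values; it exercises the ensemble-prediction machinery (per-set screens,
mean ± SE bands) and is not a GA product. GA correctness and recovery are
validated separately on toy models.

## Calibration

The objective is the variance-weighted residual sum of squares over all
datasets and time points; σ defaults to 1 for averaged/single-valued data.
Because immunoblot and bead-array intensities carry arbitrary units, each
observable can be mapped onto the data by the closed-form least-squares
scale s_j = Σ(y^D y)/Σ(y²) before residuals (enabled by default for real
data; disabled in synthetic-recovery benchmarks where data are in model
units). Integration failures return a large finite penalty (1e12) rather
than propagating exceptions into the optimizer.

The GA works on log₁₀ parameters in [−3, 3]: elites (5% of the
population) are copied unchanged, parents are chosen by tournaments of
size two, a 0.8 fraction of offspring undergo blend crossover, and all
offspring receive Gaussian mutation with the shrinking schedule
σ_k = σ_{k−1}(1 − k/G), σ₀ = 1, clipped to bounds. Elitism makes the
best-of-generation objective non-increasing by construction.

Ensembles retain starts with J ≤ (1 + τ)·J_best with τ = 0.2 ("equally
well" is not quantified in the source material; 20% is a conservative
reading) plus an absolute slack of 1e−8 so that near-machine-zero fits on
noiseless benchmarks are all retained. Ensemble predictions report mean
and SE = SD/√n per output.

## Synthetic data and recovery benchmarking

The replication battery reproduces the calibration design: pAKT/pERK at
10, 30, 90 min of 13 nM IGF-1; cyclin D1, p21, cMyc, pERK, pAKT at 120,
240, 480, 720 min of 1 nM HRG; HRG dose response at 0, 0.05, 1 nM; insulin
dose response at 0.1, 1, 5, 10, 20 nM (pAKT-T308, pERK). Dose responses
are read at 30 min post-stimulus (the read time is not part of the design
being emulated; 30 min captures near-peak receptor-proximal signaling).
Measurement noise is multiplicative log-normal with CV 15% by default
(typical of densitometry), mean-unbiased; variances are 1 by default
(emulating averaged data) or follow the noise model on request.

Ground truths are sampled log-uniformly within the calibration bounds and
rejected if any battery observable is degenerate (~0). Accepted truths
carry a per-parameter *identifiability mask* from a linearized
Fisher-information criterion: with residual sensitivities S (central
differences on log₁₀ scale) and C = (SᵀS)⁻¹ (pseudo-inverse), the
objective increase for an error δ in parameter i with the remaining
parameters re-optimized is δ²/C_ii; a parameter is identifiable when a 10%
deviation is detectable above J = 1e−3 despite that compensation. This
catches jointly sloppy directions (e.g. rate pairs that only constrain
their ratio in quasi-equilibrated stages) that pointwise perturbations
miss, without a full profile-likelihood analysis, which stays out of
scope; ensemble spread remains the only unidentifiability handling in
actual calibration. Recovery reports score only masked parameters — a
parameter the data cannot pin down is unrecoverable by any fitter.

The recovery benchmark runs on a reduced receptor → PI3K → AKT → S6 chain
with a pS6⊣receptor negative feedback (standing in for the S6K1→IRS loop),
freeing four rate constants spread along the chain (k_Ract, k_Rde, k_Aact,
k_Sde). Benchmark truths are drawn from the kinetically informative window
[−0.7, 0.7] log₁₀ (≈0.2–5 min⁻¹): outside it, stages collapse to
quasi-equilibrium on the sampled time grid and only rate *ratios* remain
jointly identifiable, which the pointwise sensitivity mask cannot detect.
At test scale (population 200, 30 generations, 5 starts) identifiable
parameters are recovered within 10% relative error with final J < 1e−3 on
noiseless data.

## Resistant-state derivation

The resistant model applies measured basal fold changes (p21 ×7,
cyclin D1 ×3; AKT, ERK ×1) to the parental initial conditions. Folds act
on the whole moiety (all phospho/complex forms of the species). Two modes:

* **raw** — initials scaled verbatim; fold ratios are exact. Used when the
  applied folds themselves are the quantity of interest.
* **sustained + re-equilibrate** (default) — the synthesis fluxes feeding a
  folded expression-level species are scaled by the same fold so the new
  level is a *fixed point*, then the model is re-equilibrated under basal
  stimulus to redistribute phospho/complex forms. Without this, first-order
  turnover would relax p21 and cyclin D1 back to parental levels within
  hours, contradicting the stable resistant phenotype the fold changes
  describe (resistant pools durably overexpress these proteins). After
  re-equilibration the realized fold is ~7.2× for p21 (feedback shifts it
  slightly off the nominal 7).

The p21 sweep reuses the sustained derivation at each level under a 1 µM
BYL719 background, reading cyclin D1, pRb and pS6 at 48 h.

## Combination screen

Normalized effect E = readout(treated)/readout(vehicle) at the evaluation
time (48 h by default — the screens ask about durable suppression; a
config override exists). CDI = E₁₂/(E₁·E₂); co-targets are ranked
ascending by ensemble-mean CDI with lexicographic tie-breaks; per-readout
CDIs are reported separately (an aggregate across readouts would have no
counterpart in the screen's design). The co-target registry holds the 24
named signaling nodes excluding the PI3Kα anchor, the pure lipid species
and readout-only species. Readouts at exactly zero (complete inhibition)
are floored at 1e−12 so effect ratios stay defined.

In this model the strong PDK1 synergy is mechanistic, not imposed: BYL719
alone is buffered by p110β-derived PIP3 and by relief of the S6K1→IRS
feedback, and PDK1's high-affinity substrate engagement keeps AKT/SGK
signaling alive at reduced PIP3 — co-inhibiting PDK1 removes exactly that
compensation, making the combined effect super-multiplicative.

ICx estimation interpolates the normalized, monotone dose response
piecewise-linearly and bisects for the crossing of 1 − x; non-monotone or
non-crossing responses raise errors (screens mark such co-targets "not
evaluable" rather than extrapolating).

## Phenotypic model

A fixed population distributes over G1, S, G2/M (M), repair (R) and
apoptosis (A); fractions sum to 1 exactly (no birth term over the screen
window, so "viability" compares fractions). Auxiliary variables: DNA
damage DD and CHK1 activity. Fluxes: cyclin-gated G1→S (Hill, n = 3,
K = 1.3 on network cyclin D1/E normalized to parental basal — steep
gating so that cytostatic cyclin loss translates into proliferation
arrest); CHK1-blocked S→M; M→G1 wrap-around; damage-gated repair entry
(∝ DD × CHK1) from S and M; CHK1-driven repair success R→M; and a
DD-proportional death flux from every live compartment, *tempered by CHK1*
(1/(1 + CHK1/K)): checkpoint arrest shelters damaged cells, so checkpoint
inhibition under damage precipitates death (the CHK1-inhibitor
sensitization mechanism). CDC25 and GADD45 are not explicit species; their
effects are folded into CHK1's block of S→M and promotion of R. DD is
produced at a small basal rate (replication stress) plus a rate
proportional to PI3Kα-inhibitor occupancy, decays slowly, and is cleared
by repair (∝ CHK1 × R). CHK1 activates saturably on DD; MK-8776 scales
CHK1 activity in every flux where it acts. With all DD sources at zero,
CHK1 activity decays to zero and viability is exactly invariant to CHK1
inhibition.

Viability V = R + M. The screen start state is the basal distribution of
the undrugged model (long-horizon integration from an all-G1 population,
live compartments renormalized). The 25-target screen pairs the BYL719
anchor (µM dose grid) and each co-target (fractional grid up to 0.99) at
their individual IC50 or IC75 on viability, then scores CDI on viability.
Co-targets whose single-drug response never crosses the ICx level are
reported not evaluable; with the demo parameterization 10 (IC50) / 8
(IC75) of 25 co-targets are evaluable, the IC50 and IC75 rankings agree
(Spearman 1.0 on the common set), and CHK1 and PDK1 rank first and second.

## Numerical choices and limitations

* Determinism: identical models, inputs and tolerances give bitwise
  identical tables on one platform; all randomness flows from explicit
  seeds (NumPy Generator / SeedSequence spawning for multi-start fits).
* The synthetic generator emulates the calibration *design* (conditions,
  times, doses, noise magnitude) but not systematic features of real blot
  data — saturation, background subtraction, inter-gel normalization —
  so passing recovery tests demonstrates the machinery, not fitness of the
  full network to real measurements.
* The SBML Level 3 export is a minimal writer (species, parameters,
  reactions with explicit MathML rate laws) intended for interoperability
  checks; it does not emit units, annotations or SBO terms.
* No spatial or stochastic simulation; no pharmacokinetics; single-cell
  fate is deterministic population flow; the apoptosis cascade
  (ATM/ATR/caspases) is deliberately collapsed into the DD → death flux.
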