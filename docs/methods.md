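# Methods

`cardiofit` personalises a human ventricular action-potential (AP) model
from steady-state AP waveforms recorded at several pacing cycle lengths
(PCLs), and maps a fitted model onto another subject through mRNA
expression ratios.  This note documents the models, the optimiser, the
synthetic-data generator, and the numerical and design choices.

## Forward models

### Ionic model

The cell model is the O'Hara-Rudy (2011) human ventricular myocyte,
endocardial variant, implemented from the published equation set: 41 state
variables (membrane potential, 29 gates and gate-like variables, 8 ionic
concentrations across myoplasm, subspace and sarcoplasmic reticulum, two
ryanodine-release fluxes and the CaMKII trap).  Thirteen conductances and
fluxes carry dimensionless multiplicative scaling factors — gNa, gKr, gK1,
gKs, PCaL, gto, gNaK, gNCX, gpCa, Jrel, Jup, CMDN, CaMKII — with baseline
model ⇔ all factors 1.  The implementation is verified by three
properties: the published resting state is an approximate equilibrium
(|dV/dt| < 0.2 mV/ms), 1-Hz steady pacing yields APD90 ≈ 273 ms, RMP ≈
−88 mV, amplitude ≈ 129 mV (published endocardial values ≈ 270 ms /
−88 mV), and halving the integrator step caps moves APD90 by ≈ 0.5 ms.

The cell is paced with −80 A/F, 0.5 ms current pulses (a conventional
choice; the protocol is configurable).

### Integrator

Gate-like states (anything with dx/dt = (x∞ − x)/τ, including the
relaxation forms of the L-type calcium `nca` variable and the two release
fluxes) advance by the exponential Rush-Larsen update; the membrane
potential, concentrations and CaMKII trap advance by forward Euler.  The
step is adaptive on |dV/dt| (at most 0.1 mV of membrane-potential change
per step), floored at 5×10⁻³ ms and capped at 0.5 ms.  Two robustness
rules were added after observing failures:

* the relative per-step change of the calcium compartments (cai, cass,
  cansr, cajsr) is capped at 10%: at high SR load (≈ 4 mM) the
  calcium-release subsystem is stiff and a dV-only rule diverges at
  millisecond steps;
* a step budget (≈ 20× the typical count) turns pathological parameter
  corners into flagged failures instead of unbounded runs.

Numerical blow-ups (|V| > 200 mV, NaN, budget exhaustion) return a
*flagged result*, never an exception, so a fitness evaluation can assign
the penalty value and the optimiser continues.

Output traces are linearly resampled onto a uniform 1-ms grid, matching
1-kHz optical mapping cameras.

Fitness evaluations inside the genetic algorithm and synthetic-baseline
generation both use a relaxed cap pair (1 ms / 0.2 mV): the ≈1 ms APD
bias is negligible against fitted RMSE values, a 9-beat evaluation runs
twice as fast, and using the same caps on both sides keeps the true
genome's self-fitness near zero.  Reference computations (steady-state
comparisons, restitution) use the tighter default caps.

### 1D cable

Tissue recordings are modelled by a cable of discrete cells coupled
through a gap-junctional conductance acting on V (default 5 mS/μF, 30
cells, no-flux ends), one node per cell.  Diffusion is integrated
explicitly with the cell update; the step is additionally capped at
0.4/g ms for stability.  The conduction velocity (CV) is the
least-squares slope of distance versus activation time (first upward
crossing of −20 mV) over interior cells, excluding five cells at each
end; the cell length used to convert to cm/s is 0.01 cm (the published
cell geometry; the source material does not print the conversion).  A
−80 A/F stimulus cannot excite a single cell loaded by 5 mS/μF coupling,
so cable simulations default to a −300 A/F edge stimulus on cell 0.
With these defaults the cable conducts at ≈ 26 cm/s (reference value
27 cm/s); the central-cell AP is insensitive to the exact coupling in
the physiological CV range.

### Toy surrogate

A closed-form AP-like waveform makes the whole optimisation stack
testable in milliseconds: V(t) = −rest + amp · up(t) · rep(t) with a
sigmoidal upstroke (fixed 5 ms latency) and a sigmoidal repolarisation
edge (width 6% of APD), where APD(pcl) = APD_long − (APD_long −
APD_short) · exp(−(pcl − 200)/350) (ms).  Each of the four parameters
(rest, amp, APD_long, APD_short) controls exactly one waveform feature;
the fourth is the PCL-dependent restitution term.  Baseline values
(85 mV, 125 mV, 290 ms, 180 ms) mimic a human ventricular AP.  The
parameterisation was chosen so that a 1% error in any parameter produces
a comparable fitness change (2.8–4.9 mV total RMSE): an earlier variant
that searched a restitution *time constant* was ~3× less identifiable
than the other parameters — the sensitivity of a restitution time
constant is bounded by the restitution-depth share of the APD — which
made recovery experiments hard to interpret.

## Fitness

For each PCL the candidate (model) trace is compared with the reference
(input) trace:

* **optical mode** (default; optical mapping gives normalised waveforms):
  the traces are aligned at their half-maximum upstroke crossings
  (sub-sample, linear interpolation), the *reference* is affinely
  rescaled (αV + β, closed-form least squares) onto the model, the
  reference's initial depolarisation below −20 mV is excluded (a
  contiguous prefix; photon scattering distorts the experimental
  upstroke), and the root-mean-square error (RMSE, mV) is taken over the
  remaining overlap.  The mask is defined on the (rescaled) reference
  side: masking on the model side would let a candidate with a slow or
  absent upstroke delete exactly the samples that condemn it;
* **absolute mode** (microelectrode-style data): plain RMSE on the common
  grid.

The total fitness is the weighted sum of per-PCL RMSEs (weights default
to 1 and are not normalised).  A candidate AP with amplitude < 30 mV at
any PCL, or a failed integration, draws a penalty of 10³ mV.  By
construction the optical fitness is invariant to any affine transform and
time shift of the reference trace.

Because the input is rescaled onto the model, absolute RMSE shrinks with
the model's own amplitude, so low-amplitude quasi-depolarised models form
a family of shallow local minima.  Two details keep that family out: the
amplitude discard measures the AP net of the stimulus artifact (a
−80 A/F × 0.5 ms pulse alone depolarises a quiescent cell by ≈40 mV, so
a peak-to-peak measure could never reject sub-threshold responses — in a
cable the recorded centre cell has no artifact and the plain measure
works as-is), and the upstroke mask sits on the reference side as
described above.

## The genetic algorithm

Each organism carries a genome (13 multipliers, bounded to [0.01, 4],
plus per-PCL slow-variable genes: [Na⁺]ᵢ ∈ [1, 20] mM and [Ca²⁺]_NSR ∈
[0.3, 6] mM), a persisted model state per PCL, and its fitness.  One
generation:

1. **Evaluation.**  For each PCL the genome's slow-variable genes are
   written into the persisted state ([Na⁺]ss follows [Na⁺]ᵢ; [Ca²⁺]_JSR
   is rescaled proportionally to the NSR change), the model runs 9 beats
   (odd, so 1:1 alternans flips parity between generations and raises the
   RMSE of alternating organisms), the 9th beat is scored, the final
   state is persisted, and its slow variables are written back into the
   genome.  Organisms therefore approach the paced steady state across
   generations, and non-steady solutions are eventually discarded because
   their waveform (hence RMSE) keeps changing.
2. **Selection.**  Size-2 tournaments over two shuffled copies of the
   population (each organism competes exactly twice).
3. **Elite breeding.**  The worst members of the mating pool are replaced
   by copies of the elite (best 6.6% of the population), so elites pass
   their parameters to offspring via crossover.
4. **SBX crossover** (organism-level probability 0.9): per gene, a spread
   factor from the order-10 polynomial distribution; children symmetric
   about the parents' mean; genewise swap with probability 0.5; clipped
   to bounds.
5. **Cauchy vector mutation** (organism-level probability 0.9): a
   direction drawn uniformly on the unit sphere in baseline-normalised
   gene space and a signed step length drawn from a Cauchy distribution
   with half-width-at-half-maximum γ = 0.18, truncated by inverse-CDF
   sampling so the result stays inside the box (the truncation realises
   the renormalisation of the Cauchy density over the admissible range).
   All genes move simultaneously; axis-aligned "point" mutation is
   provided only as a comparison operator.
6. **Elitism.**  Unspoiled elite copies replace the evaluated-worst
   offspring.  Elite genomes pass unchanged, but their persisted states
   (and hence slow-variable genes and fitness) keep evolving.

The loop is deterministic given the seed, checkpointable (HDF5 snapshot
of genomes, states, fitness, history and RNG state; a resumed run is
bit-identical), and stops on a generation budget or fitness threshold.

Elite breeding (step 3) deserves a note: without it the population
reaches a mutation–selection equilibrium whose spread (≈15–20% per
parameter under γ = 0.18 in low dimension) is too wide for fine recovery;
inserting elite copies into the mating pool lets clustered elites breed
with each other and acts as the local-refinement channel.  On the toy
problem this single mechanism moved 100-generation recovery errors from
1–4% to 0.1–0.9%.

Initial multipliers are drawn log-uniformly on [0.01, 4] (median 0.2);
slow-variable genes uniformly within their bounds.  Initial persisted
states are the baseline model's 1-Hz paced steady state (computed once
and cached) with each organism's slow-variable genes written in.

## Synthetic-data generation

`personalize.make_baselines` creates verification inputs by pacing the
forward model to steady state — 1000 s per PCL, the convergence horizon
of the slow variables — at the study PCLs (217, 225, 250, 300, 500,
1000, 2000 ms by default; reduced sets mimic shorter recordings).
Optical mode min–max normalises each trace, discarding the absolute
voltage scale exactly as fluorescence recordings do; optional additive
white Gaussian noise is parameterised by SNR in dB (experimental optical
noise is close to Gaussian; 28 dB is attainable experimentally after
60-Hz notch filtering and ensemble averaging, both provided in
`waveform`).  The generator returns the hidden truth (multipliers and
steady-state concentrations) for scoring.  What it does not emulate:
photon-scattering distortion of the upstroke, motion artifacts, spatial
APD heterogeneity, and drift — so passing recovery tests demonstrate
identifiability under ideal noise, not robustness to structured
experimental artifacts.

## Recovery experiments

Recovery error is |estimate − truth|/truth per multiplier.  Experiments
run replicate seeded GA fits (9 replicates, matching the reference
protocol) and report per-run errors and the ensemble mean of the best
genomes; the ensemble mean is the headline estimate (standard multi-start
aggregation).  At desk scale the toy experiment uses population 50 and
100 generations; single runs usually recover all four parameters within
1% and the ensemble mean does so with a safety margin.

The ionic-model problem is much harder for a cold start: with normalised
(optical-style) input the fitness surface is deceptive — compensated
parameter families (for example near-zero repolarisation conductances
balanced by altered calcium handling) occupy broad shallow minima that a
small population locks onto long before the narrow true basin is
sampled, and desk-scale cold-start runs (population ~40–100, up to
several hundred generations, single-cell) end in such families.  Warm
starts in the truth's vicinity converge cleanly, with the expected
identifiability structure: the high-amplitude currents (gNa, gKr, gK1,
PCaL) resolve to a few percent while low-amplitude and calcium-handling
parameters stay at tens of percent.  Full cold-start recovery at the
reference level therefore requires the reference-scale configuration —
population ≥100, ~700 generations, the full 7-PCL restitution protocol,
the tissue-level (cable) forward model, replicate runs — which is
cluster work, not a desktop test.  The shipped reduced smoke experiment
runs the desk configuration regardless and documents this limit.

## Convergence diagnostics

Population snapshots (multipliers only, baseline-normalised,
mean-centred, no variance scaling — the parameters are already
dimensionless and commensurate) are projected onto two principal
components fitted on the pooled snapshots; the truth projects into the
same plane.  Mean Cluster Error is the centroid-to-truth distance and
Standard Distance the RMS cluster radius; both are invariant to rigid
rotations of the PC plane.

## mRNA-based rescaling

Each multiplier maps to the pore-forming subunit gene of its current
(SCN5A→gNa, KCNH2→gKr, KCNJ2→gK1, KCNQ1→gKs, CACNA1C→PCaL, KCNA4→gto,
ATP1A1→gNaK, SLC8A1→gNCX, ATP2B4→gpCa, RYR2→Jrel, ATP2A2→Jup,
CALM1→CMDN, CAMK2D→CaMKII).  A fitted genome is mapped to a second
subject by multiplying each multiplier by the target/reference expression
ratio of its gene (TPM or equivalently normalised counts; tables must be
pre-aggregated to one row per gene).  The operation is multiplicative,
associative and invertible.  Slow-variable genes are dropped — the new
subject's concentrations re-equilibrate by pacing (1000 s per PCL).
Rescaled multipliers may leave the GA search box ([0.01, 4]): those
bounds belong to the optimiser, not to the model, so clipping is applied
only when explicit validity limits are requested.  Auxiliary channel
subunits are not modelled (single-gene proportionality assumption).

## Problem sizes used in the shipped checks

Reference comparisons run at full stated scale (1000 s pacing runs; the
30-cell cable).  Optimiser experiments are desk-scale: toy recovery at
population 50 × 100 generations × 9 replicates; operator comparisons at
population 40–60 × 40–60 generations; the ionic-model smoke at
population 40 × 150 generations × 4 PCLs.  These sizes are the package's
own verification tier; the reference-scale experiment configurations are
expressible through the same API and CLI.

## Known limitations

* Endocardial variant only (epi/M parameter sets are out of scope).
* One node per cell in the cable; no 2D/3D tissue or fibre orientation.
* The expression map uses one gene per current; auxiliary subunits and
  isoform mixtures are ignored.
* Low-amplitude and calcium-handling parameters (gKs, gto, gNCX, gNaK,
  Jrel, Jup, CMDN, CaMKII) are weakly identifiable from AP waveforms
  alone; expect materially larger recovery errors than for gNa, gKr,
  gK1, PCaL.
* Optical-pixel selection and motion correction are out of scope; inputs
  are assumed to be single clean AP traces per PCL.
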