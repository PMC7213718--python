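# cardiofit

Personalised human ventricular action-potential (AP) models from
steady-state AP waveforms, via a modified genetic algorithm, with
mRNA-expression-based rescaling between subjects.

## The problem

Optical mapping of human ventricular tissue yields normalised AP
waveforms — shape, but not absolute voltage — at a handful of pacing
cycle lengths (PCLs).  `cardiofit` fits the 13 principal conductances and
fluxes of the O'Hara-Rudy human ventricular myocyte model (gNa, gKr, gK1,
gKs, PCaL, gto, gNaK, gNCX, gpCa, Jrel, Jup, CMDN, CaMKII, as
multiplicative scaling factors) to such recordings.  Two features make
this work:

* **A renormalising fitness.**  Per PCL, the input trace is aligned at
  the half-maximum upstroke, affinely rescaled (V → αV + β, least
  squares) onto the model trace, the model's depolarisation phase below
  −20 mV is excluded, and the RMSE is accumulated across PCLs
  (RMSE_tot = Σ wᵢ·RMSEᵢ).  Sub-threshold APs (amplitude < 30 mV) draw a
  penalty.
* **Simultaneous search in parameter and slow-variable space.**  The
  paced steady state of the model depends on its initial intracellular
  state, and slow variables ([Na⁺]ᵢ, [Ca²⁺]_NSR) take hundreds of seconds
  to converge.  Instead of pacing every candidate to steady state, each
  organism persists its model state between generations, is evaluated
  after only 9 beats, and carries the per-PCL initial slow-variable
  values inside its genome, where mutation and crossover act on them.
  Non-steady solutions discard themselves: their waveform, and hence
  RMSE, keeps drifting.

The genetic algorithm uses tournament selection, simulated binary
crossover (order-10 polynomial spread, 0.9 crossover probability, 0.5
genewise swap), *Cauchy vector mutation* — the whole genome moves along a
random unit direction with a heavy-tailed step, HWHM γ = 0.18 of the
baseline value, probability 0.9 — and a large elite fraction (6.6%)
whose unspoiled genomes re-enter both the mating pool and the next
generation while their persisted states keep evolving.

A fitted model is mapped onto a second subject by multiplying each
scaling factor by the subjects' mRNA expression ratio of the
corresponding pore-forming subunit gene (SCN5A, KCNH2, KCNJ2, KCNQ1,
CACNA1C, KCNA4, ATP1A1, SLC8A1, ATP2B4, RYR2, ATP2A2, CALM1, CAMK2D).

See `docs/methods.md` for models, operators and numerical choices.

## Worked example

Fit the four-parameter closed-form toy AP (a fast surrogate wired to the
same optimiser) and inspect the recovery:

```bash
cardiofit make-baselines --model toy --pcls 217,300,500,1000,2000 \
    --mode absolute --out baselines/
cardiofit fit --baselines baselines/ --config examples/ga-toy.yaml \
    --seed 0 --out run/
cardiofit report --run run/ --truth baselines/truth.json
```

With `examples/ga-toy.yaml` (population 50, 100 generations) this prints

```
wrote 5 baselines to baselines
best RMSE_tot 1.737 after 100 generations -> run
generations: 100
final best RMSE_tot: 1.737
final mean RMSE_tot: 80.08
           mean_error_pct
parameter
rest             0.389087
amp              0.503710
apd_long         0.225258
apd_short        0.043530
```

i.e. the optimiser recovered the resting level, amplitude, long-PCL APD
and restitution depth of the hidden truth to ~0.5% or better from
waveforms alone (the mean population RMSE stays high by design: the
heavy-tailed mutation keeps most of the population exploring while the
elite track the optimum).  The same `fit` command drives the ionic model
(`model: single-cell` or `model: cable` in the config), and

```bash
cardiofit rescale --genome run/best_genome.json --expr expression.tsv \
    --ref Patient1 --target Patient2 --out patient2_model.json
```

produces the expression-rescaled second-subject model.

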