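# lucirhythm

Model-based analysis of circadian bioluminescence rhythms of luciferase
reporters expressed from a constitutive promoter.

## The problem

In duckweed (and other plants), a luciferase reporter driven by a
*constitutive* promoter such as CaMV35S still shows a circadian
bioluminescence rhythm, even though its transcription is not under clock
control. Three cell-level factors could generate such a rhythm:

1. **luminescence efficiency** — circadian changes in the cellular
   conditions of the luciferase reaction (luciferin, Mg²⁺-ATP, O₂, pH),
2. **production rate** of the luciferase protein,
3. **degradation rate** of the luciferase protein.

These alternatives can be discriminated by comparing two reporters of
different protein stability, e.g. ELuc (half-life ≈ 10 h) and ELuc-PEST
(≈ 3 h). If the rhythm enters through the luciferase *amount* (production
or degradation), the stable reporter low-pass filters it: its detrended
rhythm has a smaller relative amplitude and a phase delay. If only the
luminescence *efficiency* is rhythmic, the amount is constant and
stability is irrelevant — both reporters show identical relative rhythms.

## The model

The luciferase amount `x(t)` and emitted luminescence `L(t)` follow

```
dx/dt = k·[1 − A_prod·cos(ωt − φ_prod)] − γ·[1 − A_deg·cos(ωt − φ_deg)]·x
 L(t) = ε₀·[1 − A_eff·cos(ωt − φ_eff)]·x(t)
```

with mean production rate `k` (1 h⁻¹), degradation rate `γ` (0.07 h⁻¹
stable, 0.23 h⁻¹ unstable), angular frequency `ω = 2π/26` (a 26-h
free-running period) and relative modulation amplitudes `A ∈ [0, 1]`.
Four scenarios are analysed, each modulating at most one factor with
`A = 0.25`: `SIM_B` (baseline, no rhythm), `SIM_C` (efficiency), `SIM_D`
(production), `SIM_E` (degradation).

The analysis pipeline computes, per reporter: the raw-intensity mean
over 93–119 h; **relative values** (intensity divided by its centred
26-h moving average); the **relative amplitude** (half the swing between
the third trough of the valid region and the following peak, after a 7-h
zero-phase smoothing); and the **phase** (time since the last peak,
evaluated at 84 h). For rhythmic production/degradation the linear-system
prediction is a relative amplitude `A·γ/√(γ² + ω²)` and a peak lag
`arctan(ω/γ)/ω` — the quantitative basis of the discrimination.

## Worked example

```
$ lucirhythm table1
analysis  mean_st  mean_unst  mean_ratio  amp_st  amp_unst  amp_ratio  phase_st  phase_unst  phase_diff  classification
   SIM_B     14.3        4.3         3.3     NaN       NaN        NaN       NaN         NaN         NaN              NA
   SIM_C     14.3        4.4         3.3    0.22      0.22        1.0      19.0        19.0        -0.0      efficiency
   SIM_D     14.3        4.4         3.3    0.06      0.15        0.4      13.7        15.6        -2.0 amount-mediated
   SIM_E     14.3        4.4         3.2    0.06      0.15        0.4       0.7         2.5        -1.9 amount-mediated
```

Reading the table: mean luminescence differs 3.3-fold between the
reporters (the equilibrium ratio `γ_unst/γ_st = 0.23/0.07`) in every
scenario. Under rhythmic efficiency (`SIM_C`) the relative amplitudes
match (ratio 1.0) and phases coincide; under rhythmic production or
degradation (`SIM_D`/`SIM_E`) the stable reporter's relative amplitude
drops to 0.4 of the unstable one's and its peak is delayed by ~2 h —
the signature used to classify observed rhythms.

A synthetic two-reporter experiment (9 replicate traces each, log-normal
single-cell intensities) runs end-to-end:

```
$ lucirhythm synth --preset EXP --seed 2 --outdir demo
wrote traces, cells and truth.csv to demo
amplitude ratio 0.84, phase difference -0.6 h -> efficiency

$ lucirhythm cellstats demo/stable_cells.csv --lilliefors
n = 225
geometric mean = 83.93 photons/min
log-normality (lilliefors): statistic = 0.0369, p = 0.6833
```

The matching relative amplitudes (ratio close to 1 by the 0.8 threshold)
and sub-hour phase difference classify the rhythm as generated at the
luminescence-efficiency step.

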