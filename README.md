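# flimbind

Fluorescence-lifetime decomposition and binding-kinetics analysis for
calmodulin-regulated nitric oxide synthase (and similar flavoprotein
systems that report conformation through FMN fluorescence).

Endothelial NO synthase (eNOS) cycles through conformational states that
can be resolved by the fluorescence lifetime of its FMN cofactor: an
*input* state with FMN stacked against FAD (~90 ps), an *output* state
with FMN near the haem (~0.9 ns), and *open* states with FMN uncoupled
(several ns). Regulation — calmodulin (CaM) activation, inhibitory
phosphorylation by proline-directed kinases such as ERK — shifts the
population balance between these states and tunes CaM binding kinetics.
This package provides the computational side of that analysis:

* **Lifetime arm** — multi-exponential decay models
  `I(t) = Σᵢ αᵢ e^{−t/τᵢ}` with steady-state intensity fractions
  `fᵢ = αᵢτᵢ / Σⱼ αⱼτⱼ`; a TCSPC simulator (periodic 20 MHz excitation
  with wraparound, Gaussian IRF, Poisson counting noise); and a
  reconvolution fitter (Poisson-weighted NLLS with variable projection,
  multistart, φ²/reduced-χ² goodness of fit and φ²-guided model
  selection).
* **Binding arm** — forward models for 1:1 Langmuir binding
  (`A + B ⇌ AB`, closed form) and the two-state sequential scheme
  (`A + B ⇌ AB ⇌ AB*`, exact per-phase linear-system solution) with the
  coupled-equilibrium constant
  `K_D = (k_off1/k_on1)·k_off2/(k_off2 + k_on2)`; simulators for BLI
  multi-sensor series and SPR single-cycle kinetics; and global fitters
  with residual-bootstrap confidence intervals.
* **Motif arm** — SP/TP proline-directed motif scanning, resolution of
  ambiguous phosphosite candidate sets, and an in-silico tryptic digest.

Published parameter sets (lifetime decompositions of the resting and
CaM-activated enzyme with/without ERK phosphorylation; BLI and SPR rate
constants for CaM–eNOS binding) ship in `flimbind.presets` as simulation
ground truths.

## Worked example

Simulate a decay of the CaM-activated, ERK-phosphorylated enzyme (85%
input state at 90 ps, 15% open at 4.3 ns) and refit it:

```python
from flimbind import presets, generate_dataset, reconvolution_fit
from flimbind.decay import state_report

data = generate_dataset(presets.ENOS_CAM_ERK, seed=1)
fit = reconvolution_fit(data, 2, seed=1)
print("phi2 =", round(fit.reduced_chi2, 3))
print(state_report(fit.model).to_string(index=False))
```

```
phi2 = 1.056
 state  population_pct  intensity_fraction_pct
 input        85.08052               10.602519
output         0.00000                0.000000
  open        14.91948               89.397481
```

The fitter recovers the 85/15 amplitude split (φ² ≈ 1 confirms the model
matches the counting noise); the intensity-fraction column shows why raw
steady-state intensity is misleading here — the 15% open population emits
~89% of the photons. Both conventions are always reported side by side.

The binding arm round-trips the same way:

```python
from flimbind.pipelines import bli_recovery_report
rep = bli_recovery_report(
    presets.BLI_SINGLE_STATE["minus_erk"], presets.BLI_CONCENTRATIONS_M, seed=1
)
print(rep["fitted"])
```

```
{'kon': 119422.18569015816, 'koff': 0.00011093668521192638,
 'rmax': 1.0020736655555558, 'kd_pM': 928.9453594473017}
```

i.e. a simulated five-concentration BLI series (0–87.5 nM, 180 s
association/dissociation, 1% noise) refit globally recovers
K_D ≈ 929 pM from a 920 pM ground truth.

A `flimbind` console command exposes the same pipelines
(`simulate-decay`, `fit-decay`, `simulate-sensorgram`, `fit-sensorgram`,
`scan-motifs`, `run`); see `flimbind --help`.

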