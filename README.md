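# icepop

Single-cell analysis of bistable mobile-element activation in clonal
bacterial populations.

Integrative and conjugative elements (ICEs) such as ICE*clc* excise and
transfer from only a few percent of host cells: activation is a bistable
decision taken during stationary phase. The size of that activated
subpopulation is set upstream, by cell-to-cell variability in the
stationary-phase sigma factor RpoS — only cells whose RpoS level lands in
the upper tail of the population distribution are *permissive*, and among
those an additional factor decides who actually switches ON. `icepop`
implements the quantitative toolchain used to establish this picture from
single-cell fluorescence microscopy, together with a generative simulator
of the threshold-activation model so that every stage can be exercised and
validated without micrographs.

## What it computes

**Subpopulation fraction from cumulative curves.** Cells ranked by their
background-subtracted average gray value (AGV) trace a cumulative curve
with two near-linear regimes — a shallow OFF regime and a steep ON regime.
The breakpoint between the two slope lines is found by exhaustive
two-segment least squares; the ON fraction is `100 − breakpoint percentile`
and the ON expression level is the mean AGV above the breakpoint.

**Dual-reporter noise decomposition.** Two identical promoter copies fused
to distinguishable reporters (eGFP, eCherry) in the same cell separate
expression variability into intrinsic (uncorrelated between reporters) and
extrinsic (shared) components. With `g`, `c` the normalized per-cell
reporter values and ⟨·⟩ the population mean,

    η_int² = ⟨(g − c)²⟩ / (2⟨g⟩⟨c⟩)
    η_ext² = (⟨gc⟩ − ⟨g⟩⟨c⟩) / (⟨g⟩⟨c⟩)
    η_tot² = [(⟨g²⟩ + ⟨c²⟩)/2 − ⟨g⟩⟨c⟩] / (⟨g⟩⟨c⟩)

with the exact identity `η_tot² = η_int² + η_ext²` on every sample.
Uncertainty comes from a 1000× bootstrap over cells.

**Threshold-activation simulator.** Per cell, a sigma-factor level
`R ~ Normal(c·μ_R, σ_R)` (truncated at 0, `c` the gene copy number); the
cell is permissive if `R ≥ θ` and activates with probability `p_act`;
reporter output is `E·ε·(basal + amplitude·active)` with unit-mean
lognormal extrinsic (`E`, shared) and intrinsic (`ε`, per channel) factors,
plus Gaussian camera background, clipped to the 8-bit sensor range. The ON
fraction is the emergent tail probability `p_act · Φ((c·μ_R − θ)/σ_R)`.

Also included: segmentation + AGV quantification of grayscale TIFFs
(`icepop.imaging`), quadrant-conditioned activation analysis, Pearson
reporter correlation, conjugative transfer frequency, one-way ANOVA +
Tukey HSD with compact letter displays (`icepop.association`), and an
end-to-end pipeline with a markdown report (`icepop run`).

## Worked example

```sh
icepop run --preset wildtype --n-cells 5000 --seed 9 --out runout
```

simulates three replicate populations of 5000 cells under the wild-type
preset (activation threshold at μ + 1.881σ, so 3% of cells clear it),
estimates per-channel breakpoints, gates to the activated subpopulation,
and decomposes the noise. It prints

```
fraction ON (g): 2.79 ± 0.27 %; report at runout/report.md
```

and the report contains

```
| channel | fraction ON (%) | mean ON AGV |
| g       | 2.79 ± 0.27     | 206.0 ± 2.2 |
| c       | 2.79 ± 0.27     | 201.6 ± 3.0 |

| component | mean ± SD (replicates) |
| eta_int   | 0.214 ± 0.011          |
| eta_ext   | 0.883 ± 0.082          |
| eta_tot   | 0.909 ± 0.082          |
```

The recovered ON fraction matches the simulated 3% tail probability within
sampling error. Within the gated ON subpopulation the extrinsic component
dominates, as expected when a shared upstream factor (here the simulated
sigma-factor/extrinsic axis) gates activation. The same stages are
available as library calls (`simulate_population`, `estimate_on_fraction`,
`noise_decomposition`, `bootstrap_noise`, `quadrant_activation`, ...).

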