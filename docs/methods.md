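# Methods

## The generative model

Each simulated cell draws a global-factor (RpoS-like) level
`R ~ Normal(copy_number · mu_R, sigma_R)`, truncated at zero. A cell is
*permissive* when `R >= theta` and switches ON with probability `p_act`,
modelling an unidentified co-regulator as an independent Bernoulli gate —
the minimal reading of "a high global-factor level is necessary but not
sufficient". Nothing else about the activation mechanism is modelled: no
intracellular dynamics, no regulator kinetics, no growth.

Reporter output is multiplicative:

    raw = E · ε · (basal + amplitude · active) + Normal(bg_mean, bg_sd)

where `E` (shared by both channels of a cell) and `ε` (independent per
channel) are unit-mean lognormal factors with shapes `sigma_E`, `sigma_I`.
Lognormal rather than Gaussian noise guarantees positivity and gives
closed-form coefficients of variation, which the test suite uses as
independent truths:

    eta_ext_true = CV_E = sqrt(exp(sigma_E²) − 1)
    eta_int_true = CV_ε · sqrt(1 + CV_E²)

Raw values are clipped to `[0, 2^bit_depth − 1]`; cells that touch the
ceiling are flagged so noise estimation can exclude them (8-bit cameras
saturate the bright ON tail in practice, and so does the simulator).

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `mu_R` | 50 | AFU | population mean of the global-factor reporter |
| `sigma_R` | 10 | AFU | 20% CV, typical protein-level cell-to-cell spread |
| `theta` (wildtype) | `mu_R + 1.881·sigma_R` | AFU | upper-tail mass Φ(−1.881) = 3.0% |
| `theta` (rpos_plus) | `mu_R + 0.915·sigma_R` | AFU | tail mass 18%, the elevated-copy regime |
| `copy_number` (rpos_double) | 2 | — | doubles the mean level only; `sigma_R` fixed |
| `p_act` | 1.0 | — | factor-X probability |
| `basal` / `amplitude` | 5 / 195 | AFU | ON cells ~40× brighter than OFF |
| `sigma_E`, `sigma_I` | 0.2 | — | moderate multiplicative reporter noise |
| background | 10 ± 2 | gray | additive camera background |
| `bit_depth` | 8 | — | 8-bit camera with visible ON-tail saturation |

The simulator emulates: an approximately normal global-factor distribution,
a small skewed ON subpopulation orders of magnitude brighter than OFF,
correlated dual reporters through the shared extrinsic factor, camera
background and saturation, and (via `render_images`) spatially rendered
cells with ground-truth masks. It does **not** emulate: cell shape
heterogeneity beyond random ellipses, uneven illumination, focus drift,
cell clumping/overlap, photobleaching, temporal dynamics, or growth-phase
structure. Passing tests therefore demonstrate correctness of the
estimators under the stated noise model, not robustness to every artifact
of real micrographs.

## Breakpoint estimation

The cumulative curve ranks all cells by AGV; the i-th of n sorted values
sits at percentile `100·i/n`. The OFF/ON breakpoint is found by exhaustive
two-segment least squares: every data percentile in `[50, 99.9]` is tried
as a split (prefix-sum moments make this O(n)), a line is fitted on each
side, and the split minimizing total squared residual wins — the automated
equivalent of placing slope lines on the two linear parts by eye. The
search starts at the 50th percentile because the ON subpopulation is the
minority by construction.

Two numerical choices matter:

* **Constrained intersection.** The breakpoint is the intersection of the
  two fitted lines snapped to the nearest data percentile, but the
  intersection is first clamped to the percentile gap between the two
  segments. When the ON regime rises as a near-vertical jump, the ON
  segment's regression line is shallow and its backward extension crosses
  the OFF line deep inside the OFF regime; the clamp keeps the breakpoint
  at the geometric corner, which is where the optimal split already is for
  well-separated subpopulations.
* **Slope-ratio gate.** A breakpoint is reported only if the ON-segment
  slope exceeds the OFF-segment slope at least 20-fold (`min_slope_ratio`).
  Genuinely bistable curves show ratios of 40–1000; the upper tail of a
  unimodal population produces spurious corners with ratios around 7–14.
  Curves failing the gate (and flat, zero-variance curves) return
  `fraction_on = 0` with the `no_subpopulation` flag.

A reported subpopulation whose mean AGV falls below the detection floor
(default 10 gray levels) carries a `below_detection` flag, mirroring the
"<10" convention of replicate tables. Replicate summaries report
mean ± sample SD (ddof = 1); a single replicate reports SD 0 with a
`single_replicate` flag.

## Noise decomposition

Channels are made comparable by independent scaling: subtract the per-image
background, floor at zero, normalize to the channel's population maximum
(= 100). The literal maximum is used; a single bright outlier therefore
rescales its channel — acceptable here because gating removes the dim bulk,
but worth knowing.

Gating retains cells above the g-channel breakpoint *or* above the
c-channel breakpoint (union; an intersection mode exists for sensitivity
analysis), with saturated cells excluded by default. The decomposition then
uses the standard dual-reporter moment formulas (README). Sample
`η_ext²` can be negative at small n; it is preserved signed
(`eta_ext_sq_signed`) so the identity `η_tot² = η_int² + η_ext²` stays
exact to machine precision, and `eta_ext` is reported as the signed root.

The bootstrap resamples cells with replacement (default 1000×), recomputes
the decomposition on each resample and summarizes each component by its
across-resample mean and SD. A resample with a non-positive channel mean is
redrawn (bounded retries, counted in `n_redrawn`). Everything is
deterministic given the seed (`numpy.random.default_rng`).

## Quadrants, correlation, and group statistics

Quadrant analysis cuts the conditioning channel at its empirical
mean − SD, mean, mean + SD (population SD, not a fitted Gaussian) and
reports the fraction of cells whose reporter reaches a threshold per bin;
the count-weighted bin fractions recompose the overall activation rate
exactly. The default threshold is the reporter channel's breakpoint AGV.
Reporter correlation is Pearson r per replicate with mean ± SD across
replicates. Transfer frequency is transconjugant CFU / donor CFU, with
zero transconjugants flagged at the assay's detection limit (1/donors).

Group comparison runs one-way ANOVA (scipy) followed by Tukey's HSD
(statsmodels) and derives a compact letter display by insert-and-absorb on
the significant-pair relation at α = 0.05; letter sets are canonically
sorted, so the sharing relation is invariant to group ordering. A two-group
mode runs the homoscedastic t-test.

## Image quantification

Segmentation thresholds the image (Otsu default; Li and a robust
`background` method — median + 6·1.4826·MAD — as options), labels
8-connected components and filters by area. Otsu can split a wide, sparse
foreground (few percent of pixels) instead of separating it from
background; the `background` method is preferred for dim-object work.
Measurement reports each object's mean pixel value, subtracts the per-image
median of non-object pixels (median for robustness to the bright ON
minority), floors the corrected AGV at zero (it feeds ratio statistics),
and flags objects containing sensor-maximum pixels as saturated.
Quantification is exactly invariant to a constant offset of the whole
image.

## Problem sizes and runtime

Breakpoint recovery is validated at 10⁵ cells (sub-second via the
prefix-sum search), noise-estimator consistency at 5·10⁴ paired cells,
pipeline and rendering checks at 10²–10⁴ cells with bootstrap sizes of
20–200 in tests (1000 by default in production use). The full suite runs
in a few seconds.

## Known limitations

* The slope-ratio gate (20×) is a heuristic cut between regimes observed to
  differ by ~3× in simulations; populations with genuinely shallow ON
  regimes (weak separation) will be flagged as having no subpopulation.
* Normalization to the literal channel maximum is outlier-sensitive.
* The factor-X gate is memoryless and independent of R; any real mechanism
  coupling the two would change the quadrant enrichment profile.
* Segmentation assumes isolated convex cells on flat background; touching
  cells merge (counted as one object) and no registration between channels
  is performed — paired analyses take values from the cell table, not from
  two-channel image matching.
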