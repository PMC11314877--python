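# Methods

## Problem and model

`spadspec` estimates leaf chlorophyll status (SPAD, the unitless reading
of a handheld chlorophyll meter) of wheat canopies from hyperspectral
reflectance, in the setting of CO₂ microleakage stress monitoring: four
treatment groups (control and 1/3/5 L·min⁻¹ sub-surface CO₂ injection)
whose leaf SPAD distributions differ strongly. The estimation procedure
is a chemometric calibration chain:

1. **Quality control** — drop samples with missing channels,
   reflectance outside [−0.05, 1.5], or adjacent-channel jumps above a
   threshold (default 0.3).
2. **Five-point weighted moving-average smoothing** — channel *i*
   becomes Σⱼ wⱼ r(i+j−2)/Σⱼ wⱼ with the symmetric centre-weighted
   kernel (1, 2, 4, 2, 1)/10 by default. The first/last two channels
   use the truncated window renormalized over the weights that remain
   in range; an edge channel whose truncated window carries zero total
   weight (possible with one-sided kernels) is left unsmoothed.
3. **Grünwald–Letnikov (G-L) fractional differentiation** — for order
   α ≥ 0 and grid step h,
   D^α r(i) = h^{−α} Σ_{k=0..i} w_k r(i−k), with w₀ = 1 and
   w_k = w_{k−1}(k−1−α)/k (equal to (−1)^k C(α, k)). α = 0 is the
   identity; α = 1, 2 are the backward first/second differences. The
   sweep covers α = 0 … 2 in steps of 0.1 (21 transforms).
4. **Successive projections algorithm (SPA)** — grows a chain of
   channels from a seed column; each step appends the channel with the
   largest norm after projection onto the orthogonal complement of the
   selected span, which minimizes collinearity within the chain.
   Chains are grown from every start channel; each candidate subset is
   scored by the validation RMSE of an intercepted least-squares fit,
   and the minimizer wins (ties: smaller subset, then lower start
   index). The pipeline default keeps the chain length fixed at 10
   bands.
5. **Calibration** — MLR (ordinary least squares with intercept) and
   PLSR (NIPALS, mean-centered, no variance scaling; component count
   chosen by validation RMSE, capped at 10) on the selected bands.
6. **Scoring and order selection** — R² = 1 − SSres/SStot and
   RMSE = √(SSres/n). Per treatment group and model kind the order with
   the highest validation R² is flagged optimal, and every order's
   validation scores are expressed as percent change over order 0 (the
   raw spectra).

Models are fitted *per treatment group* (one calibration per leakage
rate), with a stratified random 2:1 train:validation split fixed across
all orders.

## Numerical choices

- **G-L window/truncation.** The derivative uses the full expanding
  left history from the first retained channel. The first ~20 channels
  are therefore edge-affected; the sweep records this width and band
  selection can optionally exclude them as chain seeds
  (`mask_edges`), default off.
- **G-L weights** are computed by the multiplicative recurrence, which
  is exact at integer orders where the Gamma closed form has poles. The
  operator is applied as a lower-triangular Toeplitz matrix product, so
  α = 0 reproduces the input bit-for-bit and integer orders match
  discrete differences to machine precision.
- **SPA batching.** All start-channel chains are grown simultaneously
  in the Gram-matrix (incremental Cholesky) formulation: residual
  squared norms are tracked by rank-one downdates of diag(XᵀX). This is
  algebraically identical to explicit Gram–Schmidt deflation (verified
  against it in the tests) but touches O(p) memory per start and step
  instead of O(n·p). Degeneracy (an exactly dependent column) is
  detected relative to each column's original squared norm
  (10⁻¹² relative, floored at 10⁻²⁴ absolute), because the downdates
  cancel only to O(machine-eps × norm). Candidate subsets are scored
  with batched pseudoinverse least squares.
- **Columns are mean-centered** with training means before SPA and
  PLSR; no variance scaling by default, since post-derivative bands are
  already commensurate (autoscaling would inflate noise-only channels).
- **Tie-breaking** is deterministic everywhere: lowest channel index at
  equal projected norms, smaller subset then lower start at equal RMSE,
  lower order at equal R².
- **R² definition.** Model ranking uses the standard coefficient of
  determination 1 − SSres/SStot; with zero-variance observations R² is
  undefined and reported as missing. RMSE uses denominator n, not n−p.
- **Modelling range** defaults to 400–1350 nm on a 1 nm grid
  (configurable); reflectance below 400 nm is noisy in field spectra
  and excluded from band selection.

## Synthetic data generator

Field campaigns of this kind rarely deposit raw spectra, so the package
carries a generator whose defaults *are* the study conditions, giving
every stage a known ground truth:

- **SPAD per group**: truncated-normal draws (exact, by rejection) with
  (mean, SD, min, max) = control (59.5, 3.7, 51.1, 65.5),
  1 L (42.9, 15.6, 10.2, 62.0), 3 L (36.6, 17.7, 5.5, 60.1),
  5 L (35.3, 18.3, 7.0, 60.2); 30 samples per group. Note the
  *truncated* mean differs slightly from the nominal mean (control:
  59.20 vs 59.5).
- **Reflectance** on 350–1350 nm at 1 nm: visible baseline 0.30 rising
  through a logistic red edge (width 4 nm) to an NIR plateau 0.55; the
  edge inflection sits at 700 + 0.4·SPAD nm, so stress (low SPAD)
  blue-shifts the red edge. Chlorophyll absorption wells at 450 and
  680 nm (the red valley) deepen with SPAD as d_max·SPAD/(SPAD+20) and
  fade out across the edge; a Gaussian green peak at 550 nm (σ = 20 nm)
  has height 0.12·25/(25+SPAD), so stressed canopies show the taller
  green peak; fixed water dips sit near 970 and 1200 nm. Gaussian
  channel noise (default SD 0.01) and optional ±amplitude "burr"
  spikes are added, and reflectance is clipped to [0, 1.2].

The encoding is strictly monotone in SPAD (green-peak height down,
red-edge position up), so noise-free spectra determine SPAD exactly.
What the generator does **not** emulate: radiative-transfer physics
(PROSPECT/SAIL), canopy-structure and soil-background effects,
illumination drift, water-band coupling to leaf water content, and
inter-channel noise correlation. Passing tests therefore demonstrate
that the pipeline recovers a monotone single-latent encoding under
additive noise — not field-data accuracy; reported R²/RMSE values on
synthetic data are upper bounds of what real canopies would give.

Because one latent variable drives all informative channels, two things
follow for tests: the recovered validation R² is high at low orders
(derivatives mostly help once noise and band redundancy bite), and
SPA's condition-number advantage over random channel subsets is only
visible on noise-free spectra (with noise, centered NIR channels are
noise-orthogonal and trivially well conditioned).

## Problem sizes and defaults used in checks

The packaged test suite and the acceptance script choose problem sizes
as follows: the end-to-end acceptance run uses the full default
conditions (4 × 30 samples, 1 nm grid, 951 modelling channels, 21
orders, 10 bands, both models); the repeated stochastic
parameter-recovery check (20 seeds, MLR only) and most unit fixtures
use a 5 nm grid (191 channels), which preserves every spectral feature
(the narrowest, the red edge, spans ~16 nm) while keeping the full
start-scan SPA cheap. Monotonicity checks of the red-edge position use
the 1 nm grid, since a 5 nm grid cannot resolve the 2 nm shift produced
by a 5-unit SPAD step.

## Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `weights` (smoother) | (1,2,4,2,1)/10 | — | five-point kernel |
| `max_abs_jump` | 0.3 | reflectance | QC adjacent-channel jump bound |
| `alpha` grid | 0–2 step 0.1 | — | G-L differentiation orders |
| `step_h` | grid step (1 nm) | nm | G-L denominator h^α |
| `n_bands` | 10 | — | SPA chain length |
| `ratio` | 2/3 | — | train fraction, stratified by group |
| `pls_max_components` | 10 | — | PLSR component scan cap |
| `noise_sd` | 0.01 | reflectance | generator channel noise |
| `red_edge_base`, shift | 700, 0.4 | nm, nm/SPAD | edge inflection encoding |

## Known limitations

- The expanding-history G-L window makes early channels depend on where
  the spectrum was cropped; compare selections across runs only at a
  fixed modelling range.
- `spa_select` scans every start channel; cost grows as
  O(p² · n_bands) per order. On grids much finer than 1 nm, pass
  `starts` to subsample seeds.
- MLR requires more training samples than bands + 1; with the default
  10 bands the per-group training set must exceed 11 samples.
- PLSR component choice uses the same validation set that later scores
  the model, a mild optimism shared by the per-order model selection
  itself; with a third data split this could be removed.
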