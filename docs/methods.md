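# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and the limits of what the test suite demonstrates.

## The developmental clock and the decay model

Fixed meiocytes are ordered in pseudo-time by their HEI10 accumulation level
`H`: the percentage of total HEI10 signal intensity residing in the most
prominent foci. Asynapsis is measured as the 3D length of the ASY1 signal
(µm), a negative proxy for synapsis completion because ASY1 is largely
removed from synapsed axes.

The central model is a Gamma GLMM with log link:

    E[asynapsis | plant] = exp(β0_g + β1_g · H + u_plant),
    u_plant ~ Normal(0, σ_u²),  asynapsis | plant ~ Gamma(shape k).

Parameters and units:

| parameter | meaning | default (generator) |
|---|---|---|
| β0_g | log µm asynapsis at H = 0 | 2X ln 25 + 0.36, NEO ln 200, HYB ln 30 + 0.24, EST ln 8 + 0.42 |
| β1_g | decay exponent per accumulation point | −0.030 / 0 / −0.020 / −0.035 |
| σ_u | SD of the per-plant random intercept (log scale) | 0.15 |
| k | Gamma shape (1/CV² of the noise) | 4 |

The generator defaults put each genotype's predicted asynapsis at the 12 %
onset near 50 (diploid, doubled scale), 200, 30 and 8 µm — the regime of the
study system — with the neo-tetraploid flat (stalled synapsis). Gamma shape
4 gives the strongly right-skewed scatter typical of per-cell length
measurements; σ_u = 0.15 makes plants differ by ±15 % around their genotype
mean. Diploid ASY1 lengths are doubled once (provenance-guarded) before
cross-ploidy comparison, since diploids carry half the axis content.

### Estimation

No installed Python package fits Gamma GLMMs, so `meioquant.glmm` implements
the marginal maximum likelihood directly. Each plant contributes a scalar
random intercept; its integral is approximated by Laplace: a vectorised
Newton iteration finds every plant's conditional mode simultaneously, and
the curvature correction is written as −½·log(1 + σ_u²·h_j) so that the
σ_u → 0 limit reproduces the plain GLM log-likelihood exactly (verified to
1e-4 relative in the tests, and to ~5 decimals against an external mixed-
model implementation during development). The outer optimisation is
L-BFGS-B over (β, σ_u, log k) with σ_u bounded at zero; the covariance is
the inverse numerical Hessian of the marginal likelihood (profiled over the
remaining parameters when σ_u sits on its boundary). When every genotype has
a single plant the random intercept is confounded with the genotype
intercepts and the fit falls back to a Gamma GLM (statsmodels) with the ML
shape profiled afterwards; the fallback is flagged.

Exact zeros (fully synapsed cells) are incompatible with the Gamma
likelihood; they are replaced by half the smallest positive measured length
and the replacement value is recorded on the fit.

Inference is Wald-based throughout (normal reference, no small-sample df
correction), with Holm adjustment applied within each family of contrasts
(onset comparisons, decay-exponent comparisons, final-asynapsis
comparisons). Pseudo-R² is the Nakagawa variance partition on the linear-
predictor scale with trigamma(k) as the Gamma log-link residual variance
(log-normal approximations for the count families). On clean synthetic
cohorts the conditional R² runs high (~0.93); real imaging data carry
measurement error the generator does not emulate, so real-data R² values
are expected to be lower.

## Image quantification

* **Normalization** maps each channel to [0, 1] between its minimum and its
  0.999 quantile (hot-pixel resistant); all downstream thresholds work on
  relative intensities, making every measurement invariant to intensity
  scaling.
* **Dual thresholds.** The total-signal mask uses the Triangle method
  (permissive); the prominent-focus mask uses Otsu restricted to voxels
  inside the total mask (stringent), forced above the total threshold so the
  masks nest. A cell's histogram holds three populations — background tails,
  dispersed signal, prominent foci — and a single split can land between
  tails and dispersed signal; the stringent threshold is therefore iterated
  within its own mask until the retained class is homogeneous (a further
  split would separate class means by less than 2×). On clean two-population
  histograms the iteration is a no-op and the result is plain Otsu.
* **Accumulation level** = 100 × (intensity in prominent foci) / (intensity
  in the total mask). A threshold mask clips each focus's PSF tails, which
  alone biases the level several points low, so each detected focus is
  integrated over a PSF-scale neighbourhood (mask dilated by 0.25 µm axially
  and 0.12 µm laterally, clipped to the total mask). With these choices the
  measured level tracks the generator's truth to well under 1 point on
  noiseless renders across H = 10–90.
* **Particle analysis** uses 26-connected 3D components with a 4-voxel
  minimum (sub-PSF specks are noise).
* **Skeleton lengths** honour anisotropic voxels by measuring physical edge
  lengths on the skeleton graph rather than resampling the image. The
  26-neighbour graph of the skeleton is reduced to a spanning tree (removing
  the spurious triangles digital diagonals create), decomposed into branch
  paths, and each path is measured by chords spanning four voxels — long
  enough to average out digital staircase jitter, short enough (≤0.16 µm)
  that curvature undershoot is negligible at biological radii. Phantom
  accuracy: ~2 % on axis-aligned lines, ~6 % along z (where 0.125 µm
  sections limit sampling), ~3 % on a 19 µm helix.
* **ZYP1 classification** thresholds the channel (Triangle), labels
  components, and calls a component punctate below 0.4 µm of skeleton length
  (a synapsis initiation site) and elongated otherwise.
* **Coalignment geometry** is an automated surrogate for by-eye scoring: a
  "parallel" structure is a pair of skeleton branch paths, each ≥ 0.5 µm,
  whose nearest-point separation stays within 0.1–0.8 µm over ≥ 0.5 µm of
  arc with SD ≤ 0.2 µm; overlapping pairs merge, and remaining qualifying
  paths count as "irregular". On rendered cells with four true pairs it
  recovers 3.4 on average (misses come from pair tracks that brush other
  structures); geometry counts can be supplied in the input table instead.
* **Linear-HEI10 QC**: a cell is excluded when any prominent HEI10 component
  has skeleton length > 1.5 µm with ≥ 50 % of its voxels within 0.2 µm of
  the ASY1 mask — the rare aberrant linear pattern that would skew
  accumulation levels.

## Staging cutoffs

* **Background**: the maximum accumulation level registered by control
  (somatic/leptotene) cells, which carry no true HEI10 signal, rounded up to
  the grid step. Cells below it are excluded as indistinguishable from
  background.
* **Plateau**: scanning integer cutoffs 13–90 ascending, the decay model is
  refitted on cells above each candidate; the first candidate at which every
  genotype's decay exponent has Wald p ≥ 0.05 marks the level where
  asynapsis has reached its minimum. The returned cutoff is non-decreasing
  in the significance level, and the trace stores every evaluated
  candidate's per-genotype p-values.
* **Late pachytene** (per genotype): the candidate cutoff whose
  mean prominent-focus count above it most closely matches the genotype's
  diakinesis crossover mean (≥ 5 cells required above the cutoff). Ties on
  the exact minimum take the smallest candidate: with a flat population every
  candidate ties and the smallest is the only reproducible choice, and with
  an exact crossing the tie set begins at the crossing point, which is then
  returned — the behaviour the recovery tests pin down.

## Synthetic data: what it emulates and what it does not

The tabular generator reproduces exactly the statistical structure the
models assume (Gamma decay with plant intercepts; Poisson / NB2 counts with
log- or identity-link means; a change-point option `h_plateau` for the
plateau search; prominent-focus counts that converge to the diakinesis
crossover count above `h_late`). One master seed spawns per-cell
substreams, so tables are bit-reproducible.

The renderer draws smooth random space curves (cubic splines through a
direction-persistent bounded random walk, trimmed to exact arc length)
inside a 64×256×256-voxel volume at (0.125, 0.04, 0.04) µm — the axial
spacing of the imaging protocol, with lateral sampling typical of
reconstructed SIM. Synapsed curves are painted into ZYP1 and asynaptic
elements into ASY1 (coaligned pairs consume twice their span, as both
homolog tracks carry ASY1; summed path lengths match the truth within 2 %).
HEI10 is rendered as compact uniform spheres (0.25 µm radius) for prominent
foci — a blurred sphere is Gaussian-edged, and compact pre-blur support
keeps the ground-truth intensity partition well defined — plus a dispersed
pool painted as a dim sheath with weak focal bumps along a fraction of the
axes that shrinks as accumulation rises, mimicking the retraction of the
dispersed signal during coarsening and keeping its per-voxel brightness
below the prominent peaks at every H. The pool is locally drained around
each prominent focus, and the two fields are rescaled so the prominent share
of pre-blur intensity equals H exactly. Channels are blurred with an
anisotropic Gaussian PSF (σ = 0.125 µm axial, 0.05 µm lateral) and
optionally carry Poisson shot noise and Gaussian read noise over a flat
background.

Not emulated: SIM reconstruction artefacts, chromatin texture, interlock
topology, antibody background structure beyond flat offset + noise, or
optical sectioning anisotropy beyond the Gaussian PSF. Passing the oracle
tests therefore shows the *operators* are correct and well calibrated, not
that thresholds transfer unchanged to real microscopy — on real data the
threshold methods and the focus-integration radii are the tunables to
revisit first.

## Test-design choices

Recovery tests are designed so the estimand is identifiable at the stated
sample sizes: the change-point recovery uses a steep decay (β1 = −0.08),
low noise (shape 20) and 600 cells per genotype so that decay below the
H* = 50 knot remains detectable in windows just under the knot (a power
analysis puts the passing band within ±5 of the knot); the CI-coverage test
uses the cohort design of the study (4 genotypes × 4 plants × 40 cells).
Simulation-based checks fix their seeds; coverage bands ([88 %, 99 %] at
nominal 95 %) allow for Monte-Carlo error at 200 replicates.

## Known limitations

* The Laplace approximation is accurate for the scalar-per-plant random
  effect used here but is not adaptive quadrature; with very few cells per
  plant and large σ_u, σ_u can be mildly underestimated.
* The parallel-axis detector under-counts dense tangles; it is a calibrated
  surrogate, not a replacement for expert scoring.
* Identity-link count models carry no variance-partition R² (the Nakagawa
  decomposition needs the log scale); requesting one raises.
* Rendered NB counts and Gamma draws are truncated at the physical axis
  budget; at default parameters the truncation affects ~1 % of
  neo-tetraploid cells and is negligible elsewhere.
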