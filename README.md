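# meioquant

Quantifying synapsis dynamics in fixed meiocytes against the HEI10
accumulation "developmental clock".

## The problem

During prophase I of meiosis, homologous chromosomes pair, coalign, and are
zipped together by the synaptonemal complex (SC). In *Arabidopsis arenosa*,
newly formed autotetraploids (NEO-4X) show severe synapsis defects and
meiotic instability, while established tetraploids (EST-4X) have evolved
synapsis that is even more efficient than in diploids (2X). Because fixed
images are snapshots of a dynamic process, a per-cell pseudo-time is needed
to compare genotypes: the **HEI10 accumulation level** — the percentage of
total HEI10 immunofluorescence residing in the most prominent foci — which
rises monotonically through pachytene as HEI10 coarsens from many dim foci
into a few bright crossover-site foci.

This package re-implements that quantitative framework as a tested pipeline,
exercised end to end on synthetic microscopy stacks and synthetic cell
tables with known ground truth:

* **`synthgen`** — generators: per-cell tables with the exact statistical
  structure the models assume, rendered 3-channel 3D stacks
  (HEI10/ASY1/ZYP1) with PSF blur and noise, and analytic phantoms.
* **`quantify`** — the image macros: normalized dual-threshold HEI10
  quantification with 3D particle analysis, ASY1 3D skeleton length with
  anisotropic voxels, punctate/elongated ZYP1 classification, automated
  detection of coaligned ("parallel") asynaptic axes, linear-HEI10 QC flags.
* **`staging`** — cutoff calibration: background cutoff from control cells,
  the plateau cutoff above which synapsis no longer progresses, per-genotype
  late-pachytene cutoffs, diploid ASY1 doubling.
* **`infer`** — the statistics: the exponential-decay Gamma GLMM, count
  GLM(M)s (Poisson / negative binomial), Wald contrasts with Holm
  correction, Nakagawa pseudo-R², AIC-based family selection.
* **`pipeline` / `cli`** — orchestration (stacks or tables in, CSV/JSON
  reports out) and a thin `meioquant` command-line wrapper.

## The core model

Let `y_ij` be the ASY1 3D length (µm of unsynapsed axis) of cell *i* from
plant *j*, and `H_ij` its HEI10 accumulation level (%). The decay model is a
Gamma GLMM with log link,

    y_ij | u_j ~ Gamma(mean = exp(β0_g + β1_g · H_ij + u_j), shape k)
    u_j ~ Normal(0, σ_u²)

with per-genotype intercepts `β0_g` (log-µm asynapsis at H = 0) and decay
exponents `β1_g` (per accumulation point), and a per-plant random intercept
to absorb individual variation. The marginal likelihood is maximised with a
Laplace approximation over each plant's scalar random effect
(`meioquant.glmm`); the fit matches R's glmmTMB to ~5 decimals and collapses
exactly to the Gamma GLM likelihood as σ_u → 0. Wald z tests on `β1_g`
decide whether a genotype's synapsis progresses at all; predictions at the
12 % onset level give the starting extent of asynapsis per genotype.

Count responses (quadrivalents, univalents, coaligned parallels vs ASY1
length, elongated ZYP1 segments vs total ZYP1 length, crossover foci vs
asynapsis) are fitted as Poisson or negative-binomial regressions, with the
same Laplace machinery when a plant random intercept is requested.

## Worked example

```python
from meioquant import synthgen, staging, infer

table = synthgen.simulate_cell_table(synthgen.default_genotypes(),
                                     plants_per_genotype=4, cells_per_plant=40,
                                     seed=11)
cells = table.rename(columns={"H_true": "accumulation_pct",
                              "asynapsis_true": "asy1_length_um"})
cells, _, _ = staging.filter_by_cutoff(cells.assign(qc_pass=True), 12.0)
cells = staging.normalize_diploid(cells, "2X")   # diploid lengths ×2
fit = infer.fit_gamma_decay(cells)
print(infer.predict_asynapsis(fit, H=12.0).round(1))
```

prints (seed 11):

```
  genotype     H  mean_um  ci_low_um  ci_high_um
0       2X  12.0     47.3       39.1        57.3
1   NEO-4X  12.0    210.0      172.2       256.0
2   HYB-4X  12.0     31.4       26.0        37.8
3   EST-4X  12.0      7.8        6.4         9.5
```

i.e. at the onset of HEI10 accumulation the neo-tetraploid carries ~200 µm
of unsynapsed axis and its decay exponent is indistinguishable from zero
(synapsis has stalled), the diploid ~50 µm, the hybrid ~30 µm, and the
established tetraploid under 10 µm — and `fit.slope_pvalues()` shows every
genotype except NEO-4X declining significantly.

The numbered drivers under `analysis/` run the full narrative on a
simulated 17-plant cohort (01 simulate → 02 phantom validation → 03 render
and quantify → 04 cutoff calibration → 05 decay model → 06 count models),
writing their tables under `results/`.

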