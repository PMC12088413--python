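"""Synthetic inputs with known ground truth, at two fidelities.

Two generators are provided:

* :func:`simulate_cell_table` draws per-cell measurement tables with exactly
  the statistical structure the inference layer assumes — asynapsis is Gamma
  noise around an exponential-decay mean ``exp(beta0_g + beta1_g * H + u_plant)``
  with per-plant random intercepts, and all count variables (prominent foci,
  parallels, elongated ZYP1 segments, multivalents, crossovers) follow
  Poisson / negative-binomial laws with log- or identity-link means.

* :func:`render_cell` and :func:`make_phantom` rasterise 3-channel 3D stacks
  (HEI10 / ASY1 / ZYP1) of curvilinear axes with partial synapsis, compact
  bright foci over a dispersed background, anisotropic PSF blur, and optional
  shot and read noise, returning voxel-level ground-truth masks.

Determinism: one master seed is split into independent per-cell substreams,
so identical seeds and parameters give bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, ndimage

from .stack import Stack3C

__all__ = [
    "GenotypeParams",
    "RenderSpec",
    "CellTruth",
    "default_genotypes",
    "simulate_cell_table",
    "render_cell",
    "make_phantom",
]


@dataclass
class GenotypeParams:
    """Generating parameters for one genotype/cytotype.

    ``beta0`` is the log-µm asynapsis at accumulation level 0 and ``beta1``
    the decay exponent per accumulation percentage point (non-positive for
    genotypes whose synapsis progresses). ``h_plateau`` optionally caps the
    linear predictor at ``min(H, h_plateau)``, i.e. asynapsis stops declining
    past that accumulation level (a change point). ``h_late`` is the
    accumulation level past which prominent-focus counts have converged to
    the diakinesis crossover count ``co_mean``.
    """

    name: str
    beta0: float
    beta1: float
    plant_sd: float = 0.15
    gamma_shape: float = 4.0
    co_mean: float = 15.0
    co_intercept: float = 2.7
    co_slope: float = 0.0015
    parallel_intercept: float = 0.9
    parallel_slope: float = 0.9  # per 100 µm of ASY1
    elong_intercept: float = 2.0
    elong_slope: float = 0.25  # per µm of ZYP1, identity link
    quad_mean: float = 0.0
    uni_mean: float = 0.0
    total_axis_um: float = 400.0
    h_plateau: float | None = None
    h_late: float = 50.0
    punctate_mean: float = 8.0
    irregular_mean: float = 1.5
    nb_theta: float = 5.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in ("name",) or v is None:
                continue
            if not math.isfinite(float(v)):
                raise ValueError(f"GenotypeParams.{f.name} is not finite: {v!r}")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.plant_sd < 0:
            raise ValueError("plant_sd must be >= 0")
        if self.total_axis_um <= 0:
            raise ValueError("total_axis_um must be > 0")
        if self.quad_mean < 0 or self.uni_mean < 0:
            raise ValueError("quad_mean and uni_mean must be >= 0")
        if self.nb_theta <= 0:
            raise ValueError("nb_theta must be > 0")


def default_genotypes() -> list[GenotypeParams]:
    """Study-regime defaults for the four genotypes.

    Magnitudes follow the published regime: asynapsis at the onset of HEI10
    accumulation (H = 12%) near 50 µm in diploids (on the doubled scale;
    ~25 µm as measured), ~200 µm in neo-tetraploids with an essentially flat
    trend, ~30 µm in first-generation hybrids and < 10 µm in established
    tetraploids; diakinesis crossover means ~10 / 22 / 18 / 17; metaphase-I
    quadrivalent means 0 / 3.0 / 1.5 / 0.7 and univalent means
    0 / 0.9 / 0.1 / 0.1 per cell.
    """
    common = dict(plant_sd=0.15, gamma_shape=4.0, nb_theta=5.0)
    return [
        GenotypeParams(
            name="2X", beta0=math.log(25.0) + 0.36, beta1=-0.030,
            co_mean=10.0, co_intercept=math.log(10.0), quad_mean=0.0,
            uni_mean=0.0, total_axis_um=250.0, h_late=44.0, **common,
        ),
        GenotypeParams(
            name="NEO-4X", beta0=math.log(200.0), beta1=0.0,
            co_mean=22.0, co_intercept=math.log(22.0) - 0.0015 * 200.0,
            parallel_intercept=0.2, quad_mean=3.0, uni_mean=0.9,
            elong_intercept=3.0, elong_slope=0.15,
            total_axis_um=500.0, h_late=59.0, **common,
        ),
        GenotypeParams(
            name="HYB-4X", beta0=math.log(30.0) + 0.24, beta1=-0.020,
            co_mean=18.0, co_intercept=math.log(18.0) - 0.0015 * 10.0,
            quad_mean=1.5, uni_mean=0.1, total_axis_um=500.0,
            h_late=48.0, **common,
        ),
        GenotypeParams(
            name="EST-4X", beta0=math.log(8.0) + 0.42, beta1=-0.035,
            co_mean=17.0, co_intercept=math.log(17.0), quad_mean=0.7,
            uni_mean=0.1, elong_intercept=1.0, elong_slope=0.35,
            total_axis_um=500.0, h_late=65.0, **common,
        ),
    ]


@dataclass
class RenderSpec:
    """Rasterisation parameters for synthetic stacks.

    Defaults: 0.125 µm optical sections with 0.04 µm lateral sampling
    (typical of reconstructed SIM data), an anisotropic Gaussian PSF, 150
    dispersed dim foci per nucleus, and a 10:1 prominent:dispersed peak
    amplitude ratio.
    """

    shape: tuple[int, int, int] = (64, 256, 256)
    voxel_size: tuple[float, float, float] = (0.125, 0.04, 0.04)
    psf_sigma: tuple[float, float, float] = (0.125, 0.05, 0.05)
    n_axes: int = 8
    background: float = 0.02
    shot_noise: bool = True
    read_noise_sd: float = 0.01
    photon_scale: float = 200.0
    dispersed_focus_amp: float = 0.1
    prominent_focus_amp: float = 1.0
    n_dispersed: int = 150
    axis_radius_um: float = 0.07
    prominent_radius_um: float = 0.25
    dispersed_radius_um: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape entries must be > 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be > 0")
        if any(v <= 0 for v in self.psf_sigma):
            raise ValueError("psf_sigma entries must be > 0")
        if self.prominent_focus_amp <= self.dispersed_focus_amp:
            raise ValueError("prominent_focus_amp must exceed dispersed_focus_amp")

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.voxel_size)


@dataclass
class CellTruth:
    """Ground-truth twin of every measured per-cell quantity."""

    plant_id: str
    genotype: str
    H_true: float
    asynapsis_true: float
    zyp1_total_true: float
    n_prominent_true: int
    dispersed_fraction_true: float
    n_parallel_true: int = 0
    n_irregular_true: int = 0
    n_punctate_true: int = 0
    n_elongated_true: int = 0
    n_quadrivalent_true: int = 0
    n_univalent_true: int = 0
    n_co_true: int = 0

    def __post_init__(self):
        if not 0.0 <= self.H_true <= 100.0:
            raise ValueError("H_true must lie in [0, 100]")
        if self.asynapsis_true < 0 or self.zyp1_total_true < 0:
            raise ValueError("lengths must be >= 0")
        for f in dataclasses.fields(self):
            if f.name.startswith("n_") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")


# ---------------------------------------------------------------------------
# Tabular generator
# ---------------------------------------------------------------------------

def _negbin(rng: np.random.Generator, mean, theta):
    """NB2 draw via Gamma-Poisson mixture; Poisson in the theta -> inf limit."""
    mean = np.asarray(mean, dtype=float)
    if np.isinf(theta):
        return rng.poisson(mean)
    lam = rng.gamma(theta, np.maximum(mean, 0.0) / theta)
    return rng.poisson(lam)


def simulate_cell_table(
    params: list[GenotypeParams],
    plants_per_genotype: int = 4,
    cells_per_plant: int = 40,
    h_range: tuple[float, float] = (12.0, 100.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a table of :class:`CellTruth` rows.

    Per cell: ``H_true ~ Uniform(h_range)``; asynapsis is Gamma with mean
    ``exp(beta0 + beta1 * min(H, h_plateau) + u_plant)`` and shape
    ``gamma_shape``, with ``u_plant ~ Normal(0, plant_sd^2)``; counts follow
    the per-genotype Poisson / negative-binomial models. Identical seeds
    give identical tables.
    """
    if not (0.0 <= h_range[0] <= h_range[1] <= 100.0):
        raise ValueError("h_range must be an interval within [0, 100]")
    if plants_per_genotype < 1 or cells_per_plant < 1:
        raise ValueError("plants_per_genotype and cells_per_plant must be >= 1")

    master = np.random.SeedSequence(seed)
    plant_ss, cell_ss = master.spawn(2)
    plant_rng = np.random.Generator(np.random.PCG64(plant_ss))

    rows = []
    n_cells_total = len(params) * plants_per_genotype * cells_per_plant
    cell_streams = cell_ss.spawn(n_cells_total)
    ci = 0
    for g in params:
        for p in range(plants_per_genotype):
            plant_id = f"{g.name}_p{p + 1}"
            u = plant_rng.normal(0.0, g.plant_sd) if g.plant_sd > 0 else 0.0
            for _ in range(cells_per_plant):
                rng = np.random.Generator(np.random.PCG64(cell_streams[ci]))
                ci += 1
                H = rng.uniform(h_range[0], h_range[1])
                h_eff = H if g.h_plateau is None else min(H, g.h_plateau)
                mean_asyn = math.exp(g.beta0 + g.beta1 * h_eff + u)
                asyn = rng.gamma(g.gamma_shape, mean_asyn / g.gamma_shape)
                asyn = min(asyn, g.total_axis_um)
                zyp1_total = g.total_axis_um - asyn
                n_co = rng.poisson(math.exp(g.co_intercept + g.co_slope * asyn))
                extra_mean = g.co_mean * max(0.0, (g.h_late - H)) / g.h_late
                n_prom = n_co + rng.poisson(extra_mean)
                n_par = int(
                    _negbin(rng, math.exp(g.parallel_intercept + g.parallel_slope * asyn / 100.0), g.nb_theta)
                )
                n_irr = rng.poisson(g.irregular_mean)
                n_punct = rng.poisson(g.punctate_mean)
                n_elong = rng.poisson(max(g.elong_intercept + g.elong_slope * zyp1_total, 0.0))
                n_quad = int(_negbin(rng, g.quad_mean, g.nb_theta))
                n_uni = int(_negbin(rng, g.uni_mean, g.nb_theta))
                rows.append(
                    dict(
                        plant_id=plant_id,
                        genotype=g.name,
                        H_true=H,
                        asynapsis_true=asyn,
                        zyp1_total_true=zyp1_total,
                        n_prominent_true=int(n_prom),
                        dispersed_fraction_true=1.0 - H / 100.0,
                        n_parallel_true=n_par,
                        n_irregular_true=int(n_irr),
                        n_punctate_true=int(n_punct),
                        n_elongated_true=int(n_elong),
                        n_quadrivalent_true=n_quad,
                        n_univalent_true=n_uni,
                        n_co_true=int(n_co),
                    )
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Curve machinery for the image renderer
# ---------------------------------------------------------------------------

def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _trim_to_length(pts: np.ndarray, target: float) -> np.ndarray:
    """Cut a densely sampled polyline at exact arc length ``target``."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] < target:
        raise ValueError("polyline shorter than target length")
    i = int(np.searchsorted(cum, target))
    frac = (target - cum[i - 1]) / max(cum[i] - cum[i - 1], 1e-12)
    end = pts[i - 1] + frac * (pts[i] - pts[i - 1])
    return np.vstack([pts[:i], end])


def _random_curve(
    rng: np.random.Generator,
    lo: np.ndarray,
    hi: np.ndarray,
    target_len: float,
    persistence: float = 0.7,
    n_ctrl: int = 10,
    sample_step: float = 0.02,
) -> np.ndarray:
    """Smooth random space curve of exact arc length ``target_len`` (µm).

    Control points follow a direction-persistent bounded random walk; a cubic
    spline through them is densely sampled and trimmed at the target arc
    length. Persistent directions keep the curve smooth and interlock-free.
    """
    for attempt in range(12):
        step = 1.25 * target_len / n_ctrl * (1.0 + 0.25 * attempt)
        pos = rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        ctrl = [pos.copy()]
        for _ in range(n_ctrl - 1):
            turn = rng.normal(size=3)
            turn /= np.linalg.norm(turn)
            d = persistence * d + (1.0 - persistence) * turn
            d /= np.linalg.norm(d)
            pos = pos + step * d
            for ax in range(3):  # reflect at the walls
                if pos[ax] < lo[ax]:
                    pos[ax] = 2 * lo[ax] - pos[ax]
                    d[ax] = -d[ax]
                if pos[ax] > hi[ax]:
                    pos[ax] = 2 * hi[ax] - pos[ax]
                    d[ax] = -d[ax]
            pos = np.clip(pos, lo, hi)
            ctrl.append(pos.copy())
        ctrl = np.asarray(ctrl)
        t = np.linspace(0.0, 1.0, n_ctrl)
        spl = interpolate.make_interp_spline(t, ctrl, k=min(3, n_ctrl - 1))
        n_samp = max(int(2.0 * target_len / sample_step), 32)
        pts = spl(np.linspace(0.0, 1.0, n_samp))
        np.clip(pts, lo, hi, out=pts)
        if _polyline_length(pts) >= target_len:
            return _trim_to_length(pts, target_len)
    raise ValueError(
        f"could not draw a curve of length {target_len:.1f} µm inside the volume"
    )


def _offset_pair(pts: np.ndarray, separation: float, rng: np.random.Generator):
    """Two tracks at constant separation: offset along a fixed normal plane."""
    tang = np.gradient(pts, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    ref = rng.normal(size=3)
    ref /= np.linalg.norm(ref)
    normals = ref - (tang @ ref)[:, None] * tang
    nrm = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.where(nrm > 1e-6, normals / np.maximum(nrm, 1e-12), [0.0, 0.0, 1.0])
    half = 0.5 * separation
    return pts + half * normals, pts - half * normals


def _paint(volume: np.ndarray, pts_um: np.ndarray, radius_um: float,
           voxel_size, value: float = 1.0, additive: bool = False):
    """Rasterise a polyline (or point set) as a tube/ball of given radius."""
    vz = np.asarray(voxel_size, dtype=float)
    r_vox = np.maximum(radius_um / vz, 1e-6)
    ext = np.ceil(r_vox).astype(int)
    offs = np.stack(
        np.meshgrid(*[np.arange(-e, e + 1) for e in ext], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    keep = np.sum((offs / np.maximum(r_vox, 1e-9)) ** 2, axis=1) <= 1.0 + 1e-9
    offs = offs[keep]
    idx = np.round(pts_um / vz).astype(int)
    idx = np.unique(idx, axis=0)
    vox = (idx[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    shape = np.asarray(volume.shape)
    ok = np.all((vox >= 0) & (vox < shape), axis=1)
    vox = vox[ok]
    if vox.size == 0:
        return
    flat = np.ravel_multi_index(vox.T, volume.shape)
    flat = np.unique(flat)
    if additive:
        volume.ravel()[flat] += value
    else:
        volume.ravel()[flat] = np.maximum(volume.ravel()[flat], value)


def _sample_along(pts: np.ndarray, n: int, rng: np.random.Generator,
                  min_sep: float = 0.0, avoid: list | None = None) -> np.ndarray:
    """Draw ``n`` positions along a polyline, optionally non-clumping.

    ``min_sep`` enforces a minimum 3D distance both among the drawn points
    and against the optional ``avoid`` list (points on other curves).
    """
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]

    def at(s):
        i = int(np.clip(np.searchsorted(cum, s), 1, len(cum) - 1))
        frac = (s - cum[i - 1]) / max(cum[i] - cum[i - 1], 1e-12)
        return pts[i - 1] + frac * (pts[i] - pts[i - 1])

    placed: list[np.ndarray] = []
    others = list(avoid) if avoid else []
    tries = 0
    while len(placed) < n and tries < 200 * n + 50:
        tries += 1
        p = at(rng.uniform(0.0, total))
        if min_sep and any(
            np.linalg.norm(p - q) < min_sep for q in placed + others
        ):
            continue
        placed.append(p)
    return np.asarray(placed) if placed else np.empty((0, 3))


def _apply_psf_and_noise(channel: np.ndarray, spec: RenderSpec,
                         rng: np.random.Generator) -> np.ndarray:
    sigma_vox = np.asarray(spec.psf_sigma) / np.asarray(spec.voxel_size)
    out = ndimage.gaussian_filter(channel, sigma=sigma_vox)
    out = out + spec.background
    if spec.shot_noise:
        out = rng.poisson(np.maximum(out, 0.0) * spec.photon_scale) / spec.photon_scale
    if spec.read_noise_sd > 0:
        out = out + rng.normal(0.0, spec.read_noise_sd, size=out.shape)
    return np.maximum(out, 0.0)


def render_cell(truth: CellTruth, spec: RenderSpec):
    """Rasterise one cell into a :class:`Stack3C` plus ground-truth masks.

    The ZYP1 channel paints synapsed axis curves totalling
    ``zyp1_total_true``; the ASY1 channel paints asynaptic elements
    (coaligned parallel pairs, lone irregular stretches, and filler
    stretches) whose summed path length equals ``asynapsis_true`` — a
    parallel pair consumes twice its span, as both homolog tracks carry
    ASY1. HEI10 is ``n_prominent_true`` bright compact foci on synapsed
    curves plus dispersed dim foci everywhere, scaled so the prominent share
    of total pre-blur intensity equals ``H_true`` exactly. Returned masks
    (``prominent``, ``dispersed``, ``asy1``, ``zyp1``) are pre-blur supports.
    """
    extent = spec.extent_um
    total_len = truth.zyp1_total_true + truth.asynapsis_true
    capacity = float(np.prod(extent)) * 2.0  # µm of axis per µm^3, loose packing bound
    if total_len > capacity:
        raise ValueError(
            f"axis budget {total_len:.0f} µm exceeds the volume capacity "
            f"~{capacity:.0f} µm for shape {spec.shape}"
        )
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    margin = 3.0 * np.asarray(spec.psf_sigma) + spec.prominent_radius_um
    lo = margin
    hi = extent - margin
    if np.any(hi <= lo):
        raise ValueError("volume too small for the PSF margin")

    zyp1 = np.zeros(spec.shape, dtype=float)
    asy1 = np.zeros(spec.shape, dtype=float)

    # --- synapsed axes (ZYP1) -------------------------------------------
    syn_curves: list[np.ndarray] = []
    if truth.zyp1_total_true > 0.5:
        n_axes = max(1, min(spec.n_axes, int(truth.zyp1_total_true // 4) or 1))
        cuts = np.sort(rng.uniform(0.25, 0.75, size=n_axes - 1)) if n_axes > 1 else np.array([])
        fracs = np.diff(np.concatenate([[0.0], cuts, [1.0]]))
        for f in fracs:
            L = truth.zyp1_total_true * f
            if L < 0.3:
                continue
            syn_curves.append(_random_curve(rng, lo, hi, L))
    for c in syn_curves:
        _paint(zyp1, c, spec.axis_radius_um, spec.voxel_size)

    # --- asynaptic elements (ASY1) --------------------------------------
    asy_budget = truth.asynapsis_true
    asy_curves: list[np.ndarray] = []
    for _ in range(truth.n_parallel_true):
        if asy_budget < 1.0:
            break
        span = min(rng.uniform(1.0, 3.0), asy_budget / 2.0)
        base = _random_curve(rng, lo, hi, span, persistence=0.97, n_ctrl=4)
        a, b = _offset_pair(base, rng.uniform(0.35, 0.55), rng)
        a = np.clip(a, lo, hi)
        b = np.clip(b, lo, hi)
        asy_curves.extend([a, b])
        asy_budget -= 2.0 * span
    for _ in range(truth.n_irregular_true):
        if asy_budget < 0.8:
            break
        L = min(rng.uniform(1.0, 4.0), asy_budget)
        asy_curves.append(_random_curve(rng, lo, hi, L, n_ctrl=6))
        asy_budget -= L
    while asy_budget > 0.3:
        L = min(rng.uniform(4.0, 10.0), asy_budget)
        if asy_budget - L < 0.3:
            L = asy_budget  # last stretch absorbs the remainder exactly
        asy_curves.append(_random_curve(rng, lo, hi, L, n_ctrl=8))
        asy_budget -= L
    for c in asy_curves:
        _paint(asy1, c, spec.axis_radius_um, spec.voxel_size)

    # --- HEI10: prominent foci + dispersed pool --------------------------
    # The dispersed pool is a faint quasi-linear signal along all axes (the
    # numerous weak early foci blur into a dim sheath) with weak focal bumps;
    # it carries its share of intensity through volume, so its per-voxel
    # brightness stays below the prominent foci across the whole H range.
    host_curves = syn_curves if syn_curves else asy_curves
    prominent = np.zeros(spec.shape, dtype=float)
    dispersed = np.zeros(spec.shape, dtype=float)
    if truth.n_prominent_true > 0 and host_curves:
        per = np.concatenate(
            [np.full(len(host_curves), truth.n_prominent_true // len(host_curves))]
        )
        for i in range(truth.n_prominent_true % len(host_curves)):
            per[i] += 1
        placed_centers: list[np.ndarray] = []
        for c, k in zip(host_curves, per):
            if k == 0:
                continue
            centers = _sample_along(c, int(k), rng, min_sep=1.2, avoid=placed_centers)
            for ctr in centers:
                placed_centers.append(ctr)
                _paint(prominent, ctr[None, :], spec.prominent_radius_um,
                       spec.voxel_size, value=spec.prominent_focus_amp)
    all_curves = syn_curves + asy_curves
    if all_curves and truth.H_true < 100.0:
        # The dispersed pool retracts as coarsening proceeds: it covers a
        # fraction of the axes that shrinks with H, keeping its per-voxel
        # brightness roughly stable (and always well below the prominent
        # peaks) while its total intensity drops.
        H = truth.H_true
        coverage = float(np.clip((100.0 / max(H, 1.0) - 1.0) / 9.0, 0.08, 1.0))
        segments = []
        for c in all_curves:
            L = _polyline_length(c)
            span = coverage * L
            if span < 0.05:
                continue
            s0 = rng.uniform(0.0, L - span)
            seg = np.linspace(s0, s0 + span, max(int(span / 0.02), 4))
            cum = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(c, axis=0), axis=1))])
            idx = np.clip(np.searchsorted(cum, seg), 1, len(cum) - 1)
            frac = (seg - cum[idx - 1]) / np.maximum(cum[idx] - cum[idx - 1], 1e-12)
            segments.append(c[idx - 1] + frac[:, None] * (c[idx] - c[idx - 1]))
        for s in segments:
            _paint(dispersed, s, spec.dispersed_radius_um, spec.voxel_size,
                   value=spec.dispersed_focus_amp)
        if spec.n_dispersed > 0 and segments:
            lens = np.array([_polyline_length(s) for s in segments])
            counts = rng.multinomial(spec.n_dispersed, lens / lens.sum())
            for s, k in zip(segments, counts):
                if k == 0:
                    continue
                centers = _sample_along(s, int(k), rng)
                for ctr in centers:
                    _paint(dispersed, ctr[None, :], 0.5 * spec.dispersed_radius_um,
                           spec.voxel_size, value=1.5 * spec.dispersed_focus_amp)
        # prominent foci locally drain the dispersed pool (coarsening), which
        # also keeps the ground-truth intensity partition exact; the drained
        # zone extends a little beyond the focus itself
        if prominent.any():
            r_excl = np.maximum(
                (np.asarray(spec.psf_sigma) * 3.0) / np.asarray(spec.voxel_size), 1.0
            )
            ez = np.ceil(r_excl).astype(int)
            zz, yy, xx = np.indices(tuple(2 * ez + 1)) - ez[:, None, None, None]
            ball = (zz / r_excl[0]) ** 2 + (yy / r_excl[1]) ** 2 + (xx / r_excl[2]) ** 2 <= 1.0
            dispersed[ndimage.binary_dilation(prominent > 0, structure=ball)] = 0.0

    # Exact intensity partition: rescale so the prominent share of total
    # pre-blur HEI10 intensity equals H_true.
    sp, sd = prominent.sum(), dispersed.sum()
    H = truth.H_true
    if sp > 0 and 0.0 < H < 100.0:
        if sd == 0:
            raise ValueError(
                "cannot realise H_true < 100 without any dispersed signal support"
            )
        dispersed *= (sp * (100.0 - H) / H) / sd
    elif sp > 0 and H >= 100.0:
        dispersed[:] = 0.0
    elif sp == 0:
        prominent[:] = 0.0  # accumulation undefined without prominent foci
    hei10 = prominent + dispersed

    masks = {
        "prominent": prominent > 0,
        "dispersed": dispersed > 0,
        "asy1": asy1 > 0,
        "zyp1": zyp1 > 0,
    }
    pre_blur = {"hei10": hei10.copy(), "prominent_sum": float(prominent.sum()),
                "dispersed_sum": float(dispersed.sum()),
                "asy1_path_length": float(sum(_polyline_length(c) for c in asy_curves)),
                "zyp1_path_length": float(sum(_polyline_length(c) for c in syn_curves))}

    stack = Stack3C(
        hei10=_apply_psf_and_noise(hei10, spec, rng),
        asy1=_apply_psf_and_noise(asy1, spec, rng),
        zyp1=_apply_psf_and_noise(zyp1, spec, rng),
        voxel_size=spec.voxel_size,
        plant_id=truth.plant_id,
        genotype=truth.genotype,
    )
    return stack, masks, pre_blur


# ---------------------------------------------------------------------------
# Analytic phantoms
# ---------------------------------------------------------------------------

def make_phantom(kind: str, spec: RenderSpec, *, length_um: float = 4.0,
                 axis: str = "x", radius_um: float = 1.0, pitch_um: float = 1.0,
                 n_turns: float = 3.0, separation_um: float = 0.3,
                 tube_radius_um: float = 0.07, channel: str = "asy1",
                 noise: bool = False):
    """Analytic-truth fixtures for the length and geometry operators.

    Kinds: ``line`` (straight segment of exact length along an axis),
    ``helix`` (arc length ``n_turns * sqrt((2*pi*r)^2 + pitch^2)``),
    ``parallel_pair`` (two straight tracks at constant separation), and
    ``bubble`` (an interstitial asynaptic parallel pair flanked by two
    synapsed stretches).
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    extent = spec.extent_um
    center = extent / 2.0
    chans = {"hei10": np.zeros(spec.shape), "asy1": np.zeros(spec.shape),
             "zyp1": np.zeros(spec.shape)}
    ax_idx = {"z": 0, "y": 1, "x": 2}[axis]

    def seg(p0, p1, n=None):
        n = n or max(int(np.linalg.norm(p1 - p0) / 0.01), 8)
        return np.linspace(p0, p1, n)

    if kind == "line":
        d = np.zeros(3)
        d[ax_idx] = 1.0
        p0 = center - 0.5 * length_um * d
        p1 = center + 0.5 * length_um * d
        if np.any(p0 < 0) or np.any(p1 > extent):
            raise ValueError("line does not fit in the volume")
        _paint(chans[channel], seg(p0, p1), tube_radius_um, spec.voxel_size)
        truth = {"length_um": float(length_um)}
    elif kind == "helix":
        arc = n_turns * math.sqrt((2.0 * math.pi * radius_um) ** 2 + pitch_um ** 2)
        height = n_turns * pitch_um
        if height > extent[0] - 1.0 or 2 * radius_um > min(extent[1], extent[2]) - 1.0:
            raise ValueError("helix does not fit in the volume")
        t = np.linspace(0.0, n_turns * 2.0 * math.pi, max(int(arc / 0.01), 64))
        pts = np.stack(
            [
                center[0] - height / 2.0 + pitch_um * t / (2.0 * math.pi),
                center[1] + radius_um * np.cos(t),
                center[2] + radius_um * np.sin(t),
            ],
            axis=1,
        )
        _paint(chans[channel], pts, tube_radius_um, spec.voxel_size)
        truth = {"length_um": float(arc)}
    elif kind == "parallel_pair":
        d = np.zeros(3)
        d[ax_idx] = 1.0
        n_vec = np.zeros(3)
        n_vec[1 if ax_idx != 1 else 2] = 1.0
        p0 = center - 0.5 * length_um * d
        p1 = center + 0.5 * length_um * d
        if np.any(p0 < 0) or np.any(p1 > extent):
            raise ValueError("pair does not fit in the volume")
        for s in (+0.5, -0.5):
            off = s * separation_um * n_vec
            _paint(chans[channel], seg(p0 + off, p1 + off), tube_radius_um, spec.voxel_size)
        truth = {"length_um": float(length_um), "separation_um": float(separation_um),
                 "n_parallel": 1, "asy1_length_um": 2.0 * float(length_um)}
    elif kind == "bubble":
        # synapsed - (parallel asynaptic bubble) - synapsed, along `axis`
        d = np.zeros(3)
        d[ax_idx] = 1.0
        n_vec = np.zeros(3)
        n_vec[1 if ax_idx != 1 else 2] = 1.0
        flank = 0.5 * length_um
        p0 = center - (0.5 * length_um + flank) * d
        p3 = center + (0.5 * length_um + flank) * d
        if np.any(p0 < 0) or np.any(p3 > extent):
            raise ValueError("bubble does not fit in the volume")
        a = center - 0.5 * length_um * d
        b = center + 0.5 * length_um * d
        _paint(chans["zyp1"], seg(p0, a - 0.3 * d), tube_radius_um, spec.voxel_size)
        _paint(chans["zyp1"], seg(b + 0.3 * d, p3), tube_radius_um, spec.voxel_size)
        for s in (+0.5, -0.5):
            off = s * separation_um * n_vec
            _paint(chans["asy1"], seg(a + off, b + off), tube_radius_um, spec.voxel_size)
        truth = {"length_um": float(length_um), "separation_um": float(separation_um),
                 "n_parallel": 1, "zyp1_length_um": 2.0 * (float(flank) - 0.3),
                 "asy1_length_um": 2.0 * float(length_um)}
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")

    if noise:
        arrays = {k: _apply_psf_and_noise(v, spec, rng) for k, v in chans.items()}
    else:
        sigma_vox = np.asarray(spec.psf_sigma) / np.asarray(spec.voxel_size)
        arrays = {k: ndimage.gaussian_filter(v, sigma=sigma_vox) if v.any() else v
                  for k, v in chans.items()}
    stack = Stack3C(hei10=arrays["hei10"], asy1=arrays["asy1"], zyp1=arrays["zyp1"],
                    voxel_size=spec.voxel_size, cell_id=f"phantom_{kind}")
    return stack, truth
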