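"""Image quantification of one meiocyte stack.

Re-implements the batch image-analysis macros: dual histogram-threshold
HEI10 quantification with 3D particle analysis (accumulation level =
percentage of total HEI10 intensity residing in prominent foci), ASY1 3D
length by skeletonisation with physical-unit edge lengths (anisotropic
voxels are honoured on the skeleton graph, never by resampling), ZYP1
punctate/elongated segment classification, coalignment geometry detection,
and quality-control flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.morphology import skeletonize

from .stack import Stack3C

__all__ = [
    "FocusSet",
    "CellMeasurements",
    "QuantifyConfig",
    "normalize_channel",
    "dual_threshold_hei10",
    "particle_analysis",
    "hei10_accumulation",
    "skeleton_length",
    "skeleton_paths",
    "classify_zyp1",
    "detect_parallel_axes",
    "flag_linear_hei10",
    "quantify_cell",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class FocusSet:
    """3D particles from a mask: sizes, integrated raw intensity, centroids."""

    foci: pd.DataFrame  # voxel_count, integrated_intensity, centroid_{z,y,x}
    threshold: float | None
    labels: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.foci)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def total_intensity(self) -> float:
        return float(self.foci["integrated_intensity"].sum())


@dataclass
class CellMeasurements:
    """Per-cell quantification record."""

    accumulation_pct: float
    n_prominent: int
    total_hei10_intensity: float
    prominent_hei10_intensity: float
    asy1_length_um: float
    zyp1_length_um: float
    n_punctate: int
    n_elongated: int
    n_parallel: int
    n_irregular: int
    has_linear_hei10: bool
    qc_pass: bool
    qc_reason: str = ""
    cell_id: str = ""
    plant_id: str = ""
    genotype: str = ""

    def __post_init__(self):
        if self.prominent_hei10_intensity > self.total_hei10_intensity + 1e-9:
            raise ValueError("prominent intensity exceeds total intensity")
        if not 0.0 <= self.accumulation_pct <= 100.0 + 1e-9:
            raise ValueError("accumulation_pct must lie in [0, 100]")


@dataclass
class QuantifyConfig:
    norm_quantile: float = 0.999
    min_voxels: int = 4
    axis_threshold: str = "otsu"  # mask method for the ASY1 skeleton channel
    focus_integrate_um: tuple[float, float, float] | None = (0.25, 0.12, 0.12)
    zyp1_elong_cutoff_um: float = 0.4
    parallel_sep_range_um: tuple[float, float] = (0.1, 0.8)
    parallel_min_len_um: float = 0.5
    linear_hei10_min_len_um: float = 1.5
    linear_hei10_dist_um: float = 0.2
    detect_geometry: bool = True


def normalize_channel(channel: np.ndarray, quantile: float = 0.999) -> np.ndarray:
    """Map intensities to [0, 1]: min -> 0, the given high quantile -> 1.

    Values above the quantile are clipped; relative ordering below it is
    preserved. The high quantile resists hot pixels. Raises on a constant
    channel ("no dynamic range").
    """
    channel = np.asarray(channel, dtype=float)
    lo = float(channel.min())
    hi = float(np.quantile(channel, quantile))
    if hi <= lo:
        hi = float(channel.max())
    if hi <= lo:
        raise ValueError("no dynamic range: channel is constant")
    return np.clip((channel - lo) / (hi - lo), 0.0, 1.0)


def dual_threshold_hei10(
    channel: np.ndarray,
    total_method: str = "triangle",
    prominent_method: str = "otsu",
    voxel_size=None,
    homogeneity_ratio: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Permissive and stringent masks from two histogram thresholds.

    The total mask uses a permissive method (Triangle by default) on the
    whole normalized channel; the prominent mask applies a stringent method
    (Otsu by default) restricted to voxels inside the total mask. The
    prominent threshold is forced >= the total threshold so the prominent
    mask is a subset of the total mask.

    With three intensity populations in a cell (background tails, dispersed
    signal, prominent foci) a single histogram split can land below the
    dispersed signal, in which case the "prominent" class still mixes two
    populations. The stringent threshold is therefore iterated within its own
    mask until the retained class is homogeneous: a further split would
    separate classes whose means differ by less than ``homogeneity_ratio``.
    """
    methods = {"triangle": threshold_triangle, "otsu": threshold_otsu}
    if np.all(channel <= 0):
        return (np.zeros(channel.shape, bool), np.zeros(channel.shape, bool), np.inf, np.inf)
    t_total = float(methods[total_method](channel))
    total_mask = channel > t_total
    if not total_mask.any():
        return total_mask, np.zeros_like(total_mask), t_total, np.inf

    t_prom = t_total
    for _ in range(5):
        inside = channel[channel > t_prom]
        if inside.size < 2 or inside.max() <= inside.min():
            break
        t_new = max(float(methods[prominent_method](inside)), t_prom)
        if t_new <= t_prom:
            break
        lo = inside[inside <= t_new]
        hi = inside[inside > t_new]
        if t_prom > t_total and (
            lo.size == 0 or hi.size == 0 or hi.mean() < homogeneity_ratio * lo.mean()
        ):
            break  # current mask already homogeneous; keep t_prom
        t_prom = t_new
    t_prom = max(t_prom, t_total)
    prominent_mask = channel > t_prom
    return total_mask, prominent_mask, t_total, t_prom


def particle_analysis(
    mask: np.ndarray,
    intensities: np.ndarray,
    min_voxels: int = 4,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    threshold: float | None = None,
) -> FocusSet:
    """26-connected 3D components with a minimum-size filter.

    Each retained particle is reported with its voxel count, integrated raw
    intensity, and centroid in physical µm coordinates (voxel centers,
    0-based (z, y, x) indexing).
    """
    if mask.shape != intensities.shape:
        raise ValueError("mask and intensity shapes differ")
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        return FocusSet(
            foci=pd.DataFrame(columns=["voxel_count", "integrated_intensity",
                                       "centroid_z", "centroid_y", "centroid_x"]),
            threshold=threshold, labels=labels,
        )
    counts = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(counts >= min_voxels) + 1
    if keep.size == 0:
        return FocusSet(
            foci=pd.DataFrame(columns=["voxel_count", "integrated_intensity",
                                       "centroid_z", "centroid_y", "centroid_x"]),
            threshold=threshold, labels=np.zeros_like(labels),
        )
    # relabel: drop the small components
    lut = np.zeros(n + 1, dtype=labels.dtype)
    lut[keep] = np.arange(1, keep.size + 1)
    labels = lut[labels]
    sums = ndimage.sum_labels(intensities, labels, index=np.arange(1, keep.size + 1))
    cents = np.asarray(ndimage.center_of_mass(mask, labels, index=np.arange(1, keep.size + 1)))
    vz = np.asarray(voxel_size)
    cents_um = cents * vz
    foci = pd.DataFrame(
        {
            "voxel_count": counts[keep - 1],
            "integrated_intensity": sums,
            "centroid_z": cents_um[:, 0],
            "centroid_y": cents_um[:, 1],
            "centroid_x": cents_um[:, 2],
        }
    )
    return FocusSet(foci=foci, threshold=threshold, labels=labels)


def _ellipsoid(radii_um, voxel_size) -> np.ndarray:
    r = np.maximum(np.asarray(radii_um, float) / np.asarray(voxel_size, float), 1e-6)
    e = np.ceil(r).astype(int)
    zz, yy, xx = np.indices(tuple(2 * e + 1)) - e[:, None, None, None]
    return (zz / r[0]) ** 2 + (yy / r[1]) ** 2 + (xx / r[2]) ** 2 <= 1.0 + 1e-9


def hei10_accumulation(
    total_mask: np.ndarray,
    prominent_foci: FocusSet,
    intensities: np.ndarray,
    voxel_size=None,
    integrate_um: tuple[float, float, float] | None = (0.25, 0.12, 0.12),
) -> float:
    """Percentage of total-mask HEI10 intensity residing in the prominent foci.

    A stringent threshold mask clips the PSF tails of each focus, so when
    ``integrate_um`` and ``voxel_size`` are given, each detected focus is
    integrated over a PSF-scale neighbourhood (its mask dilated by the given
    µm radii, intersected with the total mask); the denominator is always the
    intensity over the whole total mask.
    """
    pmask = prominent_foci.mask
    if pmask.any() and not np.all(total_mask[pmask]):
        raise ValueError(
            "prominent foci extend outside the total mask (threshold-order bug)"
        )
    denom = float(intensities[total_mask].sum())
    if denom <= 0:
        return 0.0
    if integrate_um is not None and voxel_size is not None and pmask.any():
        pmask = ndimage.binary_dilation(
            pmask, structure=_ellipsoid(integrate_um, voxel_size)
        ) & total_mask
    num = float(intensities[pmask].sum())
    return min(100.0 * num / denom, 100.0)


# ---------------------------------------------------------------------------
# Skeleton machinery
# ---------------------------------------------------------------------------

def _skeleton_graph(coords: np.ndarray, voxel_size):
    """Sparse 26-neighbour adjacency with physical edge lengths."""
    from scipy import sparse

    n = coords.shape[0]
    index = {tuple(c): i for i, c in enumerate(coords)}
    vz = np.asarray(voxel_size)
    rows, cols, data = [], [], []
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)  # each unordered pair once
    ]
    for i, c in enumerate(coords):
        for off in offsets:
            nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            j = index.get(nb)
            if j is not None:
                w = float(np.linalg.norm(np.asarray(off) * vz))
                rows.append(i)
                cols.append(j)
                data.append(w)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def _path_length_chords(path_um: np.ndarray, stride: int = 4) -> float:
    """Arc length of an ordered voxel path by chord sampling.

    Summing raw voxel steps overestimates smooth curves (digital staircase);
    chords spanning a few voxels average the jitter out while remaining short
    relative to biological curvature radii.
    """
    n = path_um.shape[0]
    if n < 2:
        return 0.0
    idx = np.arange(0, n, stride)
    if idx[-1] != n - 1:
        idx = np.append(idx, n - 1)
    pts = path_um[idx]
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def skeleton_paths(mask: np.ndarray, voxel_size) -> list[np.ndarray]:
    """Skeletonise a 3D mask and decompose into ordered branch paths (µm).

    The skeleton's 26-neighbour graph is reduced to a spanning tree (which
    removes the spurious triangles digital diagonals create) and split into
    simple paths between junctions/endpoints.
    """
    import networkx as nx

    if not mask.any():
        return []
    skel = skeletonize(mask)
    coords = np.argwhere(skel)
    if coords.shape[0] == 0:
        return []
    adj = _skeleton_graph(coords, voxel_size)
    mst = minimum_spanning_tree(adj)
    g = nx.from_scipy_sparse_array(mst + mst.T)
    vz = np.asarray(voxel_size)
    paths: list[np.ndarray] = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_nodes() == 1:
            paths.append(coords[list(comp)] * vz)
            continue
        breakpoints = [v for v in sub if sub.degree(v) != 2]
        if not breakpoints:  # pure cycle can't occur in a tree; lone path loop
            breakpoints = [next(iter(comp))]
        visited_edges = set()
        for b in breakpoints:
            for nb in sub.neighbors(b):
                if (b, nb) in visited_edges:
                    continue
                path = [b, nb]
                visited_edges.add((b, nb))
                visited_edges.add((nb, b))
                prev, cur = b, nb
                while sub.degree(cur) == 2:
                    nxt = next(v for v in sub.neighbors(cur) if v != prev)
                    visited_edges.add((cur, nxt))
                    visited_edges.add((nxt, cur))
                    path.append(nxt)
                    prev, cur = cur, nxt
                paths.append(coords[path] * vz)
    return paths


def skeleton_length(mask: np.ndarray, voxel_size) -> float:
    """3D length (µm) of a binary mask's skeleton, honouring anisotropy."""
    return float(sum(_path_length_chords(p) for p in skeleton_paths(mask, voxel_size)))


# ---------------------------------------------------------------------------
# ZYP1 / geometry / linear-HEI10 operators
# ---------------------------------------------------------------------------

def classify_zyp1(
    zyp1_norm: np.ndarray,
    voxel_size,
    elong_cutoff_um: float = 0.4,
    min_voxels: int = 2,
) -> tuple[int, int, float]:
    """Count punctate vs elongated ZYP1 segments and their total length.

    Punctate signals (synapsis initiation sites) are components whose
    skeleton length falls below ``elong_cutoff_um``; longer components are
    elongated stretches of polymerising synaptonemal complex.
    """
    if elong_cutoff_um <= 0:
        raise ValueError("elong_cutoff_um must be > 0")
    if np.all(zyp1_norm <= 0):
        return 0, 0, 0.0
    thr = float(threshold_triangle(zyp1_norm))
    mask = zyp1_norm > thr
    labels, n = ndimage.label(mask, structure=_CONN26)
    n_punct = n_elong = 0
    total = 0.0
    objects = ndimage.find_objects(labels)
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        comp = labels[sl] == i
        if comp.sum() < min_voxels:
            continue
        length = skeleton_length(comp, voxel_size)
        total += length
        if length < elong_cutoff_um:
            n_punct += 1
        else:
            n_elong += 1
    return n_punct, n_elong, total


def detect_parallel_axes(
    asy1_mask: np.ndarray,
    voxel_size,
    sep_range_um: tuple[float, float] = (0.1, 0.8),
    min_len_um: float = 0.5,
    sep_sd_max_um: float = 0.2,
) -> tuple[int, int]:
    """Count coaligned ("parallel") vs lone ("irregular") asynaptic regions.

    A parallel structure is a pair of distinct skeleton branch paths, each at
    least ``min_len_um`` long, whose mutual nearest-point separation stays
    within ``sep_range_um`` over at least ``min_len_um`` of arc length with
    low separation variance. Overlapping pairs are merged into a single
    structure; remaining qualifying paths are counted irregular. This is an
    automated surrogate for by-eye scoring, calibrated on phantoms.
    """
    paths = [p for p in skeleton_paths(asy1_mask, voxel_size)
             if _path_length_chords(p) >= min_len_um]
    n = len(paths)
    if n == 0:
        return 0, 0
    trees = [cKDTree(p) for p in paths]
    pair_edges = []
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = trees[j].query(paths[i])
            within = (d >= sep_range_um[0]) & (d <= sep_range_um[1])
            if within.sum() < 2:
                continue
            steps = np.linalg.norm(np.diff(paths[i], axis=0), axis=1)
            arc = float(np.sum(steps[within[:-1] & within[1:]]))
            if arc < min_len_um:
                continue
            if float(np.std(d[within])) > sep_sd_max_um:
                continue
            pair_edges.append((i, j))
    # union-find: overlapping pairs merge into one structure
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in pair_edges:
        parent[find(i)] = find(j)
    in_pair = {i for e in pair_edges for i in e}
    structures = {find(i) for i in in_pair}
    n_parallel = len(structures)
    n_irregular = n - len(in_pair)
    return n_parallel, n_irregular


def flag_linear_hei10(
    prominent_foci: FocusSet,
    asy1_mask: np.ndarray,
    voxel_size,
    min_len_um: float = 1.5,
    dist_um: float = 0.2,
    overlap_frac: float = 0.5,
) -> bool:
    """True when any prominent HEI10 component is a line lying on ASY1.

    Linear HEI10 signal on unsynapsed axes is a rare aberrant pattern; cells
    showing it are excluded from accumulation analyses because such signal
    would skew the level.
    """
    if len(prominent_foci) == 0 or prominent_foci.labels is None:
        return False
    if asy1_mask.any():
        dt = ndimage.distance_transform_edt(~asy1_mask, sampling=voxel_size)
    else:
        dt = None
    vz = np.asarray(voxel_size)
    labels = prominent_foci.labels
    for i, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        comp = labels[sl] == i
        # quick reject: bounding-box diagonal below the length bar
        diag = float(np.linalg.norm(np.asarray(comp.shape) * vz))
        if diag < min_len_um:
            continue
        if skeleton_length(comp, voxel_size) <= min_len_um:
            continue
        if dt is None:
            continue
        close = dt[sl][comp] <= dist_um
        if close.mean() >= overlap_frac:
            return True
    return False


def quantify_cell(stack: Stack3C, config: QuantifyConfig | None = None) -> CellMeasurements:
    """Run all operators on one stack and assemble a measurement record.

    QC fails when the HEI10 total mask is empty or when both the ASY1 and
    ZYP1 channels carry no signal.
    """
    cfg = config or QuantifyConfig()
    ctx = f"cell {stack.cell_id or '<unnamed>'}"

    def norm_or_none(ch):
        try:
            return normalize_channel(ch, cfg.norm_quantile)
        except ValueError:
            return None

    try:
        hei10_n = norm_or_none(stack.hei10)
        asy1_n = norm_or_none(stack.asy1)
        zyp1_n = norm_or_none(stack.zyp1)

        qc_reason = ""
        acc = 0.0
        n_prom = 0
        total_int = prom_int = 0.0
        has_linear = False
        prom_set = None
        if hei10_n is None:
            qc_reason = "no HEI10 signal"
        else:
            total_mask, prom_mask, t_tot, t_prom = dual_threshold_hei10(
                hei10_n, voxel_size=stack.voxel_size
            )
            if not total_mask.any():
                qc_reason = "no HEI10 signal"
            else:
                prom_set = particle_analysis(
                    prom_mask, stack.hei10, min_voxels=cfg.min_voxels,
                    voxel_size=stack.voxel_size, threshold=t_prom,
                )
                acc = hei10_accumulation(
                    total_mask, prom_set, stack.hei10,
                    voxel_size=stack.voxel_size, integrate_um=cfg.focus_integrate_um,
                )
                n_prom = len(prom_set)
                total_int = float(stack.hei10[total_mask].sum())
                prom_int = total_int * acc / 100.0

        asy1_len = 0.0
        n_par = n_irr = 0
        asy1_mask = np.zeros(stack.shape, dtype=bool)
        if asy1_n is not None:
            thr_fn = {"otsu": threshold_otsu, "triangle": threshold_triangle}[cfg.axis_threshold]
            asy1_mask = asy1_n > float(thr_fn(asy1_n))
            asy1_len = skeleton_length(asy1_mask, stack.voxel_size)
            if cfg.detect_geometry:
                n_par, n_irr = detect_parallel_axes(
                    asy1_mask, stack.voxel_size,
                    sep_range_um=cfg.parallel_sep_range_um,
                    min_len_um=cfg.parallel_min_len_um,
                )

        n_punct = n_elong = 0
        zyp1_len = 0.0
        if zyp1_n is not None:
            n_punct, n_elong, zyp1_len = classify_zyp1(
                zyp1_n, stack.voxel_size, elong_cutoff_um=cfg.zyp1_elong_cutoff_um
            )

        if prom_set is not None:
            has_linear = flag_linear_hei10(
                prom_set, asy1_mask, stack.voxel_size,
                min_len_um=cfg.linear_hei10_min_len_um,
                dist_um=cfg.linear_hei10_dist_um,
            )

        if not qc_reason and asy1_n is None and zyp1_n is None:
            qc_reason = "ASY1 and ZYP1 both empty"

        return CellMeasurements(
            accumulation_pct=float(np.clip(acc, 0.0, 100.0)),
            n_prominent=n_prom,
            total_hei10_intensity=total_int,
            prominent_hei10_intensity=min(prom_int, total_int),
            asy1_length_um=asy1_len,
            zyp1_length_um=zyp1_len,
            n_punctate=n_punct,
            n_elongated=n_elong,
            n_parallel=n_par,
            n_irregular=n_irr,
            has_linear_hei10=has_linear,
            qc_pass=qc_reason == "",
            qc_reason=qc_reason,
            cell_id=stack.cell_id,
            plant_id=stack.plant_id,
            genotype=stack.genotype,
        )
    except ValueError as err:
        raise ValueError(f"{ctx}: {err}") from err
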