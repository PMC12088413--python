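"""Image operators: thresholds, particles, skeleton lengths, geometry, QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meioquant import quantify, synthgen
from meioquant.quantify import QuantifyConfig


def test_normalize_affine_map():
    ch = np.array([[[0.0, 50.0, 100.0]]])
    out = quantify.normalize_channel(ch, quantile=1.0)
    np.testing.assert_allclose(out, [[[0.0, 0.5, 1.0]]])


@given(offset=st.floats(-1e3, 1e3), scale=st.floats(0.01, 1e3))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_normalize_shift_and_scale_invariance(offset, scale):
    rng = np.random.default_rng(0)
    ch = rng.uniform(0, 10, size=(4, 8, 8))
    base = quantify.normalize_channel(ch, quantile=1.0)
    np.testing.assert_allclose(
        quantify.normalize_channel(ch * scale + offset, quantile=1.0), base,
        atol=1e-9,
    )


def test_normalize_constant_channel_raises():
    with pytest.raises(ValueError, match="dynamic range"):
        quantify.normalize_channel(np.full((3, 3, 3), 2.0))


def test_dual_threshold_bimodal_matches_brute_force():
    """On a clean bimodal histogram the stringent threshold must isolate the
    bright mode, agreeing with an exhaustive between-class-variance sweep."""
    rng = np.random.default_rng(1)
    ch = rng.normal(0.05, 0.01, size=(8, 32, 32))
    ch[2:5, 4:8, 4:8] = rng.normal(0.8, 0.02, size=(3, 4, 4))
    ch = np.clip(ch, 0, 1)
    total, prom, t_tot, t_prom = quantify.dual_threshold_hei10(ch)
    assert prom[2:5, 4:8, 4:8].mean() > 0.95  # bright mode captured
    assert not prom[ch < 0.3].any()
    assert np.all(total[prom])  # subset relation

    # brute-force Otsu: sweep thresholds, maximise between-class variance
    vals = np.sort(ch.ravel())
    best_t, best_v = None, -1.0
    for t in np.linspace(vals[1], vals[-2], 200):
        lo, hi = vals[vals <= t], vals[vals > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w = lo.size / vals.size
        v = w * (1 - w) * (hi.mean() - lo.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    # both thresholds classify the two modes identically
    np.testing.assert_array_equal(ch > best_t, prom)


def test_dual_threshold_empty_channel():
    total, prom, *_ = quantify.dual_threshold_hei10(np.zeros((4, 4, 4)))
    assert not total.any() and not prom.any()


def test_particle_analysis_counts_and_sums():
    mask = np.zeros((10, 10, 10), bool)
    inten = np.zeros((10, 10, 10))
    mask[1:4, 1:4, 1:4] = True
    inten[1:4, 1:4, 1:4] = 2.0
    mask[6:9, 6:9, 6:9] = True
    inten[6:9, 6:9, 6:9] = 1.0
    fs = quantify.particle_analysis(mask, inten, min_voxels=4)
    assert len(fs) == 2
    assert sorted(fs.foci["integrated_intensity"]) == [27.0, 54.0]
    assert sorted(fs.foci["voxel_count"]) == [27, 27]


def test_particle_min_voxels_filter():
    mask = np.zeros((5, 5, 5), bool)
    mask[0, 0, :2] = True  # 2-voxel blob
    fs = quantify.particle_analysis(mask, np.ones((5, 5, 5)), min_voxels=4)
    assert len(fs) == 0 and not fs.mask.any()


def test_accumulation_limits():
    mask = np.zeros((4, 4, 4), bool)
    mask[1:3, 1:3, 1:3] = True
    inten = np.where(mask, 5.0, 0.0)
    foci = quantify.particle_analysis(mask, inten, min_voxels=1)
    assert quantify.hei10_accumulation(mask, foci, inten, integrate_um=None) == 100.0
    empty = quantify.particle_analysis(np.zeros_like(mask), inten, min_voxels=1)
    assert quantify.hei10_accumulation(mask, empty, inten, integrate_um=None) == 0.0


def test_accumulation_subset_violation_raises():
    total = np.zeros((4, 4, 4), bool)
    pmask = np.zeros((4, 4, 4), bool)
    pmask[0, 0, 0] = True
    foci = quantify.particle_analysis(pmask, np.ones((4, 4, 4)), min_voxels=1)
    with pytest.raises(ValueError, match="threshold-order"):
        quantify.hei10_accumulation(total, foci, np.ones((4, 4, 4)))


def test_accumulation_monotone_in_threshold():
    """Raising the stringent threshold never increases the accumulation."""
    rng = np.random.default_rng(3)
    ch = rng.uniform(0, 1, size=(6, 24, 24))
    total = ch > 0.1
    prev = 101.0
    for t in (0.3, 0.5, 0.7, 0.9):
        foci = quantify.particle_analysis(ch > t, ch, min_voxels=1)
        acc = quantify.hei10_accumulation(total, foci, ch, integrate_um=None)
        assert acc <= prev + 1e-12
        prev = acc


@pytest.mark.parametrize("axis", ["x", "y", "z"])
def test_skeleton_length_lines(axis, clean_spec):
    stack, truth = synthgen.make_phantom("line", clean_spec, length_um=4.0, axis=axis)
    mask = stack.asy1 > 0.5 * stack.asy1.max()
    L = quantify.skeleton_length(mask, stack.voxel_size)
    assert L == pytest.approx(truth["length_um"], rel=0.10)


def test_skeleton_length_diagonal():
    vox = (0.125, 0.04, 0.04)
    mask = np.zeros((8, 64, 64), bool)
    for i in range(50):  # xy diagonal line, one voxel per step
        mask[4, 5 + i, 5 + i] = True
    L = quantify.skeleton_length(mask, vox)
    expect = 49 * np.hypot(0.04, 0.04)
    assert L == pytest.approx(expect, rel=0.10)


def test_skeleton_length_empty_is_zero():
    assert quantify.skeleton_length(np.zeros((4, 4, 4), bool), (1, 1, 1)) == 0.0


def test_classify_zyp1_puncta_and_stretch(clean_spec):
    vox = clean_spec.voxel_size
    ch = np.zeros(clean_spec.shape)
    # three point-like blobs
    for k, (y, x) in enumerate([(30, 30), (60, 60), (90, 90)]):
        ch[10:12, y:y + 3, x:x + 3] = 1.0
    # one 5 µm stretch along x: 126 voxels at 0.04 µm
    ch[30, 150, 20:146] = 1.0
    n_p, n_e, total = quantify.classify_zyp1(ch, vox, elong_cutoff_um=0.4)
    assert (n_p, n_e) == (3, 1)
    assert total == pytest.approx(5.0, abs=0.6)


def test_classify_zyp1_empty():
    assert quantify.classify_zyp1(np.zeros((4, 8, 8)), (0.125, 0.04, 0.04)) == (0, 0, 0.0)


def test_parallel_pair_detected(clean_spec):
    stack, truth = synthgen.make_phantom("parallel_pair", clean_spec,
                                         length_um=5.0, separation_um=0.3)
    mask = stack.asy1 > 0.5 * stack.asy1.max()
    assert quantify.detect_parallel_axes(mask, stack.voxel_size) == (1, 0)


def test_distant_pair_is_irregular(clean_spec):
    stack, _ = synthgen.make_phantom("parallel_pair", clean_spec,
                                     length_um=5.0, separation_um=3.0)
    mask = stack.asy1 > 0.5 * stack.asy1.max()
    n_par, n_irr = quantify.detect_parallel_axes(mask, stack.voxel_size)
    assert n_par == 0 and n_irr == 2


def test_bubble_phantom_geometry(clean_spec):
    stack, truth = synthgen.make_phantom("bubble", clean_spec, length_um=3.0,
                                         separation_um=0.4)
    mask = stack.asy1 > 0.5 * stack.asy1.max()
    assert quantify.detect_parallel_axes(mask, stack.voxel_size)[0] == 1
    zmask = stack.zyp1 > 0.5 * stack.zyp1.max()
    zlen = quantify.skeleton_length(zmask, stack.voxel_size)
    assert zlen == pytest.approx(truth["zyp1_length_um"], rel=0.15)


def _line_mask(shape, vox, z, y, x0, x1):
    m = np.zeros(shape, bool)
    m[z, y, x0:x1] = True
    return m


def test_linear_hei10_flag():
    vox = (0.125, 0.04, 0.04)
    shape = (16, 128, 128)
    asy1 = _line_mask(shape, vox, 8, 60, 10, 110)  # 4 µm ASY1 line
    # compact focus on ASY1: not linear
    focus = np.zeros(shape, bool)
    focus[8, 59:62, 50:53] = True
    fs = quantify.particle_analysis(focus, np.ones(shape), min_voxels=1)
    assert not quantify.flag_linear_hei10(fs, asy1, vox)
    # 3 µm HEI10 line co-drawn on ASY1: linear
    line = _line_mask(shape, vox, 8, 60, 20, 96)
    fs = quantify.particle_analysis(line, np.ones(shape), min_voxels=1)
    assert quantify.flag_linear_hei10(fs, asy1, vox)
    # same line far from ASY1: not flagged
    far = _line_mask(shape, vox, 2, 10, 20, 96)
    fs = quantify.particle_analysis(far, np.ones(shape), min_voxels=1)
    assert not quantify.flag_linear_hei10(fs, asy1, vox)


# ---------------------------------------------------------------------------
# Whole-cell quantification
# ---------------------------------------------------------------------------

def test_blank_stack_fails_qc():
    from meioquant.stack import Stack3C

    z = np.zeros((8, 16, 16))
    st = Stack3C(hei10=z, asy1=z, zyp1=z, voxel_size=(0.125, 0.04, 0.04))
    m = quantify.quantify_cell(st)
    assert not m.qc_pass and m.accumulation_pct == 0.0


def test_rendered_cell_recovers_truth(rendered_cell):
    truth, stack, _, _ = rendered_cell
    m = quantify.quantify_cell(stack, QuantifyConfig(detect_geometry=True))
    assert m.qc_pass
    assert m.accumulation_pct == pytest.approx(truth.H_true, abs=2.0)
    assert m.n_prominent == truth.n_prominent_true
    assert m.asy1_length_um == pytest.approx(truth.asynapsis_true, rel=0.25)
    assert m.zyp1_length_um == pytest.approx(truth.zyp1_total_true, rel=0.20)
    assert not m.has_linear_hei10


def test_intensity_scale_invariance(rendered_cell):
    truth, stack, _, _ = rendered_cell
    from meioquant.stack import Stack3C

    scaled = Stack3C(hei10=stack.hei10 * 3.0, asy1=stack.asy1 * 3.0,
                     zyp1=stack.zyp1 * 3.0, voxel_size=stack.voxel_size)
    cfg = QuantifyConfig(detect_geometry=False)
    a = quantify.quantify_cell(stack, cfg)
    b = quantify.quantify_cell(scaled, cfg)
    assert b.accumulation_pct == pytest.approx(a.accumulation_pct, abs=1e-6)
    assert b.asy1_length_um == a.asy1_length_um
    assert b.zyp1_length_um == a.zyp1_length_um
    assert (b.n_prominent, b.n_punctate, b.n_elongated) == \
        (a.n_prominent, a.n_punctate, a.n_elongated)


def test_fully_synapsed_cell_has_no_asy1(clean_spec):
    truth = synthgen.CellTruth(plant_id="p", genotype="T", H_true=80.0,
                               asynapsis_true=0.0, zyp1_total_true=80.0,
                               n_prominent_true=10, dispersed_fraction_true=0.2)
    stack, _, _ = synthgen.render_cell(truth, clean_spec)
    m = quantify.quantify_cell(stack, QuantifyConfig(detect_geometry=False))
    assert m.asy1_length_um < 0.5


def test_parallel_count_on_rendered_cells():
    """Automated coalignment scoring recovers the true pair count to +-1 on
    average over seeds."""
    counts = []
    for i in range(8):
        truth = synthgen.CellTruth(plant_id="p", genotype="T", H_true=40.0,
                                   asynapsis_true=18.0, zyp1_total_true=40.0,
                                   n_prominent_true=8, dispersed_fraction_true=0.6,
                                   n_parallel_true=4, n_irregular_true=0)
        spec = synthgen.RenderSpec(shape=(48, 192, 192), background=0.0,
                                   shot_noise=False, read_noise_sd=0.0, seed=40 + i)
        stack, _, _ = synthgen.render_cell(truth, spec)
        m = quantify.quantify_cell(stack)
        counts.append(m.n_parallel)
    assert 3.0 <= np.mean(counts) <= 5.0
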