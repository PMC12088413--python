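"""Ground-truth generators: statistical structure, rendering conservation,
and analytic phantoms."""

import math

import numpy as np
import pandas as pd
import pytest

from meioquant import synthgen


def test_table_is_deterministic(genotypes):
    a = synthgen.simulate_cell_table(genotypes, 2, 10, seed=5)
    b = synthgen.simulate_cell_table(genotypes, 2, 10, seed=5)
    pd.testing.assert_frame_equal(a, b)
    c = synthgen.simulate_cell_table(genotypes, 2, 10, seed=6)
    assert not a["asynapsis_true"].equals(c["asynapsis_true"])


def test_truth_invariants_hold(genotypes):
    tab = synthgen.simulate_cell_table(genotypes, 3, 30, seed=9)
    assert tab["H_true"].between(0, 100).all()
    assert (tab["asynapsis_true"] >= 0).all()
    budgets = {g.name: g.total_axis_um for g in genotypes}
    assert (tab["asynapsis_true"] <= tab["genotype"].map(budgets) + 1e-9).all()
    count_cols = [c for c in tab.columns if c.startswith("n_")]
    assert (tab[count_cols] >= 0).all().all()


def test_flat_generator_has_no_trend():
    g = synthgen.GenotypeParams(name="F", beta0=math.log(50), beta1=0.0,
                                plant_sd=0.0, gamma_shape=8.0, total_axis_um=400.0)
    tab = synthgen.simulate_cell_table([g], 1, 4000, h_range=(0, 100), seed=3)
    lo = tab[tab["H_true"] < 30]["asynapsis_true"].mean()
    hi = tab[tab["H_true"] > 70]["asynapsis_true"].mean()
    assert abs(lo - hi) / 50.0 < 0.05  # no decay: means agree across the H range


def test_mean_function_matches_closed_form():
    """NEO-like flat vs 2X-like decaying mean functions at H = 49.

    The decaying genotype's mean drops to 50*e^0.36*e^(-0.03*49) ~ 16.5 um
    while the flat genotype stays at ~200 um; Monte-Carlo means at a huge
    Gamma shape reproduce the closed form within 1%.
    """
    neo = synthgen.GenotypeParams(name="NEO", beta0=math.log(200.0), beta1=0.0,
                                  plant_sd=0.0, gamma_shape=1e6, total_axis_um=2000.0)
    dip = synthgen.GenotypeParams(name="DIP", beta0=math.log(50.0) + 0.36,
                                  beta1=-0.03, plant_sd=0.0, gamma_shape=1e6,
                                  total_axis_um=2000.0)
    tab = synthgen.simulate_cell_table([neo, dip], 1, 10_000,
                                       h_range=(49.0, 49.0), seed=11)
    m_neo = tab[tab["genotype"] == "NEO"]["asynapsis_true"].mean()
    m_dip = tab[tab["genotype"] == "DIP"]["asynapsis_true"].mean()
    expect_dip = 50.0 * math.exp(0.36) * math.exp(-0.03 * 49.0)
    assert m_neo == pytest.approx(200.0, rel=0.01)
    assert m_dip == pytest.approx(expect_dip, rel=0.01)
    assert m_dip < 20.0 < 100.0 < m_neo  # decayed well below the flat genotype


def test_nonfinite_parameters_rejected():
    with pytest.raises(ValueError, match="beta0"):
        synthgen.GenotypeParams(name="bad", beta0=float("nan"), beta1=0.0)


def test_count_moments_match_generator():
    g = synthgen.GenotypeParams(name="Q", beta0=math.log(50), beta1=0.0,
                                plant_sd=0.0, quad_mean=3.0, uni_mean=0.9,
                                nb_theta=5.0, total_axis_um=400.0)
    tab = synthgen.simulate_cell_table([g], 1, 10_000, seed=21)
    assert tab["n_quadrivalent_true"].mean() == pytest.approx(3.0, abs=0.1)
    assert tab["n_univalent_true"].mean() == pytest.approx(0.9, abs=0.06)
    # NB2 variance = mean + mean^2/theta
    assert tab["n_quadrivalent_true"].var() == pytest.approx(3.0 + 9.0 / 5.0, rel=0.1)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def test_render_is_deterministic(rendered_cell, clean_spec):
    truth, stack, _, _ = rendered_cell
    spec = synthgen.RenderSpec(shape=(48, 192, 192), background=0.0,
                               shot_noise=False, read_noise_sd=0.0, seed=42)
    stack2, _, _ = synthgen.render_cell(truth, spec)
    np.testing.assert_array_equal(stack.hei10, stack2.hei10)
    np.testing.assert_array_equal(stack.asy1, stack2.asy1)


def test_render_conserves_path_lengths(rendered_cell):
    truth, _, _, pre = rendered_cell
    assert pre["asy1_path_length"] == pytest.approx(truth.asynapsis_true, rel=0.02)
    assert pre["zyp1_path_length"] == pytest.approx(truth.zyp1_total_true, rel=0.02)


def test_preblur_accumulation_matches_truth(rendered_cell):
    truth, _, masks, pre = rendered_cell
    h = pre["hei10"]
    acc = 100.0 * h[masks["prominent"]].sum() / h.sum()
    assert acc == pytest.approx(truth.H_true, abs=1.0)


def test_all_signal_in_foci_when_no_dispersed(clean_spec):
    truth = synthgen.CellTruth(plant_id="p", genotype="T", H_true=100.0,
                               asynapsis_true=20.0, zyp1_total_true=60.0,
                               n_prominent_true=8, dispersed_fraction_true=0.0)
    stack, masks, pre = synthgen.render_cell(truth, clean_spec)
    h = pre["hei10"]
    assert h[masks["prominent"]].sum() == pytest.approx(h.sum())


def test_no_prominent_foci_gives_empty_mask(clean_spec):
    truth = synthgen.CellTruth(plant_id="p", genotype="T", H_true=0.0,
                               asynapsis_true=20.0, zyp1_total_true=60.0,
                               n_prominent_true=0, dispersed_fraction_true=1.0)
    _, masks, pre = synthgen.render_cell(truth, clean_spec)
    assert not masks["prominent"].any()
    assert pre["prominent_sum"] == 0.0


def test_infeasible_axis_budget_raises(clean_spec):
    truth = synthgen.CellTruth(plant_id="p", genotype="T", H_true=50.0,
                               asynapsis_true=5000.0, zyp1_total_true=5000.0,
                               n_prominent_true=5, dispersed_fraction_true=0.5)
    with pytest.raises(ValueError, match="axis budget"):
        synthgen.render_cell(truth, clean_spec)


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

def test_line_phantom_truth(clean_spec):
    _, truth = synthgen.make_phantom("line", clean_spec, length_um=4.0, axis="x")
    assert truth["length_um"] == 4.0


def test_helix_phantom_arc_length(clean_spec):
    _, truth = synthgen.make_phantom("helix", clean_spec, radius_um=1.0,
                                     pitch_um=1.0, n_turns=3)
    expect = 3.0 * math.sqrt((2 * math.pi) ** 2 + 1.0)
    assert truth["length_um"] == pytest.approx(expect, rel=1e-6)
    assert truth["length_um"] == pytest.approx(19.1, abs=0.05)


def test_parallel_pair_phantom_truth(clean_spec):
    _, truth = synthgen.make_phantom("parallel_pair", clean_spec,
                                     length_um=5.0, separation_um=0.3)
    assert truth["n_parallel"] == 1
    assert truth["length_um"] == 5.0


def test_out_of_volume_phantom_raises(clean_spec):
    with pytest.raises(ValueError):
        synthgen.make_phantom("line", clean_spec, length_um=100.0, axis="x")
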