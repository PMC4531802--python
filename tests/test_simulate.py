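"""Synthetic-imaging generator: determinism, conservation laws, event
frequencies, and on-disk experiment layout."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import hibafish as hf
from hibafish import simulate as sim
from hibafish.config import CellModel, ConfigurationError, NoiseSpec
from hibafish.io import parse_metadata


def test_zero_break_probability_means_no_events(imaging):
    _, gt = sim.simulate_field(hf.negative_cell_model(), 10, imaging,
                               NoiseSpec.none(), seed=3)
    assert (gt.alleles["state"] == "intact").all()
    assert (gt.cells["n_broken"] == 0).all()
    # intact Red probes stay proximal to their Green partner
    assert (gt.alleles["rg_sep_px"] <= 4.0).all()


def test_same_seed_bitwise_identical(imaging):
    a_stacks, a_gt = sim.simulate_field(hf.positive_cell_model(), 8, imaging, seed=11)
    b_stacks, b_gt = sim.simulate_field(hf.positive_cell_model(), 8, imaging, seed=11)
    for ch in imaging.channels:
        assert np.array_equal(a_stacks[ch], b_stacks[ch])
    pd.testing.assert_frame_equal(a_gt.spots, b_gt.spots)
    pd.testing.assert_frame_equal(a_gt.alleles, b_gt.alleles)
    c_stacks, _ = sim.simulate_field(hf.positive_cell_model(), 8, imaging, seed=12)
    assert not np.array_equal(a_stacks["Red"], c_stacks["Red"])


def test_break_fraction_matches_binomial_closed_form():
    """p_break=0.5 with two alleles: P(cell has >=1 break) = 1-(1-0.5)^2 = 0.75;
    the simulated fraction over 2000 cells must sit in the exact binomial
    99% interval around it."""
    model = CellModel(n_alleles_A=2, n_alleles_B=2, p_break=0.5)
    gt = sim.GroundTruth.concat(
        sim.simulate_ground_truth(model, 25, rng=sim.field_rng(5, f),
                                  field_id=f"f{f:03d}")
        for f in range(80))
    frac = (gt.cells["n_broken"] >= 1).mean()
    lo = sps.binom.ppf(0.005, 2000, 0.75) / 2000
    hi = sps.binom.ppf(0.995, 2000, 0.75) / 2000
    assert lo <= frac <= hi


def test_spot_count_conservation(imaging):
    """Red = Green = n_alleles_A and FarRed = n_alleles_B per cell; a
    translocation relocates a FarRed signal, never duplicates it."""
    model = hf.positive_cell_model()
    _, gt = sim.simulate_field(model, 15, imaging, NoiseSpec.none(), seed=9)
    counts = gt.spots.groupby(["cell_id", "channel"]).size().unstack(fill_value=0)
    assert (counts["Red"] == model.n_alleles_A).all()
    assert (counts["Green"] == model.n_alleles_A).all()
    assert (counts["FarRed"] == model.n_alleles_B).all()
    assert gt.cells["n_transloc"].sum() > 0  # the model does translocate


def test_translocated_subset_of_broken(imaging):
    model = CellModel(n_alleles_A=3, n_alleles_B=2, p_break=0.6,
                      p_transloc_given_break=0.7)
    rng = np.random.default_rng(17)
    gt = sim.simulate_ground_truth(model, 300, rng=rng,
                                   imaging=hf.ImagingConfig(field_shape_px=(1536, 1536)))
    assert set(gt.alleles["state"]) <= {"intact", "broken", "translocated"}
    assert (gt.cells["n_transloc"] <= gt.cells["n_broken"]).all()
    # partner bookkeeping: every translocated allele has a distinct partner
    tr = gt.alleles[gt.alleles["state"] == "translocated"]
    assert (tr["partner_b"] >= 0).all()
    assert not tr.duplicated(["field_id", "cell_id", "partner_b"]).any()
    # translocations are capped by the number of gene-B partners
    assert (gt.cells["n_transloc"] <= model.n_alleles_B).all()


def test_translocated_farred_lands_near_red(imaging):
    model = CellModel(n_alleles_A=2, n_alleles_B=2, p_break=1.0,
                      p_transloc_given_break=1.0)
    _, gt = sim.simulate_field(model, 10, imaging, NoiseSpec.none(), seed=21)
    tr = gt.alleles[gt.alleles["state"] == "translocated"]
    assert len(tr) > 0
    assert (tr["rfr_min_px"] <= 4.0).mean() > 0.9  # Rayleigh mean 1 px


def test_spots_inside_nucleus(imaging):
    _, gt = sim.simulate_field(hf.positive_cell_model(), 10, imaging, seed=2)
    cells = gt.cells.set_index("cell_id")
    for s in gt.spots.itertuples():
        c = cells.loc[s.cell_id]
        dx, dy = s.x_px - c.cx_px, s.y_px - c.cy_px
        u = (dx * np.cos(c.theta_rad) + dy * np.sin(c.theta_rad)) / c.a_px
        v = (-dx * np.sin(c.theta_rad) + dy * np.cos(c.theta_rad)) / c.b_px
        assert u * u + v * v <= 1.0 + 1e-9


def test_overdense_field_raises():
    with pytest.raises(sim.SimulationError):
        sim.simulate_ground_truth(
            hf.negative_cell_model(), 50,
            imaging=hf.ImagingConfig(field_shape_px=(128, 128)),
            rng=np.random.default_rng(0))


def test_invalid_noise_spec_rejected():
    with pytest.raises(ConfigurationError):
        sim.simulate_field(hf.negative_cell_model(), 1, noise="lots")
    with pytest.raises(ConfigurationError):
        NoiseSpec(background=-5)


def test_experiment_layout_and_overwrite_refusal(tmp_path, imaging):
    conds = [
        sim.Condition("UN", hf.negative_cell_model(), 6, cell_line="M2A"),
        sim.Condition("IR", CellModel.from_cell_rates(0.02, name="irr", n_alleles_B=2),
                      6, cell_line="M2A"),
    ]
    out = sim.simulate_experiment(conds, imaging, seed=4, out_dir=tmp_path / "d",
                                  cells_per_field=6)
    dirs = sorted(p.name for p in (tmp_path / "d").iterdir())
    assert dirs == ["SIM_000001_M2A_GFP_ALK_IR", "SIM_000001_M2A_GFP_ALK_UN"]
    meta = parse_metadata(dirs[0])
    assert meta.treatment == "IR" and meta.cell_line == "M2A"
    gt = sim.GroundTruth.read(out / dirs[1])
    assert (gt.cells["n_broken"] == 0).all()
    assert any((out / dirs[0]).glob("*.ome.tif"))
    with pytest.raises(FileExistsError):
        sim.simulate_experiment(conds, imaging, seed=4, out_dir=tmp_path / "d",
                                cells_per_field=6)
    # explicit overwrite succeeds
    sim.simulate_experiment(conds[:1], imaging, seed=4, out_dir=tmp_path / "d",
                            cells_per_field=6, overwrite=True)


def test_empty_condition_list_is_fine(tmp_path):
    out = sim.simulate_experiment([], out_dir=tmp_path / "empty")
    assert out.exists() and not any(out.iterdir())


def test_duplicate_labels_rejected(tmp_path):
    c = sim.Condition("UN", hf.negative_cell_model(), 1)
    with pytest.raises(ConfigurationError):
        sim.simulate_experiment([c, c], out_dir=tmp_path / "x")


def test_titration_ground_truth_fractions():
    """Mixture conditions realize the requested positive-cell fraction up
    to binomial sampling error (here: exact 99% interval)."""
    fractions = [0.0, 0.01, 0.1, 1.0]
    pos, neg = hf.positive_cell_model(), hf.negative_cell_model()
    n = 400
    for i, f in enumerate(fractions):
        model = (pos if f == 1.0 else neg if f == 0.0
                 else [(pos, f), (neg, 1 - f)])
        gt = sim.simulate_ground_truth(
            model, n, rng=np.random.default_rng(100 + i),
            imaging=hf.ImagingConfig(field_shape_px=(1280, 1280)))
        got = (gt.cells["model"] == "positive").mean()
        lo = sps.binom.ppf(0.005, n, f) / n if f > 0 else 0.0
        hi = sps.binom.ppf(0.995, n, f) / n if f < 1 else 1.0
        assert lo <= got <= hi


def test_from_cell_rates_inverts_to_per_allele():
    m = CellModel.from_cell_rates(0.02, 0.004, n_alleles_A=3)
    assert 1 - (1 - m.p_break) ** 3 == pytest.approx(0.02)
    assert m.p_transloc_given_break == pytest.approx(0.2)


def test_ground_truth_tables_roundtrip(tmp_path, imaging):
    _, gt = sim.simulate_field(hf.positive_cell_model(), 5, imaging, seed=1)
    gt.write(tmp_path, provenance="test")
    back = sim.GroundTruth.read(tmp_path)
    assert len(back.spots) == len(gt.spots)
    assert back.alleles["state"].tolist() == gt.alleles["state"].tolist()
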