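"""Generator: layouts, rendering, ground truth, determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ncscreen import (
    KnockdownEffect,
    SimConfig,
    WellSpec,
    condition_f_cyt,
    expected_ratio,
    generate_plate_layout,
    render_field,
    simulate_screen,
)


class TestPlateLayout:
    def test_full_kinome_layout_counts(self):
        layout = generate_plate_layout(691, n_plates=2, n_replicates=3)
        lib = layout.table[layout.table["role"] == "library"]
        assert len(lib) == 3 * 691
        for (_, _), plate in layout.table.groupby(["replicate_id", "plate_id"]):
            controls = plate[plate["role"].isin(["neg_ctrl", "gfp_ctrl", "death_ctrl"])]
            assert len(controls) >= 4
            # vehicle-treated (DMEM analog) control wells on every plate
            assert (controls["treatment"] == "vehicle").sum() >= 1
        # every gene exactly once per replicate
        per_rep = lib.groupby(["replicate_id", "gene_id"]).size()
        assert (per_rep == 1).all()

    def test_empty_library_gives_controls_only(self):
        layout = generate_plate_layout(0, 1, 1, wells_per_plate=16)
        roles = set(layout.table["role"])
        assert "library" not in roles
        assert {"neg_ctrl", "gfp_ctrl", "death_ctrl"} <= roles

    def test_partial_plate_emits_empty_flagged_wells(self):
        # 28 wells, 12 controls -> 16 library positions for 10 genes
        layout = generate_plate_layout(10, 1, 1, wells_per_plate=28)
        counts = layout.table["role"].value_counts()
        assert counts["library"] == 10
        assert counts["empty"] == 6

    def test_capacity_exceeded_names_deficit(self):
        with pytest.raises(ValueError, match="capacity exceeded.*more wells"):
            generate_plate_layout(100, 1, 1, wells_per_plate=48)

    def test_deterministic_given_seed(self):
        a = generate_plate_layout(20, 1, 2, wells_per_plate=96, seed=5)
        b = generate_plate_layout(20, 1, 2, wells_per_plate=96, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)
        c = generate_plate_layout(20, 1, 2, wells_per_plate=96, seed=6)
        assert not a.table.equals(c.table)


class TestRatioModel:
    def test_knockdown_interpolates_between_stress_and_vehicle(self):
        cfg = SimConfig()
        assert condition_f_cyt(cfg, "vehicle") == cfg.f_cyt_baseline
        assert condition_f_cyt(cfg, "stress") == cfg.f_cyt_stress
        assert condition_f_cyt(cfg, "stress", effect=1.0) == pytest.approx(cfg.f_cyt_baseline)
        mid = condition_f_cyt(cfg, "stress", effect=0.5)
        assert cfg.f_cyt_baseline < mid < cfg.f_cyt_stress

    @given(
        f=st.floats(0.01, 0.98),
        delta=st.floats(1e-4, 0.01),
        t=st.floats(1e3, 1e6),
        b=st.floats(0.1, 500.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_expected_ratio_strictly_decreasing_in_f_cyt(self, f, delta, t, b):
        lo = expected_ratio(f, t, 300, 900, b)
        hi = expected_ratio(f + delta, t, 300, 900, b)
        assert lo > hi > 0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="f_cyt"):
            SimConfig(f_cyt_baseline=0.7, f_cyt_stress=0.3).validate()
        with pytest.raises(ValueError, match="64"):
            SimConfig(image_width=32).validate()
        with pytest.raises(ValueError, match="strictly positive"):
            SimConfig(nucleus_radius_mean=-1).validate()
        with pytest.raises(ValueError):
            KnockdownEffect("G", 1.5)


class TestRenderField:
    def test_zero_cells_gives_background_only(self, noiseless_config, stress_well):
        cfg = dataclasses.replace(noiseless_config, cells_per_field=0.0)
        nuc, prot, truth = render_field(cfg, stress_well)
        assert truth == []
        assert np.all(nuc == cfg.background_level)
        assert np.all(prot == cfg.background_level)

    def test_single_cell_region_means_match_truth_exactly(self, noiseless_config):
        cfg = dataclasses.replace(noiseless_config, cells_per_field=3.0, f_cyt_sd=0.0)
        well = WellSpec("P01", "R1", "B02", "", "neg_ctrl", "stress")
        rng = np.random.default_rng(4)
        nuc, prot, truth = render_field(cfg, well, rng=rng)
        assert len(truth) >= 1
        yy, xx = np.mgrid[: cfg.image_height, : cfg.image_width]
        for cell in truth:
            dy, dx = yy - cell.center_row, xx - cell.center_col
            nmask = dy**2 + dx**2 <= cell.nucleus_radius**2
            a = cell.nucleus_radius + cell.cyto_extra_row
            b = cell.nucleus_radius + cell.cyto_extra_col
            cmask = ((dy / a) ** 2 + (dx / b) ** 2 <= 1) & ~nmask
            assert nmask.sum() == cell.nuc_area
            assert cmask.sum() == cell.cyto_area
            nuc_mean = prot[nmask].mean()
            cyt_mean = prot[cmask].mean()
            assert nuc_mean / cyt_mean == pytest.approx(cell.expected_ratio, rel=1e-12)
            assert cell.f_cyt == cfg.f_cyt_stress

    def test_protein_conservation_in_noise_free_render(self, noiseless_config, stress_well):
        nuc, prot, truth = render_field(noiseless_config, stress_well)
        assert len(truth) > 1
        total = prot.sum() - prot.size * noiseless_config.background_level
        assert total == pytest.approx(sum(t.total_protein for t in truth), rel=1e-9)

    def test_nuclei_do_not_overlap(self, noiseless_config, stress_well):
        _, _, truth = render_field(noiseless_config, stress_well)
        for i, a in enumerate(truth):
            for b in truth[i + 1:]:
                d = np.hypot(a.center_row - b.center_row, a.center_col - b.center_col)
                assert d > a.nucleus_radius + b.nucleus_radius

    def test_render_is_deterministic(self, stress_well):
        cfg = SimConfig(image_width=128, image_height=128, cells_per_field=5, rng_seed=42)
        n1, p1, t1 = render_field(cfg, stress_well)
        n2, p2, t2 = render_field(cfg, stress_well)
        assert n1.tobytes() == n2.tobytes()
        assert p1.tobytes() == p2.tobytes()
        assert t1 == t2

    def test_knockdown_effect_shifts_truth_toward_vehicle(self, noiseless_config):
        well = WellSpec("P01", "R1", "C03", "HIT", "library", "stress")
        cfg = dataclasses.replace(noiseless_config, f_cyt_sd=0.0)
        _, _, blocked = render_field(cfg, well, effects=[KnockdownEffect("HIT", 1.0)])
        assert all(t.f_cyt == pytest.approx(cfg.f_cyt_baseline) for t in blocked)
        _, _, partial = render_field(cfg, well, effects=[KnockdownEffect("HIT", 0.5)])
        expected = condition_f_cyt(cfg, "stress", 0.5)
        assert all(t.f_cyt == pytest.approx(expected) for t in partial)

    def test_death_well_has_fewer_cells(self):
        cfg = SimConfig(image_width=256, image_height=256, cells_per_field=40, rng_seed=1)
        lib = WellSpec("P01", "R1", "A01", "G", "library", "stress")
        death = WellSpec("P01", "R1", "A02", "CTRL_DEATH", "death_ctrl", "stress")
        _, _, t_lib = render_field(cfg, lib)
        _, _, t_death = render_field(cfg, death)
        assert len(t_death) < len(t_lib) / 2

    def test_clipping_flagged_in_truth(self, stress_well):
        cfg = SimConfig(image_width=128, image_height=128, cells_per_field=2,
                        total_protein_mean=5e7, total_protein_sd=1e3,
                        noise_sd=0.0, shot_noise=False, rng_seed=2)
        _, prot, truth = render_field(cfg, stress_well)
        assert prot.dtype == np.uint16
        assert prot.max() == 65535
        assert len(truth) > 0
        for t in truth:
            nuc_density = (1 - t.f_cyt) * t.total_protein / t.nuc_area
            cyt_density = t.f_cyt * t.total_protein / t.cyto_area
            over = max(nuc_density, cyt_density) + cfg.background_level > 65535
            assert t.clipped == over


class TestSimulateScreen:
    def test_screen_tree_truth_and_manifest_are_stable(self, tmp_path):
        cfg = SimConfig(image_width=128, image_height=128, cells_per_field=4, rng_seed=9)
        layout = generate_plate_layout(4, 1, 2, wells_per_plate=20, seed=9)
        out1 = simulate_screen(cfg, layout, out_dir=tmp_path / "a")
        out2 = simulate_screen(cfg, layout, out_dir=tmp_path / "b")
        import json

        m1 = json.loads((out1 / "manifest.json").read_text())
        m2 = json.loads((out2 / "manifest.json").read_text())
        assert m1["content_hash"] == m2["content_hash"]
        assert m1["seed"] == 9
        truth1 = (out1 / "truth_cells.csv").read_bytes()
        assert truth1 == (out2 / "truth_cells.csv").read_bytes()
        # one image byte-identical across reruns
        rep, plate = "R1", "P01"
        tif = sorted((out1 / rep / plate).glob("*_nuc.tif"))[0]
        assert tif.read_bytes() == (out2 / rep / plate / tif.name).read_bytes()

    def test_treatment_arms_differ_by_design_shift(self, tmp_path):
        cfg = SimConfig(image_width=128, image_height=128, cells_per_field=6, rng_seed=4)
        layout = generate_plate_layout(0, 1, 1, wells_per_plate=16,
                                       controls_per_plate={"neg_ctrl": 12}, seed=4)
        out = simulate_screen(cfg, layout, out_dir=tmp_path / "s")
        truth = pd.read_csv(out / "truth_cells.csv")
        pm = pd.read_csv(out / "platemap.csv")
        merged = truth.merge(pm, on=["plate_id", "replicate_id", "well_id"])
        means = merged.groupby("treatment")["f_cyt"].mean()
        shift = cfg.f_cyt_stress - cfg.f_cyt_baseline
        assert means["stress"] - means["vehicle"] == pytest.approx(shift, abs=0.05)

    def test_planted_hit_must_be_in_layout(self, tmp_path):
        cfg = SimConfig(image_width=128, image_height=128, cells_per_field=2)
        layout = generate_plate_layout(2, 1, 1, wells_per_plate=16)
        with pytest.raises(ValueError, match="not a library gene"):
            simulate_screen(cfg, layout, planted_hits=[KnockdownEffect("NOPE", 1.0)],
                            out_dir=tmp_path / "x")
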