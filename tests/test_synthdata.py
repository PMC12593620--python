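"""Forward fluorophore model and the synthetic acquisition generator."""

import dataclasses

import numpy as np
import pytest

from redoxmap import calibration as cal
from redoxmap import synthdata, workflows
from redoxmap.synthdata import (
    PackingError,
    SimScenario,
    expected_ratio,
    make_fluorophore_model,
    simulate_calibration_endpoints,
    simulate_field,
    simulate_mosaic_labels,
    stamp_bleach_mark,
)


class TestFluorophoreModel:
    def test_coefficients_from_reference_triple(self, calib, model):
        assert model.a_ox == pytest.approx(0.45525, abs=1e-5)
        assert model.a_red == pytest.approx(0.408)
        assert model.b_ox == pytest.approx(0.497)
        assert model.b_red == pytest.approx(1.0)

    def test_identity_instrument_factor(self):
        m = make_fluorophore_model(
            cal.CalibrationParams(r_ox=2.0, r_red=1.0, instrument_factor=1.0)
        )
        assert (m.a_ox, m.a_red, m.b_ox, m.b_red) == (2.0, 1.0, 1.0, 1.0)

    def test_derived_ratios_roundtrip(self, calib, model):
        assert model.r_ox == pytest.approx(calib.r_ox)
        assert model.r_red == pytest.approx(calib.r_red)
        assert model.instrument_factor == pytest.approx(calib.instrument_factor)
        assert expected_ratio(model, 1.0) == pytest.approx(calib.r_ox)

    def test_rejects_inverted_response(self):
        with pytest.raises(ValueError):
            synthdata.FluorophoreModel(a_ox=0.4, a_red=0.9, b_ox=1.0, b_red=1.0)

    def test_expected_ratio_monotone(self, model):
        x = np.linspace(0, 1, 500)
        r = expected_ratio(model, x)
        assert np.all(np.diff(r) > 0)

    def test_expected_ratio_domain(self, model):
        with pytest.raises(ValueError):
            expected_ratio(model, 1.5)


class TestSimulateField:
    def test_empty_field(self, noise_free_scenario, model):
        field, cells = simulate_field(noise_free_scenario, model, n_cells=0, seed=0)
        assert cells == []
        assert float(field.channel("F740").max()) == 0.0

    def test_noise_free_roi_ratio_matches_forward_model(self, model):
        sc = SimScenario(
            photon_scale=np.inf,
            background=0.0,
            neuropil_level=0.0,
            read_noise_sd=0.0,
            cells_per_field=1,
        )
        field, cells = simulate_field(sc, model, seed=5)
        c = cells[0]
        # interior pixels carry the pure forward-model ratio
        f740, f910 = field.channel("F740"), field.channel("F910")
        yy, xx = np.ogrid[: field.shape[0], : field.shape[1]]
        core = (xx - c.x) ** 2 + (yy - c.y) ** 2 <= (c.radius * 0.5) ** 2
        measured = float((f740[core] / f910[core]).mean())
        assert measured == pytest.approx(expected_ratio(model, c.oxd_true), abs=1e-9)

    def test_noise_free_pipeline_recovers_truth(self, noise_free_scenario, model, calib):
        field, cells = simulate_field(noise_free_scenario, model, seed=3)
        meas = workflows.quantify_field(field, f910_floor=1e-9)
        assert len(meas) == len(cells)
        truth = {(round(c.x), round(c.y)): c.oxd_true for c in cells}
        for m in meas:
            c = min(cells, key=lambda c: (c.x - m.x) ** 2 + (c.y - m.y) ** 2)
            oxd = cal.oxd_from_ratio(m.ratio, calib)
            assert oxd == pytest.approx(c.oxd_true, abs=1e-6)

    def test_same_seed_bit_identical(self, noisy_scenario, model):
        f1, c1 = simulate_field(noisy_scenario, model, seed=11)
        f2, c2 = simulate_field(noisy_scenario, model, seed=11)
        for name in f1.channels:
            assert np.array_equal(f1.channels[name], f2.channels[name])
        assert c1 == c2

    def test_different_seed_differs(self, noisy_scenario, model):
        f1, _ = simulate_field(noisy_scenario, model, seed=11)
        f2, _ = simulate_field(noisy_scenario, model, seed=12)
        assert not np.array_equal(f1.channel("F910"), f2.channel("F910"))

    def test_somata_do_not_overlap(self, noisy_scenario, model):
        _, cells = simulate_field(noisy_scenario, model, seed=2, n_cells=20)
        for i, a in enumerate(cells):
            for b in cells[i + 1 :]:
                assert np.hypot(a.x - b.x, a.y - b.y) >= a.radius + b.radius

    def test_infeasible_packing_raises(self, model):
        sc = SimScenario(image_shape=(64, 64), soma_radius=6.0)
        with pytest.raises(PackingError):
            simulate_field(sc, model, n_cells=60, seed=0)

    def test_ground_truth_within_bounds(self, noisy_scenario, model):
        _, cells = simulate_field(noisy_scenario, model, seed=4, n_cells=20)
        h, w = noisy_scenario.image_shape
        for c in cells:
            assert 0.02 <= c.oxd_true <= 0.98
            assert c.radius <= c.x <= w - c.radius
            assert c.radius <= c.y <= h - c.radius


class TestMosaicLabels:
    def _cells(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return [
            synthdata.GroundTruthCell(
                cell_id=f"c{i}",
                x=float(rng.uniform(0, 500)),
                y=float(rng.uniform(0, 500)),
                radius=6.0,
                oxd_true=0.5,
                expression=1.0,
                slice_id="s0",
                region="CA1",
                genotype="Mecp2+/-",
                age_group="p50",
            )
            for i in range(n)
        ]

    def test_single_clone_shares_status(self):
        labelled = simulate_mosaic_labels(self._cells(50), 0.45, clone_count=1, seed=3)
        statuses = {c.mecp2_positive for c in labelled}
        assert len(statuses) == 1

    def test_many_clones_recover_fraction(self):
        """With clones ≫ cells the positive fraction is binomial around
        the mosaic fraction (10^4 cells, ±0.02)."""
        cells = self._cells(10_000, seed=1)
        labelled = simulate_mosaic_labels(cells, 0.45, clone_count=10**6, seed=2)
        frac = np.mean([c.mecp2_positive for c in labelled])
        assert frac == pytest.approx(0.45, abs=0.02)

    def test_same_seed_same_assignment(self):
        cells = self._cells(100)
        a = simulate_mosaic_labels(cells, 0.45, 20, seed=9)
        b = simulate_mosaic_labels(cells, 0.45, 20, seed=9)
        assert [c.mecp2_positive for c in a] == [c.mecp2_positive for c in b]

    def test_clones_are_spatially_contiguous(self):
        """With few clones, neighbouring cells mostly share status."""
        cells = self._cells(400, seed=5)
        labelled = simulate_mosaic_labels(cells, 0.5, clone_count=4, seed=6)
        pts = np.array([[c.x, c.y] for c in labelled])
        status = np.array([c.mecp2_positive for c in labelled])
        from scipy.spatial import cKDTree

        _, nn = cKDTree(pts).query(pts, k=2)
        agreement = np.mean(status == status[nn[:, 1]])
        assert agreement > 0.8

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            simulate_mosaic_labels(self._cells(5), 0.0, 10, seed=0)


class TestCalibrationEndpoints:
    def test_noise_free_single_cell_exact_endpoints(self, model, calib):
        sc = SimScenario(
            photon_scale=np.inf,
            background=0.0,
            neuropil_level=0.0,
            read_noise_sd=0.0,
        )
        ox_f, red_f, ox_c, red_c = simulate_calibration_endpoints(sc, model, 1, 1, seed=0)
        ox_meas = workflows.quantify_field(ox_f, f910_floor=1e-9)
        red_meas = workflows.quantify_field(red_f, f910_floor=1e-9)
        assert ox_meas[0].ratio == pytest.approx(calib.r_ox, abs=1e-9)
        assert red_meas[0].ratio == pytest.approx(calib.r_red, abs=1e-9)

    def test_shared_geometry_for_matched_cells(self, noisy_scenario, model):
        ox_f, red_f, ox_c, red_c = simulate_calibration_endpoints(
            noisy_scenario, model, 5, 7, seed=1
        )
        for a, b in zip(ox_c, red_c):
            assert (a.x, a.y) == (b.x, b.y)
            assert a.expression == b.expression
        assert len(ox_c) == 5 and len(red_c) == 7

    def test_zero_cells_error(self, noisy_scenario, model):
        with pytest.raises(ValueError):
            simulate_calibration_endpoints(noisy_scenario, model, 0, 5, seed=0)


class TestBleachMark:
    def test_mark_sets_region_to_level(self, noisy_scenario, model):
        field, _ = simulate_field(noisy_scenario, model, seed=0)
        marked = stamp_bleach_mark(field, (10, 10), 50, level=2.0)
        region = marked.channel("F910")[10:60, 10:60]
        assert np.all(region == 2)
        assert marked.fiducials == [(10, 10, 50)]
        # original untouched
        assert not np.all(field.channel("F910")[10:60, 10:60] == 2)

    def test_size_zero_unchanged(self, noisy_scenario, model):
        field, _ = simulate_field(noisy_scenario, model, seed=0)
        assert stamp_bleach_mark(field, (10, 10), 0) is field

    def test_two_disjoint_marks(self, noisy_scenario, model):
        field, _ = simulate_field(noisy_scenario, model, seed=0)
        marked = stamp_bleach_mark(field, (5, 5), 20, level=0.0)
        marked = stamp_bleach_mark(marked, (100, 100), 20, level=0.0)
        assert len(marked.fiducials) == 2
        assert np.all(marked.channel("F740")[5:25, 5:25] == 0)
        assert np.all(marked.channel("F740")[100:120, 100:120] == 0)

    def test_out_of_bounds_mark_errors(self, noisy_scenario, model):
        field, _ = simulate_field(noisy_scenario, model, seed=0)
        with pytest.raises(ValueError):
            stamp_bleach_mark(field, (240, 240), 50)


class TestScenarioValidation:
    def test_rejects_bad_mosaic_fraction(self):
        with pytest.raises(ValueError):
            SimScenario(mosaic_fraction=1.5)

    def test_rejects_out_of_range_group_mean(self):
        with pytest.raises(ValueError):
            SimScenario(group_oxd={("CA1", "WT", "p50"): (1.2, 0.1)})

    def test_mcat_suppresses_genotype_shift(self):
        sc = SimScenario(
            group_oxd={
                ("somatosensory", "WT", "gt_p100"): (0.465, 0.1),
                ("somatosensory", "Mecp2+/-", "gt_p100"): (0.518, 0.1),
            },
            mcat_effect=0.0,
        )
        mean, _ = sc.group_mean_sd("somatosensory", "Mecp2+/-", "gt_p100")
        assert mean == pytest.approx(0.465)
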