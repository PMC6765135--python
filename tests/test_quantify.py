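"""Dot-quantification tests against the forward model and constructed fixtures."""

import numpy as np
import pandas as pd
import pytest

from froskd import (
    QuantConfig,
    SaturationWarning,
    SimulationConfig,
    calibrate_saturation,
    detect_dot,
    discard_bright,
    dot_profile,
    estimate_concentration,
    max_composite,
    quantify_population,
    ring_background,
    simulate_population,
)
from froskd.constants import MOLECULES_PER_UM3_PER_NM
from froskd.quantify import quantify_cell


def _single_cell(population, index=0):
    cell = population.cells[index]
    fld = population.fields[cell.field_index]
    return cell, fld.labeled, fld.mask == cell.label


class TestMaxComposite:
    def test_single_slice_is_identity_inside_mask(self, rng):
        img = rng.random((1, 10, 10))
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        comp = max_composite(img, mask)
        assert np.array_equal(comp[mask], img[0][mask])
        assert np.all(comp[~mask] == 0)

    def test_constant_stack(self):
        stack = np.full((5, 8, 8), 3.5)
        mask = np.ones((8, 8), bool)
        assert np.all(max_composite(stack, mask) == 3.5)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            max_composite(np.ones((3, 5, 5)), np.zeros((5, 5), bool))

    def test_composite_argmax_matches_ground_truth(self, clean_midrange):
        pop = clean_midrange
        for idx in range(4):
            cell, stack, mask = _single_cell(pop, idx)
            if cell.true_bound_count < 5:
                continue
            comp = max_composite(stack, mask)
            y, x = np.unravel_index(np.argmax(np.where(mask, comp, -np.inf)), comp.shape)
            assert abs(y - cell.dot_position[1]) <= 1
            assert abs(x - cell.dot_position[2]) <= 1


class TestDetectDot:
    def test_flat_image_returns_none(self):
        comp = np.full((30, 30), 7.0)
        mask = np.ones((30, 30), bool)
        pos, n_peaks = detect_dot(comp, mask)
        assert pos is None and n_peaks == 0

    def test_noise_free_dot_found_at_truth(self, clean_midrange, quant_clean_midrange):
        pop = clean_midrange
        for idx in range(6):
            cell, stack, mask = _single_cell(pop, idx)
            if cell.true_bound_count < 20:
                continue
            pos, _ = detect_dot(max_composite(stack, mask), mask, quant_clean_midrange)
            assert pos is not None
            assert abs(pos[0] - cell.dot_position[1]) <= 1
            assert abs(pos[1] - cell.dot_position[2]) <= 1

    def test_two_separated_dots_reports_brighter_and_multiplicity(self):
        yy, xx = np.mgrid[:40, :40]
        bright = 1000 * np.exp(-((yy - 20.0) ** 2 + (xx - 17.0) ** 2) / (2 * 1.2**2))
        dim = 700 * np.exp(-((yy - 20.0) ** 2 + (xx - 25.0) ** 2) / (2 * 1.2**2))
        comp = 50.0 + bright + dim
        mask = ((yy - 20) / 16.0) ** 2 + ((xx - 20) / 18.0) ** 2 <= 1
        pos, n_peaks = detect_dot(comp, mask)
        assert pos == (20, 17)
        assert n_peaks == 2


class TestDotProfile:
    def test_photon_total_recovered_within_two_percent(self, clean_midrange, quant_clean_midrange):
        pop = clean_midrange
        cfg = pop.config
        checked = 0
        for idx in range(len(pop.cells)):
            cell, stack, mask = _single_cell(pop, idx)
            if cell.true_bound_count < 50:
                continue
            pos = (int(round(cell.dot_position[1])), int(round(cell.dot_position[2])))
            prof = dot_profile(stack, pos, quant_clean_midrange, mask=mask)
            expected = cfg.photons_per_molecule * cell.true_bound_count
            assert prof.dot_total == pytest.approx(expected, rel=0.02)
            assert prof.best_z == int(round(cell.dot_position[0]))
            checked += 1
        assert checked >= 3

    def test_zero_dot_gives_near_zero_profile(self):
        cfg = SimulationConfig(
            n_cells=2, conc_law="fixed", conc_low=300.0, true_kd=1e4,
            true_hill_n=4.0, replicated_dot_fraction=0.0, noise=False, seed=3,
        )
        pop = simulate_population(cfg)
        cell, stack, mask = _single_cell(pop)
        assert cell.true_bound_count == 0
        q = QuantConfig(autofluorescence_level=cfg.autofluorescence_rate)
        pos = (int(cell.nucleus_center[0]), int(cell.nucleus_center[1]))
        prof = dot_profile(stack, pos, q, mask=mask)
        assert np.all(np.abs(prof.dot_intensity) < 1e-6)

    def test_disc_at_image_edge_raises(self):
        stack = np.ones((3, 20, 20))
        with pytest.raises(ValueError):
            dot_profile(stack, (1, 10), QuantConfig())


class TestRingBackground:
    def test_autofluorescence_only_ring_is_zero(self):
        cfg = SimulationConfig(n_cells=2, conc_law="fixed", conc_low=0.0, noise=False, seed=4)
        pop = simulate_population(cfg)
        cell, stack, mask = _single_cell(pop)
        q = QuantConfig(autofluorescence_level=cfg.autofluorescence_rate)
        pos = (int(cell.nucleus_center[0]), int(cell.nucleus_center[1]))
        ring = ring_background(stack, pos, 4, mask, q)
        assert ring.ring_total == pytest.approx(0.0, abs=1e-9)
        assert not ring.contaminated

    def test_uniform_background_closed_form(self, clean_midrange, quant_clean_midrange):
        """ring_total = density x photons/molecule x ring_area x DOF exactly."""
        pop = clean_midrange
        cfg = pop.config
        cell, stack, mask = _single_cell(pop, 1)
        pos = (int(round(cell.dot_position[1])), int(round(cell.dot_position[2])))
        ring = ring_background(stack, pos, int(round(cell.dot_position[0])), mask, quant_clean_midrange)
        density = cell.true_free_conc * MOLECULES_PER_UM3_PER_NM
        expected = cfg.photons_per_molecule * density * ring.ring_area * cfg.dof
        # only the dot's faint tail inside the annulus perturbs the closed form
        assert ring.ring_total == pytest.approx(expected, rel=0.01)

    def test_second_dot_in_ring_flags_contamination(self):
        stack = np.full((3, 41, 41), 100.0)
        yy, xx = np.mgrid[:41, :41]
        stack[1] += 5000 * np.exp(-((yy - 20.0) ** 2 + (xx - 26.0) ** 2) / (2 * 1.2**2))
        mask = np.ones((41, 41), bool)
        ring = ring_background(stack, (20, 20), 1, mask, QuantConfig())
        assert ring.contaminated

    def test_ring_shrinks_inside_small_cell(self):
        mask = np.zeros((41, 41), bool)
        yy, xx = np.mgrid[:41, :41]
        mask[(yy - 20) ** 2 + (xx - 20) ** 2 <= 6.5**2] = True
        stack = np.zeros((3, 41, 41))
        stack[:, mask] = 10.0
        ring = ring_background(stack, (20, 20), 0, mask, QuantConfig())
        assert ring.outer_used < 8.0
        with pytest.raises(ValueError):
            tiny = np.zeros_like(mask)
            tiny[(yy - 20) ** 2 + (xx - 20) ** 2 <= 3**2] = True
            ring_background(stack, (20, 20), 0, tiny, QuantConfig())


def _records(dot_totals, **extra):
    return pd.DataFrame(
        {
            "cell_id": np.arange(len(dot_totals)),
            "dot_total": np.asarray(dot_totals, float),
            "ring_total": extra.get("ring_total", np.full(len(dot_totals), 1000.0)),
            "ring_area": extra.get("ring_area", np.full(len(dot_totals), 1.5)),
            "usable": extra.get("usable", np.ones(len(dot_totals), bool)),
            "discarded": extra.get("discarded", np.zeros(len(dot_totals), bool)),
        }
    )


class TestDiscardBright:
    def test_equal_intensities_keep_everything(self):
        out = discard_bright(_records([5.0] * 10))
        assert not out["discarded"].any()

    def test_doubles_are_exactly_the_ones_discarded(self):
        values = [100.0] * 90 + [200.0] * 10
        out = discard_bright(_records(values), factor=1.8)
        assert out["discarded"].sum() == 10
        assert np.all(out.loc[out["discarded"], "dot_total"] == 200.0)

    def test_infinite_factor_is_identity(self):
        out = discard_bright(_records([1.0, 5.0, 50.0]), factor=np.inf)
        assert not out["discarded"].any()

    def test_idempotent_and_permutation_invariant(self, rng):
        values = np.concatenate([rng.normal(100, 3, 60), rng.normal(200, 3, 8)])
        once = discard_bright(_records(values), factor=1.8)
        twice = discard_bright(once, factor=1.8)
        assert np.array_equal(once["discarded"], twice["discarded"])
        perm = rng.permutation(len(values))
        shuffled = discard_bright(_records(values[perm]), factor=1.8)
        assert np.array_equal(
            shuffled.sort_values("dot_total")["discarded"].to_numpy(),
            once.sort_values("dot_total")["discarded"].to_numpy(),
        )

    def test_too_few_records_raises(self):
        with pytest.raises(ValueError):
            discard_bright(_records([1.0, 2.0]))

    def test_fully_discarded_population_raises(self):
        df = _records([1.0, 2.0, 3.0], discarded=np.ones(3, bool))
        with pytest.raises(ValueError):
            discard_bright(df)


class TestCalibrateSaturation:
    def test_hand_built_records_recover_intensity_per_molecule_exactly(self):
        df = _records([640.0] * 12)
        assert calibrate_saturation(df, lacO_repeats=32) == pytest.approx(10.0)
        assert calibrate_saturation(df, lacO_repeats=256) == pytest.approx(640.0 / 512.0)

    def test_simulated_saturated_population(self, clean_saturated, quant_clean_saturated):
        records = quantify_population(clean_saturated, quant_clean_saturated)
        ref = calibrate_saturation(records, lacO_repeats=256)
        # finite integration aperture captures ~98.6% of the dot light
        assert ref == pytest.approx(clean_saturated.config.photons_per_molecule, rel=0.02)

    def test_unsaturated_population_warns(self, rng):
        ring = rng.uniform(100, 1000, 30)
        df = _records(ring * 0.5 + rng.normal(0, 5, 30), ring_total=ring)
        with pytest.warns(SaturationWarning):
            calibrate_saturation(df, lacO_repeats=256)

    def test_too_few_records_raises(self):
        with pytest.raises(ValueError):
            calibrate_saturation(_records([10.0] * 5), lacO_repeats=256)


class TestEstimateConcentration:
    def test_zero_ring_total_gives_zero_concentration(self):
        df = _records([0.0] * 3, ring_total=np.zeros(3))
        out = estimate_concentration(df, 10.0, QuantConfig(), 256)
        assert np.all(out["free_conc_est"] == 0.0)

    def test_saturation_equation_worked_example(self):
        """dot/background ratio of 1 with 512 bound molecules.

        Then N_free = 512 and the concentration satisfies
        C x area x DOF x 0.6022 = 512.
        """
        q = QuantConfig()
        area = 1.5  # um^2
        df = _records([512.0 * 7.0], ring_total=[512.0 * 7.0], ring_area=[area])
        out = estimate_concentration(df, 7.0, q, 256)
        expected = 512.0 / (area * q.dof * MOLECULES_PER_UM3_PER_NM)
        assert out["free_conc_est"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert out["occupancy_est"].iloc[0] == pytest.approx(1.0)

    def test_noise_free_recovery_within_five_percent(
        self, clean_midrange, quant_clean_midrange, clean_saturated, quant_clean_saturated
    ):
        sat_records = quantify_population(clean_saturated, quant_clean_saturated)
        ref = calibrate_saturation(sat_records, lacO_repeats=256)
        records = quantify_population(clean_midrange, quant_clean_midrange)
        records = estimate_concentration(records, ref, quant_clean_midrange, 256)
        for cell, (_, row) in zip(clean_midrange.cells, records.iterrows()):
            assert row["free_conc_est"] == pytest.approx(cell.true_free_conc, rel=0.05)
            if cell.true_bound_count > 20:
                assert row["n_bound_est"] == pytest.approx(cell.true_bound_count, rel=0.05)

    def test_noisy_recovery_within_fifteen_percent(self):
        cfg = SimulationConfig(
            n_cells=20, conc_law="fixed", conc_low=592.0,
            replicated_dot_fraction=0.0, noise=True, seed=21,
        )
        pop = simulate_population(cfg)
        q = QuantConfig(
            dof=cfg.dof,
            pixel_size=cfg.pixel_size,
            autofluorescence_level=cfg.autofluorescence_rate,
        )
        records = quantify_population(pop, q)
        records = estimate_concentration(
            records, cfg.photons_per_molecule, q, cfg.lacO_repeats
        )
        err = np.abs(records["free_conc_est"] - 592.0) / 592.0
        assert np.median(err) < 0.15

    def test_zero_ring_area_raises(self):
        df = _records([1.0] * 3, ring_area=np.zeros(3))
        with pytest.raises(ValueError):
            estimate_concentration(df, 10.0, QuantConfig(), 256)


class TestQuantifyCell:
    def test_dim_cell_still_measured_with_near_zero_dot(self):
        cfg = SimulationConfig(
            n_cells=2, conc_law="fixed", conc_low=100.0,
            replicated_dot_fraction=0.0, noise=True, seed=13,
        )
        pop = simulate_population(cfg)
        cell = pop.cells[0]
        fld = pop.fields[0]
        q = QuantConfig(autofluorescence_level=cfg.autofluorescence_rate)
        rec = quantify_cell(fld.labeled, fld.mask == cell.label, q)
        assert rec.usable
        # occupancy at 100 nM with Kd 592 and n 2.93 is ~0.5%: tiny dot signal
        assert rec.dot_total < 0.05 * cfg.photons_per_molecule * 512
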