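"""Tests of the synthetic plate generator against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm
from skimage.measure import label as cc_label
from skimage.morphology import disk, erosion

from flimplate.plate import default_dose_response_layout
from flimplate.simulate import (
    BACKGROUND,
    CYTOPLASM,
    DEBRIS,
    MEMBRANE,
    DoseResponseModel,
    SimulationConfig,
    amplitude_weighted_lifetime,
    decay_gate_fractions,
    expected_gate_counts,
    fret_fraction_at_dose,
    generate_plate,
    render_cell_field,
    simulate_gated_stack,
    simulate_reference,
    well_mixtures,
)


class TestHillLink:
    @pytest.mark.parametrize(
        "dose, model_kwargs, expected",
        [
            (0.0, {}, 0.8),  # zero dose -> f_max
            (0.1, {"ec50_uM": 0.1, "f_min": 0.0, "f_max": 0.8}, 0.40),  # half-maximum
            # 10x EC50, hill 1: f_max / 11
            (1.0, {"ec50_uM": 0.1, "hill": 1.0, "f_min": 0.0, "f_max": 0.8}, 0.8 / 11),
        ],
    )
    def test_known_points(self, dose, model_kwargs, expected):
        model = DoseResponseModel(**model_kwargs)
        assert fret_fraction_at_dose(dose, model) == pytest.approx(expected, abs=1e-12)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            fret_fraction_at_dose(-1.0, DoseResponseModel())

    @given(
        ec50=st.floats(0.01, 10.0),
        hill=st.floats(0.2, 5.0),
        f_min=st.floats(0.0, 0.3),
        span=st.floats(0.0, 0.7),
        d1=st.floats(0.0, 100.0),
        d2=st.floats(0.0, 100.0),
    )
    def test_monotone_nonincreasing_in_dose(self, ec50, hill, f_min, span, d1, d2):
        model = DoseResponseModel(ec50_uM=ec50, hill=hill, f_min=f_min, f_max=f_min + span)
        lo, hi = sorted((d1, d2))
        assert fret_fraction_at_dose(hi, model) <= fret_fraction_at_dose(lo, model) + 1e-12

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            DoseResponseModel(f_min=0.5, f_max=0.4)
        with pytest.raises(ValueError):
            DoseResponseModel(ec50_uM=-1.0)


class TestGateModel:
    def test_delta_irf_single_component_follows_gate_integrated_exponential(self):
        """With a delta IRF the expected counts are proportional to
        exp(-t_k/tau) after boxcar integration."""
        cfg = SimulationConfig(irf_fwhm_ps=0.0, irf_center_ps=0.0)
        tau = 2000.0
        frac = decay_gate_fractions([(1.0, tau)], cfg)
        delays = np.asarray(cfg.gate_delays_ps)
        expected = np.exp(-delays / tau)
        expected /= expected.sum()
        assert np.allclose(frac, expected, rtol=5e-3)

    def test_photon_conservation_is_exact_over_schedule(self, config):
        for f in (0.0, 0.3, 1.0):
            counts = expected_gate_counts(
                [(1.0 - f, 2950.0), (f, 766.0)], 1234.5, config
            )
            assert counts.sum() == pytest.approx(1234.5, rel=1e-12)

    def test_zero_budget_gives_all_zero_stack(self, config, rng):
        labels = np.ones((8, 8), dtype=int)
        stack = simulate_gated_stack(
            labels, {1: [(1.0, 2950.0)]}, config, rng, brightness={1: 0.0}
        )
        assert stack.counts.sum() == 0

    def test_poisson_mean_matches_analytic_expectation(self, config, rng):
        """Mean over many Poisson pixels agrees with the analytic per-gate
        expectation within 3 standard errors."""
        n = 32 * 32
        labels = np.ones((32, 32), dtype=int)
        mix = {1: [(0.5, 2950.0), (0.5, 766.0)]}
        stack = simulate_gated_stack(labels, mix, config, rng)
        expected = expected_gate_counts(mix[1], config.photon_budget, config)
        observed = stack.counts.reshape(stack.n_gates, -1).mean(axis=1)
        se = np.sqrt(expected / n)
        assert np.all(np.abs(observed - expected) <= 3.0 * np.maximum(se, 1e-9))

    def test_mixture_fractions_must_sum_to_one(self, config, rng):
        labels = np.ones((4, 4), dtype=int)
        with pytest.raises(ValueError):
            simulate_gated_stack(labels, {1: [(0.5, 2950.0), (0.4, 766.0)]}, config, rng)

    def test_amplitude_weighted_lifetime_between_components(self):
        for f in (0.01, 0.5, 0.99):
            tau = amplitude_weighted_lifetime([(1 - f, 2950.0), (f, 766.0)])
            assert 766.0 < tau < 2950.0


class TestReference:
    def test_same_seed_gives_identical_counts(self, config):
        r1 = simulate_reference(config, np.random.default_rng(5))
        r2 = simulate_reference(config, np.random.default_rng(5))
        assert np.array_equal(r1.counts, r2.counts)

    def test_short_tau_ref_limit_matches_gate_integrated_irf(self):
        """For tau_ref far below the gate spacing the reference shape
        approaches the boxcar-integrated IRF (Gaussian cdf differences)."""
        cfg = SimulationConfig(tau_ref_ps=5.0)
        ref = simulate_reference(cfg, rng=None)
        frac = ref.counts / ref.counts.sum()
        sigma = cfg.irf_fwhm_ps / (2 * np.sqrt(2 * np.log(2)))
        edges = np.concatenate(
            [np.asarray(cfg.gate_delays_ps), [cfg.gate_delays_ps[-1] + cfg.gate_width_ps]]
        )
        cdf = norm.cdf(edges, loc=cfg.irf_center_ps, scale=sigma)
        irf_frac = np.diff(cdf) / (cdf[-1] - cdf[0])
        assert np.allclose(frac, irf_frac, atol=0.02)

    def test_log_counts_tail_slope_recovers_tau_ref(self):
        """On a schedule fine enough to resolve the decay, late-gate log
        counts fall linearly with slope -1/tau_ref."""
        cfg = SimulationConfig(
            gate_delays_ps=tuple(np.arange(40) * 50.0),
            gate_width_ps=50.0,
            tau_ref_ps=400.0,
            irf_center_ps=300.0,
        )
        ref = simulate_reference(cfg, rng=None)
        delays = np.asarray(cfg.gate_delays_ps)
        tail = delays > cfg.irf_center_ps + 500.0
        slope = np.polyfit(delays[tail], np.log(ref.counts[tail]), 1)[0]
        assert -1.0 / slope == pytest.approx(400.0, rel=0.01)


class TestCellField:
    def test_zero_cells_gives_pure_background(self, rng):
        field = render_cell_field(0, (64, 64), rng)
        assert np.all(field.compartment_labels == BACKGROUND)

    def test_single_cell_topology(self, rng):
        """One cell: exactly one connected cytoplasm region enclosed by a
        closed membrane ring (background cannot flood into the cytoplasm)."""
        field = render_cell_field(1, (64, 64), rng)
        assert len(field.cells) == 1
        cyto = field.compartment_labels == CYTOPLASM
        assert cc_label(cyto, connectivity=2).max() == 1
        # flood from the border through non-membrane pixels must not reach cytoplasm
        passable = field.compartment_labels != MEMBRANE
        comp = cc_label(passable, connectivity=1)
        border_labels = set(comp[0, :]) | set(comp[-1, :]) | set(comp[:, 0]) | set(comp[:, -1])
        assert not any(lab in border_labels for lab in np.unique(comp[cyto]))

    def test_membrane_ring_is_exact_erosion_difference(self, rng):
        width = 3
        field = render_cell_field(2, (64, 64), rng, membrane_width=width)
        for cell in field.cells:
            full = cell.full_mask()
            expected = full & ~erosion(full, disk(width))
            assert np.array_equal(cell.membrane_mask, expected)

    def test_impossible_packing_returns_fewer_cells_with_warning(self, rng):
        field = render_cell_field(
            50, (30, 30), rng, axes_range=(6.0, 7.0), max_tries_per_cell=20
        )
        assert field.packing_warning
        assert len(field.cells) < 50


class TestPlateGeneration:
    def test_same_seed_is_bit_identical(self, config):
        layout = default_dose_response_layout(rows=2)
        model = DoseResponseModel()
        small = SimulationConfig(rows=2, cells_per_fov=3)
        d1 = generate_plate(layout, small, model, seed=9)
        d2 = generate_plate(layout, small, model, seed=9)
        assert d1.manifest == d2.manifest
        assert set(d1.stacks) == set(d2.stacks)
        for key in d1.stacks:
            assert np.array_equal(d1.stacks[key].counts, d2.stacks[key].counts)

    def test_positive_control_membrane_fraction_is_f_min(self):
        layout = default_dose_response_layout(rows=1)
        model = DoseResponseModel(f_min=0.07)
        dataset = generate_plate(layout, SimulationConfig(rows=1, cells_per_fov=2), model, seed=3)
        pos = dataset.manifest["wells"]["A1"]
        assert pos["role"] == "positive_control"
        assert pos["membrane_fret_fraction"] == pytest.approx(0.07)

    def test_default_dose_series_has_half_decade_steps(self):
        layout = default_dose_response_layout()
        doses = sorted({w.dose_uM for w in layout.wells if w.role == "dose"})
        ratios = np.array(doses[1:]) / np.array(doses[:-1])
        assert np.allclose(ratios, 10.0 ** (4.0 / 8.0), rtol=1e-9)

    def test_all_excluded_layout_yields_manifest_only(self, config):
        layout = default_dose_response_layout(rows=1)
        excluded = layout.__class__(
            rows=1,
            cols=12,
            wells=[w.__class__(w.well_id, w.row, w.col, w.condition, w.dose_uM, "excluded")
                   for w in layout.wells],
        )
        dataset = generate_plate(excluded, SimulationConfig(rows=1), DoseResponseModel(), seed=1)
        assert dataset.stacks == {}
        assert dataset.manifest["wells"] == {}

    def test_debris_scales_with_fret_activity(self):
        """Positive-control wells (residual FRET) carry far less debris
        than vehicle wells (full aggregation)."""
        layout = default_dose_response_layout(rows=4)
        cfg = SimulationConfig(rows=4, debris_per_frame=6.0)
        dataset = generate_plate(layout, cfg, DoseResponseModel(), seed=21)
        by_role = {"positive_control": 0, "negative_control": 0}
        for wid, entry in dataset.manifest["wells"].items():
            if entry["role"] in by_role:
                by_role[entry["role"]] += sum(f["n_debris"] for f in entry["fovs"])
        assert by_role["negative_control"] > by_role["positive_control"]
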