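"""Decay-fitting tests: reconvolution identity, recovery, binning, global fits.

Independent oracles: the reconvolution identity is checked against the
closed-form exponentially-modified-Gaussian convolution of an explicit
Gaussian IRF; fits are checked against brute-force chi-square grid scans
whose model comes from the generator's direct numerical convolution
(``expected_gate_counts``).  Neither shares code with the
reference-reconvolution path under test.
"""

import numpy as np
import pytest
from scipy.special import erfc

from flimplate.core import GatedStack, ReferenceDecay
from flimplate.fitting import (
    ReconvolutionEngine,
    fit_global_binned,
    fit_monoexp,
    fit_pixelwise,
    fit_roi_binned,
    reconvolved_model,
)
from flimplate.simulate import SimulationConfig, expected_gate_counts, simulate_reference

FINE_DT = 10.0


def _emg(t, mu, sigma, tau):
    """Closed form of (Gaussian IRF) (x) (1/tau) exp(-t/tau)."""
    arg = (sigma / tau - (t - mu) / sigma) / np.sqrt(2.0)
    return (
        0.5 / tau
        * np.exp(0.5 * (sigma / tau) ** 2 - (t - mu) / tau)
        * erfc(arg)
    )


IRF_CENTER, IRF_SIGMA = 500.0, 150.0 / (2 * np.sqrt(2 * np.log(2)))


def _fine_grid_reference(tau_ref=50.0, t_max=8000.0):
    """Reference sampled on a fine grid from the analytic convolution."""
    t = np.arange(0.0, t_max + FINE_DT, FINE_DT)
    R = _emg(t, IRF_CENTER, IRF_SIGMA, tau_ref)
    return t, ReferenceDecay(R, t, FINE_DT, tau_ref)


def _direct_convolution_shape(t, components):
    """Independent oracle: analytic IRF (x) sum_i beta_i exp(-t/tau_i)."""
    model = np.zeros_like(t)
    for beta, tau in components:
        model += beta * tau * _emg(t, IRF_CENTER, IRF_SIGMA, tau)
    return model / model.sum()


class TestReconvolvedModel:
    def test_matches_direct_convolution_for_random_mixtures(self):
        t, ref = _fine_grid_reference()
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(30):
            k = rng.integers(1, 4)
            taus = np.exp(rng.uniform(np.log(300.0), np.log(4000.0), size=k))
            betas = rng.dirichlet(np.ones(k))
            components = list(zip(betas, taus))
            pred = reconvolved_model(components, 1.0, ref)
            oracle = _direct_convolution_shape(t, components)
            worst = max(worst, np.max(np.abs(pred - oracle)) / oracle.max())
        assert worst < 1e-3

    def test_component_at_tau_ref_reduces_to_reference(self):
        _, ref = _fine_grid_reference(tau_ref=50.0)
        pred = reconvolved_model([(1.0, 50.0)], 1.0, ref)
        expected = ref.counts / ref.counts.sum()
        assert np.allclose(pred, expected, rtol=1e-9)

    def test_delta_reference_limit_is_gate_sampled_exponential(self):
        """A near-delta reference reproduces exp(-t/tau) directly."""
        t = np.arange(0.0, 6000.0, FINE_DT)
        R = np.zeros_like(t)
        R[0] = 1.0
        ref = ReferenceDecay(R, t, FINE_DT, tau_ref_ps=1e-3)
        tau = 1800.0
        pred = reconvolved_model([(1.0, tau)], 1.0, ref)
        expected = np.exp(-t / tau)
        # compare shapes over the pure-decay region, each renormalised
        assert np.allclose(
            pred[1:] / pred[1:].sum(), expected[1:] / expected[1:].sum(), rtol=1e-3
        )

    def test_nonpositive_lifetime_rejected(self, reference):
        with pytest.raises(ValueError):
            reconvolved_model([(1.0, -100.0)], 1.0, reference)

    def test_shape_is_normalised_and_nonnegative(self, reference):
        pred = reconvolved_model([(0.3, 2950.0), (0.7, 766.0)], 1.0, reference)
        assert pred.sum() == pytest.approx(1.0)
        assert np.all(pred >= 0)


class TestMonoExpFit:
    def test_noiseless_recovery_within_one_ps(self, config, reference):
        decay = expected_gate_counts([(1.0, 2500.0)], 1e5, config)
        fit = fit_monoexp(decay, reference)
        assert fit.converged
        assert fit.tau_ps == pytest.approx(2500.0, abs=1.0)

    def test_all_zero_decay_does_not_converge(self, reference):
        fit = fit_monoexp(np.zeros(16), reference)
        assert not fit.converged
        assert np.isnan(fit.tau_ps)

    def test_too_few_gates_rejected(self, reference):
        with pytest.raises(ValueError):
            fit_monoexp(np.ones(2), reference)

    def test_agrees_with_grid_search_oracle(self, config, reference, rng):
        """The LM fit lands on the minimum of a brute-force chi-square
        scan that uses the direct-convolution model."""
        truth = 2500.0
        expected = expected_gate_counts([(1.0, truth)], 1e4, config)
        counts = rng.poisson(expected).astype(float)
        fit = fit_monoexp(counts, reference)
        engine = ReconvolutionEngine(reference)
        m = engine.fit_mask
        taus = np.arange(2300.0, 2700.0, 1.0)
        w = 1.0 / np.maximum(counts[m], 1.0)
        chi2 = np.empty_like(taus)
        for j, tau in enumerate(taus):
            s = expected_gate_counts([(1.0, tau)], 1.0, config)[m]
            amp = (w * counts[m] * s).sum() / (w * s * s).sum()
            chi2[j] = (w * (counts[m] - amp * s) ** 2).sum()
        tau_grid = taus[np.argmin(chi2)]
        assert fit.tau_ps == pytest.approx(tau_grid, abs=2.0)
        # and within 3 predicted standard errors of the truth
        assert abs(fit.tau_ps - truth) < 3.0 * 2.0 * truth / np.sqrt(1e4)


class TestPixelwise:
    def test_below_threshold_pixels_never_fitted(self, config, reference, rng):
        labels = np.array([[1, 2]])
        mix = {1: [(1.0, 2500.0)], 2: [(1.0, 2500.0)]}
        stack = simulate_gated_stack_like(labels, mix, config, rng, {1: 150.0, 2: 400.0})
        li = fit_pixelwise(stack, reference, threshold=200.0)
        assert np.isnan(li.tau_map[0, 0])
        assert np.isfinite(li.tau_map[0, 1])

    def test_zero_threshold_fits_every_nonempty_pixel(self, config, reference, rng):
        labels = np.array([[1, 1]])
        stack = simulate_gated_stack_like(labels, {1: [(1.0, 2500.0)]}, config, rng, {1: 400.0})
        li = fit_pixelwise(stack, reference, threshold=0.0)
        assert np.all(np.isfinite(li.tau_map))

    def test_all_zero_stack_flags_no_pixels(self, config, reference):
        stack = GatedStack(
            np.zeros((16, 4, 4)), np.asarray(config.gate_delays_ps), config.gate_width_ps
        )
        li = fit_pixelwise(stack, reference)
        assert li.no_pixels_flag
        assert not np.any(np.isfinite(li.tau_map))

    def test_agrees_with_per_pixel_lm_fits(self, config, reference, rng):
        """The vectorised variable-projection path matches the LM path."""
        labels = np.ones((4, 4), dtype=int)
        stack = simulate_gated_stack_like(
            labels, {1: [(0.6, 2950.0), (0.4, 766.0)]}, config, rng, {1: 2000.0}
        )
        li = fit_pixelwise(stack, reference, threshold=0.0)
        engine = ReconvolutionEngine(reference)
        for i in range(4):
            for j in range(4):
                lm = fit_monoexp(stack.counts[:, i, j].astype(float), reference, engine=engine)
                assert li.tau_map[i, j] == pytest.approx(lm.tau_ps, rel=5e-3)

    def test_precision_scales_as_inverse_sqrt_photons(self, config, reference, rng):
        """Quadrupling the photon budget halves the lifetime scatter."""
        sds = []
        for budget in (1000.0, 4000.0):
            labels = np.ones((24, 24), dtype=int)
            stack = simulate_gated_stack_like(
                labels, {1: [(1.0, 2500.0)]}, config, rng, {1: budget}
            )
            li = fit_pixelwise(stack, reference, threshold=0.0)
            sds.append(np.std(li.defined_values()))
        assert sds[0] / sds[1] == pytest.approx(2.0, rel=0.15)


class TestRoiBinned:
    def test_single_pixel_roi_equals_monoexp_of_that_pixel(self, config, reference, rng):
        labels = np.ones((3, 3), dtype=int)
        stack = simulate_gated_stack_like(labels, {1: [(1.0, 2500.0)]}, config, rng, {1: 500.0})
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        roi = fit_roi_binned(stack, reference, mask)
        pix = fit_monoexp(stack.counts[:, 1, 1].astype(float), reference)
        assert roi.tau_ps == pytest.approx(pix.tau_ps, abs=1e-9)
        assert roi.n_pixels == 1

    def test_empty_roi_rejected(self, config, reference, rng):
        labels = np.ones((3, 3), dtype=int)
        stack = simulate_gated_stack_like(labels, {1: [(1.0, 2500.0)]}, config, rng, {1: 500.0})
        with pytest.raises(ValueError):
            fit_roi_binned(stack, reference, np.zeros((3, 3), dtype=bool))

    def test_invariant_under_pixel_permutation(self, config, reference, rng):
        labels = np.ones((4, 4), dtype=int)
        stack = simulate_gated_stack_like(labels, {1: [(1.0, 2000.0)]}, config, rng, {1: 800.0})
        mask = np.ones((4, 4), dtype=bool)
        fit1 = fit_roi_binned(stack, reference, mask)
        perm = rng.permutation(16)
        shuffled = GatedStack(
            stack.counts.reshape(16, -1)[:, perm].reshape(16, 4, 4),
            stack.gate_delays_ps,
            stack.gate_width_ps,
        )
        fit2 = fit_roi_binned(shuffled, reference, mask)
        assert fit1.tau_ps == fit2.tau_ps

    def test_mixed_roi_lifetime_between_components_and_matches_grid_oracle(
        self, config, reference, rng
    ):
        """A 50/50 ROI of short- and long-lifetime pixels fits to an
        effective lifetime strictly between the two, at the brute-force
        grid minimum of the pooled decay."""
        half = expected_gate_counts([(1.0, 766.0)], 5e4, config)
        other = expected_gate_counts([(1.0, 2950.0)], 5e4, config)
        pooled = rng.poisson(half + other).astype(float)
        fit = fit_monoexp(pooled, reference)
        assert 766.0 < fit.tau_ps < 2950.0
        engine = ReconvolutionEngine(reference)
        m = engine.fit_mask
        taus = np.arange(1000.0, 2800.0, 2.0)
        w = 1.0 / np.maximum(pooled[m], 1.0)
        chi2 = []
        for tau in taus:
            s = expected_gate_counts([(1.0, tau)], 1.0, config)[m]
            amp = (w * pooled[m] * s).sum() / (w * s * s).sum()
            chi2.append((w * (pooled[m] - amp * s) ** 2).sum())
        assert fit.tau_ps == pytest.approx(taus[np.argmin(chi2)], abs=4.0)


class TestGlobalBinning:
    def test_single_component_limit_flags_tau2_unidentifiable(self, config, reference, rng):
        decays = {
            c: rng.poisson(expected_gate_counts([(1.0, 2950.0)], 1e5, config)).astype(float)
            for c in ("a", "b", "c")
        }
        result = fit_global_binned(decays, reference, 2950.0)
        assert result.tau2_unidentifiable
        for fit in result.condition_fits.values():
            assert fit.beta1 == pytest.approx(1.0, abs=0.02)

    def test_parameter_recovery_with_fixed_tau1(self, config, reference, rng):
        truth_tau2 = 750.0
        decays = {}
        for b1 in (0.3, 0.5, 0.8):
            e = expected_gate_counts([(b1, 2950.0), (1 - b1, truth_tau2)], 2e5, config)
            decays[b1] = rng.poisson(e).astype(float)
        result = fit_global_binned(decays, reference, 2950.0)
        assert not result.tau2_unidentifiable
        assert result.tau2_ps == pytest.approx(truth_tau2, abs=50.0)
        for b1, fit in result.condition_fits.items():
            assert fit.beta1 == pytest.approx(b1, abs=0.05)
            assert fit.beta1 + fit.beta2 == pytest.approx(1.0, abs=1e-12)

    def test_needs_at_least_two_conditions(self, reference):
        with pytest.raises(ValueError):
            fit_global_binned({"only": np.ones(16)}, reference, 2950.0)


def simulate_gated_stack_like(labels, mixtures, config, rng, brightness):
    from flimplate.simulate import simulate_gated_stack

    return simulate_gated_stack(labels, mixtures, config, rng, brightness=brightness)
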