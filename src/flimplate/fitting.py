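"""Decay fitting for time-gated FLIM with reference reconvolution.

Instead of deconvolving an explicitly measured IRF, every model decay is
expressed through the gated measurement of a reference dye with known
short mono-exponential lifetime tau_ref.  Writing the reference as
``R = IRF (x) (1/tau_ref) exp(-t/tau_ref)`` gives the operator identity
``IRF = R + tau_ref dR/dt``, from which the IRF-convolved sample decay
for a mixture of exponentials is

    I(t) = A * sum_i beta_i [ tau_ref R(t)
                              + (1 - tau_ref/tau_i) (R (x) e^{-t/tau_i})(t) ]

up to a global normalisation.  The discrete convolution treats the
reference as piecewise linear between samples and integrates each
segment exactly (an exponential recurrence, evaluated as an IIR filter);
coarsely gated references are first upsampled onto a fine internal grid
with a monotone cubic (PCHIP) interpolant.

Fitting is weighted non-linear least squares (Levenberg-Marquardt type)
with Poisson/Neyman weights ``w = 1/max(counts, 1)``.  Three entry
points cover the analysis modes: per-pixel mono-exponential lifetime
images, ROI-binned mono-exponential fits, and globally binned
bi-exponential fits with a fixed long lifetime (population-fraction
estimation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .core import GatedStack, ReferenceDecay

__all__ = [
    "MonoExpFit",
    "BiExpFit",
    "LifetimeImage",
    "GlobalBinningResult",
    "ReconvolutionEngine",
    "reconvolved_model",
    "fit_monoexp",
    "fit_pixelwise",
    "fit_roi_binned",
    "fit_global_binned",
    "tau2_replicate_sd",
    "tail_slope_tau",
]

DEGENERACY_GUARD_PS = 50.0  # |tau2 - tau1| below this flags the bi-exp fit


@dataclass
class MonoExpFit:
    """Result of a single-exponential reconvolution fit."""

    tau_ps: float
    amplitude: float
    chi2_reduced: float
    n_photons: float
    converged: bool
    n_pixels: int | None = None


@dataclass
class BiExpFit:
    """Result of a bi-exponential fit; ``beta2 = 1 - beta1`` by construction."""

    tau1_ps: float
    tau2_ps: float
    beta1: float
    amplitude: float
    chi2_reduced: float
    converged: bool
    beta1_at_boundary: bool = False
    degenerate: bool = False

    @property
    def beta2(self) -> float:
        return 1.0 - self.beta1


@dataclass
class LifetimeImage:
    """Per-pixel lifetime map from pixel-wise mono-exponential fitting.

    ``tau_map`` is NaN wherever the pixel's total photon count falls
    below ``threshold_used`` (or the fit failed); ``photon_map`` is the
    per-pixel photon sum over the gate schedule.
    """

    tau_map: np.ndarray
    photon_map: np.ndarray
    threshold_used: float
    chi2_map: np.ndarray | None = None
    no_pixels_flag: bool = False

    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.tau_map)

    def defined_values(self) -> np.ndarray:
        return self.tau_map[self.defined_mask()]


@dataclass
class GlobalBinningResult:
    """Shared tau2 plus per-condition long-lifetime fractions (beta1)."""

    tau1_ps: float
    tau2_ps: float
    tau2_unidentifiable: bool
    pooled_fit: BiExpFit
    condition_fits: dict = field(default_factory=dict)

    def beta1_by_condition(self) -> dict:
        return {k: v.beta1 for k, v in self.condition_fits.items()}


# ---------------------------------------------------------------------------
# reference -> model machinery
# ---------------------------------------------------------------------------


def _exp_conv_uniform(R: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """(R (x) e^{-t/tau}) on a uniform grid, R piecewise linear, exact.

    The per-segment integral of a linear reference against the
    exponential kernel reduces to a first-order IIR recurrence
    ``C_k = E C_{k-1} + b0 R_k + b1 R_{k-1}`` with ``E = exp(-dt/tau)``.
    """
    E = np.exp(-dt / tau)
    P = (tau * tau / dt) * (1.0 - E)
    Q = tau * E
    b0 = tau * (1.0 - E) - P + Q
    b1 = P - Q
    # C_0 = 0; lfilter([b0, b1], [1, -E]) implements the recurrence but
    # includes b0*R_0 at k=0, which we remove to honour C_0 = 0.
    C = lfilter([b0, b1], [1.0, -E], R)
    C -= b0 * R[0] * E ** np.arange(R.size)
    return C


def _exp_conv_nonuniform(t: np.ndarray, R: np.ndarray, tau: float) -> np.ndarray:
    dt = np.diff(t)
    E = np.exp(-dt / tau)
    C = np.zeros_like(R, dtype=float)
    for k in range(1, t.size):
        d = dt[k - 1]
        e = E[k - 1]
        m = (R[k] - R[k - 1]) / d
        seg = R[k] * tau * (1.0 - e) - m * (tau * tau - e * (tau * tau + tau * d))
        C[k] = e * C[k - 1] + seg
    return C


class ReconvolutionEngine:
    """Precomputed reference representation for repeated model evaluation.

    Three regimes, chosen from the reference's gate schedule:

    * fine schedule (spacing at or below the internal resolution): the
      counts are treated as samples of R(t) on their own grid and the
      reconvolution formula is evaluated there directly — the literal
      "evaluated on the gate schedule" form;
    * coarse **contiguous** gates (spacing == width): the counts are
      exact integrals of R over adjacent windows, so the cumulative
      distribution of the reference is known exactly at every gate
      boundary.  It is interpolated with a monotone cubic (PCHIP),
      differentiated to a non-negative density on a fine internal grid
      aligned with the boundaries, the reconvolution is evaluated
      there, and the model is read back through the *same* boxcar
      gate-integration operator that produced the data;
    * coarse gapped gates: the counts are attached to the gate
      midpoints and handled like the fine case after PCHIP upsampling
      (an approximation, flagged in the methods notes).

    In every regime the discrete convolution with ``exp(-t/tau)`` uses
    the exact piecewise-linear exponential recurrence.
    """

    def __init__(self, reference: ReferenceDecay, dt_target_ps: float = 10.0):
        self.reference = reference
        self.tau_ref = float(reference.tau_ref_ps)
        delays = reference.gate_delays_ps
        width = float(reference.gate_width_ps)
        R = reference.counts.astype(float)
        total = R.sum()
        if total <= 0:
            raise ValueError("reference has no counts")
        R = R / total
        self.gate_delays = delays
        self.fit_mask = np.ones(delays.size, dtype=bool)
        spacing = np.diff(delays) if delays.size > 1 else np.array([width])
        contiguous = delays.size > 1 and np.allclose(spacing, width, rtol=1e-6)
        if delays.size < 2 or spacing.min() <= dt_target_ps * 1.5:
            self._mode = "fine"
            self.t = delays
            self.R = R
            self._uniform = delays.size > 1 and np.allclose(spacing, spacing[0])
            self._dt = float(spacing[0]) if self._uniform else None
        elif contiguous:
            self._mode = "gated"
            n_sub = max(1, int(round(width / dt_target_ps)))
            self._dt = width / n_sub
            n_fine = delays.size * n_sub
            t = delays[0] + np.arange(n_fine + 1) * self._dt
            boundaries = np.concatenate([delays, [delays[-1] + width]])
            cum = np.concatenate([[0.0], np.cumsum(R)])
            density = PchipInterpolator(boundaries, cum).derivative()(t)
            self.t = t
            self.R = np.clip(density, 0.0, None)
            self._uniform = True
            # indices of gate boundaries in the fine grid
            self._edge_index = np.arange(delays.size + 1) * n_sub
            # Gates that open while the reference still has mass in
            # flight ("rise gates") cannot be modelled without knowing
            # the sub-gate structure of the IRF; gates opening after
            # essentially all reference mass has arrived follow the
            # pure-decay model exactly, so fitting is restricted to
            # them.  Fall back to all gates if too few remain.
            clean = cum[:-1] >= 1.0 - 1e-3
            if clean.sum() >= 3:
                self.fit_mask = clean
        else:
            self._mode = "midpoint"
            midpoints = delays + width / 2.0
            span = midpoints[-1] - midpoints[0]
            n = max(int(round(span / dt_target_ps)), delays.size)
            t = np.linspace(midpoints[0], midpoints[-1], n + 1)
            self.t = t
            self.R = np.clip(PchipInterpolator(midpoints, R)(t), 0.0, None)
            self._uniform = True
            self._dt = float(t[1] - t[0])
            self._midpoints = midpoints

    def _conv(self, tau: float) -> np.ndarray:
        if self._uniform:
            return _exp_conv_uniform(self.R, self._dt, tau)
        return _exp_conv_nonuniform(self.t, self.R, tau)

    def _component_at_gates(self, tau: float) -> np.ndarray:
        """tau_ref*R + (1 - tau_ref/tau) * (R (x) e^{-t/tau}) per gate."""
        q = self.tau_ref * self.R
        if abs(tau - self.tau_ref) > 1e-12:
            q = q + (1.0 - self.tau_ref / tau) * self._conv(tau)
        if self._mode == "fine":
            return q
        if self._mode == "gated":
            # apply the boxcar gate-integration operator to the model
            cum = np.concatenate(
                [[0.0], np.cumsum(0.5 * (q[1:] + q[:-1]) * self._dt)]
            )
            edges = cum[self._edge_index]
            return np.diff(edges)
        return np.interp(self._midpoints, self.t, q)

    def shape(self, components: Sequence[tuple[float, float]]) -> np.ndarray:
        """Unit-sum predicted gate shape for an amplitude-fraction mixture."""
        q = np.zeros(self.gate_delays.size)
        beta_total = 0.0
        for beta, tau in components:
            if not tau > 0:
                raise ValueError("all lifetimes must be > 0")
            q += beta * self._component_at_gates(float(tau))
            beta_total += beta
        if abs(beta_total - 1.0) > 1e-6:
            raise ValueError("mixture fractions must sum to 1")
        q = np.clip(q, 0.0, None)
        total = q.sum()
        if total <= 0:
            raise ValueError("model shape vanishes on the gate schedule")
        return q / total

    def shape_grid(self, taus: np.ndarray) -> np.ndarray:
        """Unit-sum mono-exponential shapes for many lifetimes, (G, K)."""
        taus = np.asarray(taus, dtype=float)
        out = np.empty((self.gate_delays.size, taus.size))
        for j, tau in enumerate(taus):
            q = np.clip(self._component_at_gates(float(tau)), 0.0, None)
            out[:, j] = q / q.sum()
        return out


def reconvolved_model(
    components: Sequence[tuple[float, float]],
    amplitude: float,
    reference: ReferenceDecay,
    dt_target_ps: float = 10.0,
) -> np.ndarray:
    """Predicted counts per gate for a mixture, via reference reconvolution.

    ``components`` is a sequence of ``(beta_i, tau_i_ps)`` amplitude
    fractions (summing to 1); ``amplitude`` is the total predicted count
    over the gate schedule.
    """
    engine = ReconvolutionEngine(reference, dt_target_ps)
    return amplitude * engine.shape(components)


# ---------------------------------------------------------------------------
# mono-exponential fitting
# ---------------------------------------------------------------------------


def tail_slope_tau(counts: np.ndarray, gate_delays: np.ndarray) -> float:
    """Deterministic lifetime initialiser from the log-linear tail slope.

    Regresses log counts against delay over the last half of the gates
    (positive counts only); falls back to 2000 ps when fewer than two
    usable gates remain or the slope is non-negative.
    """
    n = counts.size
    tail = slice(n // 2, n)
    y = counts[tail].astype(float)
    t = gate_delays[tail]
    good = y > 0
    if good.sum() < 2:
        return 2000.0
    slope = np.polyfit(t[good], np.log(y[good]), 1)[0]
    if slope >= 0:
        return 2000.0
    return float(np.clip(-1.0 / slope, 100.0, 2e4))


def _weights(counts: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(counts, 1.0)


def fit_monoexp(
    counts: np.ndarray,
    reference: ReferenceDecay,
    init_tau_ps: float | None = None,
    engine: ReconvolutionEngine | None = None,
) -> MonoExpFit:
    """Weighted NLLS mono-exponential fit of one gated decay.

    Minimises ``sum_k (y_k - A s_k(tau))^2 / max(y_k, 1)`` over
    ``(tau, A)`` (both log-parameterised, Levenberg-Marquardt), where
    ``s(tau)`` is the unit-sum reconvolved shape.  All-zero decays and
    iteration-cap failures return ``converged=False`` with ``tau`` NaN.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 3:
        raise ValueError("mono-exponential fitting needs at least 3 gates")
    if counts.size != reference.n_gates:
        raise ValueError("decay and reference gate counts differ")
    total = counts.sum()
    if total <= 0:
        return MonoExpFit(np.nan, 0.0, np.nan, 0.0, converged=False)
    if engine is None:
        engine = ReconvolutionEngine(reference)
    if init_tau_ps is None:
        init_tau_ps = tail_slope_tau(counts, reference.gate_delays_ps)
    m = engine.fit_mask
    y_m = counts[m]
    w_sqrt = np.sqrt(_weights(y_m))

    def residuals(x):
        tau, amp = np.exp(x)
        s = engine.shape([(1.0, tau)])[m]
        return (y_m - amp * s) * w_sqrt

    try:
        res = least_squares(
            residuals,
            x0=np.log([init_tau_ps, total]),
            method="lm",
            xtol=1e-10,
            ftol=1e-10,
            max_nfev=200 * 4,
        )
    except Exception:
        return MonoExpFit(np.nan, 0.0, np.nan, total, converged=False)
    tau, amp = np.exp(res.x)
    dof = max(int(m.sum()) - 2, 1)
    chi2 = float(2.0 * res.cost / dof)
    ok = bool(res.success) and np.isfinite(tau) and 1.0 < tau < 1e6
    return MonoExpFit(float(tau) if ok else np.nan, float(amp), chi2, float(total), ok)


def _default_tau_grid() -> np.ndarray:
    return np.geomspace(250.0, 9000.0, 180)


def fit_pixelwise(
    stack: GatedStack,
    reference: ReferenceDecay,
    threshold: float = 200.0,
    tau_grid: np.ndarray | None = None,
    engine: ReconvolutionEngine | None = None,
) -> LifetimeImage:
    """Pixel-wise mono-exponential lifetime image.

    Every pixel whose summed counts reach ``threshold`` (and are > 0) is
    fitted; the rest are NaN.  For throughput the per-pixel fit uses
    variable projection: the amplitude is profiled out analytically for
    each lifetime on a dense logarithmic grid and the weighted chi^2
    minimum is polished by parabolic interpolation in log-lifetime,
    which agrees with the Levenberg-Marquardt path to well below the
    shot-noise scatter.
    """
    if not reference.matches_schedule(stack):
        raise ValueError("stack and reference gate schedules differ")
    if engine is None:
        engine = ReconvolutionEngine(reference)
    if tau_grid is None:
        tau_grid = _default_tau_grid()
    photon_map = stack.photon_image().astype(float)
    mask = (photon_map >= threshold) & (photon_map > 0)
    h, w = stack.frame_shape
    tau_map = np.full((h, w), np.nan)
    chi2_map = np.full((h, w), np.nan)
    if not mask.any():
        return LifetimeImage(tau_map, photon_map, threshold, chi2_map, no_pixels_flag=True)

    gm = engine.fit_mask
    Y = stack.counts[:, mask].astype(float)[gm]  # (G_fit, P)
    W = _weights(Y)
    base = (W * Y * Y).sum(axis=0)  # (P,)
    S = engine.shape_grid(tau_grid)[gm]  # (G_fit, K)
    WY = W * Y
    K = tau_grid.size
    gain = np.empty((K, Y.shape[1]))
    for j in range(K):
        s = S[:, j][:, None]
        num = (WY * s).sum(axis=0)
        den = (W * s * s).sum(axis=0)
        gain[j] = num * num / den
    chi2 = base[None, :] - gain  # (K, P)
    best = np.argmin(chi2, axis=0)

    # parabolic refinement in log-tau around the grid minimum
    log_tau = np.log(tau_grid)
    inner = np.clip(best, 1, K - 2)
    c0 = chi2[inner - 1, np.arange(best.size)]
    c1 = chi2[inner, np.arange(best.size)]
    c2 = chi2[inner + 1, np.arange(best.size)]
    denom = c0 - 2 * c1 + c2
    shift = np.where(denom > 0, 0.5 * (c0 - c2) / np.maximum(denom, 1e-300), 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    dlog = log_tau[1] - log_tau[0]
    tau_best = np.exp(log_tau[inner] + shift * dlog)
    chi2_best = np.where(denom > 0, c1 - 0.125 * (c0 - c2) ** 2 / np.maximum(denom, 1e-300), c1)

    dof = max(int(gm.sum()) - 2, 1)
    tau_map[mask] = tau_best
    chi2_map[mask] = chi2_best / dof
    return LifetimeImage(tau_map, photon_map, threshold, chi2_map)


def fit_roi_binned(
    stack: GatedStack,
    reference: ReferenceDecay,
    roi_mask: np.ndarray,
    engine: ReconvolutionEngine | None = None,
) -> MonoExpFit:
    """Bin the time-resolved data over an ROI, then fit once.

    Summing counts over all ROI pixels per gate before fitting trades
    spatial resolution for photon statistics (the near-membrane ROIs of
    the assay typically pool on the order of a thousand pixels).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    if not reference.matches_schedule(stack):
        raise ValueError("stack and reference gate schedules differ")
    decay = stack.binned_decay(roi_mask)
    fit = fit_monoexp(decay, reference, engine=engine)
    fit.n_pixels = int(roi_mask.sum())
    return fit


# ---------------------------------------------------------------------------
# global binning (population-fraction estimation)
# ---------------------------------------------------------------------------


def _fit_biexp_fixed_tau1(
    counts: np.ndarray,
    engine: ReconvolutionEngine,
    tau1: float,
    fit_tau2: bool,
    tau2_fixed: float | None = None,
) -> BiExpFit:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return BiExpFit(tau1, np.nan, np.nan, 0.0, np.nan, converged=False)
    gm = engine.fit_mask
    y_m = counts[gm]
    w_sqrt = np.sqrt(_weights(y_m))

    def model(tau2, beta1, amp):
        s = engine.shape([(beta1, tau1), (1.0 - beta1, tau2)])[gm]
        return amp * s

    if fit_tau2:
        def residuals(x):
            tau2 = np.exp(x[0])
            beta1 = x[1]
            amp = np.exp(x[2])
            return (y_m - model(tau2, beta1, amp)) * w_sqrt

        x0 = [np.log(max(tau1 * 0.25, 10.0)), 0.5, np.log(total)]
        bounds = ([np.log(10.0), 0.0, np.log(total) - 20],
                  [np.log(tau1), 1.0, np.log(total) + 20])
        res = least_squares(residuals, x0=x0, bounds=bounds, method="trf",
                            xtol=1e-12, ftol=1e-12, max_nfev=2000)
        tau2 = float(np.exp(res.x[0]))
        beta1 = float(res.x[1])
        amp = float(np.exp(res.x[2]))
    else:
        assert tau2_fixed is not None
        tau2 = float(tau2_fixed)

        def residuals(x):
            beta1 = x[0]
            amp = np.exp(x[1])
            return (y_m - model(tau2, beta1, amp)) * w_sqrt

        res = least_squares(residuals, x0=[0.5, np.log(total)],
                            bounds=([0.0, np.log(total) - 20], [1.0, np.log(total) + 20]),
                            method="trf", xtol=1e-12, ftol=1e-12, max_nfev=2000)
        beta1 = float(res.x[0])
        amp = float(np.exp(res.x[1]))
    n_params = 3 if fit_tau2 else 2
    dof = max(int(gm.sum()) - n_params, 1)
    chi2 = float(2.0 * res.cost / dof)
    beta1 = float(np.clip(beta1, 0.0, 1.0))
    return BiExpFit(
        tau1_ps=tau1,
        tau2_ps=tau2,
        beta1=beta1,
        amplitude=amp,
        chi2_reduced=chi2,
        converged=bool(res.success),
        beta1_at_boundary=beta1 <= 1e-9 or beta1 >= 1.0 - 1e-9,
        degenerate=abs(tau2 - tau1) < DEGENERACY_GUARD_PS,
    )


def fit_global_binned(
    decays_by_condition: Mapping[str, np.ndarray],
    reference: ReferenceDecay,
    tau1_fixed_ps: float,
    engine: ReconvolutionEngine | None = None,
) -> GlobalBinningResult:
    """Two-step global analysis of pooled decays.

    Step 1 pools the per-condition decays across the whole series and
    fits the bi-exponential model with tau1 fixed (tau1 is taken from a
    mono-exponential fit of the positive-control wells, the non-FRETing
    donor lifetime), yielding the shared FRET lifetime tau2.  Step 2
    holds both lifetimes fixed and fits only the long-lifetime fraction
    beta1 (and amplitude) per condition.  beta1 is clamped to [0, 1]
    with a boundary flag; tau2 is flagged unidentifiable when the pooled
    beta1 sits at the single-component boundary or tau2 collapses onto
    tau1 within the degeneracy guard.
    """
    if len(decays_by_condition) < 2:
        raise ValueError("global binning needs at least 2 conditions")
    if not tau1_fixed_ps > 0:
        raise ValueError("tau1_fixed_ps must be > 0")
    if engine is None:
        engine = ReconvolutionEngine(reference)
    decays = {k: np.asarray(v, dtype=float) for k, v in decays_by_condition.items()}
    pooled = np.sum([v for v in decays.values()], axis=0)
    pooled_fit = _fit_biexp_fixed_tau1(pooled, engine, tau1_fixed_ps, fit_tau2=True)
    # Likelihood-ratio guard: if the second component does not improve on
    # a single-exponential at tau1 by more than a chi-square(2) quantile,
    # the data are effectively mono-exponential and tau2 is meaningless.
    gm = engine.fit_mask
    s1 = engine.shape([(1.0, tau1_fixed_ps)])[gm]
    y1 = pooled[gm]
    w1 = _weights(y1)
    amp1 = (w1 * y1 * s1).sum() / (w1 * s1 * s1).sum()
    chi2_mono = (w1 * (y1 - amp1 * s1) ** 2).sum()
    chi2_bi = pooled_fit.chi2_reduced * max(int(gm.sum()) - 3, 1)
    unidentifiable = (
        not pooled_fit.converged
        or pooled_fit.degenerate
        or pooled_fit.beta1 >= 0.99
        or chi2_mono - chi2_bi < 9.0
    )
    if unidentifiable:
        # data indistinguishable from a single exponential at tau1:
        # report the mono-exponential interpretation (beta1 = 1)
        condition_fits = {}
        for cond, decay in decays.items():
            y = decay[gm]
            w = _weights(y)
            amp = (w * y * s1).sum() / max((w * s1 * s1).sum(), 1e-300)
            chi2 = (w * (y - amp * s1) ** 2).sum() / max(int(gm.sum()) - 2, 1)
            condition_fits[cond] = BiExpFit(
                tau1_ps=tau1_fixed_ps,
                tau2_ps=pooled_fit.tau2_ps,
                beta1=1.0,
                amplitude=float(amp),
                chi2_reduced=float(chi2),
                converged=True,
                beta1_at_boundary=True,
                degenerate=True,
            )
    else:
        condition_fits = {
            cond: _fit_biexp_fixed_tau1(
                decay, engine, tau1_fixed_ps, fit_tau2=False, tau2_fixed=pooled_fit.tau2_ps
            )
            for cond, decay in decays.items()
        }
    return GlobalBinningResult(
        tau1_ps=tau1_fixed_ps,
        tau2_ps=pooled_fit.tau2_ps,
        tau2_unidentifiable=unidentifiable,
        pooled_fit=pooled_fit,
        condition_fits=condition_fits,
    )


def tau2_replicate_sd(
    replicate_decays: Sequence[Mapping[str, np.ndarray]],
    reference: ReferenceDecay,
    tau1_fixed_ps: float,
) -> tuple[np.ndarray, float]:
    """Spread of tau2 across replicate groups (e.g. plate rows).

    Refits the global model within each replicate group and returns the
    per-replicate tau2 values together with their sample standard
    deviation — the uncertainty convention used for the shared FRET
    lifetime.
    """
    engine = ReconvolutionEngine(reference)
    taus = []
    for group in replicate_decays:
        result = fit_global_binned(group, reference, tau1_fixed_ps, engine=engine)
        taus.append(result.tau2_ps)
    taus = np.asarray(taus)
    sd = float(np.std(taus, ddof=1)) if taus.size > 1 else np.nan
    return taus, sd
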