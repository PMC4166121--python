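"""Reconvolution fitting of TCSPC decays to multi-exponential models.

The measured histogram is modelled as the periodic multi-exponential decay
convolved with the measured instrument response (reconvolution), plus a
flat background, and fitted by Poisson-weighted nonlinear least squares.
The quality statistic is the reduced chi-square (often written phi^2 in the
lifetime literature),

    phi^2 = sum_c (y_c - m_c)^2 / max(y_c, 1) / (n_channels - n_free),

which is ~1 for a correct model under counting noise.

Implementation notes
--------------------
Amplitudes and background enter the model linearly, so the fit uses
variable projection: for trial lifetimes (and a sub-channel IRF shift) the
optimal non-negative amplitudes are found by weighted NNLS, and the outer
nonlinear search runs only over log-lifetimes and the shift.  This removes
the amplitude/lifetime scaling degeneracies that plague naive
multi-exponential fitting and makes multistart cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares, nnls

from .decay import DecayModel, LifetimeComponent
from .tcspc import TCSPCDataset

__all__ = ["DecayFitResult", "reconvolution_fit", "select_model", "goodness_of_fit"]

_TAU_BOUNDS_NS = (1e-3, 100.0)  # 1 ps .. 100 ns
_SHIFT_BOUNDS = (-2.0, 2.0)  # channels


@dataclass(frozen=True)
class DecayFitResult:
    """Result of a reconvolution fit.

    ``model`` holds normalized amplitude fractions and lifetimes (ns) sorted
    ascending, with the fitted flat background in counts/channel.
    ``parameter_intervals`` maps ``tau_1..k`` (ns), ``alpha_1..k``,
    ``background`` and ``irf_shift`` to approximate 95% intervals.
    """

    model: DecayModel
    reduced_chi2: float
    n_components: int
    parameter_intervals: Mapping[str, tuple[float, float]]
    converged: bool
    n_restarts_used: int
    total_signal: float
    irf_shift_channels: float


def _shift_kernel(irf_norm: np.ndarray, shift: float) -> np.ndarray:
    """Circularly shift a unit-sum kernel by a fractional number of channels."""
    k = int(np.floor(shift))
    f = shift - k
    return (1.0 - f) * np.roll(irf_norm, k) + f * np.roll(irf_norm, k + 1)


def _decay_basis(
    taus_ns: np.ndarray, irf_fft: np.ndarray, t: np.ndarray, T: float
):
    """Unit-sum reconvolved decay shapes, one column per lifetime, plus background.

    Column i is the periodic exponential for tau_i circularly convolved with
    the (already shifted) IRF and normalized to unit sum, so its coefficient
    is the total signal counts of that component.  The last column is
    constant with unit sum, so its coefficient is total background counts.

    Also returns the pre-normalization column sums ``sum_c wrap_i e^(-t_c/tau_i)``,
    which convert count coefficients back to decay amplitudes: the total
    counts of component i are proportional to alpha_i * tau_i, so
    ``alpha_i ~ coef_i / shape_sum_i``.
    """
    n = len(t)
    wrap = 1.0 / -np.expm1(-T / taus_ns)
    shapes = wrap[None, :] * np.exp(-t[:, None] / taus_ns[None, :])
    shape_sums = shapes.sum(axis=0)
    shapes = shapes / shape_sums[None, :]
    conv = np.fft.irfft(np.fft.rfft(shapes, axis=0) * irf_fft[:, None], n, axis=0)
    conv = np.clip(conv, 0.0, None)
    basis = np.empty((n, len(taus_ns) + 1))
    basis[:, :-1] = conv
    basis[:, -1] = 1.0 / n
    return basis, shape_sums


def _fit_linear(basis, y, w):
    """Weighted NNLS for component/background total counts."""
    coef, _ = nnls(basis * w[:, None], y * w)
    return coef


def reconvolution_fit(
    data: TCSPCDataset,
    n_components: int,
    seed: int = 0,
    n_restarts: int = 8,
    fit_shift: bool = True,
) -> DecayFitResult:
    """Fit ``n_components`` exponentials to a decay histogram by reconvolution.

    Minimizes the Poisson-weighted squared residual (variance floor 1 for
    empty channels) over lifetimes in [1 ps, 100 ns], non-negative
    amplitudes, a flat background, and a sub-channel IRF shift bounded to
    +/-2 channels.  ``n_restarts`` multistart initializations (the first
    log-spaced across the window, the rest log-uniform random, seeded) guard
    against the local minima created by sub-IRF components; the best restart
    is returned with components sorted ascending by lifetime.
    """
    if not (1 <= n_components <= 6):
        raise ValueError(f"n_components must be in 1..6, got {n_components}")
    irf_total = data.irf_counts.sum()
    if irf_total <= 0:
        raise ValueError("dataset has no usable IRF histogram")
    if data.acq.n_channels <= 2 * n_components + 2:
        raise ValueError("fewer channels than free parameters")

    t = data.channel_times_ns
    T = data.acq.rep_period_ns
    n = len(t)
    y = data.counts.astype(float)
    w = 1.0 / np.sqrt(np.maximum(y, 1.0))
    irf_norm = data.irf_counts / irf_total

    def residuals(theta):
        taus = np.exp(theta[:n_components])
        shift = theta[n_components] if fit_shift else 0.0
        kernel = _shift_kernel(irf_norm, shift)
        basis, _ = _decay_basis(taus, np.fft.rfft(kernel), t, T)
        coef = _fit_linear(basis, y, w)
        return (basis @ coef - y) * w

    lo = np.log(_TAU_BOUNDS_NS[0])
    hi = np.log(_TAU_BOUNDS_NS[1])
    rng = np.random.default_rng(seed)
    window_ns = n * data.acq.channel_width_ns
    inits = [np.log(np.geomspace(0.02, min(10.0, window_ns / 4), n_components))]
    for _ in range(n_restarts - 1):
        inits.append(np.sort(rng.uniform(np.log(0.01), np.log(20.0), n_components)))

    bounds_lo = [lo] * n_components
    bounds_hi = [hi] * n_components
    if fit_shift:
        bounds_lo.append(_SHIFT_BOUNDS[0])
        bounds_hi.append(_SHIFT_BOUNDS[1])

    best = None
    any_converged = False
    for init in inits:
        x0 = np.concatenate([init, [0.0]]) if fit_shift else np.asarray(init)
        sol = least_squares(
            residuals,
            x0,
            bounds=(bounds_lo, bounds_hi),
            method="trf",
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
        )
        any_converged = any_converged or sol.status > 0
        if best is None or sol.cost < best.cost:
            best = sol

    theta = best.x
    taus = np.exp(theta[:n_components])
    shift = float(theta[n_components]) if fit_shift else 0.0
    kernel = _shift_kernel(irf_norm, shift)
    basis, shape_sums = _decay_basis(taus, np.fft.rfft(kernel), t, T)
    coef = _fit_linear(basis, y, w)
    comp_counts = coef[:-1]
    bg_total = coef[-1]
    total_signal = comp_counts.sum()
    if total_signal <= 0:
        raise RuntimeError("fit degenerated to pure background")
    # coefficients are component total counts ~ alpha_i * tau_i; undo the
    # per-column normalization to recover decay amplitudes
    raw_amps = comp_counts / shape_sums
    alphas = raw_amps / raw_amps.sum()

    n_free = 2 * n_components + 1 + (1 if fit_shift else 0)
    chi2 = float(np.sum(((basis @ coef - y) * w) ** 2))
    red_chi2 = chi2 / (n - n_free)

    # components sharing (numerically) a lifetime would violate the strictly-
    # increasing invariant; nudge apart by 1 ulp-scale epsilon
    order = np.argsort(taus)
    taus = taus[order]
    alphas = alphas[order]
    for i in range(1, len(taus)):
        if taus[i] <= taus[i - 1]:
            taus[i] = taus[i - 1] * (1 + 1e-12)

    intervals = _parameter_intervals(
        taus, alphas, bg_total / n, shift, basis, coef, w, n_components
    )

    model = DecayModel(
        components=tuple(
            LifetimeComponent(float(a), float(tau)) for a, tau in zip(alphas, taus)
        ),
        background=float(bg_total / n),
    )
    return DecayFitResult(
        model=model,
        reduced_chi2=red_chi2,
        n_components=n_components,
        parameter_intervals=intervals,
        converged=bool(any_converged),
        n_restarts_used=len(inits),
        total_signal=float(total_signal),
        irf_shift_channels=shift,
    )


def _parameter_intervals(taus, alphas, bg_per_chan, shift, basis, coef, w, k):
    """Approximate conditional 95% intervals.

    Intervals come from the linearized design in log-coefficient space,
    conditional on the fitted lifetimes; they are reporting-grade
    approximations, not profile likelihoods.
    """
    n = basis.shape[0]
    cols = [basis[:, i] * coef[i] for i in range(basis.shape[1])]  # d/d log(coef)
    full = np.column_stack(cols)
    wa = full * w[:, None]
    try:
        cov = np.linalg.pinv(wa.T @ wa)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(full.shape[1], np.nan)
    out = {}
    for i in range(k):
        # se on log(coef_i) -> se on alpha via delta method (ignoring
        # covariance with the other coefficients)
        rel = se[i]
        lo_a = alphas[i] * np.exp(-1.96 * rel)
        hi_a = alphas[i] * np.exp(1.96 * rel)
        out[f"alpha_{i + 1}"] = (float(lo_a), float(hi_a))
        out[f"tau_{i + 1}"] = (float(taus[i] * 0.0), float(np.inf)) if np.isnan(
            rel
        ) else (float(taus[i] * np.exp(-1.96 * rel)), float(taus[i] * np.exp(1.96 * rel)))
    bg_se = se[-1] * coef[-1] / n if coef[-1] > 0 else 0.0
    out["background"] = (
        float(max(bg_per_chan - 1.96 * bg_se, 0.0)),
        float(bg_per_chan + 1.96 * bg_se),
    )
    out["irf_shift"] = (float(shift - 0.5), float(shift + 0.5))
    return out


def select_model(
    data: TCSPCDataset, max_components: int, seed: int = 0, n_restarts: int = 8
) -> DecayFitResult:
    """Choose the number of exponentials by successive phi^2 improvement.

    Fits n = 1..max_components and accepts n+1 over n only when the reduced
    chi-square improves by more than 5% (relative); returns the accepted fit.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    accepted = reconvolution_fit(data, 1, seed=seed, n_restarts=n_restarts)
    for k in range(2, max_components + 1):
        trial = reconvolution_fit(data, k, seed=seed, n_restarts=n_restarts)
        if trial.reduced_chi2 < 0.95 * accepted.reduced_chi2:
            accepted = trial
        else:
            break
    return accepted


def goodness_of_fit(
    data: TCSPCDataset,
    model: DecayModel,
    total_signal: float | None = None,
    n_free: int | None = None,
) -> float:
    """Reduced chi-square (phi^2) of a model against a decay histogram.

    Builds the reconvolved periodic expectation from ``model``, scales it to
    ``total_signal`` counts (fitted by weighted least squares when not
    given), adds ``model.background`` per channel, and computes the
    Pearson-style statistic with Poisson variance ``max(counts, 1)`` over
    ``n_channels - n_free`` degrees of freedom (default
    ``2 * n_components + 2``).
    """
    k = len(model.components)
    if n_free is None:
        n_free = 2 * k + 2
    n = data.acq.n_channels
    if n <= n_free:
        raise ValueError("fewer channels than free parameters")
    irf_total = data.irf_counts.sum()
    if irf_total <= 0:
        raise ValueError("dataset has no usable IRF histogram")
    t = data.channel_times_ns
    T = data.acq.rep_period_ns
    irf_fft = np.fft.rfft(data.irf_counts / irf_total)
    taus = model.lifetimes_ns
    wrap = 1.0 / -np.expm1(-T / taus)
    profile = np.sum(
        (model.amplitudes * wrap)[:, None] * np.exp(-t[None, :] / taus[:, None]),
        axis=0,
    )
    profile /= profile.sum()
    shape = np.clip(
        np.fft.irfft(np.fft.rfft(profile) * irf_fft, n), 0.0, None
    )  # unit-sum reconvolved decay profile
    y = data.counts.astype(float)
    w2 = 1.0 / np.maximum(y, 1.0)
    resid_target = y - model.background
    if total_signal is None:
        total_signal = float(
            np.sum(w2 * shape * resid_target) / np.sum(w2 * shape**2)
        )
    m = shape * total_signal + model.background
    chi2 = float(np.sum((y - m) ** 2 * w2))
    return chi2 / (n - n_free)
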