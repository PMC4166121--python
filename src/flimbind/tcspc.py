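"""Synthetic TCSPC decay histograms: periodic excitation, IRF, Poisson noise.

Time-correlated single-photon counting under a pulsed laser at repetition
period ``T`` accumulates a histogram of photon arrival times over one
period.  A component with lifetime ``tau`` comparable to ``T`` keeps
emitting when the next pulse arrives, so the per-period expectation is the
geometric sum of all prior-pulse tails,

    E(t) ~ sum_i alpha_i exp(-t/tau_i) / (1 - exp(-T/tau_i)),  0 <= t < T,

convolved (circularly, because the wrapped tail re-enters the window) with
the instrument response function, and finally Poisson-sampled per channel.
The IRF is measured as a scattering reference and carries its own counting
noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .decay import DecayModel

__all__ = [
    "IRFSpec",
    "AcquisitionConfig",
    "TCSPCDataset",
    "periodic_decay_expectation",
    "irf_expectation",
    "convolve_irf",
    "sample_counts",
    "generate_dataset",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class IRFSpec:
    """Gaussian instrument response: ``fwhm_ps`` width, ``center_ns`` position."""

    fwhm_ps: float = 200.0
    center_ns: float = 2.0
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.shape != "gaussian":
            raise ValueError(f"unsupported IRF shape {self.shape!r}")
        if not (self.fwhm_ps > 0):
            raise ValueError(f"fwhm_ps must be > 0, got {self.fwhm_ps}")
        if self.center_ns < 0:
            raise ValueError(f"center_ns must be >= 0, got {self.center_ns}")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Histogram geometry and photon budget.

    Defaults model a 20 MHz pulsed diode (50 ns period) binned into 4096
    channels of 12.2 ps, 1e7 total photons with 0.1% flat background, and a
    1e6-count scattering reference for the IRF.
    """

    n_channels: int = 4096
    channel_width_ps: float = 12.2
    rep_period_ns: float = 50.0
    total_counts: float = 1.0e7
    background_fraction: float = 1.0e-3
    irf_total_counts: float = 1.0e6

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be positive")
        if self.n_channels * self.channel_width_ps > self.rep_period_ns * 1000.0:
            raise ValueError(
                "acquisition window exceeds one repetition period: "
                f"{self.n_channels * self.channel_width_ps / 1000.0:.3f} ns > "
                f"{self.rep_period_ns} ns"
            )
        if not (self.total_counts > 0):
            raise ValueError("total_counts must be > 0")
        if not (0 <= self.background_fraction < 1):
            raise ValueError("background_fraction must be in [0, 1)")

    @property
    def channel_width_ns(self) -> float:
        return self.channel_width_ps / 1000.0

    @property
    def channel_times_ns(self) -> np.ndarray:
        """Bin-center times in ns."""
        return (np.arange(self.n_channels) + 0.5) * self.channel_width_ns


@dataclass(frozen=True)
class TCSPCDataset:
    """A measured (or simulated) decay histogram with its scattering reference."""

    channel_times_ns: np.ndarray
    counts: np.ndarray
    irf_counts: np.ndarray
    acq: AcquisitionConfig
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("channel_times_ns", "counts", "irf_counts"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (
            len(self.channel_times_ns) == len(self.counts) == len(self.irf_counts)
        ):
            raise ValueError("channel_times, counts and irf_counts lengths differ")
        for name in ("counts", "irf_counts"):
            arr = getattr(self, name)
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError(f"{name} must be integer-valued")


def periodic_decay_expectation(
    model: DecayModel, acq: AcquisitionConfig
) -> np.ndarray:
    """Expected counts per channel before IRF convolution and noise.

    The multi-exponential shape includes the wraparound factor
    ``1/(1 - exp(-T/tau))`` for re-excitation every repetition period ``T``,
    is scaled so the signal totals ``total_counts * (1 - background_fraction)``,
    and a uniform background of ``total_counts * background_fraction`` is added.
    """
    if not isinstance(model, DecayModel):
        raise TypeError(f"model must be a DecayModel, got {type(model).__name__}")
    taus = model.lifetimes_ns
    slow = taus[taus >= 10.0 * acq.rep_period_ns]
    if slow.size:
        warnings.warn(
            f"lifetimes {slow.tolist()} ns are >= 10x the repetition period "
            f"({acq.rep_period_ns} ns); the wrapped decay is nearly flat and "
            "ill-conditioned to fit",
            stacklevel=2,
        )
    t = acq.channel_times_ns
    alphas = model.amplitudes
    wrap = 1.0 / -np.expm1(-acq.rep_period_ns / taus)
    shape = np.sum(
        (alphas * wrap)[:, None] * np.exp(-t[None, :] / taus[:, None]), axis=0
    )
    signal_total = acq.total_counts * (1.0 - acq.background_fraction)
    expected = shape * (signal_total / shape.sum())
    expected += acq.total_counts * acq.background_fraction / acq.n_channels
    return expected


def irf_expectation(irf: IRFSpec, acq: AcquisitionConfig) -> np.ndarray:
    """Discretized IRF profile over the window, normalized to unit sum.

    The Gaussian is wrapped periodically so that unit area is preserved even
    when the center sits near a window edge.
    """
    t = acq.channel_times_ns
    sigma = irf.fwhm_ps * _FWHM_TO_SIGMA / 1000.0
    window = acq.n_channels * acq.channel_width_ns
    if irf.center_ns > window:
        raise ValueError(
            f"IRF center {irf.center_ns} ns outside acquisition window {window} ns"
        )
    # wrap +/- 1 period; the Gaussian is negligible further out
    prof = np.zeros(acq.n_channels)
    for k in (-1, 0, 1):
        prof += np.exp(-0.5 * ((t - irf.center_ns + k * window) / sigma) ** 2)
    return prof / prof.sum()


def convolve_irf(expected: np.ndarray, irf, acq: AcquisitionConfig | None = None):
    """Circular convolution of a per-channel expectation with the IRF.

    ``irf`` is either an :class:`IRFSpec` (requires ``acq``) or a measured
    histogram, which is normalized to unit sum so total counts are preserved.
    Convolution is periodic over the window, consistent with wrapped
    re-excitation.
    """
    expected = np.asarray(expected, dtype=float)
    if isinstance(irf, IRFSpec):
        if acq is None:
            raise ValueError("acq is required when irf is an IRFSpec")
        kernel = irf_expectation(irf, acq)
    else:
        kernel = np.asarray(irf, dtype=float)
        total = kernel.sum()
        if total <= 0:
            raise ValueError("IRF histogram has zero area")
        kernel = kernel / total
    if kernel.shape != expected.shape:
        raise ValueError("IRF and expectation lengths differ")
    n = len(expected)
    out = np.fft.irfft(np.fft.rfft(expected) * np.fft.rfft(kernel), n)
    # FFT round-off can leave tiny negatives in empty channels
    return np.clip(out, 0.0, None)


def sample_counts(expected: np.ndarray, seed) -> np.ndarray:
    """Independent Poisson draw per channel; reproducible given the seed."""
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expectation must be non-negative")
    rng = np.random.default_rng(seed)
    return rng.poisson(expected)


def generate_dataset(
    model: DecayModel,
    irf: IRFSpec | None = None,
    acq: AcquisitionConfig | None = None,
    seed: int = 0,
) -> TCSPCDataset:
    """Simulate one TCSPC acquisition: decay histogram plus IRF reference.

    The decay expectation is IRF-convolved then Poisson-sampled; the IRF
    reference is an independent Poisson sample of the IRF profile scaled to
    ``irf_total_counts``.  The two draws use decorrelated substreams of
    ``seed``.
    """
    irf = irf or IRFSpec()
    acq = acq or AcquisitionConfig()
    expected = periodic_decay_expectation(model, acq)
    expected = convolve_irf(expected, irf, acq)
    seq = np.random.SeedSequence(seed).spawn(2)
    counts = sample_counts(expected, seq[0])
    irf_counts = sample_counts(irf_expectation(irf, acq) * acq.irf_total_counts, seq[1])
    return TCSPCDataset(
        channel_times_ns=acq.channel_times_ns,
        counts=counts,
        irf_counts=irf_counts,
        acq=acq,
        meta={"seed": seed, "irf": irf, "model": model},
    )
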