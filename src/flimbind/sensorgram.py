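"""Synthetic sensorgram generation for BLI and SPR single-cycle experiments.

Emulates two label-free biosensing layouts:

* BLI: one sensor per analyte concentration, each run through an
  association phase in analyte followed by a buffer-only dissociation
  phase, simulated from the 1:1 model;
* SPR single-cycle kinetics: one continuous trace over sequential
  ascending injections on the same surface with no regeneration, ending in
  a long dissociation, simulated from the two-state sequential model.

Measurement error is additive i.i.d. Gaussian noise per time point plus an
optional linear baseline drift; photophysics-free, as appropriate for
refractive-index/interferometric readouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .binding import (
    InjectionSchedule,
    SingleStateParams,
    TwoStateParams,
    bli_schedule,
    single_cycle_schedule,
    single_state_response,
    two_state_response,
)

__all__ = ["Sensorgram", "SensorgramSet", "generate_bli_set", "generate_spr_single_cycle"]

DEFAULT_SAMPLE_INTERVAL_S = 1.0


@dataclass(frozen=True)
class Sensorgram:
    """One time/response trace with its injection schedule."""

    time_s: np.ndarray
    response_ru: np.ndarray
    schedule: InjectionSchedule
    concentration_M: float
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_s", np.asarray(self.time_s, dtype=float))
        object.__setattr__(
            self, "response_ru", np.asarray(self.response_ru, dtype=float)
        )
        if len(self.time_s) != len(self.response_ru):
            raise ValueError("time and response lengths differ")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.response_ru)):
            raise ValueError("response contains non-finite values")


@dataclass(frozen=True)
class SensorgramSet:
    """Sensorgrams sharing one kinetic ground truth.

    ``mode`` is ``"bli_multiconc"`` (one trace per concentration) or
    ``"spr_single_cycle"`` (a single multi-injection trace).
    """

    sensorgrams: tuple[Sensorgram, ...]
    mode: str
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sensorgrams:
            raise ValueError("sensorgram set is empty")
        if self.mode not in ("bli_multiconc", "spr_single_cycle"):
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "sensorgrams", tuple(self.sensorgrams))


def _time_grid(total_s: float, dt: float) -> np.ndarray:
    n = int(round(total_s / dt))
    return np.arange(n + 1) * dt


def generate_bli_set(
    params: SingleStateParams,
    concentrations_M: Sequence[float],
    assoc_s: float = 180.0,
    dissoc_s: float = 180.0,
    noise_sd: float | None = None,
    drift_ru_per_s: float = 0.0,
    sample_interval_s: float = DEFAULT_SAMPLE_INTERVAL_S,
    seed: int = 0,
) -> SensorgramSet:
    """Simulate a BLI multi-sensor series under the 1:1 model.

    One sensorgram per concentration (0 M gives the reference baseline);
    response = closed-form model + linear drift + N(0, noise_sd) per point.
    ``noise_sd`` defaults to 1% of rmax.  Each trace draws from its own
    substream of ``seed``.
    """
    if assoc_s <= 0 or dissoc_s <= 0:
        raise ValueError("phase durations must be positive")
    if noise_sd is None:
        noise_sd = 0.01 * params.rmax
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    streams = np.random.SeedSequence(seed).spawn(len(concentrations_M))
    traces = []
    for conc, stream in zip(concentrations_M, streams):
        schedule = bli_schedule(conc, assoc_s, dissoc_s)
        t = _time_grid(schedule.total_duration_s, sample_interval_s)
        r = single_state_response(params, schedule, t)
        r = r + drift_ru_per_s * t
        if noise_sd > 0:
            r = r + np.random.default_rng(stream).normal(0.0, noise_sd, len(t))
        traces.append(
            Sensorgram(
                time_s=t,
                response_ru=r,
                schedule=schedule,
                concentration_M=conc,
                meta={"noise_sd": noise_sd, "drift_ru_per_s": drift_ru_per_s},
            )
        )
    return SensorgramSet(
        sensorgrams=tuple(traces),
        mode="bli_multiconc",
        meta={"seed": seed, "params": params, "noise_sd": noise_sd},
    )


def generate_spr_single_cycle(
    params: TwoStateParams,
    concentrations_M: Sequence[float],
    contact_s: float = 120.0,
    final_dissoc_s: float = 600.0,
    noise_sd: float | None = None,
    sample_interval_s: float = DEFAULT_SAMPLE_INTERVAL_S,
    seed: int = 0,
) -> SensorgramSet:
    """Simulate an SPR single-cycle trace under the two-state model.

    One continuous trace over sequential injections (conventionally
    ascending; a non-ascending order is allowed but warned about) and a
    final buffer dissociation.  ``noise_sd`` defaults to 1% of rmax.
    """
    concs = list(concentrations_M)
    if any(b <= a for a, b in zip(concs, concs[1:])):
        warnings.warn(
            "single-cycle concentrations are not strictly ascending", stacklevel=2
        )
    if noise_sd is None:
        noise_sd = 0.01 * params.rmax
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    schedule = single_cycle_schedule(concs, contact_s, final_dissoc_s)
    t = _time_grid(schedule.total_duration_s, sample_interval_s)
    r = two_state_response(params, schedule, t)
    if noise_sd > 0:
        r = r + np.random.default_rng(np.random.SeedSequence(seed)).normal(
            0.0, noise_sd, len(t)
        )
    trace = Sensorgram(
        time_s=t,
        response_ru=r,
        schedule=schedule,
        concentration_M=max(concs),
        meta={"noise_sd": noise_sd, "concentrations_M": tuple(concs)},
    )
    return SensorgramSet(
        sensorgrams=(trace,),
        mode="spr_single_cycle",
        meta={"seed": seed, "params": params, "noise_sd": noise_sd},
    )
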