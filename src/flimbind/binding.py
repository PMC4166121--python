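"""Forward kinetic models for optical biosensing of CaM-eNOS binding.

Two reaction schemes cover the experiments:

* single-state 1:1 Langmuir binding, ``A + B <-> AB`` with rates ``k_on``
  (M^-1 s^-1) and ``k_off`` (s^-1), which has a piecewise closed-form
  response within each constant-concentration phase;
* the two-state sequential (induced-fit) scheme
  ``A + B <-> AB <-> AB*``, where the second step is a
  concentration-independent conformational change with rates ``k_on2`` and
  ``k_off2`` (both s^-1).  The overall dissociation constant couples both
  equilibria:

      K_D = (k_off1 / k_on1) * k_off2 / (k_off2 + k_on2).

Responses are in instrument response units (RU) with saturation amplitude
``rmax``; concentrations are molar throughout and only converted to nM/pM
at the reporting edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SingleStateParams",
    "TwoStateParams",
    "Phase",
    "InjectionSchedule",
    "bli_schedule",
    "single_cycle_schedule",
    "single_state_response",
    "two_state_response",
    "kd_single",
    "kd_two_state",
]


def _require_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if not (value > 0):
            raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class SingleStateParams:
    """1:1 binding rates: ``kon`` (M^-1 s^-1), ``koff`` (s^-1), ``rmax`` (RU)."""

    kon: float
    koff: float
    rmax: float

    def __post_init__(self) -> None:
        _require_positive(kon=self.kon, koff=self.koff, rmax=self.rmax)


@dataclass(frozen=True)
class TwoStateParams:
    """Sequential-model rates.

    ``kon1`` (M^-1 s^-1) and ``koff1`` (s^-1) govern the encounter complex;
    ``kon2`` and ``koff2`` (both s^-1) the concentration-independent
    conformational step; ``rmax`` (RU) the saturation response.
    """

    kon1: float
    koff1: float
    kon2: float
    koff2: float
    rmax: float

    def __post_init__(self) -> None:
        _require_positive(
            kon1=self.kon1,
            koff1=self.koff1,
            kon2=self.kon2,
            koff2=self.koff2,
            rmax=self.rmax,
        )


@dataclass(frozen=True)
class Phase:
    """One constant-concentration segment of an injection schedule."""

    duration_s: float
    conc_M: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.duration_s > 0):
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.conc_M < 0:
            raise ValueError(f"conc_M must be >= 0, got {self.conc_M}")


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered analyte injection phases; time starts at 0."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("schedule needs at least one phase")
        object.__setattr__(self, "phases", tuple(self.phases))

    @property
    def total_duration_s(self) -> float:
        return sum(p.duration_s for p in self.phases)

    @property
    def boundaries_s(self) -> np.ndarray:
        """Phase start/end times, length ``len(phases) + 1``, starting at 0."""
        return np.concatenate([[0.0], np.cumsum([p.duration_s for p in self.phases])])

    def to_dict(self) -> dict:
        return {
            "phases": [
                {"duration_s": p.duration_s, "conc_M": p.conc_M, "label": p.label}
                for p in self.phases
            ]
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "InjectionSchedule":
        return cls(
            phases=tuple(
                Phase(p["duration_s"], p["conc_M"], p.get("label", ""))
                for p in doc["phases"]
            )
        )

    @classmethod
    def from_json(cls, text: str) -> "InjectionSchedule":
        return cls.from_dict(json.loads(text))


def bli_schedule(
    conc_M: float, assoc_s: float = 180.0, dissoc_s: float = 180.0
) -> InjectionSchedule:
    """Association-then-dissociation schedule of one BLI sensor."""
    return InjectionSchedule(
        phases=(
            Phase(assoc_s, conc_M, "association"),
            Phase(dissoc_s, 0.0, "dissociation"),
        )
    )


def single_cycle_schedule(
    concentrations_M: Sequence[float],
    contact_s: float = 120.0,
    final_dissoc_s: float = 600.0,
) -> InjectionSchedule:
    """Single-cycle kinetics: sequential injections without regeneration,
    ending in a buffer-only dissociation phase."""
    phases = [
        Phase(contact_s, c, f"inject_{i + 1}")
        for i, c in enumerate(concentrations_M)
    ]
    phases.append(Phase(final_dissoc_s, 0.0, "dissociation"))
    return InjectionSchedule(phases=tuple(phases))


def _phase_index(schedule: InjectionSchedule, t_grid: np.ndarray) -> np.ndarray:
    bounds = schedule.boundaries_s
    if np.any(t_grid < -1e-9) or np.any(t_grid > bounds[-1] + 1e-9):
        raise ValueError(
            f"t_grid must lie within the schedule [0, {bounds[-1]}] s"
        )
    idx = np.searchsorted(bounds, t_grid, side="right") - 1
    return np.clip(idx, 0, len(schedule.phases) - 1)


def _piecewise_1to1(
    kon: float,
    koff: float,
    rmax: float,
    schedule: InjectionSchedule,
    t_grid: np.ndarray,
    r0: float,
) -> np.ndarray:
    """Closed-form 1:1 response for plain-float parameters (rmax may be 0,
    which yields the homogeneous decay of the initial response)."""
    idx = _phase_index(schedule, t_grid)
    bounds = schedule.boundaries_s
    kd = koff / kon

    out = np.empty_like(t_grid)
    r_start = r0
    for i, phase in enumerate(schedule.phases):
        c = phase.conc_M
        req = rmax * c / (c + kd)
        rate = kon * c + koff
        sel = idx == i
        dt = t_grid[sel] - bounds[i]
        out[sel] = req + (r_start - req) * np.exp(-rate * dt)
        r_start = req + (r_start - req) * np.exp(-rate * phase.duration_s)
    return out


def single_state_response(
    params: SingleStateParams,
    schedule: InjectionSchedule,
    t_grid,
    r0: float = 0.0,
) -> np.ndarray:
    """Closed-form 1:1 response along ``t_grid`` (s), starting from ``r0`` RU.

    Within a phase at concentration C the response relaxes exponentially
    toward ``Req = rmax * C / (C + K_D)`` with observed rate
    ``kon * C + koff``; buffer phases (C = 0) decay toward 0 at ``koff``.
    The trace is continuous across phase boundaries.
    """
    if r0 < 0:
        raise ValueError(f"r0 must be >= 0, got {r0}")
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    return _piecewise_1to1(
        params.kon, params.koff, params.rmax, schedule, t_grid, r0
    )


def _two_state_matrices(params: TwoStateParams, c: float):
    """Affine system x' = A x + b for x = (R1, R2) at analyte concentration c."""
    a11 = -(params.kon1 * c + params.koff1 + params.kon2)
    a12 = -params.kon1 * c + params.koff2
    a21 = params.kon2
    a22 = -params.koff2
    A = np.array([[a11, a12], [a21, a22]])
    b = np.array([params.kon1 * c * params.rmax, 0.0])
    return A, b


def two_state_response(
    params: TwoStateParams,
    schedule: InjectionSchedule,
    t_grid,
    x0: Sequence[float] = (0.0, 0.0),
) -> np.ndarray:
    """Two-state sequential response ``R1 + R2`` along ``t_grid`` (s).

    The per-phase kinetics

        dR1/dt = kon1*C*(rmax - R1 - R2) - koff1*R1 - kon2*R1 + koff2*R2
        dR2/dt = kon2*R1 - koff2*R2

    form an affine linear system solved exactly by eigendecomposition of
    the 2x2 rate matrix, with the state carried continuously across phase
    boundaries.  ``x0`` is the initial (R1, R2) in RU.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    idx = _phase_index(schedule, t_grid)
    bounds = schedule.boundaries_s

    out = np.empty_like(t_grid)
    x = np.asarray(x0, dtype=float)
    for i, phase in enumerate(schedule.phases):
        A, b = _two_state_matrices(params, phase.conc_M)
        try:
            xeq = np.linalg.solve(A, -b)
            lam, V = np.linalg.eig(A)
            z0 = np.linalg.solve(V, x - xeq)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - generic rates
            raise RuntimeError(
                f"two-state solver failed in phase {i} ({phase.label!r}): {exc}"
            ) from exc
        sel = idx == i
        dt = t_grid[sel] - bounds[i]
        xt = (V @ (z0[:, None] * np.exp(lam[:, None] * dt[None, :]))) + xeq[:, None]
        out[sel] = np.real(xt.sum(axis=0))
        x = np.real(
            V @ (z0 * np.exp(lam * phase.duration_s)) + xeq
        )
    return out


def kd_single(params: SingleStateParams) -> float:
    """Equilibrium dissociation constant ``koff / kon`` in molar."""
    return params.koff / params.kon


def kd_two_state(params: TwoStateParams) -> float:
    """Coupled-equilibrium K_D of the sequential scheme, molar.

    ``(koff1/kon1) * koff2/(koff2 + kon2)``: the encounter-complex K_D
    tightened by the fraction of bound material pulled into AB*.
    """
    return (params.koff1 / params.kon1) * params.koff2 / (params.koff2 + params.kon2)
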