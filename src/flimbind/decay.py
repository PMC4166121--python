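"""Multi-exponential fluorescence decay models for eNOS conformational states.

The FMN cofactor of nitric oxide synthase reports on the enzyme's
conformational manifold: when the FMN- and FAD-binding domains stack
("input" state) the FMN fluorescence is quenched to a ~90 ps lifetime;
FMN-haem association ("output" state) gives ~0.9 ns; uncoupled "open"
conformations fluoresce with multi-nanosecond lifetimes.  A photon-count
decay is modelled as a discrete sum of exponentials

    I(t) = sum_i alpha_i * exp(-t / tau_i)

where ``alpha_i`` are amplitude fractions (proportional to species
populations) and ``tau_i`` the excited-state lifetimes.  The steady-state
intensity fraction of component *i* is

    f_i = alpha_i * tau_i / sum_j alpha_j * tau_j .

Amplitude and intensity fractions differ strongly when lifetimes span two
decades, so population reports always carry both.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LifetimeComponent",
    "DecayModel",
    "StateWindows",
    "default_state_windows",
    "model_intensity",
    "fractional_contributions",
    "classify_states",
    "state_report",
]

_AMP_TOL = 1e-9


@dataclass(frozen=True)
class LifetimeComponent:
    """One exponential decay component.

    Parameters
    ----------
    amplitude_fraction:
        Dimensionless amplitude ``alpha_i`` in [0, 1]; reported as % in
        population tables.
    lifetime_ns:
        Excited-state lifetime ``tau_i`` in nanoseconds, strictly positive.
    """

    amplitude_fraction: float
    lifetime_ns: float

    def __post_init__(self) -> None:
        if not (self.amplitude_fraction >= 0):
            raise ValueError(
                f"amplitude_fraction must be >= 0, got {self.amplitude_fraction}"
            )
        if not (self.lifetime_ns > 0):
            raise ValueError(f"lifetime_ns must be > 0, got {self.lifetime_ns}")


@dataclass(frozen=True)
class DecayModel:
    """A normalized multi-exponential decay with optional flat background.

    Components are stored sorted ascending by lifetime (ties broken by
    descending amplitude); amplitude fractions must sum to 1 within 1e-9.
    ``background`` is the expected counts per channel of a time-independent
    offset (dark counts / room light), >= 0.
    """

    components: tuple[LifetimeComponent, ...]
    background: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= len(self.components) <= 6):
            raise ValueError(
                f"model must have 1-6 components, got {len(self.components)}"
            )
        if self.background < 0:
            raise ValueError(f"background must be >= 0, got {self.background}")
        ordered = tuple(
            sorted(
                self.components,
                key=lambda c: (c.lifetime_ns, -c.amplitude_fraction),
            )
        )
        object.__setattr__(self, "components", ordered)
        taus = [c.lifetime_ns for c in ordered]
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValueError(f"lifetimes must be strictly increasing, got {taus}")
        total = sum(c.amplitude_fraction for c in ordered)
        if abs(total - 1.0) > _AMP_TOL:
            raise ValueError(
                f"amplitude fractions must sum to 1 (got {total}); "
                "use DecayModel.from_pairs(..., normalize=True) to renormalize"
            )

    @classmethod
    def from_pairs(
        cls,
        pairs: Sequence[tuple[float, float]],
        background: float = 0.0,
        normalize: bool = False,
    ) -> "DecayModel":
        """Build from ``(amplitude, lifetime_ns)`` pairs.

        With ``normalize=True`` amplitudes are rescaled to sum to 1, which
        accommodates published percentage tables that round to ~100%.
        """
        amps = np.asarray([p[0] for p in pairs], dtype=float)
        if normalize:
            total = amps.sum()
            if total <= 0:
                raise ValueError("cannot normalize all-zero amplitudes")
            amps = amps / total
        comps = tuple(
            LifetimeComponent(a, p[1]) for a, p in zip(amps, pairs)
        )
        return cls(components=comps, background=background)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c.amplitude_fraction for c in self.components])

    @property
    def lifetimes_ns(self) -> np.ndarray:
        return np.array([c.lifetime_ns for c in self.components])

    def to_dict(self) -> dict:
        return {
            "components": [
                {"alpha": c.amplitude_fraction, "tau_ns": c.lifetime_ns}
                for c in self.components
            ],
            "background": self.background,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "DecayModel":
        comps = tuple(
            LifetimeComponent(c["alpha"], c["tau_ns"]) for c in doc["components"]
        )
        return cls(components=comps, background=float(doc.get("background", 0.0)))

    @classmethod
    def from_json(cls, text: str) -> "DecayModel":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class StateWindows:
    """Half-open lifetime windows assigning components to conformational states.

    ``windows`` maps state labels to ``[lo, hi)`` intervals in ns.  The
    intervals must be disjoint and jointly cover (0, inf); the lower edge is
    inclusive, the upper exclusive, which resolves components sitting exactly
    on a boundary deterministically.
    """

    windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_WINDOWS)
    )

    def __post_init__(self) -> None:
        ivs = sorted(self.windows.values())
        if not ivs:
            raise ValueError("at least one state window required")
        for lo, hi in ivs:
            if not (hi > lo >= 0):
                raise ValueError(f"invalid interval [{lo}, {hi})")
        for (_, hi_a), (lo_b, _) in zip(ivs, ivs[1:]):
            if lo_b < hi_a:
                raise ValueError("state windows overlap")
            if lo_b > hi_a:
                raise ValueError("state windows leave a gap")
        if ivs[0][0] != 0 or not math.isinf(ivs[-1][1]):
            raise ValueError("state windows must cover (0, inf)")

    def assign(self, lifetime_ns: float) -> str:
        for label, (lo, hi) in self.windows.items():
            if lo <= lifetime_ns < hi:
                return label
        raise ValueError(f"lifetime {lifetime_ns} ns not covered by any window")


# Separates the ~90 ps input, ~0.9 ns output and >= 4 ns open classes with
# wide margins on a log scale.
_DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "input": (0.0, 0.3),
    "output": (0.3, 2.0),
    "open": (2.0, math.inf),
}


def default_state_windows() -> StateWindows:
    """Input [0, 0.3) ns, output [0.3, 2.0) ns, open [2.0, inf) ns."""
    return StateWindows(dict(_DEFAULT_WINDOWS))


def model_intensity(model: DecayModel, t):
    """Relative decay intensity ``sum_i alpha_i exp(-t/tau_i)`` at time(s) ``t`` (ns).

    Excludes background.  Equals 1 at t=0 (amplitudes are normalized) and is
    strictly decreasing for t > 0.  Raises for negative times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    alphas = model.amplitudes
    taus = model.lifetimes_ns
    out = np.sum(
        alphas[:, None] * np.exp(-t_arr.ravel()[None, :] / taus[:, None]), axis=0
    ).reshape(t_arr.shape)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def fractional_contributions(model: DecayModel) -> np.ndarray:
    """Steady-state intensity fractions ``f_i = alpha_i tau_i / sum_j alpha_j tau_j``.

    Sums to 1 within 1e-9.  Raises for an all-zero-amplitude model.
    """
    w = model.amplitudes * model.lifetimes_ns
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate model: all amplitudes are zero")
    return w / total


def classify_states(
    model: DecayModel, windows: StateWindows | None = None
) -> dict[str, float]:
    """Per-state amplitude populations in percent.

    Each component is assigned to the lifetime window containing its
    lifetime; a state's population is the summed amplitude fractions of its
    components, x100.  Populations sum to 100.
    """
    windows = windows or default_state_windows()
    pops = {label: 0.0 for label in windows.windows}
    for c in model.components:
        pops[windows.assign(c.lifetime_ns)] += 100.0 * c.amplitude_fraction
    return pops


def state_report(
    model: DecayModel, windows: StateWindows | None = None
) -> pd.DataFrame:
    """Population table with amplitude % and intensity % side by side.

    Published "state population" tables may mean either quantity; amplitude
    fractions track species concentrations while intensity fractions weight
    each species by its brightness (lifetime), so both are reported.
    Columns: state, population_pct (amplitude), intensity_fraction_pct.
    """
    windows = windows or default_state_windows()
    f = fractional_contributions(model)
    rows = []
    for label in windows.windows:
        amp = 0.0
        inten = 0.0
        for i, c in enumerate(model.components):
            if windows.assign(c.lifetime_ns) == label:
                amp += c.amplitude_fraction
                inten += f[i]
        rows.append(
            {
                "state": label,
                "population_pct": 100.0 * amp,
                "intensity_fraction_pct": 100.0 * inten,
            }
        )
    return pd.DataFrame(rows)
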