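"""Global kinetic fitting of sensorgram sets with bootstrap intervals.

All traces of a set are fitted jointly: rate constants are shared globally,
the saturation response ``rmax`` is shared by default (one ligand loading
across BLI sensors), and each BLI trace gets its own starting response
``r0``.  Optimization runs on log-transformed rate constants because the
fitted scales span many decades, and exploits the linearity of both
forward models in ``(rmax, r0)``: for trial rates the optimal linear
coefficients are solved in closed form (variable projection), leaving a
2- or 4-dimensional nonlinear search.

Confidence intervals come from a residual-resampling bootstrap (resample
residuals within each trace, refit, percentile 2.5/97.5), which is robust
to the serial structure a covariance-matrix approximation would ignore.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares, nnls

from .binding import (
    SingleStateParams,
    TwoStateParams,
    _piecewise_1to1,
    kd_single,
    kd_two_state,
    two_state_response,
)
from .sensorgram import SensorgramSet

__all__ = [
    "KineticFitResult",
    "global_fit_single_state",
    "global_fit_two_state",
    "bootstrap_ci",
    "compare_koff_fold",
]


@dataclass(frozen=True)
class KineticFitResult:
    """Globally fitted kinetic constants for one sensorgram set.

    ``params`` holds the shared rate constants and rmax; ``kd`` is the
    model-consistent equilibrium constant in molar; ``reduced_residual_sd``
    is sqrt(SSR / (N - p)) in RU; ``ci95`` is filled by
    :func:`bootstrap_ci` (None until then); ``r0_per_trace`` applies to BLI
    sets.
    """

    params: SingleStateParams | TwoStateParams
    kd: float
    reduced_residual_sd: float
    converged: bool
    ci95: Mapping[str, tuple[float, float]] | None = None
    r0_per_trace: tuple[float, ...] | None = None

    @property
    def model_kind(self) -> str:
        return (
            "single_state"
            if isinstance(self.params, SingleStateParams)
            else "two_state"
        )


def _single_state_design(kon, koff, sset):
    """Per-trace basis (u, v): response is rmax*u + r0*v for fixed rates."""
    parts = []
    for sg in sset.sensorgrams:
        u = _piecewise_1to1(kon, koff, 1.0, sg.schedule, sg.time_s, 0.0)
        v = _piecewise_1to1(kon, koff, 0.0, sg.schedule, sg.time_s, 1.0)
        parts.append((u, v))
    return parts


def _single_state_linear(kon, koff, sset, shared_rmax=True):
    """Solve non-negative (rmax, r0_per_trace) and return residual vector."""
    parts = _single_state_design(kon, koff, sset)
    m = len(parts)
    sizes = [len(sg.time_s) for sg in sset.sensorgrams]
    total = sum(sizes)
    y = np.concatenate([sg.response_ru for sg in sset.sensorgrams])
    if shared_rmax:
        A = np.zeros((total, 1 + m))
        pos = 0
        for j, ((u, v), n) in enumerate(zip(parts, sizes)):
            A[pos : pos + n, 0] = u
            A[pos : pos + n, 1 + j] = v
            pos += n
        coef, _ = nnls(A, y)
        rmax = coef[0]
        r0s = coef[1:]
    else:
        rmaxs = np.empty(m)
        r0s = np.empty(m)
        pos = 0
        resid_parts = []
        for j, ((u, v), n) in enumerate(zip(parts, sizes)):
            Aj = np.column_stack([u, v])
            cj, _ = nnls(Aj, y[pos : pos + n])
            rmaxs[j], r0s[j] = cj
            pos += n
        rmax = rmaxs
    fitted = []
    for j, (u, v) in enumerate(parts):
        rj = rmax if shared_rmax else rmax[j]
        fitted.append(rj * u + r0s[j] * v)
    resid = np.concatenate(fitted) - y
    return resid, rmax, tuple(float(x) for x in r0s)


def global_fit_single_state(
    sset: SensorgramSet,
    seed: int = 0,
    n_restarts: int = 4,
    shared_rmax: bool = True,
    init_params: SingleStateParams | None = None,
) -> KineticFitResult:
    """Globally fit a BLI multi-concentration set to the 1:1 model.

    ``kon`` and ``koff`` are shared across traces and optimized on a log
    scale from ``n_restarts`` initializations (one data-scale guess plus
    seeded log-uniform draws, or ``init_params`` when given); ``rmax`` is
    shared (or per-trace with ``shared_rmax=False``) and each trace carries
    its own ``r0``, both solved by non-negative linear least squares.
    """
    if sset.mode != "bli_multiconc":
        raise ValueError(f"expected a bli_multiconc set, got {sset.mode!r}")
    nonzero = [sg for sg in sset.sensorgrams if sg.concentration_M > 0]
    if len(nonzero) < 2:
        raise ValueError("need >= 2 nonzero-concentration traces for a global fit")

    def residuals(theta):
        resid, _, _ = _single_state_linear(
            np.exp(theta[0]), np.exp(theta[1]), sset, shared_rmax
        )
        return resid

    rng = np.random.default_rng(seed)
    if init_params is not None:
        inits = [np.log([init_params.kon, init_params.koff])] * 1
    else:
        inits = [np.log([1.0e5, 1.0e-3])]
        for _ in range(n_restarts - 1):
            inits.append(
                np.array(
                    [
                        rng.uniform(np.log(1e3), np.log(1e7)),
                        rng.uniform(np.log(1e-5), np.log(1e-1)),
                    ]
                )
            )

    bounds = (np.log([1e0, 1e-8]), np.log([1e9, 1e2]))
    best = None
    any_converged = False
    for x0 in inits:
        sol = least_squares(
            residuals, x0, bounds=bounds, method="trf", ftol=1e-14, xtol=1e-14
        )
        any_converged = any_converged or sol.status > 0
        if best is None or sol.cost < best.cost:
            best = sol

    kon, koff = np.exp(best.x)
    resid, rmax, r0s = _single_state_linear(kon, koff, sset, shared_rmax)
    rmax_val = float(np.max(rmax)) if not shared_rmax else float(rmax)
    params = SingleStateParams(kon=float(kon), koff=float(koff), rmax=max(rmax_val, 1e-12))
    n_free = 2 + (1 if shared_rmax else len(sset.sensorgrams)) + len(sset.sensorgrams)
    dof = max(len(resid) - n_free, 1)
    return KineticFitResult(
        params=params,
        kd=kd_single(params),
        reduced_residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        converged=bool(any_converged),
        r0_per_trace=r0s,
    )


def _two_state_linear(rates, sset):
    """Solve the shared rmax for fixed two-state rates; return residuals."""
    kon1, koff1, kon2, koff2 = rates
    probe = TwoStateParams(kon1=kon1, koff1=koff1, kon2=kon2, koff2=koff2, rmax=1.0)
    us = [
        two_state_response(probe, sg.schedule, sg.time_s)
        for sg in sset.sensorgrams
    ]
    u = np.concatenate(us)
    y = np.concatenate([sg.response_ru for sg in sset.sensorgrams])
    denom = float(u @ u)
    rmax = max(float(u @ y) / denom, 0.0) if denom > 0 else 0.0
    return rmax * u - y, rmax


def global_fit_two_state(
    sset: SensorgramSet,
    seed: int = 0,
    n_restarts: int = 8,
    init_params: TwoStateParams | None = None,
) -> KineticFitResult:
    """Globally fit an SPR single-cycle set to the two-state sequential model.

    The four rate constants are optimized on a log scale from
    ``n_restarts`` initializations; ``rmax`` is profiled out linearly.
    """
    if sset.mode != "spr_single_cycle":
        raise ValueError(f"expected an spr_single_cycle set, got {sset.mode!r}")

    def residuals(theta):
        resid, _ = _two_state_linear(np.exp(theta), sset)
        return resid

    rng = np.random.default_rng(seed)
    if init_params is not None:
        inits = [
            np.log(
                [
                    init_params.kon1,
                    init_params.koff1,
                    init_params.kon2,
                    init_params.koff2,
                ]
            )
        ]
    else:
        inits = [np.log([1.0e5, 1.0e-3, 1.0e-2, 1.0e-4])]
        for _ in range(n_restarts - 1):
            inits.append(
                np.array(
                    [
                        rng.uniform(np.log(1e3), np.log(1e7)),
                        rng.uniform(np.log(1e-5), np.log(1e-1)),
                        rng.uniform(np.log(1e-5), np.log(1e0)),
                        rng.uniform(np.log(1e-6), np.log(1e-1)),
                    ]
                )
            )

    bounds = (
        np.log([1e0, 1e-8, 1e-8, 1e-8]),
        np.log([1e9, 1e2, 1e2, 1e2]),
    )
    best = None
    any_converged = False
    for x0 in inits:
        sol = least_squares(
            residuals, x0, bounds=bounds, method="trf", ftol=1e-14, xtol=1e-14
        )
        any_converged = any_converged or sol.status > 0
        if best is None or sol.cost < best.cost:
            best = sol

    kon1, koff1, kon2, koff2 = np.exp(best.x)
    resid, rmax = _two_state_linear(np.exp(best.x), sset)
    params = TwoStateParams(
        kon1=float(kon1),
        koff1=float(koff1),
        kon2=float(kon2),
        koff2=float(koff2),
        rmax=max(float(rmax), 1e-12),
    )
    dof = max(len(resid) - 5, 1)
    return KineticFitResult(
        params=params,
        kd=kd_two_state(params),
        reduced_residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        converged=bool(any_converged),
    )


def _fitted_traces(sset: SensorgramSet, result: KineticFitResult):
    if result.model_kind == "single_state":
        parts = _single_state_design(result.params.kon, result.params.koff, sset)
        r0s = result.r0_per_trace or (0.0,) * len(sset.sensorgrams)
        return [
            result.params.rmax * u + r0 * v for (u, v), r0 in zip(parts, r0s)
        ]
    return [
        two_state_response(result.params, sg.schedule, sg.time_s)
        for sg in sset.sensorgrams
    ]


def _param_dict(result: KineticFitResult) -> dict[str, float]:
    p = result.params
    if result.model_kind == "single_state":
        return {"kon": p.kon, "koff": p.koff, "rmax": p.rmax, "kd": result.kd}
    return {
        "kon1": p.kon1,
        "koff1": p.koff1,
        "kon2": p.kon2,
        "koff2": p.koff2,
        "rmax": p.rmax,
        "kd": result.kd,
    }


def bootstrap_ci(
    sset: SensorgramSet,
    result: KineticFitResult,
    n_boot: int = 100,
    seed: int = 0,
) -> Mapping[str, tuple[float, float]]:
    """Residual-resampling bootstrap 95% intervals for the fitted constants.

    Residuals are resampled with replacement within each trace, added back
    to the fitted curves, and the set refit (initialized at the point
    estimate); intervals are the 2.5/97.5 percentiles over ``n_boot``
    replicates.  Requires a converged fit and ``n_boot >= 20``.
    """
    if n_boot < 20:
        raise ValueError(f"n_boot must be >= 20, got {n_boot}")
    if not result.converged:
        raise ValueError("bootstrap requires a converged fit")
    fitted = _fitted_traces(sset, result)
    residuals = [
        sg.response_ru - f for sg, f in zip(sset.sensorgrams, fitted)
    ]
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {k: [] for k in _param_dict(result)}
    for _ in range(n_boot):
        boot_traces = []
        for sg, f, res in zip(sset.sensorgrams, fitted, residuals):
            res_star = rng.choice(res, size=len(res), replace=True)
            boot_traces.append(replace(sg, response_ru=f + res_star))
        boot_set = SensorgramSet(
            sensorgrams=tuple(boot_traces), mode=sset.mode, meta=dict(sset.meta)
        )
        if result.model_kind == "single_state":
            fit = global_fit_single_state(boot_set, init_params=result.params)
        else:
            fit = global_fit_two_state(boot_set, init_params=result.params)
        for k, v in _param_dict(fit).items():
            draws[k].append(v)
    return {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in draws.items()
    }


def compare_koff_fold(
    result_a: KineticFitResult, result_b: KineticFitResult
) -> float:
    """Fold change ``koff_b / koff_a`` between two single-state fits."""
    for name, r in (("result_a", result_a), ("result_b", result_b)):
        if r.model_kind != "single_state":
            raise ValueError(f"{name} is not a single-state fit")
        if not r.converged:
            raise ValueError(f"{name} did not converge")
    return result_b.params.koff / result_a.params.koff
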