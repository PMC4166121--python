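"""Simulate-fit-report pipelines composing the simulation and fitting arms.

These are the programmatic entry points behind the command line: each takes
explicit parameters plus a seed, runs simulation -> fit, and returns a
JSON-serializable report that records every input needed to reproduce it.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .binding import SingleStateParams, TwoStateParams, kd_single, kd_two_state
from .decay import DecayModel, state_report
from .sensorgram import generate_bli_set, generate_spr_single_cycle
from .sensorgram_fit import (
    bootstrap_ci,
    global_fit_single_state,
    global_fit_two_state,
)
from .tcspc import AcquisitionConfig, IRFSpec, generate_dataset
from .tcspc_fit import reconvolution_fit

__all__ = [
    "decay_recovery_report",
    "decay_recovery_median",
    "bli_recovery_report",
    "spr_recovery_report",
]


def decay_recovery_report(
    model: DecayModel,
    n_components: int | None = None,
    irf: IRFSpec | None = None,
    acq: AcquisitionConfig | None = None,
    seed: int = 0,
) -> dict:
    """Simulate one TCSPC dataset from ``model`` and refit it.

    Returns the fitted components, phi^2, and the state-population table
    (amplitude and intensity percent side by side).
    """
    if n_components is None:
        n_components = len(model.components)
    data = generate_dataset(model, irf=irf, acq=acq, seed=seed)
    fit = reconvolution_fit(data, n_components, seed=seed)
    report = state_report(fit.model)
    return {
        "seed": seed,
        "true_model": model.to_dict(),
        "fitted_model": fit.model.to_dict(),
        "reduced_chi2": fit.reduced_chi2,
        "converged": fit.converged,
        "state_populations": report.to_dict(orient="records"),
    }


def decay_recovery_median(
    model: DecayModel,
    seeds: Sequence[int],
    n_components: int | None = None,
    irf: IRFSpec | None = None,
    acq: AcquisitionConfig | None = None,
) -> dict:
    """Median recovered amplitudes/lifetimes over repeated simulations.

    Components are matched by sort order (both true and fitted models are
    stored ascending in lifetime).
    """
    if n_components is None:
        n_components = len(model.components)
    alphas = []
    taus = []
    chi2s = []
    for seed in seeds:
        data = generate_dataset(model, irf=irf, acq=acq, seed=seed)
        fit = reconvolution_fit(data, n_components, seed=seed)
        alphas.append(fit.model.amplitudes)
        taus.append(fit.model.lifetimes_ns)
        chi2s.append(fit.reduced_chi2)
    return {
        "true_alphas": model.amplitudes.tolist(),
        "true_taus_ns": model.lifetimes_ns.tolist(),
        "median_alphas": np.median(alphas, axis=0).tolist(),
        "median_taus_ns": np.median(taus, axis=0).tolist(),
        "median_reduced_chi2": float(np.median(chi2s)),
        "seeds": list(seeds),
    }


def bli_recovery_report(
    params: SingleStateParams,
    concentrations_M: Sequence[float],
    seed: int = 0,
    noise_sd: float | None = None,
    n_boot: int = 0,
) -> dict:
    """Simulate a BLI multi-concentration set and globally refit it."""
    sset = generate_bli_set(
        params, concentrations_M, noise_sd=noise_sd, seed=seed
    )
    fit = global_fit_single_state(sset, seed=seed)
    report = {
        "seed": seed,
        "true": {"kon": params.kon, "koff": params.koff, "rmax": params.rmax,
                 "kd_pM": kd_single(params) * 1e12},
        "fitted": {
            "kon": fit.params.kon,
            "koff": fit.params.koff,
            "rmax": fit.params.rmax,
            "kd_pM": fit.kd * 1e12,
        },
        "reduced_residual_sd": fit.reduced_residual_sd,
        "converged": fit.converged,
    }
    if n_boot:
        report["ci95"] = {
            k: list(v) for k, v in bootstrap_ci(sset, fit, n_boot, seed).items()
        }
    return report


def spr_recovery_report(
    params: TwoStateParams,
    concentrations_M: Sequence[float],
    seed: int = 0,
    noise_sd: float | None = None,
    n_boot: int = 0,
) -> dict:
    """Simulate an SPR single-cycle set and globally refit it."""
    sset = generate_spr_single_cycle(
        params, concentrations_M, noise_sd=noise_sd, seed=seed
    )
    fit = global_fit_two_state(sset, seed=seed)
    report = {
        "seed": seed,
        "true": {
            "kon1": params.kon1,
            "koff1": params.koff1,
            "kon2": params.kon2,
            "koff2": params.koff2,
            "rmax": params.rmax,
            "kd_pM": kd_two_state(params) * 1e12,
        },
        "fitted": {
            "kon1": fit.params.kon1,
            "koff1": fit.params.koff1,
            "kon2": fit.params.kon2,
            "koff2": fit.params.koff2,
            "rmax": fit.params.rmax,
            "kd_pM": fit.kd * 1e12,
        },
        "reduced_residual_sd": fit.reduced_residual_sd,
        "converged": fit.converged,
    }
    if n_boot:
        report["ci95"] = {
            k: list(v) for k, v in bootstrap_ci(sset, fit, n_boot, seed).items()
        }
    return report
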