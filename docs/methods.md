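# Methods

## Decay model and state populations

A decay is a discrete sum of 1–6 exponentials, `I(t) = Σᵢ αᵢ e^{−t/τᵢ}`,
with amplitude fractions `αᵢ ≥ 0`, `Σαᵢ = 1`, and strictly increasing
lifetimes `τᵢ` (ns). The steady-state intensity fraction of component *i*
is `fᵢ = αᵢτᵢ / Σⱼ αⱼτⱼ`. Conformational states are assigned by lifetime
windows — input `[0, 0.3)` ns, output `[0.3, 2.0)` ns, open `[2.0, ∞)` ns,
lower-edge inclusive — chosen to separate the ~90 ps / ~0.9 ns / ≥4 ns
lifetime classes with wide margins on a log scale; the windows are
configurable. State populations are reported as **amplitude** percentages,
because amplitudes are proportional to species concentrations; published
population tables do not always say which convention they use, so every
report also carries the intensity fractions side by side. The ~4.3 ns
"open" class is an average over several open conformations but is modelled
as a single discrete component; stretched exponentials and lifetime
distributions are out of scope.

## TCSPC simulation

Excitation is periodic with repetition period `T` (default 50 ns, i.e.
20 MHz). Because a 10 ns component retains ~1% of its amplitude after one
period, wraparound is always modelled: the per-channel expectation is

    E(t_c) ∝ Σᵢ αᵢ e^{−t_c/τᵢ} / (1 − e^{−T/τᵢ}),

the geometric sum of all prior-pulse tails, evaluated at bin centers. The
expectation is convolved **circularly** with the instrument response
(consistent with wrapped re-excitation), scaled so the signal sums to
`total_counts·(1 − background_fraction)` with a uniform background making
up the rest, and Poisson-sampled per channel. The IRF is a Gaussian
(default 200 ps fwhm, centered at 2 ns) and the scattering reference is an
independent Poisson sample of the same profile (default 10⁶ counts), so
fits see a realistically noisy IRF. Defaults — 4096 channels × 12.2 ps
(≈50 ns window), 10⁷ total counts, 0.1% background — are stated
assumptions that make a 90 ps component sub-IRF yet resolvable, the
operating regime of the instrument being emulated. Detector dead-time,
pile-up, afterpulsing and IRF jitter are not modelled; lifetimes ≥10·T
trigger an ill-conditioning warning because the wrapped decay is nearly
flat.

## Reconvolution fitting

The fitted model is the periodic multi-exponential convolved with the
*measured* (noisy) IRF histogram — reconvolution rather than deconvolution
of the data, which estimates the same quantities but is numerically stable
and statistically standard. The objective is Poisson-weighted least
squares, `Σ_c (y_c − m_c)² / max(y_c, 1)`; the variance floor of 1 for
empty channels avoids the bias unweighted fitting puts on sub-IRF
lifetimes. Free parameters: `k` lifetimes (bounded to [1 ps, 100 ns], log
scale), `k` non-negative amplitudes, one flat background, and a sub-channel
IRF shift bounded to ±2 channels.

Amplitudes and background enter linearly, so the fit uses **variable
projection**: for trial lifetimes the optimal non-negative coefficients
are solved by weighted NNLS, leaving a (k+1)-dimensional outer search.
The NNLS coefficients are component *photon counts*, proportional to
`αᵢτᵢ`; they are converted back to amplitudes by undoing the per-column
shape normalization — conflating the two is the classic amplitude/
intensity-fraction mistake this package is careful about. Multistart uses
8 restarts (one log-spaced initialization plus seeded log-uniform draws on
[10 ps, 20 ns]) because sub-IRF components create local minima; the best
restart is returned with components sorted ascending in lifetime.
Goodness of fit is the reduced χ² (φ² in the lifetime literature) over
`n_channels − (2k + 2)` degrees of freedom; model selection accepts k+1
components over k only when φ² improves by more than 5% relative — the
published analyses report 2–4 component fits without stating a rule, so
this threshold is this package's convention. Reported 95% parameter
intervals are linearized, conditional approximations (reporting grade),
not profile likelihoods.

At the default conditions, φ² for a correctly specified fit settles near
1.05 rather than 1.00: the measured-IRF noise contributes model error not
accounted for by the counting-statistics denominator. This is physical,
not a defect, and stays well inside the [0.85, 1.15] acceptance band.

## Binding models

Concentrations are molar internally and converted to nM/pM only in
reports. The 1:1 model has the piecewise closed form
`R(t) = Req + (R_start − Req)e^{−(k_on C + k_off)Δt}` with
`Req = rmax·C/(C + K_D)`, continuous across injection phases. The
two-state sequential model

    dR1/dt = k_on1·C·(rmax − R1 − R2) − k_off1·R1 − k_on2·R1 + k_off2·R2
    dR2/dt = k_on2·R1 − k_off2·R2

is an affine linear system per constant-concentration phase and is solved
*exactly* by eigendecomposition of the 2×2 rate matrix (numerical
integration with `solve_ivp` serves as the independent oracle in the test
suite). The overall dissociation constant couples both equilibria:
`K_D = (k_off1/k_on1)·k_off2/(k_off2 + k_on2)`. Note that applying this
formula to published rate constants rounded to two significant figures
reproduces a published K_D only to ~5–10%; that rounding slack is inherent
to the inputs. Mass-transport limitation is deliberately not modelled:
the association being emulated is diffusion limited, but the published
analysis fits reaction-limited models, and this package reproduces that
analysis.

## Sensorgram simulation and global fitting

BLI: one sensor per concentration (default 0–87.5 nM, 180 s association +
180 s dissociation, 1 s sampling), response = forward model + optional
linear drift + i.i.d. Gaussian noise (default 1% of rmax; the instruments
report no noise figure, so this is a stated assumption producing realistic
trace quality). SPR single-cycle: one continuous trace over five
ascending injections (default 120 s contact) and a 600 s final
dissociation, per Biacore X100 convention; contact times are not published
and are stated assumptions. Default rmax is 1 RU (BLI, nm-scale) and
30 RU (SPR).

Global fits share the rate constants across all traces; rmax is shared by
default (one ligand loading across BLI sensors; per-trace rmax is a flag)
and each BLI trace carries its own starting response r0. Rates are
optimized on a log scale (they span ~9 decades); rmax and r0 are linear
in both forward models, so they are profiled out by non-negative linear
least squares at each iteration — the nonlinear search is only 2- (single
state) or 4-dimensional (two state), with 4 or 8 seeded multistarts.
Noiseless round trips recover parameters to ~1e-10 relative.

Confidence intervals use a residual-resampling bootstrap (resample
residuals with replacement within each trace, refit from the point
estimate, percentile 2.5/97.5) rather than the asymptotic covariance,
because sensorgram residuals are serially structured. Per-point i.i.d.
resampling whitens that structure, so the intervals are approximate in
the usual residual-bootstrap sense.

The two-state model fitted to data that contain no conformational step is
only set-identified: many `(k_on2, k_off2)` pairs reproduce the trace
exactly. The overall K_D and the fit quality are identified, and those
are what the nesting test asserts.

## Motif logic

`scan_motif` returns 1-based positions of S/T immediately followed by P
(X never matches; the final residue cannot match). `resolve_ambiguity`
intersects MS candidate sites with motif positions: intersection size
equal to the observed phosphate count ⇒ unique calls; larger ⇒ ambiguous;
smaller ⇒ the evidence is inconsistent with proline-directed
phosphorylation and is flagged. Localization scoring from spectral
evidence is deliberately not modelled — resolution is purely
motif-logical. The tryptic digest cleaves C-terminal to K/R except before
P, 0 missed cleavages by default (up to 2), with 1-based inclusive parent
coordinates; residue numbering across species orthologs (which can differ
by a small offset) is handled by an explicit `parent_offset`.

## What the generators do and do not establish

The synthetic data reproduce the stated acquisition geometry, photon
budgets, concentration series and schedule timings, with pure counting
noise (TCSPC) or white Gaussian noise (sensorgrams). They omit IRF drift,
detector artifacts, baseline jumps, non-specific binding and analyte
depletion. Passing recovery tests therefore demonstrates that the
*analysis* is correct and well-conditioned at the published operating
point — not that real instruments are free of systematic error.

## Problem sizes and reproducibility

Recovery checks use 20 replicate seeds for the lifetime arm and 5 for the
kinetics arm, 10⁷ photons per decay, and 100 bootstrap replicates —
enough for medians stable to well under the acceptance tolerances. All
randomness flows from explicit integer seeds through per-stage
`numpy.random.SeedSequence` substreams; identical inputs and seeds give
bit-identical outputs.
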