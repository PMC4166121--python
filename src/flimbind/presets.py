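"""Published eNOS/CaM parameter sets used as simulation ground truths.

Lifetime models come from TCSPC decompositions of eNOS FMN fluorescence:
the CaM-activated enzyme with and without prior ERK phosphorylation
(two/three-component fits), and the resting (CaM-free) holoenzyme with and
without phosphorylation (four/three-component fits).  Binding-kinetics
parameters come from global fits of CaM-eNOS optical biosensing: BLI
multi-concentration series under a 1:1 model and SPR single-cycle series
under a two-state sequential model.
"""

from __future__ import annotations

from .binding import SingleStateParams, TwoStateParams
from .decay import DecayModel

__all__ = [
    "ENOS_CAM",
    "ENOS_CAM_ERK",
    "ENOS_RESTING",
    "ENOS_RESTING_ERK",
    "BLI_SINGLE_STATE",
    "SPR_TWO_STATE",
    "BLI_CONCENTRATIONS_M",
    "SPR_CONCENTRATIONS_M",
    "LIFETIME_MODELS",
]

#: CaM-activated unphosphorylated eNOS: input 53.45% at 90 ps,
#: output 20.21% at 0.9 ns, open 26.35% at 4.3 ns (average open lifetime).
ENOS_CAM = DecayModel.from_pairs(
    [(0.5345, 0.090), (0.2021, 0.9), (0.2635, 4.3)], normalize=True
)

#: CaM-activated ERK-phosphorylated eNOS: input 85% at 90 ps, open 15% at 4.3 ns.
ENOS_CAM_ERK = DecayModel.from_pairs([(0.85, 0.090), (0.15, 4.3)])

#: Resting (CaM-free) unphosphorylated eNOS holoenzyme, four components:
#: 90 ps 78%, 0.9 ns 0.68%, 3.65 ns 20%, 10.1 ns 1.6%.  Printed amplitudes
#: sum to 100.28%; normalized here.
ENOS_RESTING = DecayModel.from_pairs(
    [(0.78, 0.090), (0.0068, 0.9), (0.20, 3.65), (0.016, 10.1)], normalize=True
)

#: Resting ERK-phosphorylated eNOS, three components:
#: 80 ps 86%, 1.1 ns 1.8%, 3.83 ns 12.4% (normalized from 100.2%).
ENOS_RESTING_ERK = DecayModel.from_pairs(
    [(0.86, 0.080), (0.018, 1.1), (0.124, 3.83)], normalize=True
)

LIFETIME_MODELS: dict[str, DecayModel] = {
    "enos_cam": ENOS_CAM,
    "enos_cam_erk": ENOS_CAM_ERK,
    "enos_resting": ENOS_RESTING,
    "enos_resting_erk": ENOS_RESTING_ERK,
}

#: BLI single-state (1:1) CaM-eNOS rate constants; K_D 920 pM (-ERK) and
#: 2700 pM (+ERK).  rmax is an instrument scale (nm-range signal), default 1.
BLI_SINGLE_STATE: dict[str, SingleStateParams] = {
    "minus_erk": SingleStateParams(kon=1.2e5, koff=1.1e-4, rmax=1.0),
    "plus_erk": SingleStateParams(kon=1.2e5, koff=3.3e-4, rmax=1.0),
}

#: SPR two-state sequential (A+B <-> AB <-> AB*) rate constants; overall
#: K_D ~720 pM (-ERK) and ~650 pM (+ERK).
SPR_TWO_STATE: dict[str, TwoStateParams] = {
    "minus_erk": TwoStateParams(
        kon1=6.4e4, koff1=2.0e-3, kon2=8.4e-3, koff2=1.9e-4, rmax=30.0
    ),
    "plus_erk": TwoStateParams(
        kon1=1.1e5, koff1=2.5e-3, kon2=3.7e-3, koff2=1.1e-4, rmax=30.0
    ),
}

#: BLI analyte (eNOS) concentrations, molar: 0, 10.9, 31.9, 43.7, 87.5 nM.
BLI_CONCENTRATIONS_M = (0.0, 10.9e-9, 31.9e-9, 43.7e-9, 87.5e-9)

#: SPR single-cycle ascending injections, molar: 6.2, 18.5, 55.6, 167, 500 nM.
SPR_CONCENTRATIONS_M = (6.2e-9, 18.5e-9, 55.6e-9, 167e-9, 500e-9)
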