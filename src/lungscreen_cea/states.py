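"""Expanded Markov state space.

The clinical model has six health states; duration-dependent values (the
three-year staged detection of a missed cancer, and the lower utility of
the first year after resection) are expressed with tunnel copies, giving
nine memoryless states.
"""

from __future__ import annotations

from enum import IntEnum

import numpy as np

__all__ = ["State", "N_STATES", "UNDETECTED_STATES", "state_costs", "state_utilities"]


class State(IntEnum):
    NO_BC = 0                # disease-free, screen-negative
    NO_BC_SUSPICIOUS = 1     # disease-free, false-positive work-up year
    UNDETECTED_Y1 = 2        # missed cancer, 1st year undetected
    UNDETECTED_Y2 = 3
    UNDETECTED_Y3 = 4
    AFTER_RESECTION_Y1 = 5   # first year after curative resection
    AFTER_RESECTION_LATER = 6
    PALLIATIVE = 7
    DEAD = 8


N_STATES = len(State)
UNDETECTED_STATES = (State.UNDETECTED_Y1, State.UNDETECTED_Y2, State.UNDETECTED_Y3)


def state_costs(params) -> np.ndarray:
    """Annual cost of membership per state (USD/year)."""
    c = np.zeros(N_STATES)
    c[State.NO_BC_SUSPICIOUS] = params.cost_fp_followup
    for s in UNDETECTED_STATES:
        c[s] = params.cost_undetected
    c[State.AFTER_RESECTION_Y1] = params.cost_post_resection_annual
    c[State.AFTER_RESECTION_LATER] = params.cost_post_resection_annual
    c[State.PALLIATIVE] = params.cost_palliative_annual
    return c


def state_utilities(params) -> np.ndarray:
    """QALY weight of membership per state."""
    u = np.zeros(N_STATES)
    u[State.NO_BC] = params.utility_no_bc
    u[State.NO_BC_SUSPICIOUS] = params.utility_fp
    for s in UNDETECTED_STATES:
        u[s] = params.utility_undetected
    u[State.AFTER_RESECTION_Y1] = params.utility_resection_year1
    u[State.AFTER_RESECTION_LATER] = params.utility_post_resection
    u[State.PALLIATIVE] = params.utility_palliative
    u[State.DEAD] = params.utility_dead
    return u
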