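"""Deterministic mean-field rate equations mirroring the ten propensities.

This is an engineering validation tool, not part of the stochastic model
itself: in the large-count limit the ensemble mean of the jump process obeys
(approximately, since the bimolecular terms are nonlinear) the ODE system
whose right-hand side mirrors the propensity formulas term for term.  The
source count ``A_s`` enters as the same constant boundary condition as in
the stochastic engine.  Means and equilibria of the SSA are validated
against this oracle; fluctuation statistics (SD, CV%) are not, as the
mean-field system has none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .reaction_network import STATE_FIELDS, RateConstants, SystemState

__all__ = ["ContinuousState", "ode_rhs", "integrate", "OracleIntegrationError"]


class OracleIntegrationError(RuntimeError):
    """The stiff integrator failed; carries the solver's diagnostic message."""


@dataclass(frozen=True)
class ContinuousState:
    """Real-valued analogue of the integer state (large-count limit)."""

    A_b: float = 0.0
    A_c: float = 0.0
    A_o: float = 0.0
    AR: float = 0.0
    ARR: float = 0.0
    R: float = 0.0
    t: float = 0.0

    @property
    def abc(self) -> float:
        return self.AR + self.ARR

    @property
    def receptor_total(self) -> float:
        return self.R + self.AR + 2.0 * self.ARR

    def as_array(self) -> np.ndarray:
        return np.array([self.A_b, self.A_c, self.A_o, self.AR, self.ARR,
                         self.R], dtype=np.float64)

    @classmethod
    def from_state(cls, state: SystemState) -> "ContinuousState":
        return cls(**{f: float(getattr(state, f)) for f in STATE_FIELDS},
                   t=float(state.t))


def ode_rhs(y: np.ndarray, rates: RateConstants, A_s: float) -> np.ndarray:
    """Time derivatives of (A_b, A_c, A_o, AR, ARR, R).

    Each propensity contributes its rate times its change vector:

    * dA_b/dt = k_2p*A_s - (k_2n + k_1p)*A_b + k_1n*A_c
    * dA_c/dt = k_1p*A_b - (k_1n + k_on)*A_c + k_off*A_o
    * dA_o/dt = k_on*A_c - k_off*A_o - k_mp*A_o*R + k_mn*AR
    * dAR/dt  = k_mp*A_o*R - k_mn*AR - k_bp*AR*R + k_bn*ARR
    * dARR/dt = k_bp*AR*R - k_bn*ARR
    * dR/dt   = -k_mp*A_o*R + k_mn*AR - k_bp*AR*R + k_bn*ARR

    The receptor combination R + AR + 2*ARR has an identically zero
    derivative (the binding terms cancel in pairs).
    """
    A_b, A_c, A_o, AR, ARR, R = y
    k = rates
    mono = k.k_mp * A_o * R - k.k_mn * AR
    biv = k.k_bp * AR * R - k.k_bn * ARR
    return np.array([
        k.k_2p * A_s - (k.k_2n + k.k_1p) * A_b + k.k_1n * A_c,
        k.k_1p * A_b - (k.k_1n + k.k_on) * A_c + k.k_off * A_o,
        k.k_on * A_c - k.k_off * A_o - mono,
        mono - biv,
        biv,
        -mono - biv,
    ])


def integrate(initial: ContinuousState | SystemState, rates: RateConstants,
              A_s: float, t_end: float, t_eval: np.ndarray | None = None,
              rtol: float = 1e-8, atol: float = 1e-6):
    """Integrate the mean-field system from ``initial`` to ``t_end``.

    Uses a stiff-capable solver (LSODA): the rate scales span roughly
    1e-8 to 1e5 per second across the labeling and wash phases.  Returns a
    :class:`scipy.integrate.OdeSolution`-style result with ``.t`` (times),
    ``.y`` (6 x n array in STATE_FIELDS order) and ``.final`` (a
    ContinuousState).  ``t_end = 0`` (or equal to the initial time) returns
    the initial state unchanged.
    """
    if isinstance(initial, SystemState):
        initial = ContinuousState.from_state(initial)
    y0 = initial.as_array()
    t0 = initial.t
    if t_end <= t0:
        class _Result:
            t = np.array([t0])
            y = y0.reshape(6, 1)
            final = initial
        return _Result()

    sol = solve_ivp(lambda t, y: ode_rhs(y, rates, A_s), (t0, t_end), y0,
                    method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise OracleIntegrationError(sol.message)
    yf = sol.y[:, -1]
    sol.final = ContinuousState(*yf, t=float(sol.t[-1]))
    return sol
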