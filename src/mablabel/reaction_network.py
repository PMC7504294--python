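"""Species, parameters and reaction channels of the mAb--CD4 labeling model.

The model tracks a single T cell surrounded by three concentric diffusive
shells (transition, boundary and cell layers).  Free monoclonal antibodies
(mAbs) hop between shells, adsorb nonspecifically onto the cell surface, and
the adsorbed pool reacts with CD4 receptors to form monovalent (``AR``) and
bivalent (``ARR``) complexes.  Ten elementary reaction channels (five
forward/backward pairs) define a jump process whose propensities are the
products of a stochastic rate constant and the current reactant counts.

The transition layer is a boundary condition, not a dynamic variable: its
count ``A_s`` is pinned to a constant source value (or to zero during a wash),
so the channel feeding the boundary layer fires at a constant rate and the
reverse channel removes molecules from the tracked system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "AVOGADRO",
    "CHANNEL_ORDER",
    "STATE_FIELDS",
    "GeometryParams",
    "RateConstants",
    "SystemState",
    "ReactionChannel",
    "ParameterError",
    "InvariantViolation",
    "build_channels",
    "propensities",
    "apply_channel",
    "change_matrix",
]

AVOGADRO = 6.02214076e23  # 1/mol

#: Canonical channel order; also the column order of the change matrix and
#: part of the on-disk file contract.
CHANNEL_ORDER: Tuple[str, ...] = (
    "k_2p", "k_2n", "k_1p", "k_1n", "k_on", "k_off",
    "k_mp", "k_mn", "k_bp", "k_bn",
)

#: Dynamic state fields, in the order used by state vectors and trajectories.
STATE_FIELDS: Tuple[str, ...] = ("A_b", "A_c", "A_o", "AR", "ARR", "R")


class ParameterError(ValueError):
    """Raised for invalid model parameters (negative rates, non-positive geometry)."""


class InvariantViolation(RuntimeError):
    """Raised when an update would break a structural invariant (engine bug)."""


@dataclass(frozen=True)
class GeometryParams:
    """Geometry of the diffusive path from bulk suspension to the cell surface.

    All three shells share the cell's average radius (3.75 um) as their
    thickness; the per-molecule hop rate between adjacent shells is D/h^2.

    Parameters
    ----------
    h_c, h_b, h_t : float
        Thickness of the cell, boundary and transition layers (m).
    D : float
        mAb diffusion coefficient in free solution (m^2/s).
    transition_volume : float
        Volume of the transition shell (m^3); together with the bulk
        concentration it sets the constant source count.
    bulk_concentration : float
        mAb concentration in the bulk labeling suspension (mol/m^3).
    """

    h_c: float = 3.75e-6
    h_b: float = 3.75e-6
    h_t: float = 3.75e-6
    D: float = 0.5e-10
    transition_volume: float = 4.76e-15
    bulk_concentration: float = 1.0e-6

    def __post_init__(self) -> None:
        for name in ("h_c", "h_b", "h_t", "D", "transition_volume",
                     "bulk_concentration"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be strictly positive")

    def hop_rate(self, h: float) -> float:
        """Per-molecule diffusive hop rate D/h^2 (1/s)."""
        return self.D / h ** 2


@dataclass(frozen=True)
class RateConstants:
    """The ten stochastic rate constants of the reaction network.

    Diffusion and adsorption rates (``k_2p`` ... ``k_off``) are first-order
    hop rates derived from the geometry; ``k_mp`` and ``k_bp`` are stochastic
    bimolecular rates applied directly to count products (1/s per pair);
    ``k_mn`` and ``k_bn`` are first-order dissociation rates.
    """

    k_2p: float
    k_2n: float
    k_1p: float
    k_1n: float
    k_on: float
    k_off: float
    k_mp: float = 1.0e-4
    k_mn: float = 1.0e-6
    k_bp: float = 2.0e-6
    k_bn: float = 1.0e-8

    def __post_init__(self) -> None:
        for name in CHANNEL_ORDER:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @classmethod
    def from_geometry(
        cls,
        geometry: GeometryParams | None = None,
        *,
        k_mp: float = 1.0e-4,
        k_mn: float = 1.0e-6,
        k_bp: float = 2.0e-6,
        k_bn: float = 1.0e-8,
        k_off_factor: float = 0.5,
    ) -> "RateConstants":
        """Build the full rate set from shell geometry plus binding constants.

        ``k_2p = D/h_t^2``, ``k_2n = D/h_b^2``, ``k_1p = k_1n = k_on = D/h_c^2``
        (all shells are equally thick, so the hop rates coincide) and
        ``k_off = k_off_factor * k_on``.  The default ``k_off_factor`` of 0.5
        keeps the adsorbed pool at twice the cell-layer count at equilibrium.
        """
        g = geometry if geometry is not None else GeometryParams()
        k_on = g.hop_rate(g.h_c)
        return cls(
            k_2p=g.hop_rate(g.h_t),
            k_2n=g.hop_rate(g.h_b),
            k_1p=g.hop_rate(g.h_c),
            k_1n=g.hop_rate(g.h_c),
            k_on=k_on,
            k_off=k_off_factor * k_on,
            k_mp=k_mp, k_mn=k_mn, k_bp=k_bp, k_bn=k_bn,
        )

    def as_array(self) -> np.ndarray:
        """Rates as a float64 vector in canonical channel order."""
        return np.array([getattr(self, name) for name in CHANNEL_ORDER],
                        dtype=np.float64)

    def with_binding(self, k_mp: float | None = None, k_mn: float | None = None,
                     k_bp: float | None = None, k_bn: float | None = None
                     ) -> "RateConstants":
        """Copy with some of the four binding constants replaced."""
        kw = {k: v for k, v in dict(k_mp=k_mp, k_mn=k_mn,
                                    k_bp=k_bp, k_bn=k_bn).items()
              if v is not None}
        return replace(self, **kw)


@dataclass(frozen=True)
class SystemState:
    """Integer molecule counts of the tracked populations plus simulated time.

    ``A_s`` is the constant transition-layer (source) count: it drives the
    influx channel but is never changed by a reaction.  ``R + AR + 2*ARR`` is
    an exact invariant of the dynamics (receptor conservation).
    """

    A_b: int = 0
    A_c: int = 0
    A_o: int = 0
    AR: int = 0
    ARR: int = 0
    R: int = 0
    A_s: int = 0
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_FIELDS + ("A_s",):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise ParameterError(f"{name} must be an integer count")
            if v < 0:
                raise ParameterError(f"{name} must be non-negative")

    @property
    def abc(self) -> int:
        """Antibodies bound per cell: ABC = AR + ARR."""
        return self.AR + self.ARR

    @property
    def bound_receptors(self) -> int:
        """Receptors engaged by bound mAbs: AR + 2*ARR."""
        return self.AR + 2 * self.ARR

    @property
    def receptor_total(self) -> int:
        """Conserved receptor total R + AR + 2*ARR."""
        return self.R + self.AR + 2 * self.ARR

    def as_array(self) -> np.ndarray:
        """Dynamic counts (A_b, A_c, A_o, AR, ARR, R) as an int64 vector."""
        return np.array([getattr(self, name) for name in STATE_FIELDS],
                        dtype=np.int64)

    @classmethod
    def from_array(cls, counts: Sequence[int], A_s: int, t: float = 0.0
                   ) -> "SystemState":
        vals = [int(c) for c in counts]
        return cls(**dict(zip(STATE_FIELDS, vals)), A_s=int(A_s), t=float(t))


@dataclass(frozen=True)
class ReactionChannel:
    """One elementary reaction: its rate law and its state-change vector.

    ``reactant_spec`` names the state fields whose counts the rate constant
    multiplies (one field for first-order channels, an ordered pair for the
    bimolecular ones; the influx channel uses the source field ``A_s``).
    ``delta`` is the signed change over ``STATE_FIELDS``.
    """

    name: str
    rate: float
    reactant_spec: Tuple[str, ...]
    delta: Tuple[int, ...] = field()

    def __post_init__(self) -> None:
        if len(self.delta) != len(STATE_FIELDS):
            raise ParameterError("delta must cover the six dynamic fields")
        if any(d not in (-1, 0, 1) for d in self.delta):
            raise ParameterError("delta entries must be in {-1, 0, +1}")

    def propensity(self, state: SystemState) -> float:
        """Rate constant times the product of the reactant counts (1/s)."""
        a = self.rate
        for fld in self.reactant_spec:
            a *= getattr(state, fld)
        return a


# (reactant fields, delta over STATE_FIELDS) per channel, in canonical order.
_CHANNEL_DEFS: dict[str, tuple[Tuple[str, ...], Tuple[int, ...]]] = {
    #          reactants        A_b A_c A_o  AR ARR   R
    "k_2p": (("A_s",),        ( +1,  0,  0,  0,  0,  0)),
    "k_2n": (("A_b",),        ( -1,  0,  0,  0,  0,  0)),
    "k_1p": (("A_b",),        ( -1, +1,  0,  0,  0,  0)),
    "k_1n": (("A_c",),        ( +1, -1,  0,  0,  0,  0)),
    "k_on": (("A_c",),        (  0, -1, +1,  0,  0,  0)),
    "k_off": (("A_o",),       (  0, +1, -1,  0,  0,  0)),
    "k_mp": (("A_o", "R"),    (  0,  0, -1, +1,  0, -1)),
    "k_mn": (("AR",),         (  0,  0, +1, -1,  0, +1)),
    "k_bp": (("AR", "R"),     (  0,  0,  0, -1, +1, -1)),
    "k_bn": (("ARR",),        (  0,  0,  0, +1, -1, +1)),
}


def build_channels(rates: RateConstants) -> list[ReactionChannel]:
    """Instantiate the ten reaction channels in canonical order.

    The influx channel ``k_2p`` has source semantics: it fires at rate
    ``k_2p * A_s`` and adds one molecule to the boundary layer without
    depleting the source; its reverse ``k_2n`` removes a boundary-layer
    molecule without crediting the source.
    """
    return [
        ReactionChannel(name=name, rate=getattr(rates, name),
                        reactant_spec=_CHANNEL_DEFS[name][0],
                        delta=_CHANNEL_DEFS[name][1])
        for name in CHANNEL_ORDER
    ]


def change_matrix(channels: Sequence[ReactionChannel] | None = None
                  ) -> np.ndarray:
    """The 10 x 6 stoichiometry (change) matrix, rows in channel order."""
    if channels is None:
        deltas = [_CHANNEL_DEFS[name][1] for name in CHANNEL_ORDER]
    else:
        deltas = [ch.delta for ch in channels]
    return np.array(deltas, dtype=np.int64)


def propensities(state: SystemState, channels: Sequence[ReactionChannel]
                 ) -> np.ndarray:
    """Propensity vector alpha (1/s), one entry per channel.

    A channel with any reactant count at zero has propensity exactly zero.
    """
    return np.array([ch.propensity(state) for ch in channels],
                    dtype=np.float64)


def apply_channel(state: SystemState, channel: ReactionChannel,
                  tau: float = 0.0) -> SystemState:
    """Apply one reaction event, returning the updated state.

    The source count ``A_s`` is untouched.  Raises :class:`InvariantViolation`
    if the update would drive any count negative, which can only happen if the
    channel was selected with an inconsistent propensity.
    """
    new = {}
    for fld, d in zip(STATE_FIELDS, channel.delta):
        v = getattr(state, fld) + d
        if v < 0:
            raise InvariantViolation(
                f"channel {channel.name} would make {fld} negative")
        new[fld] = v
    return SystemState(**new, A_s=state.A_s, t=state.t + tau)
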