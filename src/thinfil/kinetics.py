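"""State representation and the mass-action right-hand side.

The model has eight states but only six are independent: Tm position C and
the Ca2+-free uncoupled Tn state T1 are recovered from the two conservation
laws B + C + M = 1 (Tm) and B + T = 1 (Tn), where B = B1 + B2 + B3 and
T = T1 + T2 + T3.  The stored state is (B1, B2, B3, T2, T3, M).

All transitions except C->M are simple mass action, with every forward rate
written as the product (steady-state constant)·(reverse rate).  The C->M
transition follows the cooperative second-chance rate law

    dM/dt = K0'·k-0·C·(1 + (alpha-1)·M)^n  -  k-0·M

in which crossbridge turnover multiplies the opportunities for ensemble M
formation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import StateError
from .parameters import StandardConstants

STATE_LABELS = ("B1", "B2", "B3", "T2", "T3", "M")

#: negative excursions larger than this are an integration failure
NEGATIVE_HARD_LIMIT = -1e-9
#: smaller excursions are clamped to zero (round-off)
NEGATIVE_CLAMP = -1e-12
#: failure floor for the conservation-derived C and T1; negative C is a
#: strongly restoring direction, so brief solver excursions are harmless
#: (cancellation-limited and, under rigor, comparable to the true C itself)
DERIVED_NEGATIVE_HARD_LIMIT = -1e-4


@dataclass(frozen=True)
class StateVector:
    """Probabilities of the six independent states.

    B1/B2/B3: actin-coupled Tn with 0/1/2 bound Ca2+ (Tm in the blocking
    position); T2/T3: uncoupled Tn with 1/2 bound Ca2+; M: Tm in the
    myosin-dependent position.  C and T1 are conservation-derived.
    """

    B1: float = 0.0
    B2: float = 0.0
    B3: float = 0.0
    T2: float = 0.0
    T3: float = 0.0
    M: float = 0.0

    @property
    def B_total(self) -> float:
        return self.B1 + self.B2 + self.B3

    @property
    def C(self) -> float:
        """Tm central-position probability, 1 - B - M."""
        return 1.0 - self.B_total - self.M

    @property
    def T1(self) -> float:
        """Uncoupled Ca2+-free Tn probability, 1 - B - T2 - T3."""
        return 1.0 - self.B_total - self.T2 - self.T3

    @property
    def ca_bound_tn(self) -> float:
        """Total Ca2+-bound Tn, B2 + B3 + T2 + T3."""
        return self.B2 + self.B3 + self.T2 + self.T3

    @property
    def ca_bound_fast(self) -> float:
        """Fast-releasing pool (coupled states), B2 + B3."""
        return self.B2 + self.B3

    @property
    def ca_bound_slow(self) -> float:
        """Slow-releasing pool (uncoupled states), T2 + T3."""
        return self.T2 + self.T3

    def to_array(self) -> np.ndarray:
        return np.array([self.B1, self.B2, self.B3, self.T2, self.T3, self.M])

    @classmethod
    def from_array(cls, y) -> "StateVector":
        y = np.asarray(y, dtype=float)
        return cls(*[float(v) for v in y])

    def validate(self, slack: float = 1e-9) -> None:
        """Check the simplex invariants within ``slack``."""
        for name in STATE_LABELS:
            v = getattr(self, name)
            if v < -slack or v > 1.0 + slack:
                raise StateError(f"state {name}={v} outside [0, 1]")
        for name, v in (("C", self.C), ("T1", self.T1)):
            if v < -slack or v > 1.0 + slack:
                raise StateError(f"derived state {name}={v} outside [0, 1]")


class DerivedQuantities(NamedTuple):
    C: float
    T1: float
    B_total: float
    ca_bound_tn: float
    ca_bound_fast: float
    ca_bound_slow: float


def derived_quantities(state: StateVector) -> DerivedQuantities:
    """Conservation-derived probabilities and the Ca2+-bound Tn pools."""
    return DerivedQuantities(
        C=state.C,
        T1=state.T1,
        B_total=state.B_total,
        ca_bound_tn=state.ca_bound_tn,
        ca_bound_fast=state.ca_bound_fast,
        ca_bound_slow=state.ca_bound_slow,
    )


def rhs_array(y: np.ndarray, ca: float, k: StandardConstants) -> np.ndarray:
    """Time derivatives of (B1, B2, B3, T2, T3, M) at free [Ca2+] = ``ca``.

    Raw array form used by the integrators; ``ode_rhs`` is the validating
    front end.  States in (NEGATIVE_HARD_LIMIT, 0) are clamped to zero;
    anything below the hard limit raises :class:`StateError`.
    """
    if min(y) < NEGATIVE_HARD_LIMIT:
        raise StateError(
            f"state component below {NEGATIVE_HARD_LIMIT}: {np.asarray(y)}"
        )
    B1, B2, B3, T2, T3 = y[0], y[1], y[2], y[3], y[4]
    # only M enters a non-integer power; round-off negatives are clamped
    # there.  Every other occurrence is linear, where tiny negatives act as
    # a smooth restoring term — clamping them to zero would make the RHS
    # discontinuous and stall step-size control near C ~ 0 (rigor).
    M = max(y[5], 0.0)
    Btot = B1 + B2 + B3
    C = 1.0 - Btot - M
    T1 = 1.0 - Btot - T2 - T3
    # C and T1 are differences of O(1) sums, so their round-off floor is far
    # coarser than the stored states' (and under rigor the true C is ~1e-9)
    if C < DERIVED_NEGATIVE_HARD_LIMIT or T1 < DERIVED_NEGATIVE_HARD_LIMIT:
        raise StateError(f"conservation-derived state negative: C={C}, T1={T1}")

    on4 = k.K4 * k.km4 * ca  # Ca2+ on-rate of coupled Tn (1/s)
    on2 = k.K2 * k.km2 * ca  # Ca2+ on-rate of uncoupled Tn (1/s)

    dB1 = k.K1 * k.km1 * C * T1 + k.km4 * B2 - (k.km1 + on4) * B1
    dB2 = (
        k.K3 * k.km3 * C * T2 + k.km4 * B3 + on4 * B1
        - (k.km3 + k.km4 + on4) * B2
    )
    dB3 = k.K5 * k.km5 * C * T3 + on4 * B2 - (k.km4 + k.km5) * B3
    dT2 = (
        on2 * T1 + k.km3 * B2 + k.km2 * T3
        - (k.km2 + on2 + k.K3 * k.km3 * C) * T2
    )
    dT3 = on2 * T2 + k.km5 * B3 - (k.km2 + k.K5 * k.km5 * C) * T3
    dM = k.K0p * k.km0 * C * (1.0 + (k.alpha - 1.0) * M) ** k.n - k.km0 * y[5]
    return np.array([dB1, dB2, dB3, dT2, dT3, dM])


def ode_rhs(state, ca: float, constants: StandardConstants) -> np.ndarray:
    """Derivative vector (1/s) for a :class:`StateVector` or length-6 array."""
    if ca < 0:
        raise StateError("free [Ca2+] must be non-negative")
    y = state.to_array() if isinstance(state, StateVector) else np.asarray(state, float)
    return rhs_array(y, float(ca), constants)
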