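"""Model constants: equilibrium/steady-state constants and component rates.

The model couples two conserved subsystems — tropomyosin (Tm) positions
B/C/M and troponin (Tn) Ca2+ states — through the actin-coupled B states.
Each transition is parameterized by a dimensionless steady-state constant
(upper-case K) and a reverse component rate (lower-case k, written ``km*``
here for "k minus"); the forward rate is always their product.  Storing the
two factors separately makes "change the product K·k while holding K fixed"
— the operation used for all transient-data adjustments — a single-field
edit of the reverse rate.

Thermodynamics constrains the coupling ladder: K1/K3 = K3/K5 = K2/K4, so the
independent choices are K0', K1, K2 and K4; K3 and K5 follow.

Units: Ca2+ association constants K2, K4 in 1/uM; all rates in 1/s; the
coupling constants K0', K1, K3, K5, alpha and n are dimensionless.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .exceptions import ParameterError

#: relative tolerance for the thermodynamic ladder check
THERMO_RTOL = 1e-9

#: products adjustable while holding the steady-state constants fixed
ADJUSTABLE_PRODUCTS = ("K0p_km0_product", "K1_km1_product", "K4_km4_product")


@dataclass(frozen=True)
class StandardConstants:
    """Complete parameter set of the eight-state thin-filament model.

    ``K0p`` is the steady-state potential of the M state (0 simulates
    non-overlap, very large values simulate rigor); ``K1``/``K3``/``K5``
    couple Tn states with 0/1/2 bound Ca2+ to actin; ``K2`` and ``K4`` are
    the Ca2+ association constants of uncoupled and coupled Tn; ``alpha``
    and ``n`` parameterize the cooperative (second-chance) C->M rate law.
    """

    K0p: float
    K1: float
    K2: float
    K3: float
    K4: float
    K5: float
    km0: float
    km1: float
    km2: float
    km3: float
    km4: float
    km5: float
    alpha: float
    n: float

    def __post_init__(self):
        if self.K0p < 0:
            raise ParameterError("K0p must be >= 0")
        for name in ("K1", "K2", "K3", "K4", "K5", "km0", "km1", "km2", "km3",
                     "km4", "km5"):
            if not (getattr(self, name) > 0):
                raise ParameterError(f"{name} must be strictly positive")
        if self.alpha < 1:
            raise ParameterError("alpha must be >= 1")
        if self.n < 1:
            raise ParameterError("n must be >= 1")
        r = self.K2 / self.K4
        for lhs, rhs, label in (
            (self.K1 / self.K3, r, "K1/K3 = K2/K4"),
            (self.K3 / self.K5, r, "K3/K5 = K2/K4"),
        ):
            if abs(lhs - rhs) > THERMO_RTOL * abs(rhs):
                raise ParameterError(
                    f"thermodynamic constraint violated: {label} "
                    f"({lhs:.12g} != {rhs:.12g})"
                )

    # -- derived products (forward rates) -------------------------------

    @property
    def K0p_km0_product(self) -> float:
        """Forward rate of ensemble M formation, K0'·k-0 (1/s)."""
        return self.K0p * self.km0

    @property
    def K1_km1_product(self) -> float:
        """Forward rate of T1 -> B1 coupling per unit C·T1, K1·k-1 (1/s)."""
        return self.K1 * self.km1

    @property
    def K3_km3_product(self) -> float:
        return self.K3 * self.km3

    @property
    def K5_km5_product(self) -> float:
        return self.K5 * self.km5

    @property
    def K2_km2_product(self) -> float:
        """Ca2+ on-rate of uncoupled Tn, K2·k-2 (1/(uM·s))."""
        return self.K2 * self.km2

    @property
    def K4_km4_product(self) -> float:
        """Ca2+ on-rate of coupled Tn, K4·k-4 (1/(uM·s))."""
        return self.K4 * self.km4

    def cycle_products(self):
        """Detailed-balance products of the two thermodynamic cycles.

        Around T1->B1->B2->T2->T1 the forward/reverse rate ratio is
        (K1·K4)/(K3·K2); around T2->B2->B3->T3->T2 it is (K3·K4)/(K5·K2).
        Both equal 1 under the ladder constraint.
        """
        return (
            (self.K1 * self.K4) / (self.K3 * self.K2),
            (self.K3 * self.K4) / (self.K5 * self.K2),
        )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "StandardConstants":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ParameterError(f"unknown constant fields: {sorted(unknown)}")
        return cls(**payload)


def complete_constants(
    K0p: float = 1.0,
    K1: float = 800.0,
    K2: float = 1.67,
    K4: float = 0.167,
    km0: float = 50.0,
    km1: float = 100.0,
    km2: float = 15.0,
    km3: float = 100.0,
    km4: float = 150.0,
    km5: float = 100.0,
    alpha: float = 5.0,
    n: float = 3.25,
) -> StandardConstants:
    """Build a constant set from the independent parameters.

    K3 and K5 are derived from the thermodynamic ladder
    K1/K3 = K3/K5 = K2/K4, so the invariant holds by construction.
    Defaults are the standard conditions of the fast-twitch fits.
    """
    if not (K1 > 0 and K2 > 0 and K4 > 0):
        raise ParameterError("K1, K2 and K4 must be strictly positive")
    ratio = K2 / K4
    K3 = K1 / ratio
    K5 = K3 / ratio
    return StandardConstants(
        K0p=K0p, K1=K1, K2=K2, K3=K3, K4=K4, K5=K5,
        km0=km0, km1=km1, km2=km2, km3=km3, km4=km4, km5=km5,
        alpha=alpha, n=n,
    )


def standard_conditions() -> StandardConstants:
    """The standard parameter set (fast skeletal muscle, 16 C).

    K0'=1, K1=800, K2=1.67/uM, K4=0.167/uM (hence K3=80, K5=8),
    k-0=50/s, k-1=k-3=k-5=100/s, k-2=15/s, k-4=150/s, alpha=5, n=3.25.
    """
    return complete_constants()


def with_condition_k0p(constants: StandardConstants, k0p: float) -> StandardConstants:
    """Return a copy with the M-state potential K0' replaced (same k-0)."""
    if k0p < 0:
        raise ParameterError("K0p must be >= 0")
    return dataclasses.replace(constants, K0p=k0p)


def with_product_scaled(
    constants: StandardConstants, parameter: str, factor: float
) -> StandardConstants:
    """Scale one adjustable rate product while holding the K's fixed.

    The reverse rate moves "in tandem" so the steady-state constant — and
    therefore every equilibrium property — is unchanged:

    - ``K0p_km0_product``: scales k-0.
    - ``K1_km1_product``: scales the whole actin-coupling tier k-1, k-3, k-5
      together, preserving the fixed ratios of the ladder products
      K1k-1 : K3k-3 : K5k-5.  (Scaling k-1 alone is inert: the B1<->T1
      exchange is far faster than every other process, so only the ratio K1
      matters for it.)
    - ``K4_km4_product``: scales k-4, the fast Ca2+ off-rate of coupled Tn.
    """
    if parameter not in ADJUSTABLE_PRODUCTS:
        raise ParameterError(
            f"unknown adjustable parameter {parameter!r}; "
            f"choose one of {ADJUSTABLE_PRODUCTS}"
        )
    if not (factor > 0):
        raise ParameterError("scale factor must be positive")
    if parameter == "K0p_km0_product":
        return dataclasses.replace(constants, km0=constants.km0 * factor)
    if parameter == "K1_km1_product":
        return dataclasses.replace(
            constants,
            km1=constants.km1 * factor,
            km3=constants.km3 * factor,
            km5=constants.km5 * factor,
        )
    return dataclasses.replace(constants, km4=constants.km4 * factor)
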