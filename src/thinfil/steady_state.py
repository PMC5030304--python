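"""Steady-state solutions at fixed [Ca2+], activation curves, Hill fits.

Steady states are obtained by nullifying the ODE system.  The canonical
solver relaxes the dynamics from the empty (all-unbound, M = 0) state until
the residual criterion is met; this selects the branch reached from rest,
which is the branch every twitch simulation approaches.  Because the
cooperative M rate law can in principle admit multiple fixed points, an
independent algebraic solver reduces the system to a scalar root problem in
C and reports every bracketed root in [0, 1]; it serves as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, curve_fit

from .exceptions import ConvergenceError, FitDomainError, ParameterError
from .kinetics import StateVector, rhs_array
from .parameters import StandardConstants

#: default residual criterion, max |dy/dt| in 1/s
DEFAULT_RHS_TOL = 1e-8

CURVE_QUANTITIES = ("M", "ca_bound_tn")


def default_ca_grid(num: int = 60, lo: float = 1e-2, hi: float = 1e2) -> np.ndarray:
    """Log-spaced [Ca2+] grid (uM) spanning both Kd values (0.6 and 6 uM)."""
    return np.logspace(np.log10(lo), np.log10(hi), num)


def solve_steady_state(
    constants: StandardConstants,
    ca: float,
    rhs_tol: float = DEFAULT_RHS_TOL,
    max_time: float = 200.0,
    rtol: float = 1e-12,
    atol: float = 1e-14,
) -> StateVector:
    """Relax the system at fixed ``ca`` (uM) until max |dy/dt| < ``rhs_tol``.

    Integration starts from the empty state (T1 = C = 1) and proceeds in
    chunks; raises :class:`ConvergenceError` with the final residual norm if
    the criterion is not met within ``max_time`` seconds of model time.
    """
    if ca < 0:
        raise ParameterError("ca must be non-negative")
    fun = lambda t, y: rhs_array(y, ca, constants)  # noqa: E731
    # the dM/dt term multiplies the conservation-derived C, whose round-off
    # floor is ~eps, by K0'k-0(1+(alpha-1)M)^n; below that amplified noise
    # the residual criterion is unattainable in float64 (rigor: C* ~ 1e-9)
    dm_gain = constants.K0p * constants.km0 * constants.alpha ** constants.n
    noise_floor = 16.0 * np.finfo(float).eps * max(dm_gain, 1.0)
    y = np.zeros(6)
    elapsed = 0.0
    chunk = 2.0
    while elapsed < max_time:
        sol = solve_ivp(fun, (0.0, chunk), y, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise ConvergenceError(f"relaxation integrator failed: {sol.message}")
        change = float(np.max(np.abs(sol.y[:, -1] - y)))
        y = sol.y[:, -1]
        elapsed += chunk
        resid = float(np.max(np.abs(fun(0.0, y))))
        if resid < rhs_tol or (resid < noise_floor and change < 1e-10):
            return StateVector.from_array(np.clip(y, 0.0, 1.0))
    raise ConvergenceError(
        f"steady state not reached within {max_time} s (residual {resid:.3e}/s)",
        residual_norm=resid,
    )


# -- algebraic cross-check ----------------------------------------------


def _tn_equilibrium_weights(constants: StandardConstants, ca: float, C: float):
    """Unnormalized Tn-state weights at fixed C from detailed balance.

    T2/T1 = T3/T2 = K2·ca; B1/T1 = K1·C; B2/B1 = B3/B2 = K4·ca.
    """
    x2 = constants.K2 * ca
    x4 = constants.K4 * ca
    t1, t2, t3 = 1.0, x2, x2 * x2
    b1 = constants.K1 * C
    b2 = b1 * x4
    b3 = b2 * x4
    return np.array([b1, b2, b3, t1, t2, t3])


def equilibrium_roots(constants: StandardConstants, ca: float):
    """All algebraic steady states as a list of :class:`StateVector`.

    For fixed C the mass-action subsystem is at equilibrium with the chain
    ratios above; normalizing over Tn gives B_total(C), Tm conservation gives
    M = 1 - B_total - C, and the remaining condition is the fixed point of
    the cooperative rate law, M = K0'·C·(1+(alpha-1)·M)^n.  The scalar
    residual in C is scanned on a dense (linear plus logarithmic) grid and
    every sign change is bracketed with Brent's method.
    """
    if ca < 0:
        raise ParameterError("ca must be non-negative")

    def residual(C: float) -> float:
        w = _tn_equilibrium_weights(constants, ca, C)
        b_total = w[:3].sum() / w.sum()
        M = 1.0 - b_total - C
        if M < 0:
            # outside the physical simplex; monotone penalty keeps brackets sane
            return M
        return M - constants.K0p * C * (
            1.0 + (constants.alpha - 1.0) * M
        ) ** constants.n

    grid = np.unique(
        np.concatenate([np.linspace(0.0, 1.0, 2001), np.logspace(-12, 0, 241)])
    )
    vals = np.array([residual(c) for c in grid])
    roots = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0:
            roots.append(brentq(residual, grid[i], grid[i + 1], xtol=1e-15))
    if vals[-1] == 0.0:
        roots.append(grid[-1])

    states = []
    for C in roots:
        w = _tn_equilibrium_weights(constants, ca, C)
        w = w / w.sum()
        b1, b2, b3, _, t2, t3 = w
        M = max(1.0 - (b1 + b2 + b3) - C, 0.0)
        states.append(StateVector(B1=b1, B2=b2, B3=b3, T2=t2, T3=t3, M=M))
    return states


def chain_binding_closed_form(constants: StandardConstants, ca_grid) -> np.ndarray:
    """Ca2+-bound Tn of the uncoupled two-step chain (the C = 0 rigor limit).

    With all Tn uncoupled, T2/T1 = T3/T2 = K2·ca, so the bound fraction is
    (x + x^2) / (1 + x + x^2) with x = K2·ca.
    """
    x = constants.K2 * np.asarray(ca_grid, dtype=float)
    return (x + x * x) / (1.0 + x + x * x)


# -- activation / binding curves ----------------------------------------


@dataclass
class ActivationCurve:
    """A steady-state quantity sampled on a strictly increasing Ca2+ grid."""

    ca_grid: np.ndarray
    values: np.ndarray
    quantity_label: str
    normalized: bool = False
    states: list = field(default=None, repr=False)

    def __post_init__(self):
        self.ca_grid = np.asarray(self.ca_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ca_grid.shape != self.values.shape:
            raise ParameterError("ca_grid and values must have equal length")
        if np.any(np.diff(self.ca_grid) <= 0):
            raise ParameterError("ca_grid must be strictly increasing")

    @property
    def normalized_values(self) -> np.ndarray:
        """Min-max normalization of the values over the grid."""
        lo, hi = self.values.min(), self.values.max()
        if hi == lo:
            raise FitDomainError("curve is constant; cannot normalize")
        return (self.values - lo) / (hi - lo)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ca_uM": self.ca_grid,
                "value": self.values,
                "normalized_value": self.normalized_values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_curve(
    constants: StandardConstants,
    ca_grid=None,
    quantity: str = "ca_bound_tn",
    rhs_tol: float = DEFAULT_RHS_TOL,
) -> ActivationCurve:
    """Steady-state ``quantity`` ('M' or 'ca_bound_tn') over a Ca2+ grid."""
    if quantity not in CURVE_QUANTITIES:
        raise ParameterError(f"quantity must be one of {CURVE_QUANTITIES}")
    grid = default_ca_grid() if ca_grid is None else np.asarray(ca_grid, dtype=float)
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ParameterError("ca_grid must be non-negative and strictly increasing")
    values = np.empty_like(grid)
    states = []
    for i, ca in enumerate(grid):
        try:
            st = solve_steady_state(constants, float(ca), rhs_tol=rhs_tol)
        except ConvergenceError as err:
            raise ConvergenceError(
                f"steady state failed at grid point ca={ca:.6g} uM: {err}",
                residual_norm=err.residual_norm,
            ) from err
        states.append(st)
        values[i] = st.M if quantity == "M" else st.ca_bound_tn
    return ActivationCurve(grid, values, quantity_label=quantity, states=states)


# -- Hill fitting --------------------------------------------------------


@dataclass(frozen=True)
class HillFit:
    """Least-squares Hill parameters of a normalized activation curve."""

    k_half: float   # uM
    n_hill: float   # dimensionless
    rss: float
    converged: bool


def _hill(ca, k_half, n_hill, baseline, amplitude):
    return baseline + amplitude * ca ** n_hill / (k_half ** n_hill + ca ** n_hill)


def hill_fit(curve: ActivationCurve) -> HillFit:
    """Fit a Hill function to the min-max normalized curve.

    The fitted form is y0 + A·ca^n / (k^n + ca^n) with floating baseline and
    amplitude, so a curve that is exactly Hill on the absolute scale stays
    exactly Hill after min-max normalization over a finite grid (the affine
    rescaling is absorbed by y0 and A).  Requires the curve to span at least
    [0.05, 0.95] of its own maximum so the transition is actually sampled;
    otherwise :class:`FitDomainError`.
    """
    v = curve.values
    if v.max() <= 0 or v.min() > 0.05 * v.max():
        raise FitDomainError(
            "curve does not span [0.05, 0.95] of its maximum; widen the grid"
        )
    y = curve.normalized_values
    # initial guess: half-crossing of the normalized curve, unit slope
    k0 = float(np.interp(0.5, y, curve.ca_grid))
    try:
        popt, _ = curve_fit(
            _hill,
            curve.ca_grid,
            y,
            p0=[k0, 1.0, 0.0, 1.0],
            bounds=([1e-12, 1e-3, -0.5, 0.1], [np.inf, 100.0, 0.5, 2.0]),
            maxfev=20000,
        )
        converged = True
    except RuntimeError:
        popt, converged = (k0, 1.0, 0.0, 1.0), False
    resid = y - _hill(curve.ca_grid, *popt)
    return HillFit(
        k_half=float(popt[0]),
        n_hill=float(popt[1]),
        rss=float(np.sum(resid ** 2)),
        converged=converged,
    )
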