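"""Free-Ca2+ stimulus driving the thin-filament model.

The standard twitch stimulus is the empirical transient of free Ca2+ in fast
skeletal muscle: a linear rise from baseline to the peak at ``t_peak`` followed
by a single-exponential decay back to baseline.  Arbitrary measured transients
can be supplied as tabulated (time, concentration) pairs and are evaluated by
piecewise-linear interpolation with constant extrapolation beyond the last
knot (no dynamics are invented outside the measured window).

Units: time in seconds, concentration in micromolar throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, ParameterError

#: default time of the stimulus peak (s)
DEFAULT_T_PEAK = 0.005
#: default exponential decay rate constant of the stimulus (1/s)
DEFAULT_DECAY_RATE = 100.0
#: default peak free [Ca2+] (uM); near-saturating for the weak site (Kd = 1/K4 = 6 uM)
DEFAULT_AMPLITUDE = 20.0


@dataclass(frozen=True)
class CalciumTransient:
    """Free [Ca2+](t) stimulus, either analytic or tabulated.

    Parameters
    ----------
    kind : {'analytic', 'tabulated'}
    amplitude : float
        Peak free [Ca2+] in uM (analytic kind).
    t_peak : float
        Time of the peak in s (analytic kind).
    decay_rate : float
        Exponential decay rate constant in 1/s (analytic kind).
    baseline : float
        Pre-stimulus [Ca2+] in uM.
    table : tuple of (time, concentration) pairs or None
        Strictly increasing times; used for the tabulated kind.
    """

    kind: str = "analytic"
    amplitude: float = DEFAULT_AMPLITUDE
    t_peak: float = DEFAULT_T_PEAK
    decay_rate: float = DEFAULT_DECAY_RATE
    baseline: float = 0.0
    table: tuple = field(default=None)

    def __post_init__(self):
        if self.kind not in ("analytic", "tabulated"):
            raise ParameterError(f"unknown transient kind {self.kind!r}")
        if self.kind == "analytic":
            if not (self.amplitude > 0):
                raise ParameterError("amplitude must be positive")
            if not (self.t_peak > 0):
                raise ParameterError("t_peak must be positive")
            if not (self.decay_rate > 0):
                raise ParameterError("decay_rate must be positive")
            if self.baseline < 0:
                raise ParameterError("baseline must be non-negative")
            if self.baseline > self.amplitude:
                raise ParameterError("baseline must not exceed amplitude")
        else:
            if self.table is None or len(self.table) == 0:
                raise ParameterError("tabulated transient requires a non-empty table")
            t = np.asarray([p[0] for p in self.table], dtype=float)
            c = np.asarray([p[1] for p in self.table], dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ParameterError("table times must be strictly increasing")
            if np.any(t < 0):
                raise ParameterError("table times must be non-negative")
            if np.any(c < 0):
                raise ParameterError("table concentrations must be non-negative")

    # -- evaluation -----------------------------------------------------

    def __call__(self, t):
        return evaluate_transient(self, t)

    @property
    def times(self):
        """Knot times of a tabulated transient."""
        return np.asarray([p[0] for p in self.table], dtype=float)

    @property
    def concentrations(self):
        return np.asarray([p[1] for p in self.table], dtype=float)


def make_standard_transient(
    amplitude: float = DEFAULT_AMPLITUDE,
    t_peak: float = DEFAULT_T_PEAK,
    decay_rate: float = DEFAULT_DECAY_RATE,
    baseline: float = 0.0,
) -> CalciumTransient:
    """Build the analytic standard stimulus.

    [Ca2+](t) rises linearly from ``baseline`` at t=0 to ``amplitude`` at
    ``t_peak`` and then relaxes exponentially back to ``baseline`` with rate
    constant ``decay_rate``.
    """
    return CalciumTransient(
        kind="analytic",
        amplitude=amplitude,
        t_peak=t_peak,
        decay_rate=decay_rate,
        baseline=baseline,
    )


def make_tabulated_transient(times, concentrations) -> CalciumTransient:
    """Build a tabulated transient from two equal-length sequences."""
    times = np.asarray(times, dtype=float)
    concentrations = np.asarray(concentrations, dtype=float)
    if times.shape != concentrations.shape:
        raise ParameterError("times and concentrations must have equal length")
    return CalciumTransient(
        kind="tabulated", table=tuple(zip(times.tolist(), concentrations.tolist()))
    )


def evaluate_transient(transient: CalciumTransient, t):
    """Evaluate [Ca2+] at time(s) ``t`` (s), returning uM.

    Accepts a scalar or array; raises :class:`DomainError` for negative times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("stimulus is defined for t >= 0 only")
    if transient.kind == "analytic":
        rise = transient.baseline + (
            transient.amplitude - transient.baseline
        ) * t_arr / transient.t_peak
        fall = transient.baseline + (
            transient.amplitude - transient.baseline
        ) * np.exp(-transient.decay_rate * (t_arr - transient.t_peak))
        out = np.where(t_arr <= transient.t_peak, rise, fall)
    else:
        knots_t = transient.times
        knots_c = transient.concentrations
        # np.interp already holds endpoint values outside the table
        out = np.interp(t_arr, knots_t, knots_c)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


# -- CSV interface (header: time_s, ca_uM) ------------------------------


def read_transient_csv(path) -> CalciumTransient:
    """Read a tabulated transient from a 2-column CSV (time_s, ca_uM)."""
    frame = pd.read_csv(path)
    if not {"time_s", "ca_uM"}.issubset(frame.columns):
        raise ParameterError("transient CSV must have columns time_s, ca_uM")
    return make_tabulated_transient(frame["time_s"].to_numpy(), frame["ca_uM"].to_numpy())


def write_transient_csv(transient: CalciumTransient, path, horizon: float = 0.2,
                        dt: float = 0.0005) -> None:
    """Sample a transient onto a uniform grid and write it as CSV."""
    times = np.arange(0.0, horizon + dt / 2, dt)
    values = evaluate_transient(transient, times)
    pd.DataFrame({"time_s": times, "ca_uM": values}).to_csv(path, index=False)
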