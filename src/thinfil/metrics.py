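"""Twitch metrics: residual Ca2+-bound Tn pool, areas, peaks, sensitivity.

The headline quantity is the crossbridge-dependent Ca2+-bound Tn residual:
the pointwise difference between the Ca2+-bound Tn transients simulated with
and without filament overlap under an identical free-Ca2+ stimulus.  Its
area relative to the overlap transient and the time of its maximum summarize
how cycling crossbridges delay Ca2+ release from troponin.

Directional sensitivity scans adjust one rate product at fixed steady-state
constants (the reverse rate moves in tandem) and classify the response of a
peak/decay observable, reproducing the published adjustment table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import (
    ComparabilityError,
    DegenerateSeriesError,
    ParameterError,
    UndefinedFractionError,
)
from .parameters import (
    ADJUSTABLE_PRODUCTS,
    StandardConstants,
    with_product_scaled,
)
from .stimulus import CalciumTransient
from .transient import Condition, Trajectory, simulate_twitch

OBSERVABLES = ("M_peak_width", "M_peak_height", "M_peak_center", "ca_bound_decay")
RESPONSES = ("increase", "decrease", "shift_left", "shift_right", "no_change")

#: relative change below which a sensitivity response is called no_change
DEFAULT_SENSITIVITY_THRESHOLD = 0.02


@dataclass(frozen=True)
class TimeSeries:
    """A sampled scalar series on a strictly increasing time grid."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ParameterError("times and values must be equal-length 1-D arrays")
        if self.times.size == 0:
            raise ParameterError("series must be non-empty")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")

    def interp(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.values)


def trajectory_series(traj: Trajectory, name: str) -> TimeSeries:
    """Extract a named derived series from a trajectory."""
    table = {
        "M": traj.M,
        "C": traj.C,
        "B_total": traj.B_total,
        "ca_bound_tn": traj.ca_bound_tn,
        "fast": traj.ca_bound_fast,
        "slow": traj.ca_bound_slow,
        "ca": traj.ca,
    }
    if name not in table:
        raise ParameterError(f"unknown series {name!r}; choose from {sorted(table)}")
    return TimeSeries(traj.times, table[name], label=name)


def _same_stimulus(a: CalciumTransient, b: CalciumTransient) -> bool:
    if a.kind != b.kind:
        return False
    if a.kind == "analytic":
        return (
            a.amplitude == b.amplitude
            and a.t_peak == b.t_peak
            and a.decay_rate == b.decay_rate
            and a.baseline == b.baseline
        )
    return a.table == b.table


def crossbridge_dependent_residual(
    traj_overlap: Trajectory, traj_nonoverlap: Trajectory
) -> TimeSeries:
    """Overlap minus non-overlap Ca2+-bound Tn under a shared stimulus."""
    if traj_overlap.times.shape != traj_nonoverlap.times.shape or np.any(
        traj_overlap.times != traj_nonoverlap.times
    ):
        raise ComparabilityError("trajectories are not on the same time grid")
    if not _same_stimulus(traj_overlap.stimulus, traj_nonoverlap.stimulus):
        raise ComparabilityError("trajectories were driven by different stimuli")
    return TimeSeries(
        traj_overlap.times,
        traj_overlap.ca_bound_tn - traj_nonoverlap.ca_bound_tn,
        label="crossbridge_dependent_ca_bound_tn",
    )


def auc_fraction(part: TimeSeries, whole: TimeSeries, window=(0.0, 0.2)) -> float:
    """100 x (trapezoidal area of ``part``) / (area of ``whole``) over ``window``."""
    if part.times.shape != whole.times.shape or np.any(part.times != whole.times):
        raise ComparabilityError("series must share a time grid")
    lo, hi = window
    if lo < part.times[0] - 1e-12 or hi > part.times[-1] + 1e-12:
        raise ComparabilityError("window extends beyond the series span")
    mask = (part.times >= lo) & (part.times <= hi)
    t = part.times[mask]
    denom = np.trapezoid(whole.values[mask], t)
    if denom == 0.0:
        raise UndefinedFractionError("reference series has zero area over the window")
    return float(100.0 * np.trapezoid(part.values[mask], t) / denom)


def peak_time(series: TimeSeries) -> float:
    """Time of the global maximum, earliest on ties, quadratically refined.

    The three samples around the discrete maximum define a parabola whose
    vertex refines the peak to sub-grid resolution.  A constant series is
    degenerate: the first time is returned with a warning.
    """
    v = series.values
    if np.all(v == v[0]):
        warnings.warn("constant series: peak time is degenerate", RuntimeWarning)
        return float(series.times[0])
    i = int(np.argmax(v))  # argmax takes the earliest of tied maxima
    if 0 < i < v.size - 1:
        a, b, c = v[i - 1], v[i], v[i + 1]
        denom = a - 2 * b + c
        if denom < 0:  # proper local maximum; refine
            left = series.times[i] - series.times[i - 1]
            right = series.times[i + 1] - series.times[i]
            if abs(left - right) < 1e-12 * max(left, right):
                return float(series.times[i] + 0.5 * left * (a - c) / denom)
    return float(series.times[i])


def normalize_trace(series: TimeSeries, mode: str = "minmax") -> TimeSeries:
    """Map a series to [0, 1] (``minmax``) or divide by its peak (``peak``)."""
    if mode not in ("minmax", "peak"):
        raise ParameterError("mode must be 'minmax' or 'peak'")
    v = series.values
    if mode == "minmax":
        lo, hi = v.min(), v.max()
        if hi == lo:
            raise DegenerateSeriesError("constant series cannot be min-max normalized")
        out = (v - lo) / (hi - lo)
    else:
        pk = v.max()
        if pk == 0:
            raise DegenerateSeriesError("series peak is zero")
        out = v / pk
    return TimeSeries(series.times, out, label=series.label)


def full_width_half_max(series: TimeSeries) -> float:
    """FWHM of a single-peaked series, linearly interpolated crossings (s)."""
    v = series.values
    i = int(np.argmax(v))
    half = v[i] / 2.0
    before = np.nonzero(v[: i + 1] < half)[0]
    after = np.nonzero(v[i:] < half)[0]
    if before.size == 0 or after.size == 0:
        raise ComparabilityError("series does not fall below half maximum on both sides")
    li = before[-1]
    t_left = np.interp(half, [v[li], v[li + 1]], [series.times[li], series.times[li + 1]])
    ri = i + after[0]
    t_right = np.interp(half, [v[ri], v[ri - 1]], [series.times[ri], series.times[ri - 1]])
    return float(t_right - t_left)


def peak_center(series: TimeSeries) -> float:
    """Midpoint of the half-maximum crossings (s); robust peak location."""
    v = series.values
    i = int(np.argmax(v))
    half = v[i] / 2.0
    before = np.nonzero(v[: i + 1] < half)[0]
    after = np.nonzero(v[i:] < half)[0]
    if before.size == 0 or after.size == 0:
        raise ComparabilityError("series does not fall below half maximum on both sides")
    li = before[-1]
    t_left = np.interp(half, [v[li], v[li + 1]], [series.times[li], series.times[li + 1]])
    ri = i + after[0]
    t_right = np.interp(half, [v[ri], v[ri - 1]], [series.times[ri], series.times[ri - 1]])
    return float(0.5 * (t_left + t_right))


def decay_half_time(series: TimeSeries) -> float:
    """Time from the peak to the first crossing of half the peak value (s)."""
    v = series.values
    i = int(np.argmax(v))
    half = v[i] / 2.0
    after = np.nonzero(v[i:] < half)[0]
    if after.size == 0:
        raise ComparabilityError("series never decays below half its peak")
    j = i + after[0]
    t_half = np.interp(half, [v[j], v[j - 1]], [series.times[j], series.times[j - 1]])
    return float(t_half - series.times[i])


class TraceComparison(NamedTuple):
    rmse: float
    peak_time_difference: float
    decay_half_time_difference: float


def compare_traces(model: TimeSeries, data: TimeSeries) -> TraceComparison:
    """Shape comparison of a model series against a (possibly coarser) trace.

    Both series are min-max normalized, the model is linearly interpolated
    onto the data grid, and the rmse is taken over the shared support.  Peak
    times and decay half-times are compared on the normalized series.
    """
    if data.times[0] < model.times[0] - 1e-12 or data.times[-1] > model.times[-1] + 1e-12:
        raise ComparabilityError("data times extend beyond the model span")
    m = normalize_trace(model, "minmax")
    d = normalize_trace(data, "minmax")
    resid = m.interp(d.times) - d.values
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    dt_peak = peak_time(d) - peak_time(m)
    try:
        dt_decay = decay_half_time(d) - decay_half_time(m)
    except ComparabilityError:
        # one of the series never falls below half its peak (e.g. a rising
        # or truncated trace); the decay comparison is undefined, not fatal
        dt_decay = float("nan")
    return TraceComparison(rmse, float(dt_peak), float(dt_decay))


# -- directional sensitivity --------------------------------------------


@dataclass(frozen=True)
class SensitivityResult:
    """Classified response of one observable to one rate-product adjustment."""

    parameter: str
    direction: str            # 'increase' | 'decrease' of the product
    observable: str
    response: str             # one of RESPONSES
    baseline_value: float
    adjusted_value: float
    relative_change: float


def _observable_value(traj: Trajectory, observable: str) -> float:
    if observable == "M_peak_width":
        return full_width_half_max(trajectory_series(traj, "M"))
    if observable == "M_peak_height":
        return float(traj.M.max())
    if observable == "M_peak_center":
        return peak_center(trajectory_series(traj, "M"))
    if observable == "ca_bound_decay":
        return decay_half_time(trajectory_series(traj, "ca_bound_tn"))
    raise ParameterError(f"unknown observable {observable!r}; choose from {OBSERVABLES}")


def sensitivity_scan(
    constants: StandardConstants,
    parameter: str,
    factor: float,
    transient: CalciumTransient = None,
    condition: Condition = None,
    observable: str = "M_peak_width",
    threshold: float = DEFAULT_SENSITIVITY_THRESHOLD,
    **sim_kwargs,
) -> SensitivityResult:
    """Simulate baseline and adjusted twitches and classify the change.

    ``parameter`` is one of the adjustable rate products; the steady-state
    constant is held fixed (the reverse rate moves in tandem).  Timing
    observables map to shift_left/shift_right, magnitudes to
    increase/decrease; relative changes below ``threshold`` are no_change.
    """
    if parameter not in ADJUSTABLE_PRODUCTS:
        raise ParameterError(
            f"unknown parameter {parameter!r}; choose from {ADJUSTABLE_PRODUCTS}"
        )
    base = simulate_twitch(constants, transient, condition, **sim_kwargs)
    adjusted_constants = with_product_scaled(constants, parameter, factor)
    adj = simulate_twitch(adjusted_constants, transient, condition, **sim_kwargs)
    b = _observable_value(base, observable)
    a = _observable_value(adj, observable)
    rel = (a - b) / b if b != 0 else np.inf * np.sign(a - b)
    if abs(rel) < threshold:
        response = "no_change"
    elif observable == "M_peak_center":
        response = "shift_right" if rel > 0 else "shift_left"
    else:
        response = "increase" if rel > 0 else "decrease"
    return SensitivityResult(
        parameter=parameter,
        direction="increase" if factor > 1 else "decrease",
        observable=observable,
        response=response,
        baseline_value=float(b),
        adjusted_value=float(a),
        relative_change=float(rel),
    )


# -- full adjustment-table report ---------------------------------------

#: rows of the published adjustment table that are expressible as a single
#: rate-product scan: (variable, parameter, factor, condition, observable,
#: expected response)
ADJUSTMENT_TABLE_SCANS = (
    ("M_peak_width", "K0p_km0_product", 0.5, "overlap", "M_peak_width", "increase"),
    ("M_peak_width", "K1_km1_product", 0.5, "overlap", "M_peak_width", "increase"),
    ("M_peak_height", "K0p_km0_product", 2.0, "overlap", "M_peak_height", "increase"),
    ("M_peak_height", "K1_km1_product", 2.0, "overlap", "M_peak_height", "increase"),
    ("M_peak_center", "K0p_km0_product", 0.5, "overlap", "M_peak_center", "shift_right"),
    ("M_peak_center", "K1_km1_product", 0.5, "overlap", "M_peak_center", "shift_right"),
    ("ca_bound_decay_nonoverlap", "K4_km4_product", 2.0, "non_overlap",
     "ca_bound_decay", "decrease"),
    ("ca_bound_decay_overlap", "K1_km1_product", 2.0, "overlap",
     "ca_bound_decay", "decrease"),
)


def steady_state_lateral_shift(constants, factor: float = 0.5):
    """Lateral shift of the steady-state M-activation curve when K1 scales.

    Scaling the coupling ladder (K1, hence K3 and K5) moves the activation
    curve along the Ca2+ axis without reshaping it much; the returned pair
    is (baseline, adjusted) half-activation [Ca2+] in uM, read off the
    min-max normalized curve's half-crossing (robust even when the rest-state
    M floor rises and the curve no longer spans a full Hill transition).
    """
    from .parameters import complete_constants
    from .steady_state import compute_curve

    def half_crossing(curve):
        y = curve.normalized_values
        return float(np.interp(0.5, y, curve.ca_grid))

    base_curve = compute_curve(constants, quantity="M")
    adjusted = complete_constants(
        K0p=constants.K0p, K1=constants.K1 * factor, K2=constants.K2,
        K4=constants.K4, km0=constants.km0, km1=constants.km1,
        km2=constants.km2, km3=constants.km3, km4=constants.km4,
        km5=constants.km5, alpha=constants.alpha, n=constants.n,
    )
    adj_curve = compute_curve(adjusted, quantity="M")
    return half_crossing(base_curve), half_crossing(adj_curve)


def c_binding_alignment_shift(constants, transient=None, factor: float = 2.0,
                              **sim_kwargs):
    """Change in the C-state vs Ca2+-bound-Tn decay alignment (non-overlap).

    Returns (baseline difference, adjusted difference) of the two decay
    half-times when the coupling-tier products K1k-1/K3k-3/K5k-5 scale by
    ``factor``; a smaller difference means the two transients align more
    closely.
    """
    cond = Condition.non_overlap()

    def dif(k):
        traj = simulate_twitch(k, transient, cond, **sim_kwargs)
        return decay_half_time(trajectory_series(traj, "C")) - decay_half_time(
            trajectory_series(traj, "ca_bound_tn")
        )

    return dif(constants), dif(with_product_scaled(constants, "K1_km1_product", factor))


def adjustment_table_report(constants, transient=None, **sim_kwargs):
    """Evaluate every row of the published adjustment table.

    Returns a list of dicts with the adjusted parameter, the observable, the
    expected and observed responses, and a ``reproduced`` flag.  The two
    rows that are not single rate-product scans (the steady-state lateral
    shift and the C-vs-binding alignment) are computed by their dedicated
    helpers.
    """
    rows = []
    for variable, parameter, factor, cond_name, observable, expected in (
        ADJUSTMENT_TABLE_SCANS
    ):
        result = sensitivity_scan(
            constants, parameter, factor,
            transient=transient, condition=Condition.from_name(cond_name),
            observable=observable, **sim_kwargs,
        )
        rows.append(
            {
                "variable": variable,
                "parameter": parameter,
                "factor": factor,
                "condition": cond_name,
                "observable": observable,
                "expected": expected,
                "observed": result.response,
                "relative_change": result.relative_change,
                "reproduced": result.response == expected,
            }
        )
    k_base, k_adj = steady_state_lateral_shift(constants)
    rel = (k_adj - k_base) / k_base
    rows.append(
        {
            "variable": "steady_state_activation_shift",
            "parameter": "K1_ladder",
            "factor": 0.5,
            "condition": "steady_state",
            "observable": "activation_k_half",
            "expected": "lateral_shift",
            "observed": "lateral_shift" if abs(rel) > DEFAULT_SENSITIVITY_THRESHOLD
            else "no_change",
            "relative_change": float(rel),
            "reproduced": abs(rel) > DEFAULT_SENSITIVITY_THRESHOLD,
        }
    )
    d_base, d_adj = c_binding_alignment_shift(constants, transient, **sim_kwargs)
    rel = (d_adj - d_base) / d_base
    rows.append(
        {
            "variable": "c_binding_alignment",
            "parameter": "K1_km1_product",
            "factor": 2.0,
            "condition": "non_overlap",
            "observable": "c_minus_binding_decay_half_time",
            "expected": "decrease",
            "observed": "decrease" if rel < -DEFAULT_SENSITIVITY_THRESHOLD
            else ("increase" if rel > DEFAULT_SENSITIVITY_THRESHOLD else "no_change"),
            "relative_change": float(rel),
            "reproduced": rel < -DEFAULT_SENSITIVITY_THRESHOLD,
        }
    )
    return rows
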