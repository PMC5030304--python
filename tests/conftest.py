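"""Shared fixtures: standard constants, stimulus, and cached twitch pair."""

import numpy as np
import pytest

import thinfil as tf


@pytest.fixture(scope="session")
def constants():
    return tf.standard_conditions()


@pytest.fixture(scope="session")
def stimulus():
    return tf.make_standard_transient()


@pytest.fixture(scope="session")
def overlap_trajectory(constants, stimulus):
    return tf.simulate_twitch(constants, stimulus, tf.Condition.overlap())


@pytest.fixture(scope="session")
def nonoverlap_trajectory(constants, stimulus):
    return tf.simulate_twitch(constants, stimulus, tf.Condition.non_overlap())


@pytest.fixture(scope="session")
def residual_series(overlap_trajectory, nonoverlap_trajectory):
    return tf.crossbridge_dependent_residual(overlap_trajectory, nonoverlap_trajectory)


def equilibrium_oracle(constants, ca, k0p):
    """Brute-force equilibrium of the 7-state subsystem (M from its fixed point).

    Independent of the package solvers: state ratios are written directly
    from detailed balance (T2/T1 = T3/T2 = K2*ca; B1 = K1*C*T1;
    B2/B1 = B3/B2 = K4*ca), the two conservation laws close the system, and
    the scalar unknown C is found by bisection of the Tm balance.
    """
    K1, K2, K4 = constants.K1, constants.K2, constants.K4
    alpha, n = constants.alpha, constants.n

    def tm_balance(C):
        x2, x4 = K2 * ca, K4 * ca
        w = np.array([K1 * C, K1 * C * x4, K1 * C * x4 ** 2, 1.0, x2, x2 ** 2])
        w = w / w.sum()
        b_total = w[:3].sum()
        M = 1.0 - b_total - C
        if M < 0:
            return M
        return M - k0p * C * (1.0 + (alpha - 1.0) * M) ** n

    lo, hi = 0.0, 1.0
    flo = tm_balance(lo)
    # bisection on the first sign change from C=0 upward
    grid = np.linspace(0.0, 1.0, 100001)
    vals = [flo]
    root = None
    for c in grid[1:]:
        f = tm_balance(c)
        if vals[-1] * f <= 0 and (vals[-1] != 0 or f != 0):
            lo, hi = c - (grid[1] - grid[0]), c
            root = True
            break
        vals.append(f)
    assert root, "oracle found no Tm balance root"
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if tm_balance(lo) * tm_balance(mid) <= 0:
            hi = mid
        else:
            lo = mid
    C = 0.5 * (lo + hi)
    x2, x4 = K2 * ca, K4 * ca
    w = np.array([K1 * C, K1 * C * x4, K1 * C * x4 ** 2, 1.0, x2, x2 ** 2])
    w = w / w.sum()
    return tf.StateVector(B1=w[0], B2=w[1], B3=w[2], T2=w[4], T3=w[5],
                          M=max(1.0 - w[:3].sum() - C, 0.0))
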