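"""Shared fixtures and independent oracle re-implementations.

The oracle functions below re-iterate the printed update equations with
plain arithmetic, independently of the package's code paths, so tests
can compare the implementation against a second route.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def oracle_step_2d(x_p, x_s, k_p, u_p, k_s, u_s, alpha, beta, sigma, d_p, d_s):
    """Literal arithmetic of the coupled update, synchronous."""
    new_p = x_p - u_p * (k_p - x_p + x_p**3) + alpha * (x_s - x_p) + sigma * d_p
    new_s = x_s - u_s * (k_s - x_s + x_s**3) + beta * (x_p - x_s) + sigma * d_s
    return new_p, new_s


def oracle_trial(
    k_p, u_p, k_s, u_s, alpha, beta, sigma, draws, threshold=30.0, max_steps=50_000
):
    """Brute-force trial re-simulation.

    ``draws`` is an iterator of (d_fast, d_slow) pairs.  Returns
    (outcome, winner, steps, accum_fast, accum_slow) using the same
    stopping conventions as the package: first step at which either
    |sum| >= threshold; larger magnitude wins a double crossing, exact
    tie to fast; negative sum = egocentric.
    """
    x_p = x_s = 0.0
    acc_p = acc_s = 0.0
    draws = iter(draws)
    for step in range(1, max_steps + 1):
        d_p, d_s = next(draws)
        x_p, x_s = oracle_step_2d(x_p, x_s, k_p, u_p, k_s, u_s, alpha, beta, sigma, d_p, d_s)
        acc_p += x_p
        acc_s += x_s
        fast_hit = abs(acc_p) >= threshold
        slow_hit = abs(acc_s) >= threshold
        if fast_hit or slow_hit:
            if fast_hit and slow_hit:
                winner = "fast" if abs(acc_p) >= abs(acc_s) else "slow"
            else:
                winner = "fast" if fast_hit else "slow"
            value = acc_p if winner == "fast" else acc_s
            outcome = "egocentric" if value < 0 else "other_centric"
            return outcome, winner, step, acc_p, acc_s
    return "none", "none", max_steps, acc_p, acc_s


def grid_sign_scan_roots(k, lo=-2.0, hi=2.0, n=40_001):
    """Oracle for drift zeros: bisection on sign changes of x**3 - x + k."""
    xs = np.linspace(lo, hi, n)
    f = xs**3 - xs + k
    roots = []
    for i in range(n - 1):
        if f[i] == 0.0:
            roots.append(xs[i])
        elif f[i] * f[i + 1] < 0:
            a, b = xs[i], xs[i + 1]
            for _ in range(80):
                m = 0.5 * (a + b)
                if (a**3 - a + k) * (m**3 - m + k) <= 0:
                    b = m
                else:
                    a = m
            roots.append(0.5 * (a + b))
    if f[-1] == 0.0:
        roots.append(xs[-1])
    return roots


@pytest.fixture
def fig2_config():
    from doublewell import preset

    return preset("fig2")


@pytest.fixture
def fig3_config():
    from doublewell import preset

    return preset("fig3")


@pytest.fixture
def fig5_config():
    from doublewell import preset

    return preset("fig5")
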