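"""Tilted double-well potential and the stochastic update maps built on it.

The model lives on a one-dimensional perspective coordinate ``x`` per
process: the negative pole is read as the egocentric orientation, the
positive pole as the other-centric one.  The landscape is the tilted
quartic potential

    V(x; k) = k*x - x**2/2 + x**4/4

whose two local minima are the stable perspectives and whose tilt ``k``
biases the system toward one of them (positive ``k`` deepens the
egocentric, negative-``x`` well).  A state descends the gradient of V
under additive Gaussian noise; the two-process model couples a fast
("potentiation") and a slow ("simulation") copy of this descent through
linear attraction terms.

Everything in this module is a pure function of its inputs: the noise
draws are supplied by the caller, so the maps are deterministic given
the draws and directly unit-testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = [
    "ProcessParams",
    "TwoProcessConfig",
    "SystemState",
    "potential_value",
    "potential_gradient",
    "step_1d",
    "step_2d",
    "map_jacobian",
    "fixed_points_1d",
    "FOLD_TILT",
]

#: |k| beyond which the cubic drift has a single real root (the fold of
#: the cusp): 2 / (3*sqrt(3)).
FOLD_TILT = 2.0 / (3.0 * math.sqrt(3.0))


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidArgumentError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ProcessParams:
    """Parameters of one accumulation process.

    Parameters
    ----------
    k : float
        Tilt of the potential; dimensionless, typically in [-0.3, 0.3].
        Positive values bias the process toward the egocentric
        (negative-x) well.
    u : float
        Descent rate: the per-step multiplier on the potential gradient,
        in (0, 1].  Smaller u means slower information accumulation.
    """

    k: float
    u: float

    def __post_init__(self) -> None:
        _require_finite("k", self.k)
        _require_finite("u", self.u)
        if not 0.0 < self.u <= 1.0:
            raise InvalidArgumentError(
                f"u must be in (0, 1] (a process with u <= 0 never descends), got {self.u}"
            )


@dataclass(frozen=True)
class TwoProcessConfig:
    """Full parameterization of the coupled two-process model.

    ``fast`` is the rapid potentiation process (x_P), ``slow`` the
    deliberative simulation process (x_S).  ``alpha`` pulls the fast
    process toward the slow one (top-down influence of an established
    strategy); ``beta`` pulls the slow process toward the fast one
    (bottom-up).  ``sigma`` is the standard deviation of the additive
    Gaussian noise applied independently to each process per step.
    """

    fast: ProcessParams
    slow: ProcessParams
    alpha: float = 0.0
    beta: float = 0.0
    sigma: float = 0.01

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "sigma"):
            value = _require_finite(name, getattr(self, name))
            if value < 0.0:
                raise InvalidArgumentError(f"{name} must be >= 0, got {value}")


class SystemState(NamedTuple):
    """Joint state of the two processes.

    Negative coordinates lean egocentric, positive other-centric.
    Under the default parameter ranges trajectories stay within
    roughly [-2, 2] on both axes.
    """

    x_fast: float
    x_slow: float


def potential_value(x, k):
    """Tilted quartic potential V(x; k) = k*x - x**2/2 + x**4/4.

    Accepts scalars or numpy arrays (broadcasting applies).
    """
    x = _finite_array("x", x)
    k = _finite_array("k", k)
    return k * x - x**2 / 2.0 + x**4 / 4.0


def potential_gradient(x, k):
    """dV/dx = k - x + x**3 for the tilted quartic potential."""
    x = _finite_array("x", x)
    k = _finite_array("k", k)
    return k - x + x**3


def _finite_array(name: str, value):
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError(f"{name} must be finite, got {value!r}")
    if arr.ndim == 0:
        return float(arr)
    return arr


def step_1d(x: float, k: float, sigma: float, noise_draw: float) -> float:
    """One step of the single-process map.

        x_{t+1} = x_t + (-k + x_t - x_t**3) + sigma * noise_draw

    ``noise_draw`` is a standard-normal variate supplied by the caller,
    so the map is deterministic given the draw.  With sigma = 0 this is
    plain gradient descent on V at unit rate.
    """
    x = _require_finite("x", x)
    k = _require_finite("k", k)
    return x + (-k + x - x**3) + sigma * noise_draw


def step_2d(
    state: SystemState,
    cfg: TwoProcessConfig,
    draw_fast: float,
    draw_slow: float,
) -> SystemState:
    """One synchronous step of the coupled two-process map.

        x_P' = x_P - u_P * (k_P - x_P + x_P**3) + alpha * (x_S - x_P) + sigma * draw_fast
        x_S' = x_S - u_S * (k_S - x_S + x_S**3) + beta  * (x_P - x_S) + sigma * draw_slow

    Both coordinates are updated from the time-t state (no sequential
    leakage).  With alpha = beta = 0 each coordinate is the u-scaled
    single-process update.
    """
    x_p = _require_finite("x_fast", state[0])
    x_s = _require_finite("x_slow", state[1])
    new_p = (
        x_p
        - cfg.fast.u * (cfg.fast.k - x_p + x_p**3)
        + cfg.alpha * (x_s - x_p)
        + cfg.sigma * draw_fast
    )
    new_s = (
        x_s
        - cfg.slow.u * (cfg.slow.k - x_s + x_s**3)
        + cfg.beta * (x_p - x_s)
        + cfg.sigma * draw_slow
    )
    return SystemState(new_p, new_s)


def map_jacobian(state: SystemState, cfg: TwoProcessConfig) -> np.ndarray:
    """Jacobian of the noise-free two-process map at ``state``.

    Returns the 2x2 matrix

        [[1 - u_P*(-1 + 3*x_P**2) - alpha, alpha],
         [beta, 1 - u_S*(-1 + 3*x_S**2) - beta]]

    used to classify fixed points of the discrete map by eigenvalue
    magnitude relative to 1.
    """
    x_p = _require_finite("x_fast", state[0])
    x_s = _require_finite("x_slow", state[1])
    return np.array(
        [
            [1.0 - cfg.fast.u * (-1.0 + 3.0 * x_p**2) - cfg.alpha, cfg.alpha],
            [cfg.beta, 1.0 - cfg.slow.u * (-1.0 + 3.0 * x_s**2) - cfg.beta],
        ]
    )


def fixed_points_1d(k: float) -> list[tuple[float, str]]:
    """Equilibria of the single-process drift -k + x - x**3.

    Returns the real roots of x**3 - x + k = 0 in ascending order, each
    tagged ``"stable"`` (drift derivative 1 - 3x**2 < 0, a well) or
    ``"unstable"`` (the saddle between wells).  For |k| below the fold
    at 2/(3*sqrt(3)) there are three roots (stable, unstable, stable);
    beyond it a single stable root survives.
    """
    k = _require_finite("k", k)
    roots = np.roots([1.0, 0.0, -1.0, k])
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    out: list[tuple[float, str]] = []
    for r in real:
        stability = "stable" if 1.0 - 3.0 * r**2 < 0.0 else "unstable"
        out.append((float(r), stability))
    return out
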