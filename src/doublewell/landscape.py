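"""Noise-free analysis of the two-process map: vector fields and fixed points.

The "landscape" of a parameter regime is summarized by the one-step
displacement of the noise-free map over a grid of joint states (the
vector field) and by the map's equilibria with their stability.  Because
the model is a discrete-time map, stability is judged by the eigenvalue
magnitudes of the map Jacobian relative to 1, not by flow eigenvalue
signs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .dynamics import SystemState, TwoProcessConfig, map_jacobian, step_2d
from .exceptions import ConfigurationError, InvalidArgumentError

__all__ = [
    "GridSpec",
    "VectorFieldGrid",
    "FixedPoint2D",
    "vector_field",
    "find_fixed_points_2d",
    "classify_stability",
]

#: Eigenvalue magnitudes within this band of 1 trigger a marginal-case warning.
_MARGINAL_BAND = 1e-6


@dataclass(frozen=True)
class GridSpec:
    """Square grid over joint state space.

    Defaults cover all attractors of the tilted well for |k| <= 0.3.
    """

    x_min: float = -1.5
    x_max: float = 1.5
    resolution: int = 21

    def __post_init__(self) -> None:
        if not self.x_min < self.x_max:
            raise ConfigurationError(
                f"x_min must be < x_max, got [{self.x_min}, {self.x_max}]"
            )
        if self.resolution < 2:
            raise ConfigurationError(f"resolution must be >= 2, got {self.resolution}")

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.x_min, self.x_max, self.resolution)


@dataclass(frozen=True)
class VectorFieldGrid:
    """One-step displacements of the noise-free map on a grid.

    ``dx_fast[i, j]`` / ``dx_slow[i, j]`` are the displacement
    components at state (x_fast[i], x_slow[j]).
    """

    x_fast: np.ndarray
    x_slow: np.ndarray
    dx_fast: np.ndarray
    dx_slow: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (x_fast, x_slow, dx_fast, dx_slow)."""
        ff, ss = np.meshgrid(self.x_fast, self.x_slow, indexing="ij")
        return pd.DataFrame(
            {
                "x_fast": ff.ravel(),
                "x_slow": ss.ravel(),
                "dx_fast": self.dx_fast.ravel(),
                "dx_slow": self.dx_slow.ravel(),
            }
        )


@dataclass(frozen=True)
class FixedPoint2D:
    """A located equilibrium of the noise-free map."""

    location: SystemState
    eig_magnitudes: tuple[float, float]
    classification: str  # stable | saddle | unstable

    def __iter__(self):
        yield from (self.location, self.eig_magnitudes, self.classification)


def _drift(x_p: np.ndarray, x_s: np.ndarray, cfg: TwoProcessConfig):
    """Noise-free displacement components (vectorized)."""
    dp = -cfg.fast.u * (cfg.fast.k - x_p + x_p**3) + cfg.alpha * (x_s - x_p)
    ds = -cfg.slow.u * (cfg.slow.k - x_s + x_s**3) + cfg.beta * (x_p - x_s)
    return dp, ds


def vector_field(cfg: TwoProcessConfig, grid: GridSpec = GridSpec()) -> VectorFieldGrid:
    """Sample the noise-free one-step displacement on ``grid``."""
    axis = grid.axis
    ff, ss = np.meshgrid(axis, axis, indexing="ij")
    dp, ds = _drift(ff, ss, cfg)
    return VectorFieldGrid(x_fast=axis, x_slow=axis.copy(), dx_fast=dp, dx_slow=ds)


def classify_stability(p: SystemState, cfg: TwoProcessConfig) -> str:
    """Classify a (near-)fixed point by Jacobian eigenvalue magnitudes.

    Both magnitudes < 1 => stable, both > 1 => unstable, mixed =>
    saddle.  A magnitude within 1e-6 of 1 raises a warning (marginal
    case) but still classifies by the strict comparison.
    """
    mags = np.abs(np.linalg.eigvals(map_jacobian(p, cfg)))
    if np.any(np.abs(mags - 1.0) < _MARGINAL_BAND):
        warnings.warn(
            f"eigenvalue magnitude within {_MARGINAL_BAND} of 1 at {tuple(p)}: "
            "stability classification is marginal",
            stacklevel=2,
        )
    if np.all(mags < 1.0):
        return "stable"
    if np.all(mags > 1.0):
        return "unstable"
    return "saddle"


def find_fixed_points_2d(
    cfg: TwoProcessConfig,
    grid: GridSpec = GridSpec(),
    tol: float = 1e-5,
) -> list[FixedPoint2D]:
    """Locate equilibria of the noise-free map by multistart root-finding.

    Every grid node seeds a root search on the displacement; converged
    roots closer than ``tol`` are merged, classified via the map
    Jacobian, and returned sorted lexicographically by location.
    Non-convergent seeds are silently discarded.
    """
    if not tol > 0.0:
        raise InvalidArgumentError(f"tol must be > 0, got {tol}")

    def residual(z):
        dp, ds = _drift(z[0], z[1], cfg)
        return [dp, ds]

    def jac(z):
        # Jacobian of the displacement = map Jacobian - identity.
        return map_jacobian(SystemState(z[0], z[1]), cfg) - np.eye(2)

    roots: list[np.ndarray] = []
    axis = grid.axis
    for xf in axis:
        for xs in axis:
            sol = optimize.root(residual, [xf, xs], jac=jac, method="hybr")
            if not sol.success:
                continue
            z = sol.x
            if np.max(np.abs(residual(z))) > tol:
                continue
            if any(np.max(np.abs(z - r)) < tol for r in roots):
                continue
            roots.append(z)

    points = []
    # sort on rounded coordinates so ~1e-11 root-finder jitter cannot
    # reorder points that share an axis value (roots are > 0.5 apart)
    for z in sorted(roots, key=lambda r: (round(r[0], 6), round(r[1], 6))):
        loc = SystemState(float(z[0]), float(z[1]))
        mags = np.abs(np.linalg.eigvals(map_jacobian(loc, cfg)))
        points.append(
            FixedPoint2D(
                location=loc,
                eig_magnitudes=(float(mags[0]), float(mags[1])),
                classification=classify_stability(loc, cfg),
            )
        )
    return points


def fixed_points_to_frame(points: list[FixedPoint2D]) -> pd.DataFrame:
    """Small table (x_fast, x_slow, |lambda1|, |lambda2|, class)."""
    return pd.DataFrame(
        {
            "x_fast": [p.location.x_fast for p in points],
            "x_slow": [p.location.x_slow for p in points],
            "eig_mag_1": [p.eig_magnitudes[0] for p in points],
            "eig_mag_2": [p.eig_magnitudes[1] for p in points],
            "classification": [p.classification for p in points],
        }
    )


def displacement_at(state: SystemState, cfg: TwoProcessConfig) -> np.ndarray:
    """Noise-free one-step displacement at a single state."""
    nxt = step_2d(state, cfg, 0.0, 0.0)
    return np.array([nxt.x_fast - state.x_fast, nxt.x_slow - state.x_slow])


def reflect_config(cfg: TwoProcessConfig) -> TwoProcessConfig:
    """Negate both tilts; reflects the landscape through the origin."""
    return replace(
        cfg,
        fast=replace(cfg.fast, k=-cfg.fast.k),
        slow=replace(cfg.slow, k=-cfg.slow.k),
    )
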