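"""Config files, tabular writers/readers, and run manifests.

Configuration is YAML.  A config either names a preset (optionally
overriding fields) or specifies the dynamics in full; unknown keys are
an error, not a warning, so typos cannot silently fall back to
defaults.  Output files are plain CSV with ``#``-prefixed header lines
embedding the run manifest as JSON, so every file is traceable to the
exact configuration and seed that produced it and round-trips through
the readers in this module.

The manifest object records a timestamp for logging, but the timestamp
is deliberately excluded from file headers: identical invocations must
produce bitwise-identical files.
"""

from __future__ import annotations

import io as _stdlib_io
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .defaults import DEFAULTS
from .dynamics import ProcessParams, SystemState, TwoProcessConfig
from .exceptions import ConfigurationError
from .experiments import _PARAM_PATHS, preset
from .landscape import VectorFieldGrid
from .trials import TrialConfig, TrialResult, results_to_frame

__all__ = [
    "RunManifest",
    "manifest_for",
    "load_config",
    "write_results",
    "read_results",
    "write_field",
    "read_field",
]


@dataclass(frozen=True)
class RunManifest:
    """Full provenance of one run: resolved config, seed, version, time."""

    config: dict
    seed: int | None
    version: str
    timestamp: str

    def header_json(self) -> str:
        """JSON for file headers; excludes the timestamp (see module doc)."""
        payload = {"config": self.config, "seed": self.seed, "version": self.version}
        return json.dumps(payload, sort_keys=True)

    def log_line(self) -> str:
        return (
            f"manifest seed={self.seed} version={self.version} "
            f"timestamp={self.timestamp} config={json.dumps(self.config, sort_keys=True)}"
        )


def config_to_dict(config: TrialConfig) -> dict:
    """Flatten a TrialConfig into plain JSON-serializable types."""
    d = config.dynamics
    return {
        "fast": {"k": d.fast.k, "u": d.fast.u},
        "slow": {"k": d.slow.k, "u": d.slow.u},
        "alpha": d.alpha,
        "beta": d.beta,
        "sigma": d.sigma,
        "threshold": config.threshold,
        "max_steps": config.max_steps,
        "init": list(config.init),
    }


def manifest_for(config: TrialConfig, seed: int | None, **extra) -> RunManifest:
    cfg = config_to_dict(config)
    cfg.update(extra)
    return RunManifest(
        config=cfg,
        seed=seed,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


_TOP_KEYS = {
    "preset", "fast", "slow", "alpha", "beta", "sigma",
    "threshold", "max_steps", "init", "seed", "sweep",
}
_PROCESS_KEYS = {"k", "u"}
_SWEEP_KEYS = {"parameter", "values", "n_per_value"}


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}"
        )


def _process_from(mapping: dict, context: str, base: ProcessParams | None) -> ProcessParams:
    if not isinstance(mapping, dict):
        raise ConfigurationError(f"{context} must be a mapping with keys k, u")
    _check_keys(mapping, _PROCESS_KEYS, context)
    if base is None and _PROCESS_KEYS - set(mapping):
        raise ConfigurationError(f"{context} requires both k and u when no preset is named")
    k = mapping.get("k", base.k if base else None)
    u = mapping.get("u", base.u if base else None)
    return ProcessParams(k=k, u=u)


def load_config(path: str | Path) -> tuple[TrialConfig, dict | None]:
    """Load a YAML config file.

    Returns the trial configuration and, if present, the parsed
    ``sweep`` section ({parameter, values, n_per_value}).  Any violation
    (missing file, parse failure, unknown key, invariant breach) raises
    :class:`ConfigurationError` naming the offending key.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"top level of {path} must be a mapping")
    _check_keys(raw, _TOP_KEYS, str(path))

    if "preset" in raw:
        base = preset(raw["preset"])
    else:
        base = None

    base_dyn = base.dynamics if base else None
    try:
        if "fast" in raw or base is None:
            fast = _process_from(raw.get("fast", {}), "fast", base_dyn.fast if base_dyn else None)
        else:
            fast = base_dyn.fast
        if "slow" in raw or base is None:
            slow = _process_from(raw.get("slow", {}), "slow", base_dyn.slow if base_dyn else None)
        else:
            slow = base_dyn.slow
        dynamics = TwoProcessConfig(
            fast=fast,
            slow=slow,
            alpha=raw.get("alpha", base_dyn.alpha if base_dyn else DEFAULTS["alpha"]),
            beta=raw.get("beta", base_dyn.beta if base_dyn else DEFAULTS["beta"]),
            sigma=raw.get("sigma", base_dyn.sigma if base_dyn else DEFAULTS["sigma"]),
        )
        init = raw.get("init", list(base.init) if base else list(DEFAULTS["init"]))
        if not (isinstance(init, (list, tuple)) and len(init) == 2):
            raise ConfigurationError(f"init must be a pair [x_fast, x_slow], got {init!r}")
        config = TrialConfig(
            dynamics=dynamics,
            threshold=raw.get("threshold", base.threshold if base else DEFAULTS["threshold"]),
            max_steps=raw.get("max_steps", base.max_steps if base else DEFAULTS["max_steps"]),
            init=SystemState(*init),
            seed=raw.get("seed"),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigurationError):
            raise
        raise ConfigurationError(f"invalid config in {path}: {exc}") from exc

    sweep_section = raw.get("sweep")
    if sweep_section is not None:
        _check_keys(sweep_section, _SWEEP_KEYS, f"{path}:sweep")
        missing = _SWEEP_KEYS - set(sweep_section)
        if missing:
            raise ConfigurationError(f"sweep section missing key(s) {sorted(missing)}")
        if sweep_section["parameter"] not in _PARAM_PATHS:
            raise ConfigurationError(
                f"sweep.parameter {sweep_section['parameter']!r} not one of {_PARAM_PATHS}"
            )
    return config, sweep_section


def _write_with_header(frame: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    buf = _stdlib_io.StringIO()
    frame.to_csv(buf, index=False)
    try:
        path.write_text(f"# doublewell-manifest: {manifest.header_json()}\n" + buf.getvalue())
    except OSError as exc:
        raise OSError(f"could not write {path}: {exc}") from exc


def _read_with_header(path: Path) -> tuple[pd.DataFrame, dict]:
    try:
        text = path.read_text()
    except OSError as exc:
        raise OSError(f"could not read {path}: {exc}") from exc
    lines = text.splitlines(keepends=True)
    manifest = {}
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# doublewell-manifest: "):
            manifest = json.loads(line.split(": ", 1)[1])
        if not line.startswith("#"):
            data_start = i
            break
    frame = pd.read_csv(_stdlib_io.StringIO("".join(lines[data_start:])))
    return frame, manifest


def write_results(
    results: list[TrialResult], path: str | Path, manifest: RunManifest
) -> Path:
    """Write one row per trial (outcome, winner, steps, final accumulators)."""
    path = Path(path)
    _write_with_header(results_to_frame(results), path, manifest)
    return path


def read_results(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a results file back; returns (frame, embedded manifest dict)."""
    return _read_with_header(Path(path))


def write_field(grid: VectorFieldGrid, path: str | Path, manifest: RunManifest) -> Path:
    """Write a vector field as a long-format table."""
    path = Path(path)
    _write_with_header(grid.to_frame(), path, manifest)
    return path


def read_field(path: str | Path) -> tuple[pd.DataFrame, dict]:
    return _read_with_header(Path(path))
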