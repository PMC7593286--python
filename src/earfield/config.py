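"""Run configuration: TOML-backed parameters for every pipeline stage.

A config file has up to three tables — ``[head]`` (any key of
:data:`earfield.head.DEFAULTS`), ``[forward]`` (method, tol, amplitude) and
``[analysis]`` (mode, bipolar channel definitions) — plus a top-level
``seed``.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .head import DEFAULTS
from .scenarios import DEFAULT_BIPOLAR_CHANNELS

__all__ = ["RunConfig", "load_config"]

_FORWARD_DEFAULTS = {"method": "sphere", "tol": 1e-6, "amplitude": 1e-9}
_ANALYSIS_DEFAULTS = {
    "mode": "patches",
    "bipolar_channels": {k: list(v) for k, v in DEFAULT_BIPOLAR_CHANNELS.items()},
}


@dataclass(frozen=True)
class RunConfig:
    seed: int = 42
    head: dict = field(default_factory=lambda: dict(DEFAULTS))
    forward: dict = field(default_factory=lambda: dict(_FORWARD_DEFAULTS))
    analysis: dict = field(default_factory=lambda: dict(_ANALYSIS_DEFAULTS))

    def __post_init__(self):
        if not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")
        for name, table, defaults in (
            ("head", self.head, DEFAULTS),
            ("forward", self.forward, _FORWARD_DEFAULTS),
            ("analysis", self.analysis, _ANALYSIS_DEFAULTS),
        ):
            unknown = set(table) - set(defaults)
            if unknown:
                raise ValueError(f"unknown [{name}] keys: {sorted(unknown)}")
        for key in (
            "shell_radii",
            "shell_conductivities",
            "cortex_base_radius",
            "grid_spacing",
            "grid_margin",
            "source_amplitude",
        ):
            val = self.head.get(key, DEFAULTS[key])
            vals = val if isinstance(val, (list, tuple)) else [val]
            if any(v <= 0 for v in vals):
                raise ValueError(f"head.{key} must be positive, got {val}")
        if self.forward.get("tol", _FORWARD_DEFAULTS["tol"]) <= 0:
            raise ValueError("forward.tol must be positive")
        method = self.forward.get("method", _FORWARD_DEFAULTS["method"])
        if method not in ("sphere", "bem"):
            raise ValueError("forward.method must be 'sphere' or 'bem'")

    def merged_head(self) -> dict:
        out = dict(DEFAULTS)
        out.update(self.head)
        return out

    def merged_forward(self) -> dict:
        out = dict(_FORWARD_DEFAULTS)
        out.update(self.forward)
        return out

    def merged_analysis(self) -> dict:
        out = dict(_ANALYSIS_DEFAULTS)
        out.update(self.analysis)
        return out

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "head": self.merged_head(),
            "forward": self.merged_forward(),
            "analysis": self.merged_analysis(),
        }


def load_config(path: str | Path | None, seed: int | None = None) -> RunConfig:
    """Load a TOML config; ``seed`` (e.g. from the command line) overrides
    the file's value."""
    if path is None:
        data = {}
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    known = {"seed", "head", "forward", "analysis"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    head = dict(data.get("head", {}))
    for key in ("shell_radii", "shell_conductivities", "cortex_fold_degree_band"):
        if key in head:
            head[key] = tuple(head[key])
    return RunConfig(
        seed=int(seed if seed is not None else data.get("seed", 42)),
        head=head,
        forward=dict(data.get("forward", {})),
        analysis=dict(data.get("analysis", {})),
    )
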