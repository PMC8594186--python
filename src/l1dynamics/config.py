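"""Analysis configuration files.

A small YAML schema naming the pieces of a model-comparison run: which
built-in (or custom) parameter constraints to fit, the change-point
boundaries in generations before present, and the substitution-rate
conversion constant.  Example:

    subst_rate: 2.5e-8
    constraints: [unconstrained, mu0=mu1=0]
    custom_constraints:
      - id: yule
        groups: {lambda0: lambda, lambda1: lambda, mu0: null, mu1: null,
                 q01: null, q10: null}
    change_points:
      - [140]
      - [140, 4720]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .fitting import ModelConstraint, PARAM_NAMES, builtin_constraints
from .treeio import UnitConversion

__all__ = ["AnalysisConfig", "read_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    constraints: tuple[ModelConstraint, ...]
    change_points: tuple[tuple[float, ...], ...]  # generations before present
    conv: UnitConversion


def read_config(path: str) -> AnalysisConfig:
    """Read and validate an analysis configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {c.id: c for c in builtin_constraints()}
    for item in raw.get("custom_constraints", []):
        groups = item.get("groups", {})
        missing = set(PARAM_NAMES) - set(groups)
        if missing:
            raise ValueError(f"custom constraint {item.get('id')!r} misses rates {sorted(missing)}")
        c = ModelConstraint(str(item["id"]), tuple(groups[n] for n in PARAM_NAMES))
        known[c.id] = c
    names = raw.get("constraints", list(known))
    try:
        constraints = tuple(known[n] for n in names)
    except KeyError as exc:
        raise ValueError(f"unknown constraint {exc.args[0]!r}; available: {sorted(known)}") from exc
    change_points = tuple(
        tuple(float(b) for b in bounds) for bounds in raw.get("change_points", [])
    )
    conv = UnitConversion(float(raw.get("subst_rate", 2.5e-8)))
    return AnalysisConfig(constraints, change_points, conv)
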