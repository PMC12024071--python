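"""YAML condition-grid configuration.

A config file either names a built-in grid::

    grid: noninvariant   # or "all" / "invariant"

or lists conditions explicitly, with keys mirroring the condition labels::

    conditions:
      - n_per_group: 100
        lvar_ratio: 2
        mean_diff: 0.8
        n_noninv_items: 4        # omit the last three keys for an
        noninv_magnitude: 0.25   # invariant condition
        noninv_location: loading
"""

from __future__ import annotations

import yaml

from .synthetic_data import PopulationSpec, condition_grid, make_population


def load_conditions(path: str) -> list[PopulationSpec]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "conditions" in cfg:
        return [make_population(**c) for c in cfg["conditions"]]
    grid = cfg.get("grid", "noninvariant")
    if grid == "noninvariant":
        return condition_grid(include_invariant=False)
    if grid == "all":
        return condition_grid(include_invariant=True)
    if grid == "invariant":
        full = condition_grid(include_invariant=True)
        return [s for s in full if s.is_invariant]
    raise ValueError(f"unknown grid {grid!r}")
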