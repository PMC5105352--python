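"""Run configuration: a flat key/value document validated into a RunConfig.

Defaults follow the study conditions the pipeline emulates: alpha 0.05,
density grid 0.05:0.95:0.05, 30 rewired nulls with 10 swaps per edge,
203 male / 291 female subjects aged 22–36, 116 regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


def parse_density_grid(text: str) -> list[float]:
    """Expand ``start:stop:step`` (inclusive) into density levels."""
    parts = text.split(":")
    if len(parts) != 3:
        raise ValueError(f"density grid must be start:stop:step, got {text!r}")
    start, stop, step = (float(p) for p in parts)
    if step <= 0 or start > stop:
        raise ValueError(f"invalid density grid range: {text!r}")
    n = int(round((stop - start) / step)) + 1
    grid = [round(start + k * step, 10) for k in range(n)]
    grid = [g for g in grid if g <= stop + 1e-9]
    for g in grid:
        if not 0 < g <= 1:
            raise ValueError(f"density {g} outside (0, 1]")
    return grid


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; see module docstring for defaults."""

    mode: str = "direct_z"  # direct_z | timeseries
    # cohort / generator
    n_male: int = 203
    n_female: int = 291
    age_low: float = 22.0
    age_high: float = 36.0
    n_regions: int = 116
    n_timepoints: int = 1200
    n_sex_edges: int = 0
    n_age_edges: int = 0
    n_int_edges: int = 0
    b_sex: float = 0.55
    b_age: float = -0.06
    b_int: float = 0.02
    noise_sd: float = 1.0
    # optional external inputs (used instead of simulation when given)
    cohort_path: str = ""
    table_path: str = ""
    scheme_path: str = ""
    # regression
    alpha: float = 0.05
    correction: str = "bonferroni"
    alpha_remove: float = 0.05
    center_age: bool = False
    # graph
    density_grid: str = "0.05:0.95:0.05"
    n_nulls: int = 30
    swaps_per_edge: int = 10
    abs_threshold: bool = False
    # group statistics
    t_variant: str = "student"
    # bookkeeping
    seed: int = 0
    out_dir: str = "runs"

    def grid(self) -> list[float]:
        return parse_density_grid(self.density_grid)


_BOOL_FIELDS = {"center_age", "abs_threshold"}


def validate_config(raw: str | dict) -> RunConfig:
    """Parse and validate a flat ``key = value`` document (or dict).

    Unknown keys and out-of-range values are collected and reported
    together.  An empty document yields all defaults.
    """
    if isinstance(raw, str):
        data: dict[str, str] = {}
        for lineno, line in enumerate(raw.splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
            key, value = (p.strip() for p in line.split("=", 1))
            data[key] = value
    else:
        data = {k: v for k, v in raw.items()}

    known = {f.name: f.type for f in fields(RunConfig)}
    errors = []
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            errors.append(f"unknown key: {key}")
            continue
        default = getattr(RunConfig(), key)
        try:
            if key in _BOOL_FIELDS:
                if isinstance(value, bool):
                    kwargs[key] = value
                else:
                    v = str(value).strip().lower()
                    if v not in ("true", "false", "1", "0", "yes", "no"):
                        raise ValueError(f"not a boolean: {value!r}")
                    kwargs[key] = v in ("true", "1", "yes")
            elif isinstance(default, int) and not isinstance(default, bool):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = str(value)
        except (TypeError, ValueError) as exc:
            errors.append(f"{key}: {exc}")

    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    cfg = RunConfig(**kwargs)

    checks = []
    if cfg.mode not in ("direct_z", "timeseries"):
        checks.append(f"mode must be direct_z or timeseries, got {cfg.mode!r}")
    if not 0 < cfg.alpha < 1:
        checks.append(f"alpha must be in (0, 1), got {cfg.alpha}")
    if not 0 < cfg.alpha_remove < 1:
        checks.append(f"alpha_remove must be in (0, 1), got {cfg.alpha_remove}")
    if cfg.correction not in ("bonferroni", "bh_fdr"):
        checks.append(f"correction must be bonferroni or bh_fdr, got {cfg.correction!r}")
    if cfg.t_variant not in ("student", "welch"):
        checks.append(f"t_variant must be student or welch, got {cfg.t_variant!r}")
    if cfg.n_nulls < 1:
        checks.append("n_nulls must be >= 1")
    if cfg.swaps_per_edge < 1:
        checks.append("swaps_per_edge must be >= 1")
    try:
        cfg.grid()
    except ValueError as exc:
        checks.append(str(exc))
    for key in ("cohort_path", "table_path", "scheme_path"):
        path = getattr(cfg, key)
        if path and not Path(path).exists():
            checks.append(f"{key} does not exist: {path}")
    if checks:
        raise ValueError("invalid config:\n  " + "\n  ".join(checks))
    return cfg


def serialize(config: RunConfig) -> str:
    """Flat key = value text; validate(serialize(c)) == c."""
    lines = []
    for f in fields(RunConfig):
        value = getattr(config, f.name)
        if isinstance(value, bool):
            value = "true" if value else "false"
        lines.append(f"{f.name} = {value}")
    return "\n".join(lines) + "\n"
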