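"""Threshold configuration.

All tunable cut-offs of the filter live in :class:`FilterConfig`.  Users
override defaults through a small YAML file whose permitted keys depend
on the run mode: germline runs accept ``min_depth``, somatic runs accept
``min_depth_tumor``, ``min_depth_normal`` and ``min_frac``; the
mode-independent keys are shared.  Unknown keys are an error so that
typos never silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .errors import ConfigError

GERMLINE = "germline"
SOMATIC = "somatic"

#: keys accepted in either mode
COMMON_KEYS = {"min_read_pos", "min_read_pos_fraction", "assignment_tolerance", "min_baseq", "min_mapq"}
GERMLINE_KEYS = COMMON_KEYS | {"min_depth"}
SOMATIC_KEYS = COMMON_KEYS | {"min_depth_normal", "min_depth_tumor", "min_frac"}

_INT_KEYS = {
    "min_read_pos",
    "assignment_tolerance",
    "min_baseq",
    "min_mapq",
    "min_depth",
    "min_depth_normal",
    "min_depth_tumor",
}
_PERCENT_KEYS = {"min_read_pos_fraction", "min_frac"}


@dataclass(frozen=True)
class FilterConfig:
    """Resolved thresholds for one filtering run.

    Depth floors are in reads; ``min_read_pos`` is a distance in bases
    from the physical read ends; ``min_read_pos_fraction`` and
    ``min_frac`` are percentages (strict ``>`` comparisons at use sites).
    """

    mode: str = GERMLINE
    min_depth: int = 10
    min_depth_normal: int = 10
    min_depth_tumor: int = 10
    min_read_pos: int = 2
    min_read_pos_fraction: float = 10.0
    min_frac: float = 1.0
    assignment_tolerance: int = 2
    min_baseq: int = 13
    min_mapq: int = 20

    def __post_init__(self) -> None:
        if self.mode not in (GERMLINE, SOMATIC):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for key in _INT_KEYS:
            value = getattr(self, key)
            if not isinstance(value, int) or isinstance(value, bool) or value < 0:
                raise ConfigError(f"{key} must be a non-negative integer, got {value!r}")
        for key in _PERCENT_KEYS:
            value = getattr(self, key)
            if not isinstance(value, (int, float)) or isinstance(value, bool) or not 0 <= value <= 100:
                raise ConfigError(f"{key} must be a percentage in [0, 100], got {value!r}")

    def describe(self) -> str:
        keys = sorted(GERMLINE_KEYS if self.mode == GERMLINE else SOMATIC_KEYS)
        parts = [f"mode={self.mode}"] + [f"{k}={getattr(self, k)}" for k in keys]
        return " ".join(parts)


def load_config(path: str | Path | None, mode: str) -> FilterConfig:
    """Build a :class:`FilterConfig` for ``mode``, overriding defaults from YAML.

    ``path`` may be None (defaults only).  Raises :class:`ConfigError`
    naming the key for unknown keys, wrong types or out-of-range values.
    """
    base = FilterConfig(mode=mode)
    if path is None:
        return base
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        try:
            loaded = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from None
    if loaded is None:
        return base
    if not isinstance(loaded, dict):
        raise ConfigError(f"{path}: configuration must be a mapping of key: value")
    allowed = GERMLINE_KEYS if mode == GERMLINE else SOMATIC_KEYS
    overrides = {}
    for key, value in loaded.items():
        if key not in allowed:
            raise ConfigError(f"{path}: unknown configuration key {key!r} for {mode} mode")
        if key in _PERCENT_KEYS and isinstance(value, int) and not isinstance(value, bool):
            value = float(value)
        overrides[key] = value
    try:
        return replace(base, **overrides)
    except ConfigError:
        raise
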