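"""Run configuration for the command-line workflow.

The scoring choices the published rules leave open — which RC-DQI target
table variant applies, how HEI moderation points are prorated, and which
reading of the EER deduction formula is used — are deliberate, logged inputs
rather than silent defaults: a YAML config file must state them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .comparison import STRATA_COLUMNS
from .rcdqi import TABLE_VARIANTS

HEI_PRORATION_MODES = ("paper_linear", "technical_piecewise")
EER_FORMULAS = ("proportional", "literal")

#: Documented defaults, used by the CLI when no config file is given.
DEFAULTS = {
    "table_variant": "table_b",
    "hei_proration": "paper_linear",
    "eer_formula": "proportional",
}


class ConfigError(ValueError):
    """The run configuration is missing a key or holds an invalid value."""


@dataclass(frozen=True)
class RunConfig:
    """Validated scoring/comparison run options."""

    table_variant: str = "table_b"
    hei_proration: str = "paper_linear"
    eer_formula: str = "proportional"
    require_two_days: bool = True
    strata: tuple[str, ...] = STRATA_COLUMNS
    output_dir: Path = Path("results")
    seed: int = 0
    n_children: int = 1000

    def __post_init__(self) -> None:
        if self.table_variant not in TABLE_VARIANTS:
            raise ConfigError(f"table_variant must be one of {TABLE_VARIANTS}")
        if self.hei_proration not in HEI_PRORATION_MODES:
            raise ConfigError(f"hei_proration must be one of {HEI_PRORATION_MODES}")
        if self.eer_formula not in EER_FORMULAS:
            raise ConfigError(f"eer_formula must be one of {EER_FORMULAS}")
        bad = [s for s in self.strata if s not in STRATA_COLUMNS]
        if bad:
            raise ConfigError(f"unknown strata: {bad}; choose from {STRATA_COLUMNS}")


#: Keys a config file must state explicitly (no silent fallbacks).
REQUIRED_KEYS = ("table_variant", "hei_proration", "eer_formula")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config.

    The enum-like scoring choices (``table_variant``, ``hei_proration``,
    ``eer_formula``) are mandatory in the file; the remaining keys fall back
    to the dataclass defaults.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must hold a mapping")
    missing = [k for k in REQUIRED_KEYS if k not in raw]
    if missing:
        raise ConfigError(
            f"config file {path} must state: {', '.join(missing)} "
            f"(documented defaults: {DEFAULTS})"
        )
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = [k for k in raw if k not in known]
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    if "strata" in raw:
        raw["strata"] = tuple(raw["strata"])
    if "output_dir" in raw:
        raw["output_dir"] = Path(raw["output_dir"])
    return RunConfig(**raw)
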