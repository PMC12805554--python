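"""YAML run configuration with fail-closed parsing.

A config file may carry one block per CLI subcommand plus a few global
keys.  Unknown keys anywhere are rejected so typos cannot silently fall
back to defaults.
"""

from __future__ import annotations

import yaml

GLOBAL_KEYS = {"seed", "out", "verbose"}

SECTION_KEYS = {
    "simulate": {"scenario", "reps", "seed", "out", "grid_dim", "cities", "multilevel"},
    "basis": {"data", "geojson", "ratio", "resolution", "out"},
    "fit": {"variant", "effect", "q", "ratio", "burn", "keep", "thin", "seed",
            "data", "basis", "geojson", "out", "coef_scale", "var_shape",
            "var_rate", "tau_scale", "treatment_mode"},
    "study": {"scenario", "reps", "methods", "ratios", "seed", "out",
              "burn", "keep", "thin", "selection_burn", "selection_keep"},
    "check-id": {"loading_matrix", "q"},
}


def load_run_config(path, section: str | None = None) -> dict:
    """Load and validate a YAML config; unknown keys raise ``ValueError``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    allowed_sections = set(SECTION_KEYS) | GLOBAL_KEYS
    for key in raw:
        if key not in allowed_sections:
            raise ValueError(f"unknown config key {key!r}")
    for sec, block in raw.items():
        if sec in GLOBAL_KEYS:
            continue
        if not isinstance(block, dict):
            raise ValueError(f"config section {sec!r} must be a mapping")
        bad = set(block) - SECTION_KEYS[sec]
        if bad:
            raise ValueError(f"unknown key(s) {sorted(bad)} in config section {sec!r}")
    if section is not None:
        merged = {k: v for k, v in raw.items() if k in GLOBAL_KEYS}
        merged.update(raw.get(section, {}))
        return merged
    return raw
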