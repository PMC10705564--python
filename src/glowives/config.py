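"""YAML config plumbing for the CLI and scripts.

A config file may contain any of the sections ``scoring:``, ``sampler:``,
``ives:`` and ``minimize:``; each maps directly onto the corresponding
dataclass, and omitted keys keep their defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from glowives.pocket_min import MinimizeConfig
from glowives.protocols import IvesConfig
from glowives.sampling import SamplerConfig
from glowives.scoring import ScoringParams

_SECTIONS = {
    "scoring": ScoringParams,
    "sampler": SamplerConfig,
    "ives": IvesConfig,
    "minimize": MinimizeConfig,
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config into dataclass instances (defaults if path is None)."""
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a YAML mapping")
            raw = loaded
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    out = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name) or {}
        if not isinstance(section, dict):
            raise ValueError(f"config section {name!r} must be a mapping")
        out[name] = cls(**section)
    return out
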