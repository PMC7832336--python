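"""YAML round-trip for pipeline parameters."""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .clonality import ClonalityParams


def load_params(path: str | Path) -> ClonalityParams:
    """Read a params YAML; keys absent from the file keep their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(ClonalityParams)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ClonalityParams(**data)


def save_params(params: ClonalityParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=True)
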