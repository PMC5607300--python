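"""Run configuration and reproducibility manifest.

All analysis parameters live in one flat, plain-text-serialisable structure
with every default materialised, so a run's manifest plus its seed suffice to
reproduce its outputs byte-for-byte.
"""

from __future__ import annotations

import fnmatch
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "write_manifest"]


@dataclass
class RunConfig:
    """Analysis parameters; ages are cal BP integers.

    ``bracket_young_overrides`` maps region-label glob patterns to younger
    chronological brackets (the late-Neolithization north-west European
    regions conventionally get 4,000 instead of 5,000 cal BP).
    """

    seed: int = 0
    bracket_old: int = 12_000
    bracket_young: int = 5_000
    bracket_young_overrides: dict = field(default_factory=dict)
    max_sigma_lab: float = 150.0
    outlier_file: str | None = None  # one lab_code per line, dropped before analysis
    hull_step: int = 100
    hull_old: int = 12_000
    hull_young: int = 4_000
    growth_frac: float = 0.05
    pause_len: int = 2
    h: float = 200.0  # site-phase binning width, 14C yr
    n_sim: int = 1_000
    rescale_mode: str = "per-bin"
    taphonomy: bool = False
    edge_margin: int = 200  # yr near the young bracket excluded from fits
    neolithization_overrides: dict = field(default_factory=dict)

    def bracket_for(self, region: str) -> int:
        for pattern, value in self.bracket_young_overrides.items():
            if fnmatch.fnmatch(region, pattern):
                return int(value)
        return self.bracket_young

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: RunConfig, inputs: dict, extra: dict | None = None):
    """Write ``manifest.json``: config echo, seed, input digests, version."""
    from . import __version__

    manifest = {
        "package": "neodem",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in inputs.items()
            if p is not None and Path(p).exists()
        },
    }
    if extra:
        manifest.update(extra)
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
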