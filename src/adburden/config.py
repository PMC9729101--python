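"""Run configuration and provenance manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "write_manifest"]


@dataclass
class RunConfig:
    """All pipeline thresholds and gates in one serializable object.

    Defaults follow the study design: qualifying variants need MAF < 1%
    (very-rare sub-analysis < 0.1%) in both the sample and the reference
    panel; selections need cMAC >= 10; variants with > 20% missingness
    (depth < 6) or differential missingness are dropped; discovery uses
    BH FDR < 0.1 (targeted mode 0.05), confirmation is one-sided at 0.05
    and the meta-analysis familywise gate is Holm < 0.05.
    """

    vcf: str | None = None
    annotations: str | None = None
    phenotypes: str | None = None
    output_dir: str = "results"

    maf: float = 0.01
    maf_rare: float = 0.001
    revel_cuts: tuple = (25.0, 50.0, 75.0)
    cmac_min: int = 10
    missingness: float = 0.20
    differential_missingness_alpha: float = 1e-4
    hwe_alpha: float = 1e-6
    depth_min: int = 6

    fdr1: float = 0.1
    fdr_targeted: float = 0.05
    stage2_alpha: float = 0.05
    holm_alpha: float = 0.05

    n_reps: int = 25
    seed: int = 0

    def __post_init__(self):
        for name, lo, hi in (
            ("maf", 0, 0.5),
            ("maf_rare", 0, 0.5),
            ("missingness", 0, 1),
            ("fdr1", 0, 1),
            ("fdr_targeted", 0, 1),
            ("stage2_alpha", 0, 1),
            ("holm_alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.cmac_min < 1 or self.n_reps < 1:
            raise ValueError("cmac_min and n_reps must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "revel_cuts" in data:
            data["revel_cuts"] = tuple(data["revel_cuts"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["revel_cuts"] = list(d["revel_cuts"])
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(config: RunConfig, out_dir, extra: dict | None = None):
    """JSON run manifest: config (with hash), seed and package version."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
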