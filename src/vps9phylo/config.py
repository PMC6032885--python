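"""Flat key-value pipeline configuration with a versioned schema.

Every threshold the original analysis left implicit is an explicit, audited
config key.  The file format is one ``key = value`` per line, ``#`` for
comments; it round-trips unchanged through :func:`read_config` /
:func:`write_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    # input paths (empty string = stage not run)
    proteomes: str = ""        # FASTA of candidate proteomes (labelled records)
    queries: str = ""          # FASTA of query sequences
    source: str = ""           # FASTA of the query proteome (reverse search)
    backbone: str = ""         # aligned FASTA backbone
    catalog: str = ""          # backbone catalog TSV
    models: str = ""           # directory of domain-model TSVs
    species_tree: str = ""     # rooted newick with taxon tips
    matrix: str = ""           # presence matrix TSV (matrix-only runs)
    out_dir: str = "out"
    # thresholds
    e_max: float = 0.05
    min_occupancy: float = 0.5
    min_support: float = 0.80
    boots: int = 100
    prune_factor: float = 3.0
    leca_rule: str = "two-of-three"
    seed: int = 17

    def validate(self) -> None:
        if not 0.0 < self.e_max:
            raise ValueError("e_max must be positive")
        if not 0.0 < self.min_occupancy <= 1.0:
            raise ValueError("min_occupancy must be in (0, 1]")
        if not 0.0 <= self.min_support <= 1.0:
            raise ValueError("min_support must be in [0, 1]")
        if self.boots < 1:
            raise ValueError("boots must be >= 1")
        if self.prune_factor <= 1.0:
            raise ValueError("prune_factor must be > 1")
        if self.leca_rule not in ("two-of-three", "strict"):
            raise ValueError("leca_rule must be two-of-three or strict")


_TYPES = {f.name: f.type for f in fields(PipelineConfig)}


def read_config(path: str | Path) -> PipelineConfig:
    kwargs = {}
    version = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = (tok.strip() for tok in line.partition("="))
        if key == "schema_version":
            version = int(value)
            continue
        if key not in _TYPES:
            raise ValueError(f"unknown config key {key!r}")
        typ = _TYPES[key]
        if typ == "int":
            kwargs[key] = int(value)
        elif typ == "float":
            kwargs[key] = float(value)
        else:
            kwargs[key] = value
    if version != SCHEMA_VERSION:
        raise ValueError(f"config schema_version must be {SCHEMA_VERSION}")
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    lines = [f"schema_version = {SCHEMA_VERSION}"]
    for f in fields(PipelineConfig):
        lines.append(f"{f.name} = {getattr(cfg, f.name)}")
    Path(path).write_text("\n".join(lines) + "\n")
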