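"""Run configuration: every threshold of the analysis in one auditable place.

No stage module hard-codes a cutoff; they all take parameters whose defaults
mirror this configuration.  The config round-trips through YAML so a run is
fully described by one file plus a seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    #: neighbor-search cutoff in A (heavy-atom distance)
    radius: float = 5.0
    #: treat "within radius" inclusively (<=) for functional-site proximity
    near_site_inclusive: bool = True
    #: tier-2 conserved-site proximity is strict (<) as published
    tier2_inclusive: bool = False
    #: pLDDT gate (0-100) for good models and reliable residues, inclusive
    conf_gate: float = 70.0
    #: ligand-binding probability cutoff (inclusive)
    ligand_prob: float = 0.5
    #: interface score cutoff (inclusive; meta-PPISP operating point)
    interface_cut: float = 0.34
    #: FoldX ddG above this (strict) is destabilizing (kcal/mol convention)
    foldx_cut: float = 1.0
    #: DynaMut2 ddG below this (strict) is destabilizing
    dynamut_cut: float = 0.0
    #: pathogenicity score above this (strict) is pathogenic
    patho_cut: float = 0.611
    #: RSA below this percent (strict) is buried
    rsa_cut: float = 20.0
    #: tier-1 conservation threshold (inclusive)
    cons_high: float = 0.8
    #: tier-2 conservation threshold (strict)
    cons_mid: float = 0.65
    #: disorder probability above this (strict) marks a residue disordered
    disorder_cut: float = 0.5
    #: column-conservation threshold for the percent-scorecons metric
    percent_scorecons_threshold: float = 0.9
    #: Shrake-Rupley probe radius (A) and quadrature points per atom
    sasa_probe: float = 1.4
    sasa_points: int = 960
    #: Mann-Whitney observation granularity: "mutation" or "position"
    cohort_mode: str = "mutation"
    #: bootstrap draws for composition enrichment
    n_boot: int = 10_000
    seed: int = 0
    input_dir: str = ""
    output_dir: str = ""

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        for name in ("ligand_prob", "patho_cut", "disorder_cut",
                     "percent_scorecons_threshold", "cons_high", "cons_mid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.1:
                raise ValueError(f"{name}={v} outside its domain")
        if not 0.0 <= self.conf_gate <= 101.0:
            raise ValueError("conf_gate outside [0, 101]")
        if self.cohort_mode not in ("mutation", "position"):
            raise ValueError(f"unknown cohort_mode {self.cohort_mode!r}")

    def to_yaml(self, path: str | Path, include_paths: bool = False) -> None:
        """Serialize; run-local paths are omitted by default so the file
        describes the analysis, not one invocation."""
        data = asdict(self)
        if not include_paths:
            data.pop("input_dir")
            data.pop("output_dir")
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
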