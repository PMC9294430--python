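"""Readers, writers and domain types for all external formats.

Every downstream stage consumes only the types defined here:

* :class:`ProteinModel` — a single-chain predicted structure with per-residue
  confidence (pLDDT) read from the B-factor column of PDB ATOM records.
* :class:`Msa` — an aligned FASTA multiple sequence alignment, first sequence
  treated as the query.
* :class:`MutationRecord` — one missense variant (humsavar-like TSV row).
* :class:`PredictorTables` — per-position and per-mutation predictor outputs
  (ligand-site probability, interface score, FoldX/DynaMut2 ddG,
  pathogenicity, disorder probability) supplied as TSV.

Only a minimal single-chain PDB ATOM dialect is supported; HETATM records and
hydrogens are dropped at parse time.  Confidence for rosettafold-like sources
(reported on a 0-1 scale) is multiplied by 100 at parse time so one internal
0-100 scale is used everywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import AA1_TO_3, AA3_TO_1

logger = logging.getLogger(__name__)

SOURCES = ("alphafold-like", "rosettafold-like", "other")
CATEGORIES = ("disease", "polymorphism", "unclassified")

#: humsavar-style category aliases mapped onto the internal vocabulary.
CATEGORY_ALIASES = {
    "LP/P": "disease",
    "LB/B": "polymorphism",
    "US": "unclassified",
}


class StructureParseError(ValueError):
    """Raised for malformed or empty structure files."""


class MsaFormatError(ValueError):
    """Raised for ragged or otherwise malformed alignments."""


@dataclass(frozen=True)
class Atom:
    name: str
    coord: tuple[float, float, float]
    element: str


@dataclass
class ResidueRecord:
    """One residue: UniProt-numbered, heavy atoms only."""

    number: int
    aa: str
    atoms: list[Atom]
    confidence: float

    def coords(self) -> np.ndarray:
        return np.asarray([a.coord for a in self.atoms], dtype=float)


@dataclass
class ProteinModel:
    model_id: str
    source: str
    residues: list[ResidueRecord]
    confidence_scale: str = "0-100"

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise StructureParseError("residue numbers must strictly increase")
        for r in self.residues:
            if not r.atoms:
                raise StructureParseError(f"residue {r.number} has no heavy atoms")

    @property
    def numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def confidences(self) -> np.ndarray:
        return np.asarray([r.confidence for r in self.residues], dtype=float)

    def residue(self, number: int) -> ResidueRecord:
        try:
            return self._index[number]
        except AttributeError:
            self._index = {r.number: r for r in self.residues}
            return self._index[number]


@dataclass
class DomainSegment:
    """Sequence ranges of one domain; ``family_class`` mirrors the CATH /
    Pfam / unassigned partition."""

    accession: str
    ranges: list[tuple[int, int]]
    family_class: str = "unassigned"

    MIN_UNASSIGNED_LENGTH = 50

    def __post_init__(self) -> None:
        if self.family_class not in ("CATH", "Pfam", "unassigned"):
            raise ValueError(f"unknown family class {self.family_class!r}")
        if not self.ranges:
            raise ValueError("segment needs at least one range")
        self.ranges = sorted((int(a), int(b)) for a, b in self.ranges)
        for (a, b) in self.ranges:
            if b < a:
                raise ValueError(f"invalid range ({a}, {b})")
        for (_, b0), (a1, _) in zip(self.ranges, self.ranges[1:]):
            if a1 <= b0:
                raise ValueError("segment ranges overlap")
        if self.family_class == "unassigned":
            if self.length < self.MIN_UNASSIGNED_LENGTH:
                raise ValueError(
                    "unassigned segments must span at least "
                    f"{self.MIN_UNASSIGNED_LENGTH} residues"
                )

    @property
    def length(self) -> int:
        return sum(b - a + 1 for a, b in self.ranges)

    def positions(self) -> list[int]:
        out: list[int] = []
        for a, b in self.ranges:
            out.extend(range(a, b + 1))
        return out

    def __contains__(self, position: int) -> bool:
        return any(a <= position <= b for a, b in self.ranges)


@dataclass(frozen=True)
class MutationRecord:
    accession: str
    position: int
    wild_aa: str
    mutant_aa: str
    category: str
    disease_name: str = ""

    def __post_init__(self) -> None:
        if self.wild_aa == self.mutant_aa:
            raise ValueError("wild and mutant residue identical")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.accession, self.position, self.mutant_aa)


@dataclass
class PredictorTables:
    """Predictor outputs for one protein model, keyed by UniProt position.

    ``ligand_prob``/``interface_score``/``disorder_prob`` are per-position;
    ``foldx_ddg``/``dynamut_ddg``/``pathogenicity`` are per (position,
    mutant residue).  Positive FoldX ddG and negative DynaMut2 ddG mean
    destabilizing.
    """

    ligand_prob: dict[int, float] = field(default_factory=dict)
    interface_score: dict[int, float] = field(default_factory=dict)
    disorder_prob: dict[int, float] = field(default_factory=dict)
    foldx_ddg: dict[tuple[int, str], float] = field(default_factory=dict)
    dynamut_ddg: dict[tuple[int, str], float] = field(default_factory=dict)
    pathogenicity: dict[tuple[int, str], float] = field(default_factory=dict)

    def validate(self, positions: Iterable[int]) -> None:
        known = set(positions)
        for name in ("ligand_prob", "disorder_prob"):
            for pos, v in getattr(self, name).items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name}[{pos}]={v} outside [0, 1]")
        for (pos, mut), v in self.pathogenicity.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"pathogenicity[{pos},{mut}]={v} outside [0, 1]")
        for name in ("ligand_prob", "interface_score", "disorder_prob"):
            bad = set(getattr(self, name)) - known
            if bad:
                raise ValueError(f"{name} positions not in model: {sorted(bad)}")
        for name in ("foldx_ddg", "dynamut_ddg", "pathogenicity"):
            bad = {p for p, _ in getattr(self, name)} - known
            if bad:
                raise ValueError(f"{name} positions not in model: {sorted(bad)}")


@dataclass
class Msa:
    """Aligned sequences; the first sequence is the query by default."""

    ids: list[str]
    sequences: list[str]
    taxa: list[int | None] = field(default_factory=list)
    query_index: int = 0

    def __post_init__(self) -> None:
        if not self.sequences:
            raise MsaFormatError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise MsaFormatError(f"ragged alignment: lengths {sorted(lengths)}")
        if not self.taxa:
            self.taxa = [None] * len(self.sequences)

    @property
    def depth(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def query(self) -> str:
        return self.sequences[self.query_index]


# ---------------------------------------------------------------------------
# PDB ATOM-record subset (wwPDB v3.3 columns)
# ---------------------------------------------------------------------------

def _is_hydrogen(element: str, atom_name: str) -> bool:
    if element:
        return element.upper() in ("H", "D")
    name = atom_name.strip().lstrip("0123456789")
    return name[:1].upper() in ("H", "D")


def read_structure(path: str | Path, source: str = "alphafold-like",
                   model_id: str | None = None) -> ProteinModel:
    """Parse a single-chain PDB file; B-factor carries per-residue confidence.

    Hydrogens and HETATM records are dropped.  Residue confidence is taken
    from the first atom of each residue.  Rosettafold-like confidences on the
    0-1 scale are rescaled to 0-100.
    """
    path = Path(path)
    residues: list[ResidueRecord] = []
    seen: set[int] = set()
    current: ResidueRecord | None = None
    for line in path.read_text().splitlines():
        if not line.startswith("ATOM"):
            continue
        name = line[12:16].strip()
        resname = line[17:20].strip()
        resseq = int(line[22:26])
        x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 77 else ""
        if _is_hydrogen(element, name):
            continue
        if not all(np.isfinite([x, y, z])):
            raise StructureParseError(f"non-finite coordinates at residue {resseq}")
        if not element:
            element = name.lstrip("0123456789")[:1].upper()
        if current is None or current.number != resseq:
            if resseq in seen:
                raise StructureParseError(f"duplicate residue number {resseq}")
            seen.add(resseq)
            current = ResidueRecord(
                number=resseq,
                aa=AA3_TO_1.get(resname, "X"),
                atoms=[],
                confidence=bfac,
            )
            residues.append(current)
        current.atoms.append(Atom(name=name, coord=(x, y, z), element=element))
    if not residues:
        raise StructureParseError(f"no ATOM records in {path}")
    residues.sort(key=lambda r: r.number)
    if source == "rosettafold-like" and all(r.confidence <= 1.0 for r in residues):
        for r in residues:
            r.confidence *= 100.0
    return ProteinModel(
        model_id=model_id or path.stem,
        source=source,
        residues=residues,
    )


def write_structure(model: ProteinModel, path: str | Path) -> None:
    """Write the minimal ATOM-record dialect ``read_structure`` consumes."""
    scale = 0.01 if model.source == "rosettafold-like" else 1.0
    lines = []
    serial = 1
    for res in model.residues:
        resname = AA1_TO_3.get(res.aa, "UNK")
        for atom in res.atoms:
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {resname:<3s} A{res.number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{res.confidence * scale:6.2f}"
                f"          {atom.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Aligned FASTA
# ---------------------------------------------------------------------------

def _parse_taxon(description: str) -> int | None:
    # UniProt-style "OX=<taxid>" token in the header
    for token in description.split():
        if token.startswith("OX="):
            try:
                return int(token[3:])
            except ValueError:
                return None
    return None


def read_msa(path: str | Path) -> Msa:
    """Read an aligned FASTA file; first sequence is the query."""
    from Bio import SeqIO

    ids, seqs, taxa = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
        taxa.append(_parse_taxon(rec.description))
    if not seqs:
        raise MsaFormatError(f"no sequences in {path}")
    return Msa(ids=ids, sequences=seqs, taxa=taxa)


def write_msa(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq, taxon in zip(msa.ids, msa.sequences, msa.taxa):
            header = f">{sid}" + (f" OX={taxon}" if taxon is not None else "")
            fh.write(header + "\n")
            fh.write(seq + "\n")


# ---------------------------------------------------------------------------
# Mutation tables (humsavar-like TSV)
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = ["accession", "position", "wild", "mutant", "category", "disease"]


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a humsavar-like TSV.

    Categories outside the internal vocabulary are first passed through the
    alias table (LP/P → disease, LB/B → polymorphism, US → unclassified).
    Rows with wild == mutant are rejected with a logged warning, not fatally.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    records: list[MutationRecord] = []
    for row in df.itertuples(index=False):
        category = CATEGORY_ALIASES.get(row.category, row.category)
        if category not in CATEGORIES:
            raise ValueError(f"unknown mutation category {row.category!r}")
        if row.wild == row.mutant:
            logger.warning(
                "dropping mutation %s %s%s>%s: wild == mutant",
                row.accession, row.position, row.wild, row.mutant,
            )
            continue
        records.append(
            MutationRecord(
                accession=row.accession,
                position=int(row.position),
                wild_aa=row.wild,
                mutant_aa=row.mutant,
                category=category,
                disease_name=row.disease,
            )
        )
    return records


def write_mutations(records: Sequence[MutationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.accession, r.position, r.wild_aa, r.mutant_aa, r.category,
             r.disease_name)
            for r in records
        ],
        columns=MUTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Predictor tables
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["position", "ligand_prob", "interface_score", "disorder_prob"]
DDG_COLUMNS = ["position", "mutant", "foldx_ddg", "dynamut_ddg", "pathogenicity"]


def read_predictor_tables(site_path: str | Path,
                          mutation_path: str | Path | None = None) -> PredictorTables:
    """Read the per-position site table and optional per-mutation table."""
    site = pd.read_csv(site_path, sep="\t")
    missing = set(SITE_COLUMNS) - set(site.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    tables = PredictorTables(
        ligand_prob={int(p): float(v) for p, v in zip(site.position, site.ligand_prob)},
        interface_score={int(p): float(v)
                         for p, v in zip(site.position, site.interface_score)},
        disorder_prob={int(p): float(v)
                       for p, v in zip(site.position, site.disorder_prob)},
    )
    if mutation_path is not None:
        mut = pd.read_csv(mutation_path, sep="\t")
        missing = set(DDG_COLUMNS) - set(mut.columns)
        if missing:
            raise ValueError(f"mutation table missing columns: {sorted(missing)}")
        for row in mut.itertuples(index=False):
            key = (int(row.position), str(row.mutant))
            tables.foldx_ddg[key] = float(row.foldx_ddg)
            tables.dynamut_ddg[key] = float(row.dynamut_ddg)
            tables.pathogenicity[key] = float(row.pathogenicity)
    return tables


def write_predictor_tables(tables: PredictorTables, site_path: str | Path,
                           mutation_path: str | Path | None = None) -> None:
    positions = sorted(
        set(tables.ligand_prob) | set(tables.interface_score)
        | set(tables.disorder_prob)
    )
    site = pd.DataFrame(
        {
            "position": positions,
            "ligand_prob": [tables.ligand_prob.get(p, 0.0) for p in positions],
            "interface_score": [tables.interface_score.get(p, 0.0)
                                for p in positions],
            "disorder_prob": [tables.disorder_prob.get(p, 0.0) for p in positions],
        }
    )
    site.to_csv(site_path, sep="\t", index=False)
    if mutation_path is not None:
        keys = sorted(
            set(tables.foldx_ddg) | set(tables.dynamut_ddg)
            | set(tables.pathogenicity)
        )
        mut = pd.DataFrame(
            {
                "position": [p for p, _ in keys],
                "mutant": [m for _, m in keys],
                "foldx_ddg": [tables.foldx_ddg.get(k, np.nan) for k in keys],
                "dynamut_ddg": [tables.dynamut_ddg.get(k, np.nan) for k in keys],
                "pathogenicity": [tables.pathogenicity.get(k, np.nan) for k in keys],
            }
        )
        mut.to_csv(mutation_path, sep="\t", index=False)
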