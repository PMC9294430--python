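"""The mutation-explanation engine.

A mutation in a well-modeled region is *explained* when at least one line of
structural evidence applies:

* it sits on or within the cutoff radius of a predicted ligand-binding site,
  predicted protein-protein interface, or conserved site;
* FoldX predicts it destabilizing (ddG > 1, strict);
* it is predicted pathogenic (score > 0.611, strict).

DynaMut2 agreement (ddG < 0 destabilizing) is tracked as a cross-check but
does not enter the explained verdict; burial is reported descriptively.
Verdicts are only emitted for quality-gated residues (good domain model and
residue confidence at or above the gate).

Multi-model consensus merges verdicts keyed by (accession, position,
mutant): evidence is unioned over models whose residue passed the gate, and
mutations explained in the merge but not by the first model are counted as
"additional" explanations contributed by the second predictor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

from .accessibility import AccessibilityProfile, is_buried
from .geometry import NeighborMap, min_heavy_atom_distance, near_site
from .quality import QualityReport
from .structio import MutationRecord, PredictorTables, ProteinModel

logger = logging.getLogger(__name__)

LIGAND_PROB_CUT = 0.5
INTERFACE_CUT = 0.34
FOLDX_CUT = 1.0
DYNAMUT_CUT = 0.0
PATHO_CUT = 0.611

SITE_CLASSES = ("ligand", "interface", "conserved")
EVIDENCE_TAGS = SITE_CLASSES + ("destabilizing", "pathogenic")


@dataclass
class SiteSets:
    ligand: set[int]
    interface: set[int]
    conserved: set[int]

    def by_class(self) -> dict[str, set[int]]:
        return {"ligand": self.ligand, "interface": self.interface,
                "conserved": self.conserved}


@dataclass
class PositionAnnotation:
    position: int
    quality_ok: bool
    near_ligand: bool
    near_interface: bool
    near_conserved: bool
    dist_ligand: float
    dist_interface: float
    dist_conserved: float
    rsa: float
    buried: bool | None


@dataclass
class MutationVerdict:
    record: MutationRecord
    annotation: PositionAnnotation
    destabilizing_foldx: bool
    destabilizing_dynamut: bool
    pathogenic: bool
    evidence: frozenset[str]

    @property
    def explained(self) -> bool:
        return bool(self.evidence)

    @property
    def site_tags(self) -> frozenset[str]:
        return self.evidence & frozenset(SITE_CLASSES)

    @property
    def key(self) -> tuple[str, int, str]:
        return self.record.key


def site_sets(tables: PredictorTables, conserved: set[int],
              ligand_prob_cut: float = LIGAND_PROB_CUT,
              interface_cut: float = INTERFACE_CUT) -> SiteSets:
    """Threshold the predictor tables into residue site sets.

    Ligand-binding uses an inclusive probability cutoff (>= 0.5 as
    published); the interface score cutoff is inclusive as well (0.34, the
    meta-PPISP operating point).  The conserved set is computed upstream by
    the conservation module and passed through.
    """
    return SiteSets(
        ligand={p for p, v in tables.ligand_prob.items() if v >= ligand_prob_cut},
        interface={p for p, v in tables.interface_score.items()
                   if v >= interface_cut},
        conserved=set(conserved),
    )


def _min_site_distance(model: ProteinModel, position: int,
                       site: set[int]) -> float:
    if position in site:
        return 0.0
    present = site & set(model.numbers)
    if not present:
        return math.inf
    res = model.residue(position)
    return min(min_heavy_atom_distance(res, model.residue(s)) for s in present)


def annotate_position(position: int, model: ProteinModel, sites: SiteSets,
                      neighbors: NeighborMap,
                      accessibility: AccessibilityProfile,
                      quality: QualityReport,
                      rsa_cut: float = 20.0) -> PositionAnnotation:
    """Evidence flags for one residue position."""
    flags = {}
    dists = {}
    for name, site in sites.by_class().items():
        flags[name] = near_site(position, site, neighbors)
        dists[name] = _min_site_distance(model, position, site)
    rsa = accessibility.rsa.get(position, float("nan"))
    buried = is_buried(rsa, rsa_cut) if math.isfinite(rsa) else None
    quality_ok = quality.good_model and quality.residue_pass.get(position, False)
    return PositionAnnotation(
        position=position,
        quality_ok=quality_ok,
        near_ligand=flags["ligand"],
        near_interface=flags["interface"],
        near_conserved=flags["conserved"],
        dist_ligand=dists["ligand"],
        dist_interface=dists["interface"],
        dist_conserved=dists["conserved"],
        rsa=rsa,
        buried=buried,
    )


def judge_mutation(record: MutationRecord, annotation: PositionAnnotation,
                   tables: PredictorTables, foldx_cut: float = FOLDX_CUT,
                   dynamut_cut: float = DYNAMUT_CUT,
                   patho_cut: float = PATHO_CUT) -> MutationVerdict:
    """Per-mutation verdict; caller must pre-filter to quality-gated
    positions.  Missing ddG/pathogenicity entries leave the corresponding
    flag False with a logged note."""
    if not annotation.quality_ok:
        raise ValueError(
            f"no verdict for low-confidence position {record.position}"
        )
    key = (record.position, record.mutant_aa)
    foldx = tables.foldx_ddg.get(key)
    dynamut = tables.dynamut_ddg.get(key)
    patho = tables.pathogenicity.get(key)
    for name, value in (("foldx_ddg", foldx), ("dynamut_ddg", dynamut),
                        ("pathogenicity", patho)):
        if value is None:
            logger.warning("missing %s for %s p.%s%d%s", name, record.accession,
                           record.wild_aa, record.position, record.mutant_aa)
    destab_foldx = foldx is not None and foldx > foldx_cut
    destab_dynamut = dynamut is not None and dynamut < dynamut_cut
    pathogenic = patho is not None and patho > patho_cut
    evidence = set()
    if annotation.near_ligand:
        evidence.add("ligand")
    if annotation.near_interface:
        evidence.add("interface")
    if annotation.near_conserved:
        evidence.add("conserved")
    if destab_foldx:
        evidence.add("destabilizing")
    if pathogenic:
        evidence.add("pathogenic")
    return MutationVerdict(
        record=record,
        annotation=annotation,
        destabilizing_foldx=destab_foldx,
        destabilizing_dynamut=destab_dynamut,
        pathogenic=pathogenic,
        evidence=frozenset(evidence),
    )


@dataclass
class ConsensusResult:
    """Merged verdicts across models plus first-model attribution."""

    merged_evidence: dict[tuple[str, int, str], frozenset[str]]
    explained: set[tuple[str, int, str]]
    additional: set[tuple[str, int, str]]
    overlap: set[tuple[str, int, str]]

    @property
    def n_additional(self) -> int:
        return len(self.additional)

    def positions(self, keys: set[tuple[str, int, str]]) -> set[tuple[str, int]]:
        return {(acc, pos) for acc, pos, _ in keys}


def consensus_merge(
    verdicts_per_model: list[dict[tuple[str, int, str], MutationVerdict]]
) -> ConsensusResult:
    """Union evidence across models; count second-model-only explanations.

    ``additional`` holds mutations explained in the merge but not by the
    first model (unexplained there, or gated out of it entirely);
    ``overlap`` holds mutations explained by the first model and at least
    one other.
    """
    if not verdicts_per_model:
        raise ValueError("need verdicts from at least one model")
    merged: dict[tuple[str, int, str], set[str]] = {}
    for model_verdicts in verdicts_per_model:
        for key, verdict in model_verdicts.items():
            merged.setdefault(key, set()).update(verdict.evidence)
    explained = {k for k, ev in merged.items() if ev}
    first = verdicts_per_model[0]
    first_explained = {k for k, v in first.items() if v.explained}
    other_explained: set[tuple[str, int, str]] = set()
    for model_verdicts in verdicts_per_model[1:]:
        other_explained |= {k for k, v in model_verdicts.items() if v.explained}
    return ConsensusResult(
        merged_evidence={k: frozenset(v) for k, v in merged.items()},
        explained=explained,
        additional=explained - first_explained,
        overlap=first_explained & other_explained,
    )


def overlap_counts(verdicts: list[MutationVerdict]) -> dict[str, float | int]:
    """Venn partition of the three site-evidence classes.

    Returns the seven exclusive region counts (keys like ``"ligand"``,
    ``"ligand&interface"``, ``"ligand&interface&conserved"``) plus
    ``multiple_evidence_fraction``: among mutations with at least one site
    tag, the fraction carrying two or more.
    """
    regions: dict[str, int] = {}
    for k in range(1, 4):
        for combo in combinations(SITE_CLASSES, k):
            regions["&".join(combo)] = 0
    tagged = 0
    multi = 0
    for verdict in verdicts:
        tags = verdict.site_tags
        if not tags:
            continue
        tagged += 1
        if len(tags) >= 2:
            multi += 1
        regions["&".join(c for c in SITE_CLASSES if c in tags)] += 1
    out: dict[str, float | int] = dict(regions)
    out["n_site_tagged"] = tagged
    out["multiple_evidence_fraction"] = multi / tagged if tagged else 0.0
    return out


def same_disease_counts(
    records: list[MutationRecord], neighbors: NeighborMap
) -> tuple[int, int]:
    """(clustered, total) residue counts for the same-disease neighbor rule.

    Residues are grouped by disease label; within a label a residue counts
    as clustered when another residue of the same label is a spatial
    neighbor.  Labels occupying a single residue position cannot have a
    same-disease neighbor and are excluded from the denominator.
    """
    by_label: dict[str, set[int]] = {}
    for rec in records:
        if not rec.disease_name:
            raise ValueError(f"mutation {rec.key} has no disease label")
        by_label.setdefault(rec.disease_name, set()).add(rec.position)
    numerator = denominator = 0
    for positions in by_label.values():
        if len(positions) < 2:
            continue
        denominator += len(positions)
        for p in positions:
            if neighbors.neighbors(p) & (positions - {p}):
                numerator += 1
    return numerator, denominator


def same_disease_clustering(
    records: list[MutationRecord], neighbors: NeighborMap
) -> float | None:
    """Fraction of disease-mutation residues with a same-disease structural
    neighbor; None when no label occupies two or more residues."""
    numerator, denominator = same_disease_counts(records, neighbors)
    if denominator == 0:
        return None
    return numerator / denominator
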