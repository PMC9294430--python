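"""End-to-end orchestration.

Stages run in order structure -> quality -> conservation -> sites ->
explain -> cohort, first on an in-memory bundle (:func:`analyze_bundle`,
which tests and the simulator reuse directly) and then through the
file-based entry point :func:`run_pipeline`, which loads a bundle
directory, writes every stage output as TSV/JSON and records a manifest
with SHA-256 checksums so a rerun can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accessibility import AccessibilityProfile, accessibility_profile
from .cohort import CohortSummary, composition_enrichment, summarize
from .config import RunConfig
from .conservation import (
    ConservationProfile,
    DiversityMetrics,
    conserved_sites,
    diversity_metrics,
    scorecons_profile,
)
from .explain import (
    ConsensusResult,
    MutationVerdict,
    SiteSets,
    annotate_position,
    consensus_merge,
    judge_mutation,
    overlap_counts,
    same_disease_counts,
    site_sets,
)
from .geometry import model_ca_rmsd, residue_neighbors
from .quality import QualityReport, disorder_summary, domain_quality
from .structio import (
    DomainSegment,
    MutationRecord,
    Msa,
    PredictorTables,
    ProteinModel,
    read_msa,
    read_mutations,
    read_predictor_tables,
    read_structure,
)
from .synthetic import Bundle

logger = logging.getLogger(__name__)

STAGES = ("structure", "quality", "conservation", "sites", "explain", "cohort")


@dataclass
class ModelAnalysis:
    quality: QualityReport
    sites: SiteSets
    accessibility: AccessibilityProfile
    verdicts: dict[tuple[str, int, str], MutationVerdict]
    disorder_percent: float
    high_disorder: bool


@dataclass
class ProteinAnalysis:
    accession: str
    models: list[ModelAnalysis]
    profile: ConservationProfile
    diversity: DiversityMetrics
    inter_model_rmsd: float | None


@dataclass
class AnalysisResult:
    proteins: dict[str, ProteinAnalysis]
    consensus: ConsensusResult
    venn: dict[str, float | int]
    clustering: tuple[int, int]
    cohort: CohortSummary | None
    composition: pd.DataFrame | None
    config: RunConfig

    def verdicts(self, model_index: int = 0,
                 category: str | None = None) -> list[MutationVerdict]:
        out = []
        for pa in self.proteins.values():
            if model_index >= len(pa.models):
                continue
            for v in pa.models[model_index].verdicts.values():
                if category is None or v.record.category == category:
                    out.append(v)
        return out

    @property
    def explained_fraction_disease(self) -> float | None:
        """Fraction of quality-gated disease mutations explained (first
        model)."""
        disease = self.verdicts(0, "disease")
        if not disease:
            return None
        return sum(v.explained for v in disease) / len(disease)


@dataclass
class ProteinInputs:
    accession: str
    segment: DomainSegment
    models: list[ProteinModel]
    tables: list[PredictorTables]
    msa: Msa


def _analyze_model(model: ProteinModel, segment: DomainSegment,
                   tables: PredictorTables, profile: ConservationProfile,
                   mutations: list[MutationRecord],
                   config: RunConfig) -> ModelAnalysis:
    quality = domain_quality(model, segment, conf_gate=config.conf_gate)
    neighbors = residue_neighbors(model, radius=config.radius,
                                  inclusive=config.near_site_inclusive)
    tier2_neighbors = (
        neighbors if config.tier2_inclusive == config.near_site_inclusive
        else residue_neighbors(model, radius=config.radius,
                               inclusive=config.tier2_inclusive)
    )
    conserved = conserved_sites(profile, tier2_neighbors,
                                cons_high=config.cons_high,
                                cons_mid=config.cons_mid)
    sites = site_sets(tables, conserved, ligand_prob_cut=config.ligand_prob,
                      interface_cut=config.interface_cut)
    access = accessibility_profile(model, probe=config.sasa_probe,
                                   n_points=config.sasa_points)
    verdicts: dict[tuple[str, int, str], MutationVerdict] = {}
    for rec in mutations:
        if rec.position not in set(model.numbers):
            logger.warning("mutation %s at position %d outside model",
                           rec.accession, rec.position)
            continue
        annotation = annotate_position(rec.position, model, sites, neighbors,
                                       access, quality, rsa_cut=config.rsa_cut)
        if not annotation.quality_ok:
            continue
        verdicts[rec.key] = judge_mutation(
            rec, annotation, tables, foldx_cut=config.foldx_cut,
            dynamut_cut=config.dynamut_cut, patho_cut=config.patho_cut,
        )
    disorder_pct, high = disorder_summary(tables.disorder_prob, segment,
                                          disorder_cut=config.disorder_cut)
    return ModelAnalysis(quality=quality, sites=sites, accessibility=access,
                         verdicts=verdicts, disorder_percent=disorder_pct,
                         high_disorder=high)


def analyze_protein(inputs: ProteinInputs, mutations: list[MutationRecord],
                    config: RunConfig) -> ProteinAnalysis:
    profile = scorecons_profile(inputs.msa)
    diversity = diversity_metrics(
        inputs.msa, profile,
        scorecons_threshold=config.percent_scorecons_threshold,
    )
    models = [
        _analyze_model(model, inputs.segment, tables, profile, mutations,
                       config)
        for model, tables in zip(inputs.models, inputs.tables)
    ]
    rmsd = (model_ca_rmsd(inputs.models[0], inputs.models[1])
            if len(inputs.models) >= 2 else None)
    return ProteinAnalysis(accession=inputs.accession, models=models,
                           profile=profile, diversity=diversity,
                           inter_model_rmsd=rmsd)


def analyze_bundle(bundle: Bundle, config: RunConfig | None = None
                   ) -> AnalysisResult:
    """Run every stage on an in-memory synthetic bundle."""
    inputs = [
        ProteinInputs(
            accession=p.accession, segment=p.segment,
            models=[p.model1, p.model2], tables=[p.tables1, p.tables2],
            msa=p.msa,
        )
        for p in bundle.proteins
    ]
    return analyze_inputs(inputs, bundle.mutations, config or RunConfig())


def analyze_inputs(inputs: list[ProteinInputs],
                   mutations: list[MutationRecord],
                   config: RunConfig) -> AnalysisResult:
    by_acc: dict[str, list[MutationRecord]] = {}
    for rec in mutations:
        by_acc.setdefault(rec.accession, []).append(rec)
    proteins: dict[str, ProteinAnalysis] = {}
    for inp in inputs:
        proteins[inp.accession] = analyze_protein(
            inp, by_acc.get(inp.accession, []), config
        )
    n_models = max((len(pa.models) for pa in proteins.values()), default=0)
    per_model = [
        {
            key: verdict
            for pa in proteins.values() if k < len(pa.models)
            for key, verdict in pa.models[k].verdicts.items()
        }
        for k in range(n_models)
    ]
    consensus = consensus_merge(per_model if per_model else [{}])
    disease_v = [v for v in per_model[0].values()
                 if v.record.category == "disease"] if per_model else []
    poly_v = [v for v in per_model[0].values()
              if v.record.category == "polymorphism"] if per_model else []
    venn = overlap_counts(disease_v)
    num = den = 0
    tables_by_acc = {inp.accession: inp.tables[0] for inp in inputs}
    for inp in inputs:
        gated = [
            v.record for v in proteins[inp.accession].models[0].verdicts.values()
            if v.record.category == "disease" and v.record.disease_name
        ]
        if gated:
            nmap = residue_neighbors(inp.models[0], radius=config.radius,
                                     inclusive=config.near_site_inclusive)
            n_i, d_i = same_disease_counts(gated, nmap)
            num, den = num + n_i, den + d_i
    cohort = None
    composition = None
    if disease_v and poly_v:
        cohort = summarize(disease_v, poly_v,
                           tables_lookup=lambda acc: tables_by_acc[acc],
                           mode=config.cohort_mode)
        counts = Counter(v.record.mutant_aa for v in disease_v)
        composition = composition_enrichment(counts, n_boot=config.n_boot,
                                             seed=config.seed)
    else:
        warnings.warn("empty verdict class: cohort contrasts skipped")
    return AnalysisResult(proteins=proteins, consensus=consensus, venn=venn,
                          clustering=(num, den), cohort=cohort,
                          composition=composition, config=config)


# ---------------------------------------------------------------------------
# File-based entry point
# ---------------------------------------------------------------------------

def load_bundle_dir(input_dir: str | Path) -> tuple[list[ProteinInputs],
                                                    list[MutationRecord]]:
    """Load a bundle directory laid out as the simulator writes it."""
    input_dir = Path(input_dir)
    domains = pd.read_csv(input_dir / "domains.tsv", sep="\t")
    mutations = read_mutations(input_dir / "mutations.tsv")
    inputs: list[ProteinInputs] = []
    for row in domains.itertuples(index=False):
        acc = row.accession
        segment = DomainSegment(accession=acc,
                                ranges=[(int(row.start), int(row.end))],
                                family_class=row.family_class)
        models, tables = [], []
        for k, source in (("1", "alphafold-like"), ("2", "rosettafold-like")):
            pdb = input_dir / f"{acc}_model{k}.pdb"
            if not pdb.exists():
                continue
            models.append(read_structure(pdb, source=source))
            tables.append(read_predictor_tables(
                input_dir / f"{acc}_model{k}_sites.tsv",
                input_dir / f"{acc}_model{k}_ddg.tsv",
            ))
        msa = read_msa(input_dir / f"{acc}.afa")
        inputs.append(ProteinInputs(accession=acc, segment=segment,
                                    models=models, tables=tables, msa=msa))
    return inputs, mutations


def _verdict_frame(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    for model_index in range(2):
        for v in result.verdicts(model_index):
            a = v.annotation
            rows.append({
                "model": model_index + 1,
                "accession": v.record.accession,
                "position": v.record.position,
                "wild": v.record.wild_aa,
                "mutant": v.record.mutant_aa,
                "category": v.record.category,
                "disease": v.record.disease_name,
                "near_ligand": a.near_ligand,
                "near_interface": a.near_interface,
                "near_conserved": a.near_conserved,
                "dist_ligand": round(a.dist_ligand, 3),
                "dist_interface": round(a.dist_interface, 3),
                "dist_conserved": round(a.dist_conserved, 3),
                "rsa": round(a.rsa, 3),
                "buried": a.buried,
                "destabilizing_foldx": v.destabilizing_foldx,
                "destabilizing_dynamut": v.destabilizing_dynamut,
                "pathogenic": v.pathogenic,
                "explained": v.explained,
                "evidence": ",".join(sorted(v.evidence)),
            })
    return pd.DataFrame(rows).sort_values(
        ["model", "accession", "position", "mutant"]
    ).reset_index(drop=True) if rows else pd.DataFrame()


def _quality_frame(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    for acc, pa in result.proteins.items():
        for k, ma in enumerate(pa.models):
            rows.append({
                "accession": acc,
                "model": k + 1,
                "mean_confidence": round(ma.quality.mean_confidence, 3),
                "good_model": ma.quality.good_model,
                "disorder_percent": round(ma.disorder_percent, 3),
                "high_disorder": ma.high_disorder,
                "inter_model_rmsd": (round(pa.inter_model_rmsd, 3)
                                     if pa.inter_model_rmsd is not None
                                     else np.nan),
            })
    return pd.DataFrame(rows)


def _conservation_frame(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    for acc, pa in result.proteins.items():
        d = pa.diversity
        rows.append({
            "accession": acc, "neff": d.neff, "dops": round(d.dops, 3),
            "percent_scorecons": round(d.percent_scorecons, 3),
            "n_taxa": d.n_taxa,
        })
    return pd.DataFrame(rows)


def _report_dict(result: AnalysisResult) -> dict:
    cons = result.consensus
    num, den = result.clustering
    disease = result.verdicts(0, "disease")
    report: dict = {
        "n_proteins": len(result.proteins),
        "n_verdicts_model1": len(result.verdicts(0)),
        "n_disease_verdicts_model1": len(disease),
        "explained_fraction_disease": result.explained_fraction_disease,
        "explained_positions_disease": len({
            (v.record.accession, v.record.position)
            for v in disease if v.explained
        }),
        "consensus": {
            "n_explained_merged": len(cons.explained),
            "n_additional_from_other_models": cons.n_additional,
            "n_overlap": len(cons.overlap),
        },
        "venn": result.venn,
        "same_disease_clustering": {
            "clustered": num, "total": den,
            "fraction": num / den if den else None,
        },
    }
    if result.cohort is not None:
        c = result.cohort
        report["cohort"] = {
            "disease": vars(c.disease),
            "polymorphism": vars(c.polymorphism),
            "mann_whitney": {
                k: {"U": u, "p": p} for k, (u, p) in c.tests.items()
            },
        }
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Load ``config.input_dir``, run all stages, write outputs and a
    manifest into ``config.output_dir``; returns the manifest."""
    if not config.input_dir or not config.output_dir:
        raise ValueError("config.input_dir and config.output_dir are required")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        stage = "structure"
        inputs, mutations = load_bundle_dir(config.input_dir)
        stage = "analysis"
        result = analyze_inputs(inputs, mutations, config)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    outputs: dict[str, Path] = {}

    def write_df(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        outputs[name] = path

    def write_json(name: str, payload: dict) -> None:
        path = outdir / name
        path.write_text(json.dumps(payload, indent=1, sort_keys=True,
                                   default=_jsonable) + "\n")
        outputs[name] = path

    write_df("verdicts.tsv", _verdict_frame(result))
    write_df("quality.tsv", _quality_frame(result))
    write_df("conservation.tsv", _conservation_frame(result))
    report = _report_dict(result)
    write_json("report.json", report)
    write_json("venn.json", result.venn)
    if result.composition is not None:
        write_df("composition.tsv", result.composition.reset_index())
    if not result.verdicts(0):
        warnings.warn("no verdicts emitted: every residue failed the "
                      f"confidence gate ({config.conf_gate})")
    config.to_yaml(outdir / "config.yaml")
    outputs["config.yaml"] = outdir / "config.yaml"
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(STAGES),
        "counts": {
            "proteins": len(result.proteins),
            "mutations": len(mutations),
            "verdicts_model1": len(result.verdicts(0)),
        },
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
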