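"""Synthetic input bundles with known ground truth.

Generates everything the pipeline consumes — toy structures with
confidence profiles, a perturbed second model, alignments with controlled
conservation, predictor tables and labelled mutation cohorts with planted
effects — so every stage is testable offline.  The generator emulates the
statistical contrasts a disease-versus-polymorphism survey shows (disease
mutations preferentially buried, near planted functional sites, with
shifted ddG and pathogenicity distributions); it does not attempt
physically realistic side-chain packing or predictor error modes beyond a
confidence profile.

Ground truth (``should_be_explained`` per mutation, per model and merged)
is computed generator-side with direct brute-force distance checks and set
comprehensions — no cell list, no NeighborMap and no explanation-engine
code — and stored in a sidecar JSON next to the generated files.

Determinism: one global seed fans out to per-protein seeds through
``numpy.random.SeedSequence(seed, spawn_key=(protein_index,))``, so bundles
are byte-stable and unchanged proteins keep their content when
``n_proteins`` changes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

from . import accessibility, conservation
from .constants import AMINO_ACIDS
from .geometry import kabsch_rmsd
from .structio import (
    Atom,
    DomainSegment,
    Msa,
    MutationRecord,
    PredictorTables,
    ProteinModel,
    ResidueRecord,
    write_msa,
    write_mutations,
    write_predictor_tables,
    write_structure,
)

FOLDS = ("helix", "sheet-pair", "coil")


class InfeasiblePlacementError(ValueError):
    """More site-proximal mutations requested than proximal residues exist."""


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults describe the emulated survey: 20 proteins of 60 residues, 200
    disease and 200 polymorphism mutations, disease mutations placed at
    buried residues with probability 0.6 and within 5 A of a planted site
    with probability 0.6, an additive +1.5 FoldX ddG shift for the disease
    class over a N(0.2, 1.2^2) baseline, pathogenicity Beta(5, 2) versus
    Beta(2, 6), and a second model perturbed to a 1.7 A CA RMSD.
    """

    n_proteins: int = 20
    n_res: int = 60
    n_disease: int = 200
    n_polymorphism: int = 200
    burial_bias: float = 0.6
    fraction_near_site: float = 0.6
    ddg_shift: float = 1.5
    ddg_loc: float = 0.2
    ddg_scale: float = 1.2
    patho_beta_disease: tuple[float, float] = (5.0, 2.0)
    patho_beta_polymorphism: tuple[float, float] = (2.0, 6.0)
    model2_rmsd: float = 1.7
    msa_depth: int = 30
    identity_target: float = 0.55
    n_conserved_columns: int = 6
    ligand_site_size: int = 4
    interface_site_size: int = 5
    model2_extra_ligand: int = 1
    terminal_fraction: float = 0.1
    radius: float = 5.0
    conf_gate: float = 70.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("burial_bias", "fraction_near_site", "identity_target",
                     "terminal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_proteins", "n_res", "n_disease", "n_polymorphism"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ProteinBundle:
    accession: str
    segment: DomainSegment
    model1: ProteinModel
    model2: ProteinModel
    msa: Msa
    tables1: PredictorTables
    tables2: PredictorTables
    planted: dict


@dataclass
class Bundle:
    spec: CohortSpec
    proteins: list[ProteinBundle]
    mutations: list[MutationRecord]
    ground_truth: dict[str, dict] = field(default_factory=dict)

    def protein(self, accession: str) -> ProteinBundle:
        return next(p for p in self.proteins if p.accession == accession)


def _protein_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _terminal_count(n_res: int, terminal_fraction: float) -> int:
    return max(2, int(round(n_res * terminal_fraction)))


def _confidences(n_res: int, rng: np.random.Generator,
                 terminal_fraction: float = 0.1,
                 decimals: int = 2) -> np.ndarray:
    """Two-regime profile: low-confidence termini, high-confidence core."""
    n_term = _terminal_count(n_res, terminal_fraction)
    conf = rng.normal(85.0, 5.0, size=n_res)
    term = np.r_[np.arange(n_term), np.arange(n_res - n_term, n_res)]
    conf[term] = rng.normal(55.0, 8.0, size=len(term))
    return np.clip(conf, 0.0, 100.0).round(decimals)


def _helix_ca(n_res: int) -> np.ndarray:
    rise, twist = 1.5, np.deg2rad(100.0)
    # radius chosen so consecutive CA-CA distances are exactly 3.8 A
    radius = np.sqrt(3.8 ** 2 - rise ** 2) / (2.0 * np.sin(twist / 2.0))
    i = np.arange(n_res)
    return np.column_stack(
        [radius * np.cos(twist * i), radius * np.sin(twist * i), rise * i]
    )


def _sheet_pair_ca(n_res: int) -> np.ndarray:
    half = n_res // 2
    step = 3.3
    bulge = np.sqrt(3.8 ** 2 - step ** 2) / 2.0
    out = np.zeros((n_res, 3))
    for k in range(half):
        out[k] = (k * step, bulge * (-1) ** k, 0.0)
    for k in range(half, n_res):  # antiparallel partner strand
        j = k - half
        out[k] = ((half - 1 - j) * step, bulge * (-1) ** j, 4.8)
    return out


def _coil_ca(n_res: int, rng: np.random.Generator) -> np.ndarray:
    """Compact self-avoiding walk confined to a globule.

    The confinement radius scales as ``3.7 * n_res**(1/3)`` A, chosen so the
    fraction of buried residues (RSA < 20%) in a coil domain sits near the
    ~21% baseline real domains show; steps leaving the globule are accepted
    with exponentially decaying probability.
    """
    r_confine = 3.7 * n_res ** (1.0 / 3.0)
    out = np.zeros((n_res, 3))
    for k in range(1, n_res):
        cand = out[k - 1]
        for _ in range(300):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            cand = out[k - 1] + 3.8 * u
            if k >= 2 and cdist(cand[None, :], out[: k - 1]).min() < 3.4:
                continue
            r = np.linalg.norm(cand)
            if r <= r_confine or rng.random() < np.exp(-(r - r_confine)):
                break
        out[k] = cand
    return out


def _cb_directions(ca: np.ndarray, fold: str,
                   rng: np.random.Generator) -> np.ndarray:
    n = len(ca)
    if fold == "helix":
        d = ca.copy()
        d[:, 2] = 0.0
        norms = np.linalg.norm(d, axis=1, keepdims=True)
        return d / norms
    if fold == "sheet-pair":
        half = n // 2
        d = np.zeros((n, 3))
        d[:half, 2] = -1.0
        d[half:, 2] = 1.0
        return d
    d = rng.normal(size=(n, 3))
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def make_structure(n_res: int, fold: str = "helix", seed: int = 0,
                   sequence: str | None = None,
                   source: str = "alphafold-like",
                   model_id: str = "synthetic",
                   terminal_fraction: float = 0.1) -> ProteinModel:
    """Ideal-geometry CA/CB toy structure with a planted confidence profile.

    Consecutive CA atoms are 3.8 A apart for every fold; CB pseudo-atoms sit
    1.53 A from their CA.  Confidence is high (~N(85, 5^2)) in the core and
    low (~N(55, 8^2)) at the termini, clipped to [0, 100].
    """
    if n_res < 5:
        raise ValueError("n_res must be >= 5")
    if fold not in FOLDS:
        raise ValueError(f"unknown fold {fold!r}")
    rng = np.random.default_rng(seed)
    if fold == "helix":
        ca = _helix_ca(n_res)
    elif fold == "sheet-pair":
        ca = _sheet_pair_ca(n_res)
    else:
        ca = _coil_ca(n_res, rng)
    cb = ca + 1.53 * _cb_directions(ca, fold, rng)
    if sequence is None:
        sequence = "".join(rng.choice(list(AMINO_ACIDS), size=n_res))
    decimals = 0 if source == "rosettafold-like" else 2
    conf = _confidences(n_res, rng, terminal_fraction, decimals=decimals)
    ca = ca.round(3)
    cb = cb.round(3)
    residues = []
    for k in range(n_res):
        atoms = [Atom("CA", tuple(ca[k]), "C")]
        if sequence[k] != "G":
            atoms.append(Atom("CB", tuple(cb[k]), "C"))
        residues.append(
            ResidueRecord(number=k + 1, aa=sequence[k], atoms=atoms,
                          confidence=float(conf[k]))
        )
    return ProteinModel(model_id=model_id, source=source, residues=residues)


def perturb_model(model: ProteinModel, target_rmsd: float,
                  rng: np.random.Generator, source: str = "rosettafold-like",
                  model_id: str | None = None,
                  terminal_fraction: float = 0.1) -> ProteinModel:
    """Second model: noise scaled to the requested CA RMSD, then a random
    rigid motion; confidences redrawn."""
    coords = np.concatenate([r.coords() for r in model.residues])
    counts = [len(r.atoms) for r in model.residues]
    ca_rows = np.cumsum([0] + counts[:-1])  # CA is the first atom of each residue
    noise = rng.normal(size=coords.shape)
    scale = 1.0
    for _ in range(3):
        moved = coords + scale * noise
        achieved = kabsch_rmsd(coords[ca_rows], moved[ca_rows]).rmsd
        if achieved > 0:
            scale *= target_rmsd / achieved
    moved = coords + scale * noise
    # random proper rotation via QR, then a random shift
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    moved = moved @ q.T + rng.uniform(-20, 20, size=3)
    moved = moved.round(3)
    conf = _confidences(len(model.residues), rng, terminal_fraction, decimals=0)
    residues = []
    row = 0
    for k, res in enumerate(model.residues):
        atoms = []
        for atom in res.atoms:
            atoms.append(Atom(atom.name, tuple(moved[row]), atom.element))
            row += 1
        residues.append(ResidueRecord(number=res.number, aa=res.aa, atoms=atoms,
                                      confidence=float(conf[k])))
    return ProteinModel(model_id=model_id or model.model_id + "-alt",
                        source=source, residues=residues)


def _mutation_prob_for_identity(target: float, conserved_fraction: float
                                ) -> float:
    """Per-column replacement probability hitting a mean pairwise identity.

    Under uniform replacement over the 20-letter alphabet, two mutated
    sequences agree at a variable column with probability
    ``a^2 + 19 (p/20)^2`` where ``a = 1 - 19p/20``.
    """
    fc = conserved_fraction

    def realized(p: float) -> float:
        a = 1.0 - p + p / 20.0
        m = a * a + 19.0 * (p / 20.0) ** 2
        return fc + (1.0 - fc) * m

    if target >= 1.0:
        return 0.0
    if realized(1.0) >= target:
        return 1.0
    return float(brentq(lambda p: realized(p) - target, 0.0, 1.0))


def make_msa(length: int, depth: int, conserved_columns: set[int],
             identity_target: float, seed: int = 0,
             query_seq: str | None = None, query_id: str = "query") -> Msa:
    """Alignment with invariant conserved columns and a controlled mean
    pairwise identity elsewhere.  Columns are 0-based; the query is gapless,
    so column ``c`` maps to residue ``c + 1``."""
    if depth < 2:
        raise ValueError("depth must be >= 2")
    rng = np.random.default_rng(seed)
    if query_seq is None:
        query_seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    if len(query_seq) != length:
        raise ValueError("query_seq length mismatch")
    bad = {c for c in conserved_columns if not 0 <= c < length}
    if bad:
        raise ValueError(f"conserved columns out of range: {sorted(bad)}")
    p = _mutation_prob_for_identity(
        identity_target, len(conserved_columns) / length
    )
    alphabet = np.array(list(AMINO_ACIDS))
    variable = np.array(sorted(set(range(length)) - set(conserved_columns)),
                        dtype=int)
    seqs = [query_seq]
    ids = [query_id]
    taxa: list[int | None] = [9606]
    taxon_pool = rng.integers(1000, 9999, size=max(1, int(depth * 0.7)))
    for i in range(1, depth):
        chars = np.array(list(query_seq))
        if len(variable):
            mutate = rng.random(len(variable)) < p
            idx = variable[mutate]
            chars[idx] = alphabet[rng.integers(0, 20, size=len(idx))]
        seqs.append("".join(chars))
        ids.append(f"homolog{i}")
        taxa.append(int(rng.choice(taxon_pool)))
    return Msa(ids=ids, sequences=seqs, taxa=taxa)


def make_predictors(model: ProteinModel, planted_ligand: set[int],
                    planted_interface: set[int],
                    mutations: list[MutationRecord],
                    spec: CohortSpec, seed: int = 0,
                    extra_ligand: set[int] | None = None) -> PredictorTables:
    """Predictor stand-in tables with planted signal.

    Planted ligand residues score >= 0.5 (drawn U(0.55, 0.95)), others
    U(0, 0.45); interface likewise around the 0.34 cutoff.  Disorder is
    high on the termini.  Per-mutation ddG and pathogenicity follow the
    class-conditional distributions of the spec.
    """
    numbers = model.numbers
    bad = (planted_ligand | planted_interface) - set(numbers)
    if bad:
        raise ValueError(f"planted sites not in model: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    extra = extra_ligand or set()
    n_term = _terminal_count(len(numbers), spec.terminal_fraction)
    terminal = set(numbers[:n_term]) | set(numbers[-n_term:])
    tables = PredictorTables()
    for p in numbers:
        on_lig = p in planted_ligand or p in extra
        tables.ligand_prob[p] = round(
            float(rng.uniform(0.55, 0.95) if on_lig else rng.uniform(0.0, 0.45)),
            6,
        )
        on_int = p in planted_interface
        tables.interface_score[p] = round(
            float(rng.uniform(0.40, 0.90) if on_int else rng.uniform(0.0, 0.30)),
            6,
        )
        tables.disorder_prob[p] = round(
            float(rng.uniform(0.55, 0.90) if p in terminal
                  else rng.uniform(0.0, 0.45)),
            6,
        )
    for rec in mutations:
        key = (rec.position, rec.mutant_aa)
        if key in tables.foldx_ddg:
            continue
        is_disease = rec.category == "disease"
        ddg = rng.normal(spec.ddg_loc + (spec.ddg_shift if is_disease else 0.0),
                         spec.ddg_scale)
        a, b = (spec.patho_beta_disease if is_disease
                else spec.patho_beta_polymorphism)
        tables.foldx_ddg[key] = round(float(ddg), 6)
        # DynaMut2 stand-in: opposite sign convention, agrees with FoldX at
        # the 1 kcal/mol operating point up to noise
        tables.dynamut_ddg[key] = round(
            float(-(ddg - 1.0) * 0.8 + rng.normal(0.0, 0.3)), 6
        )
        tables.pathogenicity[key] = round(float(rng.beta(a, b)), 6)
    return tables


# ---------------------------------------------------------------------------
# Ground truth (brute force, independent of the geometry/explain modules)
# ---------------------------------------------------------------------------

def _residue_coords(model: ProteinModel) -> dict[int, np.ndarray]:
    return {r.number: r.coords() for r in model.residues}


def _near_set_brute(model: ProteinModel, site: set[int], radius: float,
                    inclusive: bool = True) -> set[int]:
    """Positions on a site residue or within the radius of one (direct
    pairwise distances; no cell list)."""
    if not site:
        return set()
    coords = _residue_coords(model)
    out = set()
    for p in model.numbers:
        if p in site:
            out.add(p)
            continue
        dmin = min(cdist(coords[p], coords[s]).min() for s in site)
        if (dmin <= radius) if inclusive else (dmin < radius):
            out.add(p)
    return out


def _conserved_truth(model: ProteinModel, msa: Msa, radius: float,
                     cons_high: float = 0.8, cons_mid: float = 0.65
                     ) -> set[int]:
    """Two-tier conserved set from the generated alignment, with tier-2
    proximity (< radius, strict) checked by direct distances."""
    profile = conservation.scorecons_profile(msa)
    scores = profile.residue_scores()
    tier1 = {p for p, s in scores.items() if s >= cons_high and p in set(model.numbers)}
    coords = _residue_coords(model)
    out = set(tier1)
    for p, s in scores.items():
        if p in out or s <= cons_mid or p not in coords:
            continue
        if any(cdist(coords[p], coords[t]).min() < radius for t in tier1):
            out.add(p)
    return out


def _quality_truth(model: ProteinModel, conf_gate: float
                   ) -> tuple[bool, dict[int, bool]]:
    conf = model.confidences()
    good = bool(conf.mean() >= conf_gate)
    return good, {r.number: r.confidence >= conf_gate for r in model.residues}


def _explained_truth(model: ProteinModel, msa: Msa,
                     tables: PredictorTables, mutations: list[MutationRecord],
                     spec: CohortSpec) -> dict[tuple[str, int, str], dict]:
    ligand = {p for p, v in tables.ligand_prob.items() if v >= 0.5}
    interface = {p for p, v in tables.interface_score.items() if v >= 0.34}
    near_lig = _near_set_brute(model, ligand, spec.radius)
    near_int = _near_set_brute(model, interface, spec.radius)
    conserved = _conserved_truth(model, msa, spec.radius)
    near_cons = _near_set_brute(model, conserved, spec.radius)
    good, res_pass = _quality_truth(model, spec.conf_gate)
    out = {}
    for rec in mutations:
        key = (rec.position, rec.mutant_aa)
        near = (rec.position in near_lig or rec.position in near_int
                or rec.position in near_cons)
        destab = tables.foldx_ddg[key] > 1.0
        patho = tables.pathogenicity[key] > 0.611
        out[rec.key] = {
            "quality_ok": good and res_pass[rec.position],
            "explained": near or destab or patho,
        }
    return out


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _random_site(rng: np.random.Generator, numbers: list[int], size: int,
                 exclude: set[int]) -> set[int]:
    pool = [n for n in numbers if n not in exclude]
    return set(int(x) for x in rng.choice(pool, size=min(size, len(pool)),
                                          replace=False))


def _place_mutations(rng: np.random.Generator, bundle: ProteinBundle,
                     n_disease: int, n_poly: int, spec: CohortSpec,
                     near_pool: set[int], buried_pool: set[int]
                     ) -> list[MutationRecord]:
    model = bundle.model1
    numbers = model.numbers
    seq = {r.number: r.aa for r in model.residues}
    labels = [f"{bundle.accession} syndrome"]
    if rng.random() > 0.8:
        labels.append(f"{bundle.accession} myopathy")
    used: set[tuple[int, str]] = set()
    records: list[MutationRecord] = []

    def draw(category: str) -> MutationRecord:
        for _ in range(500):
            if category == "disease":
                want_near = rng.random() < spec.fraction_near_site
                want_buried = rng.random() < spec.burial_bias
                if want_near and not near_pool:
                    raise InfeasiblePlacementError(
                        f"{bundle.accession}: no residues near a planted site"
                    )
                pool = sorted(near_pool) if want_near else numbers
                if want_buried:
                    buried_sub = [p for p in pool if p in buried_pool]
                    if buried_sub:
                        pool = buried_sub
            else:
                pool = numbers
            pos = int(rng.choice(pool))
            wild = seq[pos]
            mutant = str(rng.choice([a for a in AMINO_ACIDS if a != wild]))
            if (pos, mutant) in used:
                continue
            used.add((pos, mutant))
            disease_name = (str(rng.choice(labels))
                            if category == "disease" else "")
            return MutationRecord(
                accession=bundle.accession, position=pos, wild_aa=wild,
                mutant_aa=mutant, category=category,
                disease_name=disease_name,
            )
        raise InfeasiblePlacementError(
            f"{bundle.accession}: could not place a distinct mutation"
        )

    records.extend(draw("disease") for _ in range(n_disease))
    records.extend(draw("polymorphism") for _ in range(n_poly))
    return records


def _split_counts(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def make_cohort(spec: CohortSpec) -> Bundle:
    """Full synthetic bundle: two models, MSA, predictor tables, labelled
    mutations and sidecar ground truth for every protein."""
    proteins: list[ProteinBundle] = []
    all_mutations: list[MutationRecord] = []
    ground_truth: dict[str, dict] = {}
    n_dis = _split_counts(spec.n_disease, spec.n_proteins)
    n_pol = _split_counts(spec.n_polymorphism, spec.n_proteins)
    for i in range(spec.n_proteins):
        rng = _protein_rng(spec.seed, i)
        accession = f"SYN{i:03d}"
        # cohort proteins are compact globules: only that fold reproduces
        # the buried-residue baseline of real domains, which the planted
        # burial contrast needs; helix / sheet-pair stay available in
        # make_structure for geometric tests
        fold = "coil"
        struct_seed = int(rng.integers(0, 2 ** 31 - 1))
        model1 = make_structure(
            spec.n_res, fold=fold, seed=struct_seed,
            model_id=f"{accession}-m1", terminal_fraction=spec.terminal_fraction,
        )
        model2 = perturb_model(model1, spec.model2_rmsd, rng,
                               model_id=f"{accession}-m2",
                               terminal_fraction=spec.terminal_fraction)
        numbers = model1.numbers
        ligand = _random_site(rng, numbers, spec.ligand_site_size, set())
        interface = _random_site(rng, numbers, spec.interface_site_size, ligand)
        extra_ligand = _random_site(rng, numbers, spec.model2_extra_ligand,
                                    ligand | interface)
        conserved_cols = {p - 1 for p in
                          _random_site(rng, numbers, spec.n_conserved_columns,
                                       set())}
        msa = make_msa(spec.n_res, spec.msa_depth, conserved_cols,
                       spec.identity_target,
                       seed=int(rng.integers(0, 2 ** 31 - 1)),
                       query_seq=model1.sequence, query_id=accession)
        family = ("CATH", "Pfam", "unassigned")[i % 3]
        if family == "unassigned" and spec.n_res < DomainSegment.MIN_UNASSIGNED_LENGTH:
            family = "Pfam"
        segment = DomainSegment(accession=accession,
                                ranges=[(numbers[0], numbers[-1])],
                                family_class=family)
        bundle = ProteinBundle(
            accession=accession, segment=segment, model1=model1, model2=model2,
            msa=msa, tables1=PredictorTables(), tables2=PredictorTables(),
            planted={
                "fold": fold,
                "ligand": sorted(ligand),
                "interface": sorted(interface),
                "extra_ligand_model2": sorted(extra_ligand),
                "conserved_columns": sorted(conserved_cols),
            },
        )
        planted_sites = ligand | interface
        near_pool = _near_set_brute(model1, planted_sites, spec.radius)
        rsa = accessibility.accessibility_profile(model1).rsa
        buried_pool = {p for p, v in rsa.items()
                       if np.isfinite(v) and v < 20.0}
        mutations = _place_mutations(rng, bundle, n_dis[i], n_pol[i], spec,
                                     near_pool, buried_pool)
        tab_seed = int(rng.integers(0, 2 ** 31 - 1))
        bundle.tables1 = make_predictors(model1, ligand, interface, mutations,
                                         spec, seed=tab_seed)
        bundle.tables2 = make_predictors(model2, ligand, interface, mutations,
                                         spec, seed=tab_seed,
                                         extra_ligand=extra_ligand)
        truth1 = _explained_truth(model1, msa, bundle.tables1, mutations, spec)
        truth2 = _explained_truth(model2, msa, bundle.tables2, mutations, spec)
        for rec in mutations:
            t1, t2 = truth1[rec.key], truth2[rec.key]
            exp1 = t1["quality_ok"] and t1["explained"]
            exp2 = t2["quality_ok"] and t2["explained"]
            ground_truth["|".join(map(str, rec.key))] = {
                "category": rec.category,
                "quality_ok_model1": t1["quality_ok"],
                "quality_ok_model2": t2["quality_ok"],
                "should_be_explained_model1": exp1,
                "should_be_explained_model2": exp2,
                "should_be_explained_merged": exp1 or exp2,
                "additional_from_model2": exp2 and not exp1,
            }
        proteins.append(bundle)
        all_mutations.extend(mutations)
    return Bundle(spec=spec, proteins=proteins, mutations=all_mutations,
                  ground_truth=ground_truth)


def write_bundle(bundle: Bundle, outdir: str | Path) -> list[Path]:
    """Write a bundle in the exact formats the readers consume, plus the
    ground-truth sidecar; returns the files written (sorted)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    for prot in bundle.proteins:
        acc = prot.accession
        write_structure(prot.model1, emit(outdir / f"{acc}_model1.pdb"))
        write_structure(prot.model2, emit(outdir / f"{acc}_model2.pdb"))
        write_msa(prot.msa, emit(outdir / f"{acc}.afa"))
        for k, tables in (("1", prot.tables1), ("2", prot.tables2)):
            write_predictor_tables(
                tables,
                emit(outdir / f"{acc}_model{k}_sites.tsv"),
                emit(outdir / f"{acc}_model{k}_ddg.tsv"),
            )
    write_mutations(bundle.mutations, emit(outdir / "mutations.tsv"))
    domains = "\n".join(
        ["accession\tstart\tend\tfamily_class"]
        + [
            f"{p.accession}\t{p.segment.ranges[0][0]}\t{p.segment.ranges[0][1]}"
            f"\t{p.segment.family_class}"
            for p in bundle.proteins
        ]
    )
    emit(outdir / "domains.tsv").write_text(domains + "\n")
    meta = {
        "spec": asdict(bundle.spec),
        "planted": {p.accession: p.planted for p in bundle.proteins},
        "ground_truth": bundle.ground_truth,
    }
    emit(outdir / "ground_truth.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True) + "\n"
    )
    return sorted(written)
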