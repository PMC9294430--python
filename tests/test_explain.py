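"""Mutation-explanation engine: evidence rules, consensus, Venn, clustering."""

import math
from itertools import combinations

import numpy as np
import pytest

from mutexplain.accessibility import AccessibilityProfile
from mutexplain.explain import (
    SiteSets,
    annotate_position,
    consensus_merge,
    judge_mutation,
    overlap_counts,
    same_disease_clustering,
    site_sets,
)
from mutexplain.geometry import residue_neighbors
from mutexplain.quality import QualityReport, domain_quality
from mutexplain.structio import DomainSegment, MutationRecord, PredictorTables

from conftest import model_from_points


def flat_access(numbers, rsa=50.0):
    return AccessibilityProfile(sasa={n: 100.0 for n in numbers},
                                rsa={n: rsa for n in numbers},
                                probe=1.4, n_points=960)


def all_pass_quality(numbers):
    return QualityReport(mean_confidence=90.0, good_model=True,
                         residue_pass={n: True for n in numbers})


class TestSiteSets:
    def test_ligand_cut_inclusive(self):
        tables = PredictorTables(ligand_prob={1: 0.5, 2: 0.49},
                                 interface_score={1: 0.0, 2: 0.0})
        sets = site_sets(tables, conserved=set())
        assert sets.ligand == {1}

    def test_matches_direct_comprehension(self, rng):
        positions = range(1, 51)
        tables = PredictorTables(
            ligand_prob={p: float(rng.uniform(0, 1)) for p in positions},
            interface_score={p: float(rng.uniform(0, 1)) for p in positions},
        )
        conserved = {int(p) for p in rng.choice(50, size=5) + 1}
        sets = site_sets(tables, conserved)
        assert sets.ligand == {p for p, v in tables.ligand_prob.items()
                               if v >= 0.5}
        assert sets.interface == {p for p, v in tables.interface_score.items()
                                  if v >= 0.34}
        assert sets.conserved == conserved


class TestAnnotatePosition:
    def setup_method(self):
        # four CA-only residues in a row, 4 A apart
        self.model = model_from_points([(4 * i, 0, 0) for i in range(4)])
        self.neighbors = residue_neighbors(self.model, 5.0)

    def annotate(self, position, sites, quality=None):
        return annotate_position(
            position, self.model, sites, self.neighbors,
            flat_access(self.model.numbers),
            quality or all_pass_quality(self.model.numbers),
        )

    def test_on_site_distance_zero(self):
        sites = SiteSets(ligand={2}, interface=set(), conserved=set())
        ann = self.annotate(2, sites)
        assert ann.near_ligand and ann.dist_ligand == 0.0
        assert not ann.near_interface
        assert math.isinf(ann.dist_interface)

    def test_neighbor_within_radius(self):
        sites = SiteSets(ligand={1}, interface=set(), conserved=set())
        ann = self.annotate(2, sites)
        assert ann.near_ligand and ann.dist_ligand == pytest.approx(4.0)

    def test_low_confidence_blocks_verdict(self):
        quality = QualityReport(mean_confidence=90.0, good_model=True,
                                residue_pass={n: n != 2
                                              for n in self.model.numbers})
        sites = SiteSets(ligand={2}, interface=set(), conserved=set())
        ann = self.annotate(2, sites, quality)
        assert not ann.quality_ok
        rec = MutationRecord("P1", 2, "A", "V", "disease", "X")
        with pytest.raises(ValueError, match="low-confidence"):
            judge_mutation(rec, ann, PredictorTables())

    def test_flags_equal_naive_recomputation(self, rng):
        from conftest import random_model
        from mutexplain.geometry import min_heavy_atom_distance

        model = random_model(rng, n_res=30)
        neighbors = residue_neighbors(model, 5.0)
        quality = all_pass_quality(model.numbers)
        access = flat_access(model.numbers)
        res = {r.number: r for r in model.residues}
        for _ in range(5):
            sets = SiteSets(
                ligand=set(rng.choice(model.numbers, 3, replace=False)
                           .tolist()),
                interface=set(rng.choice(model.numbers, 3, replace=False)
                              .tolist()),
                conserved=set(),
            )
            for p in model.numbers:
                ann = annotate_position(p, model, sets, neighbors, access,
                                        quality)
                for name, site in (("near_ligand", sets.ligand),
                                   ("near_interface", sets.interface)):
                    naive = p in site or any(
                        min_heavy_atom_distance(res[p], res[s]) <= 5.0
                        for s in site
                    )
                    assert getattr(ann, name) == naive


class TestJudgeMutation:
    def verdict(self, foldx=0.0, patho=0.0, near=False):
        model = model_from_points([(0, 0, 0), (30, 0, 0)])
        neighbors = residue_neighbors(model, 5.0)
        sites = SiteSets(ligand={1} if near else set(), interface=set(),
                         conserved=set())
        ann = annotate_position(1, model, sites, neighbors,
                                flat_access(model.numbers),
                                all_pass_quality(model.numbers))
        rec = MutationRecord("P1", 1, "A", "V", "disease", "X")
        tables = PredictorTables(foldx_ddg={(1, "V"): foldx},
                                 dynamut_ddg={(1, "V"): -foldx},
                                 pathogenicity={(1, "V"): patho})
        return judge_mutation(rec, ann, tables)

    def test_destabilizing_alone_explains(self):
        v = self.verdict(foldx=1.5, patho=0.3)
        assert v.explained and v.evidence == {"destabilizing"}

    def test_foldx_boundary_strict(self):
        assert not self.verdict(foldx=1.0).destabilizing_foldx
        assert self.verdict(foldx=1.0 + 1e-9).destabilizing_foldx

    def test_patho_boundary_strict(self):
        assert not self.verdict(patho=0.611).pathogenic
        assert self.verdict(patho=0.612).pathogenic

    def test_dynamut_tracked_but_not_evidence(self):
        v = self.verdict(foldx=-2.0)  # dynamut ddg = +2 -> not destabilizing
        assert not v.destabilizing_dynamut and not v.explained
        v = self.verdict(foldx=0.5)  # dynamut ddg = -0.5 -> destabilizing
        assert v.destabilizing_dynamut and not v.explained

    def test_missing_entries_treated_false(self, caplog):
        model = model_from_points([(0, 0, 0), (30, 0, 0)])
        neighbors = residue_neighbors(model, 5.0)
        ann = annotate_position(1, model,
                                SiteSets(set(), set(), set()), neighbors,
                                flat_access(model.numbers),
                                all_pass_quality(model.numbers))
        rec = MutationRecord("P1", 1, "A", "V", "disease", "X")
        import logging

        with caplog.at_level(logging.WARNING):
            v = judge_mutation(rec, ann, PredictorTables())
        assert not v.explained
        assert sum("missing" in m for m in caplog.messages) == 3

    def test_explained_set_equals_set_algebra(self, small_bundle):
        """On a planted cohort the engine's explained set is exactly the
        union of the per-channel sets."""
        from mutexplain.config import RunConfig
        from mutexplain.pipeline import analyze_bundle

        result = analyze_bundle(small_bundle, RunConfig())
        verdicts = result.verdicts(0)
        assert len(verdicts) >= 20
        union = {
            v.key for v in verdicts
            if (v.annotation.near_ligand or v.annotation.near_interface
                or v.annotation.near_conserved or v.destabilizing_foldx
                or v.pathogenic)
        }
        assert {v.key for v in verdicts if v.explained} == union

    def test_impossible_thresholds_reduce_to_conservation_channel(
            self, small_bundle):
        from mutexplain.config import RunConfig
        from mutexplain.pipeline import analyze_bundle

        config = RunConfig(ligand_prob=1.1, interface_cut=np.inf,
                           foldx_cut=np.inf, patho_cut=1.1)
        result = analyze_bundle(small_bundle, config)
        verdicts = result.verdicts(0)
        assert all(v.evidence <= {"conserved"} for v in verdicts)
        config = RunConfig(ligand_prob=1.1, interface_cut=np.inf,
                           foldx_cut=np.inf, patho_cut=1.1, cons_high=1.01,
                           cons_mid=1.01)
        result = analyze_bundle(small_bundle, config)
        assert all(not v.explained for v in result.verdicts(0))


def make_verdict(key, evidence):
    """Minimal verdict built through the real rule engine."""
    acc, pos, mut = key
    model = model_from_points([(0, 0, 0), (30, 0, 0)])
    neighbors = residue_neighbors(model, 5.0)
    sites = SiteSets(
        ligand={pos} if "ligand" in evidence else set(),
        interface={pos} if "interface" in evidence else set(),
        conserved={pos} if "conserved" in evidence else set(),
    )
    ann = annotate_position(1, model, sites, neighbors,
                            flat_access(model.numbers),
                            all_pass_quality(model.numbers))
    tables = PredictorTables(
        foldx_ddg={(pos, mut): 2.0 if "destabilizing" in evidence else 0.0},
        dynamut_ddg={(pos, mut): 0.1},
        pathogenicity={(pos, mut): 0.9 if "pathogenic" in evidence else 0.1},
    )
    rec = MutationRecord(acc, 1, "A", mut, "disease", "X")
    return judge_mutation(rec, ann, tables)


class TestConsensus:
    def test_model2_only_counts_as_additional(self):
        key = ("P1", 1, "V")
        v2 = make_verdict(key, {"ligand"})
        merged = consensus_merge([{}, {v2.key: v2}])
        assert merged.additional == {v2.key}
        assert merged.overlap == set()

    def test_both_models_in_overlap_not_additional(self):
        key = ("P1", 1, "V")
        v1 = make_verdict(key, {"ligand"})
        v2 = make_verdict(key, {"interface"})
        merged = consensus_merge([{v1.key: v1}, {v2.key: v2}])
        assert merged.additional == set()
        assert merged.overlap == {v1.key}
        assert merged.merged_evidence[v1.key] == {"ligand", "interface"}

    def test_union_superset_property(self, small_bundle):
        from mutexplain.config import RunConfig
        from mutexplain.pipeline import analyze_bundle

        result = analyze_bundle(small_bundle, RunConfig())
        per_model = [
            {v.key: v for v in result.verdicts(k)} for k in range(2)
        ]
        merged = consensus_merge(per_model)
        for model_verdicts in per_model:
            explained = {k for k, v in model_verdicts.items() if v.explained}
            assert explained <= merged.explained


class TestOverlapCounts:
    def test_disjoint_singletons(self):
        verdicts = [
            make_verdict(("P1", 1, "V"), {"ligand"}),
            make_verdict(("P1", 1, "W"), {"interface"}),
            make_verdict(("P1", 1, "Y"), {"conserved"}),
        ]
        counts = overlap_counts(verdicts)
        assert counts["ligand"] == counts["interface"] == counts["conserved"] == 1
        assert counts["ligand&interface"] == 0
        assert counts["multiple_evidence_fraction"] == 0.0

    def test_pairwise_region(self):
        counts = overlap_counts([
            make_verdict(("P1", 1, "V"), {"ligand", "interface"}),
        ])
        assert counts["ligand&interface"] == 1
        assert counts["ligand"] == 0
        assert counts["multiple_evidence_fraction"] == 1.0

    def test_matches_inclusion_exclusion_on_random_tags(self, rng):
        classes = ("ligand", "interface", "conserved")
        verdicts = []
        mutants = "CDEFGHIKLMNPQRSTVWY"
        for i in range(40):
            tags = {c for c in classes if rng.random() < 0.5}
            verdicts.append(make_verdict(("P1", 1, mutants[i % 19]), tags))
        counts = overlap_counts(verdicts)
        tag_sets = [v.site_tags for v in verdicts if v.site_tags]
        assert counts["n_site_tagged"] == len(tag_sets)
        # region counts sum to the number of tagged mutations
        region_total = sum(
            counts["&".join(c)] for k in range(1, 4)
            for c in combinations(classes, k)
        )
        assert region_total == len(tag_sets)
        # each exact-combination region matches direct counting
        for k in range(1, 4):
            for combo in combinations(classes, k):
                direct = sum(1 for t in tag_sets if t == set(combo))
                assert counts["&".join(combo)] == direct


class TestSameDiseaseClustering:
    def neighbors_for(self, *points):
        model = model_from_points(points)
        return residue_neighbors(model, 5.0)

    def rec(self, pos, disease="D1"):
        return MutationRecord("P1", pos, "A", "V", "disease", disease)

    def test_close_pair_fully_clustered(self):
        nmap = self.neighbors_for((0, 0, 0), (4, 0, 0))
        assert same_disease_clustering([self.rec(1), self.rec(2)], nmap) == 1.0

    def test_distant_pair_unclustered(self):
        nmap = self.neighbors_for((0, 0, 0), (20, 0, 0))
        assert same_disease_clustering([self.rec(1), self.rec(2)], nmap) == 0.0

    def test_singleton_labels_excluded(self):
        nmap = self.neighbors_for((0, 0, 0), (20, 0, 0))
        records = [self.rec(1, "D1"), self.rec(2, "D2")]
        assert same_disease_clustering(records, nmap) is None

    def test_recovers_planted_fraction(self):
        # residues 1-2 adjacent (label A), 3 and 4 isolated (label B)
        nmap = self.neighbors_for((0, 0, 0), (4, 0, 0), (50, 0, 0),
                                  (100, 0, 0))
        records = [self.rec(1, "A"), self.rec(2, "A"),
                   self.rec(3, "B"), self.rec(4, "B")]
        assert same_disease_clustering(records, nmap) == pytest.approx(0.5)
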