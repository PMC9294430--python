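"""Synthetic-data generator: geometry, alignments, planted effects,
determinism."""

import numpy as np
import pytest

from mutexplain.conservation import neff_80, pairwise_identity, scorecons_profile
from mutexplain.geometry import model_ca_rmsd
from mutexplain.structio import MutationRecord
from mutexplain.synthetic import (
    CohortSpec,
    InfeasiblePlacementError,
    make_cohort,
    make_msa,
    make_predictors,
    make_structure,
    perturb_model,
    write_bundle,
)


def ca_coords(model):
    return np.asarray([r.atoms[0].coord for r in model.residues])


class TestMakeStructure:
    def test_helix_ca_spacing(self):
        model = make_structure(20, fold="helix", seed=0)
        ca = ca_coords(model)
        steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(np.abs(steps - 3.8) <= 0.01)

    @pytest.mark.parametrize("fold", ["helix", "sheet-pair", "coil"])
    def test_seed_determinism_bit_exact(self, fold):
        a = make_structure(25, fold=fold, seed=11)
        b = make_structure(25, fold=fold, seed=11)
        assert np.array_equal(ca_coords(a), ca_coords(b))
        assert np.array_equal(a.confidences(), b.confidences())
        assert a.sequence == b.sequence

    def test_helix_radius_and_pitch_match_closed_form(self):
        model = make_structure(50, fold="helix", seed=0)
        ca = ca_coords(model)
        rise, twist = 1.5, np.deg2rad(100.0)
        expected_radius = np.sqrt(3.8 ** 2 - rise ** 2) / (2 * np.sin(twist / 2))
        radii = np.linalg.norm(ca[:, :2], axis=1)
        assert np.allclose(radii, expected_radius, atol=1e-3)
        # pitch: rise per turn = rise * (360 / 100)
        z_steps = np.diff(ca[:, 2])
        assert np.allclose(z_steps, rise, atol=1e-3)

    def test_cb_pseudo_atoms_at_fixed_distance(self):
        model = make_structure(20, fold="coil", seed=5)
        for res in model.residues:
            if res.aa == "G":
                assert len(res.atoms) == 1
            else:
                ca, cb = (np.asarray(a.coord) for a in res.atoms)
                assert np.linalg.norm(ca - cb) == pytest.approx(1.53,
                                                                abs=0.01)

    def test_confidence_two_regime(self):
        model = make_structure(100, fold="helix", seed=3)
        conf = model.confidences()
        assert conf[10:90].mean() > conf[:10].mean()
        assert conf[10:90].mean() > conf[90:].mean()
        assert np.all((conf >= 0) & (conf <= 100))


class TestPerturbedSecondModel:
    @pytest.mark.parametrize("target", [1.0, 1.7, 3.0])
    def test_achieves_requested_rmsd_within_ten_percent(self, target):
        model = make_structure(60, fold="coil", seed=2)
        rng = np.random.default_rng(7)
        other = perturb_model(model, target, rng)
        achieved = model_ca_rmsd(model, other)
        assert abs(achieved - target) / target <= 0.10


class TestMakeMsa:
    def test_all_conserved_columns_score_one(self):
        msa = make_msa(12, 8, set(range(12)), identity_target=0.5, seed=0)
        assert np.allclose(scorecons_profile(msa).scores, 1.0)

    def test_identity_one_gives_neff_one(self):
        msa = make_msa(20, 10, set(), identity_target=1.0, seed=0)
        assert neff_80(msa) == 1.0

    def test_realized_identity_near_target(self):
        msa = make_msa(200, 30, set(), identity_target=0.5, seed=1)
        idents = [
            pairwise_identity(msa.sequences[i], msa.sequences[j])
            for i in range(1, 15) for j in range(i + 1, 15)
        ]
        assert abs(np.mean(idents) - 0.5) <= 0.05


class TestMakePredictors:
    def spec(self):
        return CohortSpec(n_proteins=1, n_res=30, n_disease=4,
                          n_polymorphism=4, seed=0)

    def test_planted_residues_pass_ligand_rule(self):
        model = make_structure(30, fold="coil", seed=1)
        tables = make_predictors(model, {3, 7, 9}, {15}, [], self.spec(),
                                 seed=0)
        for p in (3, 7, 9):
            assert tables.ligand_prob[p] >= 0.5
        for p in set(model.numbers) - {3, 7, 9}:
            assert tables.ligand_prob[p] < 0.5

    def test_null_effects_make_classes_exchangeable(self):
        model = make_structure(30, fold="coil", seed=1)
        spec = CohortSpec(n_proteins=1, n_res=30, ddg_shift=0.0,
                          patho_beta_disease=(2.0, 6.0),
                          patho_beta_polymorphism=(2.0, 6.0), seed=0)
        muts = [
            MutationRecord("S", p, "A" if a != "A" else "C", a, cat, "d")
            for p, a, cat in [(1, "V", "disease"), (2, "W", "disease"),
                              (3, "V", "polymorphism"),
                              (4, "W", "polymorphism")]
        ]
        tables = make_predictors(model, set(), set(), muts, spec, seed=0)
        ddg = list(tables.foldx_ddg.values())
        # same generating distribution: a two-sample test finds no shift
        from mutexplain.cohort import mann_whitney

        _, p = mann_whitney(ddg[:2], ddg[2:])
        assert p > 0.05

    def test_ddg_shift_reflected_in_class_means(self):
        model = make_structure(60, fold="coil", seed=1)
        spec = CohortSpec(ddg_shift=1.5, seed=0)
        muts = []
        mutants = "CDEFGHIKLMNPQRSTVWY"
        seq = {r.number: r.aa for r in model.residues}
        for i in range(500):
            pos = 1 + (i % 60)
            cat = "disease" if i < 250 else "polymorphism"
            mut = mutants[i % 19]
            if mut == seq[pos]:
                mut = "C" if seq[pos] != "C" else "D"
            muts.append(MutationRecord("S", pos, seq[pos], mut, cat,
                                       "d" if cat == "disease" else ""))
        muts = list({m.key: m for m in muts}.values())
        tables = make_predictors(model, set(), set(), muts, spec, seed=0)
        dis = [tables.foldx_ddg[m.key[1:]] for m in muts
               if m.category == "disease"]
        pol = [tables.foldx_ddg[m.key[1:]] for m in muts
               if m.category == "polymorphism"]
        assert abs((np.mean(dis) - np.mean(pol)) - 1.5) <= 0.25


class TestMakeCohort:
    def test_byte_identical_bundles_under_seed(self, tmp_path):
        spec = CohortSpec(n_proteins=2, n_res=30, n_disease=10,
                          n_polymorphism=10, seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        f1 = write_bundle(make_cohort(spec), d1)
        f2 = write_bundle(make_cohort(spec), d2)
        assert [f.name for f in f1] == [f.name for f in f2]
        for a, b in zip(f1, f2):
            assert a.read_bytes() == b.read_bytes()

    def test_prefix_stability_when_adding_proteins(self):
        small = make_cohort(CohortSpec(n_proteins=2, n_res=30, n_disease=4,
                                       n_polymorphism=4, seed=3))
        large = make_cohort(CohortSpec(n_proteins=3, n_res=30, n_disease=6,
                                       n_polymorphism=6, seed=3))
        a = ca_coords(small.proteins[0].model1)
        b = ca_coords(large.proteins[0].model1)
        assert np.array_equal(a, b)

    def test_every_mutation_has_ground_truth(self, small_bundle):
        keys = {"|".join(map(str, m.key)) for m in small_bundle.mutations}
        assert keys == set(small_bundle.ground_truth)
        for info in small_bundle.ground_truth.values():
            assert info["should_be_explained_merged"] == (
                info["should_be_explained_model1"]
                or info["should_be_explained_model2"]
            )

    def test_full_site_placement_explains_all_gated_disease(self):
        spec = CohortSpec(n_proteins=2, n_res=40, n_disease=20,
                          n_polymorphism=0, fraction_near_site=1.0, seed=9)
        bundle = make_cohort(spec)
        from mutexplain.config import RunConfig
        from mutexplain.pipeline import analyze_bundle

        result = analyze_bundle(bundle, RunConfig())
        disease = result.verdicts(0, "disease")
        assert disease and all(v.explained for v in disease)
        assert all(v.site_tags for v in disease)

    def test_infeasible_placement_raises(self):
        spec = CohortSpec(n_proteins=1, n_res=30, n_disease=5,
                          n_polymorphism=0, fraction_near_site=1.0,
                          ligand_site_size=0, interface_site_size=0, seed=0)
        with pytest.raises(InfeasiblePlacementError):
            make_cohort(spec)

    def test_model2_extra_sites_recorded(self, small_bundle):
        for prot in small_bundle.proteins:
            extra = set(prot.planted["extra_ligand_model2"])
            for p in extra:
                assert prot.tables2.ligand_prob[p] >= 0.5
                assert prot.tables1.ligand_prob[p] < 0.5
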