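"""Shared fixtures: small deterministic structures and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from mutexplain.structio import Atom, ProteinModel, ResidueRecord
from mutexplain.synthetic import CohortSpec, make_cohort, make_structure


def single_atom_residue(number: int, xyz, aa: str = "A",
                        confidence: float = 90.0) -> ResidueRecord:
    return ResidueRecord(number=number, aa=aa,
                         atoms=[Atom("CA", tuple(map(float, xyz)), "C")],
                         confidence=confidence)


def model_from_points(points, confidences=None,
                      source: str = "alphafold-like") -> ProteinModel:
    """CA-only model, one residue per point, numbered from 1."""
    confidences = confidences or [90.0] * len(points)
    residues = [single_atom_residue(i + 1, p, confidence=c)
                for i, (p, c) in enumerate(zip(points, confidences))]
    return ProteinModel(model_id="toy", source=source, residues=residues)


def random_model(rng: np.random.Generator, n_res: int | None = None
                 ) -> ProteinModel:
    n = n_res or int(rng.integers(30, 201))
    fold = ("helix", "sheet-pair", "coil")[int(rng.integers(3))]
    return make_structure(n, fold=fold, seed=int(rng.integers(2 ** 31)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_bundle():
    """Quick three-protein cohort used across module tests."""
    spec = CohortSpec(n_proteins=3, n_res=40, n_disease=24, n_polymorphism=24,
                      seed=7)
    return make_cohort(spec)


@pytest.fixture(scope="session")
def default_bundle():
    """The full default study cohort (20 proteins, 200 + 200 mutations)."""
    return make_cohort(CohortSpec(seed=1))
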