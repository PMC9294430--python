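"""Shrake-Rupley solvent accessibility and burial classification.

Absolute per-atom SASA is computed with the rolling-probe point-mesh
algorithm: each heavy atom is covered by a deterministic Fibonacci sphere of
test points at radius ``r_atom + probe``; a point is exposed when it lies
outside every other atom's probe-expanded sphere, and the atom's area is the
exposed fraction of ``4 * pi * (r_atom + probe)^2``.

Relative solvent accessibility (RSA, percent) divides a residue's summed
atom areas by a reference maximum area per residue type; residues with
RSA < 20 are classified as buried.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .constants import FALLBACK_ELEMENT, MAX_ASA_THEORETICAL, VDW_RADII
from .structio import ProteinModel

BURIAL_RSA_CUT = 20.0


@dataclass
class AccessibilityProfile:
    """Per-residue absolute SASA (A^2) and RSA (%) keyed by residue number.

    RSA is NaN for residues whose type has no reference area; such residues
    are excluded from burial statistics.
    """

    sasa: dict[int, float]
    rsa: dict[int, float]
    probe: float
    n_points: int

    def buried(self, rsa_cut: float = BURIAL_RSA_CUT) -> dict[int, bool]:
        return {
            n: is_buried(v, rsa_cut) for n, v in self.rsa.items()
            if np.isfinite(v)
        }


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _atom_radii(elements: list[str]) -> np.ndarray:
    radii = np.empty(len(elements))
    for i, el in enumerate(elements):
        r = VDW_RADII.get(el.upper())
        if r is None:
            warnings.warn(
                f"unknown element {el!r}: using carbon radius", stacklevel=2
            )
            r = VDW_RADII[FALLBACK_ELEMENT]
        radii[i] = r
    return radii


def sasa_atoms(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
               n_points: int = 960) -> np.ndarray:
    """Per-atom Shrake-Rupley SASA for arbitrary spheres."""
    if n_points < 96:
        raise ValueError("n_points must be >= 96")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    sphere = fibonacci_sphere(n_points)
    expanded = radii + probe
    out = np.empty(n)
    tree = cKDTree(coords)
    max_reach = expanded.max()
    for i in range(n):
        pts = coords[i] + expanded[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], expanded[i] + max_reach):
            if j == i:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 >= expanded[j] ** 2
        out[i] = exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return out


def sasa(model: ProteinModel, probe: float = 1.4,
         n_points: int = 960) -> dict[int, float]:
    """Per-residue absolute SASA (sum of constituent heavy-atom areas)."""
    coords, elements, owner = [], [], []
    for res in model.residues:
        for atom in res.atoms:
            coords.append(atom.coord)
            elements.append(atom.element)
            owner.append(res.number)
    areas = sasa_atoms(np.asarray(coords), _atom_radii(elements),
                       probe=probe, n_points=n_points)
    per_res = {res.number: 0.0 for res in model.residues}
    for n, a in zip(owner, areas):
        per_res[n] += float(a)
    return per_res


def relative_accessibility(residue_sasa: dict[int, float],
                           sequence: dict[int, str],
                           max_asa: dict[str, float] | None = None
                           ) -> dict[int, float]:
    """RSA in percent: ``100 * SASA / maxASA(aa)``.

    Nonstandard residues (no reference area) get NaN and a warning; callers
    exclude them from burial statistics.
    """
    table = max_asa or MAX_ASA_THEORETICAL
    out: dict[int, float] = {}
    for number, area in residue_sasa.items():
        aa = sequence[number]
        ref = table.get(aa)
        if ref is None:
            warnings.warn(
                f"no reference area for residue type {aa!r} at {number}",
                stacklevel=2,
            )
            out[number] = float("nan")
        else:
            out[number] = 100.0 * area / ref
    return out


def is_buried(rsa: float, rsa_cut: float = BURIAL_RSA_CUT) -> bool:
    """Buried iff RSA strictly below the cutoff (default 20%)."""
    if not np.isfinite(rsa):
        raise ValueError("RSA undefined")
    return rsa < rsa_cut


def accessibility_profile(model: ProteinModel, probe: float = 1.4,
                          n_points: int = 960,
                          max_asa: dict[str, float] | None = None
                          ) -> AccessibilityProfile:
    per_res = sasa(model, probe=probe, n_points=n_points)
    seq = {r.number: r.aa for r in model.residues}
    rsa = relative_accessibility(per_res, seq, max_asa=max_asa)
    return AccessibilityProfile(sasa=per_res, rsa=rsa, probe=probe,
                                n_points=n_points)
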