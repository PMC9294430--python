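"""Spatial primitives: heavy-atom neighbor search and rigid superposition.

Residue adjacency is defined at heavy-atom resolution: two residues are
neighbors when any pair of their heavy atoms lies within the cutoff radius
(5 A by default).  The search uses a cell list — atoms are hashed into a
grid of cubic cells with edge equal to the cutoff, so only the 27 cells
around an atom need to be scanned.

Model-versus-model comparison uses Kabsch least-squares superposition on
paired coordinates (CA atoms of shared residue numbers); the reflection case
is corrected so the rotation is always proper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structio import ProteinModel, ResidueRecord


@dataclass
class NeighborMap:
    """Symmetric, irreflexive residue adjacency at a fixed radius."""

    radius: float
    pairs: dict[int, set[int]] = field(default_factory=dict)
    inclusive: bool = True

    def neighbors(self, position: int) -> set[int]:
        return self.pairs.get(position, set())

    def __contains__(self, position: int) -> bool:
        return position in self.pairs


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def min_heavy_atom_distance(a: ResidueRecord, b: ResidueRecord) -> float:
    """Minimum Euclidean distance over all heavy-atom pairs of two residues."""
    return float(cdist(a.coords(), b.coords()).min())


def _atom_table(model: ProteinModel) -> tuple[np.ndarray, np.ndarray]:
    coords = []
    res_idx = []
    for i, res in enumerate(model.residues):
        for atom in res.atoms:
            coords.append(atom.coord)
            res_idx.append(i)
    return np.asarray(coords, dtype=float), np.asarray(res_idx, dtype=int)


def residue_neighbors(model: ProteinModel, radius: float = 5.0,
                      inclusive: bool = True) -> NeighborMap:
    """Cell-list neighbor search over all heavy atoms.

    Residues ``i != j`` are neighbors iff their minimum heavy-atom distance
    is ``<= radius`` (``< radius`` when ``inclusive`` is False).  Cell edge
    equals the radius, so candidate pairs come only from the 27 cells
    surrounding each occupied cell.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    numbers = model.numbers
    nmap = NeighborMap(radius=radius, inclusive=inclusive,
                       pairs={n: set() for n in numbers})
    if not model.residues:
        return nmap
    coords, res_idx = _atom_table(model)
    cells = np.floor(coords / radius).astype(np.int64)
    buckets: dict[tuple[int, int, int], list[int]] = {}
    for atom_i, cell in enumerate(map(tuple, cells)):
        buckets.setdefault(cell, []).append(atom_i)

    offsets = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)]
    within = (lambda d: d <= radius) if inclusive else (lambda d: d < radius)

    for cell, atoms_a in buckets.items():
        ca = coords[atoms_a]
        ra = res_idx[atoms_a]
        for off in offsets:
            other = (cell[0] + off[0], cell[1] + off[1], cell[2] + off[2])
            if other < cell:  # visit each unordered cell pair once
                continue
            atoms_b = buckets.get(other)
            if atoms_b is None:
                continue
            cb = coords[atoms_b]
            rb = res_idx[atoms_b]
            dist = cdist(ca, cb)
            ii, jj = np.nonzero(within(dist))
            for i, j in zip(ii, jj):
                a, b = ra[i], rb[j]
                if a == b:
                    continue
                na, nb = numbers[a], numbers[b]
                nmap.pairs[na].add(nb)
                nmap.pairs[nb].add(na)
    return nmap


def near_site(position: int, site: set[int], neighbors: NeighborMap) -> bool:
    """True iff ``position`` is on a site residue or adjacent to one."""
    if position not in neighbors:
        raise KeyError(f"position {position} not in model")
    if position in site:
        return True
    return bool(neighbors.neighbors(position) & site)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of paired coordinate sets.

    Returns the proper rotation ``R`` and translation ``t`` minimizing
    ``|| (a @ R.T + t) - b ||`` together with the residual RMSD.  A
    reflection in the SVD solution is corrected by flipping the smallest
    singular direction; rank-deficient (e.g. collinear) inputs are allowed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("need >= 3 paired 3D points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cb - rotation @ ca
    diff = a0 @ rotation.T - b0
    rmsd = float(np.sqrt((diff ** 2).sum() / a.shape[0]))
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd)


def model_ca_rmsd(model_a: ProteinModel, model_b: ProteinModel) -> float:
    """CA RMSD between two models of the same domain, paired by residue
    number."""
    shared = sorted(set(model_a.numbers) & set(model_b.numbers))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared residues")

    def ca_coords(model: ProteinModel) -> np.ndarray:
        out = []
        for n in shared:
            res = model.residue(n)
            ca = next((at for at in res.atoms if at.name == "CA"), res.atoms[0])
            out.append(ca.coord)
        return np.asarray(out, dtype=float)

    return kabsch_rmsd(ca_coords(model_a), ca_coords(model_b)).rmsd
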