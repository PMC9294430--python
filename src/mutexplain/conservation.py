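"""MSA conservation scoring, diversity metrics and the two-tier
conserved-site rule.

The per-column conservation score is a scorecons-style weighted sum of pairs
(Valdar): for column ``c`` with residues ``a_i``,

    score(c) = sum_{i<j} w_i w_j m(a_i, a_j) / sum_{i<j} w_i w_j

where ``m`` is BLOSUM62 normalized to unit diagonal (Karlin normalization
``B(a,b) / sqrt(B(a,a) B(b,b))``, clipped at 0) so a perfectly conserved
column scores exactly 1, and pairs involving a gap contribute 0 similarity
while remaining in the denominator (a linear gap penalty).  Sequence weights
follow Valdar's distance weighting: ``w_i`` proportional to the mean
sequence distance of ``i`` to all other sequences (uniform when all
sequences are identical or weighting is disabled).

Diversity metrics summarize an alignment the way model-building pipelines
report them: Neff (number of sequence clusters at 80% pairwise identity),
DOPs (percentage of distinct column conservation scores), percent scorecons
(percentage of columns above a conservation threshold) and the number of
distinct taxa.

Conserved sites on the structure combine two tiers: columns scoring >= 0.8,
plus columns scoring > 0.65 that are spatial neighbors of a tier-1 site.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .constants import AMINO_ACIDS
from .geometry import NeighborMap
from .structio import Msa

GAP = "-"
CONS_HIGH = 0.8
CONS_MID = 0.65


@dataclass
class ConservationProfile:
    """Per-column scores in [0, 1] plus the column -> query-residue map."""

    scores: np.ndarray
    column_to_residue: dict[int, int]

    def residue_scores(self) -> dict[int, float]:
        return {res: float(self.scores[col])
                for col, res in self.column_to_residue.items()}


@dataclass
class DiversityMetrics:
    neff: float
    dops: float
    percent_scorecons: float
    n_taxa: int


@lru_cache(maxsize=1)
def _similarity_matrix() -> dict[tuple[str, str], float]:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    sim: dict[tuple[str, str], float] = {}
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            val = blosum[a, b] / np.sqrt(blosum[a, a] * blosum[b, b])
            sim[(a, b)] = max(0.0, float(val))
    return sim


def _encode(msa: Msa) -> np.ndarray:
    """Integer-encode: 0..19 amino acids, 20 for gap/unknown."""
    lut = np.full(128, 20, dtype=np.int8)
    for i, aa in enumerate(AMINO_ACIDS):
        lut[ord(aa)] = i
    arr = np.frombuffer(
        "".join(msa.sequences).encode("ascii"), dtype=np.uint8
    ).reshape(msa.depth, msa.length)
    return lut[arr]


@lru_cache(maxsize=1)
def _similarity_array() -> np.ndarray:
    """21x21 similarity with index 20 = gap/unknown (similarity 0)."""
    m = np.zeros((21, 21))
    sim = _similarity_matrix()
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = sim[(a, b)]
    return m


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Matches over the shorter ungapped length (0 when either is all-gap)."""
    matches = sum(
        1 for x, y in zip(seq_a, seq_b) if x != GAP and y != GAP and x == y
    )
    len_a = sum(1 for x in seq_a if x != GAP)
    len_b = sum(1 for x in seq_b if x != GAP)
    shorter = min(len_a, len_b)
    return matches / shorter if shorter else 0.0


def sequence_weights(msa: Msa) -> np.ndarray:
    """Valdar distance weights, normalized to sum 1.

    ``w_i`` is the mean (1 - identity) of sequence ``i`` to all others;
    uniform for depth 1 or when all sequences are identical.
    """
    n = msa.depth
    if n == 1:
        return np.ones(1)
    dist = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                dist[i] += 1.0 - pairwise_identity(
                    msa.sequences[i], msa.sequences[j]
                )
    dist /= n - 1
    if dist.sum() == 0.0:
        return np.full(n, 1.0 / n)
    return dist / dist.sum()


def _column_map(msa: Msa, query_start: int = 1) -> dict[int, int]:
    mapping: dict[int, int] = {}
    resnum = query_start - 1
    for col, ch in enumerate(msa.query):
        if ch != GAP:
            resnum += 1
            mapping[col] = resnum
    return mapping


def scorecons_profile(msa: Msa, weights: np.ndarray | None = None,
                      query_start: int = 1) -> ConservationProfile:
    """Column conservation profile.

    ``weights=None`` uses Valdar distance weights; pass explicit (e.g.
    uniform) weights to disable sequence weighting.  A depth-1 alignment
    scores 1 on residue columns; all-gap columns score 0.
    """
    enc = _encode(msa)
    n, length = enc.shape
    if weights is None:
        w = sequence_weights(msa)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights length must equal alignment depth")
        w = w / w.sum()
    scores = np.empty(length)
    if n == 1:
        scores[:] = np.where(enc[0] != 20, 1.0, 0.0)
        return ConservationProfile(scores=scores,
                                   column_to_residue=_column_map(msa, query_start))
    sim = _similarity_array()
    outer = np.outer(w, w)
    iu = np.triu_indices(n, k=1)
    pair_w = outer[iu]
    denom = pair_w.sum()
    for col in range(length):
        c = enc[:, col]
        if (c == 20).all():
            scores[col] = 0.0
            continue
        pair_sim = sim[c[:, None], c[None, :]][iu]
        scores[col] = float((pair_w * pair_sim).sum() / denom)
    return ConservationProfile(scores=scores,
                               column_to_residue=_column_map(msa, query_start))


def neff_80(msa: Msa, identity_cut: float = 0.80) -> float:
    """Effective sequence count: clusters at >= 80% pairwise identity
    (single linkage, i.e. connected components of the identity graph)."""
    n = msa.depth
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_identity(msa.sequences[i], msa.sequences[j]) >= identity_cut:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    return float(len({find(i) for i in range(n)}))


def dops(profile: ConservationProfile, precision: int = 2) -> float:
    """Diversity of positions: percentage of distinct (rounded) column
    scores."""
    if profile.scores.size == 0:
        raise ValueError("empty profile")
    distinct = len({round(float(s), precision) for s in profile.scores})
    return 100.0 * distinct / profile.scores.size


def percent_scorecons(profile: ConservationProfile,
                      threshold: float = 0.9) -> float:
    """Percentage of columns with conservation score >= threshold."""
    if profile.scores.size == 0:
        raise ValueError("empty profile")
    return 100.0 * float((profile.scores >= threshold).mean())


def n_taxa(msa: Msa) -> int:
    """Distinct taxon identifiers; sequences without one are ignored."""
    return len({t for t in msa.taxa if t is not None})


def diversity_metrics(msa: Msa, profile: ConservationProfile | None = None,
                      scorecons_threshold: float = 0.9) -> DiversityMetrics:
    if profile is None:
        profile = scorecons_profile(msa)
    return DiversityMetrics(
        neff=neff_80(msa),
        dops=dops(profile),
        percent_scorecons=percent_scorecons(profile, scorecons_threshold),
        n_taxa=n_taxa(msa),
    )


def conserved_sites(profile: ConservationProfile, neighbors: NeighborMap,
                    cons_high: float = CONS_HIGH,
                    cons_mid: float = CONS_MID) -> set[int]:
    """Two-tier conserved-site rule on structure numbering.

    Tier 1: residues whose column scores >= ``cons_high``.  Tier 2: residues
    scoring > ``cons_mid`` with a tier-1 spatial neighbor (the strictness of
    the tier-2 distance is carried by the NeighborMap passed in).  Columns
    not mapped to the query (query-gap columns) are skipped.
    """
    res_scores = profile.residue_scores()
    tier1 = {p for p, s in res_scores.items() if s >= cons_high}
    tier2 = {
        p for p, s in res_scores.items()
        if s > cons_mid and p in neighbors and neighbors.neighbors(p) & tier1
    }
    return tier1 | tier2
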