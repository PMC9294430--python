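"""Disease-versus-polymorphism contrasts.

Summarizes the two variant classes the way structural surveys tabulate
them — percentage of mutations in or near a predicted functional site,
destabilizing (FoldX ddG > 1), buried (RSA < 20) and pathogenic (score >
0.611) — and tests the underlying score distributions (pathogenicity, RSA,
ddG) with two-sided Mann-Whitney U.  The U test is exact (full enumeration
of rank assignments) for small tie-free samples and a tie- and
continuity-corrected normal approximation otherwise.

Mutant-residue composition is contrasted against a background amino-acid
frequency vector (Swiss-Prot by default) with a seeded bootstrap null.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .constants import AMINO_ACIDS, SWISSPROT_FREQUENCIES
from .explain import MutationVerdict

EXACT_MAX_N = 14


@dataclass
class ClassPercentages:
    n: int
    near_functional_site: float
    destabilizing: float
    buried: float
    pathogenic: float


@dataclass
class CohortSummary:
    disease: ClassPercentages
    polymorphism: ClassPercentages
    tests: dict[str, tuple[float, float]] = field(default_factory=dict)
    composition: pd.DataFrame | None = None


def _percentages(verdicts: list[MutationVerdict]) -> ClassPercentages:
    n = len(verdicts)
    if n == 0:
        raise ValueError("empty verdict class: percentages undefined")
    near = sum(1 for v in verdicts if v.site_tags)
    destab = sum(1 for v in verdicts if v.destabilizing_foldx)
    buried_known = [v for v in verdicts if v.annotation.buried is not None]
    buried = sum(1 for v in buried_known if v.annotation.buried)
    patho = sum(1 for v in verdicts if v.pathogenic)
    return ClassPercentages(
        n=n,
        near_functional_site=100.0 * near / n,
        destabilizing=100.0 * destab / n,
        buried=100.0 * buried / len(buried_known) if buried_known else float("nan"),
        pathogenic=100.0 * patho / n,
    )


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U (for the first sample) and two-sided p.

    Exact p by enumeration of all C(n, n1) rank assignments when
    ``n1 + n2 <= 14`` and the pooled sample has no ties; otherwise a normal
    approximation with tie correction and continuity correction.  Two-sided
    p is ``2 * min(P(U <= u), P(U >= u))`` capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    u = float(
        (x[:, None] > y[None, :]).sum() + 0.5 * (x[:, None] == y[None, :]).sum()
    )
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2
    if n1 + n2 <= EXACT_MAX_N and not has_ties:
        order = np.sort(pooled)
        us = []
        for idx in combinations(range(n1 + n2), n1):
            xs = order[list(idx)]
            ys = np.delete(order, list(idx))
            us.append((xs[:, None] > ys[None, :]).sum())
        us = np.asarray(us, dtype=float)
        p_le = (us <= u).mean()
        p_ge = (us >= u).mean()
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u, p
    from scipy.stats import norm

    n = n1 + n2
    mean = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return u, 1.0
    z = (u - mean - 0.5 * np.sign(u - mean)) / math.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return u, float(p)


def verdict_metric(verdicts: list[MutationVerdict], metric: str,
                   tables_lookup, mode: str = "mutation") -> np.ndarray:
    """Extract one score distribution from a verdict list.

    ``metric`` is ``"pathogenicity"``, ``"rsa"`` or ``"ddg"``;
    ``tables_lookup(accession)`` returns that protein's PredictorTables.
    ``mode="position"`` averages per residue position instead of one
    observation per mutation.
    """
    rows: list[tuple[tuple[str, int], float]] = []
    for v in verdicts:
        acc, pos, mut = v.record.key
        if metric == "rsa":
            val = v.annotation.rsa
            if not math.isfinite(val):
                continue
        else:
            table = tables_lookup(acc)
            source = (table.pathogenicity if metric == "pathogenicity"
                      else table.foldx_ddg)
            raw = source.get((pos, mut))
            if raw is None:
                continue
            val = float(raw)
        rows.append(((acc, pos), val))
    if mode == "mutation":
        return np.asarray([val for _, val in rows])
    if mode == "position":
        acc_pos: dict[tuple[str, int], list[float]] = {}
        for key, val in rows:
            acc_pos.setdefault(key, []).append(val)
        return np.asarray([float(np.mean(vs)) for vs in acc_pos.values()])
    raise ValueError(f"unknown mode {mode!r}")


def summarize(disease: list[MutationVerdict], polymorphism: list[MutationVerdict],
              tables_lookup=None, mode: str = "mutation") -> CohortSummary:
    """Table-style class percentages plus Mann-Whitney tests.

    ``tables_lookup`` (accession -> PredictorTables) enables the
    pathogenicity and ddG distribution tests; without it only RSA is
    tested.
    """
    summary = CohortSummary(
        disease=_percentages(disease),
        polymorphism=_percentages(polymorphism),
    )
    metrics = ["rsa"] if tables_lookup is None else ["pathogenicity", "rsa", "ddg"]
    for metric in metrics:
        xd = verdict_metric(disease, metric, tables_lookup, mode=mode)
        xp = verdict_metric(polymorphism, metric, tables_lookup, mode=mode)
        if len(xd) and len(xp):
            summary.tests[metric] = mann_whitney(xd, xp)
    return summary


def composition_enrichment(sample_counts: dict[str, int] | Counter,
                           background: dict[str, float] | None = None,
                           n_boot: int = 10_000,
                           seed: int = 0) -> pd.DataFrame:
    """Relative abundance of mutant residues against a background.

    Per amino acid: ``ratio = (f_sample - f_bg) / f_bg`` and a two-sided
    bootstrap p — the fraction of size-matched multinomial draws from the
    background whose frequency deviates from the background at least as much
    as observed (with the +1 small-sample correction).  Amino acids with
    zero background frequency get NaN ratio and p.
    """
    background = background or SWISSPROT_FREQUENCIES
    aas = list(AMINO_ACIDS)
    bg = np.asarray([background.get(a, 0.0) for a in aas])
    if not math.isclose(bg.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("background frequencies must sum to 1")
    counts = np.asarray([int(sample_counts.get(a, 0)) for a in aas], dtype=float)
    n = counts.sum()
    if n < 1:
        raise ValueError("sample must contain at least one residue")
    f_sample = counts / n
    rng = np.random.default_rng(seed)
    boot = rng.multinomial(int(n), bg, size=n_boot) / n
    dev_obs = np.abs(f_sample - bg)
    dev_boot = np.abs(boot - bg[None, :])
    p = (1.0 + (dev_boot >= dev_obs[None, :]).sum(axis=0)) / (n_boot + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bg > 0, (f_sample - bg) / bg, np.nan)
    p = np.where(bg > 0, p, np.nan)
    return pd.DataFrame(
        {"aa": aas, "count": counts.astype(int), "f_sample": f_sample,
         "f_background": bg, "ratio": ratio, "p": p}
    ).set_index("aa")


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional correction for the 20 per-AA tests)."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    m = float(len(p))
    adj = np.empty_like(p)
    running = 1.0
    for rank in range(len(p) - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj
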