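"""Model-confidence gating and disorder summaries.

Predicted lDDT (pLDDT) is harmonized to the 0-100 scale; a domain is a
"good model" when its mean residue confidence reaches the gate (70 by
default, inclusive) and a residue passes when its own confidence does.
Disorder is summarized per domain: a residue is disordered when its
predicted probability exceeds 0.5 (strictly), and a domain is
high-disorder when more than 40% of its residues are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .structio import DomainSegment, ProteinModel

CONF_GATE = 70.0
DISORDER_PROB_CUT = 0.5
HIGH_DISORDER_PERCENT = 40.0


@dataclass
class QualityReport:
    mean_confidence: float
    good_model: bool
    residue_pass: dict[int, bool]
    disorder_percent: float | None = None
    high_disorder: bool | None = None


def normalize_confidence(model: ProteinModel) -> ProteinModel:
    """Bring confidences onto the 0-100 scale in place; idempotent.

    A rosettafold-like model whose confidences all lie in [0, 1] is
    rescaled by 100; anything already on 0-100 is left untouched.
    """
    conf = model.confidences()
    if model.source == "rosettafold-like" and conf.size and conf.max() <= 1.0:
        for r in model.residues:
            r.confidence *= 100.0
    model.confidence_scale = "0-100"
    return model


def domain_quality(model: ProteinModel, segment: DomainSegment,
                   conf_gate: float = CONF_GATE) -> QualityReport:
    """Mean-confidence gate over a domain segment.

    ``good_model`` iff the mean residue confidence >= ``conf_gate``; each
    residue passes iff its own confidence does (both inclusive).
    """
    normalize_confidence(model)
    in_segment = [r for r in model.residues if r.number in segment]
    if not in_segment:
        raise ValueError(f"segment {segment.ranges} has no residues in model")
    conf = np.asarray([r.confidence for r in in_segment])
    mean = float(conf.mean())
    good = mean >= conf_gate
    return QualityReport(
        mean_confidence=mean,
        good_model=good,
        residue_pass={r.number: r.confidence >= conf_gate for r in in_segment},
    )


def disorder_summary(disorder_prob: dict[int, float], segment: DomainSegment,
                     disorder_cut: float = DISORDER_PROB_CUT,
                     high_cut: float = HIGH_DISORDER_PERCENT
                     ) -> tuple[float, bool]:
    """Percent of segment residues with disorder probability strictly above
    the cutoff, and whether that percentage strictly exceeds ``high_cut``."""
    positions = segment.positions()
    missing = [p for p in positions if p not in disorder_prob]
    if missing:
        raise ValueError(f"missing disorder probabilities for {missing}")
    n_dis = sum(1 for p in positions if disorder_prob[p] > disorder_cut)
    percent = 100.0 * n_dis / len(positions)
    return percent, percent > high_cut


def correlate(x, y, method: str = "pearson") -> float:
    """Pearson or Spearman correlation; zero-variance input is undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")
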