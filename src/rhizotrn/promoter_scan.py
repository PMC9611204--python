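"""Scanning upstream regions with TF matrices and selecting best hits.

Every window of a promoter is scored on both strands; windows whose exact
score p-value clears the requested cutoff become site hits.  Hits carry the
stringency tier of the inferred TF gene-target relation (the p-value bands
used to fractionate motif data: low 1e-4..9.9e-4, medium 1e-5..9.9e-5, high
below 1e-5) and the ``auto`` rule keeps, per TF gene-target pair, the single
hit with the lowest p-value over all of the TF's matrices and windows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .motif_model import (
    DEFAULT_GRANULARITY,
    PSSM,
    ScoreDistribution,
    encode,
    log_odds,
    parse_matrix_id,
    score_distribution,
    significance,
)

__all__ = [
    "SiteHit",
    "STRINGENCY_TIERS",
    "classify_tier",
    "scan_promoter",
    "auto_select",
]

# Half-open p-value bands.  The printed two-significant-figure band limits
# (e.g. "1.0e-4 to 9.9e-4") leave gaps such as 9.95e-5; the half-open decades
# below contain every printed range without gaps.
STRINGENCY_TIERS: dict[str, tuple[float, float]] = {
    "low": (1e-4, 1e-3),
    "medium": (1e-5, 1e-4),
    "high": (0.0, 1e-5),
}


def classify_tier(p: float) -> str:
    """Stringency tier of a site p-value: ``low``/``medium``/``high``/``none``."""
    if not 0 < p <= 1:
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    if p < 1e-5:
        return "high"
    if p < 1e-4:
        return "medium"
    if p < 1e-3:
        return "low"
    return "none"


@dataclass(frozen=True)
class SiteHit:
    """One motif occurrence in one upstream region.

    Coordinates are 1-based inclusive positions on the forward strand of the
    upstream region; ``strand`` is ``D`` (direct) or ``R`` (reverse), and
    ``site`` is the forward-strand slice of the promoter.
    """

    matrix_id: str
    tf_gene: str
    target_gene: str
    strand: str
    start: int
    end: int
    site: str
    weight: float
    p_value: float
    significance: float
    tier: str

    @property
    def matrix_index(self) -> int:
        return parse_matrix_id(self.matrix_id)[1]


def scan_promoter(
    pssm: PSSM,
    promoter: str,
    target_gene: str,
    max_p: float = 9.9e-4,
    granularity: float = DEFAULT_GRANULARITY,
    distribution: ScoreDistribution | None = None,
) -> list[SiteHit]:
    """All windows of ``promoter`` on both strands with p-value <= ``max_p``.

    Returns hits sorted by ascending p-value (ties: smaller start, strand D
    first).  ``distribution`` may be passed to reuse a precomputed null.
    """
    w = pssm.width
    L = len(promoter)
    if L < w:
        raise ValueError(
            f"promoter of {target_gene} ({L} bp) shorter than matrix width {w}"
        )
    if distribution is None:
        distribution = score_distribution(pssm, granularity)
    lod = log_odds(pssm)
    # scoring the reverse complement of a forward window is equivalent to
    # scoring the forward window with the reverse-complemented matrix
    lod_rc = lod[::-1, ::-1]
    idx = encode(promoter)
    windows = sliding_window_view(idx, w)  # (L-w+1, w)
    cols = np.arange(w)
    weights_d = lod[windows, cols].sum(axis=1)
    weights_r = lod_rc[windows, cols].sum(axis=1)
    tf_gene = pssm.source_gene
    hits: list[SiteHit] = []
    for strand, weights in (("D", weights_d), ("R", weights_r)):
        pvals = distribution.pvalues(weights)
        # every observed window score is achievable, so a zero tail (threshold
        # rounded past the lattice maximum) snaps to the smallest positive tail
        pvals[pvals == 0] = distribution.tail_prob[-1]
        for i in np.nonzero(pvals <= max_p)[0]:
            p = float(pvals[i])
            hits.append(
                SiteHit(
                    matrix_id=pssm.matrix_id,
                    tf_gene=tf_gene,
                    target_gene=target_gene,
                    strand=strand,
                    start=int(i) + 1,
                    end=int(i) + w,
                    site=promoter[i : i + w],
                    weight=float(weights[i]),
                    p_value=p,
                    significance=significance(p),
                    tier=classify_tier(p),
                )
            )
    hits.sort(key=_hit_order)
    return hits


def _hit_order(h: SiteHit) -> tuple:
    return (h.p_value, h.start, 0 if h.strand == "D" else 1, h.matrix_index)


def auto_select(hits: Iterable[SiteHit]) -> dict[tuple[str, str], SiteHit]:
    """Best hit per (tf, target): the minimum p-value over all matrices and
    windows, ties broken by smaller start, strand D first, lower matrix index.
    """
    best: dict[tuple[str, str], SiteHit] = {}
    for h in hits:
        key = (h.tf_gene, h.target_gene)
        if key not in best or _hit_order(h) < _hit_order(best[key]):
            best[key] = h
    return best
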