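"""Motif-matrix clustering and the clustered-TF filter.

Matrices of the profile genes are compared by the best column-wise Pearson
correlation of their probability matrices over all ungapped offsets and both
orientations (``cor``), together with a width-normalised variant
(``ncor = cor * aligned_width / max_width``).  Agglomerative average-linkage
clustering on ``1 - cor`` merges matrices while the merged group still
satisfies the ``cor``/``ncor`` floors; retained clusters must span at least
two different genes.  Only clusters containing at least one transcription
factor matrix ("Clustered-TF") pass the filter — genes whose motifs resemble
no co-expressed TF motif are purged as likely false positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .motif_model import PSSM

__all__ = [
    "MatrixCluster",
    "matrix_similarity",
    "cluster_matrices",
    "clustered_tf_filter",
    "DEFAULT_COR_MIN",
    "DEFAULT_NCOR_MIN",
]

#: default correlation floors (the clustering tool's published defaults)
DEFAULT_COR_MIN = 0.6
DEFAULT_NCOR_MIN = 0.4

_MIN_OVERLAP = 2  # columns; Pearson needs at least two aligned columns


@dataclass(frozen=True)
class MatrixCluster:
    cluster_id: str
    members: frozenset[str]
    member_genes: frozenset[str]
    clustered_tfs: frozenset[str]

    @property
    def contains_tf(self) -> bool:
        return bool(self.clustered_tfs)


def _offset_correlations(pa: np.ndarray, pb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """cor and aligned width for every ungapped offset of ``pb`` along ``pa``.

    Offset ``o`` aligns column ``j`` of ``pb`` with column ``o + j`` of
    ``pa``; offsets run from ``-(wb - 1)`` to ``wa - 1``.  All offsets are
    evaluated in one vectorised pass via per-row cross-correlations plus
    prefix sums of the column moments.
    """
    wa, wb = pa.shape[1], pb.shape[1]
    offsets = np.arange(-(wb - 1), wa)
    # sum over rows of the full cross-correlation gives sum(x*y) per offset
    sxy = np.zeros(wa + wb - 1)
    for r in range(4):
        sxy += np.correlate(pa[r], pb[r], mode="full")
    # np.correlate(a, v, 'full')[k] pairs a[i] with v[i - (k - (wb-1))]:
    # index k corresponds to offset o = k - (wb - 1) ... verified empirically
    # against brute-force alignment in the test-suite oracle.
    a_lo = np.maximum(0, offsets)
    a_hi = np.minimum(wa, offsets + wb)
    b_lo = np.maximum(0, -offsets)
    width = a_hi - a_lo
    csum_a = np.concatenate([[0.0], np.cumsum(pa.sum(axis=0))])
    csum_a2 = np.concatenate([[0.0], np.cumsum((pa**2).sum(axis=0))])
    csum_b = np.concatenate([[0.0], np.cumsum(pb.sum(axis=0))])
    csum_b2 = np.concatenate([[0.0], np.cumsum((pb**2).sum(axis=0))])
    sx = csum_a[a_hi] - csum_a[a_lo]
    sxx = csum_a2[a_hi] - csum_a2[a_lo]
    sy = csum_b[b_lo + width] - csum_b[b_lo]
    syy = csum_b2[b_lo + width] - csum_b2[b_lo]
    n = 4.0 * width
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        var_x = sxx - sx**2 / n
        var_y = syy - sy**2 / n
        cor = cov / np.sqrt(var_x * var_y)
    cor[(width < _MIN_OVERLAP) | ~np.isfinite(cor)] = -np.inf
    return cor, width


def matrix_similarity(a: PSSM, b: PSSM) -> tuple[float, float, int, str]:
    """Best ungapped alignment of two matrices over offsets and orientations.

    Returns ``(cor, ncor, offset, orientation)`` where ``cor`` is the maximal
    column-wise Pearson correlation of the probability matrices, ``ncor``
    rescales it by aligned width over the wider matrix, ``offset`` is the
    position of ``b``'s first column relative to ``a``'s and ``orientation``
    is ``D`` or ``R`` (``b`` reverse-complemented).
    """
    if a.width < 2 or b.width < 2:
        raise ValueError("matrix similarity is undefined for width < 2")
    pa = a.probabilities()
    pb = b.probabilities()
    wmax = max(a.width, b.width)
    best = (-np.inf, -np.inf, 0, "D")
    for orient, mat in (("D", pb), ("R", pb[::-1, ::-1])):
        cor, width = _offset_correlations(pa, mat)
        offsets = np.arange(-(b.width - 1), a.width)
        ncor = cor * width / wmax
        i = int(np.argmax(cor))
        cand = (float(cor[i]), float(ncor[i]), int(offsets[i]), orient)
        if cand[0] > best[0]:
            best = cand
    return best


def _pairwise_similarity(pssms: Sequence[PSSM]) -> tuple[np.ndarray, np.ndarray]:
    k = len(pssms)
    cor = np.ones((k, k))
    ncor = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            c, nc, _, _ = matrix_similarity(pssms[i], pssms[j])
            cor[i, j] = cor[j, i] = c
            ncor[i, j] = ncor[j, i] = nc
    return cor, ncor


def cluster_matrices(
    pssms: Sequence[PSSM],
    cor_min: float = DEFAULT_COR_MIN,
    ncor_min: float = DEFAULT_NCOR_MIN,
) -> list[MatrixCluster]:
    """Agglomerative average-linkage clustering of motif matrices.

    Groups are merged in order of decreasing average correlation while the
    merged group's average ``cor`` and ``ncor`` stay above the floors
    (merging past a floor would dilute the cluster, so the tree is cut
    there).  Singleton clusters and clusters drawing all members from one
    gene are discarded: a cluster is only evidence of a shared motif when at
    least two different genes contribute.
    """
    if len(pssms) == 0:
        raise ValueError("at least one matrix is required")
    ids = [p.matrix_id for p in pssms]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate matrix identifiers")
    cor, ncor = _pairwise_similarity(pssms)
    k = len(pssms)
    # average-linkage agglomeration with Lance-Williams averaging on both
    # similarity matrices; `alive` tracks current clusters
    members: dict[int, list[int]] = {i: [i] for i in range(k)}
    avg_cor = cor.copy()
    avg_ncor = ncor.copy()
    np.fill_diagonal(avg_cor, -np.inf)
    alive = np.ones(k, dtype=bool)
    while True:
        qual = (avg_cor >= cor_min) & (avg_ncor >= ncor_min)
        qual &= alive[:, None] & alive[None, :]
        if not qual.any():
            break
        masked = np.where(qual, avg_cor, -np.inf)
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        if i > j:
            i, j = j, i
        ni, nj = len(members[i]), len(members[j])
        # weighted average linkage update toward every other live cluster
        new_cor = (ni * avg_cor[i] + nj * avg_cor[j]) / (ni + nj)
        new_ncor = (ni * avg_ncor[i] + nj * avg_ncor[j]) / (ni + nj)
        avg_cor[i], avg_cor[:, i] = new_cor, new_cor
        avg_ncor[i], avg_ncor[:, i] = new_ncor, new_ncor
        avg_cor[i, i] = -np.inf
        members[i].extend(members[j])
        del members[j]
        alive[j] = False
    clusters: list[MatrixCluster] = []
    n_out = 0
    for key in sorted(members, key=lambda key: min(members[key])):
        idx = members[key]
        genes = {pssms[m].source_gene for m in idx}
        if len(idx) < 2 or len(genes) < 2:
            continue
        n_out += 1
        clusters.append(
            MatrixCluster(
                cluster_id=f"cluster_{n_out}",
                members=frozenset(pssms[m].matrix_id for m in idx),
                member_genes=frozenset(genes),
                clustered_tfs=frozenset(),
            )
        )
    return clusters


def clustered_tf_filter(
    clusters: Iterable[MatrixCluster], tf_set: set[str]
) -> tuple[set[str], list[MatrixCluster]]:
    """Keep genes whose matrices share a cluster with at least one TF matrix.

    Returns the retained gene set and the clusters annotated with their
    ``Clustered-TF`` regulators.
    """
    annotated = []
    retained: set[str] = set()
    for c in clusters:
        tfs = frozenset(g for g in c.member_genes if g in tf_set)
        annotated.append(
            MatrixCluster(
                cluster_id=c.cluster_id,
                members=c.members,
                member_genes=c.member_genes,
                clustered_tfs=tfs,
            )
        )
        if tfs:
            retained |= set(c.member_genes)
    return retained, annotated
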