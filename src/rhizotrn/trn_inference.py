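"""Three-step construction of condition-specific regulatory networks.

Step 1 scans the upstream region of every profiled locus with every matrix
of every co-expressed TF and keeps, per TF gene-target pair, the best
(lowest p-value) hit; loci recognised by no TF and TFs recognising nothing
are dropped.  Step 2 clusters the motif matrices of the step-1 genes and
keeps only genes whose matrices cluster with a TF matrix (the clustered-TF
filter).  Step 3 rebuilds the network exactly as in step 1 but restricted to
the retained genes.  Filtering enriches high-stringency interactions: the
edges it removes are predominantly the marginal, low-stringency ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .matrix_clustering import (
    DEFAULT_COR_MIN,
    DEFAULT_NCOR_MIN,
    MatrixCluster,
    cluster_matrices,
    clustered_tf_filter,
)
from .motif_model import DEFAULT_GRANULARITY, PSSM, score_distribution
from .promoter_scan import SiteHit, auto_select, scan_promoter

__all__ = [
    "RegNetwork",
    "ThreeStepResult",
    "build_network",
    "three_step",
    "pvalue_range_histogram",
    "high_stringency_fraction",
    "extract_regulons",
]

logger = logging.getLogger(__name__)

DEFAULT_MAX_P = 9.9e-4


@dataclass
class RegNetwork:
    """Directed TF -> target graph with the best site hit on every edge."""

    condition: str
    graph: nx.DiGraph
    provenance: str = "step1"

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def regulators(self) -> set[str]:
        return {n for n in self.graph if self.graph.nodes[n].get("is_regulator")}

    def edge_hits(self) -> dict[tuple[str, str], SiteHit]:
        return {e: self.graph.edges[e]["hit"] for e in self.graph.edges}


def build_network(
    profile: tuple[set[str], set[str]],
    promoters: Mapping[str, str],
    matrices: Mapping[str, Sequence[PSSM]],
    max_p: float = DEFAULT_MAX_P,
    condition: str = "",
    granularity: float = DEFAULT_GRANULARITY,
    provenance: str = "step1",
) -> RegNetwork:
    """Scan all TF x target pairs of a profile and keep best hits per pair.

    Self pairs are scanned too (the motif resource is built on genes
    recognising their own promoters), so self-regulation edges appear.
    Genes participating in no relation are removed from the network.
    """
    loci, tf_loci = profile
    if not loci:
        raise ValueError("empty profile")
    loci = {g for g in loci if g in promoters}
    scanable_tfs = [t for t in sorted(tf_loci) if t in matrices and t in loci]
    hits: list[SiteHit] = []
    for tf in scanable_tfs:
        for pssm in matrices[tf]:
            dist = score_distribution(pssm, granularity)
            for target in sorted(loci):
                hits.extend(
                    scan_promoter(
                        pssm,
                        promoters[target],
                        target,
                        max_p=max_p,
                        distribution=dist,
                    )
                )
    best = auto_select(hits)
    g = nx.DiGraph()
    for (tf, target), hit in best.items():
        g.add_edge(tf, target, hit=hit)
    for n in g.nodes:
        g.nodes[n]["is_regulator"] = n in tf_loci
    isolated = [n for n in g if g.degree(n) == 0]
    g.remove_nodes_from(isolated)
    logger.info(
        "%s/%s: %d/%d profile loci (%d/%d TFs) kept in the %s network, %d edges",
        condition,
        provenance,
        g.number_of_nodes(),
        len(loci),
        sum(1 for n in g if g.nodes[n]["is_regulator"]),
        len(tf_loci),
        provenance,
        g.number_of_edges(),
    )
    return RegNetwork(condition=condition, graph=g, provenance=provenance)


@dataclass
class ThreeStepResult:
    step1: RegNetwork
    clusters: list[MatrixCluster]
    retained_genes: set[str]
    step3: RegNetwork


def three_step(
    profile: tuple[set[str], set[str]],
    promoters: Mapping[str, str],
    matrices: Mapping[str, Sequence[PSSM]],
    max_p: float = DEFAULT_MAX_P,
    cor_min: float = DEFAULT_COR_MIN,
    ncor_min: float = DEFAULT_NCOR_MIN,
    condition: str = "",
    granularity: float = DEFAULT_GRANULARITY,
) -> ThreeStepResult:
    """Step-1 network, clustered-TF gene selection, step-3 rebuilt network."""
    loci, tf_loci = profile
    step1 = build_network(
        profile, promoters, matrices, max_p, condition, granularity, "step1"
    )
    step1_genes = step1.nodes
    pool = [m for g in sorted(step1_genes) for m in matrices.get(g, [])]
    clusters = cluster_matrices(pool, cor_min=cor_min, ncor_min=ncor_min)
    retained, clusters = clustered_tf_filter(clusters, tf_loci)
    logger.info(
        "%s: %d clusters, %d clustered-TF genes of %d step-1 genes",
        condition,
        len(clusters),
        len(retained),
        len(step1_genes),
    )
    reduced = (retained & loci, retained & tf_loci)
    if reduced[0]:
        step3 = build_network(
            reduced, promoters, matrices, max_p, condition, granularity, "step3"
        )
    else:
        step3 = RegNetwork(condition=condition, graph=nx.DiGraph(), provenance="step3")
    return ThreeStepResult(
        step1=step1, clusters=clusters, retained_genes=retained, step3=step3
    )


def pvalue_range_histogram(
    net: RegNetwork, min_decade: int = -20, max_decade: int = -4
) -> dict[int, int]:
    """Number of interactions per p-value decade.

    Keys are decade exponents (-4 means p in [1e-4, 1e-3)); values below the
    smallest decade are lumped into it.  Counts sum to the edge count.
    """
    if net.graph.number_of_edges() == 0:
        raise ValueError("network has no edges")
    counts = {d: 0 for d in range(max_decade, min_decade - 1, -1)}
    for _, hit in net.edge_hits().items():
        d = math.floor(math.log10(hit.p_value))
        d = min(max(d, min_decade), max_decade)
        counts[d] += 1
    return counts


def high_stringency_fraction(net: RegNetwork) -> float:
    """Fraction of edges whose best hit is in the high-stringency tier."""
    hits = net.edge_hits()
    if not hits:
        return 0.0
    return sum(1 for h in hits.values() if h.tier == "high") / len(hits)


def extract_regulons(
    net: RegNetwork, tiers: set[str] | None = None
) -> dict[str, set[str]]:
    """Partition the edge set by regulator: TF -> set of target loci.

    ``tiers`` optionally restricts the regulons to edges of the given
    stringency tiers (e.g. ``{"high"}`` for the high-confidence regulons).
    """
    regulons: dict[str, set[str]] = {}
    for tf, target, data in net.graph.edges(data=True):
        if tiers is not None and data["hit"].tier not in tiers:
            continue
        regulons.setdefault(tf, set()).add(target)
    return regulons
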