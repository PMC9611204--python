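"""Normalised structural properties of regulatory networks and null models.

Thirteen global properties are computed per network: fraction of regulators
(nodes with out-connectivity > 0), self-regulation, maximum out-connectivity
and giant (weakly connected) component size — all normalised by node count;
density times regulator fraction; feedforward, complex-feedforward and
3-feedback-loop counts normalised by the number of potential motifs

    n! / (n - r)! * (TFn / n) ** TFm

(r = 3 nodes per motif; TFm = 3 regulators required for a feedback loop,
2 for feedforward circuits); average shortest directed path length over
reachable pairs; diameter normalised by (n - 2); average clustering
coefficient of the undirected simplification; and adjusted R-squared of
power-law fits to the degree distribution P(k) and to the degree-dependent
clustering C(k).  Profiles are min-max scaled across networks, clustered
with Ward's method, and contrasted against a G(n, m) Erdos-Renyi ensemble
with matched node and edge counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import networkx as nx
import numpy as np
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar
from scipy.special import zeta

__all__ = [
    "PROPERTY_NAMES",
    "PropertyProfile",
    "UndefinedFitError",
    "count_motifs",
    "potential_motifs",
    "property_profile",
    "fit_power_law",
    "fit_degree_law",
    "er_ensemble",
    "NetworkComparison",
    "compare_networks",
    "cluster_purity",
]

PROPERTY_NAMES = [
    "regulators_frac",
    "self_reg_frac",
    "max_out_frac",
    "giant_component_frac",
    "density_x_regfrac",
    "ffl_norm",
    "complex_ffl_norm",
    "fbl3_norm",
    "avg_shortest_path",
    "diameter_norm",
    "avg_clustering",
    "r2adj_pk",
    "r2adj_ck",
]


class UndefinedFitError(ValueError):
    """Raised when a degree law has too few distinct degrees to fit."""


@dataclass(frozen=True)
class PropertyProfile:
    label: str
    n: int
    m: int
    tfn: int
    values: dict[str, float]

    def vector(self) -> np.ndarray:
        return np.array([self.values[k] for k in PROPERTY_NAMES])


# ---------------------------------------------------------------------------
# triad census
# ---------------------------------------------------------------------------

def _triad_counts(g: nx.DiGraph) -> dict[str, int]:
    """Classify every unordered node triple whose undirected simplification
    is a triangle.  Self-loops are ignored.  A triple counts as:

    * ``fbl3`` if its induced subgraph contains a directed 3-cycle;
    * ``ffl`` if it contains the transitive pattern X->Y, Y->Z, X->Z and no
      directed 3-cycle;
    * ``complex_ffl`` additionally requires at least one edge beyond the
      three defining ones.
    """
    edges = {(u, v) for u, v in g.edges if u != v}
    und: dict = {}
    for u, v in edges:
        und.setdefault(u, set()).add(v)
        und.setdefault(v, set()).add(u)
    order = {n: i for i, n in enumerate(g.nodes)}
    counts = {"ffl": 0, "complex_ffl": 0, "fbl3": 0}
    seen_pairs = set()
    for u, v in edges:
        a, b = (u, v) if order[u] < order[v] else (v, u)
        if (a, b) in seen_pairs:
            continue
        seen_pairs.add((a, b))
        for w in und.get(a, set()) & und.get(b, set()):
            # enumerate each triangle exactly once via its two lowest nodes
            if order[w] <= order[b]:
                continue
            x, y, z = a, b, w
            e = [
                (x, y) in edges, (y, x) in edges,
                (y, z) in edges, (z, y) in edges,
                (x, z) in edges, (z, x) in edges,
            ]
            k = sum(e)
            cycle = ((x, y) in edges and (y, z) in edges and (z, x) in edges) or (
                (y, x) in edges and (z, y) in edges and (x, z) in edges
            )
            if cycle:
                counts["fbl3"] += 1
                continue
            transitive = any(
                (p, q) in edges and (q, r) in edges and (p, r) in edges
                for p, q, r in permutations((x, y, z))
            )
            if transitive:
                counts["ffl"] += 1
                if k >= 4:
                    counts["complex_ffl"] += 1
    return counts


def count_motifs(g: nx.DiGraph, kind: str) -> int:
    """Count unordered node triples realising a three-node motif.

    ``kind`` is ``ffl`` (feedforward loop, no 3-cycle), ``complex_ffl``
    (feedforward loop with at least one extra internal edge) or ``fbl3``
    (directed 3-cycle).  Each triple is counted once.
    """
    if kind not in ("ffl", "complex_ffl", "fbl3"):
        raise ValueError(f"unknown motif kind: {kind!r}")
    return _triad_counts(g)[kind]


def potential_motifs(n: int, r: int, tfn: int, tfm: int) -> float:
    """n * (n-1) * ... * (n-r+1) * (TFn/n)**TFm with 0**TFm defined as 0."""
    if n < r:
        raise ValueError(f"motif size {r} exceeds node count {n}")
    if r < 1 or tfn < 0 or tfn > n:
        raise ValueError("invalid motif parameters")
    perm = 1.0
    for i in range(r):
        perm *= n - i
    if tfn == 0 and tfm >= 1:
        return 0.0
    return perm * (tfn / n) ** tfm


# ---------------------------------------------------------------------------
# degree-law fitting
# ---------------------------------------------------------------------------

def fit_power_law(k: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Robust log-log fit y ~ c * k**exponent.

    Iteratively-reweighted (Huber) linear regression of log10 y on log10 k;
    returns the slope and the adjusted R-squared
    ``1 - (1 - R2) (N - 1) / (N - 2)`` of the robust line.
    """
    k = np.asarray(k, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (k > 0) & (y > 0)
    k, y = k[ok], y[ok]
    if len(np.unique(k)) < 3:
        raise UndefinedFitError("need at least 3 distinct positive degrees")
    lx, ly = np.log10(k), np.log10(y)
    X = sm.add_constant(lx)
    with warnings.catch_warnings():
        # a perfect fit trips a harmless scale-is-zero convergence warning
        warnings.simplefilter("ignore")
        fit = sm.RLM(ly, X, M=sm.robust.norms.HuberT()).fit()
    resid = ly - fit.fittedvalues
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedFitError("degenerate (constant) law")
    r2 = 1 - ss_res / ss_tot
    n_pts = len(ly)
    r2adj = 1 - (1 - r2) * (n_pts - 1) / (n_pts - 2)
    return float(fit.params[1]), float(r2adj)


def _mle_exponent(degrees: np.ndarray) -> float:
    """Discrete power-law exponent alpha (P(k) ~ k**-alpha) by maximum
    likelihood with the generalised zeta normaliser at kmin = min degree."""
    degrees = degrees[degrees > 0]
    kmin = degrees.min()
    slog = np.log(degrees).sum()
    n_obs = len(degrees)

    def nll(alpha: float) -> float:
        return n_obs * np.log(zeta(alpha, kmin)) + alpha * slog

    res = minimize_scalar(nll, bounds=(1.01, 10.0), method="bounded")
    return float(res.x)


def _degree_sequence(g: nx.DiGraph, degree: str) -> np.ndarray:
    if degree == "total":
        return np.array([d for _, d in g.degree()])
    if degree == "in":
        return np.array([d for _, d in g.in_degree()])
    if degree == "out":
        return np.array([d for _, d in g.out_degree()])
    raise ValueError(f"unknown degree flavour: {degree!r}")


def fit_degree_law(
    g: nx.DiGraph, which: str = "pk", method: str = "robust", degree: str = "total"
) -> tuple[float, float]:
    """Power-law fit of the degree distribution P(k) or clustering law C(k).

    ``method='robust'`` returns (slope, adjusted R2) of the robust log-log
    regression; ``method='mle'`` returns (-alpha, adjusted R2) where alpha is
    the discrete maximum-likelihood exponent and the adjusted R2 still comes
    from the robust fit (the likelihood has no R2).  Total degree is used by
    default; in- or out-degree via ``degree``.
    """
    if which not in ("pk", "ck"):
        raise ValueError("which must be 'pk' or 'ck'")
    degs = _degree_sequence(g, degree)
    if which == "pk":
        ks, counts = np.unique(degs[degs > 0], return_counts=True)
        ys = counts / len(degs)
    else:
        und = nx.Graph(g)
        und.remove_edges_from(nx.selfloop_edges(und))
        clust = nx.clustering(und)
        nodes = list(g.nodes)
        by_k: dict[int, list[float]] = {}
        for node, d in zip(nodes, degs):
            if d > 0:
                by_k.setdefault(int(d), []).append(clust.get(node, 0.0))
        ks = np.array(sorted(by_k))
        ys = np.array([np.mean(by_k[int(k)]) for k in ks])
    slope, r2adj = fit_power_law(ks, ys)
    if method == "robust":
        return slope, r2adj
    if method == "mle":
        if which != "pk":
            raise ValueError("maximum-likelihood fitting applies to P(k) only")
        return -_mle_exponent(degs), r2adj
    raise ValueError(f"unknown method: {method!r}")


# ---------------------------------------------------------------------------
# property profile
# ---------------------------------------------------------------------------

def property_profile(g: nx.DiGraph, label: str = "") -> PropertyProfile:
    """The 13 normalised structural properties of one directed network."""
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("property profile requires at least 3 nodes")
    self_loops = sum(1 for u, v in g.edges if u == v)
    m = g.number_of_edges() - self_loops
    if g.number_of_edges() == 0:
        raise ValueError("property profile requires at least one edge")
    kout = dict(g.out_degree())
    tfn = sum(1 for d in kout.values() if d > 0)
    values: dict[str, float] = {}
    values["regulators_frac"] = tfn / n
    values["self_reg_frac"] = self_loops / n
    values["max_out_frac"] = max(kout.values()) / n
    giant = max(nx.weakly_connected_components(g), key=len)
    values["giant_component_frac"] = len(giant) / n
    density = m / (n * (n - 1))
    values["density_x_regfrac"] = density * (tfn / n)
    triads = _triad_counts(g)
    pot_fb = potential_motifs(n, 3, tfn, 3)
    pot_ff = potential_motifs(n, 3, tfn, 2)
    values["ffl_norm"] = triads["ffl"] / pot_ff if pot_ff else 0.0
    values["complex_ffl_norm"] = triads["complex_ffl"] / pot_ff if pot_ff else 0.0
    values["fbl3_norm"] = triads["fbl3"] / pot_fb if pot_fb else 0.0
    # directed shortest paths over reachable ordered pairs
    total, pairs, diameter = 0, 0, 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for target, d in dists.items():
            if d > 0:
                total += d
                pairs += 1
                diameter = max(diameter, d)
    values["avg_shortest_path"] = total / pairs if pairs else 0.0
    values["diameter_norm"] = min(diameter / (n - 2), 1.0) if n > 2 else 1.0
    und = nx.Graph(g)
    und.remove_edges_from(nx.selfloop_edges(und))
    values["avg_clustering"] = nx.average_clustering(und) if und.number_of_nodes() else 0.0
    for key, which in (("r2adj_pk", "pk"), ("r2adj_ck", "ck")):
        try:
            _, r2adj = fit_degree_law(g, which)
            values[key] = r2adj
        except UndefinedFitError:
            values[key] = 0.0  # too-narrow degree support: no scale-free signal
    return PropertyProfile(label=label, n=n, m=m, tfn=tfn, values=values)


# ---------------------------------------------------------------------------
# Erdos-Renyi null ensemble
# ---------------------------------------------------------------------------

def er_ensemble(
    n: int, m: int, reps: int = 1000, seed: int = 0
) -> list[nx.DiGraph]:
    """G(n, m) ensemble: uniform simple directed graphs with exactly m edges."""
    if m > n * (n - 1):
        raise ValueError(f"cannot place {m} simple directed edges on {n} nodes")
    if m < 0 or reps < 1:
        raise ValueError("invalid ensemble parameters")
    rng = np.random.default_rng(seed)
    graphs = []
    for _ in range(reps):
        flat = rng.choice(n * (n - 1), size=m, replace=False)
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        u = flat // (n - 1)
        r = flat % (n - 1)
        v = np.where(r >= u, r + 1, r)  # skip the diagonal
        g.add_edges_from(zip(u.tolist(), v.tolist()))
        graphs.append(g)
    return graphs


# ---------------------------------------------------------------------------
# cross-network comparison
# ---------------------------------------------------------------------------

@dataclass
class NetworkComparison:
    labels: list[str]
    raw: np.ndarray           # networks x 13
    scaled: np.ndarray        # min-max scaled per property
    network_linkage: np.ndarray
    property_linkage: np.ndarray
    correlation: np.ndarray   # networks x networks Pearson


def compare_networks(
    profiles: Sequence[PropertyProfile],
    scale_before_correlation: bool = True,
) -> NetworkComparison:
    """Min-max scale property vectors across networks, Ward-cluster both
    networks and properties, and correlate the network profiles."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    raw = np.vstack([p.vector() for p in profiles])
    lo = raw.min(axis=0)
    span = raw.max(axis=0) - lo
    scaled = np.where(span > 0, (raw - lo) / np.where(span > 0, span, 1.0), 0.0)
    net_link = linkage(scaled, method="ward")
    prop_link = linkage(scaled.T, method="ward")
    basis = scaled if scale_before_correlation else raw
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(basis)
    corr = np.nan_to_num(corr, nan=1.0)
    return NetworkComparison(
        labels=[p.label for p in profiles],
        raw=raw,
        scaled=scaled,
        network_linkage=net_link,
        property_linkage=prop_link,
        correlation=corr,
    )


def cluster_purity(
    comparison: NetworkComparison, groups: Sequence[str], k: int = 2
) -> float:
    """Purity of the k-cluster Ward cut against known group labels."""
    assignment = fcluster(comparison.network_linkage, k, criterion="maxclust")
    total = 0
    for c in set(assignment):
        members = [g for g, a in zip(groups, assignment) if a == c]
        counts = {g: members.count(g) for g in set(members)}
        total += max(counts.values())
    return total / len(groups)
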