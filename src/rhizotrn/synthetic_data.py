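"""Self-contained synthetic benchmark worlds with planted ground truth.

A world emulates the inputs of the inference pipeline: upstream regulatory
sequences per gene, one-to-five motif count matrices per gene, condition
protein profiles with a TF flag, and locus-to-KO / KO-to-pathway tables —
all with known truth (which TF regulates which gene, where every motif site
was implanted, which KO groups carry condition-specific multiplicity).

Generator conventions
---------------------
* Upstream regions are fixed-length (default 250 bp) windows ending
  immediately before the gene start; positions are 1-based inclusive.
* Background is an i.i.d. 0-order base model, uniform by default
  (configurable GC content).
* Regulon sizes follow a truncated Zipf law (exponent 1.5, cap n_genes/4)
  so that hub regulators exist and degree-law fitting is exercised.
* Every regulator also recognises a site in its own promoter (the motif
  resource being emulated is built on self-recognition), so each TF's
  regulon includes itself.
* A regulated gene's own first matrix is a Dirichlet-perturbed copy of one
  of its regulators' matrices — this is what makes the clustered-TF filter
  informative.  Extra matrices (uniformly 1..5 per gene) are noisier copies,
  giving matrix clustering realistic near-duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .motif_model import ALPHABET, PSSM, reverse_complement

__all__ = [
    "PlantedSite",
    "SyntheticWorld",
    "generate_world",
    "generate_profiles",
    "generate_ko_map",
]

DEFAULT_PROMOTER_LEN = 250
DEFAULT_MOTIF_WIDTH = 14
DEFAULT_SITE_STRENGTH = 0.9  # probability of the consensus base per column
DEFAULT_REGULON_EXPONENT = 1.5
_COUNT_SCALE = 100  # sites-worth of counts in generated matrices


class PlantedSite(NamedTuple):
    """One implanted motif occurrence: source motif owner, target promoter,
    strand and 0-based offset of the site's first position."""

    tf: str
    target: str
    strand: str
    offset: int


@dataclass
class SyntheticWorld:
    genes: list[str]
    promoters: dict[str, str]
    tf_set: set[str]
    truth_network: set[tuple[str, str]]
    planted_sites: list[PlantedSite]
    matrices: dict[str, list[PSSM]]
    profiles: dict[str, tuple[set[str], set[str]]] = field(default_factory=dict)
    ko_map: dict[str, str] = field(default_factory=dict)
    ko_pathways: dict[str, set[str]] = field(default_factory=dict)
    seed: int = 0
    motif_width: int = DEFAULT_MOTIF_WIDTH
    #: per-TF probability matrices the sites were sampled from (ground truth)
    true_motifs: dict[str, np.ndarray] = field(default_factory=dict)

    def regulon_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {tf: 0 for tf in self.tf_set}
        for tf, _ in self.truth_network:
            sizes[tf] += 1
        return sizes

    def all_matrices(self, genes: set[str] | None = None) -> list[PSSM]:
        pool = self.genes if genes is None else [g for g in self.genes if g in genes]
        return [m for g in pool for m in self.matrices[g]]


def _strong_matrix(width: int, strength: float, rng: np.random.Generator) -> np.ndarray:
    """Probability matrix with one dominant base per column."""
    probs = np.full((4, width), (1 - strength) / 3)
    consensus = rng.integers(0, 4, width)
    probs[consensus, np.arange(width)] = strength
    return probs


def _sample_site(probs: np.ndarray, rng: np.random.Generator) -> str:
    cols = [rng.choice(4, p=probs[:, j]) for j in range(probs.shape[1])]
    return "".join(ALPHABET[c] for c in cols)


def _perturb(probs: np.ndarray, conc: float, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(probs)
    for j in range(probs.shape[1]):
        out[:, j] = rng.dirichlet(conc * probs[:, j] + 0.05)
    return out


def _to_counts(probs: np.ndarray) -> np.ndarray:
    return np.round(probs * _COUNT_SCALE)


def generate_world(
    n_genes: int,
    n_tfs: int,
    promoter_len: int = DEFAULT_PROMOTER_LEN,
    regulon_exponent: float = DEFAULT_REGULON_EXPONENT,
    site_strength: float = DEFAULT_SITE_STRENGTH,
    motif_width: int = DEFAULT_MOTIF_WIDTH,
    gc: float = 0.5,
    seed: int = 0,
) -> SyntheticWorld:
    """Generate promoters, planted regulons, implanted sites and matrices.

    Raises ``ValueError`` for infeasible sizes (``n_tfs`` outside
    ``[1, n_genes)`` or promoters shorter than twice the motif width).
    """
    if not 1 <= n_tfs < n_genes:
        raise ValueError("need 1 <= n_tfs < n_genes")
    if promoter_len < 2 * motif_width:
        raise ValueError("promoter_len must be at least twice the motif width")
    if not 0.5 <= site_strength < 1:
        raise ValueError("site_strength must be in [0.5, 1)")
    rng = np.random.default_rng(seed)
    background = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    tf_list = genes[:n_tfs]
    tf_set = set(tf_list)
    promoters = {
        g: "".join(
            ALPHABET[b] for b in rng.choice(4, size=promoter_len, p=background)
        )
        for g in genes
    }
    # planted regulons: heavy-tailed sizes, self-target always included
    true_motifs = {tf: _strong_matrix(motif_width, site_strength, rng) for tf in tf_list}
    truth: set[tuple[str, str]] = set()
    cap = max(1, n_genes // 4)
    for tf in tf_list:
        size = int(min(rng.zipf(regulon_exponent), cap))
        targets = set(rng.choice(genes, size=size, replace=False))
        targets.add(tf)  # self-recognition
        truth |= {(tf, t) for t in targets}
    # implant sites; per promoter choose non-overlapping offsets so that no
    # planted site destroys another
    by_target: dict[str, list[str]] = {}
    for tf, t in sorted(truth):
        by_target.setdefault(t, []).append(tf)
    regulators_of = {t: list(tfs) for t, tfs in by_target.items()}
    # genes regulated by nobody still need a self-site of their own motif
    own_motif: dict[str, np.ndarray] = {}
    for g in genes:
        if g not in by_target:
            own_motif[g] = _strong_matrix(motif_width, site_strength, rng)
            by_target.setdefault(g, []).append(g)
    planted: list[PlantedSite] = []
    for g in genes:
        sources = by_target.get(g, [])
        offsets = _disjoint_offsets(
            len(sources), promoter_len, motif_width, rng
        )
        prom = list(promoters[g])
        for src, off in zip(sources, offsets):
            probs = true_motifs.get(src, own_motif.get(src))
            site = _sample_site(probs, rng)
            strand = "D" if rng.random() < 0.5 else "R"
            implanted = site if strand == "D" else reverse_complement(site)
            prom[off : off + motif_width] = implanted
            planted.append(PlantedSite(src, g, strand, off))
        promoters[g] = "".join(prom)
    # matrices: 1..5 per gene; first matrix is (a perturbed copy of) the
    # motif whose site sits in the gene's own promoter
    matrices: dict[str, list[PSSM]] = {}
    for g in genes:
        if g in tf_set:
            base_probs = true_motifs[g]
        elif g in regulators_of:
            base_probs = _perturb(true_motifs[regulators_of[g][0]], 200.0, rng)
        else:
            base_probs = own_motif[g]
        k = int(rng.integers(1, 6))
        mats = [PSSM(f"{g}_m1", _to_counts(base_probs), background=background)]
        for j in range(2, k + 1):
            mats.append(
                PSSM(
                    f"{g}_m{j}",
                    _to_counts(_perturb(base_probs, 60.0, rng)),
                    background=background,
                )
            )
        matrices[g] = mats
    return SyntheticWorld(
        genes=genes,
        promoters=promoters,
        tf_set=tf_set,
        truth_network=truth,
        planted_sites=planted,
        matrices=matrices,
        seed=seed,
        motif_width=motif_width,
        true_motifs=true_motifs,
    )


def _disjoint_offsets(
    k: int, promoter_len: int, width: int, rng: np.random.Generator, tries: int = 200
) -> list[int]:
    """k random non-overlapping site offsets within a promoter."""
    if k == 0:
        return []
    if k * width > promoter_len:
        raise ValueError(
            f"cannot place {k} non-overlapping sites of width {width} "
            f"in a {promoter_len} bp promoter"
        )
    for _ in range(tries):
        offs = sorted(int(o) for o in rng.integers(0, promoter_len - width + 1, k))
        if all(b - a >= width for a, b in zip(offs, offs[1:])):
            rng.shuffle(offs)
            return offs
    # dense fallback: place on a jittered regular lattice
    slots = np.linspace(0, promoter_len - width, k).astype(int)
    return [int(s) for s in slots]


def generate_profiles(
    world: SyntheticWorld,
    n_conditions: int = 2,
    overlap: float = 0.3,
    tf_rate: float = 1.0,
    seed: int | None = None,
) -> SyntheticWorld:
    """Assign loci to condition profiles with a given expected shared fraction.

    Each gene is shared across all conditions with probability ``overlap``,
    otherwise it is assigned to exactly one condition chosen uniformly, so
    the expected fraction of profiled loci present in every condition equals
    ``overlap``.  TFs assigned to a condition are then retained there with
    probability ``tf_rate`` (default: always).
    """
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must lie in [0, 1]")
    if not 0 <= tf_rate <= 1:
        raise ValueError("tf_rate must lie in [0, 1]")
    if n_conditions < 1:
        raise ValueError("need at least one condition")
    rng = np.random.default_rng(world.seed + 1 if seed is None else seed)
    names = ["MM", "bacteroid"][:n_conditions] + [
        f"C{i}" for i in range(3, n_conditions + 1)
    ]
    assign: dict[str, list[str]] = {c: [] for c in names}
    for g in world.genes:
        if rng.random() < overlap:
            conds = names
        else:
            conds = [names[int(rng.integers(0, n_conditions))]]
        for c in conds:
            if g in world.tf_set and rng.random() > tf_rate:
                continue
            assign[c].append(g)
    world.profiles = {
        c: (set(loci), set(loci) & world.tf_set) for c, loci in assign.items()
    }
    return world


def generate_ko_map(
    world: SyntheticWorld,
    n_multiplicity_groups: int = 5,
    n_identical: int = 2,
    n_pathways: int = 8,
    seed: int | None = None,
) -> SyntheticWorld:
    """Assign KO identifiers planting condition-specific multiplicity.

    Exactly ``n_multiplicity_groups`` KOs receive condition-exclusive locus
    sets (true isoenzyme groups, disjoint across conditions) and
    ``n_identical`` KOs receive a single locus shared by all conditions (the
    same gene expressed in both states — not an isoenzyme).  Every other
    locus gets a private KO.  The planted groups jointly cover exactly
    ``n_pathways`` pathway labels; all other KOs draw background labels.
    """
    if not world.profiles:
        raise ValueError("generate_profiles must be called first")
    if n_multiplicity_groups < 0 or n_identical < 0:
        raise ValueError("group counts must be non-negative")
    if n_multiplicity_groups > 0 and n_pathways < 1:
        raise ValueError("planted groups need at least one pathway label")
    rng = np.random.default_rng(world.seed + 2 if seed is None else seed)
    conds = list(world.profiles)
    loci_sets = {c: set(world.profiles[c][0]) for c in conds}
    exclusive = {
        c: sorted(
            loci_sets[c].difference(*(loci_sets[o] for o in conds if o != c))
        )
        for c in conds
    }
    shared = sorted(set.intersection(*loci_sets.values())) if conds else []
    if any(len(exclusive[c]) < n_multiplicity_groups for c in conds):
        raise ValueError("not enough condition-exclusive loci for the requested groups")
    if len(shared) < n_identical:
        raise ValueError("not enough shared loci for the requested identical KOs")
    for c in conds:
        rng.shuffle(exclusive[c])
    rng.shuffle(shared)
    ko_map: dict[str, str] = {}
    ko_pathways: dict[str, set[str]] = {}
    next_ko = 1

    def fresh_ko() -> str:
        nonlocal next_ko
        ko = f"K{next_ko:05d}"
        next_ko += 1
        return ko

    planted_paths = [f"path{i:03d}" for i in range(1, n_pathways + 1)]
    group_kos = []
    for i in range(n_multiplicity_groups):
        ko = fresh_ko()
        group_kos.append(ko)
        for c in conds:
            ko_map[exclusive[c].pop()] = ko
        ko_pathways[ko] = set()
    for i, path in enumerate(planted_paths):
        if group_kos:
            ko_pathways[group_kos[i % len(group_kos)]].add(path)
    for _ in range(n_identical):
        ko = fresh_ko()
        ko_map[shared.pop()] = ko
        ko_pathways[ko] = {f"bg_path{next_ko:03d}"}
    profiled = set().union(*loci_sets.values())
    for locus in sorted(profiled - set(ko_map)):
        ko = fresh_ko()
        ko_map[locus] = ko
        ko_pathways[ko] = {f"bg_path{next_ko:03d}"}
    world.ko_map = ko_map
    world.ko_pathways = ko_pathways
    return world
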