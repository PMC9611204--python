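"""Readers and writers for the pipeline's file formats.

Promoters travel as FASTA (record id = locus tag), motif matrices as
TRANSFAC count matrices, profiles / KO tables / networks as headered TSV,
networks additionally as GML, and run configuration as YAML.  Coordinates
in all tables are 1-based inclusive positions within the upstream region.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif_model import PSSM, parse_matrix_id, read_transfac, write_transfac
from .promoter_scan import SiteHit, classify_tier
from .synthetic_data import PlantedSite, SyntheticWorld
from .trn_inference import RegNetwork

__all__ = [
    "NETWORK_COLUMNS",
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_transfac",
    "write_transfac",
    "write_network_table",
    "read_network_table",
    "write_cluster_table",
    "write_world",
    "read_world",
]

logger = logging.getLogger(__name__)

#: the network/hit table schema
NETWORK_COLUMNS = [
    "Condition",
    "Locus tag",
    "K number",
    "Upstream_region",
    "Matrix_ID",
    "Chain",
    "End_motif",
    "Start_motif",
    "Site",
    "Weight",
    "p-value",
    "Significance",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(promoters: Mapping[str, str], path: Path | str) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene, description="")
        for gene, seq in promoters.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: Path | str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# network tables
# ---------------------------------------------------------------------------

def network_to_frame(
    net: RegNetwork, ko_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """One row per TF gene-target relation, highest p-values first."""
    rows = []
    for (tf, target), hit in net.edge_hits().items():
        ko = (ko_map or {}).get(target, "")
        if not isinstance(ko, str):
            ko = ";".join(sorted(ko))
        rows.append(
            {
                "Condition": net.condition,
                "Locus tag": target,
                "K number": ko,
                "Upstream_region": target,
                "Matrix_ID": hit.matrix_id,
                "Chain": hit.strand,
                "End_motif": hit.end,
                "Start_motif": hit.start,
                "Site": hit.site,
                "Weight": hit.weight,
                "p-value": hit.p_value,
                "Significance": hit.significance,
            }
        )
    df = pd.DataFrame(rows, columns=NETWORK_COLUMNS)
    return df.sort_values(
        ["p-value", "Locus tag", "Matrix_ID"], ascending=[False, True, True],
        ignore_index=True,
    )


def write_network_table(
    net: RegNetwork, path: Path | str, ko_map: Mapping[str, str] | None = None
) -> None:
    network_to_frame(net, ko_map).to_csv(path, sep="\t", index=False)


def read_network_table(path: Path | str, provenance: str = "step1") -> RegNetwork:
    """Rebuild a network from its TSV; the TF is parsed from Matrix_ID."""
    df = pd.read_csv(path, sep="\t")
    missing = set(NETWORK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"network table {path} lacks columns: {sorted(missing)}")
    g = nx.DiGraph()
    condition = ""
    for _, row in df.iterrows():
        condition = row["Condition"] if pd.notna(row["Condition"]) else ""
        tf, _ = parse_matrix_id(row["Matrix_ID"])
        target = row["Locus tag"]
        p = float(row["p-value"])
        hit = SiteHit(
            matrix_id=row["Matrix_ID"],
            tf_gene=tf,
            target_gene=target,
            strand=row["Chain"],
            start=int(row["Start_motif"]),
            end=int(row["End_motif"]),
            site=row["Site"],
            weight=float(row["Weight"]),
            p_value=p,
            significance=float(row["Significance"]),
            tier=classify_tier(p),
        )
        g.add_edge(tf, target, hit=hit)
    for n in g.nodes:
        g.nodes[n]["is_regulator"] = g.out_degree(n) > 0
    return RegNetwork(condition=str(condition), graph=g, provenance=provenance)


def write_gml(net: RegNetwork, path: Path | str) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(net.graph.nodes(data=True))
    for (u, v), hit in net.edge_hits().items():
        g.add_edge(u, v, matrix_id=hit.matrix_id, p_value=hit.p_value, tier=hit.tier)
    nx.write_gml(g, str(path))


def write_cluster_table(clusters, path: Path | str) -> None:
    """`clusters_motif_names.tab`-style TSV with the Clustered-TF column."""
    rows = []
    for c in clusters:
        tf_label = ";".join(sorted(c.clustered_tfs))
        for mid in sorted(c.members):
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "matrix_id": mid,
                    "gene": parse_matrix_id(mid)[0],
                    "Clustered-TF": tf_label,
                }
            )
    pd.DataFrame(rows, columns=["cluster_id", "matrix_id", "gene", "Clustered-TF"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# synthetic worlds
# ---------------------------------------------------------------------------

def write_world(world: SyntheticWorld, directory: Path | str) -> None:
    """Serialise a world to FASTA + TRANSFAC + TSV files in ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_fasta(world.promoters, d / "promoters.fasta")
    with open(d / "matrices.transfac", "w") as fh:
        write_transfac(world.all_matrices(), fh)
    prof_rows = [
        {"Condition": c, "Locus tag": locus, "TF": int(locus in tfs)}
        for c, (loci, tfs) in world.profiles.items()
        for locus in sorted(loci)
    ]
    pd.DataFrame(prof_rows, columns=["Condition", "Locus tag", "TF"]).to_csv(
        d / "profiles.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"Locus tag": l, "K number": k} for l, k in sorted(world.ko_map.items())]
    ).to_csv(d / "ko_map.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"K number": k, "Pathway": p}
            for k, paths in sorted(world.ko_pathways.items())
            for p in sorted(paths)
        ]
    ).to_csv(d / "ko_pathways.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(world.truth_network), columns=["TF", "Target"]).to_csv(
        d / "truth_network.tsv", sep="\t", index=False
    )
    pd.DataFrame(world.planted_sites, columns=["TF", "Target", "Strand", "Offset"]).to_csv(
        d / "planted_sites.tsv", sep="\t", index=False
    )
    meta = {
        "seed": int(world.seed),
        "motif_width": int(world.motif_width),
        "tf_set": sorted(world.tf_set),
    }
    (d / "world.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def read_world(directory: Path | str) -> SyntheticWorld:
    """Re-read a serialised world.  Generator internals that are not part of
    the interchange format (the generating probability matrices) are not
    recovered."""
    d = Path(directory)
    meta = yaml.safe_load((d / "world.yaml").read_text())
    promoters = read_fasta(d / "promoters.fasta")
    with open(d / "matrices.transfac") as fh:
        pssms = read_transfac(fh)
    matrices: dict[str, list[PSSM]] = {}
    for p in pssms:
        matrices.setdefault(p.source_gene, []).append(p)
    prof = pd.read_csv(d / "profiles.tsv", sep="\t")
    profiles: dict[str, tuple[set[str], set[str]]] = {}
    for cond, sub in prof.groupby("Condition"):
        loci = set(sub["Locus tag"])
        tfs = set(sub.loc[sub["TF"] == 1, "Locus tag"])
        profiles[cond] = (loci, tfs)
    ko = pd.read_csv(d / "ko_map.tsv", sep="\t")
    ko_map = dict(zip(ko["Locus tag"], ko["K number"]))
    kp = pd.read_csv(d / "ko_pathways.tsv", sep="\t")
    ko_pathways: dict[str, set[str]] = {}
    for _, row in kp.iterrows():
        ko_pathways.setdefault(row["K number"], set()).add(row["Pathway"])
    truth = pd.read_csv(d / "truth_network.tsv", sep="\t")
    sites = pd.read_csv(d / "planted_sites.tsv", sep="\t")
    planted = [
        PlantedSite(r["TF"], r["Target"], r["Strand"], int(r["Offset"]))
        for _, r in sites.iterrows()
    ]
    genes = sorted(promoters)
    return SyntheticWorld(
        genes=genes,
        promoters=promoters,
        tf_set=set(meta["tf_set"]),
        truth_network={(r["TF"], r["Target"]) for _, r in truth.iterrows()},
        planted_sites=planted,
        matrices=matrices,
        profiles=profiles,
        ko_map=ko_map,
        ko_pathways=ko_pathways,
        seed=int(meta["seed"]),
        motif_width=int(meta["motif_width"]),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every knob of a pipeline run; YAML round-trip plus the seed pins all
    stochastic stages, so a config echo reproduces a run exactly."""

    world_dir: str = "world"
    out_dir: str = "out"
    max_p: float = 9.9e-4
    granularity: float = 0.01
    cor_min: float = 0.6
    ncor_min: float = 0.4
    er_reps: int = 1000
    seed: int = 0

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
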