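"""Condition-specific isoenzyme (multiplicity) detection from KO orthology.

Two loci sharing a KEGG Orthology (K) number perform the same enzymatic
step; when their expression is split between physiological conditions the K
number shows *multiplicity* — condition-specific isoenzymes.  A KO whose
per-condition locus sets are equal is the same gene expressed in both
states, not an isoenzyme.  Joining the groups against the per-condition
inferred networks reports which regulators drive each member locus and
whether the regulation itself is condition-specific.

The packaged reference table (``data/retli_mm_bacteroid_multiplicity.tsv``)
is the published KO-multiplicity table for the *Rhizobium etli* CFN42
minimal-medium vs bacteroid proteome comparison and serves as a regression
fixture for the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .trn_inference import RegNetwork

__all__ = [
    "IsoenzymeGroup",
    "detect_isoenzymes",
    "isoenzyme_groups",
    "pathway_coverage",
    "differential_regulators",
    "load_reference_multiplicity_table",
    "profiles_from_table",
]

logger = logging.getLogger(__name__)

ISOENZYME_CLASSES = ("disjoint", "overlapping")


@dataclass(frozen=True)
class IsoenzymeGroup:
    """One K number with its per-condition locus sets."""

    ko: str
    loci_by_condition: dict[str, frozenset[str]]
    multiplicity_class: str  # disjoint | overlapping | identical | single-condition
    pathways: frozenset[str] = frozenset()

    @property
    def is_isoenzyme(self) -> bool:
        return self.multiplicity_class in ISOENZYME_CLASSES

    def loci(self) -> set[str]:
        return set().union(*self.loci_by_condition.values())


def _classify(sets: list[frozenset[str]]) -> str:
    if len(sets) < 2:
        return "single-condition"
    if all(s == sets[0] for s in sets[1:]):
        return "identical"
    union = set().union(*sets)
    if len(union) == sum(len(s) for s in sets):
        return "disjoint"
    return "overlapping"


def detect_isoenzymes(
    profiles: Mapping[str, set[str]],
    ko_map: Mapping[str, str],
    ko_pathways: Mapping[str, set[str]] | None = None,
) -> list[IsoenzymeGroup]:
    """Group profiled loci by KO and classify per-condition multiplicity.

    ``profiles`` maps condition label to its locus set.  Loci absent from
    ``ko_map`` are logged and skipped.  Returns one group per KO, sorted by
    KO; KOs expressed in a single condition are classified
    ``single-condition``, the rest ``disjoint``/``overlapping`` (isoenzymes)
    or ``identical`` (the same gene in several conditions).
    """
    if not profiles or all(not loci for loci in profiles.values()):
        raise ValueError("empty profiles")
    by_ko: dict[str, dict[str, set[str]]] = {}
    unmapped = set()
    for cond, loci in profiles.items():
        for locus in loci:
            kos = ko_map.get(locus)
            if kos is None:
                unmapped.add(locus)
                continue
            # KO orthology is many-to-many: a locus may belong to several groups
            for ko in ([kos] if isinstance(kos, str) else kos):
                by_ko.setdefault(ko, {}).setdefault(cond, set()).add(locus)
    if unmapped:
        logger.warning("%d profiled loci without KO mapping skipped", len(unmapped))
    groups = []
    for ko in sorted(by_ko):
        per_cond = {c: frozenset(s) for c, s in sorted(by_ko[ko].items())}
        cls = _classify(list(per_cond.values()))
        paths = frozenset((ko_pathways or {}).get(ko, set()))
        groups.append(
            IsoenzymeGroup(
                ko=ko,
                loci_by_condition=per_cond,
                multiplicity_class=cls,
                pathways=paths,
            )
        )
    return groups


def isoenzyme_groups(groups: Iterable[IsoenzymeGroup]) -> list[IsoenzymeGroup]:
    """The subset of groups classified as isoenzymes (disjoint or overlapping)."""
    return [g for g in groups if g.is_isoenzyme]


def pathway_coverage(
    groups: Iterable[IsoenzymeGroup],
    ko_pathways: Mapping[str, set[str]] | None = None,
) -> tuple[int, pd.DataFrame]:
    """Distinct pathways covered by the isoenzyme groups.

    Returns the count of distinct pathway labels over the disjoint and
    overlapping groups, plus a per-pathway table (pathway, KO count).
    KOs without pathway annotation are logged and contribute nothing.
    """
    rows = []
    missing = 0
    for g in isoenzyme_groups(groups):
        paths = set(g.pathways)
        if ko_pathways is not None:
            paths |= set(ko_pathways.get(g.ko, set()))
        if not paths:
            missing += 1
            continue
        for p in paths:
            rows.append({"pathway": p, "ko": g.ko})
    if missing:
        logger.warning("%d isoenzyme KOs without pathway annotation", missing)
    if not rows:
        return 0, pd.DataFrame(columns=["pathway", "n_kos"])
    df = pd.DataFrame(rows)
    table = (
        df.groupby("pathway")["ko"].nunique().reset_index(name="n_kos")
        .sort_values("pathway", ignore_index=True)
    )
    return int(df["pathway"].nunique()), table


@dataclass(frozen=True)
class RegulatorComparison:
    ko: str
    regulators_by_condition: dict[str, frozenset[tuple[str, int, float]]]
    uncovered: dict[str, frozenset[str]]
    differential: bool


def differential_regulators(
    groups: Iterable[IsoenzymeGroup],
    nets: Mapping[str, RegNetwork],
) -> list[RegulatorComparison]:
    """Per-group regulator sets across conditions, flagging differential ones.

    For every isoenzyme group and condition, collects the (TF, matrix index,
    p-value) triples of the edges targeting the group's member loci in that
    condition's network.  A group is ``differential`` when the TF sets of
    the conditions with data are not all equal.  Member loci with no
    inferred regulator are reported as uncovered.
    """
    out = []
    for g in isoenzyme_groups(groups):
        regs: dict[str, frozenset[tuple[str, int, float]]] = {}
        uncovered: dict[str, frozenset[str]] = {}
        for cond, loci in g.loci_by_condition.items():
            net = nets.get(cond)
            triples = set()
            missing = set(loci)
            if net is not None:
                for locus in loci:
                    if locus not in net.graph:
                        continue
                    found = False
                    for tf, _, data in net.graph.in_edges(locus, data=True):
                        hit = data["hit"]
                        triples.add((tf, hit.matrix_index, hit.p_value))
                        found = True
                    if found:
                        missing.discard(locus)
            regs[cond] = frozenset(triples)
            uncovered[cond] = frozenset(missing)
        tf_sets = [
            frozenset(t[0] for t in triples)
            for triples in regs.values()
            if triples
        ]
        differential = len(tf_sets) >= 2 and any(s != tf_sets[0] for s in tf_sets[1:])
        out.append(
            RegulatorComparison(
                ko=g.ko,
                regulators_by_condition=regs,
                uncovered=uncovered,
                differential=differential,
            )
        )
    return out


def load_reference_multiplicity_table() -> pd.DataFrame:
    """The packaged R. etli CFN42 MM/bacteroid KO-multiplicity table."""
    ref = resources.files("rhizotrn.data") / "retli_mm_bacteroid_multiplicity.tsv"
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")


def profiles_from_table(
    table: pd.DataFrame,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Condition profiles and locus->KOs map from a (K number, condition,
    locus tag) table such as the packaged reference."""
    profiles: dict[str, set[str]] = {}
    ko_map: dict[str, set[str]] = {}
    for _, row in table.iterrows():
        cond = row["Physiological condition"]
        locus = row["Locus tag"]
        profiles.setdefault(cond, set()).add(locus)
        ko_map.setdefault(locus, set()).add(row["K number"])
    return profiles, ko_map
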