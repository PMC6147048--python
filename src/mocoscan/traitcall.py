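"""Trait calling: Moco pathway, Mo-utilization category, transporters,
orphan classes, molybdoprotein richness and tungstoprotein prediction.

The verdict logic operationalizes the classic three-step view of Moco
biosynthesis (GTP -> cPMP -> molybdopterin -> metal insertion): the
pathway is called present when at least one gene from each step is found
AND a majority of the seven key genes (moaA, moaC, moaD, moaE, moeB,
moeA, mogA) is present.  The Mo utilization trait holds when the pathway
co-occurs with at least one Moco-dependent molybdoenzyme, or when
nitrogenase is present.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd

from .homology import OrthologAssignment
from .iocore import OrganismMetadata
from .registry import (
    ABC_TRANSPORTERS,
    DMSOR_SUBFAMILIES,
    ENZYME_FAMILIES,
    MOT_TRANSPORTERS,
    NITROGENASE_FAMILY,
    NITROGENASE_LABEL,
    PATHWAY_KEY_GENES,
    PATHWAY_STEPS,
)

log = logging.getLogger(__name__)

CATEGORIES = ("both", "moco_only", "nif_only", "none")
ORPHAN_CLASSES = ("none", "pathway_no_enzyme", "enzyme_no_pathway")

#: tungstoprotein rule identifiers
W_RULE_AOR = "AOR"
W_RULE_FDH_ACH = "FDH_ACH_anaerobe"
W_RULE_FWD = "FWD_methanogen"
W_RULE_NONE = "none"


@dataclass(frozen=True)
class GenePresenceProfile:
    """Per-organism map from canonical gene label to assigned-protein count.

    Enzyme-family members are counted both under their subfamily label
    (e.g. FDH) and under the family label (DMSOR); compound labels from
    bifunctional seeds (moeA+mogA) count toward every component label.
    """

    organism_id: str
    present: Mapping[str, int] = field(default_factory=dict)

    def count(self, label: str) -> int:
        return int(self.present.get(label, 0))

    def has(self, label: str) -> bool:
        return self.count(label) > 0

    @classmethod
    def from_assignments(
        cls, organism_id: str, assignments: Iterable[OrthologAssignment]
    ) -> "GenePresenceProfile":
        counts: dict[str, int] = {}

        def bump(label: str) -> None:
            counts[label] = counts.get(label, 0) + 1

        for a in assignments:
            if a.organism_id != organism_id:
                continue
            for part in a.gene_label.split("+"):
                bump(part)
            # subfamily members also count toward the family label
            if a.family_id in ENZYME_FAMILIES and a.gene_label != a.family_id:
                bump(a.family_id)
            if a.family_id == NITROGENASE_FAMILY and a.gene_label != NITROGENASE_LABEL:
                bump(NITROGENASE_LABEL)
        return cls(organism_id=organism_id, present=counts)

    def molybdoproteome_size(self, include_nitrogenase: bool = False) -> int:
        """Number of molybdoprotein genes (enzyme-family members)."""
        size = sum(self.count(f) for f in ENZYME_FAMILIES)
        if include_nitrogenase:
            size += self.count(NITROGENASE_LABEL)
        return size


@dataclass(frozen=True)
class PathwayCall:
    """Moco biosynthetic pathway verdict with per-step breakdown."""

    step1: bool
    step2: bool
    step3: bool
    n_key_genes: int
    present: bool


@dataclass(frozen=True)
class TraitCall:
    """Per-organism Mo utilization verdict."""

    organism_id: str
    pathway: PathwayCall
    moco_enzyme: bool
    nitrogenase: bool
    category: str
    orphan_class: str
    proteome_size: int
    rich: bool
    transporters: frozenset[str] = frozenset()

    @property
    def mo_utilizing(self) -> bool:
        return self.category != "none"


def call_moco_pathway(
    profile: GenePresenceProfile, pathway_majority: int = 4
) -> PathwayCall:
    """Three-step presence rule layered with a key-gene majority.

    step1 <=> moaA or moaC; step2 <=> moaD, moaE or moeB;
    step3 <=> moeA or mogA; pathway <=> all steps and at least
    ``pathway_majority`` of the seven key genes present.
    """
    steps = {
        i: any(profile.has(g) for g in genes) for i, genes in PATHWAY_STEPS.items()
    }
    n_key = sum(1 for g in PATHWAY_KEY_GENES if profile.has(g))
    present = steps[1] and steps[2] and steps[3] and n_key >= pathway_majority
    return PathwayCall(
        step1=steps[1], step2=steps[2], step3=steps[3],
        n_key_genes=n_key, present=present,
    )


def moco_enzyme_present(
    profile: GenePresenceProfile, include_aor: bool = True
) -> bool:
    """At least one member of a Moco-dependent molybdoenzyme family.

    AOR is tungsten-specific but counted by default because the cofactor
    chemistry is shared; pass ``include_aor=False`` for a strict-Mo call.
    """
    fams = ENZYME_FAMILIES if include_aor else tuple(
        f for f in ENZYME_FAMILIES if f != "AOR"
    )
    return any(profile.has(f) for f in fams)


def call_transporters(profile: GenePresenceProfile, kingdom: str) -> frozenset[str]:
    """Transport systems present in one organism.

    An ABC system needs its substrate-binding A subunit plus at least one
    of the B/C subunits; MOT carriers are single genes.  ABC calls are
    prokaryote-only and MOT calls eukaryote-only.
    """
    found: set[str] = set()
    if kingdom in ("archaea", "bacteria"):
        for system, (a, b, c) in ABC_TRANSPORTERS.items():
            if profile.has(a) and (profile.has(b) or profile.has(c)):
                found.add(system)
    elif kingdom == "eukaryota":
        for system, gene in MOT_TRANSPORTERS.items():
            if profile.has(gene):
                found.add(system)
    return frozenset(found)


def call_mo_utilization(
    profile: GenePresenceProfile,
    kingdom: str,
    pathway_majority: int = 4,
    rich_threshold: int = 20,
    include_aor: bool = True,
    include_nitrogenase_in_proteome: bool = False,
) -> TraitCall:
    """Full per-organism trait verdict.

    Category: ``both`` if pathway+enzyme and nitrogenase; ``moco_only``
    if pathway+enzyme without nitrogenase; ``nif_only`` if nitrogenase
    without the complete Moco trait; otherwise ``none``.
    """
    pathway = call_moco_pathway(profile, pathway_majority)
    enzyme = moco_enzyme_present(profile, include_aor)
    nif = profile.has(NITROGENASE_LABEL)
    moco_trait = pathway.present and enzyme
    if moco_trait and nif:
        category = "both"
    elif moco_trait:
        category = "moco_only"
    elif nif:
        category = "nif_only"
    else:
        category = "none"
    if pathway.present and not enzyme:
        orphan = "pathway_no_enzyme"
    elif enzyme and not pathway.present:
        orphan = "enzyme_no_pathway"
    else:
        orphan = "none"
    size = profile.molybdoproteome_size(include_nitrogenase_in_proteome)
    return TraitCall(
        organism_id=profile.organism_id,
        pathway=pathway,
        moco_enzyme=enzyme,
        nitrogenase=nif,
        category=category,
        orphan_class=orphan,
        proteome_size=size,
        rich=is_rich(size, rich_threshold),
        transporters=call_transporters(profile, kingdom),
    )


def is_rich(proteome_size: int, rich_threshold: int = 20) -> bool:
    """Molybdoprotein-rich: strictly more than ``rich_threshold`` genes."""
    if proteome_size < 0:
        raise ValueError("proteome_size must be >= 0")
    return proteome_size > rich_threshold


def classify_orphans(calls: Iterable[TraitCall]) -> pd.DataFrame:
    """Cross partial-trait organisms by nitrogenase status (2x2 counts).

    Rows: pathway-without-enzyme and enzyme-without-pathway; columns:
    nitrogenase present/absent.  Organisms with both pathway and enzyme,
    or with neither, contribute to no cell.
    """
    table = pd.DataFrame(
        0,
        index=["pathway_no_enzyme", "enzyme_no_pathway"],
        columns=["nif_pos", "nif_neg"],
    )
    for call in calls:
        if call.orphan_class == "none":
            continue
        col = "nif_pos" if call.nitrogenase else "nif_neg"
        table.loc[call.orphan_class, col] += 1
    return table


@dataclass(frozen=True)
class TungstoLabel:
    """Per-protein tungstoprotein prediction."""

    protein_id: str
    organism_id: str
    family_id: str
    gene_label: str
    predicted_w: bool
    rule_fired: str

    def __post_init__(self) -> None:
        if self.predicted_w != (self.rule_fired != W_RULE_NONE):
            raise ValueError("predicted_w inconsistent with rule_fired")


def predict_tungstoproteins(
    assignments: Sequence[OrthologAssignment],
    metadata: Mapping[str, OrganismMetadata],
) -> list[TungstoLabel]:
    """Label possible tungstoproteins by three ecology-based rules:

    (i) any AOR member; (ii) FDH/ACH orthologs in strictly anaerobic
    bacteria; (iii) FWD orthologs in methanogenic archaea.  "Strictly
    anaerobic" is read as oxygen_req == anaerobic; methanogens are
    recognized from the taxon path.
    """
    labels: list[TungstoLabel] = []
    for a in assignments:
        meta = metadata.get(a.organism_id)
        rule = W_RULE_NONE
        if a.family_id == "AOR":
            rule = W_RULE_AOR
        elif a.family_id == "DMSOR" and meta is not None:
            if (
                a.gene_label in ("FDH", "ACH")
                and meta.kingdom == "bacteria"
                and meta.oxygen_req == "anaerobic"
            ):
                rule = W_RULE_FDH_ACH
            elif (
                a.gene_label == "FWD"
                and meta.kingdom == "archaea"
                and meta.is_methanogen
            ):
                rule = W_RULE_FWD
        elif a.family_id == "DMSOR" and a.gene_label not in DMSOR_SUBFAMILIES:
            log.warning(
                "protein %s: DMSOR member without subfamily label; "
                "tungstoprotein rules (ii)/(iii) cannot fire", a.protein_id,
            )
        labels.append(
            TungstoLabel(
                protein_id=a.protein_id,
                organism_id=a.organism_id,
                family_id=a.family_id,
                gene_label=a.gene_label,
                predicted_w=rule != W_RULE_NONE,
                rule_fired=rule,
            )
        )
    return labels
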