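"""Domain-architecture tiling and molybdoprotein fusion detection.

A protein's domain architecture is resolved by greedy score-descending
tiling of its domain hits (near-disjoint intervals, small overlap
tolerated for boundary jitter).  A fusion event is a protein that couples
the catalytic domain of exactly one molybdoprotein family with at least
one additional, non-catalytic partner domain.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from collections.abc import Set as AbstractSet
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

#: molybdoprotein family -> catalytic (Moco/W-binding) domain accessions
CATALYTIC_DOMAINS: dict[str, frozenset[str]] = {
    "SO": frozenset({"pfam00174"}),       # Mo-co oxidoreductase domain
    "XO": frozenset({"pfam02738"}),       # Ald_Xan_dh_C2 Moco-binding domain
    "DMSOR": frozenset({"pfam00384"}),    # molybdopterin oxidoreductase
    "AOR": frozenset({"pfam01314"}),      # AFOR catalytic domain
    "MOSC": frozenset({"pfam03473"}),     # MOSC domain
}

#: partner domains with an established functional link to molybdoproteins
#: or Moco biosynthesis (reported separately from novel partners).
KNOWN_PARTNER_DOMAINS: frozenset[str] = frozenset(
    {
        "pfam00941",  # XDH/AO FAD-binding subunit
        "pfam02613",  # nitrate reductase delta subunit
        "pfam03892",  # nitrate reductase gamma subunit
        "pfam00266",  # cysteine desulfurase (sulfur donor for Moco)
    }
)

#: novel partner domain -> molybdoprotein families it fuses with
#: (descriptions kept for reports).
NOVEL_PARTNER_FAMILIES: dict[str, tuple[str, ...]] = {
    "pfam13442": ("DMSOR", "SO", "XO"),   # cytochrome C oxidase cbb3-type su III
    "pfam03157": ("DMSOR", "SO", "XO"),   # high molecular weight glutenin subunit
    "pfam15449": ("DMSOR", "XO"),         # retinal protein, unknown function
    "COG0493": ("DMSOR",),                # NADPH-dependent glutamate synthase beta
    "COG4117": ("SO",),                   # thiosulfate reductase cytochrome b
    "COG1357": ("SO",),                   # uncharacterized protein YjbI
    "COG0518": ("DMSOR",),                # GMP synthase glutamine amidotransferase
    "pfam05887": ("DMSOR",),              # procyclic acidic repetitive protein
    "COG2197": ("DMSOR",),                # NarL/FixJ-family response regulator
}


@dataclass(frozen=True)
class DomainHit:
    """One domain match on a protein (1-based inclusive residues)."""

    protein_id: str
    domain_id: str
    start: int
    end: int
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"domain hit {self.domain_id} on {self.protein_id}: start > end")

    def overlap(self, other: "DomainHit") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass(frozen=True)
class DomainArchitecture:
    """Accepted, near-disjoint domain intervals of one protein, by position."""

    protein_id: str
    domains: tuple[DomainHit, ...]

    @property
    def domain_ids(self) -> tuple[str, ...]:
        return tuple(d.domain_id for d in self.domains)


@dataclass(frozen=True)
class FusionEvent:
    """A molybdoprotein catalytic domain fused to a partner domain."""

    protein_id: str
    organism_id: str
    family_id: str
    partner_domain: str


def tile_architecture(
    hits: Sequence[DomainHit],
    evalue_max: float = 0.01,
    overlap_tolerance: int = 10,
) -> DomainArchitecture:
    """Greedy score-descending tiling of one protein's domain hits.

    A hit is accepted iff it overlaps every previously accepted hit by at
    most ``overlap_tolerance`` residues.  Ties in score break by lower
    e-value, then smaller start, then domain id, so the result does not
    depend on input order.
    """
    proteins = {h.protein_id for h in hits}
    if len(proteins) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(proteins)}")
    candidates = sorted(
        (h for h in hits if h.evalue <= evalue_max),
        key=lambda h: (-h.score, h.evalue, h.start, h.domain_id),
    )
    accepted: list[DomainHit] = []
    for hit in candidates:
        if all(hit.overlap(a) <= overlap_tolerance for a in accepted):
            accepted.append(hit)
    accepted.sort(key=lambda h: (h.start, h.end, h.domain_id))
    return DomainArchitecture(
        protein_id=next(iter(proteins)) if proteins else "",
        domains=tuple(accepted),
    )


def detect_fusions(
    architectures: Iterable[DomainArchitecture],
    protein_organisms: Mapping[str, str],
    catalytic_domains: Mapping[str, AbstractSet[str]] | None = None,
) -> list[FusionEvent]:
    """Emit one event per (protein, partner domain) fusion.

    A protein qualifies when its architecture carries catalytic domains
    of exactly one molybdoprotein family plus at least one non-catalytic
    partner domain.  Proteins with catalytic domains of two or more
    families are logged and skipped.
    """
    registry = catalytic_domains if catalytic_domains is not None else CATALYTIC_DOMAINS
    accession_family = {
        acc: fam for fam, accs in registry.items() for acc in accs
    }
    events: list[FusionEvent] = []
    for arch in architectures:
        fams = {
            accession_family[d] for d in arch.domain_ids if d in accession_family
        }
        if not fams:
            continue
        if len(fams) > 1:
            log.warning(
                "protein %s: catalytic domains of multiple families %s; skipped",
                arch.protein_id, sorted(fams),
            )
            continue
        family = fams.pop()
        partners = sorted(
            {d for d in arch.domain_ids if d not in accession_family}
        )
        for partner in partners:
            events.append(
                FusionEvent(
                    protein_id=arch.protein_id,
                    organism_id=protein_organisms.get(arch.protein_id, ""),
                    family_id=family,
                    partner_domain=partner,
                )
            )
    return events


def cross_family_partners(events: Iterable[FusionEvent]) -> pd.DataFrame:
    """Partner-domain table: families each partner fuses with, and whether
    it recurs across multiple molybdoprotein families."""
    by_domain: dict[str, set[str]] = {}
    n_events: dict[str, int] = {}
    for ev in events:
        by_domain.setdefault(ev.partner_domain, set()).add(ev.family_id)
        n_events[ev.partner_domain] = n_events.get(ev.partner_domain, 0) + 1
    rows = [
        {
            "domain_id": dom,
            "families": ";".join(sorted(fams)),
            "n_families": len(fams),
            "n_events": n_events[dom],
            "multi_family": len(fams) >= 2,
            "known_partner": dom in KNOWN_PARTNER_DOMAINS,
        }
        for dom, fams in sorted(by_domain.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "domain_id", "families", "n_families", "n_events",
            "multi_family", "known_partner",
        ],
    )
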