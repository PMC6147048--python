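"""Summary surfaces: occurrence percentages, transporter overlap (Venn)
tables, molybdoproteome size distributions and family-occurrence tables.

Percentages are computed with round-half-up at a configurable number of
decimals so that printed one-decimal values (97.3%, 88.8%, ...) come out
of integer counts reproducibly.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from collections.abc import Set as AbstractSet
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import chain, combinations

import pandas as pd

from .homology import OrthologAssignment
from .iocore import OrganismMetadata
from .traitcall import GenePresenceProfile, TraitCall
from .registry import ENZYME_FAMILIES


class ConsistencyError(RuntimeError):
    """An internal identity (e.g. inclusion-exclusion) failed to hold."""


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.05 at 1 decimal -> 0.1)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(n_positive: int, n_total: int, decimals: int = 1) -> float:
    """Share of a group as a printed-style percentage."""
    if n_total <= 0:
        raise ZeroDivisionError("percent undefined for n_total == 0")
    if not 0 <= n_positive <= n_total:
        raise ValueError("n_positive must lie in [0, n_total]")
    return round_half_up(100.0 * n_positive / n_total, decimals)


def occurrence_summary(
    positives: Mapping[str, bool],
    groups: Mapping[str, str],
    decimals: int = 1,
) -> pd.DataFrame:
    """Per-group positive counts and percentages.

    ``positives`` maps organism -> flag, ``groups`` maps organism ->
    grouping key (kingdom, taxon, ...).  Groups with zero members yield
    NaN percent rather than a division.
    """
    rows = []
    for group in sorted(set(groups.values())):
        members = [o for o, g in groups.items() if g == group]
        n_total = len(members)
        n_pos = sum(1 for o in members if positives.get(o, False))
        rows.append(
            {
                "group": group,
                "n_total": n_total,
                "n_positive": n_pos,
                "percent": percent(n_pos, n_total, decimals) if n_total else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n_total", "n_positive", "percent"])


@dataclass(frozen=True)
class OverlapTable:
    """Exact region counts for a small family of sets (Venn arithmetic).

    ``region_counts`` maps each non-empty label subset S to the number of
    elements belonging to exactly the sets in S.
    """

    labels: tuple[str, ...]
    region_counts: Mapping[frozenset, int]
    none_count: int
    union_count: int
    total: int

    def exactly(self, *labels: str) -> int:
        return int(self.region_counts.get(frozenset(labels), 0))

    def at_least(self, *labels: str) -> int:
        """Elements in the intersection of the named sets (superset regions)."""
        want = frozenset(labels)
        return sum(
            n for region, n in self.region_counts.items() if want <= region
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": "&".join(sorted(region)),
                "n_exact": n,
            }
            for region, n in sorted(
                self.region_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        rows.append({"region": "(none)", "n_exact": self.none_count})
        return pd.DataFrame(rows, columns=["region", "n_exact"])


def transporter_overlap(
    memberships: Mapping[str, AbstractSet[str]],
    universe: AbstractSet[str],
) -> OverlapTable:
    """Exact-region overlap table for transporter (or any) set memberships.

    Verifies the inclusion-exclusion identity (union + none == total)
    before returning; a violation indicates an upstream bug.
    """
    labels = tuple(sorted(memberships))
    for label, members in memberships.items():
        stray = set(members) - set(universe)
        if stray:
            raise ConsistencyError(
                f"set {label!r} contains elements outside the universe: {sorted(stray)[:5]}"
            )
    region_counts: dict[frozenset, int] = {}
    for subset in chain.from_iterable(
        combinations(labels, k) for k in range(1, len(labels) + 1)
    ):
        inside = set(universe)
        for lab in subset:
            inside &= set(memberships[lab])
        for lab in set(labels) - set(subset):
            inside -= set(memberships[lab])
        region_counts[frozenset(subset)] = len(inside)
    union = set().union(*(set(m) for m in memberships.values())) if memberships else set()
    none_count = len(set(universe) - union)
    if sum(region_counts.values()) + none_count != len(universe):
        raise ConsistencyError("inclusion-exclusion identity violated")
    return OverlapTable(
        labels=labels,
        region_counts=region_counts,
        none_count=none_count,
        union_count=len(union),
        total=len(universe),
    )


def proteome_sizes(
    assignments: Iterable[OrthologAssignment],
    organism_ids: Iterable[str],
    include_nitrogenase: bool = False,
) -> pd.Series:
    """Molybdoprotein gene count per organism (zero for absent organisms)."""
    families = set(ENZYME_FAMILIES)
    if include_nitrogenase:
        families.add("Nitrogenase")
    counts = {org: 0 for org in organism_ids}
    for a in assignments:
        if a.family_id in families and a.organism_id in counts:
            counts[a.organism_id] += 1
    return pd.Series(counts, name="proteome_size").sort_index()


def largest_proteomes(sizes: pd.Series) -> list[tuple[str, int]]:
    """Argmax organisms (ties reported together, sorted by id)."""
    if sizes.empty:
        return []
    top = int(sizes.max())
    return [(org, top) for org in sorted(sizes.index[sizes == top])]


def sizes_by_clade(
    sizes: pd.Series,
    metadata: Mapping[str, OrganismMetadata],
    ranks: int = 2,
) -> pd.DataFrame:
    """Distribution summary of proteome sizes per clade (first taxon ranks)."""
    rows = []
    clades: dict[str, list[int]] = {}
    for org, size in sizes.items():
        meta = metadata.get(org)
        clade = "/".join(meta.taxon_path[:ranks]) if meta else "(unknown)"
        clades.setdefault(clade, []).append(int(size))
    for clade in sorted(clades):
        vals = clades[clade]
        rows.append(
            {
                "clade": clade,
                "n_organisms": len(vals),
                "mean_size": round_half_up(sum(vals) / len(vals), 2),
                "max_size": max(vals),
            }
        )
    return pd.DataFrame(rows, columns=["clade", "n_organisms", "mean_size", "max_size"])


def family_occurrence(
    calls: Sequence[TraitCall],
    profiles: Mapping[str, GenePresenceProfile],
    metadata: Mapping[str, OrganismMetadata],
    kingdom: str,
    decimals: int = 1,
) -> pd.DataFrame:
    """Per-family occurrence among the kingdom's Mo-utilizing organisms."""
    utilizers = [
        c.organism_id
        for c in calls
        if c.mo_utilizing
        and c.organism_id in metadata
        and metadata[c.organism_id].kingdom == kingdom
    ]
    n = len(utilizers)
    rows = []
    for family in ENZYME_FAMILIES + ("Nitrogenase",):
        label = "nif" if family == "Nitrogenase" else family
        n_with = sum(1 for org in utilizers if profiles[org].has(label))
        rows.append(
            {
                "family": family,
                "n_mo_utilizing": n,
                "n_with_family": n_with,
                "percent": percent(n_with, n, decimals) if n else math.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["family", "n_mo_utilizing", "n_with_family", "percent"]
    )
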