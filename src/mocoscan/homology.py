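"""Homology-hit filtering, best hits, BBH orthology and family assignment.

Hits are rows of the standard 12-column tabular homology-search output
(query, subject, %identity, alignment length, mismatches, gap opens,
query start/end, subject start/end, e-value, bit score).  The screening
convention here is seed-vs-proteome: the query is a full-length curated
seed protein, the subject a candidate protein, and alignment coverage is
computed on the query side.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HitRecord:
    """One homology-search hit (1-based inclusive coordinates)."""

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: qstart > qend"
            )
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative e-value")
        if self.aln_length <= 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: aln_length <= 0")

    @property
    def query_span(self) -> int:
        return self.qend - self.qstart + 1


@dataclass(frozen=True)
class OrthologAssignment:
    """A protein assigned to a seed family via its best seed hit."""

    organism_id: str
    protein_id: str
    family_id: str
    gene_label: str
    bitscore: float
    reciprocal: bool = False


def query_coverage(hit: HitRecord, query_length: int) -> float:
    """Aligned fraction of the (seed) query, from 1-based inclusive spans."""
    return hit.query_span / query_length


def filter_hits(
    hits: Iterable[HitRecord],
    query_lengths: Mapping[str, int],
    evalue_max: float = 0.01,
    coverage_min: float = 0.20,
) -> list[HitRecord]:
    """Keep hits with evalue <= evalue_max and query coverage >= coverage_min.

    Input order is preserved.  Raises ``KeyError`` naming any query whose
    length is missing from the companion length table.
    """
    kept: list[HitRecord] = []
    for hit in hits:
        if hit.query_id not in query_lengths:
            raise KeyError(f"no query length for {hit.query_id!r}")
        if hit.evalue <= evalue_max and (
            query_coverage(hit, query_lengths[hit.query_id]) >= coverage_min
        ):
            kept.append(hit)
    return kept


def _hit_rank_key(hit: HitRecord) -> tuple[float, float, str]:
    # maximal bitscore; ties -> lower evalue, then lexicographically
    # smaller subject id.  Sort ascending on this key.
    return (-hit.bitscore, hit.evalue, hit.subject_id)


def best_hit(hits: Iterable[HitRecord], query_id: str) -> str | None:
    """Best subject for ``query_id`` (max bitscore; ties: evalue, then id)."""
    candidates = [h for h in hits if h.query_id == query_id]
    if not candidates:
        return None
    return min(candidates, key=_hit_rank_key).subject_id


def bidirectional_best_hits(
    hits_ab: Iterable[HitRecord], hits_ba: Iterable[HitRecord]
) -> set[tuple[str, str]]:
    """Reciprocal best-hit pairs between two filtered hit tables."""
    hits_ab = list(hits_ab)
    hits_ba = list(hits_ba)
    best_fwd = {q: best_hit(hits_ab, q) for q in {h.query_id for h in hits_ab}}
    best_rev = {q: best_hit(hits_ba, q) for q in {h.query_id for h in hits_ba}}
    return {
        (a, b)
        for a, b in best_fwd.items()
        if b is not None and best_rev.get(b) == a
    }


def assign_families(
    hits: Sequence[HitRecord],
    registry_index: Mapping[str, tuple[str, str, str]],
    organism_id: str,
) -> list[OrthologAssignment]:
    """Assign each subject protein to the family of its best seed hit.

    ``registry_index`` maps seed_id -> (family_id, gene_label, role); hits
    must already be filtered.  A protein whose best hit is an exclusion
    seed (a Mo-independent homolog such as NuoG or NifE) is left
    unassigned; so is a protein whose top bitscore is shared by seeds of
    two different families (ambiguous, logged).
    """
    from .registry import ROLE_EXCLUSION

    by_subject: dict[str, list[HitRecord]] = {}
    for hit in hits:
        if hit.query_id not in registry_index:
            raise KeyError(f"hit query {hit.query_id!r} is not a registered seed")
        by_subject.setdefault(hit.subject_id, []).append(hit)

    assignments: list[OrthologAssignment] = []
    for protein_id in sorted(by_subject):
        ranked = sorted(by_subject[protein_id], key=_hit_rank_key)
        top = ranked[0]
        top_families = {
            registry_index[h.query_id][0]
            for h in ranked
            if h.bitscore == top.bitscore
        }
        if len(top_families) > 1:
            log.warning(
                "protein %s: equal top bitscore across families %s; unassigned",
                protein_id, sorted(top_families),
            )
            continue
        family_id, gene_label, role = registry_index[top.query_id]
        if role == ROLE_EXCLUSION:
            log.debug(
                "protein %s: best hit is exclusion seed %s (%s); unassigned",
                protein_id, top.query_id, family_id,
            )
            continue
        assignments.append(
            OrthologAssignment(
                organism_id=organism_id,
                protein_id=protein_id,
                family_id=family_id,
                gene_label=gene_label,
                bitscore=top.bitscore,
            )
        )
    return assignments
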