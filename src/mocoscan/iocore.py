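"""Readers/writers for external formats, run configuration and metadata.

All tables are plain tab-delimited text; sequences travel as (aligned)
FASTA.  Hit tables use the header-less 12-column tabular dialect of
protein homology searches, with 1-based inclusive coordinates.
"""

from __future__ import annotations

import csv
import dataclasses
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .homology import HitRecord

KINGDOMS = ("archaea", "bacteria", "eukaryota")
HABITATS = ("host-associated", "aquatic", "terrestrial", "multiple", "specialized")
OXYGEN_REQS = ("anaerobic", "facultative", "microaerophilic", "aerobic")
UNKNOWN = "unknown"


class ParseError(ValueError):
    """A malformed external file."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


class PipelineStageError(RuntimeError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class OrganismMetadata:
    """Taxonomic and environmental annotation for one organism."""

    organism_id: str
    kingdom: str
    taxon_path: tuple[str, ...] = ()
    habitat: str = UNKNOWN
    oxygen_req: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise ValidationError(
                f"organism {self.organism_id!r}: unknown kingdom {self.kingdom!r}"
            )
        if self.habitat not in HABITATS + (UNKNOWN,):
            raise ValidationError(
                f"organism {self.organism_id!r}: unknown habitat {self.habitat!r}"
            )
        if self.oxygen_req not in OXYGEN_REQS + (UNKNOWN,):
            raise ValidationError(
                f"organism {self.organism_id!r}: unknown oxygen_req {self.oxygen_req!r}"
            )

    @property
    def is_methanogen(self) -> bool:
        """True if any taxon rank names a methanogenic clade."""
        return any("methano" in t.lower() for t in self.taxon_path)


@dataclass
class AnalysisConfig:
    """Thresholds and options shared across pipeline stages.

    evalue_max / coverage_min are the homology-filter cutoffs (e-value
    0.01, query coverage 20%).  ``rich_threshold`` is the strict
    molybdoprotein-gene count above which an organism is molybdoprotein-
    rich (>20).  ``pathway_majority`` quantifies "most of the key genes"
    for the Moco pathway call (>=4 of 7).  ``hgt_min_trees`` is the
    number of concordant foreign-sister gene trees needed to flag a
    horizontal transfer candidate.
    """

    evalue_max: float = 0.01
    coverage_min: float = 0.20
    rich_threshold: int = 20
    pathway_majority: int = 4
    hgt_min_trees: int = 3
    percent_decimals: int = 1
    env_percent_decimals: int = 2
    include_aor_as_moco_enzyme: bool = True
    count_nitrogenase_in_proteome: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.evalue_max > 0:
            raise ValidationError("evalue_max must be > 0")
        if not 0 <= self.coverage_min <= 1:
            raise ValidationError("coverage_min must be in [0, 1]")
        if self.rich_threshold < 0:
            raise ValidationError("rich_threshold must be >= 0")
        if self.hgt_min_trees < 1:
            raise ValidationError("hgt_min_trees must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValidationError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# hit tables (12-column tabular dialect)

_HIT_FIELDS = (
    ("query_id", str), ("subject_id", str), ("percent_identity", float),
    ("aln_length", int), ("mismatches", int), ("gap_opens", int),
    ("qstart", int), ("qend", int), ("sstart", int), ("send", int),
    ("evalue", float), ("bitscore", float),
)


def read_hit_table(path) -> list[HitRecord]:
    """Parse a header-less 12-column tab-separated hit file, order preserved."""
    records: list[HitRecord] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if len(row) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(row)}"
                )
            kwargs = {}
            for (name, conv), value in zip(_HIT_FIELDS, row):
                try:
                    kwargs[name] = conv(value)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: bad {name} value {value!r}"
                    ) from exc
            records.append(HitRecord(**kwargs))
    return records


def write_hit_table(hits: Iterable[HitRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            writer.writerow([
                h.query_id, h.subject_id, h.percent_identity, h.aln_length,
                h.mismatches, h.gap_opens, h.qstart, h.qend, h.sstart, h.send,
                h.evalue, h.bitscore,
            ])


def read_length_table(path) -> dict[str, int]:
    """Companion table of full query lengths: two columns (id, residues)."""
    lengths: dict[str, int] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if len(row) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            try:
                lengths[row[0]] = int(row[1])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad length {row[1]!r}") from exc
    return lengths


def write_length_table(lengths: Mapping[str, int], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for key in sorted(lengths):
            writer.writerow([key, lengths[key]])


# ---------------------------------------------------------------------------
# organism metadata

_META_COLUMNS = ("organism_id", "kingdom", "taxon_path", "habitat", "oxygen_req")


def _norm_vocab(value, vocab: tuple[str, ...]) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return UNKNOWN
    token = str(value).strip().lower()
    return token if token in vocab else UNKNOWN


def read_metadata(path) -> list[OrganismMetadata]:
    """Read a tab-delimited metadata table with named columns.

    Habitat/oxygen values are case-normalized; blank or out-of-vocabulary
    values map to "unknown".  Duplicate organism ids and unknown kingdom
    tokens are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    dupes = df["organism_id"][df["organism_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate organism_id values: {dupes}")
    out: list[OrganismMetadata] = []
    for row in df.itertuples(index=False):
        kingdom = str(row.kingdom).strip().lower()
        if kingdom not in KINGDOMS:
            raise ValidationError(
                f"{path}: organism {row.organism_id!r}: unknown kingdom {row.kingdom!r}"
            )
        taxon_path = tuple(t for t in str(row.taxon_path).split(";") if t)
        out.append(
            OrganismMetadata(
                organism_id=str(row.organism_id),
                kingdom=kingdom,
                taxon_path=taxon_path,
                habitat=_norm_vocab(row.habitat, HABITATS),
                oxygen_req=_norm_vocab(row.oxygen_req, OXYGEN_REQS),
            )
        )
    return out


def write_metadata(metadata: Iterable[OrganismMetadata], path) -> None:
    rows = [
        {
            "organism_id": m.organism_id,
            "kingdom": m.kingdom,
            "taxon_path": ";".join(m.taxon_path),
            "habitat": m.habitat,
            "oxygen_req": m.oxygen_req,
        }
        for m in metadata
    ]
    pd.DataFrame(rows, columns=list(_META_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# domain-hit tables

_DOMAIN_COLUMNS = ("protein_id", "domain_id", "start", "end", "score", "evalue")


def read_domain_table(path):
    """Read a domain-hit table (protein_id, domain_id, start, end, score, evalue)."""
    from .fusion import DomainHit

    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domain_id": str})
    missing = set(_DOMAIN_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing domain columns {sorted(missing)}")
    return [
        DomainHit(
            protein_id=r.protein_id,
            domain_id=r.domain_id,
            start=int(r.start),
            end=int(r.end),
            score=float(r.score),
            evalue=float(r.evalue),
        )
        for r in df.itertuples(index=False)
    ]


def write_domain_table(hits, path) -> None:
    rows = [
        {
            "protein_id": h.protein_id, "domain_id": h.domain_id,
            "start": h.start, "end": h.end, "score": h.score, "evalue": h.evalue,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=list(_DOMAIN_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# aligned FASTA

def read_alignment(path) -> dict[str, str]:
    """Read an aligned FASTA file into an id -> sequence map."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValidationError(f"{path}: aligned sequences differ in length")
    return seqs


def write_alignment(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
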