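"""Seed registry for Mo/W utilization screening.

The registry is a small curated table of query ("seed") proteins used to
screen proteomes by homology.  Each row ties one seed sequence to a gene
family and a canonical gene label:

* the seven key molybdenum-cofactor (Moco) biosynthesis genes
  (moaA, moaC, moaD, moaE, moeB, moeA, mogA), plus accessory mobA;
* molybdate/tungstate ABC transporter subunits (ModABC, WtpABC, TupABC)
  and the eukaryotic carriers MOT1/MOT2;
* the five molybdoenzyme families (SO, XO, DMSOR, AOR, MOSC), with DMSOR
  subfamily labels (FDH, ACH, FWD, NarG) that the tungstoprotein rules need;
* Fe-Mo nitrogenase;
* exclusion seeds: Mo-independent homologs (NuoG for DMSOR, NifE for
  nitrogenase) whose best-hit status vetoes an assignment.

Eukaryotic Moco biosynthesis is screened with the plant CNX proteins; the
bifunctional CNX1 carries the compound label ``moeA+mogA`` and satisfies
both canonical labels at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

PATHWAY_KEY_GENES: tuple[str, ...] = (
    "moaA", "moaC", "moaD", "moaE", "moeB", "moeA", "mogA",
)

#: step index -> gene labels; at least one gene per step is required.
PATHWAY_STEPS: dict[int, tuple[str, ...]] = {
    1: ("moaA", "moaC"),
    2: ("moaD", "moaE", "moeB"),
    3: ("moeA", "mogA"),
}

ENZYME_FAMILIES: tuple[str, ...] = ("SO", "XO", "DMSOR", "AOR", "MOSC")

#: DMSOR subfamily gene labels (all count toward the DMSOR family).
DMSOR_SUBFAMILIES: tuple[str, ...] = ("FDH", "ACH", "FWD", "NarG", "DMSOR")

NITROGENASE_FAMILY = "Nitrogenase"
NITROGENASE_LABEL = "nif"

#: ABC transport system -> (substrate-binding A subunit, B, C subunits)
ABC_TRANSPORTERS: dict[str, tuple[str, str, str]] = {
    "ModABC": ("modA", "modB", "modC"),
    "WtpABC": ("wtpA", "wtpB", "wtpC"),
    "TupABC": ("tupA", "tupB", "tupC"),
}

#: eukaryotic carrier systems -> single gene label
MOT_TRANSPORTERS: dict[str, str] = {"MOT1": "mot1", "MOT2": "mot2"}

TRANSPORTER_SYSTEMS: tuple[str, ...] = ("ModABC", "WtpABC", "TupABC", "MOT1", "MOT2")

ROLE_MEMBER = "member"
ROLE_EXCLUSION = "exclusion"

REGISTRY_COLUMNS = ("family_id", "gene_label", "seed_id", "role", "seed_length")

# family_id, gene_label, seed_id, role, seed length (residues)
_DEFAULT_ROWS: list[tuple[str, str, str, str, int]] = [
    # --- Moco biosynthesis, prokaryotic seeds (E. coli operons) ---
    ("MoaA", "moaA", "ECOLI_MoaA", ROLE_MEMBER, 329),
    ("MoaC", "moaC", "ECOLI_MoaC", ROLE_MEMBER, 161),
    ("MoaD", "moaD", "ECOLI_MoaD", ROLE_MEMBER, 81),
    ("MoaE", "moaE", "ECOLI_MoaE", ROLE_MEMBER, 150),
    ("MoeB", "moeB", "ECOLI_MoeB", ROLE_MEMBER, 249),
    ("MoeA", "moeA", "ECOLI_MoeA", ROLE_MEMBER, 411),
    ("MogA", "mogA", "ECOLI_MogA", ROLE_MEMBER, 195),
    ("MobA", "mobA", "ECOLI_MobA", ROLE_MEMBER, 194),
    # --- Moco biosynthesis, eukaryotic seeds (A. thaliana CNX) ---
    ("MoaA", "moaA", "ATHAL_CNX2", ROLE_MEMBER, 370),
    ("MoaC", "moaC", "ATHAL_CNX3", ROLE_MEMBER, 271),
    ("MoaD", "moaD", "ATHAL_CNX7", ROLE_MEMBER, 110),
    ("MoaE", "moaE", "ATHAL_CNX6", ROLE_MEMBER, 201),
    ("MoeB", "moeB", "ATHAL_CNX5", ROLE_MEMBER, 465),
    # bifunctional: one protein covers metal-insertion steps moeA and mogA
    ("MoeA", "moeA+mogA", "ATHAL_CNX1", ROLE_MEMBER, 670),
    # --- Mo/W ABC transport systems ---
    ("ModABC", "modA", "ECOLI_ModA", ROLE_MEMBER, 257),
    ("ModABC", "modB", "ECOLI_ModB", ROLE_MEMBER, 229),
    ("ModABC", "modC", "ECOLI_ModC", ROLE_MEMBER, 352),
    ("WtpABC", "wtpA", "PYRFU_WtpA", ROLE_MEMBER, 319),
    ("WtpABC", "wtpB", "PYRFU_WtpB", ROLE_MEMBER, 260),
    ("WtpABC", "wtpC", "PYRFU_WtpC", ROLE_MEMBER, 341),
    ("TupABC", "tupA", "EUBAC_TupA", ROLE_MEMBER, 281),
    ("TupABC", "tupB", "EUBAC_TupB", ROLE_MEMBER, 226),
    ("TupABC", "tupC", "EUBAC_TupC", ROLE_MEMBER, 334),
    # --- eukaryotic molybdate carriers ---
    ("MOT1", "mot1", "ATHAL_MOT1", ROLE_MEMBER, 456),
    ("MOT2", "mot2", "CHLRE_MOT2", ROLE_MEMBER, 550),
    # --- molybdoenzyme families ---
    ("SO", "SO", "ECOLI_YedY", ROLE_MEMBER, 334),
    ("SO", "SO", "HUMAN_SUOX", ROLE_MEMBER, 545),
    ("SO", "SO", "ATHAL_NIA1", ROLE_MEMBER, 917),
    ("XO", "XO", "ECOLI_XdhA", ROLE_MEMBER, 752),
    ("XO", "XO", "HUMAN_XDH", ROLE_MEMBER, 1333),
    ("DMSOR", "DMSOR", "ECOLI_DmsA", ROLE_MEMBER, 814),
    ("DMSOR", "FDH", "ECOLI_FdhF", ROLE_MEMBER, 715),
    ("DMSOR", "ACH", "PELAC_Ach", ROLE_MEMBER, 730),
    ("DMSOR", "FWD", "METTH_FwdB", ROLE_MEMBER, 437),
    ("DMSOR", "NarG", "ECOLI_NarG", ROLE_MEMBER, 1247),
    ("AOR", "AOR", "PYRFU_AOR", ROLE_MEMBER, 605),
    ("MOSC", "MOSC", "ECOLI_YcbX", ROLE_MEMBER, 369),
    ("MOSC", "MOSC", "HUMAN_MARC1", ROLE_MEMBER, 337),
    ("Nitrogenase", "nif", "AZOVI_NifD", ROLE_MEMBER, 492),
    # --- exclusion seeds: Mo-independent homologs ---
    ("DMSOR", "NuoG", "ECOLI_NuoG", ROLE_EXCLUSION, 908),
    ("Nitrogenase", "NifE", "AZOVI_NifE", ROLE_EXCLUSION, 478),
]


@dataclass(frozen=True)
class SeedFamily:
    """One gene family with its member and exclusion seed sequences."""

    family_id: str
    gene_labels: frozenset[str] = field(default_factory=frozenset)
    member_seed_ids: frozenset[str] = field(default_factory=frozenset)
    exclusion_seed_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.member_seed_ids & self.exclusion_seed_ids:
            raise ValueError(
                f"family {self.family_id!r}: exclusion seeds overlap member seeds"
            )


def default_registry() -> pd.DataFrame:
    """Return the built-in seed registry as a DataFrame."""
    return pd.DataFrame(_DEFAULT_ROWS, columns=list(REGISTRY_COLUMNS))


def seed_index(registry: pd.DataFrame) -> dict[str, tuple[str, str, str]]:
    """Map seed_id -> (family_id, gene_label, role)."""
    idx: dict[str, tuple[str, str, str]] = {}
    for row in registry.itertuples(index=False):
        if row.seed_id in idx:
            raise ValueError(f"duplicate seed_id {row.seed_id!r} in registry")
        idx[row.seed_id] = (row.family_id, row.gene_label, row.role)
    return idx


def seed_lengths(registry: pd.DataFrame) -> dict[str, int]:
    """Map seed_id -> full-length residue count (for query coverage)."""
    return {r.seed_id: int(r.seed_length) for r in registry.itertuples(index=False)}


def families(registry: pd.DataFrame) -> dict[str, SeedFamily]:
    """Group the registry into :class:`SeedFamily` records."""
    out: dict[str, SeedFamily] = {}
    for fam, grp in registry.groupby("family_id", sort=True):
        members = grp[grp["role"] == ROLE_MEMBER]
        excl = grp[grp["role"] == ROLE_EXCLUSION]
        out[str(fam)] = SeedFamily(
            family_id=str(fam),
            gene_labels=frozenset(members["gene_label"]),
            member_seed_ids=frozenset(members["seed_id"]),
            exclusion_seed_ids=frozenset(excl["seed_id"]),
        )
    return out


def seeds_for_label(registry: pd.DataFrame, gene_label: str) -> list[str]:
    """Member seed ids carrying a canonical label (compound labels match parts)."""
    hits = []
    for row in registry.itertuples(index=False):
        if row.role != ROLE_MEMBER:
            continue
        if gene_label in row.gene_label.split("+"):
            hits.append(row.seed_id)
    return hits


def write_registry(registry: pd.DataFrame, path) -> None:
    registry.to_csv(path, sep="\t", index=False)


def read_registry(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"seed_length": int})
    missing = set(REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"registry missing columns: {sorted(missing)}")
    seed_index(df)  # validates uniqueness
    return df[list(REGISTRY_COLUMNS)]
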