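"""Synthetic community generator.

Emits organism metadata, per-organism homology hit tables, domain-hit
tables and gene-family alignments whose statistical structure matches
what the downstream analysis assumes, together with ground-truth labels.
Generation is noise-free by default: a present gene always yields one
comfortably-passing hit (e-value at most a tenth of the filter cutoff,
coverage at least twice the minimum) and decoy hits always fail the
filter, so trait calls on generated data must reproduce the truth
exactly.  An optional per-gene dropout emulates incompletely assembled
genomes.

Default scenario sizes and category/transporter/family frequencies mirror
the published census of 5,893 sequenced organisms (256 archaea, 5,387
bacteria, 250 eukaryotes) and its tabulated trait-category, transporter
and enzyme-family counts.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import registry as reg
from .fusion import CATALYTIC_DOMAINS, NOVEL_PARTNER_FAMILIES, DomainHit
from .homology import HitRecord
from .iocore import (
    HABITATS,
    OXYGEN_REQS,
    UNKNOWN,
    OrganismMetadata,
    write_alignment,
    write_domain_table,
    write_hit_table,
    write_length_table,
    write_metadata,
)
from .phylo import AlignedBlock

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_CLADES: dict[str, tuple[tuple[str, ...], ...]] = {
    "archaea": (
        ("Euryarchaeota", "Methanococci"),
        ("Euryarchaeota", "Methanobacteria"),
        ("Euryarchaeota", "Halobacteria"),
        ("Crenarchaeota", "Thermoprotei"),
        ("Thaumarchaeota", "Nitrososphaeria"),
    ),
    "bacteria": (
        ("Proteobacteria", "Gammaproteobacteria"),
        ("Proteobacteria", "Alphaproteobacteria"),
        ("Proteobacteria", "Deltaproteobacteria"),
        ("Firmicutes", "Clostridia"),
        ("Firmicutes", "Erysipelotrichia"),
        ("Firmicutes", "Bacilli"),
        ("Actinobacteria", "Coriobacteriia"),
        ("Cyanobacteria", "Oscillatoriophycideae"),
        ("Bacteroidetes", "Flavobacteriia"),
    ),
    "eukaryota": (
        ("Viridiplantae", "Streptophyta"),
        ("Metazoa", "Arthropoda"),
        ("Fungi", "Pezizomycotina"),
        ("Stramenopiles", "Bacillariophyta"),
        ("Alveolata", "Ciliophora"),
    ),
}

#: trait-category weights per kingdom (published census proportions)
_CATEGORY_WEIGHTS: dict[str, dict[str, float]] = {
    "archaea": {"moco_only": 176 / 256, "nif_only": 7 / 256, "both": 66 / 256,
                "none": 7 / 256},
    "bacteria": {"moco_only": 3120 / 5387, "nif_only": 69 / 5387,
                 "both": 494 / 5387, "none": 1704 / 5387},
    "eukaryota": {"moco_only": 176 / 250, "nif_only": 0.0, "both": 0.0,
                  "none": 74 / 250},
}

#: per-system inclusion probability among Mo-utilizing organisms
_TRANSPORTER_PROBS: dict[str, dict[str, float]] = {
    "archaea": {"ModABC": 74 / 249, "WtpABC": 153 / 249, "TupABC": 124 / 249},
    "bacteria": {"ModABC": 3269 / 3683, "WtpABC": 172 / 3683, "TupABC": 685 / 3683},
    "eukaryota": {"MOT1": 57 / 176, "MOT2": 135 / 176},
}

#: per-family inclusion probability among Mo-utilizing organisms
_ENZYME_PROBS: dict[str, dict[str, float]] = {
    "archaea": {"DMSOR": 0.908, "AOR": 0.723, "SO": 0.715, "MOSC": 0.422, "XO": 0.297},
    "bacteria": {"DMSOR": 0.926, "MOSC": 0.785, "XO": 0.677, "SO": 0.667, "AOR": 0.15},
    "eukaryota": {"MOSC": 0.96, "SO": 0.932, "XO": 0.915, "DMSOR": 0.0, "AOR": 0.0},
}

#: relative member weights when distributing molybdoprotein genes
_FAMILY_SIZE_WEIGHTS: dict[str, dict[str, float]] = {
    "archaea": {"DMSOR": 0.4, "AOR": 0.25, "SO": 0.15, "MOSC": 0.1, "XO": 0.1},
    "bacteria": {"DMSOR": 0.5, "MOSC": 0.15, "XO": 0.15, "SO": 0.15, "AOR": 0.05},
    "eukaryota": {"MOSC": 0.3, "SO": 0.35, "XO": 0.35, "DMSOR": 0.0, "AOR": 0.0},
}

#: negative-binomial (mean, shape) for molybdoproteome sizes per kingdom
_PROTEOME_LAW: dict[str, tuple[float, float]] = {
    "archaea": (6.0, 3.0),
    "bacteria": (10.0, 2.0),
    "eukaryota": (5.0, 5.0),
}

#: marginal habitat / oxygen distributions for metadata
_HABITAT_DIST = {
    "host-associated": 0.35, "aquatic": 0.25, "terrestrial": 0.20,
    "multiple": 0.10, "specialized": 0.05, UNKNOWN: 0.05,
}
_OXYGEN_DIST = {
    "aerobic": 0.35, "anaerobic": 0.25, "facultative": 0.25,
    "microaerophilic": 0.10, UNKNOWN: 0.05,
}

#: partial-trait ("orphan") cell counts per kingdom:
#: (orphan_class, nitrogenase present) -> organisms
_ORPHAN_COUNTS: dict[str, dict[tuple[str, bool], int]] = {
    "archaea": {
        ("enzyme_no_pathway", True): 2,
        ("enzyme_no_pathway", False): 3,
    },
    "bacteria": {
        ("pathway_no_enzyme", True): 12,
        ("pathway_no_enzyme", False): 13,
        ("enzyme_no_pathway", True): 29,
        ("enzyme_no_pathway", False): 2,
    },
}

_DMSOR_SUBFAMILY_PROBS = {
    ("bacteria", False): {"FDH": 0.35, "ACH": 0.10, "NarG": 0.20, "DMSOR": 0.35},
    ("archaea", True): {"FWD": 0.50, "FDH": 0.20, "DMSOR": 0.30},
    ("archaea", False): {"FDH": 0.30, "DMSOR": 0.70},
}


@dataclass(frozen=True)
class HgtScenario:
    """Donor/recipient setup for the transfer simulation."""

    enabled: bool = True
    donor_clade: str = "Clostridia"
    recipient_clade: str = "Erysipelotrichia"
    other_clades: tuple[str, ...] = ("Bacilli",)
    n_taxa_per_clade: int = 6
    genes: tuple[str, ...] = (
        "moaA", "moaC", "moeA", "moeB", "mogA", "MOSC", "AOR",
    )
    seq_length: int = 200
    d_within: float = 0.05
    d_between: float = 0.35


@dataclass(frozen=True)
class HgtSimulation:
    """Generated alignments plus the planted transfer truth."""

    blocks: Mapping[str, AlignedBlock]
    taxonomy: Mapping[str, str]
    recipient: str
    donor_clade: str
    transferred: bool


@dataclass
class ScenarioConfig:
    """All knobs of the community generator (defaults: published census)."""

    n_archaea: int = 256
    n_bacteria: int = 5387
    n_eukaryotes: int = 250
    category_weights: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _CATEGORY_WEIGHTS.items()
    })
    transporter_probs: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _TRANSPORTER_PROBS.items()
    })
    enzyme_probs: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _ENZYME_PROBS.items()
    })
    proteome_law: dict = field(default_factory=lambda: dict(_PROTEOME_LAW))
    habitat_dist: dict = field(default_factory=lambda: dict(_HABITAT_DIST))
    oxygen_dist: dict = field(default_factory=lambda: dict(_OXYGEN_DIST))
    orphan_counts: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _ORPHAN_COUNTS.items()
    })
    habitat_trait_prob: dict | None = None
    oxygen_trait_prob: dict | None = None
    balance_factor: bool = False
    fusion_rate: float = 0.05
    dropout: float = 0.0
    decoy_fraction: float = 0.20
    exclusion_decoy_rate: float = 0.10
    hgt: HgtScenario = field(default_factory=HgtScenario)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_archaea + self.n_bacteria + self.n_eukaryotes <= 0:
            raise ValueError("scenario requests zero organisms")
        for kingdom, weights in self.category_weights.items():
            total = sum(weights.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"category weights for {kingdom} sum to {total}, not 1"
                )
            if any(not 0 <= w <= 1 for w in weights.values()):
                raise ValueError(f"category weights for {kingdom} outside [0, 1]")
        for name in ("fusion_rate", "dropout", "decoy_fraction",
                     "exclusion_decoy_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for probs in (self.habitat_trait_prob, self.oxygen_trait_prob):
            if probs is not None and any(not 0 <= p <= 1 for p in probs.values()):
                raise ValueError("conditional trait probabilities outside [0, 1]")

    @classmethod
    def scaled(
        cls,
        n_archaea: int = 256,
        n_bacteria: int = 5387,
        n_eukaryotes: int = 250,
        rng_seed: int = 0,
    ) -> "ScenarioConfig":
        """Census-structured scenario at a custom size, with planted
        orphan counts shrunk proportionally to the kingdom sizes."""
        reference = {"archaea": 256, "bacteria": 5387}
        requested = {"archaea": n_archaea, "bacteria": n_bacteria}
        orphans = {}
        for kingdom, cells in _ORPHAN_COUNTS.items():
            factor = requested[kingdom] / reference[kingdom]
            scaled_cells = {
                cell: int(round(n * factor)) for cell, n in cells.items()
            }
            scaled_cells = {c: n for c, n in scaled_cells.items() if n > 0}
            if scaled_cells:
                orphans[kingdom] = scaled_cells
        return cls(
            n_archaea=n_archaea, n_bacteria=n_bacteria,
            n_eukaryotes=n_eukaryotes, orphan_counts=orphans,
            rng_seed=rng_seed,
        )

    @classmethod
    def habitat_survey(
        cls, n_per_category: int = 2000,
        probs: Mapping[str, float] | None = None,
        rng_seed: int = 0,
    ) -> "ScenarioConfig":
        """Bacteria-only scenario with trait presence conditioned on
        habitat (defaults emulate the published proportions: terrestrial
        0.9405 down to host-associated 0.5630)."""
        if probs is None:
            probs = {
                "terrestrial": 0.9405, "host-associated": 0.5630,
                "aquatic": 0.75, "multiple": 0.80, "specialized": 0.70,
            }
        return cls(
            n_archaea=0, n_eukaryotes=0,
            n_bacteria=n_per_category * len(probs),
            habitat_trait_prob=dict(probs),
            balance_factor=True,
            orphan_counts={},
            hgt=HgtScenario(enabled=False),
            rng_seed=rng_seed,
        )

    @classmethod
    def oxygen_survey(
        cls, n_per_category: int = 2000,
        probs: Mapping[str, float] | None = None,
        rng_seed: int = 0,
    ) -> "ScenarioConfig":
        """Bacteria-only scenario conditioning the trait on oxygen
        requirement (aerobic 0.7892 down to anaerobic 0.50)."""
        if probs is None:
            probs = {
                "aerobic": 0.7892, "facultative": 0.70,
                "microaerophilic": 0.65, "anaerobic": 0.50,
            }
        return cls(
            n_archaea=0, n_eukaryotes=0,
            n_bacteria=n_per_category * len(probs),
            oxygen_trait_prob=dict(probs),
            balance_factor=True,
            orphan_counts={},
            hgt=HgtScenario(enabled=False),
            rng_seed=rng_seed,
        )


@dataclass
class SyntheticCommunity:
    """Generated inputs plus per-organism ground truth."""

    config: ScenarioConfig
    metadata: list[OrganismMetadata]
    hits: dict[str, list[HitRecord]]
    query_lengths: dict[str, int]
    domain_hits: list[DomainHit]
    truth: pd.DataFrame
    fusion_truth: pd.DataFrame
    hgt: HgtSimulation | None = None

    def metadata_by_id(self) -> dict[str, OrganismMetadata]:
        return {m.organism_id: m for m in self.metadata}


# ---------------------------------------------------------------------------
# internal per-organism state

class _Organism:
    def __init__(self, meta: OrganismMetadata, category: str):
        self.meta = meta
        self.category = category
        self.orphan_class = "none"
        # gene label -> copy count (labels as in the seed registry)
        self.genes: dict[str, int] = {}
        self.transporters: list[str] = []
        self.proteome_size = 0
        self.n_fusions = 0

    def add(self, label: str, n: int = 1) -> None:
        if n > 0:
            self.genes[label] = self.genes.get(label, 0) + n


def _choice(rng: np.random.Generator, dist: Mapping[str, float]) -> str:
    keys = sorted(dist)
    p = np.array([dist[k] for k in keys], dtype=float)
    p = p / p.sum()
    return str(rng.choice(keys, p=p))


def _nbinom(rng: np.random.Generator, mean: float, shape: float) -> int:
    # negative binomial parameterized by mean and dispersion shape k
    p = shape / (shape + mean)
    return int(rng.negative_binomial(shape, p))


def _label_seed_map() -> dict[tuple[str, str], str]:
    """(kingdom-class, gene label) -> seed id used when emitting hits."""
    registry = reg.default_registry()
    prok: dict[str, str] = {}
    euk: dict[str, str] = {}
    for row in registry.itertuples(index=False):
        if row.role != reg.ROLE_MEMBER:
            continue
        target = euk if row.seed_id.startswith(("ATHAL", "CHLRE", "HUMAN")) else prok
        target.setdefault(row.gene_label, row.seed_id)
    # eukaryotes fall back to prokaryotic seeds for labels they lack
    mapping: dict[tuple[str, str], str] = {}
    for label, seed in prok.items():
        mapping[("prok", label)] = seed
    for label, seed in {**prok, **euk}.items():
        mapping[("euk", label)] = seed
    return mapping


_EUK_PATHWAY_LABELS = ("moaA", "moaC", "moaD", "moaE", "moeB", "moeA+mogA")


def _assign_pathway(org: _Organism) -> None:
    if org.meta.kingdom == "eukaryota":
        for label in _EUK_PATHWAY_LABELS:
            org.add(label)
    else:
        for label in reg.PATHWAY_KEY_GENES:
            org.add(label)


def _assign_enzymes(org: _Organism, cfg: ScenarioConfig,
                    rng: np.random.Generator, minimum: int = 1) -> None:
    kingdom = org.meta.kingdom
    fam_probs = cfg.enzyme_probs[kingdom]
    present = [f for f, p in sorted(fam_probs.items()) if rng.random() < p]
    if len(present) < 1 and minimum >= 1:
        # force the kingdom's most common family
        present = [max(fam_probs, key=lambda f: fam_probs[f])]
    mean, shape = cfg.proteome_law[kingdom]
    size = max(_nbinom(rng, mean, shape), len(present), minimum)
    weights = np.array(
        [max(_FAMILY_SIZE_WEIGHTS[kingdom][f], 1e-6) for f in present]
    )
    counts = np.ones(len(present), dtype=int)
    extra = rng.multinomial(size - len(present), weights / weights.sum())
    counts += extra
    for family, n in zip(present, counts):
        _add_family_members(org, family, int(n), rng)
    org.proteome_size = int(size)


def _add_family_members(org: _Organism, family: str, n: int,
                        rng: np.random.Generator) -> None:
    if family == "DMSOR":
        key = (org.meta.kingdom, org.meta.is_methanogen)
        probs = _DMSOR_SUBFAMILY_PROBS.get(key, _DMSOR_SUBFAMILY_PROBS[("bacteria", False)])
        for _ in range(n):
            org.add(_choice(rng, probs))
    else:
        org.add(family, n)


def _assign_transporters(org: _Organism, cfg: ScenarioConfig,
                         rng: np.random.Generator) -> None:
    kingdom = org.meta.kingdom
    for system, p in sorted(cfg.transporter_probs[kingdom].items()):
        if rng.random() >= p:
            continue
        org.transporters.append(system)
        if system in reg.ABC_TRANSPORTERS:
            for subunit in reg.ABC_TRANSPORTERS[system]:
                org.add(subunit)
        else:
            org.add(reg.MOT_TRANSPORTERS[system])
    org.transporters.sort()


def _build_gene_content(org: _Organism, cfg: ScenarioConfig,
                        rng: np.random.Generator) -> None:
    if org.category in ("moco_only", "both"):
        _assign_pathway(org)
        _assign_enzymes(org, cfg, rng, minimum=1)
        _assign_transporters(org, cfg, rng)
    if org.category in ("nif_only", "both"):
        org.add("nif", 1 + int(rng.random() < 0.2))


def _plant_orphans(organisms: list[_Organism], cfg: ScenarioConfig,
                   kingdom: str, rng: np.random.Generator) -> None:
    wanted = cfg.orphan_counts.get(kingdom, {})
    pool_nif = [o for o in organisms if o.category == "nif_only"]
    pool_none = [o for o in organisms if o.category == "none"]
    # last resort: repurpose trait-positive organisms (truth follows suit)
    pool_rest = [o for o in organisms if o.category in ("moco_only", "both")]
    for (orphan_class, with_nif), count in sorted(
        wanted.items(), key=lambda kv: (kv[0][0], not kv[0][1])
    ):
        for _ in range(count):
            pool = (pool_nif or pool_none or pool_rest) if with_nif else (
                pool_none or pool_rest
            )
            if not pool:
                raise ValueError(
                    f"not enough {kingdom} organisms to plant orphan cell "
                    f"({orphan_class}, nif={with_nif}); enlarge the scenario"
                )
            org = pool.pop()
            org.category = "nif_only" if with_nif else "none"
            org.orphan_class = orphan_class
            if orphan_class == "pathway_no_enzyme":
                _assign_pathway(org)
            else:
                n = 1 + int(rng.integers(0, 3))
                family = _choice(
                    rng,
                    {f: max(p, 1e-6) for f, p in cfg.enzyme_probs[org.meta.kingdom].items()},
                )
                _add_family_members(org, family, n, rng)
                org.proteome_size = n


# ---------------------------------------------------------------------------
# hit / domain emission

def _emit_hits(
    org: _Organism,
    seed_map: Mapping[tuple[str, str], str],
    seed_len: Mapping[str, int],
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[list[HitRecord], dict[str, tuple[str, str]]]:
    """Return the organism's hit rows and protein -> (family-ish label,
    gene label) map for downstream domain emission."""
    realm = "euk" if org.meta.kingdom == "eukaryota" else "prok"
    hits: list[HitRecord] = []
    proteins: dict[str, tuple[str, str]] = {}
    counter = 0
    evalue_cap = 0.01 / 10  # <= evalue_max / 10 by construction
    for label in sorted(org.genes):
        seed = seed_map.get((realm, label)) or seed_map.get(("prok", label))
        if seed is None:
            raise KeyError(f"no seed for gene label {label!r}")
        qlen = seed_len[seed]
        for _ in range(org.genes[label]):
            if cfg.dropout and rng.random() < cfg.dropout:
                continue
            counter += 1
            protein = f"{org.meta.organism_id}|p{counter:04d}"
            proteins[protein] = (seed, label)
            qend = max(int(qlen * rng.uniform(0.8, 1.0)), int(math.ceil(0.4 * qlen)) + 1)
            evalue = 10 ** rng.uniform(-40, math.log10(evalue_cap))
            hits.append(HitRecord(
                query_id=seed, subject_id=protein,
                percent_identity=round(rng.uniform(35, 95), 1),
                aln_length=qend, mismatches=int(qend * 0.3), gap_opens=1,
                qstart=1, qend=qend, sstart=1, send=qend,
                evalue=float(f"{evalue:.3e}"),
                bitscore=round(rng.uniform(80, 500), 1),
            ))
    # decoy hits: always rejected by the e-value/coverage filter
    n_decoys = int(round(cfg.decoy_fraction * len(hits)))
    all_seeds = sorted(seed_len)
    for _ in range(n_decoys):
        counter += 1
        seed = all_seeds[int(rng.integers(0, len(all_seeds)))]
        qlen = seed_len[seed]
        protein = f"{org.meta.organism_id}|d{counter:04d}"
        if rng.random() < 0.5:
            evalue, qend = rng.uniform(0.05, 5.0), max(int(qlen * 0.5), 2)
        else:
            evalue, qend = 10 ** rng.uniform(-20, -3), max(int(qlen * 0.15), 1)
        hits.append(HitRecord(
            query_id=seed, subject_id=protein,
            percent_identity=round(rng.uniform(20, 40), 1),
            aln_length=qend, mismatches=int(qend * 0.6), gap_opens=2,
            qstart=1, qend=qend, sstart=1, send=qend,
            evalue=float(f"{evalue:.3e}"), bitscore=round(rng.uniform(30, 60), 1),
        ))
    # exclusion exerciser: a protein whose best passing hit is NuoG
    if rng.random() < cfg.exclusion_decoy_rate:
        counter += 1
        protein = f"{org.meta.organism_id}|x{counter:04d}"
        for seed, score in (("ECOLI_NuoG", 320.0), ("ECOLI_DmsA", 210.0)):
            qlen = seed_len[seed]
            qend = int(qlen * 0.8)
            hits.append(HitRecord(
                query_id=seed, subject_id=protein,
                percent_identity=45.0, aln_length=qend,
                mismatches=int(qend * 0.4), gap_opens=1,
                qstart=1, qend=qend, sstart=1, send=qend,
                evalue=1e-30, bitscore=score,
            ))
    return hits, proteins


_ENZYME_SEED_FAMILY = {
    "SO": "SO", "XO": "XO", "AOR": "AOR", "MOSC": "MOSC",
    "DMSOR": "DMSOR", "FDH": "DMSOR", "ACH": "DMSOR", "FWD": "DMSOR",
    "NarG": "DMSOR",
}


def _emit_domains(
    org: _Organism,
    proteins: Mapping[str, tuple[str, str]],
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[list[DomainHit], list[dict]]:
    domain_hits: list[DomainHit] = []
    fusion_rows: list[dict] = []
    partner_pool = sorted(NOVEL_PARTNER_FAMILIES)
    for protein in sorted(proteins):
        _, label = proteins[protein]
        family = _ENZYME_SEED_FAMILY.get(label)
        if family is None:
            continue
        catalytic = sorted(CATALYTIC_DOMAINS[family])[0]
        domain_hits.append(DomainHit(
            protein_id=protein, domain_id=catalytic,
            start=40, end=420, score=round(rng.uniform(200, 400), 1),
            evalue=1e-50,
        ))
        # occasional low-score overlapping hit the tiler must reject
        if rng.random() < 0.10:
            domain_hits.append(DomainHit(
                protein_id=protein, domain_id="pfam99999",
                start=100, end=300, score=50.0, evalue=1e-4,
            ))
        if rng.random() < cfg.fusion_rate:
            compatible = [
                d for d in partner_pool if family in NOVEL_PARTNER_FAMILIES[d]
            ]
            if not compatible:
                continue
            partner = compatible[int(rng.integers(0, len(compatible)))]
            domain_hits.append(DomainHit(
                protein_id=protein, domain_id=partner,
                start=450, end=560, score=round(rng.uniform(80, 150), 1),
                evalue=1e-12,
            ))
            org.n_fusions += 1
            fusion_rows.append({
                "organism_id": org.meta.organism_id,
                "protein_id": protein,
                "family_id": family,
                "partner_domain": partner,
            })
    return domain_hits, fusion_rows


# ---------------------------------------------------------------------------
# sequence simulation for the HGT scenario

def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(ch, "")
            out.append(choices[int(rng.integers(0, len(choices)))])
        else:
            out.append(ch)
    return "".join(out)


def generate_hgt_scenario(
    scenario: HgtScenario, seed: int = 0
) -> HgtSimulation:
    """Simulate per-gene alignments with an optional planted transfer.

    Each clade descends from a mutated copy of a random ancestral protein
    (no indels, so sequences are born aligned).  When the transfer is on,
    the recipient's sequences are drawn from the donor clade's ancestor
    for every gene, so its p-distance neighborhood is the donor clade.
    """
    clades = (scenario.donor_clade, scenario.recipient_clade) + scenario.other_clades
    if len(clades) < 2:
        raise ValueError("need at least two clades")
    if scenario.n_taxa_per_clade < 3:
        raise ValueError("need at least 3 taxa per clade")
    for name, rate in (("d_within", scenario.d_within),
                       ("d_between", scenario.d_between)):
        if rate > 0.75:
            log.warning("%s=%.2f gives saturated distances (>0.75)", name, rate)
    rng = np.random.default_rng(seed)
    taxonomy: dict[str, str] = {}
    blocks: dict[str, AlignedBlock] = {}
    recipient = f"{scenario.recipient_clade}_rec"
    taxa_by_clade = {
        clade: [f"{clade}_{i:02d}" for i in range(scenario.n_taxa_per_clade)]
        for clade in clades
    }
    for clade, taxa in taxa_by_clade.items():
        for t in taxa:
            taxonomy[t] = clade
    taxonomy[recipient] = scenario.recipient_clade

    for gene in scenario.genes:
        root = "".join(
            AMINO_ACIDS[int(i)] for i in rng.integers(0, 20, scenario.seq_length)
        )
        ancestors = {
            clade: _mutate(root, scenario.d_between / 2, rng) for clade in clades
        }
        seqs: dict[str, str] = {}
        for clade, taxa in taxa_by_clade.items():
            for t in taxa:
                seqs[t] = _mutate(ancestors[clade], scenario.d_within, rng)
        source = scenario.donor_clade if scenario.enabled else scenario.recipient_clade
        seqs[recipient] = _mutate(ancestors[source], scenario.d_within, rng)
        blocks[gene] = AlignedBlock(gene_label=gene, sequences=seqs)

    return HgtSimulation(
        blocks=blocks,
        taxonomy=taxonomy,
        recipient=recipient,
        donor_clade=scenario.donor_clade,
        transferred=scenario.enabled,
    )


# ---------------------------------------------------------------------------
# community generation

def _sample_category(kingdom: str, meta: OrganismMetadata,
                     cfg: ScenarioConfig, rng: np.random.Generator) -> str:
    cond = None
    if kingdom == "bacteria":
        if cfg.habitat_trait_prob is not None and meta.habitat in cfg.habitat_trait_prob:
            cond = cfg.habitat_trait_prob[meta.habitat]
        elif cfg.oxygen_trait_prob is not None and meta.oxygen_req in cfg.oxygen_trait_prob:
            cond = cfg.oxygen_trait_prob[meta.oxygen_req]
    weights = cfg.category_weights[kingdom]
    if cond is None:
        return _choice(rng, weights)
    if rng.random() >= cond:
        return "none"
    positive = {c: w for c, w in weights.items() if c != "none"}
    if not positive or sum(positive.values()) == 0:
        return "moco_only"
    return _choice(rng, positive)


def generate_community(cfg: ScenarioConfig) -> SyntheticCommunity:
    """Generate a full synthetic community from a scenario."""
    rng = np.random.default_rng(cfg.rng_seed)
    seed_map = _label_seed_map()
    seed_len = reg.seed_lengths(reg.default_registry())

    plan = (
        ("archaea", "A", cfg.n_archaea),
        ("bacteria", "B", cfg.n_bacteria),
        ("eukaryota", "E", cfg.n_eukaryotes),
    )
    organisms: list[_Organism] = []
    for kingdom, prefix, n in plan:
        kingdom_orgs: list[_Organism] = []
        factor_categories = None
        if cfg.balance_factor and kingdom == "bacteria":
            if cfg.habitat_trait_prob is not None:
                factor_categories = ("habitat", sorted(cfg.habitat_trait_prob))
            elif cfg.oxygen_trait_prob is not None:
                factor_categories = ("oxygen_req", sorted(cfg.oxygen_trait_prob))
        for i in range(n):
            clade = _CLADES[kingdom][int(rng.integers(0, len(_CLADES[kingdom])))]
            habitat = _choice(rng, cfg.habitat_dist)
            oxygen = _choice(rng, cfg.oxygen_dist)
            if factor_categories is not None:
                name, cats = factor_categories
                value = cats[i % len(cats)]
                if name == "habitat":
                    habitat = value
                else:
                    oxygen = value
            meta = OrganismMetadata(
                organism_id=f"{prefix}{i + 1:04d}",
                kingdom=kingdom,
                taxon_path=clade,
                habitat=habitat,
                oxygen_req=oxygen,
            )
            org = _Organism(meta, _sample_category(kingdom, meta, cfg, rng))
            kingdom_orgs.append(org)
        _plant_orphans(kingdom_orgs, cfg, kingdom, rng)
        organisms.extend(kingdom_orgs)

    hits: dict[str, list[HitRecord]] = {}
    domain_hits: list[DomainHit] = []
    fusion_rows: list[dict] = []
    truth_rows: list[dict] = []
    for org in organisms:
        # orphan planting already added partial content; the regular pass
        # only adds nif for nif_only (and nothing for none), so it is safe
        # to run for every organism.
        _build_gene_content(org, cfg, rng)
        org_hits, proteins = _emit_hits(org, seed_map, seed_len, cfg, rng)
        hits[org.meta.organism_id] = org_hits
        d_hits, f_rows = _emit_domains(org, proteins, cfg, rng)
        domain_hits.extend(d_hits)
        fusion_rows.extend(f_rows)
        truth_rows.append({
            "organism_id": org.meta.organism_id,
            "kingdom": org.meta.kingdom,
            "category": org.category,
            "orphan_class": org.orphan_class,
            "nitrogenase": org.genes.get("nif", 0) > 0,
            "transporters": ";".join(org.transporters),
            "proteome_size": org.proteome_size,
            "rich": org.proteome_size > 20,
            "n_fusions": org.n_fusions,
        })

    hgt_sim = (
        generate_hgt_scenario(cfg.hgt, seed=int(rng.integers(0, 2**31 - 1)))
        if cfg.hgt.enabled
        else None
    )
    truth = pd.DataFrame(truth_rows)
    fusion_truth = pd.DataFrame(
        fusion_rows,
        columns=["organism_id", "protein_id", "family_id", "partner_domain"],
    )
    return SyntheticCommunity(
        config=cfg,
        metadata=[o.meta for o in organisms],
        hits=hits,
        query_lengths=seed_len,
        domain_hits=domain_hits,
        truth=truth,
        fusion_truth=fusion_truth,
        hgt=hgt_sim,
    )


def write_community(community: SyntheticCommunity, outdir) -> None:
    """Serialize a community as the pipeline's on-disk input layout."""
    outdir = Path(outdir)
    (outdir / "hits").mkdir(parents=True, exist_ok=True)
    write_metadata(community.metadata, outdir / "metadata.tsv")
    write_length_table(community.query_lengths, outdir / "lengths.tsv")
    for org, org_hits in sorted(community.hits.items()):
        write_hit_table(org_hits, outdir / "hits" / f"{org}.tsv")
    write_domain_table(community.domain_hits, outdir / "domains.tsv")
    community.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    community.fusion_truth.to_csv(outdir / "fusion_truth.tsv", sep="\t", index=False)
    if community.hgt is not None:
        aln_dir = outdir / "alignments"
        aln_dir.mkdir(exist_ok=True)
        for gene, block in sorted(community.hgt.blocks.items()):
            write_alignment(block.sequences, aln_dir / f"{gene}.afa")
        pd.DataFrame(
            sorted(community.hgt.taxonomy.items()),
            columns=["taxon_id", "clade"],
        ).to_csv(outdir / "hgt_taxonomy.tsv", sep="\t", index=False)
        with open(outdir / "hgt_focal.txt", "w") as fh:
            fh.write(community.hgt.recipient + "\n")
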