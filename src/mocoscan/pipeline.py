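"""End-to-end orchestration: hits -> assignments -> trait calls ->
summary tables, fusion report, HGT report and environment tables."""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import registry as reg
from .envstats import trait_by_factor
from .fusion import DomainHit, cross_family_partners, detect_fusions, tile_architecture
from .homology import HitRecord, OrthologAssignment, assign_families, filter_hits
from .iocore import (
    AnalysisConfig,
    OrganismMetadata,
    PipelineStageError,
    read_alignment,
    read_domain_table,
    read_hit_table,
    read_length_table,
    read_metadata,
)
from .phylo import AlignedBlock, HgtReport, hgt_score, nj_tree
from .profiler import (
    family_occurrence,
    largest_proteomes,
    occurrence_summary,
    percent,
    proteome_sizes,
    transporter_overlap,
)
from .traitcall import (
    GenePresenceProfile,
    TraitCall,
    call_mo_utilization,
    classify_orphans,
    predict_tungstoproteins,
)

log = logging.getLogger(__name__)


@dataclass
class ResultBundle:
    """All per-module outputs of one pipeline run."""

    trait_calls: pd.DataFrame
    summary: pd.DataFrame
    orphans: pd.DataFrame
    transporters: pd.DataFrame
    venn: dict[str, pd.DataFrame]
    proteomes: pd.DataFrame
    largest: pd.DataFrame
    families: pd.DataFrame
    tungsto: pd.DataFrame
    fusions: pd.DataFrame
    partners: pd.DataFrame
    hgt_report: pd.DataFrame
    env_tables: dict[str, pd.DataFrame]
    gene_trees: dict[str, str] = field(default_factory=dict)
    calls: list[TraitCall] = field(default_factory=list)
    assignments: list[OrthologAssignment] = field(default_factory=list)
    profiles: dict[str, GenePresenceProfile] = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trait_calls.to_csv(outdir / "trait_calls.tsv", sep="\t", index=False)
        self.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        self.orphans.to_csv(outdir / "orphans.tsv", sep="\t")
        self.transporters.to_csv(outdir / "transporters.tsv", sep="\t", index=False)
        for kingdom, table in sorted(self.venn.items()):
            table.to_csv(outdir / f"venn_{kingdom}.tsv", sep="\t", index=False)
        self.proteomes.to_csv(outdir / "proteomes.tsv", sep="\t", index=False)
        self.largest.to_csv(outdir / "largest_proteomes.tsv", sep="\t", index=False)
        self.families.to_csv(outdir / "families.tsv", sep="\t", index=False)
        self.tungsto.to_csv(outdir / "tungstoproteins.tsv", sep="\t", index=False)
        self.fusions.to_csv(outdir / "fusions.tsv", sep="\t", index=False)
        self.partners.to_csv(outdir / "partners.tsv", sep="\t", index=False)
        self.hgt_report.to_csv(outdir / "hgt_report.tsv", sep="\t", index=False)
        for name, table in sorted(self.env_tables.items()):
            table.to_csv(outdir / f"env_{name}.tsv", sep="\t", index=False)
        trees = outdir / "gene_trees"
        if self.gene_trees:
            trees.mkdir(exist_ok=True)
            for gene, newick in sorted(self.gene_trees.items()):
                (trees / f"{gene}.nwk").write_text(newick + "\n")


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    return wrap


def run_pipeline(
    config: AnalysisConfig,
    metadata: Sequence[OrganismMetadata],
    hits_by_org: Mapping[str, Sequence[HitRecord]],
    query_lengths: Mapping[str, int],
    domain_hits: Sequence[DomainHit] = (),
    alignments: Mapping[str, AlignedBlock] | None = None,
    hgt_taxonomy: Mapping[str, str] | None = None,
    hgt_focal: str | None = None,
    registry: pd.DataFrame | None = None,
) -> ResultBundle:
    """Run every analysis stage and return all result tables.

    Organisms present in ``metadata`` but missing from ``hits_by_org``
    get an all-absent profile (category "none").  The run is
    deterministic for fixed inputs.
    """
    if registry is None:
        registry = reg.default_registry()
    registry_index = reg.seed_index(registry)
    meta_by_id = {m.organism_id: m for m in metadata}

    # --- classification -------------------------------------------------
    def classify():
        calls: list[TraitCall] = []
        assignments: list[OrthologAssignment] = []
        profiles: dict[str, GenePresenceProfile] = {}
        for m in sorted(metadata, key=lambda m: m.organism_id):
            raw = list(hits_by_org.get(m.organism_id, ()))
            kept = filter_hits(raw, query_lengths, config.evalue_max, config.coverage_min)
            org_assign = assign_families(kept, registry_index, m.organism_id)
            profile = GenePresenceProfile.from_assignments(m.organism_id, org_assign)
            call = call_mo_utilization(
                profile,
                m.kingdom,
                pathway_majority=config.pathway_majority,
                rich_threshold=config.rich_threshold,
                include_aor=config.include_aor_as_moco_enzyme,
                include_nitrogenase_in_proteome=config.count_nitrogenase_in_proteome,
            )
            calls.append(call)
            assignments.extend(org_assign)
            profiles[m.organism_id] = profile
        log.info("classified %d organisms (%d assignments)",
                 len(calls), len(assignments))
        return calls, assignments, profiles

    calls, assignments, profiles = _stage("classify")(classify)

    calls_df = pd.DataFrame(
        {
            "organism_id": c.organism_id,
            "kingdom": meta_by_id[c.organism_id].kingdom,
            "step1": c.pathway.step1,
            "step2": c.pathway.step2,
            "step3": c.pathway.step3,
            "n_key_genes": c.pathway.n_key_genes,
            "moco_pathway": c.pathway.present,
            "moco_enzyme": c.moco_enzyme,
            "nitrogenase": c.nitrogenase,
            "category": c.category,
            "orphan_class": c.orphan_class,
            "proteome_size": c.proteome_size,
            "rich": c.rich,
            "transporters": ";".join(sorted(c.transporters)),
        }
        for c in calls
    )

    # --- occurrence summaries -------------------------------------------
    def summarize():
        rows = []
        for kingdom in ("archaea", "bacteria", "eukaryota"):
            sub = calls_df[calls_df["kingdom"] == kingdom]
            n = len(sub)
            if n == 0:
                continue
            n_mo = int((sub["category"] != "none").sum())
            rows.append({
                "kingdom": kingdom,
                "n_sequenced": n,
                "n_mo_utilizing": n_mo,
                "percent_mo_utilizing": percent(n_mo, n, config.percent_decimals),
                "n_moco_only": int((sub["category"] == "moco_only").sum()),
                "n_nif_only": int((sub["category"] == "nif_only").sum()),
                "n_both": int((sub["category"] == "both").sum()),
                "n_rich": int(sub["rich"].sum()),
            })
        return pd.DataFrame(rows)

    summary = _stage("summarize")(summarize)

    def orphan_tables():
        frames = []
        for kingdom in ("archaea", "bacteria", "eukaryota"):
            sub = [c for c in calls if meta_by_id[c.organism_id].kingdom == kingdom]
            if not sub:
                continue
            t = classify_orphans(sub)
            t.insert(0, "kingdom", kingdom)
            frames.append(t)
        return pd.concat(frames) if frames else pd.DataFrame()

    orphans = _stage("orphans")(orphan_tables)

    # --- transporters ----------------------------------------------------
    def transporter_tables():
        rows = []
        venn: dict[str, pd.DataFrame] = {}
        for kingdom, systems in (
            ("archaea", ("ModABC", "WtpABC", "TupABC")),
            ("bacteria", ("ModABC", "WtpABC", "TupABC")),
            ("eukaryota", ("MOT1", "MOT2")),
        ):
            utilizers = [
                c for c in calls
                if c.mo_utilizing and meta_by_id[c.organism_id].kingdom == kingdom
            ]
            n_mo = len(utilizers)
            if n_mo == 0:
                continue
            memberships = {
                s: {c.organism_id for c in utilizers if s in c.transporters}
                for s in systems
            }
            universe = {c.organism_id for c in utilizers}
            table = transporter_overlap(memberships, universe)
            venn[kingdom] = table.to_frame()
            row = {"kingdom": kingdom, "n_mo_utilizing": n_mo}
            for s in systems:
                n_s = len(memberships[s])
                row[f"n_{s}"] = n_s
                row[f"percent_{s}"] = percent(n_s, n_mo, config.percent_decimals)
            row["n_no_transporter"] = table.none_count
            rows.append(row)
        return pd.DataFrame(rows), venn

    transporters, venn = _stage("transporters")(transporter_tables)

    # --- molybdoproteomes ------------------------------------------------
    def proteome_tables():
        sizes = proteome_sizes(
            assignments,
            meta_by_id.keys(),
            include_nitrogenase=config.count_nitrogenase_in_proteome,
        )
        frames = []
        largest_rows = []
        for kingdom in ("archaea", "bacteria", "eukaryota"):
            ids = [o for o in sizes.index if meta_by_id[o].kingdom == kingdom]
            if not ids:
                continue
            ksizes = sizes.loc[ids]
            frames.append(pd.DataFrame({
                "organism_id": ksizes.index,
                "kingdom": kingdom,
                "proteome_size": ksizes.values,
            }))
            for org, size in largest_proteomes(ksizes):
                largest_rows.append(
                    {"kingdom": kingdom, "organism_id": org, "proteome_size": size}
                )
        proteomes = (
            pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        )
        return proteomes, pd.DataFrame(largest_rows)

    proteomes, largest = _stage("proteomes")(proteome_tables)

    def family_tables():
        frames = []
        for kingdom in ("archaea", "bacteria", "eukaryota"):
            t = family_occurrence(
                calls, profiles, meta_by_id, kingdom, config.percent_decimals
            )
            t.insert(0, "kingdom", kingdom)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)

    families = _stage("families")(family_tables)

    # --- tungstoproteins -------------------------------------------------
    def tungsto_table():
        labels = predict_tungstoproteins(assignments, meta_by_id)
        return pd.DataFrame(
            {
                "protein_id": t.protein_id,
                "organism_id": t.organism_id,
                "family_id": t.family_id,
                "gene_label": t.gene_label,
                "predicted_w": t.predicted_w,
                "rule_fired": t.rule_fired,
            }
            for t in labels
            if t.predicted_w
        )

    tungsto = _stage("tungstoproteins")(tungsto_table)

    # --- domain fusions --------------------------------------------------
    def fusion_tables():
        by_protein: dict[str, list[DomainHit]] = {}
        for h in domain_hits:
            by_protein.setdefault(h.protein_id, []).append(h)
        architectures = [
            tile_architecture(hlist, evalue_max=config.evalue_max)
            for _, hlist in sorted(by_protein.items())
        ]
        protein_orgs = {
            a.protein_id: a.organism_id for a in assignments
        }
        # fall back on the organism prefix baked into synthetic protein ids
        for pid in by_protein:
            protein_orgs.setdefault(pid, pid.split("|")[0] if "|" in pid else "")
        events = detect_fusions(architectures, protein_orgs)
        events_df = pd.DataFrame(
            {
                "organism_id": e.organism_id,
                "protein_id": e.protein_id,
                "family_id": e.family_id,
                "partner_domain": e.partner_domain,
            }
            for e in events
        )
        return events_df, cross_family_partners(events)

    fusions, partners = _stage("fusions")(fusion_tables)

    # --- HGT --------------------------------------------------------------
    def hgt_table():
        if not alignments or hgt_taxonomy is None or hgt_focal is None:
            return pd.DataFrame(), {}
        trees = {gene: nj_tree(block) for gene, block in sorted(alignments.items())}
        report: HgtReport = hgt_score(
            trees, hgt_taxonomy, hgt_focal, config.hgt_min_trees
        )
        rows = [
            {
                "focal": report.focal,
                "focal_class": report.focal_class,
                "gene": gene,
                "sister_clade": label,
                "supports_hgt": label not in ("ambiguous", report.focal_class),
                "n_supporting": report.n_supporting,
                "flagged": report.flagged,
            }
            for gene, label in sorted(report.per_gene.items())
        ]
        return pd.DataFrame(rows), trees

    hgt_report, gene_trees = _stage("hgt")(hgt_table)

    # --- environment ------------------------------------------------------
    def env_table_set():
        tables: dict[str, pd.DataFrame] = {}
        has_bacteria = any(m.kingdom == "bacteria" for m in metadata)
        if not has_bacteria:
            return tables
        features: list[tuple[str, object]] = [("mo_trait", "mo_trait"), ("rich", "rich")]
        features += [(s, s) for s in ("ModABC", "WtpABC", "TupABC")]
        for fam in reg.ENZYME_FAMILIES:
            features.append(
                (fam, (lambda f: (lambda c: profiles[c.organism_id].has(f)))(fam))
            )
        for factor in ("habitat", "oxygen_req"):
            for name, selector in features:
                tables[f"{factor}_{name}"] = trait_by_factor(
                    calls, meta_by_id, factor, selector,
                    decimals=config.env_percent_decimals,
                )
        return tables

    env_tables = _stage("envstats")(env_table_set)

    return ResultBundle(
        trait_calls=calls_df,
        summary=summary,
        orphans=orphans,
        transporters=transporters,
        venn=venn,
        proteomes=proteomes,
        largest=largest,
        families=families,
        tungsto=tungsto,
        fusions=fusions,
        partners=partners,
        hgt_report=hgt_report,
        env_tables=env_tables,
        gene_trees=gene_trees,
        calls=calls,
        assignments=assignments,
        profiles=profiles,
    )


def run_pipeline_from_dir(
    indir, config: AnalysisConfig | None = None
) -> ResultBundle:
    """Run the pipeline on a directory written by the ``simulate`` command
    (metadata.tsv, lengths.tsv, hits/<organism>.tsv, domains.tsv and the
    optional alignments/ + hgt_taxonomy.tsv + hgt_focal.txt)."""
    indir = Path(indir)
    if config is None:
        config = AnalysisConfig()
    metadata = read_metadata(indir / "metadata.tsv")
    query_lengths = read_length_table(indir / "lengths.tsv")
    hits_by_org = {}
    hits_dir = indir / "hits"
    if hits_dir.is_dir():
        for path in sorted(hits_dir.glob("*.tsv")):
            hits_by_org[path.stem] = read_hit_table(path)
    domain_path = indir / "domains.tsv"
    domain_hits = read_domain_table(domain_path) if domain_path.exists() else []
    alignments = None
    taxonomy = None
    focal = None
    aln_dir = indir / "alignments"
    if aln_dir.is_dir():
        alignments = {
            p.stem: AlignedBlock(gene_label=p.stem, sequences=read_alignment(p))
            for p in sorted(aln_dir.glob("*.afa"))
        }
        tax_path = indir / "hgt_taxonomy.tsv"
        if tax_path.exists():
            tax_df = pd.read_csv(tax_path, sep="\t", dtype=str)
            taxonomy = dict(zip(tax_df["taxon_id"], tax_df["clade"]))
        focal_path = indir / "hgt_focal.txt"
        if focal_path.exists():
            focal = focal_path.read_text().strip()
    return run_pipeline(
        config,
        metadata,
        hits_by_org,
        query_lengths,
        domain_hits,
        alignments=alignments,
        hgt_taxonomy=taxonomy,
        hgt_focal=focal,
    )
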