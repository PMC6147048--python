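import pandas as pd
import pytest

from mocoscan import AnalysisConfig
from mocoscan.homology import filter_hits
from mocoscan.phylo import p_distance
from mocoscan.pipeline import run_pipeline
from mocoscan.syndata import (
    HgtScenario,
    ScenarioConfig,
    generate_community,
    generate_hgt_scenario,
    write_community,
)


def tiny(seed=2, **kwargs):
    defaults = dict(n_archaea=15, n_bacteria=40, n_eukaryotes=12,
                    orphan_counts={}, rng_seed=seed)
    defaults.update(kwargs)
    return ScenarioConfig(**defaults)


class TestScenarioValidation:
    def test_zero_organisms_rejected(self):
        with pytest.raises(ValueError, match="zero organisms"):
            ScenarioConfig(n_archaea=0, n_bacteria=0, n_eukaryotes=0)

    def test_bad_category_weights_rejected(self):
        weights = {
            "archaea": {"moco_only": 0.9, "nif_only": 0.3, "both": 0.0, "none": 0.0},
            "bacteria": {"moco_only": 1.0, "nif_only": 0.0, "both": 0.0, "none": 0.0},
            "eukaryota": {"moco_only": 1.0, "nif_only": 0.0, "both": 0.0, "none": 0.0},
        }
        with pytest.raises(ValueError, match="sum"):
            ScenarioConfig(category_weights=weights)

    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            tiny(fusion_rate=1.5)


class TestDegenerateWeights:
    def test_all_both_category(self):
        weights = {
            k: {"moco_only": 0.0, "nif_only": 0.0, "both": 1.0, "none": 0.0}
            for k in ("archaea", "bacteria")
        }
        weights["eukaryota"] = {"moco_only": 1.0, "nif_only": 0.0, "both": 0.0,
                                "none": 0.0}
        com = generate_community(tiny(category_weights=weights, n_eukaryotes=0))
        assert (com.truth["category"] == "both").all()
        for org in com.truth["organism_id"]:
            subjects = {h.subject_id for h in com.hits[org]}
            assert subjects  # nif + pathway + enzymes all emitted
        bundle = run_pipeline(AnalysisConfig(), com.metadata, com.hits,
                              com.query_lengths)
        assert (bundle.trait_calls["category"] == "both").all()
        assert bundle.trait_calls["moco_pathway"].all()
        assert bundle.trait_calls["moco_enzyme"].all()
        assert bundle.trait_calls["nitrogenase"].all()


class TestEmittedHits:
    def test_true_hits_comfortably_pass_and_decoys_fail(self):
        com = generate_community(tiny())
        cfg = AnalysisConfig()
        for org, hits in com.hits.items():
            kept = filter_hits(hits, com.query_lengths,
                               cfg.evalue_max, cfg.coverage_min)
            kept_subjects = {h.subject_id for h in kept}
            for h in hits:
                tag = h.subject_id.split("|")[1][0]
                if tag == "p":  # genuine gene
                    assert h.evalue <= cfg.evalue_max / 10
                    qlen = com.query_lengths[h.query_id]
                    assert (h.qend - h.qstart + 1) / qlen >= 2 * cfg.coverage_min
                elif tag == "d":  # decoy must be filtered out
                    assert h.subject_id not in kept_subjects

    def test_decoy_fraction_zero_emits_no_decoys(self):
        com = generate_community(tiny(decoy_fraction=0.0,
                                      exclusion_decoy_rate=0.0))
        for hits in com.hits.values():
            assert all("|p" in h.subject_id for h in hits)


class TestLabelRecovery:
    def test_zero_classification_error_noise_free(self, community, bundle):
        merged = bundle.trait_calls.merge(community.truth, on="organism_id",
                                          suffixes=("", "_truth"))
        assert len(merged) == len(community.metadata)
        assert (merged["category"] == merged["category_truth"]).all()
        assert (merged["orphan_class"] == merged["orphan_class_truth"]).all()
        assert (merged["proteome_size"] == merged["proteome_size_truth"]).all()
        assert (merged["transporters"] == merged["transporters_truth"]).all()
        assert (merged["rich"] == merged["rich_truth"]).all()

    def test_planted_orphan_cells_recovered_exactly(self, community_scenario,
                                                    bundle):
        table = bundle.orphans.reset_index(names="orphan_class")
        for kingdom, cells in community_scenario.orphan_counts.items():
            sub = table[table["kingdom"] == kingdom].set_index("orphan_class")
            for (cls, nif), n in cells.items():
                assert sub.loc[cls, "nif_pos" if nif else "nif_neg"] == n

    def test_dropout_can_only_lose_genes(self):
        full = generate_community(tiny(seed=9))
        lossy = generate_community(tiny(seed=9, dropout=0.5))
        n_full = sum(len(h) for h in full.hits.values())
        n_lossy = sum(len(h) for h in lossy.hits.values())
        assert n_lossy < n_full


class TestDeterminism:
    def test_same_seed_identical_output(self):
        a = generate_community(tiny(seed=123))
        b = generate_community(tiny(seed=123))
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.hits == b.hits
        assert a.domain_hits == b.domain_hits
        for gene in a.hgt.blocks:
            assert a.hgt.blocks[gene].sequences == b.hgt.blocks[gene].sequences

    def test_different_seed_differs(self):
        a = generate_community(tiny(seed=1))
        b = generate_community(tiny(seed=2))
        assert not a.truth.equals(b.truth)


class TestHgtScenarioGeneration:
    def test_recipient_nearer_donor_clade_for_every_gene(self):
        sim = generate_hgt_scenario(HgtScenario(), seed=8)
        rec = sim.recipient
        own = [t for t, c in sim.taxonomy.items()
               if c == "Erysipelotrichia" and t != rec]
        donor = [t for t, c in sim.taxonomy.items() if c == sim.donor_clade]
        for gene, block in sim.blocks.items():
            rec_seq = block.sequences[rec]
            max_donor = max(p_distance(rec_seq, block.sequences[t]) for t in donor)
            min_own = min(p_distance(rec_seq, block.sequences[t]) for t in own)
            assert max_donor < min_own, gene

    def test_no_transfer_keeps_recipient_in_own_clade(self):
        sim = generate_hgt_scenario(HgtScenario(enabled=False), seed=8)
        rec = sim.recipient
        own = [t for t, c in sim.taxonomy.items()
               if c == "Erysipelotrichia" and t != rec]
        foreign = [t for t, c in sim.taxonomy.items()
                   if c != "Erysipelotrichia"]
        for block in sim.blocks.values():
            rec_seq = block.sequences[rec]
            nearest = min(sim.taxonomy, key=lambda t: (
                p_distance(rec_seq, block.sequences[t]) if t != rec else 2.0))
            assert nearest in own

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            generate_hgt_scenario(HgtScenario(n_taxa_per_clade=2))


class TestFactorSurveys:
    def test_balanced_habitat_assignment(self):
        cfg = ScenarioConfig.habitat_survey(n_per_category=40, rng_seed=5)
        com = generate_community(cfg)
        habitats = pd.Series([m.habitat for m in com.metadata])
        assert (habitats.value_counts() == 40).all()

    def test_conditional_trait_probability_realized(self):
        probs = {"terrestrial": 1.0, "host-associated": 0.0}
        com = generate_community(
            ScenarioConfig.habitat_survey(n_per_category=30, probs=probs,
                                          rng_seed=5))
        truth = com.truth.set_index("organism_id")
        meta = com.metadata_by_id()
        for org, row in truth.iterrows():
            if meta[org].habitat == "terrestrial":
                assert row["category"] != "none"
            else:
                assert row["category"] == "none"


def test_write_community_layout(tmp_path):
    com = generate_community(tiny())
    write_community(com, tmp_path)
    assert (tmp_path / "metadata.tsv").exists()
    assert (tmp_path / "lengths.tsv").exists()
    assert (tmp_path / "domains.tsv").exists()
    assert (tmp_path / "truth.tsv").exists()
    assert len(list((tmp_path / "hits").glob("*.tsv"))) == len(com.metadata)
    assert len(list((tmp_path / "alignments").glob("*.afa"))) == len(com.hgt.blocks)
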