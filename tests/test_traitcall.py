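from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mocoscan.homology import OrthologAssignment
from mocoscan.iocore import OrganismMetadata
from mocoscan.registry import ENZYME_FAMILIES, PATHWAY_KEY_GENES
from mocoscan.traitcall import (
    GenePresenceProfile,
    call_mo_utilization,
    call_moco_pathway,
    call_transporters,
    classify_orphans,
    is_rich,
    predict_tungstoproteins,
)


def profile(genes, org="org"):
    counts = {}
    for g in genes:
        counts[g] = counts.get(g, 0) + 1
    return GenePresenceProfile(organism_id=org, present=counts)


def pathway_oracle(genes, majority=4):
    """Independent re-statement of the three-step + majority rule."""
    s1 = "moaA" in genes or "moaC" in genes
    s2 = "moaD" in genes or "moaE" in genes or "moeB" in genes
    s3 = "moeA" in genes or "mogA" in genes
    n = sum(1 for g in PATHWAY_KEY_GENES if g in genes)
    return s1 and s2 and s3 and n >= majority


class TestMocoPathway:
    def test_six_of_seven_present(self):
        genes = {"moaA", "moaC", "moaD", "moeB", "moeA", "mogA"}
        assert call_moco_pathway(profile(genes)).present

    def test_three_steps_but_majority_fails(self):
        verdict = call_moco_pathway(profile({"moaA", "moaD", "moeA"}))
        assert verdict.step1 and verdict.step2 and verdict.step3
        assert verdict.n_key_genes == 3
        assert not verdict.present

    def test_all_128_key_gene_profiles_match_oracle(self):
        for bits in product([0, 1], repeat=7):
            genes = {g for g, b in zip(PATHWAY_KEY_GENES, bits) if b}
            assert call_moco_pathway(profile(genes)).present == pathway_oracle(genes)

    @pytest.mark.parametrize("majority", [1, 4, 7])
    def test_majority_parameter_exhaustive(self, majority):
        for bits in product([0, 1], repeat=7):
            genes = {g for g, b in zip(PATHWAY_KEY_GENES, bits) if b}
            assert (
                call_moco_pathway(profile(genes), majority).present
                == pathway_oracle(genes, majority)
            )


def category_oracle(genes):
    pathway = pathway_oracle(genes)
    enzyme = any(f in genes for f in ENZYME_FAMILIES)
    nif = "nif" in genes
    moco = pathway and enzyme
    if moco and nif:
        return "both"
    if moco:
        return "moco_only"
    if nif:
        return "nif_only"
    return "none"


class TestMoUtilization:
    def test_pathway_plus_enzyme_without_nif_is_moco_only(self):
        genes = set(PATHWAY_KEY_GENES) | {"DMSOR", "DMSOR"}
        call = call_mo_utilization(profile(list(PATHWAY_KEY_GENES) + ["DMSOR"] * 2),
                                   "bacteria")
        assert call.category == "moco_only"
        assert call.moco_enzyme and call.pathway.present and not call.nitrogenase

    def test_nif_alone_is_nif_only(self):
        assert call_mo_utilization(profile({"nif"}), "bacteria").category == "nif_only"

    def test_random_profiles_match_bruteforce_oracle(self, rng):
        pool = list(PATHWAY_KEY_GENES) + list(ENZYME_FAMILIES) + ["nif"]
        for _ in range(500):
            mask = rng.random(len(pool)) < 0.35
            genes = {g for g, m in zip(pool, mask) if m}
            call = call_mo_utilization(profile(genes), "bacteria")
            assert call.category == category_oracle(genes)

    def test_every_profile_in_exactly_one_category(self, rng):
        pool = list(PATHWAY_KEY_GENES) + list(ENZYME_FAMILIES) + ["nif"]
        counts = {"both": 0, "moco_only": 0, "nif_only": 0, "none": 0}
        n = 200
        for _ in range(n):
            genes = {g for g, m in zip(pool, rng.random(len(pool)) < 0.4) if m}
            counts[call_mo_utilization(profile(genes), "bacteria").category] += 1
        assert sum(counts.values()) == n
        mo_utilizing = counts["both"] + counts["moco_only"] + counts["nif_only"]
        assert mo_utilizing == n - counts["none"]

    def test_aor_exclusion_flag(self):
        genes = list(PATHWAY_KEY_GENES) + ["AOR"]
        assert call_mo_utilization(profile(genes), "archaea").category == "moco_only"
        strict = call_mo_utilization(profile(genes), "archaea", include_aor=False)
        assert strict.category == "none"


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_adding_a_gene_never_revokes_verdicts(data):
    pool = list(PATHWAY_KEY_GENES) + list(ENZYME_FAMILIES) + ["nif"]
    base = data.draw(st.sets(st.sampled_from(pool)))
    extra = data.draw(st.sampled_from(pool))
    before = call_mo_utilization(profile(base), "bacteria")
    after = call_mo_utilization(profile(base | {extra}), "bacteria")
    if before.pathway.present:
        assert after.pathway.present
    if before.mo_utilizing:
        assert after.mo_utilizing


class TestOrphans:
    def _call(self, genes):
        return call_mo_utilization(profile(genes), "bacteria")

    def test_pathway_without_enzyme_with_nif(self):
        call = self._call(set(PATHWAY_KEY_GENES) | {"nif"})
        table = classify_orphans([call])
        assert table.loc["pathway_no_enzyme", "nif_pos"] == 1
        assert table.values.sum() == 1

    def test_complete_trait_organisms_contribute_nothing(self):
        calls = [self._call(set(PATHWAY_KEY_GENES) | {"XO"}) for _ in range(5)]
        assert classify_orphans(calls).values.sum() == 0

    def test_planted_cell_counts_recovered(self):
        cells = {
            ("pathway_no_enzyme", True): 2,
            ("pathway_no_enzyme", False): 3,
            ("enzyme_no_pathway", True): 29,
            ("enzyme_no_pathway", False): 2,
        }
        calls = []
        for (cls, nif), n in cells.items():
            genes = set(PATHWAY_KEY_GENES) if cls == "pathway_no_enzyme" else {"XO"}
            if nif:
                genes = genes | {"nif"}
            calls.extend(self._call(genes) for _ in range(n))
        table = classify_orphans(calls)
        for (cls, nif), n in cells.items():
            assert table.loc[cls, "nif_pos" if nif else "nif_neg"] == n


class TestTransporters:
    @pytest.mark.parametrize("system,subunits", [
        ("ModABC", ("modA", "modB", "modC")),
        ("WtpABC", ("wtpA", "wtpB", "wtpC")),
        ("TupABC", ("tupA", "tupB", "tupC")),
    ])
    def test_abc_rule_exhaustive(self, system, subunits):
        a, b, c = subunits
        for bits in product([0, 1], repeat=3):
            genes = {s for s, keep in zip(subunits, bits) if keep}
            expected = (a in genes) and (b in genes or c in genes)
            called = call_transporters(profile(genes), "bacteria")
            assert (system in called) == expected

    def test_mot_in_eukaryote(self):
        assert call_transporters(profile({"mot2"}), "eukaryota") == {"MOT2"}

    def test_kingdom_gating(self):
        genes = {"modA", "modB", "mot1", "mot2"}
        assert call_transporters(profile(genes), "eukaryota") == {"MOT1", "MOT2"}
        assert call_transporters(profile(genes), "bacteria") == {"ModABC"}


class TestRich:
    @pytest.mark.parametrize("size,expected", [(73, True), (20, False), (21, True),
                                               (0, False)])
    def test_strict_threshold(self, size, expected):
        assert is_rich(size, 20) == expected

    def test_negative_size_rejected(self):
        with pytest.raises(ValueError):
            is_rich(-1)


class TestTungstoproteins:
    def _assign(self, org, family, label):
        return OrthologAssignment(org, f"{org}|p1", family, label, 100.0)

    def _meta(self, org, kingdom, oxygen="aerobic", clade=("X", "Y")):
        return {org: OrganismMetadata(org, kingdom, clade, "aquatic", oxygen)}

    def test_aor_predicted_anywhere(self):
        (label,) = predict_tungstoproteins(
            [self._assign("o", "AOR", "AOR")], self._meta("o", "bacteria"))
        assert label.predicted_w and label.rule_fired == "AOR"

    def test_fdh_in_aerobe_not_predicted(self):
        (label,) = predict_tungstoproteins(
            [self._assign("o", "DMSOR", "FDH")],
            self._meta("o", "bacteria", oxygen="aerobic"))
        assert not label.predicted_w

    @pytest.mark.parametrize("sub", ["FDH", "ACH"])
    def test_fdh_ach_in_anaerobic_bacterium_predicted(self, sub):
        (label,) = predict_tungstoproteins(
            [self._assign("o", "DMSOR", sub)],
            self._meta("o", "bacteria", oxygen="anaerobic"))
        assert label.rule_fired == "FDH_ACH_anaerobe"

    def test_fwd_requires_methanogenic_archaeon(self):
        methanogen = self._meta("o", "archaea",
                                clade=("Euryarchaeota", "Methanococci"))
        (label,) = predict_tungstoproteins(
            [self._assign("o", "DMSOR", "FWD")], methanogen)
        assert label.rule_fired == "FWD_methanogen"
        halophile = self._meta("o", "archaea",
                               clade=("Euryarchaeota", "Halobacteria"))
        (label,) = predict_tungstoproteins(
            [self._assign("o", "DMSOR", "FWD")], halophile)
        assert not label.predicted_w

    def test_so_member_never_predicted(self):
        (label,) = predict_tungstoproteins(
            [self._assign("o", "SO", "SO")],
            self._meta("o", "bacteria", oxygen="anaerobic"))
        assert not label.predicted_w


def test_compound_label_satisfies_both_genes():
    a = OrthologAssignment("o", "o|p1", "MoeA", "moeA+mogA", 200.0)
    prof = GenePresenceProfile.from_assignments("o", [a])
    assert prof.has("moeA") and prof.has("mogA")
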