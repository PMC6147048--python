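import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mocoscan import registry as reg
from mocoscan.homology import (
    assign_families,
    best_hit,
    bidirectional_best_hits,
    filter_hits,
    query_coverage,
)

from conftest import make_hit, random_hits

QLEN = {"q": 100} | {f"q{i}": 100 for i in range(10)}


class TestFilterHits:
    def test_high_evalue_removed(self):
        hit = make_hit(evalue=0.05, qend=50)  # coverage 0.5
        assert filter_hits([hit], QLEN) == []

    def test_low_coverage_removed(self):
        hit = make_hit(evalue=0.001, qend=19)  # coverage 0.19
        assert filter_hits([hit], QLEN) == []

    def test_boundary_values_kept(self):
        # thresholds are inclusive: evalue <= 0.01, coverage >= 0.20
        hit = make_hit(evalue=0.01, qend=20)
        assert filter_hits([hit], QLEN) == [hit]

    def test_matches_bruteforce_predicate(self, rng):
        hits = random_hits(rng, 200)
        kept = filter_hits(hits, QLEN)
        expected = [
            h for h in hits
            if h.evalue <= 0.01 and (h.qend - h.qstart + 1) / 100 >= 0.20
        ]
        assert kept == expected

    def test_idempotent_and_subset(self, rng):
        hits = random_hits(rng, 100)
        once = filter_hits(hits, QLEN)
        assert filter_hits(once, QLEN) == once
        assert all(h in hits for h in once)

    def test_missing_query_length_names_query(self):
        with pytest.raises(KeyError, match="mystery"):
            filter_hits([make_hit(query="mystery")], QLEN)


class TestBestHit:
    def test_higher_bitscore_wins(self):
        hits = [make_hit(subject="a", bitscore=120), make_hit(subject="b", bitscore=80)]
        assert best_hit(hits, "q") == "a"

    def test_bitscore_tie_lower_evalue_wins(self):
        hits = [
            make_hit(subject="a", bitscore=100, evalue=1e-10),
            make_hit(subject="b", bitscore=100, evalue=1e-30),
        ]
        assert best_hit(hits, "q") == "b"

    def test_full_tie_lexicographic_subject(self):
        hits = [
            make_hit(subject="zeta", bitscore=100, evalue=1e-10),
            make_hit(subject="alpha", bitscore=100, evalue=1e-10),
        ]
        assert best_hit(hits, "q") == "alpha"

    def test_no_hits_returns_none(self):
        assert best_hit([], "q") is None

    def test_matches_exhaustive_argmax(self, rng):
        hits = random_hits(rng, 50, n_queries=3)
        for q in {h.query_id for h in hits}:
            candidates = [h for h in hits if h.query_id == q]
            oracle = sorted(
                candidates, key=lambda h: (-h.bitscore, h.evalue, h.subject_id)
            )[0].subject_id
            assert best_hit(hits, q) == oracle


class TestBBH:
    def _from_matrix(self, scores, prefix_a="a", prefix_b="b"):
        ab, ba = [], []
        n, m = scores.shape
        for i in range(n):
            for j in range(m):
                ab.append(make_hit(query=f"{prefix_a}{i}", subject=f"{prefix_b}{j}",
                                   bitscore=float(scores[i, j])))
                ba.append(make_hit(query=f"{prefix_b}{j}", subject=f"{prefix_a}{i}",
                                   bitscore=float(scores[i, j])))
        return ab, ba

    def test_symmetric_one_to_one_all_pairs(self):
        scores = np.diag([100.0, 90.0, 80.0]) + 1.0
        ab, ba = self._from_matrix(scores)
        assert bidirectional_best_hits(ab, ba) == {
            ("a0", "b0"), ("a1", "b1"), ("a2", "b2"),
        }

    def test_non_reciprocal_pair_excluded(self):
        # a0's best is b0, but b0's best is a1 -> only (a1, b0) survives
        ab = [make_hit(query="a0", subject="b0", bitscore=50),
              make_hit(query="a1", subject="b0", bitscore=40)]
        ba = [make_hit(query="b0", subject="a1", bitscore=90),
              make_hit(query="b0", subject="a0", bitscore=60)]
        pairs = bidirectional_best_hits(ab, ba)
        assert ("a0", "b0") not in pairs
        assert pairs == {("a1", "b0")}

    def test_random_matrix_matches_bruteforce_reciprocal_argmax(self, rng):
        scores = rng.uniform(10, 100, size=(20, 20)).round(2)
        ab, ba = self._from_matrix(scores)
        pairs = bidirectional_best_hits(ab, ba)
        expected = set()
        for i in range(20):
            j = int(np.argmax(scores[i]))
            if int(np.argmax(scores[:, j])) == i:
                expected.add((f"a{i}", f"b{j}"))
        assert pairs == expected

    def test_pairs_form_partial_matching(self, rng):
        scores = rng.uniform(10, 100, size=(15, 12)).round(1)
        pairs = bidirectional_best_hits(*self._from_matrix(scores))
        a_side = [a for a, _ in pairs]
        b_side = [b for _, b in pairs]
        assert len(a_side) == len(set(a_side))
        assert len(b_side) == len(set(b_side))

    def test_lowering_evalue_cutoff_never_adds_pairs(self, rng):
        qlen = {f"a{i}": 100 for i in range(8)} | {f"b{i}": 100 for i in range(8)}
        ab = random_hits(rng, 60, n_queries=8, n_subjects=8)
        ab = [make_hit(query=h.query_id.replace("q", "a"),
                       subject=h.subject_id.replace("s", "b"),
                       evalue=h.evalue, bitscore=h.bitscore, qend=h.qend)
              for h in ab]
        ba = [make_hit(query=h.subject_id, subject=h.query_id,
                       evalue=h.evalue, bitscore=h.bitscore, qend=h.qend)
              for h in ab]
        loose = bidirectional_best_hits(
            filter_hits(ab, qlen, evalue_max=1.0),
            filter_hits(ba, qlen, evalue_max=1.0),
        )
        strict = bidirectional_best_hits(
            filter_hits(ab, qlen, evalue_max=1e-5),
            filter_hits(ba, qlen, evalue_max=1e-5),
        )
        # strict pairs among surviving queries are a refinement, never a
        # superset, of the loose matching's pair set on those queries
        assert all(
            pair in loose or pair[0] not in {a for a, _ in loose}
            for pair in strict
        )


@pytest.fixture(scope="module")
def index():
    return reg.seed_index(reg.default_registry())


class TestAssignFamilies:

    def test_exclusion_seed_top_hit_blocks_assignment(self, index):
        hits = [
            make_hit(query="ECOLI_NuoG", subject="p1", bitscore=300),
            make_hit(query="ECOLI_DmsA", subject="p1", bitscore=200),
        ]
        assert assign_families(hits, index, "org") == []

    def test_single_family_hit_assigned_with_label(self, index):
        hits = [make_hit(query="ECOLI_MoaA", subject="p1", bitscore=150)]
        (a,) = assign_families(hits, index, "org")
        assert (a.family_id, a.gene_label) == ("MoaA", "moaA")

    def test_equal_score_dual_family_dropped(self, index):
        hits = [
            make_hit(query="ECOLI_MoaA", subject="p1", bitscore=150, evalue=1e-20),
            make_hit(query="ECOLI_MoaC", subject="p1", bitscore=150, evalue=1e-20),
        ]
        assert assign_families(hits, index, "org") == []

    def test_planted_top_seeds_recovered(self, index, rng):
        member_seeds = [
            s for s, (_, _, role) in index.items() if role == "member"
        ]
        truth = {}
        hits = []
        for i in range(100):
            protein = f"p{i:03d}"
            planted = member_seeds[int(rng.integers(len(member_seeds)))]
            truth[protein] = index[planted][0]
            hits.append(make_hit(query=planted, subject=protein, bitscore=500))
            # weaker cross-hits to other seeds
            for _ in range(3):
                other = member_seeds[int(rng.integers(len(member_seeds)))]
                hits.append(make_hit(query=other, subject=protein,
                                     bitscore=float(rng.uniform(50, 400))))
        assignments = assign_families(hits, index, "org")
        assert {a.protein_id: a.family_id for a in assignments} == truth

    def test_unknown_seed_raises(self, index):
        with pytest.raises(KeyError, match="not a registered seed"):
            assign_families([make_hit(query="NOT_A_SEED", subject="p")], index, "o")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    evalues=st.lists(st.floats(1e-30, 1.0), min_size=1, max_size=30),
    cov_fracs=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=30),
)
def test_filter_output_always_subset_in_order(evalues, cov_fracs):
    n = min(len(evalues), len(cov_fracs))
    hits = [
        make_hit(subject=f"s{i}", evalue=evalues[i],
                 qend=max(1, int(100 * cov_fracs[i])))
        for i in range(n)
    ]
    kept = filter_hits(hits, QLEN)
    positions = [hits.index(h) for h in kept]
    assert positions == sorted(positions)
    assert set(kept) <= set(hits)
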