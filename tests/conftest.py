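import numpy as np
import pytest

from mocoscan import AnalysisConfig
from mocoscan.homology import HitRecord
from mocoscan.pipeline import run_pipeline
from mocoscan.syndata import ScenarioConfig, generate_community


def make_hit(query="q", subject="s", evalue=1e-10, bitscore=100.0,
             qstart=1, qend=100, identity=50.0):
    aln = qend - qstart + 1
    return HitRecord(
        query_id=query, subject_id=subject, percent_identity=identity,
        aln_length=aln, mismatches=aln // 3, gap_opens=1,
        qstart=qstart, qend=qend, sstart=1, send=aln,
        evalue=evalue, bitscore=bitscore,
    )


def random_hits(rng, n, n_queries=8, n_subjects=10, qlen=100):
    hits = []
    for _ in range(n):
        qend = int(rng.integers(5, qlen + 1))
        hits.append(make_hit(
            query=f"q{rng.integers(n_queries)}",
            subject=f"s{rng.integers(n_subjects)}",
            evalue=float(10.0 ** rng.uniform(-30, 1)),
            bitscore=float(rng.integers(20, 300)),
            qstart=1, qend=qend,
        ))
    return hits


@pytest.fixture(scope="session")
def community_scenario():
    return ScenarioConfig(
        n_archaea=128,
        n_bacteria=400,
        n_eukaryotes=120,
        orphan_counts={
            "archaea": {
                ("enzyme_no_pathway", True): 2,
                ("enzyme_no_pathway", False): 3,
            },
            "bacteria": {
                ("pathway_no_enzyme", True): 3,
                ("pathway_no_enzyme", False): 4,
                ("enzyme_no_pathway", True): 5,
                ("enzyme_no_pathway", False): 2,
            },
        },
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def community(community_scenario):
    return generate_community(community_scenario)


@pytest.fixture(scope="session")
def bundle(community):
    return run_pipeline(
        AnalysisConfig(),
        community.metadata,
        community.hits,
        community.query_lengths,
        community.domain_hits,
        alignments=community.hgt.blocks,
        hgt_taxonomy=community.hgt.taxonomy,
        hgt_focal=community.hgt.recipient,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
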