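"""Gene trees and HGT screening by taxonomic incongruence.

Distances are uncorrected p-distances with pairwise deletion of gap
positions; trees come from neighbor joining with deterministic
tie-breaking, written as Newick.  An organism is flagged as a horizontal
gene transfer candidate when, across several gene trees, its sister
group is dominated by a foreign taxonomic class.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from skbio import TreeNode

log = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class AlignedBlock:
    """One gene's alignment: taxon -> equal-length sequence."""

    gene_label: str
    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 3:
            raise ValueError(f"gene {self.gene_label}: need at least 3 taxa")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"gene {self.gene_label}: unequal sequence lengths")


@dataclass(frozen=True)
class HgtReport:
    """Multi-gene incongruence evidence for one focal organism."""

    focal: str
    focal_class: str
    per_gene: Mapping[str, str]  # gene -> sister-clade class label
    n_supporting: int
    flagged: bool


def p_distance(seq_a: str, seq_b: str) -> float:
    """Fraction of differing sites, gap positions pairwise-deleted."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    compared = 0
    diffs = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        compared += 1
        if a != b:
            diffs += 1
    if compared == 0:
        log.warning("no comparable (non-gap) sites; p-distance reported as 0")
        return 0.0
    return diffs / compared


def distance_matrix(block: AlignedBlock) -> tuple[list[str], np.ndarray]:
    """Symmetric p-distance matrix over the block's taxa (sorted ids)."""
    taxa = sorted(block.sequences)
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(
                block.sequences[taxa[i]], block.sequences[taxa[j]]
            )
    return taxa, d


def neighbor_joining(taxa: Sequence[str], dmat: np.ndarray) -> str:
    """Neighbor joining on a distance matrix; returns a Newick string.

    Standard Q-matrix agglomeration; ties break on the lexicographically
    smallest pair of cluster keys (a cluster's key is its smallest leaf
    name), so the topology is independent of input order.  Negative
    branch-length estimates are clamped at zero.  The result is the
    unrooted tree written with a trifurcating root.
    """
    n = len(taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if dmat.shape != (n, n):
        raise ValueError("distance matrix shape does not match taxa")
    if len(set(taxa)) != n:
        raise ValueError("duplicate taxon names")
    d = np.asarray(dmat, dtype=float).copy()
    # each active cluster: (newick fragment, smallest leaf name)
    newick = [_quote(t) for t in taxa]
    keys = list(taxa)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (len(active) - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        # new cluster u replaces i; distances by the reduction formula
        u = i
        for k in active:
            if k in (i, j):
                continue
            duk = (d[i, k] + d[j, k] - d[i, j]) / 2
            d[u, k] = d[k, u] = duk
        newick[u] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        keys[u] = min(keys[i], keys[j])
        active.remove(j)

    a, b, c = sorted(active, key=lambda i: keys[i])
    la = max((d[a, b] + d[a, c] - d[b, c]) / 2, 0.0)
    lb = max((d[a, b] + d[b, c] - d[a, c]) / 2, 0.0)
    lc = max((d[a, c] + d[b, c] - d[a, b]) / 2, 0.0)
    return (
        f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g},{newick[c]}:{lc:.10g});"
    )


def _quote(name: str) -> str:
    if any(ch in name for ch in "(),:;'\" \t"):
        return "'" + name.replace("'", "''") + "'"
    return name


def nj_tree(block: AlignedBlock) -> str:
    """Convenience: p-distance matrix + neighbor joining for one gene."""
    taxa, d = distance_matrix(block)
    return neighbor_joining(taxa, d)


def sister_clade(
    newick: str,
    focal: str,
    taxonomy: Mapping[str, str],
) -> str:
    """Dominant taxonomic class in the focal leaf's sister group.

    The tree is midpoint-rooted for orientation; the sister group is the
    set of leaves under the focal leaf's sibling subtree(s).  Ties in the
    majority vote return "ambiguous".
    """
    tree = TreeNode.read(StringIO(newick), convert_underscores=False)
    tree = tree.root_at_midpoint()
    try:
        tip = tree.find(focal)
    except Exception as exc:  # skbio raises MissingNodeError
        raise KeyError(f"focal taxon {focal!r} not in tree") from exc
    parent = tip.parent
    if parent is None:
        raise ValueError("focal taxon is the tree root")
    sisters = [
        leaf.name
        for child in parent.children
        if child is not tip
        for leaf in child.tips(include_self=child.is_tip())
    ]
    if not sisters:
        return "ambiguous"
    votes: dict[str, int] = {}
    for name in sisters:
        label = taxonomy.get(name, "unknown")
        votes[label] = votes.get(label, 0) + 1
    top = max(votes.values())
    winners = sorted(lab for lab, v in votes.items() if v == top)
    return winners[0] if len(winners) == 1 else "ambiguous"


def hgt_score(
    gene_trees: Mapping[str, str],
    taxonomy: Mapping[str, str],
    focal: str,
    hgt_min_trees: int = 3,
) -> HgtReport:
    """Concordance of foreign sister placement across gene trees.

    A gene supports transfer iff the focal leaf's sister clade is a
    definite class different from the focal organism's own; the organism
    is flagged when at least ``hgt_min_trees`` genes agree.
    """
    focal_class = taxonomy.get(focal, "unknown")
    per_gene: dict[str, str] = {}
    n_support = 0
    for gene in sorted(gene_trees):
        newick = gene_trees[gene]
        try:
            label = sister_clade(newick, focal, taxonomy)
        except KeyError:
            continue
        per_gene[gene] = label
        if label not in ("ambiguous", focal_class):
            n_support += 1
    return HgtReport(
        focal=focal,
        focal_class=focal_class,
        per_gene=per_gene,
        n_supporting=n_support,
        flagged=n_support >= hgt_min_trees,
    )


def bootstrap_sister_support(
    block: AlignedBlock,
    focal: str,
    taxonomy: Mapping[str, str],
    n_replicates: int = 100,
    seed: int = 0,
) -> float:
    """Fraction of column-resampling replicates reproducing the point
    sister-clade call for the focal taxon (optional diagnostic)."""
    point = sister_clade(nj_tree(block), focal, taxonomy)
    rng = np.random.default_rng(seed)
    taxa = sorted(block.sequences)
    length = len(block.sequences[taxa[0]])
    agree = 0
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = {
            t: "".join(block.sequences[t][c] for c in cols) for t in taxa
        }
        rep = AlignedBlock(gene_label=block.gene_label, sequences=resampled)
        if sister_clade(nj_tree(rep), focal, taxonomy) == point:
            agree += 1
    return agree / n_replicates


def tree_path_distances(newick: str) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix of a Newick tree (diagnostic)."""
    tree = TreeNode.read(StringIO(newick), convert_underscores=False)
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
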