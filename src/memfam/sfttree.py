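"""Superfamily trees from all-vs-all pairwise score matrices.

Multiple sequence alignments degrade when families are separated by
enormous phylogenetic distances; a tree built from *pairwise* alignment
scores sidesteps the MSA entirely.  Every protein is aligned with every
other, raw scores are rescaled to bit scores with Karlin–Altschul
constants, bit scores become distances, and neighbor joining produces a
tree.  An ensemble of trees built from column-bootstrapped score
matrices yields a majority-rule consensus whose clade frequencies serve
as support values.  The reproduction surface is family-level clustering
(which families are sisters), not branch lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .paircompare import AlignParams, align, alignment_score
from .seqdata import ProteinRecord

#: Karlin–Altschul constants for gapped BLOSUM62 scoring.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


def bit_score(raw: float, lam: float = DEFAULT_LAMBDA, k: float = DEFAULT_K) -> float:
    """Rescale a raw alignment score to bits: (λS − ln K) / ln 2."""
    return (lam * raw - math.log(k)) / math.log(2.0)


@dataclass
class ScoreMatrix:
    """Symmetric all-vs-all bit-score matrix with per-pair column scores.

    ``column_scores[(i, j)]`` holds the substitution score of every
    aligned residue pair for pair (i, j) (i < j), and ``gap_costs`` the
    total gap penalty of that alignment; together they reconstruct the
    raw score and allow bootstrap resampling over alignment columns.
    """

    labels: list[str]
    family_tags: list[str]
    bits: np.ndarray
    lam: float = DEFAULT_LAMBDA
    k: float = DEFAULT_K
    column_scores: dict[tuple[int, int], np.ndarray] = field(default_factory=dict, repr=False)
    gap_costs: dict[tuple[int, int], float] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.bits.shape != (n, n):
            raise ValueError("bit matrix shape does not match labels")
        if not np.allclose(self.bits, self.bits.T):
            raise ValueError("bit matrix must be symmetric")


def score_matrix(
    proteins: Sequence[ProteinRecord],
    family_tags: Sequence[str] | None = None,
    params: AlignParams | None = None,
    lam: float = DEFAULT_LAMBDA,
    k: float = DEFAULT_K,
) -> ScoreMatrix:
    """All-vs-all global alignment bit scores.

    Self-scores (the diagonal) use the self-alignment, which is maximal
    in each row for a positive-definite substitution matrix.
    """
    if len(proteins) < 4:
        raise ValueError("need at least 4 proteins for tree work")
    params = params or AlignParams()
    n = len(proteins)
    tags = list(family_tags) if family_tags is not None else [""] * n
    bits = np.zeros((n, n))
    column_scores: dict[tuple[int, int], np.ndarray] = {}
    gap_costs: dict[tuple[int, int], float] = {}
    from Bio.Align import substitution_matrices

    matrix = substitution_matrices.load(params.matrix)
    for i in range(n):
        bits[i, i] = bit_score(alignment_score(proteins[i], proteins[i], params), lam, k)
        for j in range(i + 1, n):
            result = align(proteins[i], proteins[j], params)
            cols = np.array(
                [matrix[proteins[i].residues[a], proteins[j].residues[b]] for a, b in result.pairs]
            )
            column_scores[(i, j)] = cols
            gap_costs[(i, j)] = float(cols.sum() - result.score)
            bits[i, j] = bits[j, i] = bit_score(result.score, lam, k)
    return ScoreMatrix(
        labels=[p.accession for p in proteins],
        family_tags=tags,
        bits=bits,
        lam=lam,
        k=k,
        column_scores=column_scores,
        gap_costs=gap_costs,
    )


def to_distances(m: ScoreMatrix | np.ndarray, clip: float = 1.5) -> np.ndarray:
    """Normalized bit-score distances: d(i,j) = 1 − b(i,j)/min(b(i,i), b(j,j)).

    Clipped to [0, ``clip``]; the diagonal is zero.  The transform is a
    similarity-to-distance heuristic, not an additive evolutionary
    distance; triangle-inequality violations are possible and are
    reported by :func:`triangle_violations`, not repaired.
    """
    bits = m.bits if isinstance(m, ScoreMatrix) else np.asarray(m)
    self_scores = np.diag(bits)
    if np.any(self_scores <= 0):
        raise ValueError("non-positive self bit score")
    denom = np.minimum.outer(self_scores, self_scores)
    d = 1.0 - bits / denom
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, clip)


def triangle_violations(d: np.ndarray) -> int:
    """Number of ordered triples violating d(i,k) <= d(i,j) + d(j,k)."""
    n = d.shape[0]
    count = 0
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            for k_ in range(n):
                if k_ in (i, j):
                    continue
                if d[i, k_] > d[i, j] + d[j, k_] + 1e-9:
                    count += 1
    return count


def nj_tree(d: np.ndarray, labels: Sequence[str]) -> str:
    """Neighbor-joining tree as a Newick string.

    Ties in the Q criterion are broken deterministically by label order
    (rows are passed in input order to a deterministic implementation).
    """
    if d.shape[0] < 4:
        raise ValueError("neighbor joining here requires at least 4 leaves")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")
    dm = DistanceMatrix(d, ids=list(labels))
    tree = nj(dm)
    return str(tree).strip()


@dataclass
class TreeEnsemble:
    """Bootstrap tree ensemble plus its majority-rule consensus."""

    trees: list[str]
    consensus: str
    supports: dict[frozenset[str], float]


def _resampled_bits(m: ScoreMatrix, rng: np.random.Generator) -> np.ndarray:
    bits = m.bits.copy()
    for (i, j), cols in m.column_scores.items():
        if cols.size == 0:
            continue
        resampled = cols[rng.integers(0, cols.size, size=cols.size)].sum()
        raw = float(resampled) - m.gap_costs[(i, j)]
        bits[i, j] = bits[j, i] = bit_score(raw, m.lam, m.k)
    return bits


def clade_supports(trees: Sequence[str], labels: Sequence[str]) -> dict[frozenset[str], float]:
    """Frequency of each non-trivial bipartition.

    Both orientations of a split are recorded (the sides {A,B} and
    {C,D} of a four-leaf split are the same bipartition and share one
    frequency), so callers can look up whichever leaf set they hold.
    """
    taxa = dendropy.TaxonNamespace(list(labels))
    all_leaves = frozenset(labels)
    counts: dict[frozenset[str], int] = {}
    for newick in trees:
        tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=taxa)
        tree.encode_bipartitions()
        seen: set[frozenset[str]] = set()
        for bipartition in tree.bipartition_encoding:
            side = frozenset(
                taxon.label for taxon in bipartition.leafset_taxa(taxa)
            )
            if len(side) in (0, 1, len(all_leaves), len(all_leaves) - 1):
                continue  # trivial splits
            if side in seen:
                continue
            seen.add(side)
            seen.add(all_leaves - side)
            counts[side] = counts.get(side, 0) + 1
            counts[all_leaves - side] = counts.get(all_leaves - side, 0) + 1
    return {clade: n / len(trees) for clade, n in counts.items()}


def ensemble_consensus(
    m: ScoreMatrix, n_trees: int = 100, seed: int = 0
) -> TreeEnsemble:
    """Majority-rule consensus over column-bootstrapped score matrices.

    Each replicate resamples, for every pair independently, the aligned
    column scores of that pair's alignment (with replacement), rebuilds
    the bit/distance matrices, and reruns neighbor joining.  The
    consensus contains exactly the clades appearing in more than half of
    the replicates, labeled with their frequencies.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    trees = []
    for _ in range(n_trees):
        bits = _resampled_bits(m, rng)
        trees.append(nj_tree(to_distances(ScoreMatrix(
            labels=m.labels, family_tags=m.family_tags, bits=bits, lam=m.lam, k=m.k
        )), m.labels))
    supports = clade_supports(trees, m.labels)
    taxa = dendropy.TaxonNamespace(list(m.labels))
    tree_list = dendropy.TreeList(
        [dendropy.Tree.get(data=t, schema="newick", taxon_namespace=taxa) for t in trees],
        taxon_namespace=taxa,
    )
    cons = tree_list.consensus(min_freq=0.5)
    all_leaves = frozenset(m.labels)
    for node in cons.preorder_internal_node_iter():
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if side in supports:
            node.label = f"{supports[side]:.2f}"
    consensus_newick = cons.as_string(schema="newick", suppress_rooting=True).strip()
    return TreeEnsemble(trees=trees, consensus=consensus_newick, supports=supports)


def leaves_of(newick: str) -> set[str]:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def is_monophyletic_in_unrooted(newick: str, group: set[str]) -> bool:
    """Whether ``group`` forms one side of some bipartition of the tree."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    all_leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    target = frozenset(group)
    complement = frozenset(all_leaves - group)
    tree.encode_bipartitions()
    for node in tree.preorder_node_iter():
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if side == target or side == complement:
            return True
    return False


def write_score_tsv(m: ScoreMatrix, path) -> None:
    with open(path, "w") as handle:
        handle.write("accession\tfamily\t" + "\t".join(m.labels) + "\n")
        for i, (label, tag) in enumerate(zip(m.labels, m.family_tags)):
            row = "\t".join(f"{m.bits[i, j]:.2f}" for j in range(len(m.labels)))
            handle.write(f"{label}\t{tag}\t{row}\n")
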