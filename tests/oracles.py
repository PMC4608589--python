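"""Independent oracles used by the test suite.

Each oracle is a deliberately naive re-derivation of a quantity the
package computes by another route: an explicit three-state dynamic
program for affine-gap global alignment, a regex compiler for motif
patterns, a fixed-point closure for graph components, and path-length
summation for tree distances.  They share no code with the
implementations they check.
"""

from __future__ import annotations

import itertools
import re

from Bio.Align import substitution_matrices

NEG = float("-inf")


def dp_global_score(a: str, b: str, matrix_name: str = "BLOSUM62",
                    gap_open: float = 8.0, gap_extend: float = 2.0) -> float:
    """Three-state Gotoh recursion; gap of length L costs open + L*extend.

    End gaps are charged (true global alignment).
    """
    matrix = substitution_matrices.load(matrix_name)
    n, m = len(a), len(b)
    first = gap_open + gap_extend  # cost of the first residue of a gap
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a-residue unmatched)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + s
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend, Y[i - 1][j] - first)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend, X[i][j - 1] - first)
    return max(M[n][m], X[n][m], Y[n][m])


def motif_to_regex(text: str) -> re.Pattern:
    """Compile motif notation (letters, X, (K/R)) into a regex."""
    out = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            j = text.index(")", i)
            out.append("[" + "".join(text[i + 1 : j].split("/")) + "]")
            i = j + 1
        elif ch.upper() == "X":
            out.append(".")
            i += 1
        else:
            out.append(re.escape(ch.upper()))
            i += 1
    return re.compile("(?=(" + "".join(out) + "))")


def regex_scan_offsets(sequence: str, motif_text: str) -> list[int]:
    return [m.start() for m in motif_to_regex(motif_text).finditer(sequence)]


def brute_force_components(nodes: list[str], edges: list[tuple[str, str]]) -> list[set[str]]:
    """Connected components by fixed-point expansion from each node."""
    components = []
    seen: set[str] = set()
    adjacency = {n: set() for n in nodes}
    for x, y in edges:
        adjacency[x].add(y)
        adjacency[y].add(x)
    for start in nodes:
        if start in seen:
            continue
        comp = {start}
        while True:
            grown = set(comp)
            for node in comp:
                grown |= adjacency[node]
            if grown == comp:
                break
            comp = grown
        seen |= comp
        components.append(comp)
    return components


def tree_path_distances(newick: str) -> dict[frozenset[str], float]:
    """Leaf-to-leaf path lengths by summing branch lengths (dendropy walk)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in itertools.combinations(tree.taxon_namespace, 2):
        out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out


def random_additive_matrix(rng, n_leaves: int):
    """A random additive distance matrix plus its generating tree structure.

    Built by growing a random binary tree with positive branch lengths
    and summing path lengths between leaves.
    """
    import numpy as np

    # nodes: 0..n_leaves-1 are leaves; grow by splitting random edges
    edges = {}  # (u, v) -> length
    next_node = n_leaves
    nodes = [0, 1]
    edges[(0, 1)] = float(rng.uniform(0.1, 1.0))
    for leaf in range(2, n_leaves):
        u, v = list(edges)[rng.integers(len(edges))]
        length = edges.pop((u, v))
        mid = next_node
        next_node += 1
        split = float(rng.uniform(0.2, 0.8))
        edges[(u, mid)] = length * split
        edges[(mid, v)] = length * (1 - split)
        edges[(mid, leaf)] = float(rng.uniform(0.1, 1.0))
        nodes.append(leaf)
    adjacency: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in edges.items():
        adjacency.setdefault(u, []).append((v, w))
        adjacency.setdefault(v, []).append((u, w))

    def path_length(src: int, dst: int) -> float:
        stack = [(src, -1, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node == dst:
                return dist
            for nxt, w in adjacency[node]:
                if nxt != parent:
                    stack.append((nxt, node, dist + w))
        raise AssertionError("disconnected tree")

    d = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            d[i, j] = d[j, i] = path_length(i, j)
    return d
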