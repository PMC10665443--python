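"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own algorithms: cluster detection by
connected components of the pairwise proximity graph, parsimony by exhaustive
enumeration of internal labelings, strand runs by regex, non-overlapping
envelope counting by maximum independent set.
"""

from __future__ import annotations

import itertools
import re


def brute_force_clusters(positions: list, max_index_diff: int) -> list:
    """Maximal chains of positions: connected components of the graph joining
    any two positions with index difference <= max_index_diff.

    ``positions`` is a list of (gene_index, payload); returns a list of
    clusters, each a list of (gene_index, payload) sorted by index.
    """
    items = sorted(positions)
    n = len(items)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if items[j][0] - items[i][0] <= max_index_diff:
                parent[find(i)] = find(j)
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(items[i])
    return sorted(groups.values())


def exhaustive_fitch_changes(tree, leaf_states: dict) -> int:
    """Minimum branch-change count by trying every internal labeling.

    The tree structure is flattened once (index arrays) so the 2^k labelings
    iterate over plain lists, keeping 1000-instance runs fast.
    """
    nodes = list(tree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    internal_idx = [i for i, nd in enumerate(nodes) if not nd.is_leaf()]
    edges = [
        (index[id(nd)], index[id(nd.parent_node)])
        for nd in nodes
        if nd.parent_node is not None
    ]
    fixed = [None] * len(nodes)
    for nd in tree.leaf_node_iter():
        fixed[index[id(nd)]] = bool(leaf_states[nd.taxon.label])
    best = None
    state = list(fixed)
    for combo in itertools.product([False, True], repeat=len(internal_idx)):
        for i, s in zip(internal_idx, combo):
            state[i] = s
        changes = sum(state[c] != state[p] for c, p in edges)
        if best is None or changes < best:
            best = changes
    return best


def regex_strand_segments(ss: str, mce_end: int, min_run: int) -> list:
    """Regex-based independent scan for C-terminal 'E' runs with clipping."""
    segments = []
    for m in re.finditer(r"E+", ss):
        start, end = m.start() + 1, m.end()  # 1-based inclusive
        start = max(start, mce_end + 1)
        if end >= start and end - start + 1 >= min_run:
            segments.append((start, end))
    return segments


def max_nonoverlapping_envelopes(envs: list, max_overlap_fraction: float) -> int:
    """Size of the largest subset of pairwise compatible envelopes."""
    def compatible(a, b):
        ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
        shorter = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
        return ov <= max_overlap_fraction * shorter

    best = 0
    for r in range(len(envs), 0, -1):
        for combo in itertools.combinations(envs, r):
            if all(compatible(a, b) for a, b in itertools.combinations(combo, 2)):
                return r
    return best


def recount_kept_columns(sequences: dict, max_gap_fraction: float) -> list:
    """Independent per-column gap recount for alignment trimming."""
    taxa = list(sequences)
    width = len(sequences[taxa[0]])
    kept = []
    for col in range(width):
        gaps = sum(1 for t in taxa if sequences[t][col] == "-")
        if gaps / len(taxa) <= max_gap_fraction:
            kept.append(col)
    return kept
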