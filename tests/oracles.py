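"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity by a route deliberately different from
the library implementation: alignment scores by exhaustive enumeration of
every alignment path, sequon counts by overlapping regular-expression
scans, and additive distance matrices from explicitly constructed random
trees.
"""

from __future__ import annotations

import re

import numpy as np


def brute_force_alignment_score(a, b, matrix, gap_open=10.0, gap_extend=0.05):
    """Best global alignment score by enumerating every alignment path.

    Affine gaps: the first gapped column of a run costs ``gap_open``, each
    further column ``gap_extend``; a gap in one sequence immediately
    followed by a gap in the other opens a new run.  Exponential in the
    sequence lengths — keep inputs short.
    """
    best = -np.inf

    def rec(i, j, score, state):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], "m")
        if i < len(a):
            rec(i + 1, j, score - (gap_extend if state == "a" else gap_open), "a")
        if j < len(b):
            rec(i, j + 1, score - (gap_extend if state == "b" else gap_open), "b")

    rec(0, 0, 0.0, "m")
    return best


_SEQUON_RE = re.compile(r"(?=N[^P][ST])")
_NP_RE = re.compile(r"(?=NP)")


def regex_sequon_counts(seq):
    """(sequons, N-P, total N, total P, residues) via overlapping regex scans."""
    return (
        len(_SEQUON_RE.findall(seq)),
        len(_NP_RE.findall(seq)),
        seq.count("N"),
        seq.count("P"),
        len(seq),
    )


def random_additive_tree(n_leaves, rng, blen=(0.5, 3.0)):
    """Random binary tree with positive branch lengths.

    Returns (leaf labels, pairwise distance matrix) where distances are
    path lengths through the explicitly built tree, hence additive by
    construction.
    """
    labels = [f"t{i}" for i in range(n_leaves)]
    adjacency: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_leaves)}
    active = list(range(n_leaves))
    nxt = n_leaves
    while len(active) > 1:
        i = active.pop(int(rng.integers(len(active))))
        j = active.pop(int(rng.integers(len(active))))
        for child in (i, j):
            w = float(rng.uniform(*blen))
            adjacency.setdefault(nxt, []).append((child, w))
            adjacency[child].append((nxt, w))
        active.append(nxt)
        nxt += 1
    dist = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adjacency[u]:
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for dst in range(n_leaves):
            dist[src, dst] = seen[dst]
    dist = (dist + dist.T) / 2  # float addition order differs per direction
    return labels, dist
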