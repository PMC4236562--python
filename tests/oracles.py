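"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by exhaustive enumeration or
first-principles arithmetic, sharing no code path with the package
implementation it checks.
"""

from __future__ import annotations

import itertools
import math


def brute_force_alignment_score(
    a: str,
    b: str,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Best global alignment score by enumerating every alignment path.

    Affine gaps: a run of k consecutive gaps in one sequence costs
    gap_open + (k-1) * gap_extend.  Pure recursion, no memoization.
    """

    best = [-math.inf]

    def step(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            step(i + 1, j + 1, score + s, "M")
        if i < len(a):  # gap in b
            cost = gap_extend if last == "D" else gap_open
            step(i + 1, j, score + cost, "D")
        if j < len(b):  # gap in a
            cost = gap_extend if last == "I" else gap_open
            step(i, j + 1, score + cost, "I")

    step(0, 0, 0.0, "")
    return best[0]


def brute_force_components(n: int, edges: set[tuple[int, int]]) -> list[frozenset]:
    """Connected components by repeated closure over an explicit edge set."""
    comps = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for i, j in edges:
            ci = next(c for c in comps if i in c)
            cj = next(c for c in comps if j in c)
            if ci is not cj:
                comps.remove(cj)
                ci.update(cj)
                changed = True
    return sorted((frozenset(c) for c in comps), key=min)


def expand_prosite(pattern: str, alphabet: str) -> list[str]:
    """All concrete strings matching a PROSITE-style pattern over a
    (reduced) alphabet.  Supports literals, x, [..], and (m,n) repeats."""
    elements: list[list[str]] = []
    i = 0
    text = pattern.replace("-", "")
    while i < len(text):
        ch = text[i]
        if ch == "x":
            options = list(alphabet)
            i += 1
        elif ch == "[":
            close = text.index("]", i)
            options = [c for c in text[i + 1 : close].upper() if c in alphabet]
            i = close + 1
        else:
            options = [ch.upper()]
            i += 1
        lo = hi = 1
        if i < len(text) and text[i] == "(":
            close = text.index(")", i)
            bounds = text[i + 1 : close].split(",")
            lo = int(bounds[0])
            hi = int(bounds[1]) if len(bounds) > 1 else lo
            i = close + 1
        elements.append([  # each repeat count is a separate alternative
            "".join(p)
            for k in range(lo, hi + 1)
            for p in itertools.product(options, repeat=k)
        ])
    out = [""]
    for alts in elements:
        out = [prefix + alt for prefix in out for alt in alts]
    return out


def oracle_scan(sequence: str, pattern: str, alphabet: str) -> list[tuple[int, str]]:
    """(1-based start, match) hits by concrete-expansion search;
    leftmost-shortest per start position."""
    expansions = set(expand_prosite(pattern, alphabet))
    hits = []
    for start in range(len(sequence)):
        candidates = [
            e for e in expansions if sequence[start : start + len(e)] == e
        ]
        if candidates:
            shortest = min(candidates, key=len)
            hits.append((start + 1, shortest))
    return hits


def random_tuple_tree(labels: list[str], rng) -> object:
    """A random rooted binary tree as nested tuples
    (left, left_len, right, right_len); leaves are labels."""
    if len(labels) == 1:
        return labels[0]
    k = int(rng.integers(1, len(labels)))
    left = random_tuple_tree(labels[:k], rng)
    right = random_tuple_tree(labels[k:], rng)
    llen = float(rng.uniform(0.05, 1.0))
    rlen = float(rng.uniform(0.05, 1.0))
    return (left, llen, right, rlen)


def tuple_tree_distances(node) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths of a tuple tree, by recursion."""

    def walk(n):
        if isinstance(n, str):
            return {n: 0.0}, {}
        left, llen, right, rlen = n
        dl, pl = walk(left)
        dr, pr = walk(right)
        dl = {k: v + llen for k, v in dl.items()}
        dr = {k: v + rlen for k, v in dr.items()}
        pairs = dict(pl)
        pairs.update(pr)
        for x in dl:
            for y in dr:
                pairs[tuple(sorted((x, y)))] = dl[x] + dr[y]
        depths = dict(dl)
        depths.update(dr)
        return depths, pairs

    return walk(node)[1]
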