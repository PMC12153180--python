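"""Independent reference implementations used to check the package.

These oracles deliberately avoid the code paths they validate: exhaustive
enumeration for local alignment, per-column map composition for chain
projection, breadth-first search for components, and direct tail summation
for binomial tests.
"""

from __future__ import annotations

import math
from collections import deque
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Set, Tuple


def brute_force_local_score(
    q: str,
    s: str,
    matrix: Dict[Tuple[str, str], float],
    gap_open: float,
    gap_extend: float,
) -> float:
    """Best local alignment score by exhaustive enumeration.

    Considers every alignment that starts and ends with a substitution
    column; between two substitution columns any pair of gap runs (one per
    sequence) is allowed, charged ``gap_open + len * gap_extend`` each.
    Interleaved gap runs are never better under affine costs, so this
    enumeration attains the Smith-Waterman optimum. Returns 0 when no
    alignment scores positively.
    """

    nq, ns = len(q), len(s)

    def gap_cost(g: int) -> float:
        return 0.0 if g == 0 else -(gap_open + g * gap_extend)

    @lru_cache(maxsize=None)
    def extend(i: int, j: int) -> float:
        # best score of a suffix starting with the substitution q[i]:s[j]
        here = matrix[(q[i], s[j])]
        best_tail = 0.0
        for gq in range(nq - i):
            for gs in range(ns - j):
                ni, nj = i + 1 + gq, j + 1 + gs
                if ni >= nq or nj >= ns:
                    continue
                tail = gap_cost(gq) + gap_cost(gs) + extend(ni, nj)
                if tail > best_tail:
                    best_tail = tail
        return here + best_tail

    best = 0.0
    for i in range(nq):
        for j in range(ns):
            best = max(best, extend(i, j))
    return best


# ---------------------------------------------------------------------------
# Chain projection on explicit gapless alignments

class GaplessLink:
    """A gapless alignment between sequence A (query) and B (subject):
    A[a_start..a_end] columns map one-to-one onto B[b_start..b_end]
    (1-based inclusive, equal lengths)."""

    def __init__(self, a_len: int, b_len: int, a_start: int, b_start: int, span: int):
        assert a_start + span - 1 <= a_len and b_start + span - 1 <= b_len
        self.a_len, self.b_len = a_len, b_len
        self.a_start, self.b_start = a_start, b_start
        self.span = span

    @property
    def a_end(self) -> int:
        return self.a_start + self.span - 1

    @property
    def b_end(self) -> int:
        return self.b_start + self.span - 1

    def map_a_to_b(self, cols: Set[int]) -> Set[int]:
        return {
            self.b_start + (c - self.a_start)
            for c in cols
            if self.a_start <= c <= self.a_end
        }

    def map_b_to_a(self, cols: Set[int]) -> Set[int]:
        return {
            self.a_start + (c - self.b_start)
            for c in cols
            if self.b_start <= c <= self.b_end
        }


def column_chain_decisions(
    seed_len: int,
    links: Sequence[GaplessLink],
    min_coverage: float = 0.8,
) -> List[bool]:
    """Per-link accept/reject decisions of the chain rule by explicit
    per-column set composition.

    ``links[0]`` aligns the seed (A side) to the first candidate; each later
    link aligns the previously accepted candidate to the next one. At every
    link, the columns of the new candidate that trace back to the seed and
    the seed columns they land on must both cover >= ``min_coverage``.
    Stops at the first rejection (the chain cannot be extended).
    """
    decisions: List[bool] = []
    live_parent_cols = set(range(1, seed_len + 1))  # parent columns that reach the seed
    # map from parent columns to seed columns, maintained by composition
    parent_to_seed = {c: c for c in live_parent_cols}
    for link in links:
        cand_cols = set()
        cand_to_seed = {}
        for c in sorted(live_parent_cols & set(range(link.a_start, link.a_end + 1))):
            b = link.b_start + (c - link.a_start)
            cand_cols.add(b)
            cand_to_seed[b] = parent_to_seed[c]
        seed_cols = set(cand_to_seed.values())
        self_cov = len(cand_cols) / link.b_len
        seed_cov = len(seed_cols) / seed_len
        ok = self_cov >= min_coverage and seed_cov >= min_coverage
        decisions.append(ok)
        if not ok:
            break
        live_parent_cols = cand_cols
        parent_to_seed = cand_to_seed
    return decisions


# ---------------------------------------------------------------------------
# Graph and statistics oracles

def bfs_components(nodes: Sequence[str], edges: Sequence[Tuple[str, str]]) -> List[Set[str]]:
    adj: Dict[str, Set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: Set[str] = set()
    comps = []
    for n in nodes:
        if n in seen:
            continue
        comp = {n}
        queue = deque([n])
        seen.add(n)
        while queue:
            cur = queue.popleft()
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P[X >= k] for X ~ Binomial(n, p), by direct summation."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def binomial_lower_tail(k: int, n: int, p: float) -> float:
    """P[X <= k] for X ~ Binomial(n, p), by direct summation."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1))


def mixing_matrix_assortativity(
    edges: Sequence[Tuple[str, str]], label_of: Dict[str, str]
) -> float:
    """Newman attribute assortativity from the edge mixing matrix, computed
    directly from its definition."""
    labels = sorted({label_of[a] for a, b in edges} | {label_of[b] for a, b in edges})
    index = {l: i for i, l in enumerate(labels)}
    k = len(labels)
    e = [[0.0] * k for _ in range(k)]
    for a, b in edges:
        i, j = index[label_of[a]], index[label_of[b]]
        e[i][j] += 1
        e[j][i] += 1
    total = sum(sum(row) for row in e)
    e = [[x / total for x in row] for row in e]
    trace = sum(e[i][i] for i in range(k))
    ab = sum(sum(e[i]) * sum(e[j][i] for j in range(k)) for i in range(k))
    if ab == 1.0:
        return 1.0
    return (trace - ab) / (1 - ab)
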