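"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results by enumeration or closed form, without
touching the implementation code paths they are checked against.
"""

from __future__ import annotations

import itertools
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> float:
    return float(_B62[a, b])


def brute_force_global_score(
    s1: str, s2: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Best global alignment score by exhaustive recursion over alignments.

    Affine convention: a gap of length k costs gap_open + k * gap_extend;
    consecutive gaps in opposite sequences are separate gaps.
    """
    best = [-np.inf]

    def rec(i: int, j: int, score: float, last: str) -> None:
        if i == len(s1) and j == len(s2):
            if score > best[0]:
                best[0] = score
            return
        if i < len(s1) and j < len(s2):
            rec(i + 1, j + 1, score + blosum62(s1[i], s2[j]), "M")
        if i < len(s1):
            cost = gap_extend if last == "D" else gap_open + gap_extend
            rec(i + 1, j, score - cost, "D")
        if j < len(s2):
            cost = gap_extend if last == "I" else gap_open + gap_extend
            rec(i, j + 1, score - cost, "I")

    rec(0, 0, 0.0, "")
    return best[0]


def brute_force_edge_connectivity(
    edges: Sequence[Tuple[int, int]], u: int, v: int
) -> int:
    """Minimum edges to remove to disconnect u from v, by subset enumeration."""

    def connected(remaining: Sequence[Tuple[int, int]]) -> bool:
        adj: Dict[int, Set[int]] = {}
        for a, b in remaining:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        seen = {u}
        stack = [u]
        while stack:
            x = stack.pop()
            if x == v:
                return True
            for y in adj.get(x, ()):  # noqa: B905
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return u == v

    if not connected(edges):
        return 0
    for size in range(1, len(edges) + 1):
        for cut in itertools.combinations(range(len(edges)), size):
            remaining = [e for k, e in enumerate(edges) if k not in cut]
            if not connected(remaining):
                return size
    return len(edges)


def connected_components(edges: Iterable[Tuple[str, str]], nodes: Iterable[str]) -> List[Set[str]]:
    adj: Dict[str, Set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: Set[str] = set()
    comps = []
    for n in adj:
        if n in seen:
            continue
        comp = {n}
        stack = [n]
        seen.add(n)
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    comp.add(y)
                    stack.append(y)
        comps.append(comp)
    return comps


def exact_binomial_two_sided(k: int, n: int, p: float) -> float:
    """Minimum-likelihood two-sided exact binomial p by outcome enumeration."""
    from scipy.stats import binom

    probs = binom.pmf(np.arange(n + 1), n, p)
    return float(probs[probs <= probs[k] * (1 + 1e-9)].sum())


def exact_rank_sum_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of group assignments."""
    vals = list(x) + list(y)
    na, n = len(x), len(vals)

    def ustat(a: Sequence[float], b: Sequence[float]) -> float:
        return sum(1.0 for xi in a for yi in b if xi > yi) + 0.5 * sum(
            1.0 for xi in a for yi in b if xi == yi
        )

    u_obs = ustat(x, y)
    us = []
    for idx in itertools.combinations(range(n), na):
        sel = set(idx)
        a = [vals[i] for i in idx]
        b = [vals[i] for i in range(n) if i not in sel]
        us.append(ustat(a, b))
    us = np.asarray(us)
    lo = (us <= u_obs + 1e-12).mean()
    hi = (us >= u_obs - 1e-12).mean()
    return float(min(1.0, 2 * min(lo, hi)))


def chi_square_statistic(observed: np.ndarray) -> float:
    """Pearson chi-square from the textbook formula on a contingency table."""
    observed = np.asarray(observed, dtype=float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row * col / observed.sum()
    return float(((observed - expected) ** 2 / expected).sum())
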