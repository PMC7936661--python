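"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (exhaustive scans, exact
rational arithmetic) and deliberately shares no code path with the package.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def brute_triangles(network) -> set[tuple[str, str, str]]:
    """All triangles by scanning every node triple."""
    nodes = sorted(network.nodes)
    out = set()
    for a, b, c in itertools.combinations(nodes, 3):
        if network.has_edge(a, b) and network.has_edge(a, c) and network.has_edge(b, c):
            out.add((a, b, c))
    return out


def brute_4cycles(network) -> set[tuple[str, ...]]:
    """All simple 4-cycles (chords allowed) by checking every 4-subset's three
    distinct cyclic arrangements."""
    nodes = sorted(network.nodes)
    out = set()
    for quad in itertools.combinations(nodes, 4):
        a, b, c, d = quad
        # the three distinct cycles on {a,b,c,d}: a-b-c-d, a-b-d-c, a-c-b-d
        for cyc in ((a, b, c, d), (a, b, d, c), (a, c, b, d)):
            ok = all(
                network.has_edge(cyc[i], cyc[(i + 1) % 4]) for i in range(4)
            )
            if ok:
                out.add(canonical_4cycle(cyc))
    return out


def canonical_4cycle(cycle: tuple[str, ...]) -> tuple[str, ...]:
    best = None
    for seq in (cycle, cycle[::-1]):
        for i in range(4):
            rot = seq[i:] + seq[:i]
            if best is None or rot < best:
                best = rot
    return best


def brute_partner_pairs(network) -> dict[str, set[frozenset[str]]]:
    out: dict[str, set[frozenset[str]]] = {}
    for a, b, c in brute_triangles(network):
        out.setdefault(a, set()).add(frozenset((b, c)))
        out.setdefault(b, set()).add(frozenset((a, c)))
        out.setdefault(c, set()).add(frozenset((a, b)))
    return out


def brute_commonality(network, min_shared=3, min_frac=0.95) -> set[tuple[str, str]]:
    """Exhaustive pair scan against the brute-force partner-pair sets."""
    pairs_of = brute_partner_pairs(network)
    owners = sorted(pairs_of)
    out = set()
    for x, y in itertools.combinations(owners, 2):
        if network.has_edge(x, y):
            continue
        shared = len(pairs_of[x] & pairs_of[y])
        if shared < min_shared:
            continue
        if shared >= min_frac * len(pairs_of[x]) and shared >= min_frac * len(pairs_of[y]):
            out.add((x, y))
    return out


def enum_fisher(a: int, b: int, c: int, d: int, side: str) -> float:
    """Fisher's exact p by full hypergeometric enumeration in exact rationals.

    Two-sided sums outcome probabilities no greater than the observed one,
    with the customary (1 + 1e-7) relative slack on ties.
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, r1)
    probs = {k: Fraction(comb(c1, k) * comb(n - c1, r1 - k), denom) for k in range(lo, hi + 1)}
    pobs = probs[a]
    if side == "greater":
        total = sum(p for k, p in probs.items() if k >= a)
    elif side == "less":
        total = sum(p for k, p in probs.items() if k <= a)
    else:
        total = sum(p for p in probs.values() if p <= pobs * Fraction(10**7 + 1, 10**7))
    return float(min(total, Fraction(1)))
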