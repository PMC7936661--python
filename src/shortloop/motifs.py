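"""Short-loop (network-motif) enumeration and loop-density profiling.

A short loop of length ``k`` is a simple cycle of ``k`` distinct proteins in
which every cyclically consecutive pair interacts. Length 3 (a triangle of
mutually interacting proteins) is the default; length-4 cycles are supported
and counted with chords allowed, i.e. a 4-cycle embedded in a 4-clique still
counts (use ``chordless=True`` for the stricter reading). Loop counts scale
with network size, so the comparable statistic is the loop ratio: loops
divided by interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

from shortloop.netio import Network

ShortLoop = tuple[str, ...]


def _canonical_cycle(cycle: tuple[str, str, str, str]) -> ShortLoop:
    """Lexicographically smallest rotation/reflection of a 4-node cycle."""
    best = None
    n = len(cycle)
    for seq in (cycle, cycle[::-1]):
        for i in range(n):
            rot = seq[i:] + seq[:i]
            if best is None or rot < best:
                best = rot
    return best


def enumerate_short_loops(network: Network, k: int = 3, chordless: bool = False) -> set[ShortLoop]:
    """Enumerate all short loops of length ``k`` in canonical form.

    Triangles are returned as sorted 3-tuples (each 3-clique once). 4-cycles
    are returned as the lexicographically smallest rotation/reflection of the
    node cycle, each node-cycle once regardless of chords unless
    ``chordless`` is set.
    """
    if k not in (3, 4):
        raise ValueError(f"loop length must be 3 or 4, got {k}")
    g = network.graph
    if k == 3:
        # sorted-adjacency neighbour intersection: each triangle found exactly
        # once at its lexicographically smallest edge
        adj = {v: set(g.neighbors(v)) for v in g.nodes}
        loops: set[ShortLoop] = set()
        for a, b in g.edges:
            u, v = (a, b) if a < b else (b, a)
            for w in adj[u] & adj[v]:
                if w > v:
                    loops.add((u, v, w))
        return loops
    # k == 4: walk diagonals. A 4-cycle u-x-w-y has diagonals {u,w} and {x,y};
    # canonicalisation dedupes the two discoveries.
    loops = set()
    adj = {v: set(g.neighbors(v)) for v in g.nodes}
    nodes = sorted(g.nodes)
    for i, u in enumerate(nodes):
        for w in nodes[i + 1:]:
            common = sorted(adj[u] & adj[w])
            for j, x in enumerate(common):
                for y in common[j + 1:]:
                    if chordless and (g.has_edge(u, w) or g.has_edge(x, y)):
                        continue
                    loops.add(_canonical_cycle((u, x, w, y)))
    return loops


def loop_ratio(n_loops: int, n_edges: int) -> float:
    """Normalised loop density: loop count divided by interaction count."""
    if n_edges <= 0:
        raise ValueError("loop ratio undefined for a network with no interactions")
    return n_loops / n_edges


def partner_pairs(loops: set[ShortLoop]) -> dict[str, set[frozenset[str]]]:
    """Per-protein partner-pair sets from a triangle set.

    Each triangle {X, A, B} contributes the pair {A, B} to X's set (and
    symmetrically for A and B). Proteins in no triangle are absent from the
    mapping. Defined for length-3 loops only.
    """
    out: dict[str, set[frozenset[str]]] = {}
    for loop in loops:
        if len(loop) != 3:
            raise ValueError("partner pairs are defined for length-3 loops only")
        a, b, c = loop
        out.setdefault(a, set()).add(frozenset((b, c)))
        out.setdefault(b, set()).add(frozenset((a, c)))
        out.setdefault(c, set()).add(frozenset((a, b)))
    return out


@dataclass
class LoopProfile:
    """Network-level short-loop summary (one table row per network)."""

    network_label: str
    n_proteins: int
    n_edges: int
    n_loops: int
    ratio: float
    consensus_pct: float | None = None

    def as_dict(self) -> dict:
        d = {
            "network": self.network_label,
            "n_proteins": self.n_proteins,
            "n_edges": self.n_edges,
            "n_loops": self.n_loops,
            "ratio": round(self.ratio, 2),
        }
        if self.consensus_pct is not None:
            d["consensus_pct"] = round(self.consensus_pct, 2)
        return d


def loop_profile(
    network: Network,
    annotations: dict[str, set[str]] | None = None,
    k: int = 3,
    label: str = "",
    unannotated_policy: str = "count-as-no-consensus",
) -> LoopProfile:
    """Compute the full loop profile of a network.

    The functional-consensus percentage is filled only when an annotation map
    is supplied and the network has at least one loop.
    """
    from shortloop.consensus import consensus_ratio

    loops = enumerate_short_loops(network, k=k)
    ratio = loop_ratio(len(loops), network.n_edges) if network.n_edges else 0.0
    pct = None
    if annotations is not None and loops:
        pct = consensus_ratio(loops, annotations, unannotated_policy=unannotated_policy)
    return LoopProfile(
        network_label=label,
        n_proteins=network.n_nodes,
        n_edges=network.n_edges,
        n_loops=len(loops),
        ratio=ratio,
        consensus_pct=pct,
    )


def write_loops(loops: set[ShortLoop], path) -> None:
    """One loop per row, members tab-separated in canonical order."""
    with open(path, "w") as fh:
        for loop in sorted(loops):
            fh.write("\t".join(loop) + "\n")
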