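"""Short-loop commonality: indirect association via shared partner pairs.

Two proteins X and Y are in *short loop commonality* when they do not interact
directly but form triangles with the same partner pairs: X makes loops with
{A,B}, {B,C}, {C,D} and so does Y, yet there is no X-Y interaction. The
default criteria require at least three shared partner pairs and that 95% of
each protein's partner pairs are shared (the symmetric, strictest reading;
``frac_mode`` relaxes it).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from shortloop.motifs import ShortLoop, partner_pairs
from shortloop.netio import Network

_FRAC_MODES = ("both", "either", "max", "min")


@dataclass(frozen=True)
class CommonalityPair:
    """An unordered commonality pair with its overlap statistics.

    ``shared`` is the number of common partner pairs; ``frac_x`` and
    ``frac_y`` are the shared fraction of each protein's partner-pair set.
    Stored with ``x < y`` so (x, y) and (y, x) are the same object.
    """

    x: str
    y: str
    shared: int
    frac_x: float
    frac_y: float

    def proteins(self) -> frozenset[str]:
        return frozenset((self.x, self.y))


def find_commonality_pairs(
    network: Network,
    loops: set[ShortLoop],
    min_shared: int = 3,
    min_frac: float = 0.95,
    frac_mode: str = "both",
) -> list[CommonalityPair]:
    """Detect all commonality pairs of a network from its triangle set.

    A pair (x, y) qualifies when x and y are not adjacent, they share at least
    ``min_shared`` partner pairs, and the shared fraction passes ``min_frac``
    under ``frac_mode``: "both" requires both fractions to pass (default),
    "either"/"max" requires the larger to pass, "min" is an alias of "both"'s
    binding constraint. Output is sorted lexicographically and duplicate-free.
    """
    if not (0.0 < min_frac <= 1.0):
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    if frac_mode not in _FRAC_MODES:
        raise ValueError(f"unknown frac_mode {frac_mode!r}; expected one of {_FRAC_MODES}")
    pairs_of = partner_pairs(loops)
    # invert: partner pair -> owners; only owners sharing >=1 pair are candidates
    owners: dict[frozenset[str], set[str]] = {}
    for prot, pp in pairs_of.items():
        for pair in pp:
            owners.setdefault(pair, set()).add(prot)
    candidates: set[tuple[str, str]] = set()
    for prots in owners.values():
        ordered = sorted(prots)
        for i, x in enumerate(ordered):
            for y in ordered[i + 1:]:
                candidates.add((x, y))
    out: list[CommonalityPair] = []
    for x, y in sorted(candidates):
        if network.has_edge(x, y):
            continue
        px, py = pairs_of[x], pairs_of[y]
        shared = len(px & py)
        if shared < min_shared:
            continue
        fx, fy = shared / len(px), shared / len(py)
        if frac_mode in ("both", "min"):
            ok = min(fx, fy) >= min_frac
        else:  # either / max
            ok = max(fx, fy) >= min_frac
        if ok:
            out.append(CommonalityPair(x, y, shared, fx, fy))
    return out


def mean_neighbours(n_nodes: int, n_pairs: int) -> float:
    """Average neighbour count of a commonality network: 2*pairs/nodes."""
    if n_nodes <= 0:
        raise ValueError("mean neighbours undefined for an empty network")
    return 2.0 * n_pairs / n_nodes


def commonality_network(pairs: list[CommonalityPair]) -> tuple[Network, dict]:
    """Assemble the commonality network (pairs as edges) and its summary.

    The summary reports node and pair counts, the mean neighbour count
    (rounded to 2 decimals), and connected-component ("cluster") sizes in
    descending order.
    """
    g = nx.Graph()
    for p in pairs:
        g.add_edge(p.x, p.y, shared=p.shared)
    net = Network(g)
    if not pairs:
        summary = {"n_nodes": 0, "n_pairs": 0, "mean_neighbours": None, "cluster_sizes": []}
        return net, summary
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    summary = {
        "n_nodes": g.number_of_nodes(),
        "n_pairs": g.number_of_edges(),
        "mean_neighbours": round(mean_neighbours(g.number_of_nodes(), g.number_of_edges()), 2),
        "cluster_sizes": sizes,
    }
    return net, summary


def control_set(
    disease_pairs: list[CommonalityPair],
    general_network: Network,
    general_loops: set[ShortLoop],
    disease_proteins: set[str],
    min_shared: int = 3,
    min_frac: float = 0.95,
    frac_mode: str = "both",
) -> list[CommonalityPair]:
    """Build the control pair set matched to a disease commonality set.

    Control pairs (A, B) are commonality pairs of the *general* network, under
    the same thresholds, where A occurs in some disease pair, B carries no
    disease mutation, and (A, B) is not itself a disease pair.
    """
    disease_members = {p for cp in disease_pairs for p in (cp.x, cp.y)}
    disease_keys = {cp.proteins() for cp in disease_pairs}
    general = find_commonality_pairs(
        general_network, general_loops, min_shared=min_shared,
        min_frac=min_frac, frac_mode=frac_mode,
    )
    out = []
    for cp in general:
        if cp.proteins() in disease_keys:
            continue
        for a, b in ((cp.x, cp.y), (cp.y, cp.x)):
            if a in disease_members and b not in disease_proteins:
                out.append(cp)
                break
    return out


def write_pairs(pairs: list[CommonalityPair], path) -> None:
    """Pairs TSV: x, y, shared, frac_x, frac_y."""
    with open(path, "w") as fh:
        fh.write("#x\ty\tshared\tfrac_x\tfrac_y\n")
        for p in pairs:
            fh.write(f"{p.x}\t{p.y}\t{p.shared}\t{p.frac_x:.4f}\t{p.frac_y:.4f}\n")
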