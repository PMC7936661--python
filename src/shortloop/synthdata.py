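"""Seedable generators for every input format the analysis modules consume.

Each generator emits data plus a :class:`SyntheticTruth` record of what was
planted, so detector output can be checked against known ground truth. At zero
background density / zero noise the planted structure is exactly recoverable
by construction. Generators write the same plain-text formats the readers
consume, so end-to-end tests exercise the public I/O surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from shortloop.motifs import enumerate_short_loops
from shortloop.netio import Network


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator, sufficient to predict detector
    output at the stated parameter regime."""

    planted_commonality_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_control_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_hotspots: dict[str, list[int]] = field(default_factory=dict)
    planted_dependency_classes: dict[tuple[str, str], str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_commonality_pairs": [list(p) for p in self.planted_commonality_pairs],
            "planted_control_pairs": [list(p) for p in self.planted_control_pairs],
            "planted_hotspots": {k: sorted(v) for k, v in self.planted_hotspots.items()},
            "planted_dependency_classes": {
                f"{x}|{y}": k for (x, y), k in self.planted_dependency_classes.items()
            },
            "params": self.params,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def gen_er_network(n: int, p: float, seed: int = 0, prefix: str = "P") -> Network:
    """Erdos-Renyi G(n, p) over accessions ``P0000..``; seed-reproducible.

    Every unordered node pair is an edge independently with probability p.
    All n nodes are retained (including isolates).
    """
    rng = np.random.default_rng(seed)
    labels = [f"{prefix}{i:04d}" for i in range(n)]
    net = Network.from_edges([], nodes=labels)
    if p <= 0 or n < 2:
        return net
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < p
    for i, j in zip(iu[mask], ju[mask]):
        net.add_edge(labels[i], labels[j], "er")
    return net


def gen_planted_commonality(
    n_background: int = 50,
    p_background: float = 0.0,
    n_motifs: int = 3,
    fan_size: int = 3,
    seed: int = 0,
) -> tuple[Network, SyntheticTruth]:
    """Plant commonality motifs on an ER background.

    Each motif has a hub pair (X, Y) with no X-Y edge and a chain of
    ``fan_size`` adjacent partner pairs (P1P2, P2P3, ... sharing members),
    every chain member connected to both X and Y. Both hubs then own exactly
    the same ``fan_size`` partner pairs, so the pair qualifies at the default
    criteria whenever ``fan_size >= 3``. Motifs use node labels disjoint from
    the background so at ``p_background = 0`` detection is exact.
    """
    if fan_size < 1:
        raise ValueError("fan_size must be >= 1")
    background = gen_er_network(n_background, p_background, seed=seed, prefix="B")
    net = background
    planted: list[tuple[str, str]] = []
    for m in range(n_motifs):
        x, y = f"M{m}_X", f"M{m}_Y"
        chain = [f"M{m}_P{i}" for i in range(fan_size + 1)]
        for a, b in zip(chain, chain[1:]):
            net.add_edge(a, b, "motif")
        for node in chain:
            net.add_edge(x, node, "motif")
            net.add_edge(y, node, "motif")
        planted.append((x, y))
    truth = SyntheticTruth(
        planted_commonality_pairs=planted,
        params={
            "n_background": n_background,
            "p_background": p_background,
            "n_motifs": n_motifs,
            "fan_size": fan_size,
        },
        seed=seed,
    )
    return net, truth


def gen_planted_control(
    n_disease_motifs: int = 3,
    n_control_motifs: int = 2,
    fan_size: int = 3,
    seed: int = 0,
) -> tuple[Network, Network, set[str], SyntheticTruth]:
    """Two-layer construction for disease vs control commonality sets.

    The *general* network carries disease motifs (both hubs X, Y mutated)
    plus, for each of the first ``n_control_motifs`` motifs, a fresh unmutated
    hub Y' wired to the *same* partner chain, so X, Y and Y' all own the
    identical partner-pair set. The *disease* subnetwork is induced on the
    mutated proteins, so it contains only the disease motifs and yields the
    (X, Y) pairs; the general network additionally yields (X, Y') and
    (Y, Y'), which are exactly the control pairs. Returns
    ``(general, disease, disease_proteins, truth)``.
    """
    from shortloop.netio import induce_subnetwork

    if n_control_motifs > n_disease_motifs:
        raise ValueError("n_control_motifs must be <= n_disease_motifs")
    general, truth = gen_planted_commonality(
        n_background=0, p_background=0.0, n_motifs=n_disease_motifs,
        fan_size=fan_size, seed=seed,
    )
    disease_proteins = set(general.nodes)
    controls: list[tuple[str, str]] = []
    for c in range(n_control_motifs):
        y2 = f"C{c}_Y"
        chain = [f"M{c}_P{i}" for i in range(fan_size + 1)]
        for node in chain:
            general.add_edge(y2, node, "control")
        controls.append((f"M{c}_X", y2))
        controls.append((f"M{c}_Y", y2))
    truth.planted_control_pairs = controls
    truth.params.update({"n_control_motifs": n_control_motifs})
    disease, _ = induce_subnetwork(general, disease_proteins)
    return general, disease, disease_proteins, truth


def gen_annotations(
    network: Network,
    n_terms: int = 50,
    p_consensus: float = 0.9,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Annotation map in which each triangle independently shares a term.

    With probability ``p_consensus`` a triangle's three members all receive a
    term unique to that triangle; every protein additionally carries one
    private term drawn from a pool of ``n_terms`` protein-specific labels, so
    no accidental sharing arises from the private layer. On a network of
    node-disjoint triangles the consensual fraction is exactly
    Binomial(n_loops, p_consensus).
    """
    rng = np.random.default_rng(seed)
    annotations: dict[str, set[str]] = {p: set() for p in network.nodes}
    for prot in sorted(annotations):
        annotations[prot].add(f"PRIV_{prot}_{rng.integers(n_terms)}")
    loops = sorted(enumerate_short_loops(network, k=3))
    for i, loop in enumerate(loops):
        if rng.random() < p_consensus:
            for prot in loop:
                annotations[prot].add(f"SHARED_{i}")
    return annotations


def gen_mutations(
    protein_length: int,
    n_records: int,
    hotspot_positions: list[int],
    hotspot_mass: float,
    n_samples: int = 10,
    seed: int = 0,
    protein: str = "PROT1",
) -> list["MutationRecord"]:
    """Mutation records with a planted hotspot mass.

    Exactly ``round(hotspot_mass * n_records)`` records land on the planted
    positions (cycled), the rest uniformly on non-hotspot positions; sample
    ids cycle over ``n_samples`` patients, so MHRD on the planted set equals
    ``hotspot_mass`` by construction (up to the rounding of the count).
    """
    from shortloop.mutations import MutationRecord

    if not 0.0 <= hotspot_mass <= 1.0:
        raise ValueError("hotspot_mass must be in [0, 1]")
    rng = np.random.default_rng(seed)
    hot = sorted(set(hotspot_positions))
    cold = [p for p in range(1, protein_length + 1) if p not in set(hot)]
    n_hot = round(hotspot_mass * n_records) if hot else 0
    positions: list[int] = [hot[i % len(hot)] for i in range(n_hot)] if n_hot else []
    if n_records - n_hot > 0:
        if not cold:
            raise ValueError("no non-hotspot positions available for background mass")
        positions += rng.choice(cold, size=n_records - n_hot, replace=True).tolist()
    return [
        MutationRecord(protein, f"S{i % n_samples:03d}", int(pos), "substitution_missense")
        for i, pos in enumerate(positions)
    ]


def gen_dependency(
    n_lines: int = 67,
    planted: dict[tuple[str, str], str] | None = None,
    n_decoy_genes: int = 4,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Dependency score matrix with planted mutual-exclusive / co-occurring
    gene pairs.

    Mutually exclusive pairs get disjoint three-line dependent blocks for each
    gene; co-occurring pairs get one shared three-line block. Decoy genes are
    dependent in at most one random line (below both the per-arm and the
    essentiality criteria). Dependent entries score around -2, others around
    0, so binarisation at -1 recovers the blocks; ``noise_rate`` flips entries
    at random to stress recovery.
    """
    if planted is None:
        planted = {("GME_A", "GME_B"): "mutual_exclusive", ("GCO_A", "GCO_B"): "co_occurring"}
    rng = np.random.default_rng(seed)
    genes: list[str] = []
    for x, y in planted:
        genes.extend([x, y])
    genes += [f"DECOY{i}" for i in range(n_decoy_genes)]
    if len(set(genes)) != len(genes):
        raise ValueError("planted pair genes must be distinct")
    dep = pd.DataFrame(False, index=[f"CL{i:03d}" for i in range(n_lines)], columns=genes)
    block = 3
    cursor = 0

    def take(k: int) -> list[int]:
        nonlocal cursor
        if cursor + k > n_lines:
            raise ValueError("not enough cell lines for the planted blocks")
        rows = list(range(cursor, cursor + k))
        cursor += k
        return rows

    for (x, y), klass in planted.items():
        if klass == "mutual_exclusive":
            dep.iloc[take(block), dep.columns.get_loc(x)] = True
            dep.iloc[take(block), dep.columns.get_loc(y)] = True
        elif klass == "co_occurring":
            rows = take(block)
            dep.iloc[rows, dep.columns.get_loc(x)] = True
            dep.iloc[rows, dep.columns.get_loc(y)] = True
        else:
            raise ValueError(f"unknown planted class {klass!r}")
    for i in range(n_decoy_genes):
        dep.iloc[int(rng.integers(n_lines)), dep.columns.get_loc(f"DECOY{i}")] = True
    if noise_rate > 0:
        flips = rng.random(dep.shape) < noise_rate
        dep = dep ^ flips
    scores = pd.DataFrame(
        rng.uniform(-0.4, 0.4, size=dep.shape), index=dep.index, columns=dep.columns
    )
    scores = scores.mask(dep, rng.uniform(-2.5, -1.5, size=dep.shape))
    truth = SyntheticTruth(
        planted_dependency_classes=dict(planted),
        params={"n_lines": n_lines, "n_decoy_genes": n_decoy_genes, "noise_rate": noise_rate},
        seed=seed,
    )
    return scores, truth


# ---------------------------------------------------------------------------
# file writers (same formats the readers consume)

def write_annotation_table(annotations: dict[str, set[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for prot in sorted(annotations):
            for term in sorted(annotations[prot]):
                fh.write(f"{prot}\t{term}\n")


def write_mutation_table(records, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#protein\tsample_id\tposition\tmutation_type\taa_change\n")
        for r in records:
            fh.write(f"{r.protein}\t{r.sample_id}\t{r.position}\t{r.mutation_type}\t{r.aa_change or ''}\n")


def write_length_table(lengths: dict[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for prot in sorted(lengths):
            fh.write(f"{prot}\t{lengths[prot]}\n")


def write_dependency_csv(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path)
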