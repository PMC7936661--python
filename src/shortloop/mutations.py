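"""Mutation tables, hotspot detection and the mutation-hotspot ratio density.

Per-sample mutation records (protein, sample id, 1-based residue position,
mutation type) are filtered to non-synonymous types observed in at least two
distinct patients per protein. A *hotspot* is a residue position carrying a
disproportionate share of a protein's mutations; the mutation-hotspot ratio
density (MHRD) is the fraction of the protein's mutations that fall on its
hotspots, tested for significance against a null that scatters the same
number of mutations uniformly over the protein sequence.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: non-synonymous mutation-type labels admitted by default
DEFAULT_ALLOWED_TYPES = frozenset({
    "substitution_nonsense",
    "substitution_missense",
    "insertion_inframe",
    "insertion_frameshift",
    "deletion_inframe",
    "deletion_frameshift",
    "complex",
})


@dataclass(frozen=True)
class MutationRecord:
    """One observed mutation: protein, patient sample, residue position, type.

    Positions are 1-based indices on the canonical protein sequence;
    insertions and deletions carry their start position.
    """

    protein: str
    sample_id: str
    position: int
    mutation_type: str
    aa_change: str | None = None


@dataclass
class HotspotResult:
    """Hotspot positions and MHRD of one protein, with null-model scores."""

    protein: str
    hotspot_positions: set[int]
    mhrd: float
    z: float
    p_empirical: float
    n_sims: int
    seed: int


def read_mutation_table(
    path: str | Path,
    allowed_types: frozenset[str] | set[str] = DEFAULT_ALLOWED_TYPES,
    min_patients: int = 2,
) -> dict[str, list[MutationRecord]]:
    """Read a mutation TSV and apply the inclusion filters.

    Columns: protein, sample_id, position, mutation_type, [aa_change]; ``#``
    comment lines skipped. Rows with a type outside ``allowed_types`` are
    dropped (count logged). Proteins mutated in fewer than ``min_patients``
    distinct samples are removed entirely. Returns records grouped per
    protein.
    """
    per_protein: dict[str, list[MutationRecord]] = defaultdict(list)
    n_skipped = 0
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns, got {line!r}")
            protein, sample_id, pos_s, mtype = (p.strip() for p in parts[:4])
            if mtype not in allowed_types:
                n_skipped += 1
                continue
            position = int(pos_s)
            if position < 1:
                raise ValueError(f"{path}:{lineno}: position must be >= 1, got {position}")
            aa = parts[4].strip() if len(parts) > 4 and parts[4].strip() else None
            per_protein[protein].append(MutationRecord(protein, sample_id, position, mtype, aa))
    if n_skipped:
        logger.info("%s: skipped %d rows with disallowed mutation types", path, n_skipped)
    return {
        prot: recs
        for prot, recs in per_protein.items()
        if len({r.sample_id for r in recs}) >= min_patients
    }


def read_length_table(path: str | Path) -> dict[str, int]:
    """Read a ``protein<TAB>length`` table (residue counts)."""
    out: dict[str, int] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            prot, length = line.split("\t")[:2]
            out[prot.strip()] = int(length)
    return out


def nsnv_frequency(n_variants: int, protein_length: int) -> float:
    """Length-normalised variant frequency: variants per residue.

    Assumes protein mutability scales with sequence length, so proteins of
    different sizes become comparable.
    """
    if protein_length <= 0:
        raise ValueError("protein length must be positive")
    return n_variants / protein_length


def detect_hotspots(
    records: list[MutationRecord],
    protein_length: int,
    min_fraction: float = 0.05,
    min_samples: int = 2,
) -> set[int]:
    """Residue positions carrying a disproportionate share of mutations.

    A position is a hotspot when it holds at least ``min_fraction`` of the
    protein's mutations and is mutated in at least ``min_samples`` distinct
    samples.
    """
    if not records:
        raise ValueError("hotspot detection requires at least one record")
    total = len(records)
    counts = Counter(r.position for r in records)
    samples_at: dict[int, set[str]] = defaultdict(set)
    for r in records:
        samples_at[r.position].add(r.sample_id)
    return {
        pos
        for pos, c in counts.items()
        if c >= min_fraction * total and len(samples_at[pos]) >= min_samples
    }


def mhrd(records: list[MutationRecord], hotspot_positions: set[int]) -> float:
    """Mutation-hotspot ratio density: hotspot mutations / all mutations."""
    if not records:
        raise ValueError("MHRD requires at least one record")
    at_hotspot = sum(r.position in hotspot_positions for r in records)
    return at_hotspot / len(records)


def hotspot_significance(
    records: list[MutationRecord],
    hotspot_positions: set[int],
    protein_length: int,
    n_sims: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Score the observed MHRD against a uniform-placement null.

    Each simulation scatters N = len(records) mutations uniformly and
    independently over positions 1..L and measures the mass landing on the
    *fixed* observed hotspot positions (hotspots are not re-detected per
    simulation). Returns ``(z, p_empirical)`` where z standardises the
    observed MHRD by the null mean and sd, and p is the add-one-smoothed
    upper-tail fraction ``(r + 1) / (n_sims + 1)``. A degenerate null
    (sd = 0, e.g. every position a hotspot) yields z = inf with p computed
    as usual, or z = 0 when observed equals the null mean.
    """
    if protein_length < 1:
        raise ValueError("protein length must be >= 1")
    if n_sims < 100:
        raise ValueError("need at least 100 simulations")
    n = len(records)
    if n == 0:
        raise ValueError("significance requires at least one record")
    observed = mhrd(records, hotspot_positions)
    hot = np.zeros(protein_length + 1, dtype=bool)
    for pos in hotspot_positions:
        if 1 <= pos <= protein_length:
            hot[pos] = True
    rng = np.random.default_rng(seed)
    null_stats = np.empty(n_sims)
    # chunked so memory stays bounded for large N * n_sims
    chunk = max(1, min(n_sims, 10_000_000 // max(n, 1)))
    done = 0
    while done < n_sims:
        m = min(chunk, n_sims - done)
        placements = rng.integers(1, protein_length + 1, size=(m, n))
        null_stats[done:done + m] = hot[placements].sum(axis=1) / n
        done += m
    null_mean = float(null_stats.mean())
    null_sd = float(null_stats.std(ddof=1))
    r = int((null_stats >= observed).sum())
    p_emp = (r + 1) / (n_sims + 1)
    if null_sd == 0:
        z = 0.0 if observed == null_mean else math.copysign(math.inf, observed - null_mean)
    else:
        z = (observed - null_mean) / null_sd
    return z, p_emp


def hotspot_report(
    per_protein: dict[str, list[MutationRecord]],
    lengths: dict[str, int],
    min_fraction: float = 0.05,
    min_samples: int = 2,
    n_sims: int = 10000,
    seed: int = 0,
) -> list[HotspotResult]:
    """Detect hotspots and score MHRD for every protein with a known length."""
    results = []
    ss = np.random.SeedSequence(seed)
    for prot, child in zip(sorted(per_protein), ss.spawn(len(per_protein))):
        if prot not in lengths:
            logger.info("no length for %s; skipped", prot)
            continue
        recs = per_protein[prot]
        length = lengths[prot]
        hotspots = detect_hotspots(recs, length, min_fraction=min_fraction, min_samples=min_samples)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        z, p = hotspot_significance(recs, hotspots, length, n_sims=n_sims, seed=sub_seed)
        results.append(HotspotResult(prot, hotspots, mhrd(recs, hotspots), z, p, n_sims, sub_seed))
    return results
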