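"""Functional consensus of short loops from protein annotation terms.

A loop has functional consensus when its member proteins share at least one
annotation term (exact term-identifier match; no ontology-hierarchy
propagation -- apply ancestor closure to the annotation table beforehand if
hierarchy-aware sharing is wanted). The network-level statistic is the
percentage of loops with consensus.
"""

from __future__ import annotations

from pathlib import Path

AnnotationMap = dict[str, set[str]]

_POLICIES = ("count-as-no-consensus", "exclude")


def loop_consensus(loop: tuple[str, ...], annotations: AnnotationMap) -> tuple[bool, float]:
    """Whether a loop's members share a term, plus a graded Jaccard percent.

    Returns ``(has_consensus, graded_pct)`` where ``has_consensus`` is true iff
    the intersection of the members' term sets is non-empty and ``graded_pct``
    is ``100 * |intersection| / |union|`` (0 when the union is empty).
    """
    term_sets = [annotations.get(p, set()) for p in loop]
    inter = set.intersection(*term_sets) if term_sets else set()
    union = set.union(*term_sets) if term_sets else set()
    pct = 100.0 * len(inter) / len(union) if union else 0.0
    return bool(inter), pct


def consensus_ratio(
    loops: set[tuple[str, ...]],
    annotations: AnnotationMap,
    unannotated_policy: str = "count-as-no-consensus",
) -> float | None:
    """Percentage of loops whose members share at least one term.

    Under the default policy a loop containing an unannotated protein simply
    cannot have consensus and counts in the denominator; under ``"exclude"``
    such loops are removed from numerator and denominator. Returns ``None``
    when no loops remain after the policy (the statistic is undefined).
    """
    if unannotated_policy not in _POLICIES:
        raise ValueError(f"unknown policy {unannotated_policy!r}; expected one of {_POLICIES}")
    if not loops:
        raise ValueError("consensus ratio requires a non-empty loop set")
    eligible = 0
    consensual = 0
    for loop in loops:
        if unannotated_policy == "exclude" and any(not annotations.get(p) for p in loop):
            continue
        eligible += 1
        if loop_consensus(loop, annotations)[0]:
            consensual += 1
    if eligible == 0:
        return None
    return 100.0 * consensual / eligible


def read_annotation_table(path: str | Path) -> AnnotationMap:
    """Read a ``protein<TAB>term`` table (one pair per row, # comments)."""
    out: AnnotationMap = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected protein<TAB>term, got {line!r}")
            out.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    return out


def read_gaf(path: str | Path) -> AnnotationMap:
    """Read a GAF 2.x subset: column 2 = accession, column 5 = term id."""
    out: AnnotationMap = {}
    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            out.setdefault(parts[1].strip(), set()).add(parts[4].strip())
    return out
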