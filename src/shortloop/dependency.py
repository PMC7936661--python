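"""Mutual-exclusivity / co-occurrence calling on CRISPR gene-dependency data.

Dependency matrices are depmap-style: one normalised knockout-effect score per
cell line x gene, scaled so a non-essential gene sits at 0 and the median
essential effect at -1. A cell line is *dependent* on a gene when its score is
strictly below -1. For a gene pair, dependency profiles are crossed in a 2x2
contingency table and Fisher's exact test is reported for both directions, but
classification follows count criteria rather than p-value cut-offs: sparse,
near-binary dependency profiles make raw independence p-values a poor ranking,
so they are reported for ordering only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_SIDES = {"greater": "greater", "less": "less", "two-sided": "two-sided"}


@dataclass
class DependencyCall:
    """Classification of one gene pair from crossed dependency profiles."""

    gene_x: str
    gene_y: str
    n_both: int
    n_x_only: int
    n_y_only: int
    n_neither: int
    p_me: float
    p_co: float
    klass: str  # mutual_exclusive | co_occurring | neither

    @property
    def n_lines(self) -> int:
        return self.n_both + self.n_x_only + self.n_y_only + self.n_neither


def read_dependency_csv(path: str | Path) -> pd.DataFrame:
    """Read a depmap-style CSV: first column cell-line label, one column per
    gene, real-valued scores (blank = missing)."""
    return pd.read_csv(path, index_col=0)


def binarize_dependency(matrix: pd.DataFrame, threshold: float = -1.0) -> pd.DataFrame:
    """Label dependent cells: score strictly below the threshold.

    A score exactly at the threshold is NOT dependent. Missing scores stay
    missing (pandas NA) so they can be excluded pairwise downstream.
    """
    binary = matrix < threshold
    return binary.mask(matrix.isna())


def pair_contingency(binary: pd.DataFrame, gene_x: str, gene_y: str) -> tuple[int, int, int, int]:
    """2x2 counts (both, x only, y only, neither) over cell lines with
    non-missing scores for both genes."""
    for g in (gene_x, gene_y):
        if g not in binary.columns:
            raise KeyError(f"gene {g!r} not in dependency matrix")
    sub = binary[[gene_x, gene_y]].dropna()
    x = sub[gene_x].astype(bool)
    y = sub[gene_y].astype(bool)
    n_both = int((x & y).sum())
    n_x_only = int((x & ~y).sum())
    n_y_only = int((~x & y).sum())
    n_neither = int((~x & ~y).sum())
    return n_both, n_x_only, n_y_only, n_neither


def fisher_exact(table: tuple[int, int, int, int], side: str = "two-sided") -> float:
    """Fisher's exact test on a 2x2 table given as (both, x_only, y_only,
    neither).

    ``side="greater"`` tests enrichment of the both/both cell (co-occurrence
    direction), ``"less"`` tests depletion (exclusivity direction),
    ``"two-sided"`` sums hypergeometric outcomes no more probable than the
    observed one.
    """
    if side not in _SIDES:
        raise ValueError(f"unknown side {side!r}; expected one of {sorted(_SIDES)}")
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=_SIDES[side]).pvalue)


def classify_pair(
    counts: tuple[int, int, int, int],
    max_dependent_fraction: float = 0.5,
    min_lines: int = 2,
    max_overlap: int = 0,
) -> DependencyCall:
    """Classify a gene pair as mutually exclusive, co-occurring or neither.

    Mutual exclusivity: at most ``max_overlap`` (default zero) co-dependent
    lines, at least ``min_lines`` lines dependent on each gene alone, and
    each gene dependent in strictly less than ``max_dependent_fraction`` of
    the lines (filters near-universally essential genes). Co-occurrence: at
    least ``min_lines`` co-dependent lines under the same essentiality cap.
    The two classes cannot both hold (co-occurrence needs >= 2 shared lines,
    exclusivity at most ``max_overlap`` < 2). Fisher p-values for both
    directions are attached for ranking, never for the class itself.
    """
    n_both, n_x_only, n_y_only, n_neither = counts
    n_lines = n_both + n_x_only + n_y_only + n_neither
    total_x = n_both + n_x_only
    total_y = n_both + n_y_only
    cap = max_dependent_fraction * n_lines
    under_cap = total_x < cap and total_y < cap
    if under_cap and n_both <= max_overlap and n_x_only >= min_lines and n_y_only >= min_lines:
        klass = "mutual_exclusive"
    elif under_cap and n_both >= min_lines:
        klass = "co_occurring"
    else:
        klass = "neither"
    p_me = fisher_exact(counts, side="less")
    p_co = fisher_exact(counts, side="greater")
    return DependencyCall("", "", n_both, n_x_only, n_y_only, n_neither, p_me, p_co, klass)


def screen_pairs(
    binary: pd.DataFrame,
    pairs: list[tuple[str, str]],
    max_dependent_fraction: float = 0.5,
    min_lines: int = 2,
    max_overlap: int = 0,
) -> tuple[list[DependencyCall], dict[str, int]]:
    """Classify a list of gene pairs; returns calls plus per-class tallies.

    Pairs with a gene absent from the matrix are skipped (logged); a
    degenerate pair (x, x) is an error.
    """
    calls: list[DependencyCall] = []
    summary = {"mutual_exclusive": 0, "co_occurring": 0, "neither": 0}
    for gx, gy in pairs:
        if gx == gy:
            raise ValueError(f"degenerate pair ({gx}, {gx})")
        if gx not in binary.columns or gy not in binary.columns:
            logger.info("pair (%s, %s) skipped: gene absent from matrix", gx, gy)
            continue
        counts = pair_contingency(binary, gx, gy)
        call = classify_pair(
            counts,
            max_dependent_fraction=max_dependent_fraction,
            min_lines=min_lines,
            max_overlap=max_overlap,
        )
        call.gene_x, call.gene_y = gx, gy
        calls.append(call)
        summary[call.klass] += 1
    return calls, summary


def write_calls(calls: list[DependencyCall], path) -> None:
    """Calls TSV: gene_x, gene_y, the four counts, both p-values, class."""
    with open(path, "w") as fh:
        fh.write("#gene_x\tgene_y\tn_both\tn_x_only\tn_y_only\tn_neither\tp_me\tp_co\tclass\n")
        for c in calls:
            fh.write(
                f"{c.gene_x}\t{c.gene_y}\t{c.n_both}\t{c.n_x_only}\t{c.n_y_only}\t"
                f"{c.n_neither}\t{c.p_me:.6g}\t{c.p_co:.6g}\t{c.klass}\n"
            )
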