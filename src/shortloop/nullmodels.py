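"""Random-subnetwork null models and z-scores for network statistics.

The null distribution of a statistic is built by repeatedly drawing a uniform
random protein subset (without replacement) of the size of the observed
subnetwork, inducing its interactions from the reference network, and
recomputing the statistic. Sampling is uniform over proteins, not
degree-matched. An observed value is then located on the null by its z-score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from shortloop.commonality import find_commonality_pairs, mean_neighbours
from shortloop.motifs import enumerate_short_loops
from shortloop.netio import Network, induce_subnetwork

STATISTICS = ("loop3_ratio", "mean_neighbours_commonality")


@dataclass
class NullDistribution:
    """Empirical null of a network statistic over random subnetworks.

    ``sd`` uses the n-1 denominator (sample standard deviation) and
    ``se = sd / sqrt(n_samples)``. ``n_degenerate`` counts samples on which
    the statistic was undefined (e.g. an edgeless subnetwork) and recorded
    as 0.
    """

    statistic_name: str
    samples: list[float]
    seed: int
    n_degenerate: int = 0
    mean: float = field(init=False)
    sd: float = field(init=False)
    se: float = field(init=False)

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        self.mean = float(arr.mean())
        if arr.size > 1 and not np.all(arr == arr[0]):
            self.sd = float(arr.std(ddof=1))
        else:
            self.sd = 0.0  # a constant null is exactly degenerate
        self.se = self.sd / math.sqrt(arr.size) if arr.size else 0.0

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "n_samples": self.n_samples,
            "mean": self.mean,
            "sd": self.sd,
            "se": self.se,
            "seed": self.seed,
            "n_degenerate": self.n_degenerate,
        }


def _loop3_ratio_stat(sub: Network) -> tuple[float, bool]:
    if sub.n_edges == 0:
        return 0.0, True
    loops = enumerate_short_loops(sub, k=3)
    return len(loops) / sub.n_edges, False


def _mean_neighbours_commonality_stat(sub: Network, min_shared: int, min_frac: float) -> tuple[float, bool]:
    loops = enumerate_short_loops(sub, k=3)
    pairs = find_commonality_pairs(sub, loops, min_shared=min_shared, min_frac=min_frac)
    if not pairs:
        return 0.0, True
    nodes = {p for cp in pairs for p in (cp.x, cp.y)}
    return mean_neighbours(len(nodes), len(pairs)), False


def sample_random_subnetworks(
    network: Network,
    n_proteins: int,
    n_samples: int,
    statistic: str = "loop3_ratio",
    seed: int = 0,
    min_shared: int = 3,
    min_frac: float = 0.95,
) -> NullDistribution:
    """Null distribution of a statistic over uniform random protein subsets.

    Each of the ``n_samples`` draws selects ``n_proteins`` proteins uniformly
    without replacement, induces their subnetwork, and evaluates the
    statistic. Samples on which the statistic is undefined (no edges; no
    commonality pairs) score 0 and are counted in ``n_degenerate`` rather than
    redrawn -- redrawing would bias the null upward. Fully reproducible given
    ``seed``.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    nodes = sorted(network.graph.nodes)
    if n_proteins > len(nodes):
        raise ValueError("n_proteins exceeds the number of proteins in the network")
    if n_samples < 2:
        raise ValueError("need at least 2 samples for a null distribution")
    rng = np.random.default_rng(seed)
    samples: list[float] = []
    n_degenerate = 0
    for _ in range(n_samples):
        chosen = set(rng.choice(len(nodes), size=n_proteins, replace=False).tolist())
        sub, _ = induce_subnetwork(network, {nodes[i] for i in chosen})
        if statistic == "loop3_ratio":
            value, degenerate = _loop3_ratio_stat(sub)
        else:
            value, degenerate = _mean_neighbours_commonality_stat(sub, min_shared, min_frac)
        samples.append(value)
        n_degenerate += degenerate
    return NullDistribution(statistic, samples, seed=seed, n_degenerate=n_degenerate)


def z_score(observed: float, null: NullDistribution) -> float:
    """Standard score of an observed value against an empirical null.

    A degenerate null (sd = 0) yields signed infinity (0 when the observation
    equals the null mean exactly).
    """
    if null.sd == 0:
        if observed == null.mean:
            return 0.0
        return math.inf if observed > null.mean else -math.inf
    return (observed - null.mean) / null.sd
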