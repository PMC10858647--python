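"""Monte-Carlo restart-walk simulation for tuning the continuation parameter.

Simulates the random walk with restart explicitly: from the current node the
walk continues to a weight-proportional random neighbour with probability
``alpha`` and otherwise records the current node as a *termination* (the
point where it restarts) and resets to the start gene. The restart decision
is evaluated before each move, so a walk can terminate after zero moves (a
self-termination); under this convention the empirical termination frequency
converges exactly to the RWR stationary distribution started from the seed.

Binning the non-self terminations by shortest-path (hop) distance from the
start gene yields a histogram that shows how far a given ``alpha`` lets the
walk explore — small alpha stays in the one-hop neighbourhood, larger alpha
reaches two- and three-hop genes. Sweeping alpha over the seed genes of a
disease gives a practical criterion for choosing the parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .propagation import normalize_adjacency

__all__ = [
    "TerminationCounts",
    "HopHistogram",
    "simulate_restart_walks",
    "hop_distance_histogram",
    "sweep_alpha_profile",
    "aggregate_hop_profiles",
]

#: hop bins reported by the histogram; 4 collects every distance >= 4
HOP_BINS = (1, 2, 3, 4)


@dataclass(frozen=True)
class TerminationCounts:
    """Termination (restart) node tallies of one simulation run."""

    start: str
    alpha: float
    n_restarts: int
    counts: dict[str, int]

    def __post_init__(self):
        if sum(self.counts.values()) != self.n_restarts:
            raise ValidationError("termination counts must sum to n_restarts")

    def frequencies(self) -> dict[str, float]:
        return {g: c / self.n_restarts for g, c in self.counts.items()}


@dataclass(frozen=True)
class HopHistogram:
    """Fractions of non-self terminations by hop distance (bin 4 = '>= 4')."""

    fractions: dict[int, float]
    n_nonself: int
    n_self: int

    @property
    def empty(self) -> bool:
        return self.n_nonself == 0

    def mean_hop(self) -> float:
        """Mean binned hop distance (bin 4 counted as 4)."""
        if self.empty:
            raise ValidationError("empty histogram has no mean hop distance")
        return sum(h * f for h, f in self.fractions.items())


def simulate_restart_walks(
    net: nx.Graph,
    start: str,
    alpha: float,
    n_restarts: int,
    rng_seed,
) -> TerminationCounts:
    """Simulate ``n_restarts`` terminations of the restart walk from ``start``.

    Neighbour choice is proportional to edge weight, matching the
    column-stochastic transition matrix used by the analytic solver, so the
    termination frequencies converge to the stationary RWR distribution with
    the start-gene indicator as initial state.

    ``rng_seed`` may be an int, a sequence of ints, or a Generator.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValidationError(f"alpha must be in [0, 1), got {alpha}")
    if n_restarts < 1:
        raise ValidationError("n_restarts must be >= 1")
    tm = normalize_adjacency(net)
    index = tm.index
    if start not in index:
        raise ValidationError(f"start gene {start!r} is not in the network")
    s = index[start]
    if tm.isolated[s]:
        raise ValidationError(f"start gene {start!r} is isolated")
    rng = np.random.default_rng(rng_seed)

    # number of moves before each termination: P(M = k) = alpha^k (1 - alpha)
    if alpha == 0.0:
        lengths = np.zeros(n_restarts, dtype=np.int64)
    else:
        lengths = rng.geometric(1.0 - alpha, size=n_restarts) - 1

    # row-normalized cumulative weights for per-node neighbour sampling
    W = tm.matrix.T.tocsr()  # row i: out-neighbours of i with probabilities
    indptr, indices, data = W.indptr, W.indices, W.data
    cumw = np.empty_like(data)
    for v in range(tm.n_nodes):
        lo, hi = indptr[v], indptr[v + 1]
        if hi > lo:
            c = np.cumsum(data[lo:hi])
            c /= c[-1]
            cumw[lo:hi] = c

    pos = np.full(n_restarts, s, dtype=np.int64)
    remaining = lengths.copy()
    while True:
        active = np.flatnonzero(remaining > 0)
        if active.size == 0:
            break
        cur = pos[active]
        u = rng.random(active.size)
        nxt = np.empty(active.size, dtype=np.int64)
        order = np.argsort(cur, kind="stable")
        sorted_cur = cur[order]
        # group walks by current node; one vectorized searchsorted per node
        boundaries = np.flatnonzero(np.diff(sorted_cur)) + 1
        for grp in np.split(np.arange(active.size)[order], boundaries):
            v = cur[grp[0]]
            lo, hi = indptr[v], indptr[v + 1]
            choice = np.searchsorted(cumw[lo:hi], u[grp], side="right")
            choice = np.minimum(choice, hi - lo - 1)  # guard against u == 1.0 rounding
            nxt[grp] = indices[lo + choice]
        pos[active] = nxt
        remaining[active] -= 1

    tallies = np.bincount(pos, minlength=tm.n_nodes)
    counts = {tm.nodes[i]: int(c) for i, c in enumerate(tallies) if c > 0}
    return TerminationCounts(start=start, alpha=float(alpha), n_restarts=n_restarts, counts=counts)


def hop_distance_histogram(counts: TerminationCounts, net: nx.Graph) -> HopHistogram:
    """Bin non-self terminations by unweighted shortest-path distance.

    Walks terminating on the start gene itself are filtered out; the
    remaining terminations are binned at hop distance 1, 2, 3 and >= 4 (so
    the fractions always sum to 1 when any non-self termination exists).
    """
    dist = nx.single_source_shortest_path_length(net, counts.start)
    binned = {h: 0 for h in HOP_BINS}
    n_self = counts.counts.get(counts.start, 0)
    n_nonself = 0
    for gene, c in counts.counts.items():
        if gene == counts.start:
            continue
        d = dist.get(gene)
        if d is None:
            continue  # unreachable terminations cannot occur for walks from start
        binned[min(d, 4)] += c
        n_nonself += c
    if n_nonself == 0:
        warnings.warn("no non-self termination: empty hop histogram", stacklevel=2)
        return HopHistogram(fractions={}, n_nonself=0, n_self=n_self)
    fractions = {h: binned[h] / n_nonself for h in HOP_BINS}
    return HopHistogram(fractions=fractions, n_nonself=n_nonself, n_self=n_self)


def sweep_alpha_profile(
    net: nx.Graph,
    seeds: Iterable[str],
    alphas: Sequence[float],
    n_restarts: int = 100_000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Hop histograms for every (seed, alpha); tidy frame ``start alpha hop fraction``.

    Seeds absent from the network or isolated are skipped with a warning.
    Use :func:`aggregate_hop_profiles` for the seed-pooled fractions per
    alpha.
    """
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValidationError("sweep needs at least one seed gene")
    rows = []
    for i, start in enumerate(seeds):
        for j, alpha in enumerate(alphas):
            try:
                counts = simulate_restart_walks(net, start, alpha, n_restarts, [rng_seed, i, j])
            except ValidationError as exc:
                warnings.warn(f"skipping seed {start!r}: {exc}", stacklevel=2)
                break
            hist = hop_distance_histogram(counts, net)
            for h in HOP_BINS:
                rows.append((start, alpha, h, hist.fractions.get(h, np.nan), hist.n_nonself))
    if not rows:
        raise ValidationError("no seed could be simulated on this network")
    return pd.DataFrame(rows, columns=["start", "alpha", "hop", "fraction", "n_nonself"])


def aggregate_hop_profiles(profile: pd.DataFrame) -> pd.DataFrame:
    """Pool hop fractions over seeds, weighting by non-self termination counts."""
    rows = []
    for (alpha, hop), grp in profile.dropna().groupby(["alpha", "hop"], sort=True):
        weight = grp["n_nonself"].to_numpy(dtype=float)
        frac = grp["fraction"].to_numpy(dtype=float)
        rows.append((alpha, hop, float((frac * weight).sum() / weight.sum())))
    return pd.DataFrame(rows, columns=["alpha", "hop", "fraction"])
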