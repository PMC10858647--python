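"""Ranked-retrieval evaluation: P@K, AP@K, mAP@K, and network density.

Disease-gene prioritization is scored as an information-retrieval task: a
ranking of candidate genes is compared against a target set of known disease
genes. Precision@K counts targets among the top K; Average Precision@K
additionally rewards placing them early, normalized by ``min(K, M)`` (M =
number of targets) so the metric always lies in [0, 1]; mAP@K averages AP@K
over disease-network queries. Classification-style metrics such as AUROC are
deliberately not offered — a ranking metric reflects the actual use of a
prioritization, reading candidates off the top of the list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._exceptions import UndefinedMetricError, ValidationError
from .scoring import TargetSet

__all__ = [
    "BenchmarkQuery",
    "precision_at_k",
    "average_precision_at_k",
    "mean_average_precision",
    "map_confidence_interval",
    "evaluate_queries",
    "summarize_map",
    "network_density",
]

DEFAULT_KS = (20, 50, 100)


@dataclass(frozen=True)
class BenchmarkQuery:
    """One (disease, network, alpha, init-mode, K) evaluation unit."""

    disease: str
    network: str
    alpha: float
    init_mode: str
    k: int
    ranking: Sequence[str]
    targets: TargetSet | frozenset[str]

    def target_genes(self) -> frozenset[str]:
        t = self.targets
        return t.genes if isinstance(t, TargetSet) else frozenset(t)


def _check_k(k: int) -> int:
    if k < 1:
        raise ValidationError(f"K must be >= 1, got {k}")
    return int(k)


def precision_at_k(ranking: Sequence[str], targets: Iterable[str], k: int) -> float:
    """Fraction of the first K ranked genes that are targets.

    If the ranking is shorter than K the missing slots count as
    non-relevant (denominator stays K).
    """
    k = _check_k(k)
    targets = set(targets)
    hits = sum(1 for g in ranking[:k] if g in targets)
    return hits / k


def average_precision_at_k(ranking: Sequence[str], targets: Iterable[str], k: int) -> float:
    """AP@K = (1 / min(K, M)) * sum over N=1..K of P@N * rel(N).

    ``rel(N)`` is 1 iff the N-th ranked gene is a target and M is the total
    number of targets; normalizing by ``min(K, M)`` keeps AP@K in [0, 1] for
    every query.
    """
    k = _check_k(k)
    targets = set(targets)
    m = len(targets)
    if m == 0:
        raise UndefinedMetricError("AP@K is undefined for an empty target set (M = 0)")
    hits = 0
    total = 0.0
    for n, gene in enumerate(ranking[:k], start=1):
        if gene in targets:
            hits += 1
            total += hits / n  # P@N at a relevant position
    return total / min(k, m)


def mean_average_precision(ap_values: Iterable[float]) -> float:
    """Arithmetic mean of per-query AP@K values."""
    vals = list(ap_values)
    if not vals:
        raise ValidationError("mean_average_precision needs at least one query")
    return float(np.mean(vals))


def map_confidence_interval(
    ap_values: Sequence[float],
    level: float = 0.95,
    method: str = "normal",
    n_boot: int = 2000,
    rng: np.random.Generator | int | None = 0,
) -> tuple[float, float]:
    """Confidence interval for mAP@K across queries.

    ``normal`` uses the mean +/- z * SEM approximation; ``bootstrap``
    resamples queries with replacement and takes percentile bounds.
    """
    vals = np.asarray(ap_values, dtype=float)
    if vals.size == 0:
        raise ValidationError("no AP values")
    if method == "normal":
        from scipy import stats

        z = stats.norm.ppf(0.5 + level / 2)
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
        m = vals.mean()
        return float(m - z * sem), float(m + z * sem)
    if method == "bootstrap":
        gen = np.random.default_rng(rng)
        means = gen.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
        lo, hi = np.quantile(means, [(1 - level) / 2, 0.5 + level / 2])
        return float(lo), float(hi)
    raise ValidationError(f"unknown CI method {method!r}")


def evaluate_queries(queries: Iterable[BenchmarkQuery]) -> pd.DataFrame:
    """Score every query; emit the long-format table.

    Queries whose target set is empty (AP undefined) are skipped with a
    warning and counted in the frame's ``attrs['n_skipped']``.
    """
    rows = []
    skipped = 0
    for q in queries:
        try:
            ap = average_precision_at_k(q.ranking, q.target_genes(), q.k)
        except UndefinedMetricError:
            warnings.warn(
                f"skipping query ({q.disease}, {q.network}, alpha={q.alpha}, "
                f"init={q.init_mode}, K={q.k}): empty target set",
                stacklevel=2,
            )
            skipped += 1
            continue
        rows.append((q.disease, q.network, q.alpha, q.init_mode, q.k, ap))
    if not rows:
        raise ValidationError("no valid query: every target set was empty")
    df = pd.DataFrame(rows, columns=["disease", "network", "alpha", "init", "K", "AP"])
    df.attrs["n_skipped"] = skipped
    return df


def summarize_map(
    results: pd.DataFrame,
    level: float = 0.95,
    method: str = "normal",
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """mAP@K per (alpha, init, K) with confidence bounds across queries."""
    if results.empty:
        raise ValidationError("empty results table")
    rows = []
    for (alpha, init, k), grp in results.groupby(["alpha", "init", "K"], sort=True):
        aps = grp["AP"].to_numpy()
        lo, hi = map_confidence_interval(aps, level=level, method=method, rng=rng)
        rows.append((alpha, init, k, float(aps.mean()), lo, hi, len(aps)))
    return pd.DataFrame(
        rows, columns=["alpha", "init", "K", "mAP", "ci_low", "ci_high", "n_queries"]
    )


def network_density(net: nx.Graph) -> float:
    """Ratio of observed to possible edges: ``E / (N (N - 1) / 2)``."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValidationError("density needs at least 2 nodes")
    return net.number_of_edges() / (n * (n - 1) / 2)
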