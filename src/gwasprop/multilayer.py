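"""Combining several gene networks: supra-adjacency RWR and rank averaging.

Two complementary strategies:

* **Multilayer RWR** — the layers' adjacency matrices are joined into one
  block-diagonal supra-adjacency matrix and inter-layer edges of a fixed
  coupling weight link every pair of copies of the same gene across layers.
  The single-network RWR machinery then runs unchanged on the supra graph;
  per-gene output aggregates the stationary mass of the gene's layer copies.
* **Average rank (Avg. Rank)** — propagation runs independently per network
  and a gene's final rank is the mean of its per-network ranks, restricted
  to genes present in at least ``min_networks`` rankings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator

from ._exceptions import ValidationError
from .propagation import (
    InitMode,
    InitialState,
    PropagationResult,
    TransitionMatrix,
    rank_genes,
    rwr_closed_form,
    rwr_power_iteration,
    _DIRECT_SOLVE_LIMIT,
)

__all__ = [
    "MultilayerNetwork",
    "build_supra_adjacency",
    "multilayer_rwr",
    "average_rank_ensemble",
    "MultilayerRandomWalkRestart",
]


@dataclass(frozen=True)
class MultilayerNetwork:
    """Supra-adjacency representation of a list of network layers.

    Supra nodes are ``(gene, layer_index)`` pairs; ``positions`` maps a gene
    to its supra indices (one per layer containing it). The supra adjacency
    is symmetric; an inter-layer edge of weight ``coupling`` exists for gene
    g between layers i != j iff g is a node of both.
    """

    adjacency: sparse.csr_array
    supra_nodes: tuple[tuple[str, int], ...]
    positions: Mapping[str, tuple[int, ...]]
    coupling: float
    n_layers: int

    @property
    def genes(self) -> list[str]:
        return sorted(self.positions)

    def transition_matrix(self) -> TransitionMatrix:
        """Column-stochastic normalization of the supra adjacency."""
        deg = np.asarray(self.adjacency.sum(axis=0)).ravel()
        isolated = deg == 0
        inv = np.zeros_like(deg)
        inv[~isolated] = 1.0 / deg[~isolated]
        W = (self.adjacency @ sparse.diags_array(inv)).tocsr()
        labels = tuple(f"{g}@{l}" for g, l in self.supra_nodes)
        return TransitionMatrix(matrix=W, nodes=labels, isolated=isolated)


def build_supra_adjacency(
    layers: Sequence[nx.Graph], coupling: float = 1.0
) -> MultilayerNetwork:
    """Join network layers into the multilayer supra-adjacency matrix.

    Intra-layer blocks are the layers' weighted adjacencies; copies of the
    same gene in different layers are linked pairwise with weight
    ``coupling``. ``coupling = 0`` keeps the block structure (independent
    layers).
    """
    if len(layers) < 2:
        raise ValidationError("a multilayer network needs at least 2 layers")
    if coupling < 0:
        raise ValidationError("coupling weight must be >= 0")
    supra_nodes: list[tuple[str, int]] = []
    positions: dict[str, list[int]] = {}
    blocks = []
    for li, layer in enumerate(layers):
        nodes = sorted(layer.nodes)
        blocks.append(
            nx.to_scipy_sparse_array(layer, nodelist=nodes, weight="weight", format="coo").astype(float)
        )
        for g in nodes:
            positions.setdefault(g, []).append(len(supra_nodes))
            supra_nodes.append((g, li))
    A = sparse.block_diag(blocks, format="lil").astype(float)
    if coupling > 0:
        for pos in positions.values():
            for i, a in enumerate(pos):
                for b in pos[i + 1 :]:
                    A[a, b] = coupling
                    A[b, a] = coupling
    return MultilayerNetwork(
        adjacency=sparse.csr_array(A),
        supra_nodes=tuple(supra_nodes),
        positions={g: tuple(v) for g, v in positions.items()},
        coupling=float(coupling),
        n_layers=len(layers),
    )


def _supra_initial_state(
    mnet: MultilayerNetwork,
    scores: Mapping[str, float] | None,
    seeds: Iterable[str] | None,
) -> InitialState:
    """Per-gene initial mass split equally among the gene's layer copies."""
    if (scores is None) == (seeds is None):
        raise ValidationError("pass either scores or seeds")
    n = len(mnet.supra_nodes)
    p0 = np.zeros(n)
    if seeds is not None:
        mode = InitMode.SEED_BINARY
        present = sorted({g for g in seeds if g in mnet.positions})
        if not present:
            raise ValidationError("no propagation input on this network: no seed found in any layer")
        gene_mass = {g: 1.0 / len(present) for g in present}
    else:
        mode = InitMode.PVALUE_SCORE
        gene_mass = {}
        for g, s in scores.items():
            if s < 0:
                raise ValidationError(f"negative score for gene {g!r}")
            if g in mnet.positions and s > 0:
                gene_mass[g] = s
        total = sum(gene_mass.values())
        if total <= 0:
            raise ValidationError("no propagation input on this network: no positive score maps to a layer node")
        gene_mass = {g: s / total for g, s in gene_mass.items()}
    for g, mass in gene_mass.items():
        pos = mnet.positions[g]
        for p in pos:
            p0[p] = mass / len(pos)
    return InitialState(vector=p0, mode=mode)


def multilayer_rwr(
    mnet: MultilayerNetwork,
    scores: Mapping[str, float] | None = None,
    seeds: Iterable[str] | None = None,
    alpha: float = 0.3,
    aggregate: str = "sum",
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> PropagationResult:
    """RWR on the supra matrix with per-gene aggregation over layer copies.

    The initial mass of a gene is split equally among its copies; after the
    walk, each gene's stationary mass is the ``sum`` (default; ``max`` and
    ``mean`` offered) over its copies, so total mass stays 1 under the sum
    rule.

    The solve is always by power iteration: the inter-layer coupling pattern
    induces severe fill-in in a direct sparse factorization of the supra
    matrix, while the iteration contracts with factor ``alpha`` per matvec
    and reaches ``tol`` in tens of iterations.
    """
    if aggregate not in ("sum", "max", "mean"):
        raise ValidationError(f"unknown aggregate {aggregate!r}")
    tm = mnet.transition_matrix()
    p0 = _supra_initial_state(mnet, scores, seeds)
    if alpha == 0.0:
        supra = rwr_closed_form(tm, p0, alpha)
    else:
        supra = rwr_power_iteration(tm, p0, alpha, tol=tol, max_iter=max_iter)
    genes = mnet.genes
    agg = np.empty(len(genes))
    for i, g in enumerate(genes):
        vals = supra.ps[list(mnet.positions[g])]
        if aggregate == "sum":
            agg[i] = vals.sum()
        elif aggregate == "max":
            agg[i] = vals.max()
        else:
            agg[i] = vals.mean()
    return PropagationResult(
        ps=agg, nodes=tuple(genes), alpha=float(alpha), mode=p0.mode,
        n_iter=supra.n_iter, residual=supra.residual,
    )


def average_rank_ensemble(
    rankings: Sequence[Sequence[str]],
    min_networks: int = 2,
    normalize_ranks: bool = False,
) -> pd.DataFrame:
    """Average a gene's rank across per-network rankings (Avg. Rank).

    Genes present in fewer than ``min_networks`` rankings are excluded;
    networks where a gene is absent contribute nothing to its average. The
    output is sorted by average rank ascending, ties broken by number of
    supporting networks (more first) then by gene identifier, with final
    ranks 1..n in column ``rank``.

    ``normalize_ranks`` divides each rank by its ranking's length before
    averaging, compensating for networks of very different sizes.
    """
    if len(rankings) < 2:
        raise ValidationError("average_rank_ensemble needs at least 2 rankings")
    if min_networks < 1:
        raise ValidationError("min_networks must be >= 1")
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for ranking in rankings:
        size = len(ranking)
        for pos, gene in enumerate(ranking, start=1):
            r = pos / size if normalize_ranks else float(pos)
            sums[gene] = sums.get(gene, 0.0) + r
            counts[gene] = counts.get(gene, 0) + 1
    rows = [
        (g, sums[g] / c, c)
        for g, c in counts.items()
        if c >= min_networks
    ]
    rows.sort(key=lambda t: (t[1], -t[2], t[0]))
    df = pd.DataFrame(rows, columns=["gene", "avg_rank", "n_networks"])
    df["rank"] = np.arange(1, len(df) + 1)
    return df


class MultilayerRandomWalkRestart(BaseEstimator):
    """Multilayer RWR as a scikit-learn style estimator.

    ``fit`` takes a list of undirected :class:`networkx.Graph` layers and
    builds the supra-adjacency matrix; :meth:`propagate` runs the walk from
    gene scores or seeds and aggregates per gene.
    """

    def __init__(self, alpha: float = 0.3, coupling: float = 1.0, aggregate: str = "sum"):
        self.alpha = alpha
        self.coupling = coupling
        self.aggregate = aggregate

    def fit(self, X: Sequence[nx.Graph], y=None) -> "MultilayerRandomWalkRestart":
        self.multilayer_ = build_supra_adjacency(X, coupling=self.coupling)
        self.genes_ = self.multilayer_.genes
        return self

    def propagate(
        self,
        scores: Mapping[str, float] | None = None,
        seeds: Iterable[str] | None = None,
    ) -> PropagationResult:
        if not hasattr(self, "multilayer_"):
            raise ValidationError("MultilayerRandomWalkRestart is not fitted")
        return multilayer_rwr(
            self.multilayer_, scores=scores, seeds=seeds,
            alpha=self.alpha, aggregate=self.aggregate,
        )

    def rank(
        self,
        scores: Mapping[str, float] | None = None,
        seeds: Iterable[str] | None = None,
        exclude: Iterable[str] = (),
    ) -> list[str]:
        return rank_genes(self.propagate(scores=scores, seeds=seeds), exclude=exclude)
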