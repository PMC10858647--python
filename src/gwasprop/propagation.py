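"""Random walk with restart (personalized PageRank) on a single gene network.

The propagation substrate is the column-stochastic transition matrix
``W[i, j] = w(i, j) / deg_w(j)`` built from the weighted adjacency of an
undirected network. Given an initial probability vector ``p0`` and a
continuation probability ``alpha`` in ``[0, 1)``, the stationary distribution
of the walk is

    ps = (1 - alpha) (I - alpha W)^{-1} p0

``alpha`` is the probability of *continuing* the walk at each step; the walk
restarts to ``p0`` with probability ``1 - alpha``. Tools differ on this
convention — here ``alpha = 0`` means no propagation at all (``ps = p0``) and
values close to 1 diffuse far from the initial support.

Isolated (zero-degree) nodes cannot transmit mass; any initial mass placed on
them is retained in place so total probability mass is conserved, and such
nodes are reported through the :class:`TransitionMatrix` flags and a log
message when they carry initial mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import linalg as spla
from sklearn.base import BaseEstimator, TransformerMixin

from ._exceptions import ConvergenceError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "InitMode",
    "TransitionMatrix",
    "InitialState",
    "PropagationResult",
    "normalize_adjacency",
    "build_initial_state",
    "rwr_closed_form",
    "rwr_power_iteration",
    "rank_genes",
    "RandomWalkRestart",
]

#: node count above which the default solver switches to power iteration
_DIRECT_SOLVE_LIMIT = 50_000
_DEFAULT_TOL = 1e-10
_DEFAULT_MAX_ITER = 10_000


class InitMode(str, Enum):
    """How the initial state vector ``p0`` is constructed."""

    SEED_BINARY = "seed_binary"  # uniform mass over seed genes
    PVALUE_SCORE = "pvalue_score"  # mass proportional to -log10(P)


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic propagation substrate over a fixed node ordering.

    Attributes
    ----------
    matrix : scipy.sparse.csr_array
        ``W`` with ``W[i, j] = w(i, j) / deg_w(j)``. Columns of isolated
        nodes are all zero; the sparsity pattern equals the adjacency
        pattern of the source network.
    nodes : tuple of str
        Gene identifiers in deterministic (lexicographic) order.
    isolated : numpy.ndarray of bool
        Flags zero-degree nodes (all-zero columns).
    """

    matrix: sparse.csr_array
    nodes: tuple[str, ...]
    isolated: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    def solver_matrix(self) -> sparse.csr_array:
        """W plus a unit diagonal on isolated columns.

        This is the matrix the solvers iterate: isolated nodes keep their
        mass in place instead of leaking it, so every column sums to 1 and
        total mass is conserved for any network.
        """
        if not self.isolated.any():
            return self.matrix
        return (self.matrix + sparse.diags_array(self.isolated.astype(float))).tocsr()


@dataclass(frozen=True)
class InitialState:
    """Initial probability vector ``p0`` aligned to a TransitionMatrix."""

    vector: np.ndarray
    mode: InitMode

    def __post_init__(self):
        v = self.vector
        if (v < 0).any():
            raise ValidationError("p0 must be non-negative")
        if not np.isclose(v.sum(), 1.0):
            raise ValidationError(f"p0 must sum to 1, got {v.sum()!r}")
        if not (v > 0).any():
            raise ValidationError("no propagation input on this network")


@dataclass(frozen=True)
class PropagationResult:
    """Stationary distribution of one RWR run.

    ``ps`` sums to 1 (isolated nodes retain their initial mass in place).
    ``n_iter`` is None for the closed-form solver.
    """

    ps: np.ndarray
    nodes: tuple[str, ...]
    alpha: float
    mode: InitMode
    n_iter: int | None = None
    residual: float | None = None

    def scores(self) -> dict[str, float]:
        return dict(zip(self.nodes, self.ps.tolist()))

    def to_frame(self, exclude: Iterable[str] = ()) -> pd.DataFrame:
        """Long-format result: ``gene  ps  rank`` (rank 1 = best)."""
        ranking = rank_genes(self, exclude=exclude)
        by_gene = self.scores()
        return pd.DataFrame(
            {
                "gene": ranking,
                "ps": [by_gene[g] for g in ranking],
                "rank": np.arange(1, len(ranking) + 1),
            }
        )


def _validate_simple(net: nx.Graph) -> None:
    if net.number_of_nodes() == 0:
        raise ValidationError("network is empty")
    if net.is_directed() or net.is_multigraph():
        raise ValidationError("network must be a simple undirected graph")
    loops = list(nx.nodes_with_selfloops(net))
    if loops:
        raise ValidationError(f"network has self-loops (e.g. {loops[0]!r})")


def normalize_adjacency(net: nx.Graph, binarize: bool = False) -> TransitionMatrix:
    """Build the column-stochastic transition matrix of an undirected network.

    Parameters
    ----------
    net : networkx.Graph
        Simple undirected network; edge attribute ``weight`` (default 1.0)
        is used unless ``binarize``.
    binarize : bool
        Ignore edge weights and treat every edge as weight 1.

    Returns
    -------
    TransitionMatrix
        ``W[i, j] = w(i, j) / deg_w(j)``; zero-degree nodes give all-zero
        columns and are flagged.
    """
    _validate_simple(net)
    nodes = tuple(sorted(net.nodes))
    weight = None if binarize else "weight"
    A = nx.to_scipy_sparse_array(net, nodelist=list(nodes), weight=weight, format="csr")
    A = A.astype(float)
    if A.data.size and (A.data < 0).any():
        raise ValidationError("negative edge weights are not allowed")
    deg = np.asarray(A.sum(axis=0)).ravel()
    isolated = deg == 0
    if isolated.any():
        logger.info("network has %d isolated node(s)", int(isolated.sum()))
    inv = np.zeros_like(deg)
    inv[~isolated] = 1.0 / deg[~isolated]
    W = (A @ sparse.diags_array(inv)).tocsr()
    return TransitionMatrix(matrix=W, nodes=nodes, isolated=isolated)


def build_initial_state(
    tm: TransitionMatrix,
    scores: Mapping[str, float] | None = None,
    seeds: Iterable[str] | None = None,
    mode: InitMode | str | None = None,
) -> InitialState:
    """Construct ``p0`` from seed genes or from gene scores.

    In ``seed_binary`` mode each seed present in the network receives mass
    ``1/|seeds ∩ nodes|``. In ``pvalue_score`` mode ``p0(g)`` is proportional
    to the (non-negative) score of ``g``, typically ``-log10 P``; genes
    without a score, or absent from the network, get 0. The vector is always
    renormalized to sum 1 — the final ranking is invariant to this scaling.
    """
    if mode is not None:
        mode = InitMode(mode)
    if seeds is not None and scores is not None:
        raise ValidationError("pass either scores or seeds, not both")
    n = tm.n_nodes
    index = tm.index
    p0 = np.zeros(n)
    if seeds is not None or mode is InitMode.SEED_BINARY:
        if seeds is None:
            raise ValidationError("seed_binary mode requires a seed set")
        mode = InitMode.SEED_BINARY
        present = sorted({g for g in seeds if g in index})
        if not present:
            raise ValidationError("no propagation input on this network: no seed is a network node")
        p0[[index[g] for g in present]] = 1.0 / len(present)
    else:
        if scores is None:
            raise ValidationError("pvalue_score mode requires gene scores")
        mode = InitMode.PVALUE_SCORE
        dropped = 0
        for g, s in scores.items():
            if s < 0:
                raise ValidationError(f"negative score for gene {g!r}")
            i = index.get(g)
            if i is None:
                dropped += 1
            else:
                p0[i] = s
        if dropped:
            logger.info("dropped %d scored gene(s) absent from the network", dropped)
        total = p0.sum()
        if total <= 0:
            raise ValidationError("no propagation input on this network: no positive score maps to a node")
        p0 /= total
    if (p0[tm.isolated] > 0).any():
        logger.warning(
            "initial mass %.3g sits on isolated node(s); it will be retained in place",
            float(p0[tm.isolated].sum()),
        )
    return InitialState(vector=p0, mode=mode)


def _check_alpha(alpha: float) -> float:
    if not 0.0 <= alpha < 1.0:
        raise ValidationError(f"alpha must be in [0, 1), got {alpha}")
    return float(alpha)


def rwr_closed_form(tm: TransitionMatrix, p0: InitialState, alpha: float) -> PropagationResult:
    """Stationary RWR distribution by sparse direct solve.

    Solves ``(I - alpha W) x = (1 - alpha) p0``; at ``alpha = 0`` the result
    is ``p0`` exactly (propagation skipped).
    """
    alpha = _check_alpha(alpha)
    if alpha == 0.0:
        return PropagationResult(ps=p0.vector.copy(), nodes=tm.nodes, alpha=0.0, mode=p0.mode)
    W = tm.solver_matrix()
    n = tm.n_nodes
    A = (sparse.identity(n, format="csc") - alpha * W).tocsc()
    x = spla.spsolve(A, (1.0 - alpha) * p0.vector)
    x = np.asarray(x, dtype=float).ravel()
    x[x < 0] = 0.0  # round-off guard; the exact solution is non-negative
    return PropagationResult(ps=x, nodes=tm.nodes, alpha=alpha, mode=p0.mode)


def rwr_power_iteration(
    tm: TransitionMatrix,
    p0: InitialState,
    alpha: float,
    tol: float = _DEFAULT_TOL,
    max_iter: int = _DEFAULT_MAX_ITER,
) -> PropagationResult:
    """Stationary RWR distribution by damped power iteration.

    Iterates ``p <- alpha W p + (1 - alpha) p0`` until the L1 change drops
    below ``tol``. The contraction factor is ``alpha``, so convergence is
    geometric for ``alpha < 1``.
    """
    alpha = _check_alpha(alpha)
    if tol <= 0:
        raise ValidationError("tol must be positive")
    W = tm.solver_matrix()
    p = p0.vector.copy()
    restart = (1.0 - alpha) * p0.vector
    for it in range(1, max_iter + 1):
        p_next = alpha * (W @ p) + restart
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return PropagationResult(
                ps=p, nodes=tm.nodes, alpha=alpha, mode=p0.mode, n_iter=it, residual=residual
            )
    raise ConvergenceError(
        f"power iteration did not reach tol={tol} in {max_iter} iterations "
        f"(last L1 residual {residual:.3e})",
        residual=residual,
        n_iter=max_iter,
    )


def rank_genes(result: PropagationResult, exclude: Iterable[str] = ()) -> list[str]:
    """Deterministic ranking: ps descending, ties by gene identifier."""
    excluded = set(exclude)
    pairs = [(g, s) for g, s in zip(result.nodes, result.ps) if g not in excluded]
    pairs.sort(key=lambda gs: (-gs[1], gs[0]))
    return [g for g, _ in pairs]


class RandomWalkRestart(BaseEstimator, TransformerMixin):
    """Random-walk-with-restart propagation as a scikit-learn transformer.

    ``fit`` takes an undirected :class:`networkx.Graph` and builds the
    column-stochastic transition matrix; ``transform`` smooths one or more
    initial distributions over the network. The domain-level entry point is
    :meth:`propagate`, which accepts gene scores or seed sets.

    Parameters
    ----------
    alpha : float in [0, 1)
        Probability of continuing the walk at each step (restart probability
        is ``1 - alpha``); 0 skips propagation entirely.
    solver : {"auto", "closed_form", "power_iteration"}
        "auto" uses the sparse direct solve up to 50 000 nodes, power
        iteration above.
    tol, max_iter : float, int
        Power-iteration stopping rule (L1 change below ``tol``).
    binarize : bool
        Drop edge weights before normalization.

    Examples
    --------
    >>> import networkx as nx
    >>> rwr = RandomWalkRestart(alpha=0.5).fit(nx.path_graph(["a", "b"]))
    >>> rwr.propagate(seeds=["a"]).ps
    array([0.66666667, 0.33333333])
    """

    def __init__(
        self,
        alpha: float = 0.3,
        solver: str = "auto",
        tol: float = _DEFAULT_TOL,
        max_iter: int = _DEFAULT_MAX_ITER,
        binarize: bool = False,
    ):
        self.alpha = alpha
        self.solver = solver
        self.tol = tol
        self.max_iter = max_iter
        self.binarize = binarize

    def fit(self, X: nx.Graph, y=None) -> "RandomWalkRestart":
        _check_alpha(self.alpha)
        if self.solver not in ("auto", "closed_form", "power_iteration"):
            raise ValidationError(f"unknown solver {self.solver!r}")
        self.transition_ = normalize_adjacency(X, binarize=self.binarize)
        self.nodes_ = self.transition_.nodes
        self.n_features_in_ = len(self.nodes_)
        return self

    def _solve(self, p0: InitialState) -> PropagationResult:
        solver = self.solver
        if solver == "auto":
            solver = "closed_form" if self.n_features_in_ <= _DIRECT_SOLVE_LIMIT else "power_iteration"
        if solver == "closed_form":
            return rwr_closed_form(self.transition_, p0, self.alpha)
        return rwr_power_iteration(
            self.transition_, p0, self.alpha, tol=self.tol, max_iter=self.max_iter
        )

    def transform(self, X) -> np.ndarray:
        """Propagate rows of ``X`` (shape ``(n_queries, n_nodes)``).

        Each row is treated as an initial mass vector (renormalized to sum
        1) and replaced by its stationary distribution.
        """
        if not hasattr(self, "transition_"):
            raise ValidationError("RandomWalkRestart is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} columns, network has {self.n_features_in_} nodes"
            )
        out = np.empty_like(X)
        for i, row in enumerate(X):
            total = row.sum()
            if total <= 0 or (row < 0).any():
                raise ValidationError(f"row {i} is not a valid initial mass vector")
            state = InitialState(vector=row / total, mode=InitMode.PVALUE_SCORE)
            out[i] = self._solve(state).ps
        return out

    def propagate(
        self,
        scores: Mapping[str, float] | None = None,
        seeds: Iterable[str] | None = None,
        mode: InitMode | str | None = None,
    ) -> PropagationResult:
        """Run one RWR from gene scores or from a seed set."""
        if not hasattr(self, "transition_"):
            raise ValidationError("RandomWalkRestart is not fitted")
        p0 = build_initial_state(self.transition_, scores=scores, seeds=seeds, mode=mode)
        return self._solve(p0)

    def rank(
        self,
        scores: Mapping[str, float] | None = None,
        seeds: Iterable[str] | None = None,
        mode: InitMode | str | None = None,
        exclude: Iterable[str] = (),
    ) -> list[str]:
        """Propagate and return the deterministic gene ranking."""
        return rank_genes(self.propagate(scores=scores, seeds=seeds, mode=mode), exclude=exclude)
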