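"""Reading and writing the pipeline's plain-text formats.

Networks: 2- or 3-column TSV edge lists (``geneA geneB [weight]``) or SIF
(``geneA relation geneB [geneC ...]``). Score tables: TSV with headers
``gene pvalue`` or ``snp gene pvalue``. Gene sets: one gene per line.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from ._exceptions import ValidationError
from .scoring import validate_pvalues

logger = logging.getLogger(__name__)

__all__ = [
    "read_network",
    "write_network",
    "read_gene_scores",
    "write_gene_scores",
    "read_snp_scores",
    "read_gene_set",
    "write_gene_set",
]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "sif" if path.suffix.lower() == ".sif" else "tsv"


def _add_edge(net: nx.Graph, u: str, v: str, w: float, stats: dict) -> None:
    if u == v:
        stats["self_loops"] += 1
        return
    if net.has_edge(u, v):
        stats["duplicates"] += 1
        # duplicate edges collapse to the maximum weight
        net[u][v]["weight"] = max(net[u][v]["weight"], w)
    else:
        net.add_edge(u, v, weight=w)


def read_network(path: str | Path, fmt: str | None = None) -> nx.Graph:
    """Read a simple undirected network from a TSV edge list or SIF file.

    Duplicate edges (either direction) collapse to the maximum weight;
    self-loops are dropped; both counts are logged. Lines starting with
    ``#`` are ignored, as is an optional header line starting with
    ``geneA``/``source``.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt not in ("tsv", "sif"):
        raise ValidationError(f"unknown network format {fmt!r}")
    net = nx.Graph()
    stats = {"self_loops": 0, "duplicates": 0}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and parts[0].lower() in ("genea", "source", "gene1", "node1"):
                continue
            try:
                if fmt == "tsv":
                    if len(parts) < 2 or len(parts) > 3:
                        raise ValueError("expected 2 or 3 columns")
                    u, v = parts[0], parts[1]
                    w = float(parts[2]) if len(parts) == 3 else 1.0
                    if w <= 0:
                        raise ValueError("edge weight must be positive")
                    _add_edge(net, u, v, w, stats)
                else:  # sif: source relation target [target2 ...]
                    if len(parts) == 1:
                        net.add_node(parts[0])
                        continue
                    if len(parts) < 3:
                        raise ValueError("SIF line needs source, relation, target(s)")
                    for v in parts[2:]:
                        _add_edge(net, parts[0], v, 1.0, stats)
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: malformed line ({exc}): {line!r}") from exc
    if net.number_of_nodes() == 0:
        raise ValidationError(f"{path}: no edges or nodes parsed")
    if stats["self_loops"] or stats["duplicates"]:
        logger.info(
            "%s: dropped %d self-loop(s), collapsed %d duplicate edge(s)",
            path, stats["self_loops"], stats["duplicates"],
        )
    return net


def write_network(net: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write a network as a TSV edge list (weight column only if non-unit) or SIF."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    with open(path, "w") as fh:
        if fmt == "tsv":
            weighted = any(d.get("weight", 1.0) != 1.0 for _, _, d in net.edges(data=True))
            for u, v in sorted(map(lambda e: tuple(sorted(e)), net.edges())):
                if weighted:
                    fh.write(f"{u}\t{v}\t{net[u][v].get('weight', 1.0):g}\n")
                else:
                    fh.write(f"{u}\t{v}\n")
        elif fmt == "sif":
            for u, v in sorted(map(lambda e: tuple(sorted(e)), net.edges())):
                fh.write(f"{u}\tinteracts\t{v}\n")
            for n in sorted(net.nodes):
                if net.degree(n) == 0:
                    fh.write(f"{n}\n")
        else:
            raise ValidationError(f"unknown network format {fmt!r}")


def read_gene_scores(path: str | Path) -> pd.DataFrame:
    """Read a ``gene pvalue`` TSV table."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "pvalue"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns 'gene' and 'pvalue', got {list(df.columns)}")
    df["gene"] = df["gene"].astype(str)
    return validate_pvalues(df)


def write_gene_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index=False)


def read_snp_scores(path: str | Path) -> pd.DataFrame:
    """Read a ``snp gene pvalue`` TSV table."""
    df = pd.read_csv(path, sep="\t")
    if not {"snp", "gene", "pvalue"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns 'snp', 'gene', 'pvalue'")
    df["gene"] = df["gene"].astype(str)
    return validate_pvalues(df)


def read_gene_set(path: str | Path) -> frozenset[str]:
    """Read a one-gene-per-line set."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
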