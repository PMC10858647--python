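"""Gene scoring: minSNP aggregation, -log10 transforms, seed and target sets.

Converts SNP- or gene-level association P-values into the inputs of network
propagation. Seed genes are those significant after a Bonferroni correction
of a nominal level over the number of tested genes (the prior knowledge);
target genes are externally catalogued disease genes at genome-wide
significance, minus the seeds, so that evaluation measures the retrieval of
*new* knowledge only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ValidationError

__all__ = [
    "SeedSet",
    "TargetSet",
    "validate_pvalues",
    "minsnp_aggregate",
    "neglog10_scores",
    "select_seed_genes",
    "build_target_set",
]

#: default floor for -log10 transform; summary-statistics files routinely
#: contain P = 0, which is clamped here before taking logs
PVALUE_FLOOR = 1e-300

#: conventional genome-wide significance threshold for catalog associations
GENOMEWIDE_THRESHOLD = 5e-8


@dataclass(frozen=True)
class SeedSet:
    """Bonferroni-significant genes plus the threshold that selected them."""

    genes: frozenset[str]
    threshold: float

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class TargetSet:
    """Catalogued disease genes with seeds removed; the retrieval ground truth."""

    genes: frozenset[str]
    threshold: float

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def validate_pvalues(table: pd.DataFrame, column: str = "pvalue") -> pd.DataFrame:
    """Check that every P-value lies in (0, 1]; name the offending row."""
    p = table[column].to_numpy(dtype=float)
    bad = np.flatnonzero(~((p > 0) & (p <= 1)))
    if bad.size:
        row = table.iloc[int(bad[0])]
        raise ValidationError(
            f"P-value out of (0, 1] at row {int(bad[0])}: {row.to_dict()!r}"
        )
    return table


def minsnp_aggregate(snps: pd.DataFrame) -> pd.DataFrame:
    """Aggregate SNP P-values per gene by taking the minimum (minSNP).

    The table needs columns ``gene`` and ``pvalue`` (``snp`` is carried
    along if present but ignored). The minimum-P rule is simple but biased
    towards genes with many SNPs — under the null the expected minimum of k
    uniform P-values is 1/(k+1).
    """
    if snps.empty:
        raise ValidationError("SNP table is empty")
    if snps["gene"].isna().any() or (snps["gene"].astype(str).str.len() == 0).any():
        raise ValidationError("every SNP row must carry a gene identifier")
    validate_pvalues(snps)
    out = (
        snps.groupby("gene", sort=True)["pvalue"]
        .min()
        .rename("pvalue")
        .reset_index()
    )
    return out


def neglog10_scores(
    scores: pd.DataFrame, floor: float | None = PVALUE_FLOOR
) -> dict[str, float]:
    """Map gene P-values to -log10 scores.

    P-values below ``floor`` are clamped before the transform; pass
    ``floor=None`` to disable clamping (P = 0 then raises).
    """
    p = scores["pvalue"].to_numpy(dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("P-values must lie in [0, 1]")
    if floor is not None:
        p = np.clip(p, floor, 1.0)
    elif (p <= 0).any():
        raise ValidationError("P = 0 encountered with clamping disabled")
    vals = -np.log10(p)
    return dict(zip(scores["gene"].astype(str), vals.tolist()))


def select_seed_genes(scores: pd.DataFrame, nominal_level: float = 0.01) -> SeedSet:
    """Bonferroni seed selection.

    The threshold is ``nominal_level / n_genes`` where ``n_genes`` counts the
    genes present in the table; genes with P less than or equal to the
    threshold are seeds (the comparison at exact equality is inclusive).
    """
    if scores.empty:
        raise ValidationError("gene score table is empty")
    if not 0 < nominal_level < 1:
        raise ValidationError("nominal_level must be in (0, 1)")
    validate_pvalues(scores)
    threshold = nominal_level / len(scores)
    mask = scores["pvalue"].to_numpy(dtype=float) <= threshold
    return SeedSet(genes=frozenset(scores.loc[mask, "gene"].astype(str)), threshold=threshold)


def build_target_set(
    catalog: pd.DataFrame,
    genomewide_threshold: float = GENOMEWIDE_THRESHOLD,
    seeds: SeedSet | None = None,
) -> TargetSet:
    """Targets: catalog genes strictly below genome-wide significance, minus seeds.

    Removing the seed overlap ensures the evaluation rewards only genes that
    were not already known from the input study.
    """
    if not 0 < genomewide_threshold < 1:
        raise ValidationError("genomewide_threshold must be in (0, 1)")
    validate_pvalues(catalog)
    mask = catalog["pvalue"].to_numpy(dtype=float) < genomewide_threshold
    genes = set(catalog.loc[mask, "gene"].astype(str))
    if seeds is not None:
        genes -= set(seeds.genes)
    return TargetSet(genes=frozenset(genes), threshold=genomewide_threshold)
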