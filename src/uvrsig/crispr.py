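"""Meta-ranking of genes across CRISPR knockout screens.

Each screen reports a per-gene log fold change (logFC) of guide
abundance; a negative shift after knockout under immune pressure marks
a candidate immune-resistance gene.  Screens differ in location and
scale, so each dataset column is z-normalized over its observed cells
(missing cells stay missing; no imputation).  Genes are then ranked by
their average z-score over the datasets observing them — rank 1 is the
lowest (most resistance-like) average.

Top-fraction membership uses ``floor(frac * N)`` genes of the ranking,
and signature coverage reports the percentage of a signature's genes
falling in each top set (denominator: signature genes present in the
ranked universe; the full-signature denominator is reported alongside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneSet

logger = logging.getLogger("uvrsig")

__all__ = [
    "ScreenTable",
    "RankedGenes",
    "zscore_normalize",
    "average_and_rank",
    "top_fraction",
    "signature_top_coverage",
]


@dataclass
class ScreenTable:
    """Gene × dataset logFC matrix and its z-normalized twin."""

    logfc: pd.DataFrame  # genes x datasets, NaN = missing
    z: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.logfc.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.logfc.columns.has_duplicates:
            raise ValueError("duplicate dataset ids")

    @property
    def n_obs(self) -> pd.Series:
        return self.logfc.notna().sum(axis=1)


@dataclass
class RankedGenes:
    """Genes ordered ascending by average z-score (rank 1 = lowest)."""

    table: pd.DataFrame  # index gene (ordered), columns avg_z, n_obs, rank, percentile
    excluded: list[str]  # genes dropped for insufficient observations

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def zscore_normalize(table: ScreenTable) -> ScreenTable:
    """Z-normalize each dataset column over its observed cells (ddof=1)."""
    df = table.logfc
    counts = df.notna().sum(axis=0)
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"datasets with < 2 observed genes: {bad}")
    sd = df.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = sd[sd == 0].index.tolist()
        raise ValueError(f"zero-variance datasets: {bad}")
    z = (df - df.mean(axis=0)) / sd
    return ScreenTable(df, z)


def average_and_rank(table: ScreenTable, min_obs: int = 1) -> RankedGenes:
    """Rank genes ascending by mean z over observed datasets.

    Ties are broken alphabetically by gene id; genes observed in fewer
    than ``min_obs`` datasets are excluded and listed.
    """
    if table.z is None:
        table = zscore_normalize(table)
    avg = table.z.mean(axis=1)
    n_obs = table.z.notna().sum(axis=1)
    keep = n_obs >= min_obs
    excluded = sorted(avg.index[~keep])
    if not keep.any():
        raise ValueError("no gene has enough observations")
    sub = pd.DataFrame({"avg_z": avg[keep], "n_obs": n_obs[keep]})
    sub = sub.iloc[np.lexsort((sub.index.to_numpy(), sub["avg_z"].to_numpy()))]
    sub["rank"] = np.arange(1, len(sub) + 1)
    sub["percentile"] = sub["rank"] / len(sub) * 100
    return RankedGenes(sub, excluded)


def top_fraction(ranked: RankedGenes, frac: float):
    """First ``floor(frac * N)`` genes of the ranking.

    Returns a :class:`GeneSet`; a fraction too small to contain any gene
    yields an empty stand-in with a warning (GeneSet itself requires
    at least one member).
    """
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")
    k = int(np.floor(frac * len(ranked)))
    if k == 0:
        logger.warning("top fraction %.4f of %d genes is empty", frac, len(ranked))
        return _EmptyGeneSet(f"top_{frac:g}")
    return GeneSet(f"top_{frac:g}", frozenset(ranked.genes[:k]))


class _EmptyGeneSet:
    """Stand-in for an empty top set."""

    def __init__(self, name: str):
        self.name = name
        self.genes: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return 0

    def __contains__(self, gene: str) -> bool:
        return False

    def sorted_genes(self) -> list[str]:
        return []


def signature_top_coverage(
    signature: GeneSet, ranked: RankedGenes, fracs=(0.01, 0.02, 0.03)
) -> pd.DataFrame:
    """Percentage of signature genes inside each top fraction.

    ``coverage_pct`` uses the signature ∩ ranked-universe denominator;
    ``coverage_pct_full`` divides by the full signature size.  The
    member genes per fraction are returned in the ``members`` column.
    """
    universe = set(ranked.genes)
    present = signature.genes & universe
    if not present:
        raise ValueError("signature is disjoint from the ranked universe")
    rows = []
    for frac in fracs:
        top = top_fraction(ranked, frac)
        members = sorted(present & set(top.genes))
        rows.append(
            {
                "frac": frac,
                "n_top": len(top.genes),
                "n_members": len(members),
                "coverage_pct": 100.0 * len(members) / len(present),
                "coverage_pct_full": 100.0 * len(members) / len(signature.genes),
                "members": ",".join(members),
            }
        )
    return pd.DataFrame(rows).set_index("frac")
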