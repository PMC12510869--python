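"""Single-sample gene-set enrichment and marker-based abundance scores.

Two scoring engines are provided:

``ssgsea_score``
    The single-sample GSEA random walk.  Within each sample, genes are
    ranked by expression (mid-ranks for ties).  Walking down the genes in
    descending expression order, set members contribute
    ``rank^alpha`` (normalized so the hit increments sum to one) and
    non-members contribute ``1/(N - |S|)``.  The score is the *integral*
    of the running hit-minus-miss difference over all positions.  Scores
    therefore depend only on within-sample ranks.

``gsva_ecdf_score``
    A rank/ECDF variant of gene-set variation analysis: each gene's
    expression is first transformed to its empirical-CDF statistic
    across samples, then each sample is scored by a weighted
    Kolmogorov–Smirnov-style walk over genes ordered by that statistic;
    the score is the sum of the maximum positive and maximum negative
    deviations.  This is a deliberately simplified reimplementation of
    the ECDF ("no-kernel") flavour of GSVA, not a numerical clone.

``marker_abundance`` gives per-cell-type abundance proxies as the mean
log-scale expression of marker genes, in the spirit of marker-mean
deconvolution-free estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    ExpressionMatrix,
    SignatureCollection,
    bh_adjust,
    spearman_test,
)

logger = logging.getLogger("uvrsig")

__all__ = [
    "EnrichmentScores",
    "ssgsea_score",
    "gsva_ecdf_score",
    "marker_abundance",
    "score_correlation_panel",
]


@dataclass
class EnrichmentScores:
    """Set × sample score matrix with the scoring configuration attached."""

    frame: pd.DataFrame  # sets x samples
    method: str  # "ssgsea" | "gsva_ecdf" | "marker_mean"
    alpha: float | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy()
        if vals.size and not np.all(np.isfinite(vals[~np.isnan(vals)])):
            raise ValueError("scores must be finite (NaN allowed for missing sets)")

    def series(self, set_name: str) -> pd.Series:
        return self.frame.loc[set_name]


def _filter_sets(matrix: ExpressionMatrix, sets: SignatureCollection, min_genes: int):
    """Restrict each set to the matrix universe; drop undersized sets."""
    universe = set(matrix.gene_ids)
    kept: dict[str, list[str]] = {}
    for gs in sets:
        present = sorted(gs.genes & universe)
        if len(present) < min_genes:
            logger.warning(
                "set %r has %d gene(s) in the matrix (< %d); skipped",
                gs.name, len(present), min_genes,
            )
            continue
        kept[gs.name] = present
    if not kept:
        raise ValueError("no gene set retains enough genes in the matrix")
    return kept


def ssgsea_score(
    matrix: ExpressionMatrix,
    sets: SignatureCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> EnrichmentScores:
    """Single-sample GSEA scores for every set and sample.

    Sets with fewer than 2 genes in the matrix are skipped with a
    warning.  With ``normalize`` the whole score matrix is divided by its
    range (max − min), the conventional cross-sample normalization.
    """
    kept = _filter_sets(matrix, sets, min_genes=2)
    X = matrix.values
    n_genes = matrix.n_genes
    gene_pos = matrix.gene_index()

    # descending expression order per sample; ties keep stable gene order
    order = np.argsort(-X, axis=0, kind="stable")
    ranks = sps.rankdata(X, axis=0)  # ascending mid-ranks
    ranked_w = np.take_along_axis(ranks, order, axis=0) ** alpha

    rows = {}
    for name, genes in kept.items():
        member = np.zeros(n_genes, dtype=bool)
        member[[gene_pos[g] for g in genes]] = True
        m = member.sum()
        in_ord = member[order]  # positions x samples
        hit_w = np.where(in_ord, ranked_w, 0.0)
        hit_cum = np.cumsum(hit_w / hit_w.sum(axis=0, keepdims=True), axis=0)
        miss_cum = np.cumsum(np.where(in_ord, 0.0, 1.0 / (n_genes - m)), axis=0)
        rows[name] = (hit_cum - miss_cum).sum(axis=0)

    frame = pd.DataFrame(rows, index=matrix.sample_ids).T
    if normalize:
        rng = frame.to_numpy().max() - frame.to_numpy().min()
        if rng > 0:
            frame = frame / rng
    return EnrichmentScores(frame, "ssgsea", alpha=alpha, normalized=normalize)


def gsva_ecdf_score(
    matrix: ExpressionMatrix, sets: SignatureCollection
) -> EnrichmentScores:
    """ECDF-based GSVA-style scores (cross-sample rank statistic).

    Needs at least 3 samples, since the gene-level statistic is an
    empirical CDF across samples; for fewer samples use
    :func:`ssgsea_score`, which is purely within-sample.
    """
    if matrix.n_samples < 3:
        raise ValueError(
            "gsva_ecdf_score needs >= 3 samples; use ssgsea_score for fewer"
        )
    kept = _filter_sets(matrix, sets, min_genes=2)
    n_genes = matrix.n_genes
    gene_pos = matrix.gene_index()

    # per-gene ECDF statistic across samples, in (0, 1]
    E = sps.rankdata(matrix.values, axis=1) / matrix.n_samples
    order = np.argsort(-E, axis=0, kind="stable")
    ranked_w = np.take_along_axis(E, order, axis=0)

    rows = {}
    for name, genes in kept.items():
        member = np.zeros(n_genes, dtype=bool)
        member[[gene_pos[g] for g in genes]] = True
        m = member.sum()
        in_ord = member[order]
        hit_w = np.where(in_ord, ranked_w, 0.0)
        walk = np.cumsum(
            hit_w / hit_w.sum(axis=0, keepdims=True)
            - np.where(in_ord, 0.0, 1.0 / (n_genes - m)),
            axis=0,
        )
        rows[name] = walk.max(axis=0).clip(min=0) + walk.min(axis=0).clip(max=0)

    frame = pd.DataFrame(rows, index=matrix.sample_ids).T
    return EnrichmentScores(frame, "gsva_ecdf")


def marker_abundance(
    matrix: ExpressionMatrix, marker_sets: SignatureCollection
) -> EnrichmentScores:
    """Mean log-scale marker expression per cell type and sample.

    A set with no marker present in the matrix yields NaN scores with a
    warning rather than an error, so panels with partially overlapping
    universes degrade gracefully.
    """
    universe = set(matrix.gene_ids)
    rows = {}
    for gs in marker_sets:
        present = sorted(gs.genes & universe)
        if not present:
            logger.warning("no marker of set %r present in matrix", gs.name)
            rows[gs.name] = np.full(matrix.n_samples, np.nan)
            continue
        sub = matrix.subset_genes(present)
        rows[gs.name] = sub.values.mean(axis=0)
    frame = pd.DataFrame(rows, index=matrix.sample_ids).T
    return EnrichmentScores(frame, "marker_mean")


def score_correlation_panel(scores: pd.Series, features) -> pd.DataFrame:
    """Spearman-correlate a per-sample score against each feature row.

    ``features`` is an :class:`ExpressionMatrix` or a feature × sample
    DataFrame whose columns must match the score's sample index exactly.
    Returns a table with columns ``r``, ``p``, ``n``, ``q`` (BH-adjusted
    across features).
    """
    if isinstance(features, ExpressionMatrix):
        feat = features.to_frame()
    else:
        feat = features
    missing = [s for s in feat.columns if s not in scores.index]
    extra = [s for s in scores.index if s not in feat.columns]
    if missing or extra:
        raise ValueError(
            f"sample-id mismatch; features-only: {missing[:5]}, scores-only: {extra[:5]}"
        )
    s = scores.loc[feat.columns].to_numpy(dtype=float)
    records = []
    for name, row in feat.iterrows():
        res = spearman_test(row.to_numpy(dtype=float), s)
        records.append((name, res.r, res.p, res.n))
    out = pd.DataFrame(records, columns=["feature", "r", "p", "n"]).set_index("feature")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
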