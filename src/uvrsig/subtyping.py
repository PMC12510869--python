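"""Consensus-clustering subtyping, score comparisons and deconvolution.

Consensus clustering follows the Monti resampling scheme: for each k in
the requested range, the samples are repeatedly subsampled (80% by
default), k-means (Euclidean, k-means++ with 10 restarts) clusters each
subsample, and the consensus matrix records how often each sample pair
co-clusters among the resamples that drew both.  Final labels per k
come from average-linkage hierarchical clustering of 1 − consensus; the
number of clusters is picked from the relative change in the area under
the consensus CDF (delta-area criterion), overridable by the caller.

Immune-cell deconvolution is linear ν-support-vector regression against
a marker signature matrix: mixture and signature are z-scored on their
shared genes, ν ∈ {0.25, 0.5, 0.75} is chosen per sample by
reconstruction RMSE, negative coefficients are truncated to zero and
the remainder renormalized to fractions summing to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.svm import NuSVR

from .core import ExpressionMatrix, bh_adjust, spearman_test, wilcoxon_rank_sum

logger = logging.getLogger("uvrsig")

__all__ = [
    "ConsensusResult",
    "DeconvolutionResult",
    "consensus_cluster",
    "compare_subtype_scores",
    "svr_deconvolve",
    "hub_immune_correlations",
]


@dataclass
class ConsensusResult:
    sample_ids: list[str]
    consensus: dict[int, np.ndarray]  # k -> samples x samples in [0, 1]
    labels: dict[int, np.ndarray]  # k -> cluster labels in 1..k
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int | None

    def label_series(self, k: int) -> pd.Series:
        return pd.Series(self.labels[k], index=self.sample_ids, name=f"k{k}")


@dataclass
class DeconvolutionResult:
    fractions: pd.DataFrame  # samples x cell types
    rmse: pd.Series
    nu: pd.Series
    ok: pd.Series  # False where the fit collapsed to all-zero coefficients


def consensus_cluster(
    matrix: ExpressionMatrix,
    k_range=range(2, 7),
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    delta_threshold: float = 0.1,
) -> ConsensusResult:
    """Monti consensus clustering of samples on z-scaled features."""
    n = matrix.n_samples
    if n < 20:
        raise ValueError("need at least 20 samples")
    X = matrix.values
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = ((X - X.mean(axis=1, keepdims=True)) / sd).T  # samples x features
    rng = np.random.default_rng(seed)
    m = int(np.floor(subsample_frac * n))

    consensus: dict[int, np.ndarray] = {}
    labels: dict[int, np.ndarray] = {}
    for k in k_range:
        co = np.zeros((n, n))
        both = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            km = KMeans(
                n_clusters=k, n_init=10, init="k-means++",
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(Z[idx])
            same = km.labels_[:, None] == km.labels_[None, :]
            both[np.ix_(idx, idx)] += 1
            co[np.ix_(idx, idx)] += same
        if (both == 0).any():
            raise ValueError(
                "some sample pairs never co-sampled; increase n_resamples"
            )
        C = co / both
        np.fill_diagonal(C, 1.0)
        C = (C + C.T) / 2
        consensus[k] = C
        hl = linkage(squareform(1 - C, checks=False), method="average")
        labels[k] = fcluster(hl, t=k, criterion="maxclust")

    cdf_area: dict[int, float] = {}
    for k, C in consensus.items():
        vals = np.sort(C[np.triu_indices(n, 1)])
        # area under the empirical CDF over [0, 1]
        cdf = np.arange(1, vals.size + 1) / vals.size
        grid = np.concatenate([[0.0], vals, [1.0]])
        heights = np.concatenate([[0.0], cdf])
        cdf_area[k] = float(np.sum(heights * np.diff(grid)))

    ks = sorted(cdf_area)
    delta_area: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta_area[k] = cdf_area[k]
        else:
            prev = cdf_area[ks[i - 1]]
            delta_area[k] = (cdf_area[k] - prev) / prev if prev > 0 else 0.0
    stable = [k for k in ks if delta_area[k] >= delta_threshold]
    chosen_k = max(stable) if stable else None

    return ConsensusResult(
        list(matrix.sample_ids), consensus, labels, cdf_area, delta_area, chosen_k
    )


def compare_subtype_scores(labels: pd.Series, scores: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon rank-sum of each score column between two subtypes.

    Returns one row per score with the test statistic, p, q (BH over
    scores), per-group medians and the direction of the difference.
    """
    common = [s for s in scores.index if s in labels.index]
    lab = labels.loc[common]
    groups = sorted(lab.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 subtypes, got {groups}")
    rows = []
    for col in scores.columns:
        vals = scores.loc[common, col]
        a = vals[lab == groups[0]].dropna().to_numpy()
        b = vals[lab == groups[1]].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            logger.warning("score %r all-missing in one subtype; skipped", col)
            continue
        res = wilcoxon_rank_sum(a, b)
        rows.append(
            {
                "score": col,
                "statistic": res.statistic,
                "p": res.p,
                f"median_{groups[0]}": float(np.median(a)),
                f"median_{groups[1]}": float(np.median(b)),
                "direction": res.effect_direction,
            }
        )
    out = pd.DataFrame(rows).set_index("score")
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def svr_deconvolve(
    mixtures: ExpressionMatrix,
    basis: ExpressionMatrix,
    nus=(0.25, 0.5, 0.75),
) -> DeconvolutionResult:
    """Estimate cell-type fractions by linear ν-SVR against a signature matrix.

    ``basis`` is marker genes × cell types.  Fractions are non-negative
    and sum to one for every sample whose fit produced at least one
    positive coefficient (``ok`` flag).
    """
    cell_types = basis.sample_ids
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types in the basis")
    shared = [g for g in basis.gene_ids if g in set(mixtures.gene_ids)]
    if not shared:
        raise ValueError("no basis gene present in the mixtures")
    B = basis.subset_genes(shared).values  # genes x types
    M = mixtures.subset_genes(shared).values  # genes x samples
    Bz = (B - B.mean()) / B.std()

    frac_rows, rmse_rows, nu_rows, ok_rows = [], [], [], []
    for j in range(M.shape[1]):
        y = M[:, j]
        yz = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)
        best = None
        for nu in nus:
            svr = NuSVR(nu=nu, kernel="linear", C=1.0).fit(Bz, yz)
            pred = svr.predict(Bz)
            rmse = float(np.sqrt(np.mean((pred - yz) ** 2)))
            if best is None or rmse < best[0]:
                best = (rmse, nu, svr.coef_.ravel().copy())
        rmse, nu, w = best
        w = np.clip(w, 0.0, None)
        total = w.sum()
        ok = total > 0
        frac = w / total if ok else np.full(len(cell_types), np.nan)
        frac_rows.append(frac)
        rmse_rows.append(rmse)
        nu_rows.append(nu)
        ok_rows.append(ok)
        if not ok:
            logger.warning(
                "sample %s: all coefficients non-positive; fractions undefined",
                mixtures.sample_ids[j],
            )
    idx = pd.Index(mixtures.sample_ids, name="sample")
    return DeconvolutionResult(
        fractions=pd.DataFrame(frac_rows, index=idx, columns=cell_types),
        rmse=pd.Series(rmse_rows, index=idx, name="rmse"),
        nu=pd.Series(nu_rows, index=idx, name="nu"),
        ok=pd.Series(ok_rows, index=idx, name="ok"),
    )


def hub_immune_correlations(
    hub_expr: ExpressionMatrix,
    fractions: pd.DataFrame,
    filter_p: float = 0.05,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Spearman correlation of each hub gene with each cell-type fraction.

    For every (gene, cell type) pair only samples with fraction > 0 are
    used.  Pairs with p < ``filter_p`` are ranked by r; the two most
    positive and two most negative are flagged in the ``highlight``
    column.  Returns an empty table (with a logged notice) when nothing
    passes the filter.
    """
    expr = hub_expr.to_frame()
    common = [s for s in expr.columns if s in fractions.index]
    if not common:
        raise ValueError("no shared samples between expression and fractions")
    rows = []
    for gene in expr.index:
        for ct in fractions.columns:
            f = fractions.loc[common, ct]
            mask = f > 0
            if mask.sum() < min_samples:
                continue
            res = spearman_test(
                expr.loc[gene, np.array(common)[mask.to_numpy()]].to_numpy(),
                f[mask].to_numpy(),
            )
            rows.append(
                {"gene": gene, "cell_type": ct, "r": res.r, "p": res.p, "n": res.n}
            )
    table = pd.DataFrame(rows)
    if table.empty:
        logger.warning("no (gene, cell type) pair had enough positive fractions")
        return table
    sig = table[table["p"] < filter_p].sort_values("r", ascending=False).copy()
    if sig.empty:
        logger.warning("no pair passes the p < %g filter", filter_p)
        return sig
    sig["highlight"] = ""
    pos = sig.index[sig["r"] > 0][:2]
    neg = sig.index[sig["r"] < 0][-2:]
    sig.loc[pos, "highlight"] = "top_positive"
    sig.loc[neg, "highlight"] = "top_negative"
    return sig.reset_index(drop=True)
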