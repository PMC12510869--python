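"""Shared data model, standard-format I/O, and statistical primitives.

The pipeline's canonical container is :class:`ExpressionMatrix` — a dense
genes × samples matrix with aligned identifier lists and an explicit scale
flag (``counts`` or ``log_normalized``).  Gene sets travel as
:class:`GeneSet` / :class:`SignatureCollection`, backed by the GMT format.

Statistical conventions used throughout the package:

* Spearman correlation uses mid-ranks for ties; the p-value comes from the
  t approximation for n >= 10 and from exhaustive permutation of one rank
  vector for n < 10.
* The Wilcoxon rank-sum test uses the tie-corrected normal approximation
  with continuity correction.
* Multiple testing is controlled with the Benjamini–Hochberg step-up.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("uvrsig")

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "SignatureCollection",
    "CorrelationResult",
    "TestResult",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "read_matrix",
    "write_matrix",
    "spearman_test",
    "wilcoxon_rank_sum",
    "bh_adjust",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Dense genes × samples expression matrix with aligned identifiers.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per row of ``values``.
    sample_ids
        Unique sample (or cell) identifiers, one per column.
    values
        Numeric matrix of shape ``(len(gene_ids), len(sample_ids))``.
    scale
        ``"counts"`` for non-negative linear-scale values or
        ``"log_normalized"`` for log1p-transformed normalized expression.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "log_normalized"

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("counts", "log_normalized"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.scale == "counts" and self.values.min() < 0:
            raise ValueError("counts-scale values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (order preserved from this matrix)."""
        keep = set(genes)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx],
            self.sample_ids,
            self.values[idx, :],
            self.scale,
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        """Restrict to ``samples`` in the given order."""
        pos = self.sample_index()
        idx = [pos[s] for s in samples]
        return ExpressionMatrix(
            self.gene_ids, list(samples), self.values[:, idx], self.scale
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: str = "log_normalized"):
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), scale)

    def linear_values(self) -> np.ndarray:
        """Expression on the linear scale (``expm1`` of log1p-normalized values)."""
        if self.scale == "counts":
            return self.values
        return np.expm1(self.values)


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty set of gene symbols."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)

    def intersect(self, universe) -> frozenset[str]:
        return self.genes & set(universe)


@dataclass
class SignatureCollection:
    """Ordered mapping of unique names to gene sets (GMT-backed)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValueError(f"key {name!r} does not match set name {gs.name!r}")

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValueError(f"duplicate set name {gs.name!r}")
        self.sets[gs.name] = gs

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation with its p-value and pair count."""

    r: float
    p: float
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if not (0 <= self.p <= 1):
            raise ValueError("p must be in [0, 1]")


@dataclass(frozen=True)
class TestResult:
    """Two-sample rank-sum test result."""

    statistic: float
    p: float
    effect_direction: int  # sign of median(a) - median(b)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1):
            raise ValueError("p must be in [0, 1]")


# ---------------------------------------------------------------------------
# GMT and matrix I/O
# ---------------------------------------------------------------------------


class GmtParseError(ValueError):
    pass


def read_gmt(path) -> SignatureCollection:
    """Read a GMT file (one tab-separated gene set per line).

    Each line must carry at least three fields: name, description, and one
    or more gene symbols.  Duplicate symbols within a line are collapsed
    with a logged warning; duplicate set names raise.
    """
    coll = SignatureCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "expected name, description and at least one gene"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) != len(genes):
                logger.warning(
                    "GMT set %r (line %d): duplicate symbols collapsed", name, lineno
                )
            if name in coll.sets:
                raise GmtParseError(f"{path}: duplicate set name {name!r}")
            coll.add(GeneSet(name, frozenset(genes), description))
    return coll


def write_gmt(coll: SignatureCollection, path) -> None:
    """Write a collection to GMT; genes in deterministic alphabetical order."""
    with open(path, "w") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.description, *gs.sorted_genes()]) + "\n")


def read_matrix(path, fmt: str = "tsv", scale: str = "log_normalized",
                genes_path=None, samples_path=None) -> ExpressionMatrix:
    """Read a genes × samples matrix from TSV or MatrixMarket coordinates.

    TSV layout: header row of sample ids, first column of gene ids.  MTX
    input needs sidecar id files (defaults: ``genes.txt`` / ``samples.txt``
    next to the matrix), one identifier per line.
    """
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        bad = df.map(lambda v: isinstance(v, str))
        if bad.to_numpy().any():
            g = bad.index[bad.any(axis=1)][0]
            s = bad.columns[bad.loc[g]][0]
            raise ValueError(f"non-numeric cell at gene {g!r}, sample {s!r}")
        return ExpressionMatrix.from_frame(df.astype(float), scale)
    if fmt == "mtx":
        import os

        base = os.path.dirname(str(path))
        genes_path = genes_path or os.path.join(base, "genes.txt")
        samples_path = samples_path or os.path.join(base, "samples.txt")
        mat = spio.mmread(str(path)).toarray()
        genes = [ln.strip() for ln in open(genes_path) if ln.strip()]
        samples = [ln.strip() for ln in open(samples_path) if ln.strip()]
        return ExpressionMatrix(genes, samples, mat, scale)
    raise ValueError(f"unknown format {fmt!r}")


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Statistical primitives
# ---------------------------------------------------------------------------

_EXACT_SPEARMAN_N = 10  # below this, p by exhaustive permutation


def spearman_test(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    r is the Pearson correlation of the mid-ranks.  For n >= 10 the
    p-value uses the t approximation ``t = r * sqrt((n-2)/(1-r^2))`` on
    n - 2 degrees of freedom; for n < 10 it is the exact two-sided
    permutation p over all orderings of one rank vector.  A constant
    input yields r = 0, p = 1 with the degenerate flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(0.0, 1.0, n, degenerate=True)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-14:
        # perfect monotone association
        return CorrelationResult(float(np.sign(r)), 0.0, n)
    if n >= _EXACT_SPEARMAN_N:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2 * sps.t.sf(abs(t), df=n - 2)
    else:
        p = _spearman_exact_p(rx, ry, abs(r))
    return CorrelationResult(r, float(min(p, 1.0)), n)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, abs_r: float) -> float:
    """Two-sided permutation p over all orderings of ``ry``."""
    rxc = rx - rx.mean()
    denom = math.sqrt(float(np.sum(rxc**2) * np.sum((ry - ry.mean()) ** 2)))
    # |dot(rxc, perm)| is proportional to |r| with a permutation-invariant
    # denominator, so thresholding the dot product thresholds |r|
    perms = np.array(list(itertools.permutations(ry)))
    stats = np.abs(perms @ rxc)
    thresh = abs_r * denom - 1e-12
    return float(np.mean(stats >= thresh))


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon (Mann–Whitney) rank-sum test with mid-ranks.

    For small tie-free samples (pooled n <= 25) the exact rank-sum
    distribution is used; otherwise the tie-corrected normal
    approximation with continuity correction.  ``alternative`` follows
    the usual convention with respect to ``a`` ("two-sided", "greater",
    "less").  Identical pooled values in both groups give p = 1 with
    the degenerate flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return TestResult(float(a.size * b.size / 2), 1.0, 0, degenerate=True)
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and pooled.size <= 25) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    direction = int(np.sign(np.median(a) - np.median(b)))
    return TestResult(float(res.statistic), float(res.pvalue), direction)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_matrix(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mid-ranks along ``axis`` (ascending)."""
    return sps.rankdata(values, axis=axis)


def spearman_matrix(values: np.ndarray, target: np.ndarray):
    """Vectorized Spearman of each row of ``values`` against ``target``.

    Returns ``(r, p)`` arrays; p from the t approximation (intended for
    n >= 10).  Rows or targets with zero variance get r = 0, p = 1.
    """
    n = target.size
    if values.shape[1] != n:
        raise ValueError("column count must match target length")
    rt = sps.rankdata(target)
    rv = sps.rankdata(values, axis=1)
    rt_c = rt - rt.mean()
    rv_c = rv - rv.mean(axis=1, keepdims=True)
    denom = np.sqrt((rv_c**2).sum(axis=1) * (rt_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rv_c @ rt_c) / denom
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0 - 1e-14, 0.0, p)
    p = np.where(denom == 0, 1.0, p)
    return r, p
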