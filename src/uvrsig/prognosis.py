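"""Hub-gene selection, Cox risk modelling and survival stratification.

Hub genes are chosen by consensus over a registry of feature selectors
run on a labeled cohort: a gene enters the hub set when at least
``min_votes`` selectors (default 4 of 6) retain it.  The registry
reimplements the usual selector families rather than cloning any
particular toolkit:

``lasso``
    L1-penalized logistic regression; the penalty is chosen by
    stratified 5-fold cross-validated log-loss with the one-standard-
    error rule, and selected genes are those with nonzero coefficients.
``boruta``
    Shadow-feature testing: each iteration appends permuted copies of
    all features, fits a random forest, and counts a "hit" when a
    feature's importance beats the best shadow importance; features are
    confirmed (or rejected) by a binomial test at p < 0.01.
``rf_importance`` / ``bagged_trees_importance``
    Permutation importance of a random forest / bagged trees model,
    thresholded at the 95th percentile of a permuted-label null
    distribution (50 label permutations).
``univariate_auc``
    Per-gene two-sided rank-sum test of the gene against the label
    (equivalently |AUC - 0.5| > 0), BH-corrected, q < 0.05.  A simple
    univariate probabilistic filter.
``lvq_importance``
    ROC-filter importance (|AUC - 0.5|) thresholded at the 95th
    percentile of the same permuted-label null.

The risk model is multivariate Cox proportional hazards with Efron tie
handling; the risk score is the linear predictor Σ β·expression.  The
high/low dichotomization scans observed score cutpoints between the 10%
and 90% quantiles and keeps the cutpoint maximizing the log-rank
statistic.  P-values reported for groups chosen this way are flagged
``cutoff_optimized``: the maximization makes the plain log-rank p
anti-conservative, and the flag surfaces that caveat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .core import ExpressionMatrix, GeneSet, bh_adjust

logger = logging.getLogger("uvrsig")

__all__ = [
    "SelectorResult",
    "CoxModel",
    "SurvivalTable",
    "SELECTOR_REGISTRY",
    "run_selector",
    "consensus_hub",
    "fit_cox",
    "risk_scores",
    "optimal_cutoff",
    "km_logrank",
]


@dataclass
class SelectorResult:
    selector_name: str
    selected: frozenset[str]
    importance: pd.Series  # per-candidate score
    seed: int


@dataclass
class CoxModel:
    genes: list[str]
    coef: np.ndarray
    se: np.ndarray
    log_likelihood: float
    converged: bool

    def __post_init__(self) -> None:
        if self.converged and not np.all(np.isfinite(self.coef)):
            raise ValueError("non-finite coefficients on a converged fit")
        if len(self.genes) != self.coef.size:
            raise ValueError("genes and coefficients must align")


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (days), event indicator and optional risk data."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    risk_score: np.ndarray | None = None
    group: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if np.any(self.time <= 0):
            raise ValueError("times must be > 0")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event must be 0/1")
        n = len(self.sample_ids)
        if self.time.size != n or self.event.size != n:
            raise ValueError("time/event must align with sample_ids")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event}, index=self.sample_ids
        )


# ---------------------------------------------------------------------------
# Feature selectors
# ---------------------------------------------------------------------------


def _design(matrix: ExpressionMatrix, candidates: GeneSet):
    genes = [g for g in matrix.gene_ids if g in candidates.genes]
    if len(genes) < 1:
        raise ValueError("no candidate gene present in the matrix")
    X = matrix.subset_genes(genes).values.T  # samples x genes
    return genes, X


def _check_labels(y: np.ndarray) -> None:
    if len(set(y.tolist())) != 2:
        raise ValueError("labels must contain both classes")


def _select_lasso(X, y, genes, seed):
    Cs = np.logspace(-2.5, 2.0, 20)
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    losses = np.zeros((len(Cs), 5))
    for f, (tr, te) in enumerate(skf.split(X, y)):
        for i, C in enumerate(Cs):
            clf = LogisticRegression(
                l1_ratio=1.0, C=C, solver="liblinear", random_state=seed
            ).fit(X[tr], y[tr])
            losses[i, f] = log_loss(y[te], clf.predict_proba(X[te])[:, 1], labels=[0, 1])
    mean = losses.mean(axis=1)
    se = losses.std(axis=1, ddof=1) / np.sqrt(5)
    best = int(np.argmin(mean))
    # one-SE rule: strongest penalty whose CV loss is within one SE of the best
    ok = np.where(mean <= mean[best] + se[best])[0]
    C_star = Cs[ok.min()]
    clf = LogisticRegression(
        l1_ratio=1.0, C=C_star, solver="liblinear", random_state=seed
    ).fit(X, y)
    imp = pd.Series(np.abs(clf.coef_[0]), index=genes)
    return imp[imp > 0].index, imp


def _select_boruta(X, y, genes, seed, max_iter=100, alpha=0.01):
    rng = np.random.default_rng(seed)
    n_feat = len(genes)
    hits = np.zeros(n_feat, dtype=int)
    decided = np.zeros(n_feat, dtype=int)  # 0 tentative, 1 confirmed, -1 rejected
    n_iter = 0
    for it in range(max_iter):
        shadow = X.copy()
        for j in range(n_feat):
            shadow[:, j] = shadow[rng.permutation(X.shape[0]), j]
        rf = RandomForestClassifier(
            n_estimators=100, random_state=seed + it, n_jobs=1
        ).fit(np.hstack([X, shadow]), y)
        imp = rf.feature_importances_
        hits += imp[:n_feat] > imp[n_feat:].max()
        n_iter = it + 1
        # binomial test against the p=0.5 null
        p_hi = sps.binom.sf(hits - 1, n_iter, 0.5)
        p_lo = sps.binom.cdf(hits, n_iter, 0.5)
        decided = np.where((decided == 0) & (p_hi < alpha), 1, decided)
        decided = np.where((decided == 0) & (p_lo < alpha), -1, decided)
        if np.all(decided != 0):
            break
    imp = pd.Series(hits / n_iter, index=genes)
    return imp.index[decided == 1], imp


def _null_threshold(importance_fn, X, y, seed, n_perm=50, q=95.0):
    """95th percentile of pooled importances under label permutation."""
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_perm):
        null.append(importance_fn(X, y[rng.permutation(y.size)]))
    return float(np.percentile(np.concatenate(null), q))


def _perm_importance_factory(estimator_fn, seed):
    def importances(X, y):
        est = estimator_fn().fit(X, y)
        r = permutation_importance(
            est, X, y, n_repeats=5, random_state=seed, n_jobs=1
        )
        return r.importances_mean

    return importances


def _select_tree_importance(X, y, genes, seed, bagged: bool):
    if bagged:
        est_fn = lambda: BaggingClassifier(  # noqa: E731
            DecisionTreeClassifier(random_state=seed),
            n_estimators=50,
            random_state=seed,
        )
    else:
        est_fn = lambda: RandomForestClassifier(  # noqa: E731
            n_estimators=100, random_state=seed, n_jobs=1
        )
    fn = _perm_importance_factory(est_fn, seed)
    obs = fn(X, y)
    thr = _null_threshold(fn, X, y, seed, n_perm=50)
    imp = pd.Series(obs, index=genes)
    return imp.index[obs > thr], imp


def _auc_importance(X, y):
    from scipy.stats import rankdata

    ranks = rankdata(X, axis=0)
    n_pos = int((y == 1).sum())
    n_neg = y.size - n_pos
    u = ranks[y == 1].sum(axis=0) - n_pos * (n_pos + 1) / 2
    return np.abs(u / (n_pos * n_neg) - 0.5)


def _select_univariate_auc(X, y, genes, seed, q_max=0.05):
    res = sps.mannwhitneyu(
        X[y == 1], X[y == 0], axis=0, alternative="two-sided", method="asymptotic"
    )
    qvals = bh_adjust(res.pvalue)
    imp = pd.Series(_auc_importance(X, y), index=genes)
    return imp.index[qvals < q_max], imp


def _select_lvq(X, y, genes, seed):
    obs = _auc_importance(X, y)
    thr = _null_threshold(_auc_importance, X, y, seed, n_perm=50)
    imp = pd.Series(obs, index=genes)
    return imp.index[obs > thr], imp


SELECTOR_REGISTRY = {
    "lasso": _select_lasso,
    "boruta": _select_boruta,
    "rf_importance": lambda X, y, g, s: _select_tree_importance(X, y, g, s, False),
    "bagged_trees_importance": lambda X, y, g, s: _select_tree_importance(
        X, y, g, s, True
    ),
    "univariate_auc": _select_univariate_auc,
    "lvq_importance": _select_lvq,
}


def run_selector(
    matrix: ExpressionMatrix,
    labels,
    candidates: GeneSet,
    selector: str,
    seed: int = 0,
) -> SelectorResult:
    """Run one registered feature selector on a labeled expression matrix.

    ``labels`` is a 0/1 vector aligned to the matrix samples (1 = the
    class of interest, e.g. non-responder or high-risk).
    """
    if selector not in SELECTOR_REGISTRY:
        raise ValueError(
            f"unknown selector {selector!r}; registered: {sorted(SELECTOR_REGISTRY)}"
        )
    y = np.asarray(labels, dtype=int)
    _check_labels(y)
    genes, X = _design(matrix, candidates)
    selected, importance = SELECTOR_REGISTRY[selector](X, y, genes, seed)
    return SelectorResult(selector, frozenset(selected), importance, seed)


def consensus_hub(
    results: list[SelectorResult], min_votes: int = 4
) -> tuple[GeneSet, pd.DataFrame]:
    """Genes selected by at least ``min_votes`` selectors, plus the vote table."""
    if len(results) < min_votes:
        raise ValueError(
            f"only {len(results)} selector results for min_votes={min_votes}"
        )
    all_genes = sorted({g for r in results for g in r.selected})
    votes = pd.DataFrame(
        {r.selector_name: [g in r.selected for g in all_genes] for r in results},
        index=pd.Index(all_genes, name="gene"),
    )
    votes["votes"] = votes.sum(axis=1)
    hub = votes.index[votes["votes"] >= min_votes]
    if len(hub) == 0:
        raise ValueError("no gene reaches the vote threshold")
    return GeneSet("hub", frozenset(hub)), votes


# ---------------------------------------------------------------------------
# Cox model, risk scores, cutoff, KM
# ---------------------------------------------------------------------------


def fit_cox(
    matrix: ExpressionMatrix, survival: SurvivalTable, genes: GeneSet
) -> CoxModel:
    """Multivariate Cox proportional hazards with Efron tie handling."""
    present = [g for g in matrix.gene_ids if g in genes.genes]
    missing = genes.genes - set(present)
    if missing:
        raise ValueError(f"genes missing from matrix: {sorted(missing)[:5]}")
    if int(survival.event.sum()) < 10:
        raise ValueError("need at least 10 events")
    sub = matrix.subset_genes(present).subset_samples(survival.sample_ids)
    df = pd.DataFrame(sub.values.T, columns=present, index=survival.sample_ids)
    df["time"] = survival.time
    df["event"] = survival.event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence / separation
        raise ValueError(f"Cox fit failed: {exc}") from exc
    coef = cph.params_.loc[present].to_numpy()
    se = cph.standard_errors_.loc[present].to_numpy()
    return CoxModel(present, coef, se, float(cph.log_likelihood_), True)


def risk_scores(model: CoxModel, matrix: ExpressionMatrix) -> pd.Series:
    """Linear predictor Σ β·expression per sample."""
    missing = set(model.genes) - set(matrix.gene_ids)
    if missing:
        raise ValueError(f"model genes missing from matrix: {sorted(missing)[:5]}")
    sub = matrix.subset_genes(model.genes)
    order = [sub.gene_ids.index(g) for g in model.genes]
    return pd.Series(
        model.coef @ sub.values[order, :], index=matrix.sample_ids, name="risk_score"
    )


def optimal_cutoff(
    scores: pd.Series, survival: SurvivalTable, min_prop: float = 0.1
) -> tuple[float, pd.Series]:
    """Log-rank-maximizing dichotomization of a risk score.

    Candidate cutpoints are the observed score values between the
    ``min_prop`` and ``1 - min_prop`` quantiles; the cutpoint with the
    largest log-rank statistic wins, ties going to the lower cutoff.
    Groups: ``high`` (> cutoff) / ``low`` (<= cutoff).
    """
    s = scores.loc[survival.sample_ids].to_numpy(dtype=float)
    lo, hi = np.quantile(s, [min_prop, 1 - min_prop])
    candidates = np.unique(s[(s >= lo) & (s <= hi)])
    candidates = candidates[candidates < s.max()]  # cutoff must split
    if candidates.size < 2:
        logger.warning("fewer than 2 candidate cutpoints; falling back to median")
        candidates = np.array([float(np.median(s))])
    best_stat, best_cut = -np.inf, candidates[0]
    for cut in candidates:
        grp = s > cut
        if grp.all() or not grp.any():
            continue
        res = logrank_test(
            survival.time[grp], survival.time[~grp],
            event_observed_A=survival.event[grp],
            event_observed_B=survival.event[~grp],
        )
        if res.test_statistic > best_stat + 1e-12:
            best_stat, best_cut = res.test_statistic, float(cut)
    groups = pd.Series(
        np.where(s > best_cut, "high", "low"), index=survival.sample_ids, name="group"
    )
    return best_cut, groups


@dataclass
class KmResult:
    curves: dict[str, pd.DataFrame]  # group -> survival function with CI
    statistic: float
    p: float
    degenerate: bool = False
    cutoff_optimized: bool = False


def km_logrank(
    groups: pd.Series, survival: SurvivalTable, cutoff_optimized: bool = False
) -> KmResult:
    """Kaplan–Meier curves per group and the two-group log-rank test.

    ``cutoff_optimized`` should be set when the groups came from
    :func:`optimal_cutoff`; it marks the p-value as anti-conservative.
    With no events at all the test is degenerate (statistic 0, p = 1).
    """
    g = groups.loc[survival.sample_ids]
    names = sorted(g.unique())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {names}")
    curves = {}
    for name in names:
        mask = (g == name).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(survival.time[mask], survival.event[mask], label=name)
        curves[name] = kmf.survival_function_.join(kmf.confidence_interval_)
    if survival.event.sum() == 0:
        return KmResult(curves, 0.0, 1.0, degenerate=True,
                        cutoff_optimized=cutoff_optimized)
    mask = (g == names[0]).to_numpy()
    res = logrank_test(
        survival.time[mask], survival.time[~mask],
        event_observed_A=survival.event[mask],
        event_observed_B=survival.event[~mask],
    )
    return KmResult(
        curves, float(res.test_statistic), float(res.p_value),
        cutoff_optimized=cutoff_optimized,
    )
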