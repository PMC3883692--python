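"""Global ranking of parental features across predictable hybrid metabolites.

For every predictable metabolite a linear SVM is refit on the full
parental-pair matrix and its feature weights are converted to ranks (rank 1
= largest absolute weight, average ranks for ties, scaled by the feature
count so ranks lie in (0, 1]).  Features are then ordered by the median of
their scaled ranks over all predictable metabolites -- features that are
often important get a low median scaled rank.  Ranking stability is
assessed by leaving out all replicates of one hybrid at a time and
re-running label assignment, screening and ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from . import crl as crl_mod
from . import screen as screen_mod
from .design import DiallelDesign
from .simulate import MATERNAL, SampleTable, split_feature_id


@dataclass
class FeatureRanking:
    """Aggregated parental-feature importance.

    ``table`` has one row per parental feature (sorted ascending by median
    scaled rank): feature_id, tag (maternal/paternal), median_scaled_rank,
    n_metabolites.  ``distributions`` holds the underlying per-metabolite
    scaled rank vectors (features x metabolites).
    """

    table: pd.DataFrame
    distributions: pd.DataFrame

    @property
    def order(self) -> list[str]:
        return list(self.table.index)

    def top(self, k: int) -> list[str]:
        return self.order[:k]

    def bottom(self, k: int) -> list[str]:
        return self.order[-k:]

    def maternal_paternal_counts(self, k: int) -> tuple[int, int]:
        """Numbers of maternal and paternal features among the top k."""
        tags = self.table["tag"].iloc[:k]
        return int((tags == "maternal").sum()), int((tags == "paternal").sum())


def svm_feature_ranks(
    xpp: screen_mod.ParentalPairMatrix,
    labels: pd.Series,
    C: float = 1.0,
    rfe_steps: int = 0,
) -> np.ndarray:
    """Scaled feature ranks from a linear SVM fit on all rows.

    Multi-class problems use one-vs-one machines; a feature's importance is
    the maximum absolute weight over the binary machines.  Ranks are
    descending in importance (rank 1 = most important), averaged over ties,
    and scaled by ``1 / n_features``.  A degenerate fit (all weights zero)
    yields uniform ranks and a warning.  ``rfe_steps > 0`` switches to
    recursive feature elimination: the given number of elimination rounds is
    performed, each dropping the lowest-weight half, and the elimination
    order defines the ranks (experimental, off by default).
    """
    labels = labels.dropna().astype(int)
    if labels.nunique() < 2:
        raise ValueError("need at least 2 classes to rank features")
    rows = xpp.rows_for(list(labels.index))
    X = xpp.values.to_numpy(dtype=float)[rows]
    y = labels.loc[xpp.row_hybrid[rows]].to_numpy()
    n_feat = X.shape[1]

    if rfe_steps > 0:
        remaining = np.arange(n_feat)
        elimination_rank = np.zeros(n_feat)
        round_no = 0
        while len(remaining) > 1 and round_no < rfe_steps:
            clf = SVC(kernel="linear", C=C).fit(X[:, remaining], y)
            imp = np.max(np.abs(clf.coef_), axis=0)
            order = np.argsort(imp)
            n_drop = max(len(remaining) // 2, 1)
            dropped = remaining[order[:n_drop]]
            elimination_rank[dropped] = rfe_steps - round_no
            remaining = np.setdiff1d(remaining, dropped)
            round_no += 1
        clf = SVC(kernel="linear", C=C).fit(X[:, remaining], y)
        imp_final = np.max(np.abs(clf.coef_), axis=0)
        importance = np.zeros(n_feat)
        importance[remaining] = imp_final + elimination_rank.max() + 1
        importance += elimination_rank
    else:
        clf = SVC(kernel="linear", C=C).fit(X, y)
        importance = np.max(np.abs(clf.coef_), axis=0)

    if not np.any(importance > 0):
        warnings.warn("degenerate SVM fit (all weights zero); uniform ranks", stacklevel=2)
        return np.full(n_feat, (n_feat + 1) / 2.0 / n_feat)
    ranks = stats.rankdata(-importance, method="average")
    return ranks / n_feat


def aggregate_ranks(
    rank_vectors: dict[str, np.ndarray], feature_ids: list[str]
) -> FeatureRanking:
    """Median scaled rank per parental feature over predictable metabolites."""
    if not rank_vectors:
        raise ValueError("no rank vectors to aggregate (no predictable metabolites)")
    dist = pd.DataFrame(
        {met: np.asarray(v, dtype=float) for met, v in rank_vectors.items()},
        index=feature_ids,
    )
    med = dist.median(axis=1)
    tags = []
    for fid in feature_ids:
        _, tag = split_feature_id(fid)
        tags.append("maternal" if tag == MATERNAL else "paternal")
    table = pd.DataFrame(
        {
            "tag": tags,
            "median_scaled_rank": med,
            "n_metabolites": dist.shape[1],
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    table = table.sort_values(
        ["median_scaled_rank", "feature_id"], kind="mergesort"
    )
    return FeatureRanking(table=table, distributions=dist)


def rank_features(
    xpp: screen_mod.ParentalPairMatrix,
    crl: crl_mod.CRLMatrix,
    predictable: list[str],
    C: float = 1.0,
    rfe_steps: int = 0,
) -> FeatureRanking:
    """SVM rank vectors for each predictable metabolite, aggregated."""
    vectors: dict[str, np.ndarray] = {}
    for met in predictable:
        labels = crl.usable_labels(met)
        if labels.nunique() < 2:
            continue
        vectors[met] = svm_feature_ranks(xpp, labels, C=C, rfe_steps=rfe_steps)
    return aggregate_ranks(vectors, xpp.feature_ids)


def _ranking_run(
    table: SampleTable,
    design: DiallelDesign,
    seed: int,
    alpha: float,
    screen_kwargs: dict,
) -> FeatureRanking | None:
    crl = crl_mod.assign_labels(table, None, design, alpha=alpha)
    crl = crl_mod.balance_filter(crl)
    xpp = screen_mod.build_xpp(table, design, seed=seed)
    summary, _ = screen_mod.screen_metabolites(xpp, crl, seed=seed, **screen_kwargs)
    predictable = list(summary.index[summary["predictable"]])
    if not predictable:
        return None
    return rank_features(xpp, crl, predictable)


def loo_stability(
    table: SampleTable,
    design: DiallelDesign,
    seed: int = 0,
    alpha: float = 0.05,
    top_k: int = 20,
    **screen_kwargs,
) -> pd.DataFrame:
    """Leave-one-hybrid-out stability of the aggregated feature ranking.

    ``table`` must already be normalized.  For every hybrid, all its
    replicates are removed and label assignment -> screening -> ranking is
    re-run; the Spearman correlation between the leave-one-out median
    scaled ranks and the full-data ranks is reported together with the
    overlap of the top-``top_k`` feature sets.  A run with no predictable
    metabolites yields NaN (logged).
    """
    if len(design.hybrids) < 3:
        raise ValueError("leave-one-out needs at least 3 hybrids")
    full = _ranking_run(table, design, seed, alpha, screen_kwargs)
    if full is None:
        raise ValueError("no predictable metabolites on the full data")
    full_med = full.table["median_scaled_rank"]
    rows = []
    for hyb in design.hybrid_ids:
        sub_design = design.drop_hybrid(hyb)
        sub_table = table.drop_genotype(hyb)
        loo = _ranking_run(sub_table, sub_design, seed, alpha, screen_kwargs)
        if loo is None:
            warnings.warn(f"LOO run without {hyb}: no predictable metabolites", stacklevel=2)
            rows.append({"left_out": hyb, "spearman": np.nan, "top_overlap": np.nan})
            continue
        loo_med = loo.table["median_scaled_rank"].reindex(full_med.index)
        rho = float(stats.spearmanr(full_med.to_numpy(), loo_med.to_numpy()).statistic)
        overlap = len(set(full.top(top_k)) & set(loo.top(top_k))) / top_k
        rows.append({"left_out": hyb, "spearman": rho, "top_overlap": overlap})
    return pd.DataFrame(rows).set_index("left_out")
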