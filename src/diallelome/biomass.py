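"""Validation of the parental-feature ranking by hybrid biomass prediction.

Support vector regression (RBF kernel) predicts per-sample hybrid root
biomass from subsets of parental-pair features.  Subsets are drawn from the
aggregated ranking (top 5, random 5 of the top 10/20/50, random 5 of the
bottom block, or all features) and evaluated over many random 60/40
genotype-coherent train/test splits by the Pearson correlation between
predicted and observed test biomass.  Two nulls calibrate the procedure:
block-permuted biomass (replicates of a hybrid move together) and a
cell-permuted parental matrix (every column shuffled independently, which
destroys row coherence while preserving column marginals).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .ranking import FeatureRanking
from .screen import ParentalPairMatrix
from .simulate import SampleTable

DEFAULT_SCHEMES = (
    "top5",
    "rand5_of_top10",
    "rand5_of_top20",
    "rand5_of_top50",
    "rand5_of_bottom50",
    "all",
)

_SCHEME_RE = re.compile(r"^(?:top(?P<topk>\d+)|rand(?P<size>\d+)_of_(?P<end>top|bottom)(?P<pool>\d+)|all)$")


@dataclass
class BiomassEvaluation:
    """Per-repetition Pearson r for one feature-subset scheme."""

    scheme: str
    r_values: np.ndarray
    degenerate: int = 0  # repetitions with constant predictions (r recorded 0)

    @property
    def median_r(self) -> float:
        return float(np.median(self.r_values))

    def quartiles(self) -> tuple[float, float, float]:
        q1, q2, q3 = np.percentile(self.r_values, [25, 50, 75])
        return float(q1), float(q2), float(q3)


def select_subset(
    ranking: FeatureRanking, scheme: str, size: int = 5, seed: int = 0
) -> list[str]:
    """Feature subset for a scheme id (deterministic given the seed).

    ``topK`` takes the K best-ranked features outright; ``randS_of_topK`` /
    ``randS_of_bottomK`` sample S uniformly without replacement from the
    top/bottom K pool; ``all`` returns every feature.
    """
    m = _SCHEME_RE.match(scheme)
    if m is None:
        raise ValueError(f"unrecognized scheme {scheme!r}")
    order = ranking.order
    if scheme == "all":
        return list(order)
    if m.group("topk") is not None:
        k = int(m.group("topk"))
        if k > len(order):
            raise ValueError(f"scheme {scheme}: only {len(order)} features available")
        return order[:k]
    size = int(m.group("size"))
    pool_size = int(m.group("pool"))
    if pool_size > len(order) or size > pool_size:
        raise ValueError(
            f"scheme {scheme}: pool {pool_size} / size {size} exceeds "
            f"{len(order)} available features"
        )
    pool = order[:pool_size] if m.group("end") == "top" else order[-pool_size:]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return list(rng.choice(np.asarray(pool, dtype=object), size=size, replace=False))


def hybrid_biomass(table: SampleTable, xpp: ParentalPairMatrix) -> np.ndarray:
    """Per-row biomass vector aligned to the parental-pair matrix.

    Row i of hybrid h receives the biomass of h's replicate sample i
    (replicate order).
    """
    out = np.empty(len(xpp.row_hybrid))
    for hyb in xpp.hybrids:
        rows = xpp.rows_for([hyb])
        mask = table.meta["genotype"] == hyb
        bio = table.meta.loc[mask].sort_values("replicate")["biomass"].to_numpy()
        if len(bio) < len(rows):
            raise ValueError(f"hybrid {hyb}: fewer biomass samples than X_pp rows")
        out[rows] = bio[: len(rows)]
    return out


def block_permute_biomass(
    biomass: np.ndarray, row_hybrid: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Permute biomass across hybrid blocks, replicates moving together."""
    hybrids = list(dict.fromkeys(row_hybrid))
    if len(hybrids) < 2:
        raise ValueError("block permutation needs at least 2 hybrids")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    perm = rng.permutation(len(hybrids))
    out = np.empty_like(np.asarray(biomass, dtype=float))
    for i, hyb in enumerate(hybrids):
        src = np.nonzero(row_hybrid == hybrids[perm[i]])[0]
        dst = np.nonzero(row_hybrid == hyb)[0]
        n = min(len(src), len(dst))
        out[dst[:n]] = np.asarray(biomass, dtype=float)[src[:n]]
        if len(dst) > n:  # unequal block sizes: recycle
            out[dst[n:]] = np.asarray(biomass, dtype=float)[src[np.arange(len(dst) - n) % n]]
    return out


def cell_permute(xpp: ParentalPairMatrix, seed: int = 0) -> ParentalPairMatrix:
    """Shuffle every column independently across rows (destroys row coherence)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    vals = xpp.values.to_numpy(dtype=float).copy()
    for j in range(vals.shape[1]):
        vals[:, j] = vals[rng.permutation(vals.shape[0]), j]
    values = pd.DataFrame(vals, index=xpp.values.index, columns=xpp.values.columns)
    return ParentalPairMatrix(values=values, row_hybrid=xpp.row_hybrid.copy(), pairing_seed=xpp.pairing_seed)


def svr_evaluate(
    xpp: ParentalPairMatrix,
    biomass: np.ndarray,
    subset: list[str],
    train_frac: float = 0.6,
    reps: int = 500,
    seed: int = 0,
    scheme: str = "",
    C: float = 1.0,
    epsilon: float = 0.1,
    shuffle_replicates: bool = True,
    permute: str | None = None,
    subset_pool: list[str] | None = None,
    subset_size: int | None = None,
) -> BiomassEvaluation:
    """Repeated 60/40 SVR evaluation of one feature subset.

    Per repetition the hybrids are split train/test (all replicate rows of a
    hybrid on one side), biomass replicates are re-assigned within each
    hybrid block when ``shuffle_replicates`` (each construction re-randomizes
    the replicate pairing), an RBF SVR is fit on the training rows restricted
    to the subset columns (targets standardized on the training set), and
    the Pearson r between predictions and observed test biomass is recorded.
    Constant predictions or constant test targets give r = 0 with a
    degenerate-fit flag.

    ``permute`` turns the evaluation into a null: ``'block'`` block-permutes
    the biomass across hybrids (replicates moving together) and ``'cell'``
    shuffles every feature column independently -- redrawn in every
    repetition, so no single accidental permutation dominates the
    distribution.  When ``subset_pool`` is given, a fresh random
    ``subset_size``-subset of the pool is drawn per repetition (the
    random-K-of-top-N schemes), and ``subset`` is ignored.
    """
    if not subset:
        raise ValueError("empty feature subset")
    if permute not in (None, "block", "cell"):
        raise ValueError(f"permute must be None, 'block' or 'cell', got {permute!r}")
    biomass = np.asarray(biomass, dtype=float)
    feature_pos = {f: i for i, f in enumerate(xpp.feature_ids)}
    cols = [feature_pos[f] for f in subset]
    X_full = xpp.values.to_numpy(dtype=float)
    X_base = X_full[:, cols]
    hybrids = np.asarray(xpp.hybrids, dtype=object)
    n_train = max(int(round(train_frac * len(hybrids))), 1)
    n_train = min(n_train, len(hybrids) - 1)
    ss = np.random.SeedSequence(seed)
    r_values = np.empty(reps)
    degenerate = 0
    for rep, child in enumerate(ss.spawn(reps)):
        rng = np.random.default_rng(child)
        bio = biomass.copy()
        if subset_pool is not None:
            size = subset_size if subset_size is not None else len(subset)
            drawn = rng.choice(np.asarray(subset_pool, dtype=object), size=size, replace=False)
            X_all = X_full[:, [feature_pos[f] for f in drawn]]
        else:
            X_all = X_base
        if permute == "block":
            perm_seed = int(child.generate_state(2)[1] % (2**31 - 1))
            bio = block_permute_biomass(bio, xpp.row_hybrid, seed=perm_seed)
        elif permute == "cell":
            X_all = X_all.copy()
            for j in range(X_all.shape[1]):
                X_all[:, j] = X_all[rng.permutation(X_all.shape[0]), j]
        if shuffle_replicates:
            for hyb in hybrids:
                rows = np.nonzero(xpp.row_hybrid == hyb)[0]
                bio[rows] = bio[rows[rng.permutation(len(rows))]]
        train_h = rng.choice(hybrids, size=n_train, replace=False)
        train_mask = np.isin(xpp.row_hybrid, train_h)
        X_tr, X_te = X_all[train_mask], X_all[~train_mask]
        y_tr, y_te = bio[train_mask], bio[~train_mask]
        mu, sd = y_tr.mean(), y_tr.std()
        sd = sd if sd > 0 else 1.0
        model = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma="scale")
        model.fit(X_tr, (y_tr - mu) / sd)
        pred = model.predict(X_te)
        if np.ptp(pred) < 1e-12 or np.ptp(y_te) < 1e-12:
            r_values[rep] = 0.0
            degenerate += 1
        else:
            r_values[rep] = float(stats.pearsonr(pred, y_te).statistic)
    return BiomassEvaluation(scheme=scheme, r_values=r_values, degenerate=degenerate)


def run_validation(
    xpp: ParentalPairMatrix,
    biomass: np.ndarray,
    ranking: FeatureRanking,
    schemes: tuple[str, ...] = DEFAULT_SCHEMES,
    reps: int = 500,
    seed: int = 0,
    include_nulls: bool = True,
    **svr_kwargs,
) -> pd.DataFrame:
    """Evaluate all schemes (plus permutation nulls); tidy (scheme, rep, r) table.

    The nulls added when ``include_nulls`` is set are ``top5_blockperm`` and
    ``all_blockperm`` (block-permuted biomass, permutation redrawn per
    repetition) and ``top5_cellperm`` and ``all_cellperm`` (cell-permuted
    parental matrix, likewise redrawn).
    """
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(2 * len(schemes) + 16))

    def _seed() -> int:
        return int(next(children).generate_state(1)[0] % (2**31 - 1))

    def _job(scheme: str, permute: str | None) -> dict:
        m = _SCHEME_RE.match(scheme.replace("_blockperm", "").replace("_cellperm", ""))
        base = scheme.replace("_blockperm", "").replace("_cellperm", "")
        if m is None:
            raise ValueError(f"unrecognized scheme {scheme!r}")
        kwargs: dict = {"permute": permute}
        if m.group("size") is not None:  # randS_of_(top|bottom)K: redraw per rep
            pool_size = int(m.group("pool"))
            order = ranking.order
            pool = order[:pool_size] if m.group("end") == "top" else order[-pool_size:]
            kwargs["subset"] = pool[: int(m.group("size"))]  # placeholder, ignored
            kwargs["subset_pool"] = pool
            kwargs["subset_size"] = int(m.group("size"))
        else:
            kwargs["subset"] = select_subset(ranking, base, seed=_seed())
        return kwargs

    jobs: list[tuple[str, dict]] = [(s, _job(s, None)) for s in schemes]
    if include_nulls:
        jobs.append(("top5_blockperm", _job("top5", "block")))
        jobs.append(("all_blockperm", _job("all", "block")))
        jobs.append(("top5_cellperm", _job("top5", "cell")))
        jobs.append(("all_cellperm", _job("all", "cell")))
    frames = []
    for scheme, kwargs in jobs:
        ev = svr_evaluate(
            xpp, biomass, reps=reps, seed=_seed(), scheme=scheme, **kwargs, **svr_kwargs
        )
        frames.append(pd.DataFrame({"scheme": scheme, "rep": np.arange(reps), "r": ev.r_values}))
    return pd.concat(frames, ignore_index=True)
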