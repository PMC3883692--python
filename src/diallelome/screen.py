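"""Predictability screening of hybrid metabolite labels from parental profiles.

The parental-pair matrix X_pp represents every hybrid replicate as the
concatenation of one maternal and one paternal replicate profile (columns
autoscaled), so a hybrid metabolite's CRL label column can be treated as a
classification target over parental features.  Per metabolite, five
classifier families (linear SVM, shrinkage LDA, PLS-LDA, PLS-RF, RF) are run
in repeated stratified 3-fold cross-validation against a permuted-label
null (labels permuted across hybrid genotypes, replicate rows moving
together), and a metabolite is declared predictable when the two overall
best methods separate the original-label error distribution from the
permuted one (third quartile of original medians below first quartile of
permuted medians), or -- under the alternative rule -- when the minimum
original median error beats the minimum permuted median error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .crl import CRLMatrix
from .design import DiallelDesign
from .normalize import autoscale_columns
from .simulate import MATERNAL, PATERNAL, SampleTable, feature_id

METHODS = ("svm", "lda", "pls_lda", "pls_rf", "rf")


@dataclass
class ParentalPairMatrix:
    """Hybrid replicates x concatenated parental features (autoscaled).

    Each hybrid contributes ``r`` rows; row i of hybrid (mother, father)
    pairs the mother's replicate i with a seeded random permutation of the
    father's replicates.  Columns are ``<metabolite>_m`` then
    ``<metabolite>_p``.
    """

    values: pd.DataFrame
    row_hybrid: np.ndarray
    pairing_seed: int

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def hybrids(self) -> list[str]:
        seen: dict[str, None] = {}
        for h in self.row_hybrid:
            seen.setdefault(h, None)
        return list(seen)

    def rows_for(self, hybrids: list[str]) -> np.ndarray:
        mask = np.isin(self.row_hybrid, hybrids)
        return np.nonzero(mask)[0]


def build_xpp(
    parents: SampleTable,
    design: DiallelDesign,
    seed: int = 0,
) -> ParentalPairMatrix:
    """Build the parental-pair matrix X_pp from normalized parent profiles.

    Maternal and paternal replicate rows are paired one-to-one by a seeded
    random matching per hybrid; columns are autoscaled afterwards.  Unequal
    replicate counts are paired up to the smaller count (logged).  Masked
    cells are imputed with the genotype's replicate mean for that
    metabolite (classifiers need complete rows); a fully masked group falls
    back to the column mean.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mets = parents.metabolite_ids
    cols = [feature_id(m, MATERNAL) for m in mets] + [feature_id(m, PATERNAL) for m in mets]

    def _complete(genotype: str) -> np.ndarray:
        vals = parents.genotype_values(genotype)
        if vals.isna().any().any():
            fill = vals.mean(axis=0)
            fill = fill.fillna(parents.values.mean(axis=0))
            vals = vals.fillna(fill)
        return vals.to_numpy(dtype=float)

    blocks, row_hybrid, row_ids = [], [], []
    for (mo, fa), hyb in zip(design.hybrids, design.hybrid_ids):
        vm = _complete(mo)
        vf = _complete(fa)
        r = min(len(vm), len(vf))
        if len(vm) != len(vf):
            warnings.warn(
                f"hybrid {hyb}: unequal parental replicate counts "
                f"({len(vm)} vs {len(vf)}); pairing first {r}",
                stacklevel=2,
            )
        perm = rng.permutation(r)
        blocks.append(np.hstack([vm[:r], vf[perm]]))
        row_hybrid.extend([hyb] * r)
        row_ids.extend(f"{hyb}#{i}" for i in range(r))
    values = pd.DataFrame(np.vstack(blocks), index=row_ids, columns=cols)
    scaled, _ = autoscale_columns(values)
    return ParentalPairMatrix(values=scaled, row_hybrid=np.asarray(row_hybrid), pairing_seed=int(seed))


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------


class _PLSReduced:
    """PLS dimension reduction to <=n_components scores, then a base classifier."""

    def __init__(self, base, n_components: int = 10):
        self.base = base
        self.n_components = n_components

    def fit(self, X: np.ndarray, y: np.ndarray):
        classes = np.unique(y)
        Y = (y[:, None] == classes[None, :]).astype(float)
        n_comp = int(min(self.n_components, X.shape[1], X.shape[0] - 1))
        n_comp = max(n_comp, 1)
        self.pls_ = PLSRegression(n_components=n_comp, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.pls_.fit(X, Y)
            self.base.fit(self.pls_.transform(X), y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.base.predict(self.pls_.transform(X))


def make_classifier(
    name: str,
    random_state: int = 0,
    rf_trees: int = 500,
    pls_components: int = 10,
):
    """Instantiate one of the five screening classifier families."""
    if name == "svm":
        return SVC(kernel="linear", C=1.0)
    if name == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if name == "rf":
        return RandomForestClassifier(n_estimators=rf_trees, random_state=random_state)
    if name == "pls_lda":
        return _PLSReduced(
            LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"), pls_components
        )
    if name == "pls_rf":
        return _PLSReduced(
            RandomForestClassifier(n_estimators=rf_trees, random_state=random_state),
            pls_components,
        )
    raise ValueError(f"unknown classifier {name!r}; choose from {METHODS}")


# ---------------------------------------------------------------------------
# Cross-validation screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    """Per-metabolite CV screen outcome (original vs permuted labels)."""

    metabolite: str
    orig_medians: dict[str, np.ndarray]  # method -> reps median fold errors
    perm_medians: dict[str, np.ndarray]
    flags: list[str] = field(default_factory=list)

    @property
    def methods(self) -> list[str]:
        return list(self.orig_medians)


def _stratified_hybrid_folds(
    labels: pd.Series, k: int, rng: np.random.Generator, max_attempts: int = 20
) -> list[list[str]]:
    """Split hybrids into k folds, each class spread round-robin over folds.

    Replicate rows of one hybrid never straddle folds (the split is at the
    genotype level).  Redraws (up to ``max_attempts``) if some training set
    would see fewer than two classes.
    """
    classes = labels.unique()
    for _ in range(max_attempts):
        folds: list[list[str]] = [[] for _ in range(k)]
        start = int(rng.integers(k))
        pos = start
        for c in rng.permutation(classes):
            members = labels.index[labels == c].to_numpy()
            for hyb in rng.permutation(members):
                folds[pos % k].append(hyb)
                pos += 1
        ok = True
        for i in range(k):
            train = [h for j in range(k) if j != i for h in folds[j]]
            if len(folds[i]) == 0 or labels.loc[train].nunique() < 2:
                ok = False
                break
        if ok:
            return folds
    raise RuntimeError("could not build stratified folds with >=2 classes per training set")


def cv_screen(
    xpp: ParentalPairMatrix,
    labels: pd.Series,
    methods: tuple[str, ...] = METHODS,
    k: int = 3,
    reps: int = 25,
    seed: int = 0,
    rf_trees: int = 500,
    pls_components: int = 10,
    metabolite: str = "",
) -> ScreenResult:
    """Repeated stratified k-fold CV of all methods, original vs permuted labels.

    ``labels`` maps hybrid ids to integer classes (hybrids already dropped
    by the balance rescue are simply absent).  Per repetition one permuted
    label vector is drawn by permuting labels across hybrids (replicate rows
    keep a common label) and independent folds are used for the original and
    the permuted run.  The per-repetition statistic is the median over the k
    fold misclassification rates.
    """
    labels = labels.dropna().astype(int)
    if labels.nunique() < 2:
        raise ValueError("need at least 2 label classes to screen")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(reps)
    rows = xpp.rows_for(list(labels.index))
    X = xpp.values.to_numpy(dtype=float)[rows]
    row_hyb = xpp.row_hybrid[rows]
    orig = {f: np.empty(reps) for f in methods}
    perm = {f: np.empty(reps) for f in methods}
    flags: list[str] = []

    def _run(y_by_hybrid: pd.Series, rng: np.random.Generator, rep_seed: int, store, rep: int):
        folds = _stratified_hybrid_folds(y_by_hybrid, k, rng)
        y_rows = y_by_hybrid.loc[row_hyb].to_numpy()
        fold_errors = {f: [] for f in methods}
        for i in range(k):
            test_h = folds[i]
            test_mask = np.isin(row_hyb, test_h)
            X_tr, X_te = X[~test_mask], X[test_mask]
            y_tr, y_te = y_rows[~test_mask], y_rows[test_mask]
            for f in methods:
                clf = make_classifier(f, random_state=rep_seed + i, rf_trees=rf_trees,
                                      pls_components=pls_components)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(X_tr, y_tr)
                    err = float(np.mean(clf.predict(X_te) != y_te))
                fold_errors[f].append(err)
        for f in methods:
            store[f][rep] = float(np.median(fold_errors[f]))

    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        try:
            _run(labels, rng, rep_seed, orig, rep)
        except RuntimeError:
            flags.append(f"rep {rep}: untestable (fold construction failed)")
            for f in methods:
                orig[f][rep] = np.nan
        permuted = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        try:
            _run(permuted, rng, rep_seed + 10007, perm, rep)
        except RuntimeError:
            flags.append(f"rep {rep}: permuted untestable")
            for f in methods:
                perm[f][rep] = np.nan

    return ScreenResult(metabolite=metabolite, orig_medians=orig, perm_medians=perm, flags=flags)


def decide_predictable(
    result: ScreenResult, rule: str = "quartile"
) -> tuple[bool, dict]:
    """Decide whether a metabolite's labels are predictable from X_pp.

    Primary rule (``'quartile'``): pick the two methods with the overall
    lowest median errors under both the original and the permuted runs
    (Borda aggregation of the two rankings, ties broken by mean error then
    fixed method order); predictable iff, for both, the third quartile of
    the 25 original medians lies below the first quartile of the permuted
    medians (delta = Q1(perm) - Q3(orig) > 0).  Alternative rule
    (``'min_median'``): the minimum original median error over all methods
    is lower than the minimum permuted median error.  Both verdicts are
    reported in the diagnostics.
    """
    if rule not in ("quartile", "min_median"):
        raise ValueError(f"unknown rule {rule!r}")
    methods = result.methods
    usable = [
        f
        for f in methods
        if np.isfinite(result.orig_medians[f]).sum() >= 2
        and np.isfinite(result.perm_medians[f]).sum() >= 2
    ]
    diagnostics: dict = {"rule": rule, "flags": list(result.flags)}
    if len(usable) < 2:
        diagnostics["reason"] = "fewer than two usable methods"
        diagnostics["predictable_quartile"] = False
        diagnostics["predictable_min_median"] = False
        return False, diagnostics

    med_o = {f: float(np.nanmedian(result.orig_medians[f])) for f in usable}
    med_p = {f: float(np.nanmedian(result.perm_medians[f])) for f in usable}
    mean_o = {f: float(np.nanmean(result.orig_medians[f])) for f in usable}

    def _rank(values: dict[str, float]) -> dict[str, int]:
        ordered = sorted(values, key=lambda f: (values[f], METHODS.index(f)))
        return {f: i for i, f in enumerate(ordered)}

    r_o, r_p = _rank(med_o), _rank(med_p)
    chosen = sorted(
        usable, key=lambda f: (r_o[f] + r_p[f], mean_o[f], METHODS.index(f))
    )[:2]

    deltas = {}
    for f in chosen:
        q3_o = float(np.nanpercentile(result.orig_medians[f], 75))
        q1_p = float(np.nanpercentile(result.perm_medians[f], 25))
        deltas[f] = q1_p - q3_o
    quartile_verdict = all(d > 0 for d in deltas.values())
    min_median_verdict = min(med_o.values()) < min(med_p.values())

    diagnostics.update(
        chosen_methods=chosen,
        delta=deltas,
        median_orig=med_o,
        median_perm=med_p,
        predictable_quartile=quartile_verdict,
        predictable_min_median=min_median_verdict,
    )
    verdict = quartile_verdict if rule == "quartile" else min_median_verdict
    return verdict, diagnostics


def screen_metabolites(
    xpp: ParentalPairMatrix,
    crl: CRLMatrix,
    methods: tuple[str, ...] = METHODS,
    k: int = 3,
    reps: int = 25,
    seed: int = 0,
    rule: str = "quartile",
    rf_trees: int = 500,
    pls_components: int = 10,
) -> tuple[pd.DataFrame, dict[str, ScreenResult]]:
    """Screen every balanced metabolite; return a summary table and raw results.

    The summary has one row per screened metabolite: predictable verdicts
    under both decision rules, the chosen methods and their error medians.
    Metabolites with weight 0 or fewer than two classes are skipped.
    """
    ss = np.random.SeedSequence(seed)
    mets = [m for m in crl.metabolites if crl.weights[m] == 1]
    children = ss.spawn(len(mets))
    rows = []
    results: dict[str, ScreenResult] = {}
    for met, child in zip(mets, children):
        labels = crl.usable_labels(met)
        if labels.nunique() < 2:
            rows.append(
                {"metabolite": met, "screened": False, "predictable": False,
                 "predictable_quartile": False, "predictable_min_median": False,
                 "reason": "fewer than 2 classes"}
            )
            continue
        res = cv_screen(
            xpp, labels, methods=methods, k=k, reps=reps,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
            rf_trees=rf_trees, pls_components=pls_components, metabolite=met,
        )
        verdict, diag = decide_predictable(res, rule=rule)
        results[met] = res
        rows.append(
            {
                "metabolite": met,
                "screened": True,
                "predictable": verdict,
                "predictable_quartile": diag["predictable_quartile"],
                "predictable_min_median": diag["predictable_min_median"],
                "chosen_methods": ",".join(diag.get("chosen_methods", [])),
                "reason": diag.get("reason", ""),
            }
        )
    columns = [
        "metabolite", "screened", "predictable", "predictable_quartile",
        "predictable_min_median", "chosen_methods", "reason",
    ]
    summary = pd.DataFrame(rows, columns=columns).set_index("metabolite")
    return summary, results
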