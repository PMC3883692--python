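"""Self-contained validation studies on synthetic diallel data.

Each function simulates data with known ground truth, runs the relevant
pipeline stages and measures how well the planted structure is recovered:
label-recovery and null calibration of the CRL encoding, chance-rate
calibration of the permutation screen, driver recovery by the aggregated
feature ranking, the biomass-prediction correlation chain across feature
subsets, and leave-one-hybrid-out ranking stability.  They are used by the
test suite and by the reproduction script; problem sizes default to desk
scale (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import biomass as biomass_mod
from . import crl as crl_mod
from . import ranking as ranking_mod
from . import screen as screen_mod
from .design import DiallelDesign, make_design
from .normalize import normalize_pipeline
from .simulate import SampleTable, simulate_dataset, simulate_null_dataset

DEFAULT_PARENTS = ["P1", "P2", "P3", "P4"]

#: scaled-down screen settings used inside multi-seed studies (the full
#: five-method, 25-repetition screen is exercised separately)
FAST_SCREEN = dict(methods=("svm", "lda"), reps=10, rule="min_median")


def _default_design() -> DiallelDesign:
    return make_design(DEFAULT_PARENTS, n_replicates=6, n_batches=3)


# ---------------------------------------------------------------------------
# CRL recovery and null calibration
# ---------------------------------------------------------------------------


def crl_recovery_study(
    seed: int = 0,
    m: int = 60,
    n_drivers: int = 6,
    n_driven: int = 16,
    effect_size: float = 5.0,
    noise_sd: float = 0.0,
    dominance_fraction: float = 0.5,
) -> dict:
    """Fraction of driven (and of all) cells whose CRL label equals the truth.

    Defaults plant both dominance and overdominance patterns on a zero-noise
    fixture, where recovery should be exact.
    """
    design = _default_design()
    table, truth = simulate_dataset(
        design,
        m=m,
        n_drivers=n_drivers,
        n_driven=n_driven,
        effect_size=effect_size,
        noise_sd=noise_sd,
        batch_sd=0.0 if noise_sd == 0 else 0.1,
        seed=seed,
        dominance_fraction=dominance_fraction,
    )
    normalized, _ = normalize_pipeline(table)
    labels = crl_mod.assign_labels(normalized, None, design)
    driven = truth.driven_metabolites
    got = labels.labels.loc[:, driven].to_numpy()
    want = truth.true_labels.loc[:, driven].to_numpy()
    all_got = labels.labels.to_numpy()
    all_want = truth.true_labels.to_numpy()
    return {
        "driven_recovery": float(np.mean(got == want)),
        "all_recovery": float(np.mean(all_got == all_want)),
        "n_driven_cells": int(got.size),
    }


def crl_null_study(n_seeds: int = 20, m: int = 50, alpha: float = 0.05, seed: int = 0) -> dict:
    """Fraction of nonzero labels under the global null, averaged over seeds."""
    design = _default_design()
    fractions = []
    for child in np.random.SeedSequence(seed).spawn(n_seeds):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        table, _ = simulate_null_dataset(design, m=m, noise_sd=0.1, seed=s)
        normalized, _ = normalize_pipeline(table)
        labels = crl_mod.assign_labels(normalized, None, design, alpha=alpha)
        fractions.append(float((labels.labels.to_numpy() != 0).mean()))
    return {
        "mean_nonzero_fraction": float(np.mean(fractions)),
        "max_nonzero_fraction": float(np.max(fractions)),
        "alpha": alpha,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Screen calibration
# ---------------------------------------------------------------------------


def _arbitrary_labels(design: DiallelDesign, classes: tuple[int, ...], rng) -> pd.Series:
    """Balanced label vector over hybrids, assignment shuffled by rng."""
    hybrids = list(design.hybrid_ids)
    reps = -(-len(hybrids) // len(classes))
    lab = np.tile(np.asarray(classes, dtype=int), reps)[: len(hybrids)]
    rng.shuffle(lab)
    return pd.Series(lab, index=hybrids)


def screen_calibration_study(
    n_seeds: int = 50,
    m: int = 12,
    reps: int = 10,
    methods: tuple[str, ...] = screen_mod.METHODS,
    rf_trees: int = 25,
    seed: int = 0,
) -> dict:
    """Permuted-label error vs the analytic chance rate on label-free data.

    Features come from global-null fixtures and the (balanced three-class)
    labels are assigned independently of them, so both the original and the
    permuted runs are at chance: 1 - modal class frequency.  Also reports
    how often the quartile rule declares such a null metabolite predictable
    (it should almost never).
    """
    design = _default_design()
    classes = (-1, 0, 1)
    per_method: dict[str, list[float]] = {f: [] for f in methods}
    false_calls = 0
    chance = None
    for child in np.random.SeedSequence(seed).spawn(n_seeds):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(child)
        table, _ = simulate_null_dataset(design, m=m, noise_sd=0.1, seed=s)
        normalized, _ = normalize_pipeline(table)
        xpp = screen_mod.build_xpp(normalized, design, seed=s)
        labels = _arbitrary_labels(design, classes, rng)
        counts = labels.value_counts()
        chance = 1.0 - counts.max() / counts.sum()
        res = screen_mod.cv_screen(
            xpp, labels, methods=methods, reps=reps, seed=s, rf_trees=rf_trees
        )
        for f in methods:
            per_method[f].append(float(np.nanmean(res.perm_medians[f])))
        verdict, _ = screen_mod.decide_predictable(res, rule="quartile")
        false_calls += int(verdict)
    mean_perm = {f: float(np.mean(v)) for f, v in per_method.items()}
    return {
        "chance_rate": float(chance),
        "mean_permuted_error": mean_perm,
        "max_abs_deviation": float(max(abs(v - chance) for v in mean_perm.values())),
        "null_predictable_rate": false_calls / n_seeds,
        "n_seeds": n_seeds,
    }


#: Label-column shapes a balanced-filter-passing CRL metabolite typically
#: shows over 12 hybrids (modal count <= 8, two or three classes).
NULL_LABEL_SHAPES: tuple[tuple[int, ...], ...] = (
    (-1,) * 4 + (0,) * 4 + (1,) * 4,
    (0,) * 6 + (2,) * 6,
    (0,) * 6 + (1,) * 3 + (-1,) * 3,
    (0,) * 8 + (1,) * 4,
)


def null_decision_study(
    n_seeds: int = 24,
    m: int = 12,
    reps: int = 10,
    methods: tuple[str, ...] = screen_mod.METHODS,
    rf_trees: int = 25,
    seed: int = 0,
) -> dict:
    """How often the quartile rule calls a null metabolite predictable.

    Global-null features with label columns drawn from a representative set
    of post-filter shapes (balanced and unbalanced, two and three classes),
    rotated across seeds.  A fixed label assignment can correlate with the
    features by chance, so the false-positive rate is not zero; it should
    stay below ~10%.
    """
    design = _default_design()
    false_calls = 0
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_seeds)):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(child)
        table, _ = simulate_null_dataset(design, m=m, noise_sd=0.1, seed=s)
        normalized, _ = normalize_pipeline(table)
        xpp = screen_mod.build_xpp(normalized, design, seed=s)
        lab = np.asarray(NULL_LABEL_SHAPES[i % len(NULL_LABEL_SHAPES)], dtype=int).copy()
        rng.shuffle(lab)
        labels = pd.Series(lab, index=list(design.hybrid_ids))
        res = screen_mod.cv_screen(
            xpp, labels, methods=methods, reps=reps, seed=s, rf_trees=rf_trees
        )
        verdict, _ = screen_mod.decide_predictable(res, rule="quartile")
        false_calls += int(verdict)
    return {"null_predictable_rate": false_calls / n_seeds, "n_seeds": n_seeds}


def null_pipeline_study(
    n_seeds: int = 50,
    m: int = 20,
    reps: int = 10,
    methods: tuple[str, ...] = screen_mod.METHODS,
    rf_trees: int = 25,
    seed: int = 0,
) -> dict:
    """Predictable-metabolite count when the full chain runs on null data.

    Global-null datasets: the CRL stage yields (almost) all-additive label
    columns, the balance filter removes them, and the rare surviving
    metabolite should still fail the quartile rule -- so the predictable
    set is empty in the vast majority of seeds.
    """
    design = _default_design()
    seeds_with_calls = 0
    screened_total = 0
    for child in np.random.SeedSequence(seed).spawn(n_seeds):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        table, _ = simulate_null_dataset(design, m=m, noise_sd=0.1, seed=s)
        normalized, _ = normalize_pipeline(table)
        labels = crl_mod.balance_filter(crl_mod.assign_labels(normalized, None, design))
        xpp = screen_mod.build_xpp(normalized, design, seed=s)
        summary, _ = screen_mod.screen_metabolites(
            xpp, labels, methods=methods, reps=reps, seed=s,
            rule="quartile", rf_trees=rf_trees,
        )
        screened_total += int(summary["screened"].sum()) if len(summary) else 0
        if len(summary) and summary["predictable"].any():
            seeds_with_calls += 1
    return {
        "seeds_with_predictable_calls": seeds_with_calls,
        "null_predictable_seed_rate": seeds_with_calls / n_seeds,
        "metabolites_screened_total": screened_total,
        "n_seeds": n_seeds,
    }


def separable_screen_study(
    n_seeds: int = 10,
    n_hybrids: int = 12,
    r: int = 6,
    n_features: int = 16,
    margin: float = 6.0,
    reps: int = 10,
    methods: tuple[str, ...] = screen_mod.METHODS,
    rf_trees: int = 25,
    seed: int = 0,
) -> dict:
    """Quartile-rule behaviour on perfectly separable label problems.

    One feature determines the (three-class) labels with a wide margin; the
    rest is noise.  The quartile rule should declare predictability, and the
    permuted-label error should sit near chance.
    """
    calls = 0
    perm_err = []
    for child in np.random.SeedSequence(seed).spawn(n_seeds):
        rng = np.random.default_rng(child)
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        hybrids = [f"H{i}" for i in range(n_hybrids)]
        labels = pd.Series(np.tile([-1, 0, 1], -(-n_hybrids // 3))[:n_hybrids], index=hybrids)
        vals = rng.normal(size=(n_hybrids * r, n_features))
        row_hybrid = np.repeat(hybrids, r)
        vals[:, 0] = labels.loc[row_hybrid].to_numpy() * margin + rng.normal(
            0, 0.2, size=n_hybrids * r
        )
        values = pd.DataFrame(
            vals, columns=[f"f{j}_m" for j in range(n_features // 2)] + [f"f{j}_p" for j in range(n_features - n_features // 2)]
        )
        values = (values - values.mean()) / values.std(ddof=1)
        xpp = screen_mod.ParentalPairMatrix(values=values, row_hybrid=row_hybrid, pairing_seed=s)
        res = screen_mod.cv_screen(xpp, labels, methods=methods, reps=reps, seed=s, rf_trees=rf_trees)
        verdict, diag = screen_mod.decide_predictable(res, rule="quartile")
        calls += int(verdict)
        perm_err.append(float(np.mean([np.nanmean(res.perm_medians[f]) for f in methods])))
    return {
        "separable_predictable_rate": calls / n_seeds,
        "mean_permuted_error": float(np.mean(perm_err)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Driver recovery and biomass chain
# ---------------------------------------------------------------------------


def _ranked_fixture(seed: int, m: int, n_drivers: int, n_driven: int,
                    effect_size: float, noise_sd: float):
    design = _default_design()
    table, truth = simulate_dataset(
        design, m=m, n_drivers=n_drivers, n_driven=n_driven,
        effect_size=effect_size, noise_sd=noise_sd, batch_sd=0.1, seed=seed,
    )
    normalized, _ = normalize_pipeline(table)
    labels = crl_mod.balance_filter(crl_mod.assign_labels(normalized, None, design))
    xpp = screen_mod.build_xpp(normalized, design, seed=seed)
    summary, _ = screen_mod.screen_metabolites(xpp, labels, seed=seed, **FAST_SCREEN)
    predictable = list(summary.index[summary["predictable"]])
    ranking = ranking_mod.rank_features(xpp, labels, predictable) if predictable else None
    return design, normalized, truth, xpp, ranking


def driver_recovery_study(
    n_seeds: int = 20,
    m: int = 24,
    n_drivers: int = 6,
    n_driven: int = 12,
    effect_size: float = 5.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> dict:
    """How often all planted drivers aggregate into the top 2 * n_drivers."""
    top_k = 2 * n_drivers
    hits = []
    for child in np.random.SeedSequence(seed).spawn(n_seeds):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        _, _, truth, _, ranking = _ranked_fixture(s, m, n_drivers, n_driven, effect_size, noise_sd)
        if ranking is None:
            hits.append(0)
            continue
        hits.append(len(set(truth.driver_features) & set(ranking.top(top_k))))
    hits = np.asarray(hits)
    return {
        "all_recovered_rate": float(np.mean(hits == n_drivers)),
        "mean_recovered": float(np.mean(hits)),
        "n_drivers": n_drivers,
        "top_k": top_k,
        "n_seeds": n_seeds,
    }


def biomass_chain_study(
    n_seeds: int = 5,
    reps: int = 100,
    m: int = 24,
    n_drivers: int = 6,
    n_driven: int = 12,
    effect_size: float = 5.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> dict:
    """Median SVR Pearson r per feature-subset scheme, pooled over fixtures.

    The expected ordering is top5 ~ all > random-5-of-top pools > bottom
    pools ~ permutation nulls.
    """
    schemes = ("top5", "rand5_of_top10", "rand5_of_top20", "rand5_of_bottom20", "all")
    frames = []
    for child in np.random.SeedSequence(seed).spawn(n_seeds):
        s = int(child.generate_state(1)[0] % (2**31 - 1))
        design, normalized, truth, xpp, ranking = _ranked_fixture(
            s, m, n_drivers, n_driven, effect_size, noise_sd
        )
        if ranking is None:
            continue
        bio = biomass_mod.hybrid_biomass(normalized, xpp)
        frames.append(
            biomass_mod.run_validation(xpp, bio, ranking, schemes=schemes, reps=reps, seed=s)
        )
    pooled = pd.concat(frames, ignore_index=True)
    medians = pooled.groupby("scheme")["r"].median()
    return {"median_r": {k: float(v) for k, v in medians.items()}, "n_seeds": n_seeds, "reps": reps}


def loo_stability_study(
    seed: int = 0,
    m: int = 40,
    n_drivers: int = 6,
    n_driven: int = 28,
    effect_size: float = 5.0,
    noise_sd: float = 0.02,
) -> dict:
    """Leave-one-hybrid-out ranking stability on a strong-effect fixture."""
    design = _default_design()
    table, _ = simulate_dataset(
        design, m=m, n_drivers=n_drivers, n_driven=n_driven,
        effect_size=effect_size, noise_sd=noise_sd, batch_sd=0.1, seed=seed,
    )
    normalized, _ = normalize_pipeline(table)
    stability = ranking_mod.loo_stability(normalized, design, seed=seed, **FAST_SCREEN)
    return {
        "min_spearman": float(stability["spearman"].min()),
        "mean_spearman": float(stability["spearman"].mean()),
        "min_top_overlap": float(stability["top_overlap"].min()),
        "n_hybrids": len(stability),
    }
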