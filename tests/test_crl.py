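"""CRL encoding: moderated t-statistics, label assignment, balance filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import diallelome as dm
from diallelome.crl import trigamma_inverse
from diallelome.simulate import SampleTable

from _oracles import reference_moderated_t, reference_pooled_t


class TestModeratedT:
    def test_identical_groups_give_t_zero_p_one(self, rng):
        a = rng.normal(size=(6, 10))
        res = dm.moderated_t(a, a.copy())
        assert np.allclose(res.t_mod, 0.0)
        assert np.allclose(res.p_two_sided, 1.0)

    def test_degenerate_prior_reduces_to_pooled_t(self, rng):
        a = rng.normal(0, 0.2, size=(6, 15))
        b = rng.normal(0.1, 0.2, size=(6, 15))
        res = dm.moderated_t(a, b, shared_variances=(0.0, float("nan")))
        assert np.allclose(res.t_mod, reference_pooled_t(a, b), atol=1e-12)
        assert res.d0 == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_step_by_step_reference(self, seed):
        rng = np.random.default_rng(seed)
        sds = rng.uniform(0.05, 0.4, size=50)
        a = rng.normal(5, 1, size=50) + rng.normal(0, 1, size=(6, 50)) * sds
        b = rng.normal(5, 1, size=50) + rng.normal(0, 1, size=(6, 50)) * sds
        res = dm.moderated_t(a, b)
        ref = reference_moderated_t(a, b)
        assert np.isclose(res.d0, ref["d0"], rtol=1e-6)
        assert np.isclose(res.s2_prior, ref["s0_sq"], rtol=1e-6)
        assert np.abs(res.t_mod - ref["t"]).max() < 1e-8
        assert np.abs(res.p_two_sided - ref["p"]).max() < 1e-8

    def test_matches_limma_reference_values(self):
        """Frozen cross-check against limma::eBayes on a fixed dataset.

        The expected numbers below were computed with limma 3.58 (lmFit +
        eBayes on the transposed matrix, two-group design) on exactly the
        data regenerated here.
        """
        rng = np.random.default_rng(12345)
        m, n = 20, 6
        true_sd = rng.uniform(0.05, 0.3, size=m)
        mu_a = rng.normal(5, 1, size=m)
        effect = rng.normal(0, 0.3, size=m)
        a = mu_a + rng.normal(0, 1, size=(n, m)) * true_sd
        b = (mu_a + effect) + rng.normal(0, 1, size=(n, m)) * true_sd
        res = dm.moderated_t(a, b)
        assert np.isclose(res.d0, 3.171514, atol=1e-5)
        assert np.isclose(res.s2_prior, 0.02104673, rtol=1e-5)
        t_limma = np.array([
            -1.8927219978, 0.6642744519, -2.9539214777, 0.0491291271,
            -0.3422108695, 3.5623146898, -0.4142391712, -6.3498120910,
            0.1363719744, -1.9103529977, -1.6914027517, -0.0487826530,
            -0.7592301245, -2.3149798303, -1.8948754923, 2.7912810009,
            0.7401694958, 8.0809831716, -1.1655943442, 6.0239987891,
        ])
        assert np.abs(res.t_mod - t_limma).max() < 1e-8

    def test_posterior_variance_between_sample_and_prior(self, rng):
        a = rng.normal(0, 0.3, size=(6, 40))
        b = rng.normal(0, 0.3, size=(6, 40))
        res = dm.moderated_t(a, b)
        lo = np.minimum(res.s2, res.s2_prior)
        hi = np.maximum(res.s2, res.s2_prior)
        assert ((res.s2_post >= lo - 1e-12) & (res.s2_post <= hi + 1e-12)).all()
        assert res.d0 >= 0
        assert ((res.p_two_sided >= 0) & (res.p_two_sided <= 1)).all()

    def test_small_groups_are_skipped(self, rng):
        a = rng.normal(size=(6, 4))
        b = rng.normal(size=(6, 4))
        a[1:, 2] = np.nan  # one unmasked replicate left
        with pytest.warns(UserWarning, match="skipped"):
            res = dm.moderated_t(a, b)
        assert np.isnan(res.t_mod[2])
        assert np.isfinite(res.t_mod[[0, 1, 3]]).all()


def test_trigamma_inverse_roundtrip():
    for y in [0.05, 0.5, 2.0, 17.0, 300.0]:
        x = float(special.polygamma(1, y))
        assert np.isclose(trigamma_inverse(x), y, rtol=1e-8)


def _geometry_table(design, hybrid_offsets, n_rep=6, sd=0.05, seed=0, m=30):
    """Table where one metabolite's genotype means are set explicitly."""
    rng = np.random.default_rng(seed)
    mets = [f"met{j}" for j in range(m)]
    rows, meta_rows, ids = [], [], []
    for g in design.genotypes:
        mean = np.full(m, 5.0) + rng.normal(0, 0.2, size=m)
        mean[0] = hybrid_offsets.get(g, 0.0)
        for rep in range(1, n_rep + 1):
            rows.append(mean + rng.normal(0, sd, size=m))
            ids.append(f"{g}_r{rep}")
            mo, fa = ("", "")
            if "x" in g:
                mo, fa = g.split("x")
            meta_rows.append(
                {"genotype": g, "mother": mo, "father": fa, "replicate": rep,
                 "batch": 1, "biomass": 100.0}
            )
    values = pd.DataFrame(np.vstack(rows), index=ids, columns=mets)
    return SampleTable(values, pd.DataFrame(meta_rows, index=ids))


class TestAssignLabels:
    def test_forced_geometry_labels(self, design4):
        """Hybrid far above both parents -> +2; between parents -> 0 etc."""
        offsets = {"P1": 0.0, "P2": 1.0, "P3": -1.0, "P4": 0.0}
        offsets["P1xP2"] = 3.0    # >> both parents -> +2
        offsets["P2xP1"] = -4.0   # << both parents -> -2
        offsets["P1xP3"] = -0.5   # between P1 (0) and P3 (-1): crossing -> 0
        offsets["P3xP1"] = 0.0    # at P1's level, above P3 -> +1
        offsets["P2xP3"] = -1.0   # at P3's level, below P2 -> -1
        table = _geometry_table(design4, offsets, sd=0.02)
        crl = dm.assign_labels(table, None, design4)
        col = crl.labels["met0"]
        assert col["P1xP2"] == 2
        assert col["P2xP1"] == -2
        assert col["P1xP3"] == 0
        assert col["P3xP1"] == 1
        assert col["P2xP3"] == -1

    def test_label_antisymmetry(self, design4):
        table, _ = dm.simulate_dataset(
            design4, m=16, n_drivers=4, effect_size=4, noise_sd=0.1, batch_sd=0.0, seed=13
        )
        crl = dm.assign_labels(table, None, design4)
        negated = table.copy()
        negated.values = -negated.values
        crl_neg = dm.assign_labels(negated, None, design4)
        assert np.allclose(crl.labels.to_numpy(), -crl_neg.labels.to_numpy(), equal_nan=True)

    def test_null_data_yields_few_nonzero_labels(self, design4):
        fractions = []
        for seed in range(4):
            table, _ = dm.simulate_null_dataset(design4, m=40, noise_sd=0.1, seed=seed)
            crl = dm.assign_labels(table, None, design4, alpha=0.05)
            fractions.append(float((crl.labels.to_numpy() != 0).mean()))
        assert np.mean(fractions) <= 2 * 0.05 + 0.02

    def test_zero_noise_planted_fixture_recovered_exactly(self, design4):
        table, truth = dm.simulate_dataset(
            design4, m=24, n_drivers=4, n_driven=8, effect_size=5,
            noise_sd=0.0, batch_sd=0.0, seed=21, dominance_fraction=0.5,
        )
        crl = dm.assign_labels(table, None, design4)
        assert (crl.labels.to_numpy() == truth.true_labels.to_numpy()).all()


def _crl_from_columns(columns: dict) -> dm.CRLMatrix:
    hybrids = [f"H{i}" for i in range(12)]
    labels = pd.DataFrame({k: list(v) for k, v in columns.items()}, index=hybrids, dtype=float)
    return dm.CRLMatrix(labels=labels)


def brute_force_rescue(col, max_same=8):
    """Oracle: weight and best single-hybrid drop by full enumeration."""
    counts = col.value_counts()
    if counts.iloc[0] <= max_same:
        return 1, None
    options = []
    for h in col.index:
        modal = col.drop(index=h).value_counts().iloc[0]
        if modal <= max_same:
            options.append((modal, list(col.index).index(h), h))
    if options:
        return 1, sorted(options)[0][2]
    return 0, None


class TestBalanceFilter:
    def test_nine_of_twelve_removed_eight_kept(self):
        crl = _crl_from_columns(
            {
                "unbal": [0] * 9 + [1] * 3,
                "edge": [0] * 8 + [1] * 4,
                "balanced": [0] * 6 + [1] * 6,
            }
        )
        out = dm.balance_filter(crl)
        # nine 0s curable by dropping one hybrid -> rescued, not removed
        assert out.weights["edge"] == 1 and not out.genotype_drops.get("edge")
        assert out.weights["balanced"] == 1
        assert out.weights["unbal"] == 1
        assert len(out.genotype_drops["unbal"]) == 1
        # plain remove-at-nine rule (no rescue)
        plain = dm.balance_filter(crl, rescue=False)
        assert plain.weights["unbal"] == 0
        assert plain.weights["edge"] == 1
        assert plain.genotype_drops == {}

    def test_uncurable_column_gets_zero_weight(self):
        crl = _crl_from_columns({"flat": [0] * 12, "tenofs": [0] * 10 + [1] * 2})
        out = dm.balance_filter(crl)
        assert out.weights["flat"] == 0
        assert out.weights["tenofs"] == 0  # one drop cannot reach modal <= 8

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        cols = {
            f"c{k}": rng.choice([-2, -1, 0, 1, 2], size=12, p=[0.05, 0.1, 0.6, 0.15, 0.1])
            for k in range(6)
        }
        crl = _crl_from_columns(cols)
        out = dm.balance_filter(crl)
        for met, col in crl.labels.items():
            w_ref, drop_ref = brute_force_rescue(col.astype(int))
            assert out.weights[met] == w_ref
            got_drop = out.genotype_drops.get(met, [None])[0] if met in out.genotype_drops else None
            assert got_drop == drop_ref

    def test_class_counts_after_drop(self):
        crl = _crl_from_columns({"c": [0] * 9 + [1] * 3})
        out = dm.balance_filter(crl)
        counts = out.class_counts("c")
        assert sum(counts.values()) == 11
        assert counts[0] == 8
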