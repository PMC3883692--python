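"""Preprocessing: log transform, ANOVA batch removal, outlier cut, scaling."""

import numpy as np
import pandas as pd
import pytest

import diallelome as dm
from diallelome.simulate import SampleTable

from _oracles import reference_studentized_residuals


def _tiny_table(values, genotypes, batches, replicates=None):
    values = pd.DataFrame(np.asarray(values, dtype=float))
    values.index = [f"s{i}" for i in range(len(values))]
    values.columns = [f"met{j}" for j in range(values.shape[1])]
    if replicates is None:
        replicates = list(range(1, len(values) + 1))
    meta = pd.DataFrame(
        {
            "genotype": genotypes,
            "mother": "",
            "father": "",
            "replicate": replicates,
            "batch": batches,
            "biomass": 100.0,
        },
        index=values.index,
    )
    return SampleTable(values, meta)


class TestLogTransform:
    def test_known_values(self):
        t = _tiny_table([[1000.0], [1.0], [10.0]], ["A"] * 3, [1, 1, 1])
        out = dm.log_transform(t)
        assert np.allclose(out.values.iloc[:, 0], [3.0, 0.0, 1.0])

    def test_column_powers_of_ten(self):
        t = _tiny_table([[10.0], [100.0], [1000.0]], ["A"] * 3, [1] * 3)
        assert np.allclose(dm.log_transform(t).values.iloc[:, 0], [1, 2, 3])

    def test_nonpositive_rejected_with_cell(self):
        t = _tiny_table([[10.0], [-1.0]], ["A", "A"], [1, 1])
        with pytest.raises(ValueError, match="non-positive"):
            dm.log_transform(t)

    def test_masked_cells_stay_masked(self):
        t = _tiny_table([[10.0], [np.nan]], ["A", "A"], [1, 1])
        out = dm.log_transform(t)
        assert np.isnan(out.values.iloc[1, 0])


class TestBatchRemoval:
    def test_injected_offset_recovered_exactly(self, design4):
        table, _ = dm.simulate_dataset(
            design4, m=8, n_drivers=2, noise_sd=0.0, batch_sd=0.0, seed=2
        )
        injected = table.copy()
        mask = injected.meta["batch"] == 2
        injected.values.loc[mask] += 0.5
        corrected, report = dm.remove_batch_effects(injected)
        offsets = report.batch_effects_removed
        # sum-to-zero offsets recover the +0.5 contrast on batch 2
        rel = offsets.loc[2] - offsets.loc[[1, 3]].mean()
        assert np.allclose(rel, 0.5, atol=1e-9)
        # corrected table equals the pre-injection table up to the constant
        # absorbed into the genotype effects (mean injected offset)
        dev = corrected.values.to_numpy() - table.values.to_numpy()
        assert float(np.std(dev)) < 1e-9
        assert np.allclose(dev.mean(), 0.5 * mask.mean(), atol=1e-9)

    def test_single_batch_is_identity(self):
        t = _tiny_table([[1.0], [2.0], [3.0], [4.0]], ["A", "A", "B", "B"], [1, 1, 1, 1])
        out, report = dm.remove_batch_effects(t)
        assert out.values.equals(t.values)
        assert (report.batch_effects_removed.to_numpy() == 0).all()

    def test_no_batch_effect_leaves_table_unchanged(self, design4):
        table, _ = dm.simulate_dataset(
            design4, m=6, n_drivers=2, noise_sd=0.0, batch_sd=0.0, seed=5
        )
        out, _ = dm.remove_batch_effects(table)
        assert np.allclose(out.values.to_numpy(), table.values.to_numpy(), atol=1e-12)


class TestOutlierRemoval:
    def test_planted_spike_is_the_only_masked_cell(self, design4):
        table, _ = dm.simulate_dataset(
            design4, m=8, n_drivers=2, noise_sd=0.05, batch_sd=0.0, seed=3
        )
        spiked = table.copy()
        spiked.values.iloc[10, 3] += 10 * 0.05 * 10  # 100 sigma
        out, report = dm.remove_outliers(spiked, threshold=4.0)
        assert (str(spiked.values.index[10]), "met004") in report.outliers_removed
        assert len(report.outliers_removed) <= 2
        assert np.isnan(out.values.iloc[10, 3])

    def test_infinite_threshold_masks_nothing(self, design4):
        table, _ = dm.simulate_dataset(design4, m=6, n_drivers=2, seed=4)
        _, report = dm.remove_outliers(table, threshold=np.inf)
        assert report.outliers_removed == []

    def test_matches_reference_studentized_residuals(self, rng):
        """Brute-force externally studentized residuals agree on the flags."""
        n_per = 5
        genotypes = ["A"] * n_per + ["B"] * n_per
        batches = [1, 2, 1, 2, 1, 2, 1, 2, 1, 2]
        vals = rng.normal(0, 0.1, size=(2 * n_per, 1))
        vals[3, 0] += 2.0  # clear spike
        t = _tiny_table(vals, genotypes, batches)
        _, report = dm.remove_outliers(t, threshold=4.0)
        # oracle: same two-factor design matrix, by hand
        X = np.column_stack(
            [
                np.ones(2 * n_per),
                (np.asarray(genotypes) == "B").astype(float),
                np.where(np.asarray(batches) == 1, 1.0, -1.0),
            ]
        )
        r_ext = reference_studentized_residuals(vals[:, 0], X)
        expected = {(f"s{i}", "met0") for i in np.nonzero(np.abs(r_ext) > 4.0)[0]}
        assert set(report.outliers_removed) == expected
        assert ("s3", "met0") in expected

    def test_clean_gaussian_data_rarely_flagged(self, design4):
        flagged = 0
        for seed in range(5):
            table, _ = dm.simulate_null_dataset(design4, m=20, noise_sd=0.1, seed=seed)
            _, report = dm.remove_outliers(table, threshold=4.0)
            flagged += len(report.outliers_removed)
        # 5 * 96 * 20 = 9600 cells; |t|>4 false positives are rare
        assert flagged <= 10


class TestSampleScaling:
    def test_injected_row_shift_removed(self):
        """A whole-row offset is removed exactly when it leaves the genotype
        cell median untouched (the shifted cells stay above it)."""
        rows = [[0.0] * 5, [1.0] * 5, [2.0] * 5]
        base = _tiny_table(rows, ["A"] * 3, [1] * 3)
        shifted = _tiny_table([rows[0], rows[1], [7.0] * 5], ["A"] * 3, [1] * 3)
        out_b, _ = dm.scale_samples(base)
        out_s, rep = dm.scale_samples(shifted)
        assert np.allclose(out_s.values.to_numpy(), out_b.values.to_numpy(), atol=1e-12)
        assert np.isclose(rep.scale_factors.iloc[2], 6.0)  # 7 - group median 1

    def test_identical_replicates_scale_identically(self):
        row = [1.0, 2.0, 3.0]
        t = _tiny_table([row, row], ["A", "A"], [1, 1])
        out, report = dm.scale_samples(t)
        assert np.allclose(out.values.iloc[0], out.values.iloc[1])
        assert np.allclose(report.scale_factors, 0.0)

    def test_all_masked_sample_rejected(self):
        t = _tiny_table([[1.0, 2.0], [np.nan, np.nan]], ["A", "A"], [1, 1])
        with pytest.raises(ValueError, match="masked"):
            dm.scale_samples(t)


class TestAutoscale:
    def test_columns_standardized(self, rng):
        mat = pd.DataFrame(rng.normal(2, 3, size=(20, 5)))
        out, report = dm.autoscale_columns(mat)
        assert np.abs(out.mean()).max() < 1e-10
        assert np.abs(out.std(ddof=1) - 1).max() < 1e-10

    def test_idempotent(self, rng):
        mat = pd.DataFrame(rng.normal(size=(10, 3)))
        once, _ = dm.autoscale_columns(mat)
        twice, _ = dm.autoscale_columns(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy())

    def test_constant_column_rejected_or_dropped(self):
        mat = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="b"):
            dm.autoscale_columns(mat)
        with pytest.warns(UserWarning, match="b"):
            out, _ = dm.autoscale_columns(mat, drop_constant=True)
        assert list(out.columns) == ["a"]


def test_pipeline_order_is_deterministic(design4):
    table, _ = dm.simulate_dataset(design4, m=10, n_drivers=2, seed=8)
    a, _ = dm.normalize_pipeline(table)
    b, _ = dm.normalize_pipeline(table)
    assert a.values.equals(b.values)
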