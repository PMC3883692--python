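"""Preprocessing of GC-MS metabolite intensity tables.

The pipeline (fixed order) is: log10 transform, two-way ANOVA batch-effect
removal (genotype + batch, additive), elimination of cells with externally
studentized residuals above a cutoff (single pass), and per-sample median
scaling within genotype.  Column autoscaling (mean 0, unit variance) is a
separate operation applied when classifier input matrices are built.

All model fitting uses the standard additive two-factor linear model solved
by least squares with a shared design matrix across metabolites; batch
effects use a sum-to-zero constraint so genotype effects are untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import SampleTable


@dataclass
class NormalizationReport:
    """Record of what each preprocessing step estimated and removed."""

    batch_effects_removed: pd.DataFrame | None = None  # batch x metabolite offsets
    outliers_removed: list[tuple[str, str]] = field(default_factory=list)  # (sample, metabolite)
    scale_factors: pd.Series | None = None  # per-sample log10 correction
    columns_scaled: pd.DataFrame | None = None  # per-metabolite mean/sd

    def merge(self, other: "NormalizationReport") -> "NormalizationReport":
        return NormalizationReport(
            batch_effects_removed=(
                other.batch_effects_removed
                if other.batch_effects_removed is not None
                else self.batch_effects_removed
            ),
            outliers_removed=self.outliers_removed + other.outliers_removed,
            scale_factors=other.scale_factors if other.scale_factors is not None else self.scale_factors,
            columns_scaled=other.columns_scaled if other.columns_scaled is not None else self.columns_scaled,
        )

    def to_dict(self) -> dict:
        return {
            "batch_effects_removed": (
                None
                if self.batch_effects_removed is None
                else self.batch_effects_removed.to_dict()
            ),
            "outliers_removed": [list(c) for c in self.outliers_removed],
            "scale_factors": None if self.scale_factors is None else self.scale_factors.to_dict(),
            "columns_scaled": None if self.columns_scaled is None else self.columns_scaled.to_dict(),
        }


def log_transform(raw: SampleTable) -> SampleTable:
    """log10-transform intensities (masked cells stay masked).

    Raises if any unmasked intensity is non-positive, reporting the cells.
    """
    vals = raw.values
    bad = (vals <= 0) & vals.notna()
    if bad.any().any():
        cells = [(str(i), str(j)) for i, j in zip(*np.nonzero(bad.to_numpy()))]
        named = [
            (vals.index[int(i)], vals.columns[int(j)])
            for i, j in zip(*np.nonzero(bad.to_numpy()))
        ][:10]
        raise ValueError(f"non-positive intensities at cells (sample, metabolite): {named}")
    out = raw.copy()
    out.values = np.log10(vals)
    return out


def _design_matrix(genotype: pd.Series, batch: pd.Series):
    """Intercept + genotype treatment dummies + batch effect (sum-zero) coding."""
    geno_levels = list(dict.fromkeys(genotype))
    batch_levels = sorted(set(batch))
    n = len(genotype)
    n_b = len(batch_levels)
    X = np.zeros((n, 1 + (len(geno_levels) - 1) + max(n_b - 1, 0)))
    X[:, 0] = 1.0
    for i, g in enumerate(geno_levels[1:], start=1):
        X[(genotype == g).to_numpy(), i] = 1.0
    off = len(geno_levels)
    for k, b in enumerate(batch_levels[:-1]):
        X[(batch == b).to_numpy(), off + k] = 1.0
        X[(batch == batch_levels[-1]).to_numpy(), off + k] = -1.0
    return X, geno_levels, batch_levels, off


def _fit_columns(X: np.ndarray, Y: np.ndarray):
    """Least-squares fit of all columns of Y on X, tolerating NaNs per column.

    Returns (beta, residuals, leverage, rank_info) where residuals and
    leverage are NaN at masked cells; columns sharing a missingness pattern
    are solved together.
    """
    n, m = Y.shape
    beta = np.full((X.shape[1], m), np.nan)
    resid = np.full((n, m), np.nan)
    lev = np.full((n, m), np.nan)
    ranks = np.zeros(m, dtype=int)
    miss = np.isnan(Y)
    patterns: dict[bytes, list[int]] = {}
    for j in range(m):
        patterns.setdefault(miss[:, j].tobytes(), []).append(j)
    for key, cols in patterns.items():
        mask = ~np.frombuffer(key, dtype=bool)
        Xs = X[mask]
        Ys = Y[np.ix_(mask, cols)]
        if Xs.shape[0] == 0:
            continue
        b, _, rank, _ = np.linalg.lstsq(Xs, Ys, rcond=None)
        if rank < X.shape[1]:
            warnings.warn(
                "rank-deficient two-factor design (confounded factor levels); "
                "minimum-norm solution used",
                stacklevel=3,
            )
        fitted = Xs @ b
        q, _ = np.linalg.qr(Xs)
        h = np.sum(q * q, axis=1)
        for idx, j in enumerate(cols):
            beta[:, j] = b[:, idx]
            resid[mask, j] = Ys[:, idx] - fitted[:, idx]
            lev[mask, j] = h
            ranks[j] = rank
    return beta, resid, lev, ranks


def remove_batch_effects(table: SampleTable) -> tuple[SampleTable, NormalizationReport]:
    """Remove measurement-batch offsets via an additive genotype+batch ANOVA.

    Per metabolite the additive two-factor model is fitted and the estimated
    batch effects (sum-to-zero over batches) are subtracted; genotype effects
    are untouched.  With a single batch this is the identity.
    """
    batch = table.meta["batch"]
    batch_levels = sorted(set(batch))
    mets = table.metabolite_ids
    if len(batch_levels) < 2:
        report = NormalizationReport(
            batch_effects_removed=pd.DataFrame(0.0, index=batch_levels, columns=mets)
        )
        return table.copy(), report
    X, _, levels, off = _design_matrix(table.meta["genotype"], batch)
    Y = table.values.to_numpy(dtype=float)
    beta, _, _, _ = _fit_columns(X, Y)
    n_b = len(levels)
    offsets = np.zeros((n_b, len(mets)))
    offsets[: n_b - 1] = beta[off : off + n_b - 1]
    offsets[n_b - 1] = -np.nansum(beta[off : off + n_b - 1], axis=0)
    offsets = np.nan_to_num(offsets)
    offsets_df = pd.DataFrame(offsets, index=levels, columns=mets)
    batch_idx = np.asarray([levels.index(b) for b in batch])
    corrected = table.values - offsets[batch_idx, :]
    out = table.copy()
    out.values = corrected
    return out, NormalizationReport(batch_effects_removed=offsets_df)


def remove_outliers(
    table: SampleTable, threshold: float = 4.0
) -> tuple[SampleTable, NormalizationReport]:
    """Mask cells whose externally studentized residual exceeds ``threshold``.

    Residuals come from the additive genotype+batch fit; the pass is not
    iterated.  Cells that cannot be studentized (zero residual variance or
    leverage ~1) are never masked.
    """
    X, _, _, _ = _design_matrix(table.meta["genotype"], table.meta["batch"])
    Y = table.values.to_numpy(dtype=float)
    _, resid, lev, ranks = _fit_columns(X, Y)
    n_obs = (~np.isnan(Y)).sum(axis=0)
    removed: list[tuple[str, str]] = []
    out_vals = table.values.copy()
    for j in range(Y.shape[1]):
        df = n_obs[j] - ranks[j]
        if df < 2:  # external variance needs at least one spare df
            continue
        e = resid[:, j]
        h = lev[:, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = 1.0 - h
            sse = np.nansum(e**2)
            if sse <= 1e-24:
                continue
            press = e**2 / np.where(denom > 1e-10, denom, np.nan)
            s2_i = (sse - press) / (df - 1)
            r_ext = e / np.sqrt(np.where(s2_i > 0, s2_i, np.nan) * denom)
            r_ext = np.where((s2_i <= 0) & np.isfinite(press), np.inf * np.sign(e), r_ext)
        flag = np.abs(r_ext) > threshold
        flag &= np.isfinite(e)
        for i in np.nonzero(flag)[0]:
            removed.append((str(table.values.index[i]), str(table.values.columns[j])))
            out_vals.iloc[i, j] = np.nan
    out = table.copy()
    out.values = out_vals
    return out, NormalizationReport(outliers_removed=removed)


def scale_samples(table: SampleTable) -> tuple[SampleTable, NormalizationReport]:
    """Per-sample median scaling within genotype (log-scale subtraction).

    Each sample's correction factor is its median metabolite level minus the
    median over all cells of its genotype group; subtracting it on the log
    scale equals dividing by the intensity-scale ratio of medians.
    """
    vals = table.values
    if vals.notna().sum(axis=1).eq(0).any():
        bad = vals.index[vals.notna().sum(axis=1).eq(0)].tolist()
        raise ValueError(f"sample(s) with all cells masked: {bad}")
    sample_medians = vals.median(axis=1)
    geno_medians = {}
    for g, idx in table.meta.groupby("genotype").groups.items():
        geno_medians[g] = np.nanmedian(vals.loc[idx].to_numpy())
    group_median = table.meta["genotype"].map(geno_medians)
    factors = sample_medians - group_median
    out = table.copy()
    out.values = vals.sub(factors, axis=0)
    return out, NormalizationReport(scale_factors=factors)


def autoscale_columns(
    matrix: pd.DataFrame, drop_constant: bool = False
) -> tuple[pd.DataFrame, NormalizationReport]:
    """Mean-center and scale every column to unit variance (ddof=1).

    Masked cells are ignored in the statistics.  Constant columns are
    rejected, or dropped (and logged) when ``drop_constant`` is set.
    """
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    constant = sds.le(0) | sds.isna()
    if constant.any():
        bad = list(matrix.columns[constant])
        if not drop_constant:
            raise ValueError(f"constant column(s), cannot autoscale: {bad}")
        warnings.warn(f"dropping constant column(s): {bad}", stacklevel=2)
        matrix = matrix.loc[:, ~constant]
        means = means[~constant]
        sds = sds[~constant]
    scaled = (matrix - means) / sds
    report = NormalizationReport(
        columns_scaled=pd.DataFrame({"mean": means, "sd": sds})
    )
    return scaled, report


def normalize_pipeline(
    table: SampleTable,
    outlier_threshold: float = 4.0,
    log_input: bool = False,
) -> tuple[SampleTable, NormalizationReport]:
    """Run log transform (optional), batch removal, outlier cut, sample scaling."""
    report = NormalizationReport()
    if log_input:
        table = log_transform(table)
    table, rep = remove_batch_effects(table)
    report = report.merge(rep)
    table, rep = remove_outliers(table, threshold=outlier_threshold)
    report = report.merge(rep)
    table, rep = scale_samples(table)
    report = report.merge(rep)
    return table, report
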