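"""Combined Relative Level (CRL) encoding of hybrid metabolite heterosis.

Each hybrid metabolite level is compared to the corresponding maternal and
paternal levels with moderated t-statistics (empirical Bayes variance
shrinkage across the metabolite ensemble, after Smyth's hierarchical model)
and encoded as a five-class label:

* ``+2`` / ``-2`` -- significantly above / below both parents (positive /
  negative overdominance),
* ``+1`` / ``-1`` -- significantly above / below exactly one parent, not
  distinguishable from the other (dominance),
* ``0`` -- indistinguishable from both parents, or significantly above one
  and below the other (additivity / mid-parent crossing).

Metabolites whose label column is dominated by a single class (modal count
at least 9 of 12 hybrids by default) are down-weighted for the downstream
classification, with a single-genotype-drop rescue.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import DiallelDesign
from .simulate import SampleTable


# ---------------------------------------------------------------------------
# Empirical Bayes variance shrinkage (moderated t)
# ---------------------------------------------------------------------------


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Monotone decreasing; the iteration follows the standard scheme used for
    the scaled inverse-chi-square moment fit.
    """
    if not np.isfinite(x) or x <= 0:
        raise ValueError(f"trigamma_inverse needs x > 0, got {x}")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-10:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray | float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to variances.

    Works on log variances: if s2_j ~ s0^2 * chisq(d_j)/d_j scaled by a
    chisq(d0) mixing variance, then log s2_j has known digamma/trigamma
    moments; matching the empirical mean and variance of the log variances
    yields (d0, s0^2).  When the empirical spread is at or below the
    chi-square baseline the solution degenerates to d0 = infinity (complete
    shrinkage).  With fewer than 3 positive finite variances no shrinkage is
    attempted (d0 = 0).

    Returns
    -------
    (d0, s0_squared); ``(0.0, nan)`` when no prior is estimable.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & np.isfinite(df) & (df > 0)
    if ok.sum() < 3:
        return 0.0, float("nan")
    s2 = s2[ok]
    d = df[ok]
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, d / 2.0)))
    if evar <= 0:
        return float("inf"), float(math.exp(emean))
    d0 = 2.0 * trigamma_inverse(evar)
    s0_sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return float(d0), float(s0_sq)


@dataclass
class ModeratedTResult:
    """Per-metabolite moderated two-sample t statistics for one comparison."""

    delta: np.ndarray  # mean(group_a) - mean(group_b)
    s2: np.ndarray  # pooled sample variance
    s2_prior: float  # s0^2
    d0: float  # prior degrees of freedom
    s2_post: np.ndarray  # moderated (posterior) variance
    t_mod: np.ndarray
    df_total: np.ndarray  # d0 + residual df
    p_two_sided: np.ndarray


def moderated_t(
    group_a: np.ndarray | pd.DataFrame,
    group_b: np.ndarray | pd.DataFrame,
    shared_variances: tuple[float, float] | None = None,
) -> ModeratedTResult:
    """Moderated two-sample t over a metabolite ensemble.

    ``group_a`` and ``group_b`` are replicate-by-metabolite arrays (NaN =
    masked).  The per-metabolite pooled variances form the ensemble from
    which the inverse-chi-square prior is fitted, unless a pre-fitted
    ``(d0, s0_squared)`` pair is passed in ``shared_variances``.  Metabolites
    with fewer than two unmasked replicates in either group yield NaN
    statistics.  Zero posterior variance is handled by convention:
    ``t = 0`` when the mean difference is 0, else signed infinity.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[1] != b.shape[1]:
        raise ValueError("group_a and group_b must cover the same metabolites")

    n_a = (~np.isnan(a)).sum(axis=0).astype(float)
    n_b = (~np.isnan(b)).sum(axis=0).astype(float)
    usable = (n_a >= 2) & (n_b >= 2)
    if not usable.all():
        warnings.warn(
            f"{int((~usable).sum())} metabolite(s) skipped: fewer than 2 "
            "unmasked replicates in a group",
            stacklevel=2,
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = np.nanmean(np.where(np.isnan(a), np.nan, a), axis=0)
        mean_b = np.nanmean(np.where(np.isnan(b), np.nan, b), axis=0)
        ss_a = np.nansum((a - mean_a) ** 2, axis=0)
        ss_b = np.nansum((b - mean_b) ** 2, axis=0)
    delta = mean_a - mean_b
    d_resid = n_a + n_b - 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = (ss_a + ss_b) / d_resid
    s2 = np.where(usable, s2, np.nan)
    delta = np.where(usable, delta, np.nan)
    # Pooled variances at float-noise level are true zeros (e.g. identical
    # replicates after exact arithmetic); keep them exactly zero so the
    # degenerate-variance conventions below apply instead of jitter ratios.
    s2 = np.where(s2 < 1e-16, 0.0, s2)

    if shared_variances is not None:
        d0, s0_sq = shared_variances
    elif s2.size >= 3:
        d0, s0_sq = fit_variance_prior(s2, d_resid)
    else:
        d0, s0_sq = 0.0, float("nan")

    if d0 == 0 or not np.isfinite(s0_sq):
        d0 = 0.0
        s2_post = s2.copy()
    elif np.isinf(d0):
        s2_post = np.where(np.isnan(s2), np.nan, s0_sq)
    else:
        s2_post = (d0 * s0_sq + d_resid * s2) / (d0 + d_resid)

    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
        t = delta / se
    # Degenerate (zero) variance: zero difference -> t = 0, else signed
    # infinity.  |delta| below a numerical tolerance counts as zero so that
    # float jitter from earlier normalization steps cannot fake an effect.
    zero_tol = 1e-8
    zero_se = usable & ~(se > 0)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se & (np.abs(delta) <= zero_tol), 0.0, t)
        t = np.where(zero_se & (np.abs(delta) > zero_tol), np.sign(delta) * np.inf, t)

    df_total = d0 + d_resid
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(np.isnan(t), np.nan, p)

    return ModeratedTResult(
        delta=delta,
        s2=s2,
        s2_prior=float(s0_sq),
        d0=float(d0),
        s2_post=s2_post,
        t_mod=t,
        df_total=np.where(usable, df_total, np.nan),
        p_two_sided=p,
    )


# ---------------------------------------------------------------------------
# Label assignment and balance filtering
# ---------------------------------------------------------------------------


@dataclass
class CRLMatrix:
    """Hybrids x metabolites CRL labels with balance weights.

    ``labels`` holds floats so that untestable cells can be NaN; usable
    labels are integers in {-2,-1,0,+1,+2}.  ``weights`` in {0,1} flag
    metabolites with acceptably balanced label columns; ``genotype_drops``
    lists hybrids excluded row-wise for specific metabolites by the balance
    rescue.
    """

    labels: pd.DataFrame
    weights: pd.Series = field(default=None)  # type: ignore[assignment]
    genotype_drops: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = pd.Series(1, index=self.labels.columns, dtype=int)
        vals = self.labels.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and not np.isin(finite, [-2, -1, 0, 1, 2]).all():
            raise ValueError("labels must lie in {-2,-1,0,+1,+2}")

    @property
    def hybrids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.labels.columns)

    def class_counts(self, metabolite: str) -> dict[int, int]:
        """Tally of labels for one metabolite, excluding dropped/missing rows."""
        col = self.labels[metabolite]
        col = col.drop(index=self.genotype_drops.get(metabolite, []), errors="ignore")
        col = col.dropna()
        return {int(k): int(v) for k, v in col.value_counts().items()}

    def usable_labels(self, metabolite: str) -> pd.Series:
        """Per-hybrid labels for one metabolite after drops, NaN removed."""
        col = self.labels[metabolite]
        col = col.drop(index=self.genotype_drops.get(metabolite, []), errors="ignore")
        return col.dropna().astype(int)


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg rejection mask (NaNs never rejected)."""
    out = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return out
    q = stats.false_discovery_control(p[ok], method="bh")
    out[ok] = q <= alpha
    return out


def assign_labels(
    hybrids: SampleTable,
    parents: SampleTable | None,
    design: DiallelDesign,
    alpha: float = 0.05,
    adjust: str = "bh",
) -> CRLMatrix:
    """Assign CRL labels to every (hybrid, metabolite) cell.

    For each hybrid the replicate group is tested against the maternal and
    the paternal replicate group with moderated t-statistics; within each
    (hybrid, parent) comparison the p-values are Benjamini-Hochberg adjusted
    across metabolites (``adjust='none'`` switches the adjustment off).  The
    signed significance pattern maps to the five-class label; the
    significant-crossing pattern (above one parent, below the other) maps
    to 0.

    ``hybrids`` and ``parents`` may be the same table; when ``parents`` is
    None, ``hybrids`` must contain all genotypes.
    """
    if adjust not in ("bh", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    table_h = hybrids
    table_p = parents if parents is not None else hybrids
    mets = table_h.metabolite_ids
    labels = pd.DataFrame(np.nan, index=list(design.hybrid_ids), columns=mets)

    for (mo, fa), hyb in zip(design.hybrids, design.hybrid_ids):
        try:
            h_vals = table_h.genotype_values(hyb).to_numpy(dtype=float)
            m_vals = table_p.genotype_values(mo).to_numpy(dtype=float)
            f_vals = table_p.genotype_values(fa).to_numpy(dtype=float)
        except KeyError as exc:
            raise ValueError(f"missing genotype for hybrid {hyb}: {exc}") from exc
        res_m = moderated_t(h_vals, m_vals)
        res_f = moderated_t(h_vals, f_vals)
        if adjust == "bh":
            sig_m = _bh_reject(res_m.p_two_sided, alpha)
            sig_f = _bh_reject(res_f.p_two_sided, alpha)
        else:
            sig_m = np.nan_to_num(res_m.p_two_sided, nan=1.0) <= alpha
            sig_f = np.nan_to_num(res_f.p_two_sided, nan=1.0) <= alpha
        up_m = sig_m & (res_m.delta > 0)
        dn_m = sig_m & (res_m.delta < 0)
        up_f = sig_f & (res_f.delta > 0)
        dn_f = sig_f & (res_f.delta < 0)
        lab = np.zeros(len(mets), dtype=float)
        lab[up_m & up_f] = 2
        lab[dn_m & dn_f] = -2
        one_up = (up_m & ~sig_f) | (up_f & ~sig_m)
        one_dn = (dn_m & ~sig_f) | (dn_f & ~sig_m)
        lab[one_up] = 1
        lab[one_dn] = -1
        # crossing (up one parent, down the other) stays 0
        untestable = np.isnan(res_m.p_two_sided) | np.isnan(res_f.p_two_sided)
        lab[untestable] = np.nan
        labels.loc[hyb] = lab

    crl = CRLMatrix(labels=labels)
    flagged = labels.columns[labels.isna().any(axis=0)]
    if len(flagged):
        warnings.warn(
            f"{len(flagged)} metabolite(s) have untestable cells: "
            f"{list(flagged)[:5]}...",
            stacklevel=2,
        )
    return crl


def balance_filter(
    crl: CRLMatrix, max_same: int | None = None, rescue: bool = True
) -> CRLMatrix:
    """Down-weight metabolites with an overly unbalanced label column.

    A metabolite whose modal class count reaches ``max_same + 1`` (default
    cut: ceil(0.75 * n_hybrids), i.e. 9 of 12) gets weight 0.  With
    ``rescue`` enabled (default), a metabolite at the cut whose modal count
    falls back to ``max_same`` or below when all rows of exactly one hybrid
    genotype are dropped keeps weight 1 with the drop recorded; the plain
    remove-at-nine rule is ``rescue=False``.
    """
    n_h = len(crl.hybrids)
    if max_same is None:
        max_same = math.ceil(0.75 * n_h) - 1
    weights = pd.Series(1, index=crl.labels.columns, dtype=int)
    drops: dict[str, list[str]] = {}
    for met in crl.labels.columns:
        col = crl.labels[met].dropna()
        if col.empty:
            weights[met] = 0
            continue
        counts = col.value_counts()
        if counts.iloc[0] <= max_same:
            continue
        best_hyb, best_modal = None, None
        if rescue:
            for hyb in col.index:
                reduced = col.drop(index=hyb)
                modal = reduced.value_counts().iloc[0] if not reduced.empty else 0
                if modal <= max_same and (best_modal is None or modal < best_modal):
                    best_hyb, best_modal = hyb, modal
        if best_hyb is not None:
            drops[met] = [best_hyb]
        else:
            weights[met] = 0
    return CRLMatrix(labels=crl.labels.copy(), weights=weights, genotype_drops=drops)
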