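"""Synthetic full-diallel metabolome + biomass datasets with known ground truth.

The generator emulates the structure of a GC-MS diallel root metabolome
study: four inbred parents and their twelve reciprocal hybrids, six
biological replicates per genotype, 112 metabolites measured in three
batches, log-normal intensities.  Hybrid heterosis behaviour is planted: a
small set of parental "driver" features (the maternal and paternal levels
of a few wide-spread metabolites) deterministically sets, for each driven
metabolite, which hybrids are additive (class 0), dominant (+/-1) or
overdominant (+/-2), and the same drivers determine root biomass through a
linear model.  A ground-truth sidecar records everything, so every
downstream stage can be tested against what was planted.

Design notes on identifiability: with only four parents every maternal (or
paternal) feature block has rank 4, so two parental features can only be
told apart through signal strength.  The generator therefore plants drivers
as maternal+paternal pairs of the same metabolites with a wide, evenly
spaced parental grid (strong columns), keeps background metabolites'
between-parent spread small, and gives driven metabolites either identical
parent means (pure overdominance; their own parental columns carry no
signal) or -- for the optional dominance fraction -- a narrower grid that
makes the one-parent-shift geometry testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DiallelDesign, hybrid_id

MATERNAL = "m"
PATERNAL = "p"

META_COLUMNS = ["genotype", "mother", "father", "replicate", "batch", "biomass"]

#: log10 offset used for the overdominant shift when noise_sd == 0 (the
#: shift effect_size * noise_sd would otherwise vanish and the planted
#: geometry "label +2 => hybrid mean strictly above both parents" break).
_ZERO_NOISE_SHIFT_UNIT = 0.05

#: Heterosis-mode patterns for driven metabolites: the hybrids are split
#: into equal rank blocks of the driver score and each block gets one
#: class.  Real label columns rarely exercise all five classes at once;
#: balanced two/three-class columns pass the balance filter and keep the
#: classification target learnable.  Overdominance patterns need no
#: parental separation; dominance patterns do.
OVERDOMINANCE_PATTERNS: tuple[tuple[int, ...], ...] = ((-2, 0, 2), (0, 2), (-2, 0))
DOMINANCE_PATTERNS: tuple[tuple[int, ...], ...] = ((-1, 0, 1), (0, 1), (-1, 0))


def feature_id(metabolite: str, tag: str) -> str:
    """Parental-feature identifier, e.g. ``met007_m`` (maternal level)."""
    if tag not in (MATERNAL, PATERNAL):
        raise ValueError(f"tag must be '{MATERNAL}' or '{PATERNAL}', got {tag!r}")
    return f"{metabolite}_{tag}"


def split_feature_id(fid: str) -> tuple[str, str]:
    met, _, tag = fid.rpartition("_")
    if tag not in (MATERNAL, PATERNAL) or not met:
        raise ValueError(f"malformed parental feature id {fid!r}")
    return met, tag


@dataclass
class SampleTable:
    """Samples x metabolites matrix with genotype/batch/biomass annotations.

    ``values`` rows are biological replicate samples (index = sample ids),
    columns are metabolites; entries are log10 intensities unless stated
    otherwise.  Masked (eliminated) cells are NaN.  ``meta`` is indexed like
    ``values`` and carries genotype, mother, father (empty for inbreds),
    replicate, batch and per-sample biomass (fresh weight, mg).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the same sample index")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"meta is missing columns {missing}")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def genotype_values(self, genotype: str) -> pd.DataFrame:
        """Replicate rows of one genotype, sorted by replicate index."""
        mask = self.meta["genotype"] == genotype
        if not mask.any():
            raise KeyError(f"no samples for genotype {genotype!r}")
        sub = self.values.loc[mask]
        order = self.meta.loc[mask, "replicate"].sort_values().index
        return sub.loc[order]

    def drop_genotype(self, genotype: str) -> "SampleTable":
        keep = self.meta["genotype"] != genotype
        return SampleTable(self.values.loc[keep].copy(), self.meta.loc[keep].copy())

    def copy(self) -> "SampleTable":
        return SampleTable(self.values.copy(), self.meta.copy())


@dataclass
class GroundTruth:
    """What the generator planted: drivers, true labels, biomass model.

    ``true_labels`` is hybrids x metabolites in {-2,-1,0,+1,+2};
    ``driver_features`` are parental-feature ids (``<met>_m`` / ``<met>_p``);
    ``biomass_weights`` maps each driver feature to its linear effect on
    biomass (mg per log10 unit); ``batch_effects`` are the per-batch
    additive log10 offsets.
    """

    driver_features: list[str]
    driven_metabolites: list[str]
    true_labels: pd.DataFrame
    biomass_weights: dict[str, float]
    noise_sd: float
    batch_effects: list[float]
    seed: int | None = None

    def __post_init__(self) -> None:
        for fid in self.driver_features:
            split_feature_id(fid)

    def to_json(self) -> str:
        payload = {
            "driver_features": list(self.driver_features),
            "driven_metabolites": list(self.driven_metabolites),
            "true_labels": {
                "index": list(self.true_labels.index),
                "columns": list(self.true_labels.columns),
                "data": self.true_labels.to_numpy().astype(int).tolist(),
            },
            "biomass_weights": {k: float(v) for k, v in self.biomass_weights.items()},
            "noise_sd": float(self.noise_sd),
            "batch_effects": [float(b) for b in self.batch_effects],
            "seed": self.seed,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        labels = pd.DataFrame(
            np.asarray(d["true_labels"]["data"], dtype=int),
            index=d["true_labels"]["index"],
            columns=d["true_labels"]["columns"],
        )
        return cls(
            driver_features=list(d["driver_features"]),
            driven_metabolites=list(d["driven_metabolites"]),
            true_labels=labels,
            biomass_weights=d["biomass_weights"],
            noise_sd=d["noise_sd"],
            batch_effects=d["batch_effects"],
            seed=d.get("seed"),
        )


def _metabolite_ids(m: int) -> list[str]:
    width = max(3, len(str(m)))
    return [f"met{i + 1:0{width}d}" for i in range(m)]


def _labels_from_scores(scores: np.ndarray, pattern: tuple[int, ...]) -> np.ndarray:
    """Deterministic rank-threshold map from driver scores to CRL labels.

    The score ranking is cut into ``len(pattern)`` equal blocks; hybrids in
    block b get class ``pattern[b]`` -- a balanced label column by
    construction.
    """
    n = len(scores)
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    blocks = (ranks * len(pattern)) // n
    return np.asarray(pattern, dtype=int)[blocks]


def simulate_dataset(
    design: DiallelDesign,
    m: int = 112,
    n_drivers: int = 6,
    effect_size: float = 3.0,
    noise_sd: float = 0.1,
    batch_sd: float = 0.1,
    seed: int = 0,
    *,
    n_driven: int | None = None,
    maternal_weight: float = 1.5,
    dominance_fraction: float = 0.0,
    mu_center: float = 5.0,
    mu_spread: float = 1.0,
    parent_tau: float = 0.06,
    driver_parent_spacing: float = 1.0,
    driven_parent_spacing: float = 0.4,
    biomass_baseline: float = 350.0,
    biomass_coef: float = 30.0,
    biomass_noise_sd: float | None = None,
    as_intensities: bool = False,
) -> tuple[SampleTable, GroundTruth]:
    """Simulate a full-diallel metabolome + biomass dataset.

    Parameters
    ----------
    design:
        Diallel design (parents, hybrids, replicates, batches).
    m:
        Number of metabolites.
    n_drivers:
        Number of planted driver parental features.  Drivers are the
        maternal and paternal levels of ``ceil(n_drivers / 2)`` driver
        metabolites (both tags of the same metabolite -- with four parents
        the two tag columns of a strong metabolite are equally strong, so
        planting them in pairs keeps every driver identifiable).  Requires
        ``m >= 2 * n_drivers``.
    effect_size:
        Overdominant shift beyond the parental range, in units of the
        replicate noise standard deviation.  ``effect_size = 0`` means no
        heterosis: every hybrid sits exactly at the mid-parent and all true
        labels are 0.
    noise_sd:
        Replicate noise standard deviation on the log10 scale.
    batch_sd:
        Standard deviation of the per-batch additive log10 offsets.
    seed:
        Reproducibility seed; identical seeds give byte-identical output.
    n_driven:
        Number of driven metabolites (non-additive hybrid behaviour
        planted); defaults to ``m // 4``.  Driver and driven metabolites
        are disjoint, so predictive information crosses metabolites, as
        assumed downstream.
    maternal_weight:
        Multiplier on maternal driver weights in the label scores; > 1
        makes maternal levels more influential on hybrid outcomes (the
        maternal bias seen in seed endosperm dosage and plastid
        inheritance).
    dominance_fraction:
        Fraction of driven metabolites whose planted labels are dominance
        patterns (+/-1, hybrid at one parent's level) rather than
        overdominance patterns; these need separated parent means, whose
        strong parental columns compete with the drivers in downstream
        feature ranking -- keep the fraction small when studying driver
        recovery.
    mu_center, mu_spread:
        Metabolite-level mean log10 intensity distribution.
    parent_tau:
        Between-parent spread of background metabolite means (log10 scale).
    driver_parent_spacing, driven_parent_spacing:
        Adjacent gaps of the evenly spaced parental grids (random parent
        order) of driver metabolites and of dominance-driven metabolites.
        Overdominance-driven metabolites have identical parent means (pure
        overdominance).
    biomass_baseline, biomass_coef, biomass_noise_sd:
        Biomass linear model: baseline (mg) plus per-driver effects of
        magnitude ~``biomass_coef`` mg per log10 unit and Normal noise
        (default ``biomass_coef * noise_sd``).
    as_intensities:
        If True, return raw intensities (``10**x``) instead of log10 values.

    Returns
    -------
    (SampleTable, GroundTruth)
    """
    if n_drivers < 1:
        raise ValueError("n_drivers must be >= 1")
    if m < 2 * n_drivers:
        raise ValueError(f"need m >= 2 * n_drivers, got m={m}, n_drivers={n_drivers}")
    for name, val in [
        ("effect_size", effect_size),
        ("noise_sd", noise_sd),
        ("batch_sd", batch_sd),
    ]:
        if val < 0:
            raise ValueError(f"{name} must be >= 0, got {val}")
    if not 0.0 <= dominance_fraction <= 1.0:
        raise ValueError("dominance_fraction must lie in [0, 1]")
    if n_driven is None:
        n_driven = m // 4
    n_driver_mets = (n_drivers + 1) // 2
    if n_driver_mets + n_driven > m:
        raise ValueError("driver metabolites + n_driven exceeds the number of metabolites")
    if biomass_noise_sd is None:
        biomass_noise_sd = biomass_coef * noise_sd

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    parents = list(design.parents)
    p = len(parents)
    mets = _metabolite_ids(m)

    mu = rng.normal(mu_center, mu_spread, size=m)

    special = rng.choice(m, size=n_driver_mets + n_driven, replace=False)
    driver_idx = np.sort(special[:n_driver_mets])
    driven_idx = np.sort(special[n_driver_mets:])
    # maternal tags of all driver metabolites, paternal tags of the first
    # floor(n_drivers/2): odd n_drivers leaves the last metabolite maternal-only
    driver_features = [feature_id(mets[j], MATERNAL) for j in driver_idx]
    driver_features += [feature_id(mets[j], PATERNAL) for j in driver_idx[: n_drivers // 2]]
    feature_tags = [MATERNAL] * n_driver_mets + [PATERNAL] * (n_drivers // 2)
    feature_mets = list(driver_idx) + list(driver_idx[: n_drivers // 2])

    # Parent means: Normal(mu_j, tau) background; wide grid for drivers;
    # driven metabolites identical parents (overdominance) or a narrower
    # grid (dominance fraction).
    parent_means = rng.normal(mu[None, :], parent_tau, size=(p, m))
    unit = np.arange(p) - (p - 1) / 2.0
    for j in driver_idx:
        parent_means[rng.permutation(p), j] = mu[j] + driver_parent_spacing * unit
    n_dom = int(round(dominance_fraction * n_driven))
    dom_set = set(rng.choice(driven_idx, size=n_dom, replace=False).tolist()) if n_dom else set()
    for j in driven_idx:
        if j in dom_set:
            parent_means[rng.permutation(p), j] = mu[j] + driven_parent_spacing * unit
        else:
            parent_means[:, j] = mu[j]

    # Driver z-scores per hybrid: the tagged parent's standardized level.
    parent_pos = {g: i for i, g in enumerate(parents)}
    hybrids = list(design.hybrid_ids)
    n_h = len(hybrids)
    n_feat = len(driver_features)
    z = np.zeros((n_h, n_feat))
    for k, (j, t) in enumerate(zip(feature_mets, feature_tags)):
        for hi, (mo, fa) in enumerate(design.hybrids):
            g = mo if t == MATERNAL else fa
            z[hi, k] = parent_means[parent_pos[g], j] - mu[j]
    z_sd = z.std(axis=0, ddof=0)
    z = z / np.where(z_sd > 0, z_sd, 1.0)

    # True labels: deterministic rank thresholds on a signed dense mixing of
    # driver z-scores (every driver contributes, magnitudes bounded away
    # from zero, maternal features weighted by maternal_weight).
    true_labels = pd.DataFrame(0, index=hybrids, columns=mets, dtype=int)
    if effect_size > 0:
        for j in driven_idx:
            signs = rng.choice([-1.0, 1.0], size=n_feat)
            w = signs * (0.75 + 0.5 * rng.uniform(size=n_feat))
            w[np.asarray(feature_tags) == MATERNAL] *= maternal_weight
            scores = z @ w
            pats = DOMINANCE_PATTERNS if j in dom_set else OVERDOMINANCE_PATTERNS
            pattern = pats[int(rng.integers(len(pats)))]
            true_labels.iloc[:, j] = _labels_from_scores(scores, pattern)

    shift_unit = noise_sd if noise_sd > 0 else _ZERO_NOISE_SHIFT_UNIT
    shift = effect_size * shift_unit

    # Genotype means consistent with the planted labels.
    geno_means: dict[str, np.ndarray] = {g: parent_means[parent_pos[g]] for g in parents}
    for hi, (mo, fa) in enumerate(design.hybrids):
        pm = parent_means[parent_pos[mo]]
        pf = parent_means[parent_pos[fa]]
        lo = np.minimum(pm, pf)
        hi_mean = np.maximum(pm, pf)
        lab = true_labels.iloc[hi].to_numpy()
        mean = (pm + pf) / 2.0
        mean = np.where(lab == 2, hi_mean + shift, mean)
        mean = np.where(lab == 1, hi_mean, mean)
        mean = np.where(lab == -1, lo, mean)
        mean = np.where(lab == -2, lo - shift, mean)
        geno_means[hybrid_id(mo, fa)] = mean

    # Biomass linear model on (centered) driver parental levels.
    beta = biomass_coef * rng.uniform(0.5, 1.5, size=n_feat)
    biomass_weights = dict(zip(driver_features, beta.tolist()))

    def _driver_levels(genotype: str, mo: str | None, fa: str | None) -> np.ndarray:
        out = np.zeros(n_feat)
        for k, (j, t) in enumerate(zip(feature_mets, feature_tags)):
            if mo is None:  # inbred: both parental roles are itself
                g = genotype
            else:
                g = mo if t == MATERNAL else fa
            out[k] = parent_means[parent_pos[g], j] - mu[j]
        return out

    rows, meta_rows, sample_ids = [], [], []
    genotype_parents: dict[str, tuple[str | None, str | None]] = {g: (None, None) for g in parents}
    for mo, fa in design.hybrids:
        genotype_parents[hybrid_id(mo, fa)] = (mo, fa)
    for g in design.genotypes:
        mo, fa = genotype_parents[g]
        mean_biomass = biomass_baseline + float(beta @ _driver_levels(g, mo, fa))
        for rep in range(1, design.n_replicates + 1):
            if noise_sd > 0:
                vals = geno_means[g] + rng.normal(0.0, noise_sd, size=m)
            else:
                vals = geno_means[g].copy()
            bio = mean_biomass + (rng.normal(0.0, biomass_noise_sd) if biomass_noise_sd > 0 else 0.0)
            rows.append(vals)
            sample_ids.append(f"{g}_r{rep}")
            meta_rows.append(
                {
                    "genotype": g,
                    "mother": mo if mo is not None else "",
                    "father": fa if fa is not None else "",
                    "replicate": rep,
                    "batch": 0,  # assigned below
                    "biomass": max(bio, 1.0),
                }
            )
    values = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=mets)
    meta = pd.DataFrame(meta_rows, index=sample_ids)

    # Batches: round-robin across a randomized sample order (mirrors
    # measurement in completely randomized order in consecutive batches).
    batch_effects = (
        rng.normal(0.0, batch_sd, size=design.n_batches)
        if batch_sd > 0
        else np.zeros(design.n_batches)
    )
    order = rng.permutation(len(values))
    batches = np.empty(len(values), dtype=int)
    batches[order] = np.arange(len(values)) % design.n_batches + 1
    meta["batch"] = batches
    values = values.add(pd.Series(batch_effects[batches - 1], index=values.index), axis=0)

    if as_intensities:
        values = 10.0**values

    truth = GroundTruth(
        driver_features=driver_features,
        driven_metabolites=[mets[j] for j in driven_idx],
        true_labels=true_labels,
        biomass_weights=biomass_weights,
        noise_sd=float(noise_sd),
        batch_effects=[float(b) for b in batch_effects],
        seed=int(seed),
    )
    return SampleTable(values, meta), truth


def simulate_null_dataset(
    design: DiallelDesign,
    m: int = 50,
    noise_sd: float = 0.1,
    batch_sd: float = 0.0,
    seed: int = 0,
    *,
    mu_center: float = 5.0,
    mu_spread: float = 1.0,
    biomass_baseline: float = 350.0,
    biomass_noise_sd: float = 20.0,
) -> tuple[SampleTable, GroundTruth]:
    """Global-null dataset: every genotype drawn from the same distribution.

    All genotype means coincide per metabolite, so every hybrid-vs-parent
    comparison satisfies its null hypothesis and biomass is pure noise.
    The returned ground truth has no drivers and all-zero labels.
    """
    if noise_sd <= 0:
        raise ValueError("null simulation needs noise_sd > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mets = _metabolite_ids(m)
    mu = rng.normal(mu_center, mu_spread, size=m)
    hybrids = list(design.hybrid_ids)
    genotype_parents: dict[str, tuple[str, str]] = {
        hybrid_id(mo, fa): (mo, fa) for mo, fa in design.hybrids
    }
    rows, meta_rows, ids = [], [], []
    for g in design.genotypes:
        mo, fa = genotype_parents.get(g, ("", ""))
        for rep in range(1, design.n_replicates + 1):
            rows.append(mu + rng.normal(0.0, noise_sd, size=m))
            ids.append(f"{g}_r{rep}")
            meta_rows.append(
                {
                    "genotype": g,
                    "mother": mo,
                    "father": fa,
                    "replicate": rep,
                    "batch": 0,
                    "biomass": max(biomass_baseline + rng.normal(0.0, biomass_noise_sd), 1.0),
                }
            )
    values = pd.DataFrame(np.vstack(rows), index=ids, columns=mets)
    meta = pd.DataFrame(meta_rows, index=ids)
    batch_effects = (
        rng.normal(0.0, batch_sd, size=design.n_batches)
        if batch_sd > 0
        else np.zeros(design.n_batches)
    )
    order = rng.permutation(len(values))
    batches = np.empty(len(values), dtype=int)
    batches[order] = np.arange(len(values)) % design.n_batches + 1
    meta["batch"] = batches
    values = values.add(pd.Series(batch_effects[batches - 1], index=values.index), axis=0)
    truth = GroundTruth(
        driver_features=[],
        driven_metabolites=[],
        true_labels=pd.DataFrame(0, index=hybrids, columns=mets, dtype=int),
        biomass_weights={},
        noise_sd=float(noise_sd),
        batch_effects=[float(b) for b in batch_effects],
        seed=int(seed),
    )
    return SampleTable(values, meta), truth


def write_fixture(table: SampleTable, truth: GroundTruth, directory: str | Path) -> dict:
    """Write a fixture (values + design sheet + truth sidecar); see io module."""
    from . import io as _io

    return _io.write_fixture(table, truth, directory)
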