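"""End-to-end pipeline: normalization -> CRL -> screen -> ranking -> biomass.

A single master seed drives every stochastic stage through spawned
substreams, so a full run is reproducible bit-for-bit from the
configuration.  Stage defaults equal the protocol constants: outlier cutoff
4, balance cut 9-of-12, 3-fold CV with 25 repetitions, 60% training split,
500 SVR constructions, 5-feature subsets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomass as biomass_mod
from . import crl as crl_mod
from . import io as io_mod
from . import ranking as ranking_mod
from . import screen as screen_mod
from .design import DiallelDesign, make_design
from .normalize import NormalizationReport, normalize_pipeline
from .simulate import GroundTruth, SampleTable, simulate_dataset


@dataclass
class PipelineConfig:
    """All tunable stage parameters with protocol defaults."""

    seed: int = 0
    # simulate block (used by `simulate`; ignored when data is loaded)
    parents: list[str] = field(default_factory=lambda: ["P1", "P2", "P3", "P4"])
    n_replicates: int = 6
    n_batches: int = 3
    m: int = 112
    n_drivers: int = 6
    effect_size: float = 3.0
    noise_sd: float = 0.1
    batch_sd: float = 0.1
    # normalization
    outlier_threshold: float = 4.0
    log_input: bool = False
    # crl
    alpha: float = 0.05
    adjust: str = "bh"
    max_same: int | None = None  # None -> ceil(0.75 * n_hybrids) - 1
    # screen
    k: int = 3
    reps: int = 25
    methods: tuple[str, ...] = screen_mod.METHODS
    rule: str = "quartile"
    rf_trees: int = 500
    pls_components: int = 10
    # ranking
    rfe_steps: int = 0
    # biomass
    train_frac: float = 0.6
    biomass_reps: int = 500
    subset_size: int = 5
    schemes: tuple[str, ...] = biomass_mod.DEFAULT_SCHEMES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        if "schemes" in data:
            data["schemes"] = tuple(data["schemes"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    design: DiallelDesign
    normalized: SampleTable
    normalization_report: NormalizationReport
    crl: crl_mod.CRLMatrix
    xpp: screen_mod.ParentalPairMatrix
    screen_summary: pd.DataFrame
    predictable: list[str]
    ranking: ranking_mod.FeatureRanking | None
    biomass_results: pd.DataFrame | None

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"config_hash": self.config.config_hash(), "seed": self.config.seed}
        (directory / "run.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")
        io_mod.write_sample_table(self.normalized, directory / "normalized")
        (directory / "normalization_report.json").write_text(
            json.dumps(self.normalization_report.to_dict(), indent=1, default=str),
            encoding="utf-8",
        )
        self.crl.labels.rename_axis("hybrid").to_csv(directory / "crl_labels.tsv", sep="\t")
        sidecar = {
            "weights": {k: int(v) for k, v in self.crl.weights.items()},
            "genotype_drops": self.crl.genotype_drops,
        }
        (directory / "crl_sidecar.json").write_text(json.dumps(sidecar, indent=1), encoding="utf-8")
        self.screen_summary.to_csv(directory / "screen_summary.tsv", sep="\t")
        if self.ranking is not None:
            self.ranking.table.to_csv(directory / "feature_ranking.tsv", sep="\t")
        if self.biomass_results is not None:
            self.biomass_results.to_csv(directory / "biomass_evaluation.tsv", sep="\t", index=False)


def design_from_table(table: SampleTable, n_batches: int | None = None) -> DiallelDesign:
    """Reconstruct the diallel design from a sample table's design sheet."""
    meta = table.meta
    parents = list(dict.fromkeys(meta.loc[meta["mother"] == "", "genotype"]))
    reps = int(meta.groupby("genotype")["replicate"].count().min())
    if n_batches is None:
        n_batches = int(meta["batch"].nunique())
    return make_design(parents, n_replicates=reps, n_batches=n_batches)


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Generate a fixture directory from the config's simulate block."""
    design = make_design(config.parents, config.n_replicates, config.n_batches)
    table, truth = simulate_dataset(
        design,
        m=config.m,
        n_drivers=config.n_drivers,
        effect_size=config.effect_size,
        noise_sd=config.noise_sd,
        batch_sd=config.batch_sd,
        seed=config.seed,
    )
    manifest = io_mod.write_fixture(table, truth, out_dir)
    manifest["config_hash"] = config.config_hash()
    manifest["seed"] = config.seed
    (Path(out_dir) / io_mod.MANIFEST_FILE).write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    return manifest


def run_all(
    table: SampleTable,
    design: DiallelDesign,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute the full analysis on a (raw or simulated) sample table."""
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(4)]

    normalized, report = normalize_pipeline(
        table, outlier_threshold=config.outlier_threshold, log_input=config.log_input
    )
    labels = crl_mod.assign_labels(normalized, None, design, alpha=config.alpha, adjust=config.adjust)
    labels = crl_mod.balance_filter(labels, max_same=config.max_same)
    xpp = screen_mod.build_xpp(normalized, design, seed=seeds[0])
    summary, _ = screen_mod.screen_metabolites(
        xpp,
        labels,
        methods=config.methods,
        k=config.k,
        reps=config.reps,
        seed=seeds[1],
        rule=config.rule,
        rf_trees=config.rf_trees,
        pls_components=config.pls_components,
    )
    predictable = list(summary.index[summary["predictable"]])
    ranking = None
    biomass_results = None
    if predictable:
        ranking = ranking_mod.rank_features(xpp, labels, predictable, rfe_steps=config.rfe_steps)
        schemes = [
            s
            for s in config.schemes
            if _scheme_feasible(s, len(xpp.feature_ids))
        ]
        bio = biomass_mod.hybrid_biomass(normalized, xpp)
        biomass_results = biomass_mod.run_validation(
            xpp,
            bio,
            ranking,
            schemes=tuple(schemes),
            reps=config.biomass_reps,
            seed=seeds[2],
            train_frac=config.train_frac,
        )
    return PipelineResult(
        config=config,
        design=design,
        normalized=normalized,
        normalization_report=report,
        crl=labels,
        xpp=xpp,
        screen_summary=summary,
        predictable=predictable,
        ranking=ranking,
        biomass_results=biomass_results,
    )


def _scheme_feasible(scheme: str, n_features: int) -> bool:
    m = biomass_mod._SCHEME_RE.match(scheme)
    if m is None:
        return False
    if scheme == "all":
        return True
    if m.group("topk") is not None:
        return int(m.group("topk")) <= n_features
    return int(m.group("pool")) <= n_features
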