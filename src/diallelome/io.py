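"""TSV / JSON readers and writers for the package's on-disk dialect.

Values table: tab-delimited UTF-8, first column the sample id, header row of
metabolite ids.  Design sheet columns are exactly ``sample, genotype, mother,
father, replicate, batch, biomass`` (mother/father empty for inbreds).
Ground-truth sidecars and reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import META_COLUMNS, GroundTruth, SampleTable

VALUES_FILE = "values.tsv"
DESIGN_FILE = "design.tsv"
TRUTH_FILE = "truth.json"
MANIFEST_FILE = "manifest.json"


def write_sample_table(table: SampleTable, directory: str | Path) -> dict:
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        values_path = directory / VALUES_FILE
        design_path = directory / DESIGN_FILE
        # %.17g round-trips float64 exactly
        table.values.rename_axis("sample").to_csv(values_path, sep="\t", float_format="%.17g")
        design = table.meta[META_COLUMNS].rename_axis("sample")
        design.to_csv(design_path, sep="\t", float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write fixture under {directory}: {exc}") from exc
    return {
        "files": [
            {"name": VALUES_FILE, "rows": int(table.values.shape[0]), "cols": int(table.values.shape[1])},
            {"name": DESIGN_FILE, "rows": int(table.meta.shape[0]), "cols": len(META_COLUMNS)},
        ]
    }


def read_sample_table(directory: str | Path) -> SampleTable:
    directory = Path(directory)
    values = pd.read_csv(
        directory / VALUES_FILE, sep="\t", index_col="sample", float_precision="round_trip"
    )
    meta = pd.read_csv(
        directory / DESIGN_FILE,
        sep="\t",
        index_col="sample",
        float_precision="round_trip",
        dtype={"genotype": str, "mother": str, "father": str},
        keep_default_na=False,
        na_values=[],
    )
    meta["replicate"] = meta["replicate"].astype(int)
    meta["batch"] = meta["batch"].astype(int)
    meta["biomass"] = meta["biomass"].astype(float)
    values.index = values.index.astype(str)
    meta.index = meta.index.astype(str)
    values.index.name = None
    meta.index.name = None
    return SampleTable(values, meta.loc[values.index])


def write_fixture(table: SampleTable, truth: GroundTruth, directory: str | Path) -> dict:
    """Write values + design sheet + ground-truth sidecar; return a manifest."""
    directory = Path(directory)
    manifest = write_sample_table(table, directory)
    truth_path = directory / TRUTH_FILE
    truth_path.write_text(truth.to_json(), encoding="utf-8")
    manifest["files"].append(
        {
            "name": TRUTH_FILE,
            "rows": int(truth.true_labels.shape[0]),
            "cols": int(truth.true_labels.shape[1]),
        }
    )
    (directory / MANIFEST_FILE).write_text(json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8")
    return manifest


def read_fixture(directory: str | Path) -> tuple[SampleTable, GroundTruth]:
    directory = Path(directory)
    table = read_sample_table(directory)
    truth = GroundTruth.from_json((directory / TRUTH_FILE).read_text(encoding="utf-8"))
    return table, truth
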