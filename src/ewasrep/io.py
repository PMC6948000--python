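"""TSV/JSON readers and writers for the pipeline's tabular interchange formats.

All matrices travel as TSV with probes as rows and a header row of sample
IDs; summary tables use the bit-stable column order
``probe_id, trait, cohort, ancestry, n, effect, se, p, ci_low, ci_high,
model_id``.  Writers and readers round-trip losslessly (floats are written
with full repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from ewasrep.concordance import GeneticAnnotation

SUMMARY_COLUMNS = [
    "probe_id",
    "trait",
    "cohort",
    "ancestry",
    "n",
    "effect",
    "se",
    "p",
    "ci_low",
    "ci_high",
    "model_id",
]


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.columns.name = "sample_id"
    return matrix


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_summary_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SUMMARY_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, sep="\t", index=False)


def read_summary_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ("probe_id", "effect", "se") if c not in table.columns]
    if missing:
        raise ValueError(f"summary table at {path} lacks required columns: {missing}")
    return table


def read_genetic_annotation(
    mqtl_path: str | Path,
    maf_path: str | Path,
    flags_path: str | Path | None = None,
) -> GeneticAnnotation:
    mqtl = pd.read_csv(mqtl_path, sep="\t")
    maf = pd.read_csv(maf_path, sep="\t")
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t")
    else:
        flags = pd.DataFrame(columns=["probe_id", "flag"])
    return GeneticAnnotation(mqtl=mqtl, maf=maf, flags=flags)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
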