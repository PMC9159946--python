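"""Readers and writers for the on-disk formats.

Barcode/clone tables travel as TSV, count matrices as Matrix Market (MTX)
with companion gene/cell TSVs, ground truth as JSON and configuration as
YAML.  Gzip is handled transparently by pandas.  All writers emit
deterministic column order; all readers validate and raise
:class:`~clonescar.tables.ValidationError` with the offending row or column
named.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .simulate import SimConfig, SimTruth, InvalidConfigError
from .tables import BarcodeCountTable, ValidationError

__all__ = [
    "read_barcode_table",
    "write_barcode_table",
    "read_clone_map",
    "write_clone_map",
    "read_count_matrix",
    "write_count_matrix",
    "read_sim_config",
    "write_sim_config",
    "write_truth",
]


def read_barcode_table(counts_path, samples_path=None) -> BarcodeCountTable:
    """Load a barcode x sample TSV plus its companion sample sheet.

    The first column holds barcode identifiers; remaining columns are
    samples.  Validation failures name the offending barcode or column.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = (
        pd.read_csv(samples_path, sep="\t") if samples_path is not None else None
    )
    return BarcodeCountTable(counts, samples)


def write_barcode_table(table: BarcodeCountTable, counts_path, samples_path=None):
    counts = table.counts.copy()
    counts.index.name = "barcode"
    counts.to_csv(counts_path, sep="\t")
    if samples_path is not None:
        cols = ["sample_id", "mouse_id", "compartment", "age_group", "sex"]
        table.samples[cols].to_csv(samples_path, sep="\t", index=False)


CLONE_MAP_COLUMNS = ["cell_id", "barcode_1", "barcode_2", "population"]


def read_clone_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in CLONE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"clone map {path} lacks column(s): {missing}")
    if df["cell_id"].duplicated().any():
        dup = df["cell_id"][df["cell_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicated cell_id in clone map: {dup!r}")
    return df


def write_clone_map(clone_map: pd.DataFrame, path):
    cols = [c for c in CLONE_MAP_COLUMNS + ["founder_id"] if c in clone_map.columns]
    clone_map[cols].to_csv(path, sep="\t", index=False)


def write_count_matrix(matrix: pd.DataFrame, prefix):
    """Write genes x cells counts as <prefix>.mtx + .genes.tsv + .cells.tsv."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sp = scipy.sparse.csc_matrix(matrix.to_numpy())
    scipy.io.mmwrite(str(prefix) + ".mtx", sp)
    pd.Series(matrix.index, name="gene").to_csv(
        str(prefix) + ".genes.tsv", sep="\t", index=False
    )
    pd.Series(matrix.columns, name="cell_id").to_csv(
        str(prefix) + ".cells.tsv", sep="\t", index=False
    )


def read_count_matrix(prefix) -> pd.DataFrame:
    prefix = str(prefix)
    mat = scipy.io.mmread(prefix + ".mtx").toarray().astype(np.int64)
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t")["gene"]
    cells = pd.read_csv(prefix + ".cells.tsv", sep="\t")["cell_id"]
    if mat.shape != (len(genes), len(cells)):
        raise ValidationError(
            f"matrix shape {mat.shape} does not match gene/cell lists "
            f"({len(genes)}, {len(cells)})"
        )
    return pd.DataFrame(mat, index=genes.to_numpy(), columns=cells.to_numpy())


# ---------------------------------------------------------------------------
# config and truth
# ---------------------------------------------------------------------------

def read_sim_config(path) -> SimConfig:
    """Load a YAML simulation config; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - known
    if unknown:
        raise InvalidConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = SimConfig(**data)
    cfg.validate()
    return cfg


def write_sim_config(config: SimConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def config_hash(config: SimConfig) -> str:
    blob = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_truth(truth: SimTruth, path):
    payload = {
        "null": truth.null,
        "founders": truth.founders.to_dict(orient="records"),
        "outcome_probs": [float(p) for p in truth.outcome_probs],
        "outcome_seqs": list(truth.outcome_seqs),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
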