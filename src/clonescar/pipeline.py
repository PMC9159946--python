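"""End-to-end pipeline driver: simulate -> extract -> cooccur -> lineage
-> signatures, with a provenance manifest.

Each stage reads its inputs from the run directory written by the previous
stage, so stages can be toggled and re-run individually; a rerun with the
same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cooccur import CooccurrenceModel
from .io import (
    config_hash,
    read_barcode_table,
    read_clone_map,
    write_barcode_table,
    write_clone_map,
    write_count_matrix,
    write_sim_config,
    write_truth,
)
from .lineage import LineageModel, background_frequency
from .simulate import Cohort, SimConfig, simulate_cohort, simulate_null_cohort
from .signatures import GeneSetCollection, derive_gene_sets, score_cells


@dataclasses.dataclass
class PipelineConfig:
    """Stage toggles and parameters for one pipeline run."""

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    null_cohort: bool = False
    run_cooccur: bool = True
    run_lineage: bool = True
    run_signatures: bool = True
    rare_threshold: int = 2
    alpha: float = 0.001
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed, sim=dataclasses.replace(self.sim, seed=seed)
        )


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the toggled stages and write outputs plus a manifest.

    Returns the manifest (config hash, seed, versions, per-stage row
    counts).  Any stage error aborts with a stage-tagged RuntimeError.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "clonescar_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_hash": config_hash(config.sim),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                manifest["stages"][name] = fn()
            except Exception as exc:  # pragma: no cover - error path
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return deco

    cohort_box = {}

    @stage("simulate")
    def _simulate():
        sim = dataclasses.replace(config.sim, seed=config.seed)
        cohort = (simulate_null_cohort if config.null_cohort else simulate_cohort)(sim)
        cohort_box["cohort"] = cohort
        write_sim_config(sim, out / "config.yaml")
        write_barcode_table(cohort.bulk, out / "bulk_counts.tsv",
                            out / "samples.tsv")
        write_truth(cohort.truth, out / "truth.json")
        for mouse, ds in cohort.sc.items():
            write_clone_map(ds.clone_map, out / f"clones_{mouse}.tsv")
            if ds.counts is not None:
                write_count_matrix(ds.counts, out / f"counts_{mouse}")
        return {
            "mice": sim.n_mice,
            "bulk_barcodes": int(cohort.bulk.counts.shape[0]),
            "sc_cells": int(sum(len(d.clone_map) for d in cohort.sc.values())),
        }

    cohort: Cohort = cohort_box["cohort"]

    if config.run_cooccur:
        @stage("cooccur")
        def _cooccur():
            res = CooccurrenceModel(cohort.bulk, config.rare_threshold).fit()
            res.P.to_csv(out / "cooccurrence_P.tsv", sep="\t")
            res.enrichment.to_csv(out / "enrichment.tsv", sep="\t")
            return {"samples": res.n_samples,
                    "defined_E_m": int(np.isfinite(res.enrichment["E_m"]).sum())}

    if config.run_lineage:
        @stage("lineage")
        def _lineage():
            bg = background_frequency(cohort.bulk)
            n_rows = n_sig = 0
            for mouse, ds in cohort.sc.items():
                res = LineageModel(ds.clone_map, bg, alpha=config.alpha).fit()
                res.table.to_csv(out / f"lineage_{mouse}.tsv", sep="\t",
                                 index=False)
                res.patterns.rename_axis("barcode").to_frame().to_csv(
                    out / f"patterns_{mouse}.tsv", sep="\t")
                n_rows += len(res.table)
                n_sig += int(res.table["significant"].sum())
            return {"tests": n_rows, "significant": n_sig}

    if config.run_signatures and config.sim.make_count_matrices:
        @stage("signatures")
        def _signatures():
            mouse, ds = next(iter(cohort.sc.items()))
            cluster_map = {
                "early_progenitor": ["EP"], "postnatal_progenitor": ["PP"],
                "cTEC": ["cTEC"], "mTEC": ["mTEC"],
            }
            clusters = pd.Series(
                ds.clone_map["population"].to_numpy(),
                index=ds.clone_map["cell_id"],
            )
            sets = derive_gene_sets(ds.counts, cluster_map, clusters)
            sets.to_frame().to_csv(out / "gene_sets.tsv", sep="\t", index=False)
            scores = score_cells(ds.counts, sets)
            scores.rename_axis("cell_id").to_csv(out / "cell_scores.tsv", sep="\t")
            return {"set_sizes": {k: len(v) for k, v in sets.as_dict().items()},
                    "scored_cells": len(scores)}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
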