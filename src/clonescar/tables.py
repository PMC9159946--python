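"""Shared tabular containers for bulk barcode count data.

The central object is :class:`BarcodeCountTable`, a validated pairing of a
barcode x sample integer count matrix with per-sample metadata (mouse,
compartment, age group, sex).  Bulk amplicon sequencing of sorted cTEC and
mTEC fractions produces one column per sample; downstream co-occurrence and
background-frequency computations consume this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_COMPARTMENTS = ("cTEC", "mTEC")

REQUIRED_SAMPLE_COLUMNS = ("sample_id", "mouse_id", "compartment")


class ValidationError(ValueError):
    """Raised when an on-disk or in-memory table violates its invariants."""


@dataclass
class BarcodeCountTable:
    """Barcode x sample counts with sample metadata.

    Parameters
    ----------
    counts
        DataFrame with unique barcode identifiers (scar sequences) as index
        and one integer column per sample.
    samples
        DataFrame with at least ``sample_id``, ``mouse_id`` and
        ``compartment`` columns; ``age_group`` and ``sex`` are optional and
        filled with ``"unknown"`` when absent.  Each mouse may contribute at
        most one cTEC and one mTEC sample.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts is None or self.counts.shape[1] == 0:
            raise ValidationError("count table has no sample columns")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicated barcode id: {dup!r}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if (vals < 0).any():
            bad = self.counts.index[(vals < 0).any(axis=1)][0]
            raise ValidationError(f"negative count in barcode row {bad!r}")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "barcode"
        zero_cols = self.counts.columns[self.counts.sum(axis=0) == 0]
        if len(zero_cols):
            raise ValidationError(
                f"sample column(s) with zero total count: {list(zero_cols)}"
            )
        if self.samples is None:
            # minimal metadata inferred from column names (sample_id only)
            self.samples = pd.DataFrame({"sample_id": list(self.counts.columns)})
        samples = self.samples.copy()
        for col in REQUIRED_SAMPLE_COLUMNS:
            if col not in samples.columns:
                if col == "sample_id":
                    raise ValidationError("sample sheet lacks 'sample_id' column")
                samples[col] = "unknown"
        for col in ("age_group", "sex"):
            if col not in samples.columns:
                samples[col] = "unknown"
        if samples["sample_id"].duplicated().any():
            dup = samples["sample_id"][samples["sample_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicated sample_id in sample sheet: {dup!r}")
        missing = set(self.counts.columns) - set(samples["sample_id"])
        if missing:
            raise ValidationError(
                f"count columns missing from sample sheet: {sorted(missing)}"
            )
        samples = samples.set_index("sample_id", drop=False)
        samples = samples.loc[list(self.counts.columns)]
        known = samples[samples["compartment"].isin(VALID_COMPARTMENTS)]
        dup_pairs = known.duplicated(subset=["mouse_id", "compartment"])
        if dup_pairs.any():
            row = known[dup_pairs].iloc[0]
            raise ValidationError(
                "mouse {0!r} contributes more than one {1} sample".format(
                    row["mouse_id"], row["compartment"]
                )
            )
        self.samples = samples

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def mice(self) -> list:
        return list(pd.unique(self.samples["mouse_id"]))

    def sample_for(self, mouse_id, compartment: str):
        """Return the sample_id of *mouse_id*'s sample in *compartment*, or None."""
        sel = self.samples[
            (self.samples["mouse_id"] == mouse_id)
            & (self.samples["compartment"] == compartment)
        ]
        if len(sel) == 0:
            return None
        return sel["sample_id"].iloc[0]

    def relative_frequencies(self) -> pd.DataFrame:
        """Per-sample relative barcode frequencies (each column sums to 1)."""
        return self.counts / self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "BarcodeCountTable":
        sub = self.counts[list(sample_ids)]
        sub = sub[sub.sum(axis=1) > 0]
        meta = self.samples.loc[list(sample_ids)].reset_index(drop=True)
        return BarcodeCountTable(sub, meta)
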