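"""Binomial over-representation lineage inference.

Single-cell datasets attach a scar barcode and a population label (early
progenitor EP, postnatal progenitor PP, mature cTEC, mature mTEC) to each
cell.  A barcode carried by ``c_b,i`` of the ``C_i`` barcode-carrying cells
of population *i* is tested for over-representation against its background
frequency ``f_b`` -- the mean of its per-sample relative frequencies across
bulk samples -- via the right tail of Binomial(C_i, f_b).  P values are
Benjamini-Hochberg corrected jointly over all (barcode, population) tests of
a dataset, and barcodes with adjusted P < 0.001 are flagged; the pattern of
flags across populations names the clone's inferred behaviour (bipotent,
lineage-biased, dormant, compartment-private).

Cells with two barcodes contribute an ordered barcode pair whose background
frequency is the product of the two singleton frequencies; cells with more
than two barcodes are excluded upstream (doublets/errors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import BarcodeCountTable, ValidationError

__all__ = [
    "BackgroundFrequencies",
    "CloneAssignment",
    "background_frequency",
    "binomial_right_tail",
    "barcode_population_tests",
    "classify_barcode_patterns",
    "LineageModel",
    "LineageResults",
]

logger = logging.getLogger(__name__)

DEFAULT_POPULATIONS = ("EP", "PP", "cTEC", "mTEC")
PAIR_SEP = "|"


@dataclass
class BackgroundFrequencies:
    """Background barcode frequencies f_b averaged over bulk samples."""

    f: pd.Series  # barcode -> frequency
    n_samples: int
    sample_ids: list

    def __getitem__(self, barcode) -> float:
        return float(self.f.get(barcode, 0.0))

    def __contains__(self, barcode) -> bool:
        return barcode in self.f.index


def background_frequency(bulk: BarcodeCountTable) -> BackgroundFrequencies:
    """Unweighted mean of per-sample relative frequencies.

    Each sample's count column is normalised to sum to 1 before averaging,
    so deeply and shallowly sequenced samples contribute equally.  Barcodes
    absent from every sample would get f_b = 0 and are excluded from
    testing (the table only carries observed barcodes).
    """
    if bulk.counts.shape[0] == 0:
        raise ValidationError("empty bulk table: no barcodes to average")
    rel = bulk.relative_frequencies()
    f = rel.mean(axis=1)
    f = f[f > 0]
    return BackgroundFrequencies(f, bulk.n_samples, bulk.sample_ids)


@dataclass
class CloneAssignment:
    """Barcode (or barcode pair) x population cell counts for one dataset."""

    counts: pd.DataFrame  # barcode-key x population, c_b,i
    totals: pd.Series  # population -> C_i
    is_pair: pd.Series  # barcode-key -> bool
    n_discarded_multi: int = 0

    @classmethod
    def from_clone_map(
        cls, clone_map: pd.DataFrame, populations=DEFAULT_POPULATIONS
    ) -> "CloneAssignment":
        """Aggregate a per-cell clone map.

        Expects columns ``cell_id, barcode_1, barcode_2, population``;
        barcode_2 may be empty/NaN.  A cell with two barcodes counts once
        under the (order-normalised) pair key ``b1|b2``.
        """
        cm = clone_map.copy()
        cm["barcode_2"] = cm.get("barcode_2", "").fillna("") if "barcode_2" in cm else ""
        keep = cm["barcode_1"].notna() & (cm["barcode_1"] != "")
        cm = cm[keep]

        def key(row):
            b1, b2 = row
            if b2:
                return PAIR_SEP.join(sorted([b1, b2]))
            return b1

        keys = [key(t) for t in zip(cm["barcode_1"], cm["barcode_2"])]
        cm = cm.assign(_key=keys)
        counts = (
            cm.groupby(["_key", "population"], sort=True)
            .size()
            .unstack(fill_value=0)
            .reindex(columns=list(populations), fill_value=0)
        )
        counts.index.name = "barcode"
        totals = counts.sum(axis=0)
        is_pair = pd.Series(
            [PAIR_SEP in k for k in counts.index], index=counts.index
        )
        return cls(counts, totals, is_pair)


def binomial_right_tail(c: int, C: int, f: float) -> float:
    """P(X >= c) for X ~ Binomial(C, f), computed via the survival function.

    The survival function is evaluated directly (not as 1 - CDF) so small
    right tails keep full relative precision.
    """
    if not 0 <= c <= C:
        raise ValueError(f"need 0 <= c <= C, got c={c}, C={C}")
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"need 0 <= f <= 1, got f={f}")
    if c == 0:
        return 1.0
    return float(stats.binom.sf(c - 1, C, f))


def barcode_population_tests(
    clones: CloneAssignment,
    bg: BackgroundFrequencies,
    alpha: float = 0.001,
    joint_family: bool = True,
) -> pd.DataFrame:
    """Right-tail binomial tests for every (barcode, population) pair.

    Pairs of barcodes use the product of the singleton background
    frequencies.  BH correction is applied jointly over all tests of the
    dataset by default (``joint_family=False`` switches to per-population
    families for sensitivity analysis).  Barcodes without any background
    frequency are excluded from testing and reported with status
    "bulk_unseen" (a zero-background binomial is degenerate; such barcodes
    may simply be too rare for reliable bulk sampling).

    Returns a long-format frame with raw/adjusted P, -log10(adjusted P) and
    significance flags at *alpha*.
    """
    rows = []
    unseen = []
    for key in clones.counts.index:
        if PAIR_SEP in key:
            b1, b2 = key.split(PAIR_SEP)
            if b1 in bg and b2 in bg:
                f = bg[b1] * bg[b2]
            else:
                unseen.append(key)
                continue
        elif key in bg:
            f = bg[key]
        else:
            unseen.append(key)
            continue
        for pop in clones.counts.columns:
            c = int(clones.counts.loc[key, pop])
            C = int(clones.totals[pop])
            rows.append(
                {
                    "barcode": key,
                    "population": pop,
                    "c": c,
                    "C": C,
                    "f": f,
                    "p_raw": binomial_right_tail(c, C, f),
                }
            )
    if unseen:
        logger.warning(
            "%d barcode(s) absent from bulk background excluded (bulk-unseen)",
            len(unseen),
        )
    table = pd.DataFrame(
        rows, columns=["barcode", "population", "c", "C", "f", "p_raw"]
    )
    if len(table) == 0:
        table["p_adj"] = []
        table["neglog10_p_adj"] = []
        table["significant"] = []
        table.attrs["bulk_unseen"] = unseen
        return table
    if joint_family:
        table["p_adj"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    else:
        table["p_adj"] = np.nan
        for pop, idx in table.groupby("population").groups.items():
            table.loc[idx, "p_adj"] = multipletests(
                table.loc[idx, "p_raw"], method="fdr_bh"
            )[1]
    table["neglog10_p_adj"] = -np.log10(np.maximum(table["p_adj"], 1e-300))
    table["significant"] = table["p_adj"] < alpha
    table.attrs["bulk_unseen"] = unseen
    return table


def classify_barcode_patterns(
    matrix: pd.DataFrame, populations=DEFAULT_POPULATIONS
) -> pd.Series:
    """Deterministic clone-behaviour label from the per-population flags.

    Label grammar (progenitor prefix: "early" if EP flagged, "postnatal" if
    PP, "dual" if both):

    * progenitor + both mature compartments  -> "<prefix> bipotent"
    * progenitor + one mature compartment    -> "<prefix> {cTEC,mTEC}-biased"
    * progenitor only                        -> "<prefix> dormant"
    * mature compartment(s) only             -> "{cTEC,mTEC,bilateral}-private"
    * nothing significant                    -> "unclassified"
    """
    flags = (
        matrix.pivot_table(
            index="barcode", columns="population", values="significant",
            aggfunc="any", fill_value=False,
        )
        .reindex(columns=list(populations), fill_value=False)
        .astype(bool)
    )
    labels = {}
    for b, row in flags.iterrows():
        ep, pp, ct, mt = (bool(row[p]) for p in ("EP", "PP", "cTEC", "mTEC"))
        if ep and pp:
            prefix = "dual"
        elif ep:
            prefix = "early"
        elif pp:
            prefix = "postnatal"
        else:
            prefix = None
        if prefix is not None:
            if ct and mt:
                labels[b] = f"{prefix} bipotent"
            elif ct:
                labels[b] = f"{prefix} cTEC-biased"
            elif mt:
                labels[b] = f"{prefix} mTEC-biased"
            else:
                labels[b] = f"{prefix} dormant"
        else:
            if ct and mt:
                labels[b] = "bilateral-private"
            elif ct:
                labels[b] = "cTEC-private"
            elif mt:
                labels[b] = "mTEC-private"
            else:
                labels[b] = "unclassified"
    return pd.Series(labels, name="pattern")


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class LineageModel:
    """Over-representation analysis of one single-cell dataset.

    Parameters
    ----------
    clones
        :class:`CloneAssignment` (or a per-cell clone map DataFrame, which
        is aggregated automatically).
    background
        :class:`BackgroundFrequencies` or a bulk
        :class:`~clonescar.tables.BarcodeCountTable` to derive them from.
    alpha
        Adjusted-P significance cutoff (default 0.001).
    joint_family
        BH family: one joint family across all barcode x population tests
        (default) or per-population families.
    """

    def __init__(self, clones, background, alpha: float = 0.001,
                 joint_family: bool = True,
                 populations=DEFAULT_POPULATIONS):
        if isinstance(clones, pd.DataFrame):
            clones = CloneAssignment.from_clone_map(clones, populations)
        if isinstance(background, BarcodeCountTable):
            background = background_frequency(background)
        self.clones = clones
        self.background = background
        self.alpha = alpha
        self.joint_family = joint_family
        self.populations = populations

    def fit(self) -> "LineageResults":
        table = barcode_population_tests(
            self.clones, self.background, self.alpha, self.joint_family
        )
        patterns = classify_barcode_patterns(table, self.populations)
        return LineageResults(self, table, patterns)


@dataclass
class LineageResults:
    """Lineage call matrix with clone-pattern labels and a text summary."""

    model: LineageModel
    table: pd.DataFrame
    patterns: pd.Series

    @property
    def bulk_unseen(self) -> list:
        return list(self.table.attrs.get("bulk_unseen", []))

    def matrix(self, value: str = "neglog10_p_adj") -> pd.DataFrame:
        """Barcode x population matrix of the chosen column (heatmap-ready)."""
        return self.table.pivot_table(
            index="barcode", columns="population", values=value
        ).reindex(columns=list(self.model.populations))

    def significant_calls(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        sig = self.significant_calls()
        pattern_counts = self.patterns.value_counts()
        lines = [
            "Lineage over-representation summary",
            "===================================",
            f"tests: {len(self.table)}  barcodes: {self.table['barcode'].nunique()}  "
            f"alpha (BH-adjusted): {self.model.alpha}",
            f"significant calls: {len(sig)}  bulk-unseen barcodes: "
            f"{len(self.bulk_unseen)}",
            "clone patterns:",
        ]
        for name, n in pattern_counts.items():
            lines.append(f"  {name:<22s} {n}")
        return "\n".join(lines)

    def plot_calls(self, ax=None):
        """Heatmap of -log10 adjusted P for barcodes with >= 1 significant call."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mat = self.matrix()
        keep = self.table.groupby("barcode")["significant"].any()
        mat = mat.loc[keep[keep].index]
        im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(mat.shape[1]), mat.columns)
        ax.set_ylabel("barcode")
        plt.colorbar(im, ax=ax, label=r"$-\log_{10}$ adjusted $P$")
        return ax
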