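"""Rare-barcode co-occurrence and per-mouse enrichment statistics.

Shared clonal origin of the cortical and medullary TEC compartments leaves a
signature in bulk barcode tables: rare barcodes (observed no more than twice
across all samples) co-occur in the cTEC and mTEC samples of the same mouse
far more often than in samples from different mice.  The statistics are

* ``P_ij = |B_i ∩ B_j| / |B_i|`` -- the fraction of sample *i*'s rare
  barcodes also present in sample *j*;
* ``E_m`` -- the per-mouse enrichment of same-mouse over cross-mouse
  co-occurrence, the maximum of the two directional ratios with the cTEC or
  mTEC sample of mouse *m* as reference, each denominator being the mean of
  ``P`` over the N-2 samples of all other mice;
* a one-sided exact Wilcoxon rank-sum comparison of enrichment values
  between age groups.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tables import BarcodeCountTable, ValidationError

__all__ = [
    "RareBarcodeSets",
    "rare_barcode_sets",
    "cooccurrence_probability",
    "cooccurrence_matrix",
    "enrichment_value",
    "compare_age_groups",
    "CooccurrenceModel",
    "CooccurrenceResults",
]

logger = logging.getLogger(__name__)


@dataclass
class RareBarcodeSets:
    """Per-sample sets of rare barcodes.

    ``sets[i]`` contains the barcodes with at least one count in sample *i*
    whose total abundance across ALL samples does not exceed ``threshold``
    (counted in reads by default, or in number of samples of occurrence with
    ``count_mode="samples"``).
    """

    sets: dict
    threshold: int = 2
    count_mode: str = "reads"

    def __getitem__(self, sample_id):
        return self.sets[sample_id]

    @property
    def sample_ids(self):
        return list(self.sets)


def rare_barcode_sets(
    table: BarcodeCountTable, threshold: int = 2, count_mode: str = "reads"
) -> RareBarcodeSets:
    """Extract the rare-barcode set B_i of every sample.

    ``count_mode="reads"`` (default) takes "observed no more than twice"
    to mean total read occurrences across all samples; ``"samples"`` counts
    the number of samples a barcode appears in instead.
    """
    if threshold < 1:
        raise ValidationError(f"rarity threshold must be >= 1, got {threshold}")
    if count_mode not in ("reads", "samples"):
        raise ValidationError(f"unknown count_mode: {count_mode!r}")
    counts = table.counts
    if count_mode == "reads":
        total = counts.sum(axis=1)
    else:
        total = (counts > 0).sum(axis=1)
    rare = total <= threshold
    sets = {}
    present = counts > 0
    for s in counts.columns:
        sets[s] = frozenset(counts.index[rare & present[s]])
    return RareBarcodeSets(sets, threshold, count_mode)


def cooccurrence_probability(sets: RareBarcodeSets, i, j) -> float:
    """P_ij = |B_i ∩ B_j| / |B_i|; NaN when B_i is empty (undefined)."""
    bi, bj = sets[i], sets[j]
    if not bi:
        logger.info("empty rare-barcode set for sample %s; P undefined", i)
        return float("nan")
    return len(bi & bj) / len(bi)


def cooccurrence_matrix(sets: RareBarcodeSets) -> pd.DataFrame:
    ids = sets.sample_ids
    P = pd.DataFrame(np.nan, index=ids, columns=ids)
    for i in ids:
        for j in ids:
            P.loc[i, j] = cooccurrence_probability(sets, i, j)
    return P


def enrichment_value(
    P: pd.DataFrame, table: BarcodeCountTable, mouse
) -> tuple[float, str]:
    """Enrichment E_m of same-mouse over cross-mouse co-occurrence.

    Numerators are the same-mouse probabilities P(m_cTEC, m_mTEC) and
    P(m_mTEC, m_cTEC); each denominator is the mean of P over all samples j
    that belong to other mice (normalisation 1/(N-2), with undefined P
    excluded from the average and N reduced accordingly).  E_m is the
    maximum of the two directional ratios.

    Returns ``(value, reason)`` where reason is "" when defined, else a
    short explanation.  A zero denominator with positive numerator yields
    +inf (flagged via reason "zero_denominator") to preserve ordering for
    rank-based comparisons.
    """
    c = table.sample_for(mouse, "cTEC")
    m = table.sample_for(mouse, "mTEC")
    if c is None or m is None:
        return float("nan"), "missing_compartment_sample"
    others = [s for s in table.sample_ids if s not in (c, m)]
    if len(others) < 2:
        return float("nan"), "too_few_samples"
    ratios = []
    flagged_inf = False
    for ref in (c, m):
        num = P.loc[ref, m if ref == c else c]
        cross = P.loc[ref, others].to_numpy(dtype=float)
        cross = cross[~np.isnan(cross)]
        if np.isnan(num) or cross.size == 0:
            continue
        denom = cross.mean()
        if denom == 0:
            if num > 0:
                ratios.append(float("inf"))
                flagged_inf = True
            # 0/0 contributes nothing
            continue
        ratios.append(num / denom)
    if not ratios:
        return float("nan"), "undefined_probabilities"
    return max(ratios), ("zero_denominator" if flagged_inf else "")


# ---------------------------------------------------------------------------
# exact one-sided rank-sum comparison
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 25


def compare_age_groups(
    younger, older, exact_limit: int = _EXACT_LIMIT
) -> dict:
    """One-sided Wilcoxon rank-sum test that the older group's E_m are larger.

    For combined sample sizes up to *exact_limit* the P value is exact:
    ``P(W >= W_obs)`` by full enumeration of group assignments over average
    ranks (ties handled naturally).  When the permutation distribution is
    degenerate (e.g. identical groups) the convention P = 0.5 is returned.
    Larger samples use the normal approximation with tie correction and
    continuity correction.  Infinite enrichment values are rank-safe and
    kept.
    """
    y = np.asarray([v for v in np.asarray(younger, dtype=float) if not math.isnan(v)])
    o = np.asarray([v for v in np.asarray(older, dtype=float) if not math.isnan(v)])
    if len(y) < 3 or len(o) < 3:
        raise ValidationError("each age group needs >= 3 defined enrichment values")
    pooled = np.concatenate([y, o])
    ranks = stats.rankdata(pooled)
    n, n_o = len(pooled), len(o)
    w_obs = ranks[len(y):].sum()
    if n <= exact_limit:
        # chunked full enumeration of group assignments (memory-bounded)
        total = n_ge = 0
        w_min = math.inf
        w_max = -math.inf
        it = itertools.combinations(range(n), n_o)
        while True:
            chunk = list(itertools.islice(it, 200_000))
            if not chunk:
                break
            w_perm = ranks[np.asarray(chunk, dtype=np.intp)].sum(axis=1)
            total += w_perm.size
            n_ge += int((w_perm >= w_obs - 1e-12).sum())
            w_min = min(w_min, float(w_perm.min()))
            w_max = max(w_max, float(w_perm.max()))
        if w_max == w_min:
            return {"p_value": 0.5, "statistic": float(w_obs), "method": "degenerate"}
        return {
            "p_value": n_ge / total,
            "statistic": float(w_obs),
            "method": "exact",
        }
    # normal approximation with tie correction
    n_y = len(y)
    mu = n_o * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = n_y * n_o / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return {"p_value": 0.5, "statistic": float(w_obs), "method": "degenerate"}
    z = (w_obs - mu - 0.5) / math.sqrt(var)
    return {
        "p_value": float(stats.norm.sf(z)),
        "statistic": float(w_obs),
        "method": "normal_tie_corrected",
    }


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class CooccurrenceModel:
    """Co-occurrence analysis of a bulk barcode count table.

    Parameters
    ----------
    table
        Validated :class:`~clonescar.tables.BarcodeCountTable`.
    rare_threshold
        Maximum total abundance for a barcode to count as rare (default 2).
    count_mode
        "reads" (total read occurrences, default) or "samples".
    """

    def __init__(self, table: BarcodeCountTable, rare_threshold: int = 2,
                 count_mode: str = "reads"):
        self.table = table
        self.rare_threshold = rare_threshold
        self.count_mode = count_mode

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, samples: pd.DataFrame, **kw):
        return cls(BarcodeCountTable(counts, samples), **kw)

    def fit(self) -> "CooccurrenceResults":
        sets = rare_barcode_sets(self.table, self.rare_threshold, self.count_mode)
        P = cooccurrence_matrix(sets)
        rows = []
        for mouse in self.table.mice():
            e, reason = enrichment_value(P, self.table, mouse)
            meta = self.table.samples[self.table.samples["mouse_id"] == mouse]
            rows.append(
                {
                    "mouse_id": mouse,
                    "E_m": e,
                    "reason": reason,
                    "age_group": meta["age_group"].iloc[0],
                    "sex": meta["sex"].iloc[0],
                }
            )
        enrichment = pd.DataFrame(rows).set_index("mouse_id")
        return CooccurrenceResults(self, sets, P, enrichment)


@dataclass
class CooccurrenceResults:
    """Fitted co-occurrence statistics with a text summary."""

    model: CooccurrenceModel
    rare_sets: RareBarcodeSets
    P: pd.DataFrame
    enrichment: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return len(self.P)

    def same_mouse_pairs(self) -> list:
        pairs = []
        for mouse in self.model.table.mice():
            c = self.model.table.sample_for(mouse, "cTEC")
            m = self.model.table.sample_for(mouse, "mTEC")
            if c is not None and m is not None:
                pairs.append((c, m))
        return pairs

    @staticmethod
    def _mean_defined(vals) -> float:
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        return float(arr.mean()) if arr.size else float("nan")

    def mean_same_mouse_P(self) -> float:
        vals = []
        for c, m in self.same_mouse_pairs():
            vals.extend([self.P.loc[c, m], self.P.loc[m, c]])
        return self._mean_defined(vals)

    def mean_cross_mouse_P(self) -> float:
        mouse_of = self.model.table.samples["mouse_id"]
        vals = []
        for i in self.P.index:
            for j in self.P.columns:
                if i != j and mouse_of[i] != mouse_of[j]:
                    vals.append(self.P.loc[i, j])
        return self._mean_defined(vals)

    def compare_age_groups(self, younger: str, older: str) -> dict:
        e = self.enrichment
        return compare_age_groups(
            e.loc[e["age_group"] == younger, "E_m"],
            e.loc[e["age_group"] == older, "E_m"],
        )

    def summary(self) -> str:
        e = self.enrichment["E_m"]
        defined = e[np.isfinite(e)]
        lines = [
            "Rare-barcode co-occurrence summary",
            "==================================",
            f"samples: {self.n_samples}   mice: {len(self.enrichment)}   "
            f"rarity threshold: {self.model.rare_threshold} "
            f"({self.model.count_mode})",
            f"mean same-mouse P_ij : {self.mean_same_mouse_P():.4f}",
            f"mean cross-mouse P_ij: {self.mean_cross_mouse_P():.4f}",
            f"enrichment E_m (defined n={len(defined)}): "
            f"median {defined.median():.2f}, mean {defined.mean():.2f}"
            if len(defined)
            else "enrichment E_m: no defined values",
        ]
        return "\n".join(lines)

    def plot_enrichment(self, ax=None):
        """Box plot of E_m by age group (matplotlib, created on demand)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        e = self.enrichment
        groups = [g for g, _ in e.groupby("age_group")]
        data = [grp["E_m"][np.isfinite(grp["E_m"])] for _, grp in e.groupby("age_group")]
        ax.boxplot(data, tick_labels=groups)
        ax.set_ylabel("enrichment $E_m$")
        ax.axhline(1.0, ls="--", c="grey", lw=0.8)
        return ax
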