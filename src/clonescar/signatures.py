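"""UMI conversion, QC, NB differential expression and gene-set scoring.

This module carries the transcriptome side of the analysis: observed UMI
counts are corrected for tag collisions over the 4096-tag space (6 nt UMIs),
cells and genes pass the study's QC rules, four population gene sets (early
progenitor, postnatal progenitor, cTEC, mTEC) are derived by one-vs-rest
negative-binomial differential expression, per-cell signature scores are
summed transcript counts over those sets, and clusters are placed in the
EP/PP x C/M log-ratio coordinate system relative to a reference dataset.

Count matrices are plain DataFrames with genes as rows and cells as columns.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "umi_to_transcripts",
    "qc_filter_cells",
    "qc_filter_genes",
    "diffexp_nb",
    "derive_gene_sets",
    "score_cells",
    "cluster_ratio_coordinates",
    "GeneSetCollection",
]

logger = logging.getLogger(__name__)

UMI_SPACE = 4096  # 4^6 possible 6 nt tags

POPULATION_SETS = ("early_progenitor", "postnatal_progenitor", "cTEC", "mTEC")

# identifier patterns never admitted to gene sets
DEFAULT_ID_EXCLUSIONS = ("Gm*", "*Rik")
# heat-shock families excluded from the final lists: elevated in both
# progenitor types, hence uninformative for separating them
DEFAULT_HEATSHOCK_PATTERNS = ("Hspa*", "Hspb*", "Hsph*", "Dnaj*")


# ---------------------------------------------------------------------------
# UMI saturation correction
# ---------------------------------------------------------------------------

def umi_to_transcripts(k, K: int = UMI_SPACE):
    """Convert observed UMI counts to transcript estimates.

    With t transcripts labelled uniformly at random by one of K tags, the
    expected number of distinct observed tags is K(1 - (1 - 1/K)^t);
    inverting (in the Poissonised form) gives

        t = -K * ln(1 - k / K)

    which is 0 at k = 0, monotone and convex in k, and >= k for k >= 1.
    Saturated counts k = K are evaluated at K - 0.5.  Accepts scalars or
    arrays; raises for k > K.
    """
    arr = np.asarray(k, dtype=float)
    if np.any(arr < 0) or np.any(arr > K):
        raise ValueError(f"UMI counts must lie in [0, K={K}]")
    arr = np.where(arr >= K, K - 0.5, arr)
    out = -K * np.log1p(-arr / K)
    return float(out) if np.isscalar(k) else out


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def downsample_counts(matrix: pd.DataFrame, target: Optional[int] = None,
                      seed: int = 0) -> pd.DataFrame:
    """Multinomial downsampling of every cell to a common total.

    Each cell's counts are subsampled without replacement (multivariate
    hypergeometric) to *target* (default: the minimum per-cell total), the
    established meaning of "normalised by downscaling" in plate-based UMI
    pipelines.  Seeded and deterministic.
    """
    totals = matrix.sum(axis=0).to_numpy()
    if target is None:
        target = int(totals.min())
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD05A]))
    out = np.empty(matrix.shape, dtype=np.int64)
    vals = matrix.to_numpy().astype(np.int64)
    for j in range(matrix.shape[1]):
        col = vals[:, j]
        tot = int(col.sum())
        if tot <= target:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, target,
                                                        method="marginals")
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def qc_filter_cells(
    matrix: pd.DataFrame,
    min_total: int,
    kcnq1ot1_max_frac: float = 0.02,
    anchor: str = "Kcnq1ot1",
    normalize: str = "downsample",
    seed: int = 0,
) -> pd.DataFrame:
    """Remove low-quality cells and normalise the survivors.

    Cells with fewer than *min_total* transcripts are discarded (the cutoff
    is dataset-specific configuration), as are cells in which the
    low-quality marker *anchor* exceeds *kcnq1ot1_max_frac* of transcripts.
    Remaining counts are normalised by downscaling every cell to the
    minimum retained total (``normalize="scale"`` switches to simple
    rescaling for speed; ``"none"`` skips normalisation).
    """
    totals = matrix.sum(axis=0)
    keep = totals >= min_total
    if anchor in matrix.index:
        frac = matrix.loc[anchor] / totals.replace(0, np.nan)
        keep &= ~(frac > kcnq1ot1_max_frac)
    kept = matrix.loc[:, keep[keep].index]
    if kept.shape[1] == 0:
        raise ValueError(
            f"all {matrix.shape[1]} cells removed by QC "
            f"(min_total={min_total}, {anchor} > {kcnq1ot1_max_frac:.0%})"
        )
    if normalize == "downsample":
        return downsample_counts(kept, seed=seed)
    if normalize == "scale":
        target = kept.sum(axis=0).min()
        return kept * (target / kept.sum(axis=0))
    return kept


def _matches_any(names: pd.Index, patterns: Iterable[str]) -> np.ndarray:
    mask = np.zeros(len(names), dtype=bool)
    for pat in patterns:
        mask |= np.fromiter(
            (fnmatch.fnmatch(n, pat) for n in names), dtype=bool, count=len(names)
        )
    return mask


def qc_filter_genes(
    matrix: pd.DataFrame,
    anchor: str = "Kcnq1ot1",
    corr_threshold: float = 0.65,
    exclusions: Iterable[str] = ("Jun", "Fos", "Gm*", "mt-*", "Hprt"),
) -> pd.DataFrame:
    """Remove QC-problematic genes.

    Drops the low-quality anchor gene itself, genes whose expression has a
    Pearson correlation > *corr_threshold* with the anchor across cells,
    and every gene matching the exclusion patterns (immediate-early genes,
    predicted-gene identifiers, mitochondrial genes and the edited locus
    itself by default).  If the anchor is absent the correlation step is
    skipped with a warning.
    """
    drop = _matches_any(matrix.index, exclusions)
    if anchor in matrix.index:
        x = matrix.loc[anchor].to_numpy(dtype=float)
        vals = matrix.to_numpy(dtype=float)
        xc = x - x.mean()
        vc = vals - vals.mean(axis=1, keepdims=True)
        denom = np.sqrt((vc ** 2).sum(axis=1) * (xc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (vc @ xc) / denom, 0.0)
        drop |= r > corr_threshold
        drop |= matrix.index == anchor
    else:
        logger.warning("anchor gene %r absent; skipping correlation filter", anchor)
    return matrix.loc[~drop]


# ---------------------------------------------------------------------------
# NB differential expression
# ---------------------------------------------------------------------------

def _fit_dispersion_trend(matrix: pd.DataFrame) -> float:
    """Least-squares coefficient a of the background trend v(m) = m + a m^2.

    Fitted across genes on per-cell means/variances; this quadratic
    mean-variance law is the minimal background model for plate-based UMI
    count variability.
    """
    vals = matrix.to_numpy(dtype=float)
    m = vals.mean(axis=1)
    v = vals.var(axis=1, ddof=1)
    keep = m > 0
    m, v = m[keep], v[keep]
    num = float((m ** 2 * (v - m)).sum())
    den = float((m ** 4).sum())
    a = num / den if den > 0 else 0.0
    return max(a, 1e-6)


def diffexp_nb(
    matrix: pd.DataFrame,
    group_a,
    group_b,
    dispersion: Optional[float] = None,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Two-sided NB test per gene between two cell groups.

    Under the null both groups share the gene's pooled per-cell mean m with
    variance following the background trend v(m) = m + a*m^2 (a fitted
    across genes unless *dispersion* is given).  The group-A total is
    compared to NB(mean = n_A * m, size = n_A / a); the two-sided P value
    doubles the smaller tail.  log2 fold changes are (b + pc) / (a + pc) on
    per-cell means.  Genes with zero counts in both groups get P = 1 and
    fold change 0 by convention.  BH adjustment runs over all tested genes.
    """
    sub = matrix[list(group_a) + list(group_b)]
    if len(group_a) < 5 or len(group_b) < 5:
        raise ValueError("both groups need >= 5 cells")
    a_disp = dispersion if dispersion is not None else _fit_dispersion_trend(sub)
    va = matrix[list(group_a)].to_numpy(dtype=float)
    vb = matrix[list(group_b)].to_numpy(dtype=float)
    n_a, n_b = va.shape[1], vb.shape[1]
    k_a, k_b = va.sum(axis=1), vb.sum(axis=1)
    mean_a, mean_b = k_a / n_a, k_b / n_b
    m = (k_a + k_b) / (n_a + n_b)

    mu = n_a * m
    r = n_a / a_disp
    with np.errstate(divide="ignore", invalid="ignore"):
        p_nb = r / (r + mu)
        lower = stats.nbinom.cdf(k_a, r, p_nb)
        upper = stats.nbinom.sf(k_a - 1, r, p_nb)
    p_raw = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    zero = (k_a + k_b) == 0
    p_raw[zero] = 1.0
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    log2fc[zero] = 0.0
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fold_change": log2fc,
            "p_raw": p_raw,
        },
        index=matrix.index,
    )
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Four population gene lists (EP/cTEC overlap removed from EP)."""

    early_progenitor: list = field(default_factory=list)
    postnatal_progenitor: list = field(default_factory=list)
    cTEC: list = field(default_factory=list)
    mTEC: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "early_progenitor": list(self.early_progenitor),
            "postnatal_progenitor": list(self.postnatal_progenitor),
            "cTEC": list(self.cTEC),
            "mTEC": list(self.mTEC),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "set": name}
            for name, genes in self.as_dict().items()
            for g in genes
        ]
        return pd.DataFrame(rows, columns=["gene", "set"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GeneSetCollection":
        d = {name: list(sub["gene"]) for name, sub in frame.groupby("set")}
        return cls(**{k: d.get(k, []) for k in POPULATION_SETS})


def derive_gene_sets(
    matrix: pd.DataFrame,
    cluster_map: dict,
    clusters: pd.Series,
    p_threshold: float = 0.01,
    log2fc_threshold: float = 1.0,
    id_exclusions: Iterable[str] = DEFAULT_ID_EXCLUSIONS,
    heatshock_patterns: Iterable[str] = DEFAULT_HEATSHOCK_PATTERNS,
    dispersion: Optional[float] = None,
) -> GeneSetCollection:
    """One-vs-rest NB differential expression per population.

    *cluster_map* maps population names (``early_progenitor``,
    ``postnatal_progenitor``, ``cTEC``, ``mTEC``) to lists of cluster ids;
    *clusters* labels each cell (index = cell ids).  Genes enter a set with
    adjusted P < *p_threshold* and log2 fold change strictly greater than
    *log2fc_threshold* (boundary values are excluded), minus predicted-gene
    identifiers (Gm*/...Rik), minus heat-shock families, and with the
    EP ∩ cTEC overlap removed from the EP set.
    """
    clusters = clusters.reindex(matrix.columns)
    raw_sets = {}
    for pop in POPULATION_SETS:
        ids = cluster_map.get(pop, [])
        in_pop = clusters.isin(ids)
        cells_pop = list(clusters.index[in_pop])
        cells_rest = list(clusters.index[~in_pop])
        if len(cells_pop) < 5 or len(cells_rest) < 5:
            logger.warning("population %s has too few cells; empty set", pop)
            raw_sets[pop] = []
            continue
        de = diffexp_nb(matrix, cells_rest, cells_pop, dispersion=dispersion)
        hits = de[(de["p_adj"] < p_threshold)
                  & (de["log2_fold_change"] > log2fc_threshold)]
        names = hits.index
        drop = _matches_any(names, list(id_exclusions) + list(heatshock_patterns))
        raw_sets[pop] = sorted(names[~drop])
        if not raw_sets[pop]:
            logger.warning("empty gene set for population %s", pop)
    ep = [g for g in raw_sets["early_progenitor"] if g not in set(raw_sets["cTEC"])]
    return GeneSetCollection(
        early_progenitor=ep,
        postnatal_progenitor=raw_sets["postnatal_progenitor"],
        cTEC=raw_sets["cTEC"],
        mTEC=raw_sets["mTEC"],
    )


def score_cells(matrix: pd.DataFrame, sets: GeneSetCollection) -> pd.DataFrame:
    """Per-cell population scores: summed transcript counts over each set."""
    out = {}
    for name, genes in sets.as_dict().items():
        present = [g for g in genes if g in matrix.index]
        out[name] = (
            matrix.loc[present].sum(axis=0)
            if present
            else pd.Series(0.0, index=matrix.columns)
        )
    return pd.DataFrame(out, index=matrix.columns)


# ---------------------------------------------------------------------------
# cluster ratio coordinates
# ---------------------------------------------------------------------------

def cluster_ratio_coordinates(
    scores: pd.DataFrame,
    clusters: pd.Series,
    datasets: pd.Series,
    reference: str,
    epsilon: float = 1.0,
    exclude_clusters: Iterable = (),
) -> pd.DataFrame:
    """Place clusters in the EP/PP x C/M log-ratio coordinate system.

    Per (dataset, cluster): EP/PP = log2((ΣEP + ε)/(ΣPP + ε)) and C/M
    analogously on summed scores; coordinates are centred by the reference
    dataset's mean cluster coordinates, so the reference evaluated against
    itself sits around the origin.  ``fraction`` is the cluster's share of
    its dataset's cells (dot size in the standard representation).
    Clusters named in *exclude_clusters* (e.g. nurse-cell-like or
    parathyroid-like clusters identified by marker genes) are dropped.
    Clusters with zero aggregate score in every set are flagged undefined.
    """
    if reference not in set(datasets):
        raise ValueError(f"reference dataset {reference!r} not present")
    df = scores.copy()
    df["cluster"] = clusters.reindex(scores.index)
    df["dataset"] = datasets.reindex(scores.index)
    df = df[~df["cluster"].isin(set(exclude_clusters))]
    rows = []
    for (ds, cl), sub in df.groupby(["dataset", "cluster"], sort=True):
        s = sub[list(POPULATION_SETS)].sum(axis=0)
        defined = s.sum() > 0
        ep_pp = np.log2((s["early_progenitor"] + epsilon)
                        / (s["postnatal_progenitor"] + epsilon))
        c_m = np.log2((s["cTEC"] + epsilon) / (s["mTEC"] + epsilon))
        rows.append(
            {
                "dataset": ds,
                "cluster": cl,
                "ep_pp_log2": ep_pp,
                "c_m_log2": c_m,
                "fraction": len(sub) / (df["dataset"] == ds).sum(),
                "defined": bool(defined),
            }
        )
    out = pd.DataFrame(rows)
    ref = out[(out["dataset"] == reference) & out["defined"]]
    out["ep_pp_log2"] -= ref["ep_pp_log2"].mean()
    out["c_m_log2"] -= ref["c_m_log2"].mean()
    out.loc[~out["defined"], ["ep_pp_log2", "c_m_log2"]] = np.nan
    return out
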