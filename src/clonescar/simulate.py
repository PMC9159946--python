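"""Synthetic clonal-barcoding cohorts with known ground truth.

The generator emulates the CRISPR-Cas9 scar-barcoding experiment: a founder
pool of ~4,000 epithelial cells in the thymic rudiment is marked once, each
founder drawing a repair outcome ("barcode") from a heavy-tailed outcome
distribution shared across mice; clones expand with fate biases into the
cortical (cTEC) and medullary (mTEC) compartments, with a fraction of
descendants remaining progenitor-like (EP = early progenitor, PP = postnatal
progenitor).  Bulk amplicon sequencing of the sorted compartments and
single-cell sampling with population labels are simulated on top, optionally
with negative-binomial count matrices carrying four planted signature gene
sets.

All randomness flows from a single cohort seed via per-mouse derived
substreams, so identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .scarseq import (
    FORWARD_PRIMER,
    GERMLINE_WINDOW,
    LEFT_FLANK,
    RIGHT_FLANK,
    TARGET_SITE,
    revcomp,
    REVERSE_PRIMER,
)
from .tables import BarcodeCountTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "ScDataset",
    "Cohort",
    "draw_outcome_distribution",
    "make_scar_panel",
    "simulate_cohort",
    "simulate_null_cohort",
    "synthesize_fastq",
    "synthesize_bulk_fastq",
    "POPULATIONS",
]

POPULATIONS = ("EP", "PP", "cTEC", "mTEC")

_REV_ANCHOR = revcomp(REVERSE_PRIMER)


class InvalidConfigError(ValueError):
    """A simulation config violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the experimental regime of the barcoding study: ~4,000
    marked founders per thymic rudiment, a heavy-tailed (Zipf-like) repair
    outcome distribution shared by all mice, an 18-mouse cohort with bulk
    cTEC/mTEC amplicon sampling, and ~1,000 single cells per mouse.
    """

    n_mice: int = 18
    founders_per_mouse: int = 4000
    n_outcomes: int = 30000
    outcome_skew: float = 1.15
    frac_early_progenitor: float = 0.4
    bias_early_to_cTEC: float = 0.85
    bias_postnatal_to_mTEC: float = 0.85
    frac_remain_progenitor: float = 0.15
    clone_size_log_mean: float = 2.0
    clone_size_log_sd: float = 1.0
    bulk_reads_per_sample: int = 5000
    cells_per_sc_dataset: int = 1000
    sex: str = "male"
    both_allele_readout_prob: float = 0.02
    # count-matrix panel
    make_count_matrices: bool = True
    genes_per_set: int = 50
    n_background_genes: int = 800
    sig_fold_change: float = 4.0
    nb_dispersion: float = 0.1
    age_group: str = "adult"
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_mice": self.n_mice,
            "founders_per_mouse": self.founders_per_mouse,
            "n_outcomes": self.n_outcomes,
            "bulk_reads_per_sample": self.bulk_reads_per_sample,
            "cells_per_sc_dataset": self.cells_per_sc_dataset,
            "genes_per_set": self.genes_per_set,
            "n_background_genes": self.n_background_genes,
        }
        for name, v in counts.items():
            if int(v) != v or v <= 0:
                raise InvalidConfigError(f"{name} must be a positive integer, got {v}")
        if self.n_outcomes < 2:
            raise InvalidConfigError("n_outcomes must be >= 2")
        fracs = {
            "frac_early_progenitor": self.frac_early_progenitor,
            "bias_early_to_cTEC": self.bias_early_to_cTEC,
            "bias_postnatal_to_mTEC": self.bias_postnatal_to_mTEC,
            "frac_remain_progenitor": self.frac_remain_progenitor,
            "both_allele_readout_prob": self.both_allele_readout_prob,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        if self.outcome_skew < 0:
            raise InvalidConfigError("outcome_skew must be >= 0")
        if self.sex not in ("male", "female"):
            raise InvalidConfigError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.clone_size_log_sd < 0 or self.nb_dispersion <= 0:
            raise InvalidConfigError("dispersion parameters must be positive")


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator.

    ``founders`` has one row per founder with its barcode sequence(s),
    progenitor type and per-compartment descendant counts; the realized
    barcode multiset per mouse is recoverable from it.  Null cohorts carry
    an empty founder table (they have no clonal structure by design).
    """

    founders: pd.DataFrame
    outcome_probs: np.ndarray
    outcome_seqs: list
    null: bool = False

    def barcode_multiset(self, mouse_id) -> pd.Series:
        sub = self.founders[self.founders["mouse_id"] == mouse_id]
        seqs = list(sub["barcode_1"]) + [b for b in sub["barcode_2"] if b]
        return pd.Series(seqs).value_counts()


@dataclass
class ScDataset:
    """One mouse's single-cell dataset: clone map plus optional count matrix."""

    mouse_id: str
    clone_map: pd.DataFrame  # cell_id, barcode_1, barcode_2, population, founder_id
    counts: Optional[pd.DataFrame] = None  # genes x cells
    gene_sets: Optional[pd.DataFrame] = None  # gene, set  (planted truth)


@dataclass
class Cohort:
    config: SimConfig
    truth: SimTruth
    bulk: BarcodeCountTable
    sc: dict


# ---------------------------------------------------------------------------
# outcome distribution and scar panel
# ---------------------------------------------------------------------------

def draw_outcome_distribution(
    n_outcomes: int, outcome_skew: float, seed: int = 0
) -> np.ndarray:
    """Probability vector over repair outcomes, rank k gets mass ~ (k+1)^-skew.

    A truncated power law (Zipf-like) reproduces the monotone rank-frequency
    profile of observed scar barcodes with a single shape parameter; zero
    skew degenerates to the uniform distribution.  The vector is a
    deterministic function of its arguments (the seed argument is accepted
    for interface symmetry with the stochastic generators).
    """
    if int(n_outcomes) != n_outcomes or n_outcomes < 2:
        raise InvalidConfigError(f"n_outcomes must be an integer >= 2, got {n_outcomes}")
    if outcome_skew < 0:
        raise InvalidConfigError("outcome_skew must be >= 0")
    ranks = np.arange(1, int(n_outcomes) + 1, dtype=float)
    w = ranks ** (-float(outcome_skew))
    return w / w.sum()


def _deletion_enumeration():
    """Simple deletions fully inside the target site, small lengths first."""
    t = len(TARGET_SITE)
    for length in range(1, 15):
        for start in range(0, t - length + 1):
            yield start, length, ""


def make_scar_panel(n_outcomes: int, seed: int = 0) -> list:
    """Deterministic panel of distinct scar window sequences.

    Outcome ranks map to edits of the germline window: the most frequent
    outcomes are simple deletions inside the target site (most observed
    scars carry deletions), while the long tail adds insertion and
    deletion+insertion alleles at the cut site.  Sequences are guaranteed
    distinct from each other and from the germline window.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5CA9]))
    seqs: list = []
    seen = {GERMLINE_WINDOW}
    t = TARGET_SITE
    cut = len(t) - 4  # blunt cut 3 bp upstream of the PAM

    def build(start, length, ins):
        edited = t[:start] + ins + t[start + length :]
        return LEFT_FLANK + edited + RIGHT_FLANK

    enum = _deletion_enumeration()
    bases = np.array(list("ACGT"))
    while len(seqs) < n_outcomes:
        got = None
        for start, length, ins in enum:
            s = build(start, length, ins)
            if s not in seen:
                got = s
                break
        if got is None:
            # random deletion+insertion alleles at the cut site
            while True:
                dlen = int(rng.integers(0, 9))
                start = int(np.clip(cut - rng.integers(0, dlen + 1), 0, len(t) - dlen))
                ilen = int(rng.integers(1, 9))
                ins = "".join(rng.choice(bases, size=ilen))
                s = build(start, dlen, ins)
                if s not in seen:
                    got = s
                    break
        seen.add(got)
        seqs.append(got)
    return seqs


# ---------------------------------------------------------------------------
# gene panel for count matrices
# ---------------------------------------------------------------------------

_SET_PREFIX = {"EP": "eps", "PP": "pps", "cTEC": "cts", "mTEC": "mts"}


def _gene_panel(config: SimConfig, seed_seq) -> pd.DataFrame:
    """Gene panel shared by all mice of a cohort: 4 disjoint signature sets
    plus background genes, each with a fixed NB base mean."""
    rng = np.random.default_rng(seed_seq)
    rows = []
    for pop in POPULATIONS:
        for i in range(config.genes_per_set):
            rows.append((f"{_SET_PREFIX[pop]}_{i + 1:03d}", pop))
    for i in range(config.n_background_genes):
        rows.append((f"bg_{i + 1:04d}", "background"))
    panel = pd.DataFrame(rows, columns=["gene", "set"])
    base = rng.lognormal(mean=0.5, sigma=0.7, size=len(panel))
    panel["base_mean"] = np.clip(base, 0.2, 50.0)
    # a low-quality-cell marker present for QC plumbing exercises
    panel.loc[len(panel)] = ["Kcnq1ot1", "background", 0.3]
    return panel


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with var = m + dispersion * m^2 (size r = 1/dispersion)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _count_matrix(rng, panel: pd.DataFrame, populations, config: SimConfig,
                  cell_ids) -> pd.DataFrame:
    genes = panel["gene"].to_numpy()
    base = panel["base_mean"].to_numpy()
    sets = panel["set"].to_numpy()
    pops = np.asarray(populations)
    out = np.zeros((len(pops), len(genes)), dtype=np.int64)
    for pop in POPULATIONS:
        idx = np.flatnonzero(pops == pop)
        if idx.size == 0:
            continue
        mean = base.copy()
        mean[sets == pop] *= config.sig_fold_change
        out[idx] = _nb_counts(
            rng, np.broadcast_to(mean, (idx.size, len(genes))), config.nb_dispersion
        )
    return pd.DataFrame(out.T, index=genes, columns=list(cell_ids))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _mouse_ids(n: int) -> list:
    return [f"m{i + 1:02d}" for i in range(n)]


def _sample_meta(config: SimConfig) -> pd.DataFrame:
    rows = []
    for m in _mouse_ids(config.n_mice):
        for comp in ("cTEC", "mTEC"):
            rows.append(
                {
                    "sample_id": f"{m}_{comp}",
                    "mouse_id": m,
                    "compartment": comp,
                    "age_group": config.age_group,
                    "sex": config.sex,
                }
            )
    return pd.DataFrame(rows)


def _assemble_bulk(per_sample_counts: dict, config: SimConfig,
                   outcome_seqs) -> BarcodeCountTable:
    # one extra slot for germline reads (emitted when a sorted fraction
    # contains no scarred cells, mimicking unmarked carry-over cells)
    labels = list(outcome_seqs) + [GERMLINE_WINDOW]
    mat = np.column_stack([per_sample_counts[s] for s in per_sample_counts])
    observed = mat.sum(axis=1) > 0
    counts = pd.DataFrame(
        mat[observed],
        index=np.asarray(labels, dtype=object)[observed],
        columns=list(per_sample_counts),
    )
    return BarcodeCountTable(counts, _sample_meta(config))


def _expose_alleles(rng, bc1_seq, bc2_seq, config: SimConfig):
    """Single-cell readout of a female cell: dosage compensation exposes one
    X-linked allele, with a small 'relaxed X-inactivation' chance of both."""
    n = len(bc1_seq)
    u = rng.random(n)
    pick2 = u < 0.5
    both = rng.random(n) < config.both_allele_readout_prob
    a1 = np.where(pick2 & ~both, bc2_seq, bc1_seq)
    a2 = np.where(both, bc2_seq, "")
    return a1, a2


def simulate_cohort(config: SimConfig = SimConfig()) -> Cohort:
    """Simulate a full clonally structured cohort.

    Per mouse: founders draw barcodes from the shared outcome distribution
    (two independent draws per founder when ``sex == "female"``), clone
    sizes are log-normal, and descendants are allocated multinomially to
    (EP-like, PP-like, cTEC, mTEC) according to the founder's progenitor
    type and fate bias.  Bulk samples are multinomial reads over barcode
    abundance within each sorted compartment (EP-like cells sort with the
    cTEC fraction, PP-like cells with the mTEC fraction); single-cell
    datasets sample cells without replacement and attach population labels
    and exposed barcode(s).
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    panel_ss, scar_ss, *mouse_ss = root.spawn(config.n_mice + 2)
    probs = draw_outcome_distribution(config.n_outcomes, config.outcome_skew)
    seqs = make_scar_panel(config.n_outcomes, config.seed)
    panel = _gene_panel(config, panel_ss) if config.make_count_matrices else None

    stay = config.frac_remain_progenitor
    p_ep = np.array([
        stay, 0.0,
        (1 - stay) * config.bias_early_to_cTEC,
        (1 - stay) * (1 - config.bias_early_to_cTEC),
    ])
    p_pp = np.array([
        0.0, stay,
        (1 - stay) * (1 - config.bias_postnatal_to_mTEC),
        (1 - stay) * config.bias_postnatal_to_mTEC,
    ])

    founders_frames = []
    per_sample = {}
    sc = {}
    seq_arr = np.asarray(seqs, dtype=object)
    for mouse, ss in zip(_mouse_ids(config.n_mice), mouse_ss):
        rng = np.random.default_rng(ss)
        F = config.founders_per_mouse
        bc1 = rng.choice(config.n_outcomes, size=F, p=probs)
        female = config.sex == "female"
        bc2 = rng.choice(config.n_outcomes, size=F, p=probs) if female else None
        is_ep = rng.random(F) < config.frac_early_progenitor
        sizes = np.maximum(
            1, np.round(rng.lognormal(config.clone_size_log_mean,
                                      config.clone_size_log_sd, F))
        ).astype(np.int64)
        alloc = np.zeros((F, 4), dtype=np.int64)
        if is_ep.any():
            alloc[is_ep] = rng.multinomial(sizes[is_ep], p_ep)
        if (~is_ep).any():
            alloc[~is_ep] = rng.multinomial(sizes[~is_ep], p_pp)

        # bulk: sorted fractions; progenitor-like cells sort with their
        # biased compartment (EP -> Ly51+ cTEC fraction, PP -> UEA-1+ mTEC)
        w = 0.5 if female else 1.0
        ctec_cells = alloc[:, 0] + alloc[:, 2]
        mtec_cells = alloc[:, 1] + alloc[:, 3]
        for comp, cells in (("cTEC", ctec_cells), ("mTEC", mtec_cells)):
            ab = np.zeros(config.n_outcomes + 1)
            ab[:-1] = np.bincount(bc1, weights=cells * w, minlength=config.n_outcomes)
            if female:
                ab[:-1] += np.bincount(bc2, weights=cells * w,
                                       minlength=config.n_outcomes)
            if ab.sum() == 0:
                ab[-1] = 1.0  # empty fraction: only unmarked (germline) cells
            per_sample[f"{mouse}_{comp}"] = rng.multinomial(
                config.bulk_reads_per_sample, ab / ab.sum()
            )

        # single-cell sampling without replacement over (founder, category)
        colors = alloc.reshape(-1)
        nsample = int(min(config.cells_per_sc_dataset, colors.sum()))
        drawn = rng.multivariate_hypergeometric(colors, nsample, method="marginals")
        nz = np.flatnonzero(drawn)
        founder_idx = np.repeat(nz // 4, drawn[nz])
        cat_idx = np.repeat(nz % 4, drawn[nz])
        order = rng.permutation(founder_idx.size)
        founder_idx, cat_idx = founder_idx[order], cat_idx[order]
        cell_ids = [f"{mouse}_c{i + 1:04d}" for i in range(founder_idx.size)]
        pops = np.asarray(POPULATIONS, dtype=object)[cat_idx]
        b1_seq = seq_arr[bc1[founder_idx]]
        if female:
            b2_seq = seq_arr[bc2[founder_idx]]
            a1, a2 = _expose_alleles(rng, b1_seq, b2_seq, config)
            same = b1_seq == b2_seq  # homozygous exposure collapses to one
            a2 = np.where(same, "", a2)
        else:
            a1, a2 = b1_seq, np.full(founder_idx.size, "", dtype=object)
        clone_map = pd.DataFrame(
            {
                "cell_id": cell_ids,
                "barcode_1": a1,
                "barcode_2": a2,
                "population": pops,
                "founder_id": [f"{mouse}_f{j:04d}" for j in founder_idx],
            }
        )
        counts = (
            _count_matrix(rng, panel, pops, config, cell_ids)
            if config.make_count_matrices
            else None
        )
        gene_sets = (
            panel.loc[panel["set"] != "background", ["gene", "set"]].reset_index(drop=True)
            if panel is not None
            else None
        )
        sc[mouse] = ScDataset(mouse, clone_map, counts, gene_sets)

        founders_frames.append(
            pd.DataFrame(
                {
                    "mouse_id": mouse,
                    "founder_id": [f"{mouse}_f{j:04d}" for j in range(F)],
                    "barcode_1": seq_arr[bc1],
                    "barcode_2": seq_arr[bc2] if female else "",
                    "progenitor_type": np.where(is_ep, "EP", "PP"),
                    "clone_size": sizes,
                    "n_EP": alloc[:, 0],
                    "n_PP": alloc[:, 1],
                    "n_cTEC": alloc[:, 2],
                    "n_mTEC": alloc[:, 3],
                }
            )
        )

    truth = SimTruth(
        founders=pd.concat(founders_frames, ignore_index=True),
        outcome_probs=probs,
        outcome_seqs=seqs,
    )
    bulk = _assemble_bulk(per_sample, config, seqs)
    return Cohort(config, truth, bulk, sc)


def simulate_null_cohort(config: SimConfig = SimConfig()) -> Cohort:
    """Calibration null: no clonal structure at all.

    Bulk reads and single cells draw barcodes independently from the shared
    outcome distribution, and compartment/population labels are drawn
    independently of barcode identity.  Under this null, rare-barcode
    co-occurrence is driven purely by sequence collisions (expected
    enrichment E_m ~ 1) and no barcode is over-represented in any population
    relative to the bulk background.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    panel_ss, scar_ss, *mouse_ss = root.spawn(config.n_mice + 2)
    probs = draw_outcome_distribution(config.n_outcomes, config.outcome_skew)
    seqs = make_scar_panel(config.n_outcomes, config.seed)
    panel = _gene_panel(config, panel_ss) if config.make_count_matrices else None
    seq_arr = np.asarray(seqs, dtype=object)

    per_sample = {}
    sc = {}
    for mouse, ss in zip(_mouse_ids(config.n_mice), mouse_ss):
        rng = np.random.default_rng(ss)
        for comp in ("cTEC", "mTEC"):
            per_sample[f"{mouse}_{comp}"] = np.append(
                rng.multinomial(config.bulk_reads_per_sample, probs), 0
            )
        n = config.cells_per_sc_dataset
        bc = rng.choice(config.n_outcomes, size=n, p=probs)
        pops = np.asarray(POPULATIONS, dtype=object)[rng.integers(0, 4, size=n)]
        cell_ids = [f"{mouse}_c{i + 1:04d}" for i in range(n)]
        clone_map = pd.DataFrame(
            {
                "cell_id": cell_ids,
                "barcode_1": seq_arr[bc],
                "barcode_2": "",
                "population": pops,
                "founder_id": cell_ids,
            }
        )
        counts = (
            _count_matrix(rng, panel, pops, config, cell_ids)
            if config.make_count_matrices
            else None
        )
        sc[mouse] = ScDataset(mouse, clone_map, counts,
                              panel.loc[panel["set"] != "background",
                                        ["gene", "set"]].reset_index(drop=True)
                              if panel is not None else None)

    truth = SimTruth(
        founders=pd.DataFrame(
            columns=["mouse_id", "founder_id", "barcode_1", "barcode_2",
                     "progenitor_type", "clone_size", "n_EP", "n_PP",
                     "n_cTEC", "n_mTEC"]
        ),
        outcome_probs=probs,
        outcome_seqs=seqs,
        null=True,
    )
    bulk = _assemble_bulk(per_sample, config, seqs)
    return Cohort(config, truth, bulk, sc)


# ---------------------------------------------------------------------------
# FASTQ synthesis
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _mutate(rng, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(arr.size) < error_rate)
    if hits.size:
        subs = rng.choice(_BASES, size=hits.size)
        for i, b in zip(hits, subs):
            arr[i] = b.encode()
    return arr.tobytes().decode()


def _cell_barcode_pool(n: int) -> list:
    pool = []
    for tup in itertools.product("ACGT", repeat=6):
        pool.append("".join(tup))
        if len(pool) >= n:
            break
    if len(pool) < n:
        raise InvalidConfigError("more cells than the 4096-barcode space")
    return pool


def synthesize_fastq(
    clone_map: pd.DataFrame,
    fastq1,
    fastq2,
    reads_per_cell: int = 300,
    error_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Write a paired-end single-cell amplicon library for a clone map.

    Left mates are ``6 nt UMI + 6 nt cell barcode + amplicon``; right mates
    are the reverse complement of the amplicon, so the scar window appears
    in both mates and anchored extraction is exercised end to end.  Cells
    with two exposed alleles split their reads between them.  Returns the
    cell_id -> cell_barcode assignment.
    """
    if reads_per_cell < 1:
        raise InvalidConfigError("reads_per_cell must be >= 1")
    if not 0.0 <= error_rate <= 0.05:
        raise InvalidConfigError("error_rate must be in [0, 0.05]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFA57]))
    barcodes = _cell_barcode_pool(len(clone_map))
    with gzip.open(str(fastq1), "wt") as f1, gzip.open(str(fastq2), "wt") as f2:
        for row, cell_bc in zip(clone_map.itertuples(index=False), barcodes):
            alleles = [row.barcode_1]
            if getattr(row, "barcode_2", ""):
                alleles.append(row.barcode_2)
            for r in range(reads_per_cell):
                allele = alleles[r % len(alleles)]
                amplicon = FORWARD_PRIMER + allele + _REV_ANCHOR
                umi = "".join(rng.choice(_BASES, size=6))
                left = _mutate(rng, umi + cell_bc + amplicon, error_rate)
                right = _mutate(rng, revcomp(amplicon), error_rate)
                name = f"{row.cell_id}:{r}"
                f1.write(f"@{name}/1\n{left}\n+\n{'I' * len(left)}\n")
                f2.write(f"@{name}/2\n{right}\n+\n{'I' * len(right)}\n")
    return pd.DataFrame(
        {"cell_id": clone_map["cell_id"], "cell_barcode": barcodes}
    )


def synthesize_bulk_fastq(
    counts: pd.Series,
    fastq1,
    fastq2,
    error_rate: float = 0.0,
    seed: int = 0,
) -> int:
    """Write a bulk amplicon library with one read pair per count unit."""
    if not 0.0 <= error_rate <= 0.05:
        raise InvalidConfigError("error_rate must be in [0, 0.05]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB07C]))
    n = 0
    with gzip.open(str(fastq1), "wt") as f1, gzip.open(str(fastq2), "wt") as f2:
        for seq, count in counts.items():
            amplicon = FORWARD_PRIMER + seq + _REV_ANCHOR
            for _ in range(int(count)):
                left = _mutate(rng, amplicon, error_rate)
                right = _mutate(rng, revcomp(amplicon), error_rate)
                f1.write(f"@b{n}/1\n{left}\n+\n{'I' * len(left)}\n")
                f2.write(f"@b{n}/2\n{right}\n+\n{'I' * len(right)}\n")
                n += 1
    return n
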