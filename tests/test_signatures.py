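"""UMI conversion, QC filters, NB differential expression, set scoring."""

import numpy as np
import pandas as pd
import pytest

import clonescar.signatures as sig
from clonescar.signatures import (
    GeneSetCollection,
    cluster_ratio_coordinates,
    derive_gene_sets,
    diffexp_nb,
    downsample_counts,
    qc_filter_cells,
    qc_filter_genes,
    score_cells,
    umi_to_transcripts,
)
from clonescar.simulate import SimConfig, simulate_null_cohort

POPMAP = {
    "early_progenitor": ["EP"],
    "postnatal_progenitor": ["PP"],
    "cTEC": ["cTEC"],
    "mTEC": ["mTEC"],
}
PREFIX = {"EP": "eps", "PP": "pps", "cTEC": "cts", "mTEC": "mts"}


class TestUmiToTranscripts:
    def test_identity_at_zero(self):
        assert umi_to_transcripts(0) == 0.0

    def test_closed_form_values(self):
        assert umi_to_transcripts(1, 4096) == pytest.approx(1.000122, abs=1e-5)
        assert umi_to_transcripts(2048, 4096) == pytest.approx(
            4096 * np.log(2), rel=1e-12
        )

    def test_saturation_guard_and_bounds(self):
        assert np.isfinite(umi_to_transcripts(4096, 4096))
        with pytest.raises(ValueError):
            umi_to_transcripts(4097, 4096)

    def test_monotone_convex_and_above_count(self):
        k = np.arange(0, 4000)
        t = umi_to_transcripts(k, 4096)
        d = np.diff(t)
        assert np.all(d > 0) and np.all(np.diff(d) > -1e-9)
        assert np.all(t[1:] >= k[1:])

    def test_collision_simulation_matches_closed_form(self):
        """Monte-Carlo UMI collision oracle: drawing t molecules into 4096
        tags yields on average the k that inverts to t."""
        rng = np.random.default_rng(0)
        for k in (10, 500, 2000):
            t = int(round(umi_to_transcripts(k, 4096)))
            sim = [
                len(np.unique(rng.integers(0, 4096, size=t))) for _ in range(200)
            ]
            se = np.std(sim) / np.sqrt(len(sim))
            assert abs(np.mean(sim) - k) < 3 * max(se, 0.5)


def _matrix(vals, genes=None, cells=None):
    vals = np.asarray(vals)
    genes = genes or [f"g{i}" for i in range(vals.shape[0])]
    cells = cells or [f"c{j}" for j in range(vals.shape[1])]
    return pd.DataFrame(vals, index=genes, columns=cells)


class TestCellQC:
    def test_exactly_the_violators_removed(self):
        rng = np.random.default_rng(5)
        n = 100
        vals = rng.poisson(20, size=(60, n))
        mat = _matrix(vals, genes=[f"g{i}" for i in range(59)] + ["Kcnq1ot1"])
        mat.loc["Kcnq1ot1"] = 0
        low = {"c3", "c17", "c50"}
        for c in low:
            mat[c] = (mat[c] * 0.2).astype(int)  # push below the cutoff
        kc = {"c8", "c77"}
        for c in kc:
            mat.loc["Kcnq1ot1", c] = int(mat[c].sum())  # ~50% marker content
        min_total = int(mat.sum(axis=0).drop(list(low | kc)).min())
        out = qc_filter_cells(mat, min_total=min_total, normalize="none")
        brute = {
            c
            for c in mat.columns
            if mat[c].sum() < min_total
            or mat.loc["Kcnq1ot1", c] / mat[c].sum() > 0.02
        }
        assert set(mat.columns) - set(out.columns) == brute
        assert (low | kc) <= brute

    def test_boundary_cell_below_cutoff_removed(self):
        mat = _matrix([[999], [0]], cells=["bad"]).join(
            _matrix([[1000], [0]], cells=["good"])
        )
        out = qc_filter_cells(mat, min_total=1000, normalize="none")
        assert list(out.columns) == ["good"]

    def test_three_percent_marker_removed(self):
        vals = np.zeros((2, 2), dtype=int)
        vals[0] = [97, 99]
        vals[1] = [3, 1]  # 3% and 1% marker content
        mat = _matrix(vals, genes=["other", "Kcnq1ot1"])
        out = qc_filter_cells(mat, min_total=50, normalize="none")
        assert list(out.columns) == ["c1"]

    def test_all_removed_raises_with_summary(self):
        mat = _matrix([[1], [1]])
        with pytest.raises(ValueError, match="min_total"):
            qc_filter_cells(mat, min_total=1000)

    def test_downsampling_normalises_totals_deterministically(self):
        rng = np.random.default_rng(6)
        mat = _matrix(rng.poisson(10, size=(50, 20)))
        out = downsample_counts(mat, seed=1)
        target = mat.sum(axis=0).min()
        assert (out.sum(axis=0) == target).all()
        assert (out.to_numpy() <= mat.to_numpy()).all()
        pd.testing.assert_frame_equal(out, downsample_counts(mat, seed=1))


class TestGeneQC:
    def _anchored(self, target_r, rng):
        """Matrix with genes mixed toward the anchor at target correlations."""
        n = 400
        anchor = rng.poisson(20, n).astype(float)
        mat = {"Kcnq1ot1": anchor}
        z = (anchor - anchor.mean()) / anchor.std()
        for name, r in target_r.items():
            noise = rng.normal(0, 1, n)
            mat[name] = 10 + 3 * (r * z + np.sqrt(1 - r**2) * noise)
        df = pd.DataFrame(mat).T
        df.columns = [f"c{j}" for j in range(n)]
        return df

    def test_correlated_genes_removed_uncorrelated_kept(self):
        rng = np.random.default_rng(8)
        mat = self._anchored({"hi": 0.70, "lo": 0.60, "zero": 0.0}, rng)
        # verify the fixture hits its target correlations before asserting
        r_hi = np.corrcoef(mat.loc["hi"], mat.loc["Kcnq1ot1"])[0, 1]
        r_lo = np.corrcoef(mat.loc["lo"], mat.loc["Kcnq1ot1"])[0, 1]
        assert r_hi > 0.65 and r_lo < 0.65
        out = qc_filter_genes(mat, exclusions=())
        assert "hi" not in out.index
        assert "Kcnq1ot1" not in out.index  # anchor removed with its correlates
        assert {"lo", "zero"} <= set(out.index)

    def test_pattern_exclusions(self):
        rng = np.random.default_rng(9)
        genes = ["Jun", "Fos", "Gm4200", "mt-Co1", "Hprt", "Actb", "Kcnq1ot1"]
        mat = _matrix(rng.poisson(5, size=(7, 30)), genes=genes)
        out = qc_filter_genes(mat)
        assert list(out.index) == ["Actb"]

    def test_absent_anchor_warns_and_skips_correlation(self, caplog):
        import logging

        mat = _matrix(np.ones((3, 10), dtype=int), genes=["a", "b", "c"])
        with caplog.at_level(logging.WARNING, logger="clonescar.signatures"):
            out = qc_filter_genes(mat, exclusions=())
        assert len(out) == 3
        assert any("anchor" in r.message for r in caplog.records)


class TestDiffexpNB:
    def _nb(self, rng, mean, disp, size):
        r = 1 / disp
        return rng.negative_binomial(r, r / (r + mean), size=size)

    def test_identical_groups_null(self):
        rng = np.random.default_rng(10)
        mat = _matrix(self._nb(rng, 5.0, 0.1, (100, 30)))
        cells = list(mat.columns)
        de = diffexp_nb(mat, cells, cells)
        assert (de["p_adj"] > 0.5).all()
        assert np.allclose(de["log2_fold_change"], 0.0)

    def test_power_at_fourfold_elevation(self):
        """200 genes with a true 4-fold shift, 50 vs 50 cells, NB dispersion
        0.1: essentially all are recovered at adjusted P < 0.01, |lfc| > 1."""
        rng = np.random.default_rng(12)
        a = self._nb(rng, 2.0, 0.1, (200, 50))
        b = self._nb(rng, 8.0, 0.1, (200, 50))
        mat = _matrix(
            np.hstack([a, b]),
            cells=[f"a{i}" for i in range(50)] + [f"b{i}" for i in range(50)],
        )
        de = diffexp_nb(mat, [f"a{i}" for i in range(50)],
                        [f"b{i}" for i in range(50)])
        hit = (de["p_adj"] < 0.01) & (de["log2_fold_change"].abs() > 1)
        assert hit.mean() >= 0.95

    def test_null_type_one_error_controlled(self):
        rng = np.random.default_rng(13)
        mat = _matrix(
            self._nb(rng, 3.0, 0.1, (500, 100)),
            cells=[f"a{i}" for i in range(50)] + [f"b{i}" for i in range(50)],
        )
        de = diffexp_nb(mat, [f"a{i}" for i in range(50)],
                        [f"b{i}" for i in range(50)])
        assert (de["p_adj"] < 0.01).mean() <= 0.01

    def test_zero_genes_convention(self):
        mat = _matrix(np.vstack([np.zeros((1, 10)), np.ones((1, 10))]))
        de = diffexp_nb(mat, list(mat.columns[:5]), list(mat.columns[5:]))
        assert de["p_raw"].iloc[0] == 1.0
        assert de["log2_fold_change"].iloc[0] == 0.0

    def test_small_groups_rejected(self):
        mat = _matrix(np.ones((3, 8), dtype=int))
        with pytest.raises(ValueError):
            diffexp_nb(mat, list(mat.columns[:4]), list(mat.columns[4:]))


@pytest.fixture(scope="module")
def planted(sc_dataset):
    clusters = pd.Series(
        sc_dataset.clone_map["population"].to_numpy(),
        index=sc_dataset.clone_map["cell_id"],
    )
    return sc_dataset.counts, clusters, sc_dataset.gene_sets


class TestDeriveGeneSets:
    def test_planted_sets_recovered(self, planted):
        mat, clusters, truth_sets = planted
        sets = derive_gene_sets(mat, POPMAP, clusters)
        got = sets.as_dict()
        name = {"EP": "early_progenitor", "PP": "postnatal_progenitor",
                "cTEC": "cTEC", "mTEC": "mTEC"}
        for pop, key in name.items():
            planted_genes = set(truth_sets.loc[truth_sets["set"] == pop, "gene"])
            recovered = set(got[key])
            assert len(recovered & planted_genes) / len(planted_genes) >= 0.9
            # no contamination from other planted sets
            others = set(truth_sets["gene"]) - planted_genes
            assert not (recovered & others)

    def test_ep_ctec_overlap_removed(self, planted):
        mat, clusters, _ = planted
        sets = derive_gene_sets(mat, POPMAP, clusters)
        assert not set(sets.early_progenitor) & set(sets.cTEC)

    def test_identifier_exclusions(self, planted):
        mat, clusters, truth_sets = planted
        ep_genes = truth_sets.loc[truth_sets["set"] == "EP", "gene"].tolist()
        renamed = mat.rename(
            index={ep_genes[0]: "Gm12345", ep_genes[1]: "1700012A34Rik"}
        )
        sets = derive_gene_sets(renamed, POPMAP, clusters)
        assert "Gm12345" not in sets.early_progenitor
        assert "1700012A34Rik" not in sets.early_progenitor

    def test_thresholds_are_strict(self, planted, monkeypatch):
        mat, clusters, _ = planted

        def fake_de(matrix, a, b, dispersion=None, pseudocount=0.1):
            return pd.DataFrame(
                {
                    "mean_a": 1.0,
                    "mean_b": 2.0,
                    "log2_fold_change": [1.0, 1.01, 2.0],
                    "p_raw": [1e-6, 1e-6, 0.01],
                    "p_adj": [1e-6, 1e-6, 0.01],
                },
                index=["at_fc_boundary", "above_fc", "at_p_boundary"],
            )

        monkeypatch.setattr(sig, "diffexp_nb", fake_de)
        sets = derive_gene_sets(mat, POPMAP, clusters)
        d = sets.as_dict()
        for key in ("postnatal_progenitor", "cTEC", "mTEC"):
            assert "above_fc" in d[key]
            assert "at_fc_boundary" not in d[key]  # log2fc must exceed 1
            assert "at_p_boundary" not in d[key]  # adjusted P must be < 0.01
        # the EP set loses its overlap with the cTEC set by construction
        assert d["early_progenitor"] == []


class TestScoreCells:
    def test_zero_and_single_set_expression(self):
        sets = GeneSetCollection(["e1"], ["p1"], ["c1"], ["m1"])
        mat = _matrix(
            [[0, 5], [0, 0], [0, 0], [0, 0]],
            genes=["e1", "p1", "c1", "m1"],
            cells=["empty", "ep_only"],
        )
        scores = score_cells(mat, sets)
        assert (scores.loc["empty"] == 0).all()
        assert scores.loc["ep_only", "early_progenitor"] == 5
        assert scores.loc["ep_only"].drop("early_progenitor").sum() == 0

    def test_additive_over_set_partition(self, planted):
        mat, clusters, truth_sets = planted
        genes = truth_sets.loc[truth_sets["set"] == "EP", "gene"].tolist()
        full = score_cells(mat, GeneSetCollection(early_progenitor=genes))
        half1 = score_cells(mat, GeneSetCollection(early_progenitor=genes[:25]))
        half2 = score_cells(mat, GeneSetCollection(early_progenitor=genes[25:]))
        np.testing.assert_allclose(
            full["early_progenitor"],
            half1["early_progenitor"] + half2["early_progenitor"],
        )

    def test_argmax_score_predicts_population(self, planted):
        mat, clusters, truth_sets = planted
        sets = derive_gene_sets(mat, POPMAP, clusters)
        scores = score_cells(mat, sets)
        order = ["early_progenitor", "postnatal_progenitor", "cTEC", "mTEC"]
        pred = np.asarray(order)[scores[order].to_numpy().argmax(axis=1)]
        name = {"EP": "early_progenitor", "PP": "postnatal_progenitor",
                "cTEC": "cTEC", "mTEC": "mTEC"}
        truth = clusters.map(name).reindex(scores.index)
        assert (pred == truth.to_numpy()).mean() >= 0.9


class TestClusterRatioCoordinates:
    def _two_datasets(self):
        ref = simulate_null_cohort(
            SimConfig(n_mice=1, cells_per_sc_dataset=400, seed=23)
        ).sc["m01"]
        # embryonic-like: EP/cTEC dominated
        from clonescar.simulate import simulate_cohort

        emb = simulate_cohort(
            SimConfig(
                n_mice=1, founders_per_mouse=300, cells_per_sc_dataset=400,
                frac_early_progenitor=0.9, frac_remain_progenitor=0.5, seed=24,
            )
        ).sc["m01"]
        frames, clusters, datasets = [], [], []
        for label, ds in (("P28", ref), ("E16", emb)):
            clusters_s = pd.Series(
                ds.clone_map["population"].to_numpy(), index=ds.clone_map["cell_id"]
            )
            truth_sets = ds.gene_sets
            sets = GeneSetCollection(
                early_progenitor=truth_sets.loc[truth_sets["set"] == "EP", "gene"].tolist(),
                postnatal_progenitor=truth_sets.loc[truth_sets["set"] == "PP", "gene"].tolist(),
                cTEC=truth_sets.loc[truth_sets["set"] == "cTEC", "gene"].tolist(),
                mTEC=truth_sets.loc[truth_sets["set"] == "mTEC", "gene"].tolist(),
            )
            s = score_cells(ds.counts, sets)
            s.index = [f"{label}_{c}" for c in s.index]
            frames.append(s)
            clusters.append(pd.Series(clusters_s.to_numpy(), index=s.index))
            datasets.append(pd.Series(label, index=s.index))
        return (
            pd.concat(frames),
            pd.concat(clusters),
            pd.concat(datasets),
        )

    def test_self_reference_centres_at_origin(self, planted):
        mat, clusters_s, truth_sets = planted
        sets = GeneSetCollection.from_frame(
            truth_sets.replace(
                {"set": {"EP": "early_progenitor", "PP": "postnatal_progenitor"}}
            )
        )
        scores = score_cells(mat, sets)
        clusters = clusters_s.reindex(scores.index)
        datasets = pd.Series("ref", index=scores.index)
        out = cluster_ratio_coordinates(scores, clusters, datasets, "ref")
        assert out["ep_pp_log2"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out["c_m_log2"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_embryonic_cohort_lands_in_ep_high_c_high_quadrant(self):
        """The fraction-weighted centroid of an EP/cTEC-dominated cohort
        sits in the EP-high / C-high quadrant relative to the reference."""
        scores, clusters, datasets = self._two_datasets()
        out = cluster_ratio_coordinates(scores, clusters, datasets, "P28")
        emb = out[out["dataset"] == "E16"]
        w = emb["fraction"]
        assert np.average(emb["ep_pp_log2"], weights=w) > 0
        assert np.average(emb["c_m_log2"], weights=w) > 0

    def test_epsilon_insensitive_quadrants(self):
        scores, clusters, datasets = self._two_datasets()
        a = cluster_ratio_coordinates(scores, clusters, datasets, "P28", epsilon=1.0)
        b = cluster_ratio_coordinates(scores, clusters, datasets, "P28", epsilon=2.0)
        np.testing.assert_array_equal(
            np.sign(a[["ep_pp_log2", "c_m_log2"]].round(6)),
            np.sign(b[["ep_pp_log2", "c_m_log2"]].round(6)),
        )

    def test_excluded_clusters_dropped_and_missing_reference_rejected(self):
        scores, clusters, datasets = self._two_datasets()
        out = cluster_ratio_coordinates(
            scores, clusters, datasets, "P28", exclude_clusters=["mTEC"]
        )
        assert "mTEC" not in set(out["cluster"])
        with pytest.raises(ValueError):
            cluster_ratio_coordinates(scores, clusters, datasets, "nope")
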