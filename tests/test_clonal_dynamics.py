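"""Clone frequencies, paired dynamics filters, rank-sum markers, pipeline."""

import json
import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import tcrfirst as tf
from tcrfirst.repertoire_io import Chain, Clonotype, Repertoire


def repertoire_from_counts(counts: dict, sample_id: str) -> Repertoire:
    cts = []
    i = 0
    for cdr3, n in counts.items():
        for _ in range(n):
            cts.append(Clonotype(
                barcode=f"{sample_id}_C{i}", sample_id=sample_id,
                chain_bd=Chain("TRB", "TRBV9", "TRBJ1-1", cdr3)))
            i += 1
    return Repertoire(clonotypes=cts)


def freq_table(counts: dict, sample_id: str) -> pd.DataFrame:
    return tf.clone_frequencies(repertoire_from_counts(counts, sample_id), sample_id)


class TestCloneFrequencies:
    def test_counts_normalized_by_sample_total(self):
        table = freq_table({"CASSAELYF": 3, "CASSGELYF": 1}, "S1")
        assert sorted(table["frequency"]) == [0.25, 0.75]

    def test_single_clone_has_frequency_one(self):
        table = freq_table({"CASSAELYF": 5}, "S1")
        assert table["frequency"].tolist() == [1.0]

    def test_frequencies_sum_to_one(self, rng):
        counts = {f"CASS{a}{b}ELYF": int(rng.integers(1, 30))
                  for a in "ADEF" for b in "GHIK"}
        table = freq_table(counts, "S1")
        assert table["frequency"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tf.clone_frequencies(Repertoire(), "S1")


class TestPairedDynamics:
    def test_contracted_clone_selected_by_both_filters(self):
        pre = freq_table({"CASSAELYF": 4, "CASSOTHERF": 196}, "pre")
        post = freq_table({"CASSAELYF": 1, "CASSOTHERF": 199}, "post")
        calls = {c.clone_key: c for c in tf.paired_dynamics(pre, post)}
        call = calls["NA|TRBV9.TRBJ1-1_CASSAELYF"]
        assert call.selected and call.direction == "contracted"
        assert call.fold_change == pytest.approx(4.0)

    def test_below_one_percent_never_selected(self):
        pre = freq_table({"CASSAELYF": 1, "CASSOTHERF": 199}, "pre")
        post = freq_table({"CASSAELYF": 1, "CASSOTHERF": 799}, "post")
        calls = {c.clone_key: c for c in tf.paired_dynamics(pre, post)}
        call = calls["NA|TRBV9.TRBJ1-1_CASSAELYF"]
        assert call.fold_change == pytest.approx(4.0) and not call.selected

    def test_absent_clone_uses_pseudo_frequency(self):
        # 192 cells pre (frequency 2%), absent post: classic responder profile
        pre = freq_table({"CASSAELYF": 192, "CASSOTHERF": 9408}, "pre")
        post = freq_table({"CASSOTHERF": 9600}, "post")
        calls = {c.clone_key: c for c in tf.paired_dynamics(pre, post)}
        call = calls["NA|TRBV9.TRBJ1-1_CASSAELYF"]
        assert call.count_post == 0 and call.freq_post == 0.0
        assert call.selected and call.direction == "contracted"
        assert call.fold_change == pytest.approx(192.0)  # vs pseudo-count 1

    def test_identical_sample_ids_rejected(self):
        t = freq_table({"CASSAELYF": 5}, "S1")
        with pytest.raises(ValueError, match="share sample ids"):
            tf.paired_dynamics(t, t)

    def test_selection_equals_brute_force_on_random_tables(self, rng):
        for _ in range(10):
            keys = [f"CASS{a}{b}F" for a in "ADEFGH" for b in "IKLM"]
            pre_counts = {k: int(rng.integers(1, 60)) for k in keys
                          if rng.random() > 0.3}
            post_counts = {k: int(rng.integers(1, 60)) for k in keys
                           if rng.random() > 0.3}
            if not pre_counts or not post_counts:
                continue
            pre, post = freq_table(pre_counts, "pre"), freq_table(post_counts, "post")
            calls = tf.paired_dynamics(pre, post)
            tot_pre = sum(pre_counts.values())
            tot_post = sum(post_counts.values())
            for c in calls:
                cdr3 = c.clone_key.split("_")[-1]
                f_pre = pre_counts.get(cdr3, 0) / tot_pre
                f_post = post_counts.get(cdr3, 0) / tot_post
                fp_pre = f_pre or 1 / tot_pre
                fp_post = f_post or 1 / tot_post
                fold = max(fp_pre, fp_post) / min(fp_pre, fp_post)
                expected = max(f_pre, f_post) >= 0.01 and fold >= 2.0
                assert c.selected == expected


class TestExpansionBins:
    @pytest.mark.parametrize("count,label", [
        (1, "single"), (2, "small"), (5, "small"), (6, "medium"),
        (17, "medium"), (20, "medium"), (21, "large"), (100, "large"),
        (101, "hyperexpanded"), (192, "hyperexpanded"),
    ])
    def test_default_bin_edges(self, count, label):
        labels, meta = tf.expansion_bins([count])
        assert labels == [label]
        assert meta["bins"][0]["label"] == "single"

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            tf.expansion_bins([0])


class TestRankSumMarkers:
    def make_gex(self, rng, n1=20, n2=40, n_genes=60, boost=None):
        counts = rng.negative_binomial(2, 2 / (2 + 1.0), size=(n1 + n2, n_genes))
        if boost:
            counts[:n1, boost] = rng.negative_binomial(
                2, 2 / (2 + 8.0), size=(n1, len(boost)))
        return tf.GexMatrix(
            barcodes=[f"B{i}" for i in range(n1 + n2)],
            features=[f"G{i}" for i in range(n_genes)],
            counts=sp.csr_matrix(counts))

    def test_planted_marker_reported_with_positive_lfc(self, rng):
        gex = self.make_gex(rng, boost=[0, 1, 2])
        table = tf.rank_sum_markers(gex, [f"B{i}" for i in range(20)],
                                    [f"B{i}" for i in range(20, 60)])
        top = set(table["gene"].head(10))
        assert {"G0", "G1", "G2"} <= top
        planted = table[table["gene"].isin(["G0", "G1", "G2"])]
        assert (planted["log2_fold_change"] > 0).all()

    def test_reported_rows_satisfy_thresholds(self, rng):
        gex = self.make_gex(rng, boost=[0, 1])
        table = tf.rank_sum_markers(gex, [f"B{i}" for i in range(20)],
                                    [f"B{i}" for i in range(20, 60)])
        assert (table["log2_fold_change"].abs() >= 0.25).all()
        assert (table["p_value"] < 0.05).all()
        assert len(table) <= 30

    def test_group_of_two_cells_is_insufficient(self, rng):
        gex = self.make_gex(rng)
        with pytest.raises(ValueError, match="insufficient cells"):
            tf.rank_sum_markers(gex, ["B0", "B1"], [f"B{i}" for i in range(10, 30)])

    def test_overlapping_groups_rejected(self, rng):
        gex = self.make_gex(rng)
        with pytest.raises(ValueError, match="overlap"):
            tf.rank_sum_markers(gex, ["B0", "B1", "B2"], ["B2", "B3", "B4", "B5"])

    def test_pvalues_match_exact_permutation_within_3_se(self, rng):
        """Reported rank-sum p vs a hand-rolled permutation oracle, 8+8 cells."""
        from scipy.stats import rankdata

        gex = self.make_gex(rng, n1=8, n2=8, n_genes=12, boost=[0])
        dense = gex.counts.toarray().astype(float)
        lib = dense.sum(axis=1, keepdims=True)
        norm = np.log1p(dense / lib * 1e4)
        table = tf.rank_sum_markers(gex, [f"B{i}" for i in range(8)],
                                    [f"B{i}" for i in range(8, 16)],
                                    lfc_min=0.0, p_max=1.01, top_n=100)
        pmap = dict(zip(table["gene"], table["p_value"]))
        n_perm = 20_000
        for gi in range(8):
            ranks = rankdata(norm[:, gi])  # permuting labels permutes ranks
            obs_dev = abs(ranks[:8].sum() - ranks.sum() / 2)
            perm_sums = np.array([
                ranks[rng.permutation(16)[:8]].sum() for _ in range(n_perm)])
            p_perm = np.mean(np.abs(perm_sums - ranks.sum() / 2) >= obs_dev - 1e-9)
            se = math.sqrt(max(p_perm * (1 - p_perm), 1e-9) / n_perm)
            gene = f"G{gi}"
            if gene in pmap:
                assert abs(pmap[gene] - p_perm) <= 3 * se + 0.01


class TestRunPipeline:
    def config(self, outdir, seed=3):
        return {
            "seed": seed,
            "outdir": str(outdir),
            "input": {"kind": "synthetic", "n_clones": 120,
                      "samples": [
                          {"sample_id": "pre", "condition": "ACR"},
                          {"sample_id": "post", "condition": "treated"},
                      ]},
            "cluster": {"chains": ["B"]},
            "enrich": {"fold": 10},
            "dynamics": {"pre": "pre", "post": "post"},
        }

    def test_manifest_counts_match_direct_recomputation(self, tmp_path):
        manifest = tf.run_pipeline(self.config(tmp_path / "run1"))
        model = tf.default_model()
        spec = tf.SyntheticSpec(
            n_clones=120, seed=3,
            samples=[("pre", "ACR", {}), ("post", "treated", {})])
        rep, _ = tf.simulate_repertoire(model, spec)
        assert manifest["stages"]["io"]["cells"] == len(rep)
        assert manifest["stages"]["io"]["unique_clones"] == len(rep.unique_clones())
        assert manifest["stages"]["dynamics"]["samples"] == ["post", "pre"]

    def test_rerun_is_byte_identical(self, tmp_path):
        tf.run_pipeline(self.config(tmp_path / "a"))
        tf.run_pipeline(self.config(tmp_path / "b"))
        for name in ("manifest.json", "repertoire.tsv", "clusters.tsv",
                     "enrichment.tsv", "annotation.tsv", "frequencies.tsv",
                     "dynamics.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes(), name

    def test_missing_contigs_fails_at_io_stage(self, tmp_path):
        cfg = self.config(tmp_path / "x")
        cfg["input"] = {"kind": "files"}
        with pytest.raises(tf.PipelineError, match="stage 'io'"):
            tf.run_pipeline(cfg)

    def test_manifest_is_valid_json_with_stage_counts(self, tmp_path):
        tf.run_pipeline(self.config(tmp_path / "m"))
        manifest = json.loads((tmp_path / "m" / "manifest.json").read_text())
        assert set(manifest["stages"]) == {
            "io", "clustering", "enrichment", "annotation", "dynamics"}
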