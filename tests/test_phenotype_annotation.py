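"""TCR-rule classification, rank-based signature scoring, hierarchical gating."""

import math

import numpy as np
import pytest
import scipy.sparse as sp

import tcrfirst as tf
from tcrfirst.repertoire_io import Chain, Clonotype, Repertoire


def ct(ag=None, bd=None):
    return Clonotype(barcode="C1", chain_ag=ag, chain_bd=bd)


class TestClassifyByTcr:
    def test_mait_rule(self):
        c = ct(ag=Chain("TRA", "TRAV1-2", "TRAJ33", "CAVMDSNYQLIW"))
        assert tf.classify_by_tcr(c) == "MAIT"

    @pytest.mark.parametrize("j", ["TRAJ33", "TRAJ20", "TRAJ12"])
    def test_all_three_mait_junction_genes(self, j):
        c = ct(ag=Chain("TRA", "TRAV1-2", j, "CAVMDSNYQLIW"))
        assert tf.classify_by_tcr(c) == "MAIT"

    def test_trav12_with_other_j_is_not_mait(self):
        c = ct(ag=Chain("TRA", "TRAV1-2", "TRAJ17", "CAVMDSNYQLIW"))
        assert tf.classify_by_tcr(c) == "alpha_beta"

    def test_gamma_delta_rule(self):
        c = ct(ag=Chain("TRG", "TRGV4", "TRGJ2", "CALWEVF"),
               bd=Chain("TRD", "TRDV1", "TRDJ1", "CALGELF"))
        assert tf.classify_by_tcr(c) == "gamma_delta"

    def test_cd1bc_candidate_pairing(self):
        c = ct(ag=Chain("TRA", "TRAV13-2", "TRAJ45", "CAVMDSNYQLIW"),
               bd=Chain("TRB", "TRBV4-1", "TRBJ1-1", "CASSFELYF"))
        assert tf.classify_by_tcr(c) == "CD1bc_candidate"

    def test_plain_alpha_beta_falls_through(self):
        c = ct(ag=Chain("TRA", "TRAV8-3", "TRAJ17", "CAVGASKAAGNKLTF"),
               bd=Chain("TRB", "TRBV6-5", "TRBJ1-5", "CASRRTGRNQPQHF"))
        assert tf.classify_by_tcr(c) == "alpha_beta"

    def test_rule_without_requirements_rejected(self):
        with pytest.raises(ValueError, match="no requirements"):
            tf.TcrRule(label="bad", priority=0)

    def test_rules_on_synthetic_repertoire_exact_precision_recall(self, rng):
        """Clones constructed to satisfy each rule are recovered exactly."""
        cells = []
        truth = []
        for i in range(120):
            kind = ["MAIT", "gamma_delta", "CD1bc_candidate", "alpha_beta"][i % 4]
            b = f"C{i}"
            if kind == "MAIT":
                j = ["TRAJ33", "TRAJ20", "TRAJ12"][i % 3]
                cells.append(Clonotype(b, chain_ag=Chain("TRA", "TRAV1-2", j, "CAVMF")))
            elif kind == "gamma_delta":
                cells.append(Clonotype(b, chain_ag=Chain("TRG", "TRGV4", "TRGJ2", "CALWF")))
            elif kind == "CD1bc_candidate":
                cells.append(Clonotype(
                    b, chain_ag=Chain("TRA", "TRAV13-2", "TRAJ45", "CAVMF"),
                    chain_bd=Chain("TRB", "TRBV4-1", "TRBJ1-1", "CASSF")))
            else:
                cells.append(Clonotype(
                    b, chain_ag=Chain("TRA", "TRAV8-3", "TRAJ17", "CAVMF"),
                    chain_bd=Chain("TRB", "TRBV6-5", "TRBJ1-5", "CASSF")))
            truth.append(kind)
        predicted = [tf.classify_by_tcr(c) for c in cells]
        assert predicted == truth


class TestSignatureScore:
    def test_top_ranked_signature_scores_one(self):
        counts = np.zeros(2000)
        counts[:10] = np.arange(100, 90, -1)  # signature occupies ranks 1..10
        assert tf.signature_score(counts, list(range(10))) == pytest.approx(1.0)

    def test_unexpressed_signature_scores_near_zero(self):
        # all 10 signature ranks capped at r_max+1: maximal R, score
        # (n-1)/(2*r_max) ~ 0.003 -- indistinguishable from 0 at gate scale
        counts = np.zeros(3000)
        counts[:1400] = 1  # everything else expressed; signature all zero
        score = tf.signature_score(counts, list(range(2990, 3000)), r_max=1500)
        assert score == pytest.approx(9 / 3000, abs=1e-9)

    def test_null_mean_is_half_under_exchangeable_ranks(self, rng):
        n_genes, r_max = 1500, 1500
        scores = []
        for _ in range(400):
            counts = rng.permutation(n_genes).astype(float)
            genes = rng.choice(n_genes, size=10, replace=False)
            scores.append(tf.signature_score(counts, genes, r_max=r_max))
        se = np.std(scores) / math.sqrt(len(scores))
        assert abs(np.mean(scores) - 0.5) <= 3 * se + 0.01

    def test_invariant_to_monotone_count_transformations(self, rng):
        counts = rng.poisson(2.0, size=500).astype(float)
        genes = [3, 77, 200, 433]
        a = tf.signature_score(counts, genes)
        b = tf.signature_score(np.log1p(counts) * 7.3, genes)
        assert a == pytest.approx(b)

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            tf.signature_score(np.ones(10), [])


def gex_from_dense(dense, features):
    return tf.GexMatrix(
        barcodes=[f"B{i}" for i in range(dense.shape[0])],
        features=features, counts=sp.csr_matrix(dense))


class TestGateCells:
    SIGS = {"CD4": [f"M4_{i}" for i in range(10)],
            "CD8": [f"M8_{i}" for i in range(10)],
            "T": [f"MT_{i}" for i in range(10)]}

    def tree(self):
        # positive-only children: off-phenotype scores are low but noisy, so
        # descent relies on the best-scoring child rather than negative gates
        return tf.GatingNode(
            name="T", positive_signatures=[self.SIGS["T"]],
            children=[
                tf.GatingNode("CD4", positive_signatures=[self.SIGS["CD4"]]),
                tf.GatingNode("CD8", positive_signatures=[self.SIGS["CD8"]]),
            ])

    def simulate(self, effect, seed, n=200):
        phenos = ["CD4"] * (n // 2) + ["CD8"] * (n // 2)
        sigs = {
            "CD4": self.SIGS["CD4"] + self.SIGS["T"],
            "CD8": self.SIGS["CD8"] + self.SIGS["T"],
        }
        gex, labels = tf.simulate_counts(phenos, sigs, n_genes=5000,
                                         nb_mean=0.3, effect=effect, seed=seed)
        return gex, labels

    def test_planted_phenotypes_recovered_at_effect_8(self):
        gex, truth = self.simulate(effect=8, seed=42)
        labels = tf.gate_cells(gex, self.tree())
        acc = np.mean([lbl.gex_label == t for lbl, t in zip(labels, truth)])
        assert acc >= 0.95

    def test_chance_recovery_at_effect_1(self):
        correct = total = 0
        for seed in range(5):
            gex, truth = self.simulate(effect=1, seed=100 + seed)
            labels = tf.gate_cells(gex, self.tree())
            for lbl, t in zip(labels, truth):
                if lbl.gex_label in ("CD4", "CD8"):
                    total += 1
                    correct += lbl.gex_label == t
        if total:
            assert abs(correct / total - 0.5) <= 0.2

    def test_cell_failing_root_is_unknown(self):
        dense = np.zeros((1, 5000))
        features = [g for gs in self.SIGS.values() for g in gs]
        features += [f"G{i}" for i in range(5000 - len(features))]
        labels = tf.gate_cells(gex_from_dense(dense, features), self.tree())
        assert labels[0].gex_label == "non-T/unknown"

    def test_tau_pos_zero_passes_every_positive_gate(self, rng):
        dense = rng.poisson(0.3, size=(20, 5000)).astype(float)
        features = [g for gs in self.SIGS.values() for g in gs]
        features += [f"G{i}" for i in range(5000 - len(features))]
        tree = tf.GatingNode(name="T", positive_signatures=[self.SIGS["T"]])
        labels = tf.gate_cells(gex_from_dense(dense, features), tree, tau_pos=0.0)
        assert all(lbl.gex_label == "T" for lbl in labels)

    def test_batch_size_does_not_change_labels(self):
        gex, _ = self.simulate(effect=8, seed=9)
        a = tf.gate_cells(gex, self.tree(), batch_size=7)
        b = tf.gate_cells(gex, self.tree(), batch_size=1000)
        assert [x.gex_label for x in a] == [y.gex_label for y in b]

    def test_expressed_negative_signature_blocks_gate(self):
        """A cell strongly expressing the negative markers fails the gate."""
        phenos = ["CD8"] * 50
        sigs = {"CD8": self.SIGS["CD8"] + self.SIGS["T"]}
        gex, _ = tf.simulate_counts(phenos, sigs, n_genes=5000,
                                    nb_mean=0.3, effect=8, seed=13)
        gated = tf.GatingNode("notCD8", positive_signatures=[self.SIGS["T"]],
                              negative_signatures=[self.SIGS["CD8"]])
        labels = tf.gate_cells(gex, gated)
        blocked = np.mean([lbl.gex_label == "non-T/unknown" for lbl in labels])
        assert blocked >= 0.95

    def test_cyclic_tree_rejected(self):
        node = tf.GatingNode(name="loop", positive_signatures=[["CD4"]])
        node.children.append(node)
        gex = gex_from_dense(np.ones((1, 2)), ["CD4", "CD8"])
        with pytest.raises(ValueError, match="cycle"):
            tf.gate_cells(gex, node)

    def test_unresolvable_signature_names_missing_genes(self):
        gex = gex_from_dense(np.ones((1, 2)), ["CD4", "CD8"])
        tree = tf.GatingNode(name="T", positive_signatures=[["FOXP3"]])
        with pytest.raises(ValueError, match="FOXP3"):
            tf.gate_cells(gex, tree)


class TestYamlConfig:
    def test_shipped_example_gating_tree_loads(self):
        import importlib.resources as res
        path = res.files("tcrfirst").joinpath("data/example_gating.yaml")
        tree = tf.load_gating_tree(str(path))
        assert tree.name == "T"
        assert {c.name for c in tree.children} >= {"CD4", "CD8"}

    def test_shipped_rules_equal_defaults(self):
        import importlib.resources as res
        path = res.files("tcrfirst").joinpath("data/example_tcr_rules.yaml")
        loaded = tf.load_tcr_rules(str(path))
        assert loaded == tf.default_tcr_rules()

    def test_unknown_gating_key_rejected(self):
        with pytest.raises(ValueError, match="unknown gating node keys"):
            tf.gating_tree_from_dict({"name": "T", "positve": []})


class TestJoinExternalEpitopes:
    def repertoire(self):
        cts = [Clonotype("C1", chain_bd=Chain("TRB", "TRBV9", "TRBJ1", "CASSF")),
               Clonotype("C2", chain_bd=Chain("TRB", "TRBV5-1", "TRBJ1", "CASSG"))]
        return Repertoire(clonotypes=cts)

    def test_threshold_filters_low_scores(self, tmp_path):
        rep = self.repertoire()
        key1 = rep.clonotypes[0].clone_key
        key2 = rep.clonotypes[1].clone_key
        p = tmp_path / "epi.tsv"
        p.write_text("clone_key\tepitope\tscore\n"
                     f"{key1}\tGILGFVFTL\t0.5\n{key2}\tNLVPMVATV\t0.1\n")
        ann = tf.join_external_epitopes(rep, p)
        assert key1 in ann and ann[key1] == ("GILGFVFTL", 0.5)
        assert key2 not in ann

    def test_empty_table_leaves_repertoire_unannotated(self, tmp_path):
        p = tmp_path / "epi.tsv"
        p.write_text("clone_key\tepitope\tscore\n")
        assert tf.join_external_epitopes(self.repertoire(), p) == {}

    def test_malformed_table_rejected(self, tmp_path):
        p = tmp_path / "epi.tsv"
        p.write_text("clone\tscore\nX\t0.5\n")
        with pytest.raises(tf.FormatError):
            tf.join_external_epitopes(self.repertoire(), p)
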