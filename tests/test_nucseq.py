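"""snRNA-seq rules: QC boundaries, normalisation, feature selection,
marker k-means and IEG activation ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from _oracles import qc_keep_bruteforce, top_features_bruteforce
from uihkit import nucseq as ns, synth
from uihkit.core import CountMatrix


def matrix_from_dense(dense, genes=None, labels=None):
    dense = np.asarray(dense)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    barcodes = [f"c{j}" for j in range(dense.shape[1])]
    return CountMatrix(sp.csr_matrix(dense), genes, barcodes, cluster_labels=labels)


class TestQcFilter:
    def make_boundary_matrix(self):
        # 300 genes: 1 mito + 299 nuclear; craft cells at each QC boundary
        n_genes = 8000
        genes = ["mt-Nd1"] + [f"g{i}" for i in range(n_genes - 1)]
        cols = {}
        # mito fraction exactly 5%: 20 mito counts of 400 total, 381 features
        col = np.zeros(n_genes, int)
        col[0] = 20
        col[1:381] = 1  # 380 nuclear counts over 380 genes
        cols["mito_at_boundary_kept"] = col  # 20/400 == 0.05 -> kept
        col = np.zeros(n_genes, int)
        col[0] = 21
        col[1:381] = 1
        cols["mito_above_removed"] = col  # 21/401 > 0.05 -> removed
        col = np.zeros(n_genes, int)
        col[1:200] = 1
        cols["n199_removed"] = col  # 199 features < 200 -> removed
        col = np.zeros(n_genes, int)
        col[1:201] = 1
        cols["n200_kept"] = col
        col = np.zeros(n_genes, int)
        col[1:7501] = 1
        cols["n7500_kept"] = col
        col = np.zeros(n_genes, int)
        col[1:7502] = 1
        cols["n7501_removed"] = col
        dense = np.stack(list(cols.values()), axis=1)
        m = CountMatrix(sp.csr_matrix(dense), genes, list(cols.keys()))
        return m

    def test_boundary_behaviour_exact(self):
        m = self.make_boundary_matrix()
        kept, report = ns.qc_filter(m)
        assert kept.barcodes == ["mito_at_boundary_kept", "n200_kept", "n7500_kept"]
        assert report["removed_mito"] == 1
        assert report["removed_features_low"] == 1
        assert report["removed_features_high"] == 1

    def test_idempotent(self, rng):
        dense = rng.poisson(1.0, (50, 200))
        genes = ["mt-a", "mt-b"] + [f"g{i}" for i in range(48)]
        m = matrix_from_dense(dense, genes)
        thr = ns.QCThresholds(mito_max=0.05, features_min=5, features_max=45)
        once, _ = ns.qc_filter(m, thr)
        twice, rep = ns.qc_filter(once, thr)
        assert twice.barcodes == once.barcodes
        assert rep["n_kept"] == rep["n_input"]

    def test_matches_bruteforce_per_cell_evaluation(self, rng):
        genes = ["mt-a"] + [f"g{i}" for i in range(29)]
        for _ in range(20):
            dense = rng.poisson(rng.uniform(0.2, 2.0), (30, 40))
            dense[:, 0] += 1  # no empty first cell
            m = matrix_from_dense(dense, genes)
            thr = ns.QCThresholds(mito_max=0.1, features_min=3, features_max=25)
            kept, _ = ns.qc_filter(m, thr)
            exp = qc_keep_bruteforce(dense, genes, 0.1, 3, 25)
            assert kept.barcodes == [f"c{j}" for j in range(40) if exp[j]]

    def test_all_removed_warns_and_returns_empty(self):
        dense = np.ones((30, 5), int)  # 30 features < 200 everywhere
        m = matrix_from_dense(dense)
        with pytest.warns(UserWarning, match="all cells removed"):
            kept, _ = ns.qc_filter(m)
        assert kept.n_cells == 0


class TestLognormalize:
    def test_zero_count_stays_zero_and_arithmetic(self):
        dense = np.zeros((3, 1), int)
        dense[0, 0] = 10
        dense[1, 0] = 9990
        m = matrix_from_dense(dense)
        norm = ns.lognormalize(m)  # cell total 10,000
        assert norm[0, 0] == pytest.approx(np.log(11.0))
        assert norm[2, 0] == 0.0

    def test_depth_invariance(self, rng):
        dense = rng.poisson(2.0, (20, 1)) + 1
        a = ns.lognormalize(matrix_from_dense(dense))
        b = ns.lognormalize(matrix_from_dense(dense * 2))
        assert np.allclose(a.toarray(), b.toarray())

    def test_zero_pattern_preserved(self, rng):
        dense = rng.poisson(0.5, (30, 20))
        dense[:, dense.sum(axis=0) == 0] += 1
        m = matrix_from_dense(dense)
        norm = ns.lognormalize(m)
        assert np.array_equal(norm.toarray() != 0, dense != 0)


class TestVariableFeatures:
    def test_constant_gene_never_beats_variable_gene(self, rng):
        dense = np.vstack([np.full(20, 5), rng.poisson(5.0, (5, 20))])
        genes = ["flat"] + [f"v{i}" for i in range(5)]
        m = matrix_from_dense(dense, genes)
        top = ns.select_variable_features(ns.lognormalize(m), genes, n=5, exclude=[])
        assert "flat" not in top

    def test_ieg_excluded_regardless_of_dispersion(self, rng):
        dense = rng.poisson(1.0, (10, 30)) + 1
        dense[0] = rng.poisson(20.0, 30)  # hugely variable IEG
        genes = ["Fos"] + [f"g{i}" for i in range(9)]
        m = matrix_from_dense(dense, genes)
        top = ns.select_variable_features(ns.lognormalize(m), genes, n=5)
        assert "Fos" not in top

    def test_matches_bruteforce_on_toys(self, rng):
        for _ in range(20):
            dense = rng.poisson(rng.uniform(0.5, 3.0), (50, 20))
            dense[:, dense.sum(axis=0) == 0] += 1
            genes = [f"g{i}" for i in range(50)]
            exclude = [genes[i] for i in rng.choice(50, 5, replace=False)]
            m = matrix_from_dense(dense, genes)
            norm = ns.lognormalize(m)
            got = ns.select_variable_features(norm, genes, n=10, exclude=exclude)
            exp = top_features_bruteforce(norm.toarray(), genes, 10, exclude)
            assert got == exp

    def test_too_few_candidates_warns_and_returns_all(self, rng):
        dense = rng.poisson(2.0, (5, 10)) + 1
        genes = [f"g{i}" for i in range(5)]
        m = matrix_from_dense(dense, genes)
        with pytest.warns(UserWarning, match="candidate"):
            got = ns.select_variable_features(ns.lognormalize(m), genes, n=100, exclude=[])
        assert sorted(got) == sorted(genes)


def kmeans_partition_cost(X, assign):
    cost = 0.0
    for k in set(assign):
        pts = X[[i for i, a in enumerate(assign) if a == k]]
        cost += ((pts - pts.mean(axis=0)) ** 2).sum()
    return cost


class TestTorporKmeans:
    def test_separated_groups_exact_recovery_vs_enumeration(self, rng):
        profiles = pd.DataFrame(
            np.vstack([rng.normal(5.0, 0.1, (3, 3)), rng.normal(0.5, 0.1, (5, 3))]),
            index=[f"c{i}" for i in range(8)],
            columns=list(synth.TORPOR_MARKERS),
        )
        got = ns.torpor_kmeans(profiles, k=2, seed=0)
        assert got == {"c0", "c1", "c2"}
        # exhaustive 2-partition oracle: k-means objective minimiser
        X = profiles.to_numpy()
        best, best_cost = None, np.inf
        for bits in itertools.product([0, 1], repeat=8):
            if len(set(bits)) < 2:
                continue
            cost = kmeans_partition_cost(X, bits)
            if cost < best_cost:
                best, best_cost = bits, cost
        hi = max(set(best), key=lambda k: X[[i for i, b in enumerate(best) if b == k]].mean())
        assert got == {f"c{i}" for i, b in enumerate(best) if b == hi}

    def test_identical_profiles_degenerate_warning(self):
        profiles = pd.DataFrame(
            np.ones((4, 3)), index=list("abcd"), columns=list(synth.TORPOR_MARKERS)
        )
        with pytest.warns(UserWarning, match="degenerate"):
            got = ns.torpor_kmeans(profiles, k=2)
        assert got == {"a", "b", "c", "d"}

    def test_row_permutation_invariance(self, rng):
        X = np.vstack([rng.normal(4.0, 0.2, (2, 3)), rng.normal(0.2, 0.1, (4, 3))])
        names = [f"c{i}" for i in range(6)]
        profiles = pd.DataFrame(X, index=names, columns=list(synth.TORPOR_MARKERS))
        got = ns.torpor_kmeans(profiles, k=2, seed=1)
        perm = rng.permutation(6)
        shuffled = profiles.iloc[perm]
        assert ns.torpor_kmeans(shuffled, k=2, seed=1) == got

    def test_k_larger_than_clusters_rejected(self):
        profiles = pd.DataFrame(np.eye(3), columns=list(synth.TORPOR_MARKERS))
        with pytest.raises(ValueError, match="k="):
            ns.torpor_kmeans(profiles, k=5)


class TestIegRank:
    def make_profiles(self):
        return pd.DataFrame(
            [[5, 5, 5, 5, 5], [1, 1, 1, 1, 1], [2, 2, 2, 2, 2]],
            index=["hot", "cold", "mid"],
            columns=list(synth.IEG_MARKERS),
            dtype=float,
        )

    def test_maximal_cluster_ranks_first(self):
        rank = ns.ieg_activation_rank(self.make_profiles(), {"hot", "cold", "mid"})
        assert rank.index[0] == "hot" and rank["rank"].iloc[0] == 1

    def test_all_equal_ties_flagged_and_ordered_by_id(self):
        profiles = pd.DataFrame(
            np.ones((3, 5)), index=["b", "a", "c"], columns=list(synth.IEG_MARKERS)
        )
        rank = ns.ieg_activation_rank(profiles, {"a", "b", "c"})
        assert list(rank.index) == ["a", "b", "c"]
        assert rank["tied"].all()

    def test_score_matches_bruteforce(self, rng):
        X = rng.uniform(0, 4, (6, 5))
        profiles = pd.DataFrame(
            X, index=[f"c{i}" for i in range(6)], columns=list(synth.IEG_MARKERS)
        )
        torpor = {"c0", "c2", "c4", "c5"}
        rank = ns.ieg_activation_rank(profiles, torpor)
        sub = profiles.loc[sorted(torpor)].to_numpy()
        z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
        for i, c in enumerate(sorted(torpor)):
            assert rank.loc[c, "ieg_score"] == pytest.approx(z[i].mean())

    def test_empty_torpor_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ns.ieg_activation_rank(self.make_profiles(), set())


class TestClassifyExcInh:
    def make(self, slc, gad):
        return pd.DataFrame(
            {"Slc17a6": slc, "Gad1": gad}, index=[f"c{i}" for i in range(len(slc))]
        )

    def test_four_quadrants(self):
        profiles = self.make([2.0, 0.1, 2.0, 0.1], [0.1, 2.0, 2.0, 0.1])
        labels = ns.classify_excitatory_inhibitory(profiles)
        assert labels == {
            "c0": "excitatory", "c1": "inhibitory", "c2": "hybrid", "c3": "unassigned"
        }

    def test_threshold_sweep_monotone_in_unassigned(self, rng):
        profiles = self.make(rng.uniform(0, 3, 20), rng.uniform(0, 3, 20))
        prev = -1
        for thr in np.linspace(0.0, 3.0, 13):
            labels = ns.classify_excitatory_inhibitory(profiles, threshold=thr)
            n_unassigned = sum(v == "unassigned" for v in labels.values())
            assert n_unassigned >= prev
            prev = n_unassigned

    def test_missing_marker_rejected(self):
        profiles = pd.DataFrame({"Slc17a6": [1.0]})
        with pytest.raises(ValueError, match="Gad1"):
            ns.classify_excitatory_inhibitory(profiles)


class TestPipelineRecovery:
    def test_planted_activated_cluster_recovered(self):
        """QC + log-normalisation + marker k-means + IEG ranking recover the
        planted activated torpor cluster on a small matrix."""
        from uihkit.validation import _nucseq_spec

        spec = _nucseq_spec(8.0)
        m, truth = synth.simulate_counts(800, spec, seed=5, n_genes=400)
        filtered, _ = ns.qc_filter(m)
        norm = ns.lognormalize(filtered)
        prof = ns.cluster_profiles(
            norm, filtered.genes, filtered.cluster_labels, synth.TORPOR_MARKERS
        )
        torpor = ns.torpor_kmeans(prof, k=2, seed=5)
        assert torpor == {"c0", "c1", "c2"}
        ieg = ns.cluster_profiles(
            norm, filtered.genes, filtered.cluster_labels, synth.IEG_MARKERS
        )
        rank = ns.ieg_activation_rank(ieg, torpor)
        assert rank.index[0] == truth["activated_cluster"]
        exc = ns.cluster_profiles(
            norm, filtered.genes, filtered.cluster_labels, ("Slc17a6", "Gad1")
        )
        labels = ns.classify_excitatory_inhibitory(exc)
        assert all(labels[c] == "excitatory" for c in torpor)
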