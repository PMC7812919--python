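"""Specificity scores, marker selection, merge correction, annotation."""

import numpy as np
import pandas as pd
import pytest

from sliceglia import (
    GeneSetCollection,
    annotate_clusters,
    cluster_cells,
    cluster_profile,
    default_populations,
    merge_correlated_clusters,
    normalize_counts,
    replay_merges,
    select_cluster_markers,
    simulate_single_cell_counts,
    specificity_scores,
)
from sliceglia.clustering import ClusterAssignment, ClusterProfile
from sliceglia.errors import ConfigError


def _profile(mean_umi: dict, genes: list[str], n_cells: dict) -> ClusterProfile:
    return ClusterProfile(
        mean_umi=pd.DataFrame(mean_umi, index=genes),
        n_cells=pd.Series(n_cells),
    )


def _assignment_from_labels(labels: np.ndarray, obs_ids: list[str]) -> ClusterAssignment:
    return ClusterAssignment(
        labels=pd.Series(labels, index=obs_ids, name="cluster"),
        k=int(labels.max()) + 1,
        provenance={"merges": [], "pre_merge_labels": dict(zip(obs_ids, map(int, labels)))},
    )


class TestSpecificityScores:
    def test_exclusive_gene_scores_one(self):
        prof = _profile({0: [3.0, 1.0], 1: [0.0, 1.0], 2: [0.0, 2.0]},
                        ["gA", "gB"], {0: 5, 1: 5, 2: 5})
        spec = specificity_scores(prof)
        np.testing.assert_allclose(spec.spec.loc["gA"], [1.0, 0.0, 0.0])
        np.testing.assert_allclose(spec.spec.loc["gB"], [0.25, 0.25, 0.5])

    def test_equal_means_split_evenly(self):
        prof = _profile({c: [2.0] for c in range(4)}, ["gA"], {c: 5 for c in range(4)})
        np.testing.assert_allclose(specificity_scores(prof).spec.loc["gA"], [0.25] * 4)

    def test_hand_computed_2_1_1(self):
        prof = _profile({0: [2.0], 1: [1.0], 2: [1.0]}, ["gA"], {0: 2, 1: 2, 2: 2})
        np.testing.assert_allclose(specificity_scores(prof).spec.loc["gA"], [0.5, 0.25, 0.25])

    def test_all_zero_gene_has_zero_row_and_others_sum_to_one(self):
        prof = _profile({0: [0.0, 1.0], 1: [0.0, 3.0]}, ["dead", "live"], {0: 5, 1: 5})
        spec = specificity_scores(prof).spec
        np.testing.assert_array_equal(spec.loc["dead"], [0.0, 0.0])
        assert spec.loc["live"].sum() == pytest.approx(1.0)


class TestSelectClusterMarkers:
    def test_low_mean_excluded_despite_perfect_specificity(self):
        prof = _profile({0: [0.19, 5.0], 1: [0.0, 4.0]}, ["rare", "common"], {0: 5, 1: 5})
        per_cluster, union = select_cluster_markers(prof, specificity_scores(prof), top_n=10)
        assert "rare" not in per_cluster[0]
        assert "common" in per_cluster[0]

    def test_truncation_returns_all_when_fewer_eligible(self):
        genes = [f"g{i}" for i in range(40)]
        prof = _profile({0: np.full(40, 1.0), 1: np.full(40, 0.3)}, genes, {0: 5, 1: 5})
        per_cluster, _ = select_cluster_markers(prof, specificity_scores(prof), top_n=100)
        assert len(per_cluster[0]) == 40

    def test_tie_broken_by_lexicographic_gene_id(self):
        # identical specificity for all genes; top_n=2 keeps smallest ids
        genes = ["gC", "gA", "gB"]
        prof = _profile({0: np.full(3, 2.0), 1: np.full(3, 2.0)}, genes, {0: 5, 1: 5})
        per_cluster, _ = select_cluster_markers(prof, specificity_scores(prof), top_n=2)
        assert per_cluster[0] == ["gA", "gB"]

    def test_cluster_with_no_eligible_gene_raises(self):
        prof = _profile({0: [1.0], 1: [0.05]}, ["gA"], {0: 5, 1: 5})
        with pytest.raises(ConfigError, match="cluster 1"):
            select_cluster_markers(prof, specificity_scores(prof))


# chain fixture: corr(A,B)=0.830, corr(A,C)=0.774, corr(B,C)=0.783,
# corr(mean(A,B),C)=0.814, D uncorrelated with everything (max |r|=0.129)
CHAIN_A = [2.663, 1.756, 4.208, 4.374, 2.386, 4.604, 3.65, 2.751, 2.15, 2.904,
           2.34, 1.642, 1.641, 3.217, 1.844, 3.851, 4.491, 2.51, 3.786, 2.313]
CHAIN_B = [2.88, 2.319, 3.424, 4.701, 2.078, 4.941, 3.039, 2.049, 3.312, 3.153,
           2.503, 1.833, 0.767, 3.097, 2.044, 4.545, 3.632, 3.594, 3.707, 2.271]
CHAIN_C = [3.3, 2.92, 2.747, 3.68, 2.102, 4.438, 4.032, 1.513, 2.239, 3.972,
           2.284, 1.544, 1.52, 2.771, 2.473, 3.941, 4.626, 2.985, 4.597, 2.314]
CHAIN_D = [0.586, 1.736, 3.01, 3.406, 1.62, 1.437, 1.821, 4.487, 2.367, 3.91,
           3.197, 4.576, 3.598, 2.45, 2.138, 4.064, 3.24, 3.426, 4.327, 3.235]


def brute_force_merge_partitions(profile: ClusterProfile, markers, threshold):
    """All terminal partitions reachable by merging any pair above threshold
    (weighted-mean profiles recomputed after each merge)."""
    def corr_pairs(prof):
        vals = prof.mean_umi.loc[markers].to_numpy().T
        corr = np.corrcoef(vals)
        np.fill_diagonal(corr, -np.inf)
        cols = list(prof.mean_umi.columns)
        return [(corr[i, j], cols[i], cols[j])
                for i in range(len(cols)) for j in range(i + 1, len(cols))
                if corr[i, j] > threshold]

    def merge(prof, members, a, b):
        na, nb = prof.n_cells[a], prof.n_cells[b]
        merged_col = (prof.mean_umi[a] * na + prof.mean_umi[b] * nb) / (na + nb)
        mean_umi = prof.mean_umi.drop(columns=[b]).copy()
        mean_umi[a] = merged_col
        n_cells = prof.n_cells.drop(b).copy()
        n_cells[a] = na + nb
        order = [c for c in prof.mean_umi.columns if c != b]
        new_members = {k: v for k, v in members.items() if k != b}
        new_members[a] = members[a] | members[b]
        return ClusterProfile(mean_umi[order], n_cells[order]), new_members

    terminals = set()

    def explore(prof, members):
        pairs = corr_pairs(prof)
        if not pairs:
            terminals.add(frozenset(frozenset(v) for v in members.values()))
            return
        for _, a, b in pairs:
            explore(*merge(prof, members, a, b))

    explore(profile, {c: frozenset([c]) for c in profile.mean_umi.columns})
    return terminals


class TestMergeCorrelatedClusters:
    def _chain_setup(self):
        genes = [f"m{i:02d}" for i in range(20)]
        prof = _profile({0: CHAIN_A, 1: CHAIN_B, 2: CHAIN_C, 3: CHAIN_D},
                        genes, {0: 10, 1: 10, 2: 10, 3: 10})
        obs = [f"c{i}" for i in range(8)]
        asg = _assignment_from_labels(np.array([0, 0, 1, 1, 2, 2, 3, 3]), obs)
        return asg, prof, genes

    def test_chain_merge_matches_exhaustive_oracle(self):
        """A~B merge first, then (A∪B)~C; D untouched — and the result
        equals every terminal partition of a brute-force merge-order search."""
        asg, prof, genes = self._chain_setup()
        merged = merge_correlated_clusters(
            asg, prof, marker_union=genes, recompute_markers=False, min_avg_umi=0.0
        )
        assert merged.k == 2
        # original clusters 0,1,2 end together, 3 alone
        final = merged.labels
        assert final["c0"] == final["c2"] == final["c4"]
        assert final["c6"] != final["c0"]
        terminals = brute_force_merge_partitions(prof, genes, 0.8)
        assert terminals == {frozenset({frozenset({0, 1, 2}), frozenset({3})})}
        assert len(merged.provenance["merges"]) == 2
        assert merged.provenance["merges"][0]["correlation"] == pytest.approx(0.830, abs=0.001)

    def test_random_profiles_match_oracle_terminal_set(self):
        rng = np.random.default_rng(77)
        genes = [f"m{i}" for i in range(12)]
        for _ in range(20):
            prof = _profile({c: rng.uniform(0.5, 8, 12) for c in range(4)},
                            genes, {c: 10 for c in range(4)})
            obs = [f"c{i}" for i in range(8)]
            asg = _assignment_from_labels(np.array([0, 0, 1, 1, 2, 2, 3, 3]), obs)
            merged = merge_correlated_clusters(
                asg, prof, marker_union=genes, recompute_markers=False, min_avg_umi=0.0
            )
            groups: dict[int, set] = {}
            pre = merged.provenance["pre_merge_labels"]
            for o in obs:
                groups.setdefault(int(merged.labels[o]), set()).add(pre[o])
            got = frozenset(frozenset(v) for v in groups.values())
            assert got in brute_force_merge_partitions(prof, genes, 0.8)

    def test_noop_above_max_correlation_threshold(self):
        asg, prof, genes = self._chain_setup()
        merged = merge_correlated_clusters(
            asg, prof, marker_union=genes, recompute_markers=False,
            corr_threshold=1.0 + 1e-9, min_avg_umi=0.0,
        )
        assert merged.k == 4
        assert merged.provenance["merges"] == []

    def test_merges_everything_at_threshold_minus_one(self):
        asg, prof, genes = self._chain_setup()
        merged = merge_correlated_clusters(
            asg, prof, marker_union=genes, recompute_markers=False,
            corr_threshold=-1.0, min_avg_umi=0.0,
        )
        assert merged.k == 1

    def test_never_increases_cluster_count(self):
        asg, prof, genes = self._chain_setup()
        merged = merge_correlated_clusters(asg, prof, marker_union=genes,
                                           recompute_markers=False, min_avg_umi=0.0)
        assert merged.k <= asg.k

    def test_provenance_replay_reconstructs_final_labels(self):
        asg, prof, genes = self._chain_setup()
        merged = merge_correlated_clusters(asg, prof, marker_union=genes,
                                           recompute_markers=False, min_avg_umi=0.0)
        pre = pd.Series(merged.provenance["pre_merge_labels"])
        replayed = replay_merges(pre, merged.provenance)
        pd.testing.assert_series_equal(replayed, merged.labels.rename(None), check_names=False)
        # and the recorded pre-merge labels are the input labels
        pd.testing.assert_series_equal(pre, asg.labels.rename(None), check_names=False,
                                       check_dtype=False)

    def test_marker_genes_missing_from_profile_rejected(self):
        asg, prof, genes = self._chain_setup()
        with pytest.raises(ConfigError, match="absent"):
            merge_correlated_clusters(asg, prof, marker_union=["ghost_gene"],
                                      recompute_markers=False)

    def test_planted_split_restored_and_distinct_preserved(self):
        """An artificial 2-way split of one population is merged back;
        three genuinely distinct populations stay distinct."""
        pops, genes, _ = default_populations(n_genes=1000, n_cells=200, seed=5)
        m, truth = simulate_single_cell_counts(pops[:2], n_genes=1000, seed=55)
        labels = np.where(truth.obs_labels.to_numpy() == pops[0].name, 0, 2)
        half = np.random.default_rng(5).permutation(np.flatnonzero(labels == 0))[:100]
        labels[half] = 1
        asg = _assignment_from_labels(labels, m.obs_ids)
        merged = merge_correlated_clusters(asg, cluster_profile(m, asg))
        assert merged.k == 2

        m3, truth3 = simulate_single_cell_counts(pops[:3], n_genes=1000, seed=56)
        lab3 = pd.factorize(truth3.obs_labels)[0]
        asg3 = _assignment_from_labels(lab3, m3.obs_ids)
        merged3 = merge_correlated_clusters(asg3, cluster_profile(m3, asg3))
        assert merged3.k == 3
        assert merged3.provenance["merges"] == []


class TestClusterCells:
    def test_separated_populations_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score
        pops, genes, _ = default_populations(n_genes=800, n_cells=300, seed=2)
        m, truth = simulate_single_cell_counts(pops[:2], n_genes=800, seed=21)
        logm = normalize_counts(m, log_transform=True)
        asg = cluster_cells(logm, n_pcs=50, n_neighbors=20, resolution=0.5, seed=1)
        assert adjusted_rand_score(truth.obs_labels.to_numpy(), asg.labels.to_numpy()) == 1.0

    def test_same_seed_identical_labels(self):
        pops, genes, _ = default_populations(n_genes=400, n_cells=60, seed=3)
        m, _ = simulate_single_cell_counts(pops[:3], n_genes=400, seed=31)
        logm = normalize_counts(m, log_transform=True)
        a1 = cluster_cells(logm, n_pcs=30, n_neighbors=10, seed=4)
        a2 = cluster_cells(logm, n_pcs=30, n_neighbors=10, seed=4)
        pd.testing.assert_series_equal(a1.labels, a2.labels)

    def test_n_neighbors_at_least_cell_count_rejected(self):
        pops, genes, _ = default_populations(n_genes=300, n_cells=5, program_size=20, seed=0)
        m, _ = simulate_single_cell_counts(pops[:2], n_genes=300, seed=1)
        logm = normalize_counts(m, log_transform=True)
        with pytest.raises(ConfigError, match="n_neighbors"):
            cluster_cells(logm, n_neighbors=20)

    def test_labels_renumbered_by_descending_size(self):
        pops, genes, _ = default_populations(n_genes=400, n_cells=100, seed=6)
        pops[1].n_cells = 200  # population 1 larger -> its cluster should be 0
        m, truth = simulate_single_cell_counts(pops[:2], n_genes=400, seed=61)
        logm = normalize_counts(m, log_transform=True)
        asg = cluster_cells(logm, n_pcs=30, n_neighbors=15, seed=2)
        sizes = asg.labels.value_counts().sort_index()
        assert (sizes.diff().dropna() <= 0).all()


class TestAnnotateClusters:
    def test_planted_programs_annotated_by_argmax_signature(self):
        pops, genes, programs = default_populations(n_genes=700, n_cells=80,
                                                    program_fold=6.0, seed=8)
        use = [p.name for p in pops[:3]]
        m, truth = simulate_single_cell_counts(pops[:3], n_genes=700, seed=81)
        cpm = normalize_counts(m)
        lab = pd.factorize(truth.obs_labels)[0]
        asg = _assignment_from_labels(lab, m.obs_ids)
        gsets = GeneSetCollection(sets={name: programs[name] for name in use})
        out = annotate_clusters(cpm, asg, gsets, run_marker_test=False)
        for cluster, name in enumerate(use):
            assert out["annotation"][cluster] == name

    def test_marker_test_flags_program_genes(self):
        pops, genes, programs = default_populations(n_genes=500, n_cells=60,
                                                    program_fold=8.0, seed=9)
        m, truth = simulate_single_cell_counts(pops[:2], n_genes=500, seed=91)
        cpm = normalize_counts(m)
        lab = pd.factorize(truth.obs_labels)[0]
        asg = _assignment_from_labels(lab, m.obs_ids)
        gsets = GeneSetCollection(sets={p.name: programs[p.name] for p in pops[:2]})
        out = annotate_clusters(cpm, asg, gsets)
        res = out["markers"][0].table
        prog = programs[pops[0].name]
        assert (res.loc[prog, "fdr"] < 0.05).mean() > 0.9
        assert (res.loc[prog, "log2fc"] > 0).all()

    def test_empty_geneset_collection_rejected(self, tiny_matrix):
        from sliceglia import GeneSetCollection as GSC
        cpm = normalize_counts(tiny_matrix)
        asg = _assignment_from_labels(np.array([0, 0, 1, 1]), tiny_matrix.obs_ids)
        with pytest.raises(ConfigError):
            annotate_clusters(cpm, asg, GSC(sets={}), min_cells=2)
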