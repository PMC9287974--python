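import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from methylhet import phylo
from methylhet.exceptions import IdentityError, ValidationError
from methylhet.io_formats import BetaMatrix, SampleSheet
from methylhet.phylo import (
    DistanceMatrix,
    attach_reference_and_root,
    build_me_tree,
    classical_mds,
    euclidean_distances,
    hierarchical_clustering,
    neighbor_joining,
    select_top_variable_probes,
    verify_sample_identity,
)
from methylhet.synthetic_data import SimulationDesign, simulate

from _oracles import (
    brute_agglomerate,
    min_ols_total_exhaustive,
    tree_metric_from_random_tree,
)
from conftest import random_beta


def _dist_from_points(n, dims, rng, ids=None):
    pts = rng.random((n, dims))
    ids = ids or [f"L{i}" for i in range(n)]
    return DistanceMatrix(ids, squareform(pdist(pts))), pts


class TestProbeSelection:
    def test_variance_ranking(self):
        values = pd.DataFrame(
            {"A": [0.0, 0.45, 0.0], "B": [0.2, 0.55, 0.3], "C": [0.4, 0.50, 0.6]},
            index=pd.Index(["p1", "p2", "p3"], name="probe_id"))
        top = select_top_variable_probes(BetaMatrix(values), ["A", "B", "C"], 2)
        assert top == ["p3", "p1"]  # variances 0.09, 0.04, 0.0025

    def test_k_equals_all(self):
        rng = np.random.default_rng(0)
        bm = random_beta(rng, 10, ["A", "B", "C"])
        top = select_top_variable_probes(bm, ["A", "B", "C"], 10)
        assert len(top) == 10
        var = bm.values.var(axis=1, ddof=1)
        assert list(var[top]) == sorted(var, reverse=True)

    def test_reference_excluded_from_ranking_but_not_distances(self):
        # probe p1 varies only in the reference; excluding the reference from
        # the ranking must drop it below p2
        values = pd.DataFrame(
            {"A": [0.5, 0.1], "B": [0.5, 0.3], "REF": [1.0, 0.2]},
            index=pd.Index(["p1", "p2"], name="probe_id"))
        top = select_top_variable_probes(
            BetaMatrix(values), ["A", "B", "REF"], 1,
            exclude_from_selection=["REF"])
        assert top == ["p2"]
        dist = euclidean_distances(BetaMatrix(values), ["A", "B", "REF"], top)
        assert dist.get("A", "REF") == pytest.approx(0.1)

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(1)
        bm = random_beta(rng, 500, ["A", "B", "C", "D"])
        top = select_top_variable_probes(bm, ["A", "B", "C", "D"], 50)
        var = bm.values.var(axis=1, ddof=1)
        brute = sorted(var.index, key=lambda p: (-var[p], p))[:50]
        assert top == brute

    def test_too_large_k_rejected(self):
        rng = np.random.default_rng(2)
        bm = random_beta(rng, 5, ["A", "B"])
        with pytest.raises(ValidationError, match="top"):
            select_top_variable_probes(bm, ["A", "B"], 6)


class TestDistances:
    def test_identical_samples_zero(self):
        rng = np.random.default_rng(3)
        bm = random_beta(rng, 10, ["A"])
        bm2 = BetaMatrix(bm.values.assign(B=bm.values["A"]))
        dist = euclidean_distances(bm2, ["A", "B"], list(bm2.probe_ids))
        assert dist.get("A", "B") == 0.0

    def test_three_four_five(self):
        values = pd.DataFrame(
            {"i": [0.0, 0.0], "j": [0.3, 0.4]},
            index=pd.Index(["p1", "p2"], name="probe_id"))
        dist = euclidean_distances(BetaMatrix(values), ["i", "j"], ["p1", "p2"])
        assert dist.get("i", "j") == pytest.approx(0.5)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        bm = random_beta(rng, 30, ["A", "B", "C"])
        d = euclidean_distances(bm, ["A", "B", "C"], list(bm.probe_ids))
        for x, y, z in itertools.permutations(["A", "B", "C"]):
            assert d.get(x, z) <= d.get(x, y) + d.get(y, z) + 1e-12

    def test_missing_value_among_selected_probes_rejected(self):
        values = pd.DataFrame(
            {"A": [0.1, np.nan], "B": [0.2, 0.3]},
            index=pd.Index(["p1", "p2"], name="probe_id"))
        with pytest.raises(ValidationError, match="missing"):
            euclidean_distances(BetaMatrix(values), ["A", "B"], ["p1", "p2"])


class TestMinimalEvolutionTree:
    def test_three_leaf_closed_form(self):
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = build_me_tree(D)
        lengths = {leaf: tree.adj[leaf][next(iter(tree.adj[leaf]))]
                   for leaf in tree.leaves()}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    @pytest.mark.parametrize("n_leaves", [5, 6])
    def test_additive_metric_recovered_exactly(self, n_leaves):
        rng = np.random.default_rng(17)
        leaves, D, true_total = tree_metric_from_random_tree(n_leaves, rng)
        tree = build_me_tree(DistanceMatrix(leaves, D))
        fitted = tree.leaf_path_lengths().loc[leaves, leaves].to_numpy()
        np.testing.assert_allclose(fitted, D, atol=1e-9)
        assert tree.total_length == pytest.approx(true_total, abs=1e-9)

    def test_nj_four_point_consistency_on_additive_input(self):
        rng = np.random.default_rng(23)
        leaves, D, _ = tree_metric_from_random_tree(5, rng)
        tree = neighbor_joining(DistanceMatrix(leaves, D))
        fitted = tree.leaf_path_lengths().loc[leaves, leaves].to_numpy()
        np.testing.assert_allclose(fitted, D, atol=1e-9)

    @pytest.mark.parametrize("n_leaves,seed", [(5, 0), (5, 1), (6, 2), (6, 3)])
    def test_total_length_matches_exhaustive_enumeration(self, n_leaves, seed):
        rng = np.random.default_rng(seed)
        # perturbed tree metric: realistic near-additive distances
        leaves, D, _ = tree_metric_from_random_tree(n_leaves, rng)
        D = D + rng.uniform(0, 0.2, D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = build_me_tree(DistanceMatrix(leaves, D))
        best = min_ols_total_exhaustive(D, leaves)
        assert tree.ols_total_length == pytest.approx(best, abs=1e-9)

    def test_nni_never_worsens_ols_residual(self):
        rng = np.random.default_rng(31)
        D, _ = _dist_from_points(7, 3, rng)
        start = neighbor_joining(D)
        from methylhet.phylo import ols_branch_lengths
        _, _, start_resid = ols_branch_lengths(start.copy_topology(), D)
        tree = build_me_tree(D)
        _, _, final_resid = ols_branch_lengths(tree.copy_topology(), D)
        assert final_resid <= start_resid + 1e-12

    def test_deterministic_newick(self):
        rng = np.random.default_rng(41)
        D, _ = _dist_from_points(6, 3, rng)
        assert build_me_tree(D).to_newick() == build_me_tree(D).to_newick()

    def test_nonfinite_distance_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["A", "B", "C"],
                           np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]]))


class TestRooting:
    def test_root_at_leaf_makes_others_siblings(self):
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        rooted = attach_reference_and_root(build_me_tree(D), "A")
        assert rooted.to_newick() == "(A:0.5,(B:1.5,C:2.5):0);"

    def test_rerooting_preserves_path_lengths(self):
        rng = np.random.default_rng(43)
        D, _ = _dist_from_points(6, 3, rng)
        tree = build_me_tree(D)
        unrooted = tree.leaf_path_lengths()

        def pairwise(node):
            """(leaf -> distance to node, {(a, b) -> path length})."""
            if not node.children:
                return {node.name: 0.0}, {}
            depth, pairs, child_maps = {}, {}, []
            for c in node.children:
                cd, cp = pairwise(c)
                cd = {k: v + c.length for k, v in cd.items()}
                pairs.update(cp)
                child_maps.append(cd)
                depth.update(cd)
            for i in range(len(child_maps)):
                for j in range(i + 1, len(child_maps)):
                    for a, da in child_maps[i].items():
                        for b, db in child_maps[j].items():
                            pairs[tuple(sorted((a, b)))] = da + db
            return depth, pairs

        for ref in tree.leaves():
            _, pairs = pairwise(attach_reference_and_root(tree, ref))
            for (a, b), d in pairs.items():
                assert d == pytest.approx(unrooted.loc[a, b], abs=1e-9)

    def test_unknown_reference_rejected(self):
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        with pytest.raises(ValidationError, match="unknown reference"):
            attach_reference_and_root(build_me_tree(D), "Z")

    def test_rooting_matches_dendropy_edge_rooting(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(47)
        D, _ = _dist_from_points(6, 3, rng)
        tree = build_me_tree(D)
        ref = tree.leaves()[2]
        rooted = attach_reference_and_root(tree, ref)
        t1 = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        t2 = dendropy.Tree.get(data=rooted.to_newick(), schema="newick")
        pdm1 = t1.phylogenetic_distance_matrix()
        pdm2 = t2.phylogenetic_distance_matrix()
        tax1 = {t.label: t for t in t1.taxon_namespace}
        tax2 = {t.label: t for t in t2.taxon_namespace}
        for a, b in itertools.combinations(tree.leaves(), 2):
            assert pdm1.distance(tax1[a], tax1[b]) == pytest.approx(
                pdm2.distance(tax2[a], tax2[b]), abs=1e-9)


class TestClustering:
    @pytest.mark.parametrize("method", ["complete", "average"])
    def test_matches_brute_force_agglomeration(self, method):
        rng = np.random.default_rng(53)
        D, _ = _dist_from_points(8, 3, rng)
        dend = hierarchical_clustering(D, method)
        brute = brute_agglomerate(D.values, method)
        np.testing.assert_allclose(dend.merge_heights, brute, atol=1e-12)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(59)
        D, _ = _dist_from_points(10, 4, rng)
        heights = hierarchical_clustering(D).merge_heights
        assert (np.diff(heights) >= -1e-12).all()

    def test_first_split_separates_synthetic_groups(self):
        rng = np.random.default_rng(61)
        g1 = rng.normal(0.2, 0.02, (4, 30))
        g2 = rng.normal(0.8, 0.02, (4, 30))
        pts = np.vstack([g1, g2])
        ids = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        D = DistanceMatrix(ids, squareform(pdist(pts)))
        cut = hierarchical_clustering(D).cut(2)
        assert len({cut[f"a{i}"] for i in range(4)}) == 1
        assert len({cut[f"b{i}"] for i in range(4)}) == 1
        assert cut["a0"] != cut["b0"]


class TestClassicalMds:
    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(67)
        pts = rng.random((8, 2))
        D = DistanceMatrix([f"s{i}" for i in range(8)], squareform(pdist(pts)))
        coords, _ = classical_mds(D, dims=2)
        from scipy.spatial import procrustes
        _, _, disparity = procrustes(pts, coords)
        assert disparity < 1e-8

    def test_centroid_at_origin(self):
        rng = np.random.default_rng(71)
        D, _ = _dist_from_points(7, 3, rng)
        coords, _ = classical_mds(D, dims=2)
        np.testing.assert_allclose(coords.mean(axis=0), 0, atol=1e-10)

    def test_three_points_embed_exactly(self):
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        coords, _ = classical_mds(D, dims=2)
        np.testing.assert_allclose(squareform(pdist(coords)), D.values, atol=1e-9)

    def test_matches_skbio_pcoa_eigenvalues(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(73)
        D, _ = _dist_from_points(9, 4, rng)
        _, eigval = classical_mds(D, dims=2)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D.values, D.sample_ids))
        np.testing.assert_allclose(
            eigval[:5], ref.eigvals.to_numpy()[:5], atol=1e-9)

    def test_too_many_dims_rejected(self):
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        with pytest.raises(ValidationError, match="dimensions"):
            classical_mds(D, dims=3)


class TestIdentity:
    def test_synthetic_cohort_has_no_violations(self, small_study):
        report = verify_sample_identity(
            small_study.beta, small_study.sheet, small_study.manifest)
        assert report.ok
        assert (report.records["margin"].dropna() > 0).all()

    def test_label_swap_flags_exactly_the_swapped_samples(self):
        design = SimulationDesign(
            n_probes=500, spatial_groups={"LGG": (2, 1.0)},
            temporal_groups=None, n_temporal_patients=0,
            spatial_dmps_per_biopsy=(5, 10), noise_sd=0.0,
            purity_range=(1.0, 1.0), deletion_prob=0.0,
        )
        study = simulate(design, seed=13)
        table = study.sheet.table.copy()
        a = table.index[table["patient_id"] == "SP01"][0]
        b = table.index[table["patient_id"] == "SP02"][0]
        table.loc[a, "patient_id"], table.loc[b, "patient_id"] = "SP02", "SP01"
        swapped_sheet = SampleSheet(table)
        report = verify_sample_identity(study.beta, swapped_sheet, study.manifest)
        expected = {table.loc[a, "sample_id"], table.loc[b, "sample_id"]}
        assert set(report.violations) == expected

    def test_single_sample_patient_never_flagged(self, small_study):
        report = verify_sample_identity(
            small_study.beta, small_study.sheet, small_study.manifest)
        norm_row = report.records[report.records["patient_id"] == "NORM"]
        assert not norm_row["flagged"].any()

    def test_no_snp_probes_is_hard_error(self, small_study):
        from methylhet.io_formats import ProbeManifest
        table = small_study.manifest.table
        stripped = ProbeManifest(table[~table["is_snp_probe"]])
        with pytest.raises(IdentityError, match="no SNP probes"):
            verify_sample_identity(small_study.beta, small_study.sheet, stripped)
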