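import numpy as np
import pandas as pd
import pytest

from brainsig import (
    DegenerateInputError,
    ExpressionMatrix,
    FormatError,
    Thresholds,
    cluster_signature,
    compute_gene_stats,
    extract_signature,
    venn_partition,
    zscore_matrix,
)


def brute_force_stats(m, groups, rg_order):
    """Independent per-gene loop recomputation of the filtering statistics."""
    rows = {}
    for g in m.feature_ids:
        x = m.data.loc[g]
        mu, sd = x.mean(), x.std(ddof=1)
        z = (x - mu) / sd if sd > 0 else x * 0.0
        rows[g] = {
            "rg_z": float(np.mean([z[s] for s in groups.rg])),
            "msg_z": float(np.mean([z[s] for s in groups.msg])),
            "rg_logfc": float(x[rg_order[1]] - x[rg_order[0]]),
            "rg_msg_logfc": float(
                np.mean([x[s] for s in groups.rg]) - np.mean([x[s] for s in groups.msg])
            ),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def brute_force_sets(table, t):
    """Exhaustive per-gene predicate evaluation of all six criteria sets."""
    out = {k: set() for k in ("rg_up", "rg_down", "msg_up", "msg_down", "up", "down")}
    for g, r in table.iterrows():
        consistent = -t.rg_consistency_cut < r.rg_logfc < t.rg_consistency_cut
        if consistent and r.rg_z > t.z_cut:
            out["rg_up"].add(g)
        if consistent and r.rg_z < -t.z_cut:
            out["rg_down"].add(g)
        if r.msg_z > t.z_cut:
            out["msg_up"].add(g)
        if r.msg_z < -t.z_cut:
            out["msg_down"].add(g)
        if consistent and r.rg_msg_logfc > t.rg_msg_cut and r.rg_z > t.z_cut:
            out["up"].add(g)
        if consistent and r.rg_msg_logfc < -t.rg_msg_cut and r.rg_z < -t.z_cut:
            out["down"].add(g)
    return out


class TestZscore:
    def test_unit_spaced_triple(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc")))
        np.testing.assert_allclose(zscore_matrix(m).loc["g"], [-1, 0, 1])

    def test_constant_row_maps_to_zero(self):
        m = ExpressionMatrix(pd.DataFrame([[5.0, 5.0, 5.0]], index=["g"], columns=list("abc")))
        np.testing.assert_array_equal(zscore_matrix(m).loc["g"], [0, 0, 0])

    def test_rows_normalized(self, random_matrix):
        z = zscore_matrix(random_matrix(seed=2, n_genes=100))
        assert np.abs(z.mean(axis=1)).max() < 1e-12
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-12

    def test_single_sample_rejected(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0]], index=["g"], columns=["a"]))
        with pytest.raises(DegenerateInputError):
            zscore_matrix(m)


class TestGeneStats:
    def test_constant_group_values(self, groups):
        rg, msg = groups.rg, groups.msg
        row = {s: 4.0 for s in rg} | {s: 2.0 for s in msg}
        m = ExpressionMatrix(pd.DataFrame([row], index=["g"])[groups.samples])
        tab = compute_gene_stats(m, groups).table
        assert tab.loc["g", "rg_logfc"] == 0.0
        assert tab.loc["g", "rg_msg_logfc"] == pytest.approx(2.0)

    def test_rg_logfc_is_log_scale_subtraction(self, groups):
        row = {s: 8.0 for s in groups.samples}
        row[groups.rg[0]] = 10.0
        row[groups.rg[1]] = 11.5
        m = ExpressionMatrix(pd.DataFrame([row], index=["g"])[groups.samples])
        tab = compute_gene_stats(m, groups, rg_order=tuple(groups.rg)).table
        assert tab.loc["g", "rg_logfc"] == pytest.approx(1.5)

    def test_matches_brute_force_loop_exactly(self, groups, random_matrix):
        m = random_matrix(seed=9, n_genes=500)
        stats = compute_gene_stats(m, groups)
        expected = brute_force_stats(m, groups, stats.rg_order)
        pd.testing.assert_frame_equal(stats.table, expected, check_exact=True)

    def test_wrong_rg_size_rejected(self, random_matrix):
        from brainsig import GroupAssignment

        m = random_matrix(seed=0)
        bad = GroupAssignment(
            {s: ("RG" if i < 3 else "MSG") for i, s in enumerate(m.sample_ids)}
        )
        with pytest.raises(FormatError, match="exactly 2"):
            compute_gene_stats(m, bad)


class TestVennAndSignature:
    def _stats_from_rows(self, rows, groups):
        """Build GeneStats from explicit per-gene statistic values."""
        from brainsig.signature import GeneStats

        tab = pd.DataFrame.from_dict(rows, orient="index")
        z = pd.DataFrame(0.0, index=tab.index, columns=groups.samples)
        return GeneStats(z=z, table=tab, rg_order=tuple(groups.rg))

    def test_inconsistent_rg_pair_excluded_from_rg_up(self, groups):
        stats = self._stats_from_rows(
            {"g": {"rg_z": 2.0, "msg_z": 0.0, "rg_logfc": 1.5, "rg_msg_logfc": 3.0}},
            groups,
        )
        v = venn_partition(stats)
        assert "g" not in v.rg_up
        assert "g" not in extract_signature(stats).up

    def test_threshold_boundary_is_strict(self, groups):
        stats = self._stats_from_rows(
            {"g": {"rg_z": 1.0, "msg_z": 0.0, "rg_logfc": 0.0, "rg_msg_logfc": 2.0}},
            groups,
        )
        assert "g" not in venn_partition(stats).rg_up
        assert "g" not in extract_signature(stats).up

    def test_all_criteria_met_included(self, groups):
        stats = self._stats_from_rows(
            {"g": {"rg_z": 1.5, "msg_z": -0.4, "rg_logfc": 0.0, "rg_msg_logfc": 2.0}},
            groups,
        )
        assert "g" in extract_signature(stats).up

    def test_sets_match_exhaustive_predicates(self, groups, random_matrix):
        t = Thresholds()
        for seed in range(5):
            stats = compute_gene_stats(random_matrix(seed=seed), groups)
            expected = brute_force_sets(stats.table, t)
            v = venn_partition(stats, t)
            sig = extract_signature(stats, t)
            assert v.rg_up == expected["rg_up"]
            assert v.rg_down == expected["rg_down"]
            assert v.msg_up == expected["msg_up"]
            assert v.msg_down == expected["msg_down"]
            assert sig.up == expected["up"]
            assert sig.down == expected["down"]

    def test_negating_matrix_swaps_up_and_down(self, groups, random_matrix):
        m = random_matrix(seed=13)
        neg = ExpressionMatrix(-m.data, level="gene")
        sig = extract_signature(compute_gene_stats(m, groups))
        sig_neg = extract_signature(compute_gene_stats(neg, groups))
        assert sig_neg.up == sig.down and sig_neg.down == sig.up

    def test_signature_subset_of_venn_sets(self, groups, random_matrix):
        stats = compute_gene_stats(random_matrix(seed=21), groups)
        v = venn_partition(stats)
        sig = extract_signature(stats)
        assert sig.up <= v.rg_up and sig.down <= v.rg_down

    def test_both_mode_is_stricter_than_mean(self, groups, random_matrix):
        stats = compute_gene_stats(random_matrix(seed=4), groups)
        mean_sig = extract_signature(stats, rg_z_mode="mean")
        both_sig = extract_signature(stats, rg_z_mode="both")
        assert both_sig.up <= mean_sig.up and both_sig.down <= mean_sig.down


def brute_force_complete_linkage(points):
    """O(n^3) agglomeration with complete linkage on Euclidean distances."""
    clusters = {i: [i] for i in range(len(points))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                d = max(
                    np.linalg.norm(points[i] - points[j])
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        new_key = max(clusters) + 1
        clusters[new_key] = clusters.pop(a) + clusters.pop(b)
    return np.array(heights)


class TestClustering:
    def test_identical_rows_merge_at_height_zero(self):
        z = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]], index=list("ABC"))
        res = cluster_signature(z)
        assert res.linkage_matrix[0, 2] == 0.0
        assert set(res.leaf_order) == {"A", "B", "C"}

    def test_nearest_pair_merges_first(self):
        z = pd.DataFrame([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0]], index=list("ABC"))
        res = cluster_signature(z)
        assert sorted(res.linkage_matrix[0, :2]) == [0, 1]  # A and B

    def test_merge_heights_match_brute_force(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(20, 9))
        z = pd.DataFrame(pts, index=[f"g{i}" for i in range(20)])
        res = cluster_signature(z, linkage="complete", distance="euclidean")
        np.testing.assert_allclose(
            np.sort(res.linkage_matrix[:, 2]),
            np.sort(brute_force_complete_linkage(pts)),
            rtol=1e-10,
        )

    def test_single_feature_rejected(self):
        z = pd.DataFrame([[1.0, 2.0]], index=["A"])
        with pytest.raises(DegenerateInputError):
            cluster_signature(z)

    def test_leaf_order_is_permutation(self, groups, random_matrix):
        stats = compute_gene_stats(random_matrix(seed=8, n_genes=30), groups)
        res = cluster_signature(stats.z)
        assert sorted(res.leaf_order) == sorted(stats.z.index)
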