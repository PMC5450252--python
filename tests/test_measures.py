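"""Internal, stability and biological validation measures."""

import numpy as np
import pytest

from clustagg.datatypes import (
    AnnotationMap,
    CandidateKey,
    DataMatrix,
    DegenerateCandidateError,
    MEASURE_SPECS,
    Partition,
)
from clustagg.measures import (
    bhi,
    bsi,
    connectivity,
    dunn,
    score_all,
    silhouette,
    stability_suite,
)
from clustagg.partition import compute_distance
from clustagg.simulate import make_gaussian


def relabel(part, perm):
    """Apply a label permutation: perm maps old label -> new label."""
    return Partition(part.key, np.array([perm[l] for l in part.labels]))


class TestInternal:
    def test_line_fixture_hand_values(self, line_partition, line_dist):
        assert connectivity(line_partition, line_dist, L=2) == pytest.approx(2.0)
        assert dunn(line_partition, line_dist) == pytest.approx(9.0)
        assert silhouette(line_partition, line_dist) == pytest.approx(0.89975, abs=1e-5)

    def test_connectivity_zero_when_neighbors_co_clustered(self, line_partition, line_dist):
        assert connectivity(line_partition, line_dist, L=1) == 0.0

    def test_connectivity_neighbor_bound(self, line_partition, line_dist):
        with pytest.raises(ValueError):
            connectivity(line_partition, line_dist, L=4)

    def test_dunn_scale_invariant(self, line_partition, line_matrix):
        d10 = compute_distance(
            DataMatrix(line_matrix.values * 10, list(line_matrix.row_ids),
                       list(line_matrix.col_ids))
        )
        assert dunn(line_partition, d10) == pytest.approx(9.0)

    def test_dunn_degenerate_on_zero_diameters(self):
        m = DataMatrix(np.array([[0.0], [0.0], [5.0], [5.0]]), list("abcd"), ["x"])
        part = Partition(CandidateKey("pam", 2), [1, 1, 2, 2])
        with pytest.raises(DegenerateCandidateError):
            dunn(part, compute_distance(m))

    def test_merging_separated_blobs_lowers_dunn(self):
        ds = make_gaussian(3, 8, 3, separation=8, seed=0)
        d = compute_distance(ds.matrix)
        good = Partition(CandidateKey("x", 3), ds.true_labels)
        merged = Partition(CandidateKey("x", 2), np.minimum(ds.true_labels, 2))
        assert dunn(merged, d) < dunn(good, d)

    def test_silhouette_near_zero_for_random_labels(self):
        rng = np.random.default_rng(0)
        ds = make_gaussian(1, 40, 3, separation=0, seed=1)
        d = compute_distance(ds.matrix)
        vals = []
        for _ in range(50):
            labels = np.append(rng.integers(1, 3, size=38), [1, 2])  # both present
            vals.append(silhouette(Partition(CandidateKey("x", 2), labels), d))
        assert abs(np.mean(vals)) < 0.1

    @pytest.mark.parametrize("measure", [connectivity, dunn, silhouette])
    def test_label_permutation_invariance(self, measure, line_partition, line_dist):
        swapped = relabel(line_partition, {1: 2, 2: 1})
        args = (line_dist, 2) if measure is connectivity else (line_dist,)
        assert measure(line_partition, *args) == pytest.approx(measure(swapped, *args))


class TestStability:
    def test_duplicated_column_line_hand_trace(self, line2_matrix):
        """Deleting either duplicate column leaves the same bipartition,
        so APN = ADM = 0; AD and FOM follow by direct enumeration."""
        out = stability_suite(line2_matrix, CandidateKey("hierarchical", 2), seed=0)
        assert out["APN"] == pytest.approx(0.0)
        assert out["ADM"] == pytest.approx(0.0, abs=1e-12)
        # AD: mean over the 2x2 cluster pair of full-data distances
        # {0, sqrt2, sqrt2, 0}/4 for every item and column
        assert out["AD"] == pytest.approx(np.sqrt(2) / 2)
        # FOM: within-cluster sq sum on the deleted column = 4*(0.5)^2 = 1;
        # sqrt(1/4) * sqrt(4/(4-2)) = 0.5 * sqrt(2)
        assert out["FOM"] == pytest.approx(0.5 * np.sqrt(2))

    def test_apn_bounded_and_zero_for_stable_candidate(self):
        ds = make_gaussian(2, 10, 4, separation=10, seed=3)
        out = stability_suite(ds.matrix, CandidateKey("kmeans", 2), seed=3)
        assert out["APN"] == pytest.approx(0.0, abs=1e-12)
        assert out["AD"] >= 0 and out["ADM"] >= 0 and out["FOM"] >= 0

    def test_needs_at_least_two_columns(self, line_matrix):
        with pytest.raises(ValueError, match="2 feature"):
            stability_suite(line_matrix, CandidateKey("hierarchical", 2))


class TestBiological:
    def test_pure_clusters_score_one(self, line_partition):
        ann = AnnotationMap({"a": {"A"}, "b": {"A"}, "c": {"B"}, "d": {"B"}})
        assert bhi(line_partition, ann, ["a", "b", "c", "d"]) == 1.0

    def test_no_shared_class_scores_zero(self, line_partition):
        ann = AnnotationMap({"a": {"A"}, "b": {"B"}, "c": {"C"}, "d": {"D"}})
        assert bhi(line_partition, ann, ["a", "b", "c", "d"]) == 0.0

    def test_worked_three_gene_cluster(self):
        """g1,g2 share class A, g3 has only B: 2 of 6 ordered pairs agree."""
        part = Partition(CandidateKey("x", 2), [1, 1, 1, 2, 2])
        ann = AnnotationMap({"g1": {"A"}, "g2": {"A"}, "g3": {"B"},
                             "g4": {"C"}, "g5": {"D"}})
        ids = ["g1", "g2", "g3", "g4", "g5"]
        # cluster 1 term = 2/6 = 1/3, cluster 2 term = 0
        assert bhi(part, ann, ids) == pytest.approx((1 / 3 + 0) / 2)

    def test_bhi_undefined_without_annotated_pairs(self, line_partition):
        ann = AnnotationMap({"a": {"A"}, "c": {"B"}})
        with pytest.raises(ValueError, match="BHI undefined"):
            bhi(line_partition, ann, ["a", "b", "c", "d"])

    def test_bhi_ignores_unannotated_items(self, line_partition):
        ann = AnnotationMap({"a": {"A"}, "b": {"A"}, "c": {"B"}, "d": {"C"}})
        # cluster {a,b} -> 1; cluster {c,d} -> 0
        assert bhi(line_partition, ann, ["a", "b", "c", "d"]) == pytest.approx(0.5)

    def test_bsi_perfectly_stable_pure_classes(self, line2_matrix):
        ann = AnnotationMap({"a": {"A"}, "b": {"A"}, "c": {"B"}, "d": {"B"}})
        assert bsi(line2_matrix, CandidateKey("hierarchical", 2), ann, seed=0) == 1.0

    def test_bsi_hand_trace_split_class(self, line2_matrix):
        """Class A = {a,b} co-clustered (term 1); class B = {b,c} split
        across the two clusters (term 0); BSI = 0.5."""
        ann = AnnotationMap({"a": {"A"}, "b": {"A", "B"}, "c": {"B"}})
        val = bsi(line2_matrix, CandidateKey("hierarchical", 2), ann, seed=0)
        assert val == pytest.approx(0.5)

    def test_bsi_in_unit_interval(self):
        ds = make_gaussian(2, 8, 3, separation=4, seed=5)
        rng = np.random.default_rng(5)
        ann = AnnotationMap({
            rid: {f"C{rng.integers(3)}"} for rid in ds.matrix.row_ids
        })
        val = bsi(ds.matrix, CandidateKey("kmeans", 2), ann, seed=5)
        assert 0.0 <= val <= 1.0


class TestScoreAll:
    def test_single_candidate_rejected(self, line_matrix):
        with pytest.raises(ValueError, match="2 candidates"):
            score_all(line_matrix, [CandidateKey("pam", 2)],
                      [MEASURE_SPECS["dunn"]])

    def test_internal_only_never_needs_annotation(self):
        ds = make_gaussian(2, 6, 3, separation=8, seed=7)
        table = score_all(
            ds.matrix,
            [CandidateKey("pam", 2), CandidateKey("hierarchical", 2)],
            [MEASURE_SPECS[n] for n in ("connectivity", "dunn", "silhouette")],
            ann=None, seed=7, opts={"neighb_size": 3},
        )
        assert table.scores.shape == (3, 2)

    def test_biological_specs_require_annotation(self, line_matrix):
        with pytest.raises(ValueError, match="annotation"):
            score_all(line_matrix,
                      [CandidateKey("pam", 2), CandidateKey("hierarchical", 2)],
                      [MEASURE_SPECS["BHI"]])

    def test_bit_for_bit_reproducible(self):
        ds = make_gaussian(3, 6, 4, separation=6, seed=9)
        cands = [CandidateKey(m, k) for m in ("kmeans", "pam") for k in (2, 3)]
        specs = [MEASURE_SPECS[n] for n in ("connectivity", "silhouette", "APN", "FOM")]
        a = score_all(ds.matrix, cands, specs, seed=9, opts={"neighb_size": 4})
        b = score_all(ds.matrix, cands, specs, seed=9, opts={"neighb_size": 4})
        assert np.array_equal(a.scores, b.scores)
        assert a.candidates == b.candidates

    def test_degenerate_candidates_dropped_everywhere(self):
        """Three duplicate pairs: at k=3 every cluster has zero diameter,
        so Dunn is degenerate and the k=3 candidate must vanish from the
        whole table while the k=2 candidates survive."""
        m = DataMatrix(np.array([[0.0], [0.0], [4.0], [4.0], [8.0], [8.0]]),
                       [f"r{i}" for i in range(6)], ["x"])
        warnings_out = []
        table = score_all(
            m,
            [CandidateKey("pam", 2), CandidateKey("hierarchical", 2),
             CandidateKey("hierarchical", 3)],
            [MEASURE_SPECS["dunn"], MEASURE_SPECS["connectivity"]],
            seed=0, opts={"neighb_size": 2}, warnings_out=warnings_out,
        )
        assert CandidateKey("hierarchical", 3) not in table.candidates
        assert len(table.candidates) == 2
        assert any("hierarchical-3" in w for w in warnings_out)
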