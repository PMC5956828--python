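"""Reference-map construction, 300-NN refinement and joint re-embedding."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import embedclass as ec


def _own_class_purity(coords, labels, query_coords, query_labels, k=25):
    """Mean own-class fraction among each query's k nearest reference points."""
    tree = cKDTree(coords)
    _, idx = tree.query(query_coords, k=k)
    return (labels[idx] == np.asarray(query_labels)[:, None]).mean(axis=1)


class TestBuildMap:
    def test_pca_on_collinear_points_is_rank_one(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        feats = np.outer([0.0, 1.0, 2.0], base)
        m = ec.build_map(feats, np.array(["a", "b", "a"]), params=ec.EmbedParams(method="pca"))
        assert len(m.points) == 3
        assert np.var(m.points["y"]) < 1e-20

    def test_point_count_conserved_and_deterministic(self, reference, tsne_map):
        frame, X, y = reference
        assert len(tsne_map.points) == len(frame)
        again = ec.build_map(X, y, tile_ids=frame["tile_id"].to_numpy(), params=ec.EmbedParams(seed=0))
        np.testing.assert_array_equal(tsne_map.coords, again.coords)

    def test_reference_clusters_are_pure_on_the_plane(self, tsne_map):
        purity = _own_class_purity(tsne_map.coords, tsne_map.labels, tsne_map.coords, tsne_map.labels)
        assert purity.mean() >= 0.9

    def test_single_class_reference_is_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            ec.build_map(np.zeros((40, 4)), np.array(["a"] * 40))

    def test_too_few_points_for_perplexity(self):
        with pytest.raises(ValueError, match="perplexity"):
            ec.build_map(np.random.default_rng(0).normal(size=(5, 3)),
                         np.array(["a", "a", "b", "b", "a"]),
                         params=ec.EmbedParams(perplexity=30))


class TestRefine:
    def test_planted_mislabel_is_removed_and_refinement_is_idempotent(self, reference):
        """The neighbor window must stay below the per-class point count for
        the own-class fraction to be meaningful; at 60 tiles/class we check
        50 neighbors (the 300 default mirrors a 350-600 tiles/class map)."""
        frame, X, y = reference
        # plant one glioma-labeled point in the middle of the meningioma cluster
        X2 = X.copy()
        y2 = y.copy()
        victim = int(np.where(y == "glioma")[0][0])
        donor_rows = np.where(y == "meningioma")[0]
        X2[victim] = X[donor_rows].mean(axis=0)
        m = ec.build_map(X2, y2, params=ec.EmbedParams(seed=1))
        refined = ec.refine_map(m, n_check_neighbors=50, own_class_min=0.5)
        assert refined.refined
        removed_ids = set(m.points["tile_id"]) - set(refined.points["tile_id"])
        assert m.points["tile_id"].iloc[victim] in removed_ids
        assert refined.provenance["removed"]["glioma"] >= 1
        again = ec.refine_map(refined, n_check_neighbors=50, own_class_min=0.5)
        assert set(again.points["tile_id"]) == set(refined.points["tile_id"])

    def test_zero_threshold_is_identity(self, tsne_map):
        refined = ec.refine_map(tsne_map, n_check_neighbors=50, own_class_min=0.0)
        assert len(refined.points) == len(tsne_map.points)

    def test_every_class_survives(self, tsne_map):
        refined = ec.refine_map(tsne_map, n_check_neighbors=50)
        assert set(refined.points["label"]) == set(tsne_map.points["label"])

    def test_refinement_needs_enough_points(self, tsne_map):
        with pytest.raises(ValueError, match="needs more than"):
            ec.refine_map(tsne_map, n_check_neighbors=len(tsne_map.points))

    def test_emptying_a_class_raises(self):
        rng = np.random.default_rng(0)
        # one lone point of class b inside a big cluster of a
        X = np.vstack([rng.normal(size=(400, 3)), rng.normal(size=(1, 3))])
        y = np.array(["a"] * 400 + ["b"])
        m = ec.build_map(X, y, params=ec.EmbedParams(method="pca"))
        with pytest.raises(ValueError, match="b"):
            ec.refine_map(m, n_check_neighbors=300, own_class_min=0.5)


class TestJointEmbedding:
    def test_size_conservation_and_query_purity(self, fixture_config, reference):
        frame, X, y = reference
        slide = ec.make_slide(fixture_config, truth_class=9, n_lesional=80, n_background=0, seed=21)
        Q = np.vstack([t.feature_vector for t in slide.tiles])
        joint = ec.embed_with_queries(X, y, Q, ec.EmbedParams(seed=0))
        assert joint.ref_coords.shape == (len(X), 2)
        assert joint.query_coords.shape == (80, 2)
        purity = _own_class_purity(joint.ref_coords, joint.ref_labels,
                                   joint.query_coords, ["meningioma"] * 80)
        assert (purity >= 0.85).mean() >= 0.85

    def test_reference_structure_survives_re_embedding(self, fixture_config, reference, tsne_map):
        frame, X, y = reference
        slide = ec.make_slide(fixture_config, truth_class=10, n_lesional=100, n_background=0, seed=22)
        Q = np.vstack([t.feature_vector for t in slide.tiles])
        joint = ec.embed_with_queries(X, y, Q, ec.EmbedParams(seed=0))
        before = _own_class_purity(tsne_map.coords, tsne_map.labels, tsne_map.coords, tsne_map.labels)
        after = _own_class_purity(joint.ref_coords, joint.ref_labels, joint.ref_coords, joint.ref_labels)
        labels = tsne_map.labels
        for lab in set(labels.tolist()):
            sel = labels == lab
            assert abs(before[sel].mean() - after[sel].mean()) <= 0.05

    def test_dimension_mismatch_raises(self, reference):
        frame, X, y = reference
        with pytest.raises(ValueError, match="dimension mismatch"):
            ec.embed_with_queries(X, y, np.zeros((3, 5)))

    def test_empty_query_raises(self, reference):
        frame, X, y = reference
        with pytest.raises(ValueError, match="at least one query"):
            ec.embed_with_queries(X, y, np.zeros((0, X.shape[1])))

    def test_pca_projection_is_exactly_reproducible(self, reference):
        frame, X, y = reference
        Q = X[:10] + 0.1
        p = ec.EmbedParams(method="pca")
        a = ec.embed_with_queries(X, y, Q, p)
        b = ec.embed_with_queries(X, y, Q, p)
        np.testing.assert_array_equal(a.query_coords, b.query_coords)
        np.testing.assert_array_equal(a.ref_coords, b.ref_coords)


class TestSerialization:
    def test_map_json_roundtrip(self, tmp_path, tsne_map):
        path = tmp_path / "map.json"
        tsne_map.to_json(path)
        back = ec.ReferenceMap.from_json(path)
        assert back.method == tsne_map.method
        assert back.params == tsne_map.params
        np.testing.assert_allclose(back.coords, tsne_map.coords, rtol=0, atol=1e-12)

    def test_plot_writes_png(self, tmp_path, tsne_map):
        out = tmp_path / "map.png"
        tsne_map.plot(out, query_coords=tsne_map.coords[:5])
        assert out.stat().st_size > 0
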