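import numpy as np
import pandas as pd
import pytest

from tastechip.classify import (
    ClusterAssignment,
    cluster_conditions,
    pca_project,
    resolve_detection_threshold,
    select_specific_electrodes,
)
from tastechip.features import FEATURE_COLUMNS
from tastechip.recording import StimulusLabel, TASTANT_UNITS, Tastant


def pca_eigendecomposition_oracle(x, n_components=3):
    """Brute-force standardize + eigendecompose the covariance of the
    standardized data; return scores on the top components."""
    z = (x - x.mean(0)) / x.std(0)
    cov = z.T @ z / len(z)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:n_components]
    return z @ v[:, order]


class TestSpecificity:
    def test_single_tastant_response_is_specific(self):
        mask = select_specific_electrodes(
            {"e1": {"sour_acetic": 10.0, "sweet_sucrose": 1.1, "bitter_PTC": 0.9,
                    "salty_NaCl": 1.0}},
            {"e1": 1.0},
            fold_threshold=2.0,
        )
        assert mask.is_specific("e1")
        assert mask.specific_channels("sour_acetic") == ["e1"]

    def test_multi_responsive_channel_excluded(self):
        mask = select_specific_electrodes(
            {"e1": {"sour_acetic": 3.0, "sweet_sucrose": 3.0, "bitter_PTC": 1.0,
                    "salty_NaCl": 1.0}},
            {"e1": 1.0},
        )
        assert not mask.is_specific("e1")

    def test_unresponsive_channel_excluded(self):
        mask = select_specific_electrodes(
            {"e1": {t.value: 1.2 for t in Tastant if t != Tastant.NONE}}, {"e1": 1.0}
        )
        assert mask.responsive["e1"] == frozenset() and not mask.is_specific("e1")

    def test_zero_baseline_flagged(self):
        with pytest.warns(UserWarning, match="undefined baseline"):
            mask = select_specific_electrodes(
                {"e1": {"sour_acetic": 5.0}}, {"e1": 0.0}
            )
        assert "e1" in mask.undefined_baseline and not mask.is_specific("e1")

    def test_monotone_in_fold_threshold(self):
        rng = np.random.default_rng(0)
        responses = {
            f"e{i}": {t.value: float(rng.uniform(0.5, 6)) for t in Tastant
                      if t != Tastant.NONE}
            for i in range(12)
        }
        baselines = {ch: 1.0 for ch in responses}
        previous = None
        for fold in (1.5, 2.0, 3.0, 4.5):
            mask = select_specific_electrodes(responses, baselines, fold)
            if previous is not None:
                for ch in responses:
                    assert mask.responsive[ch] <= previous[ch]
            previous = mask.responsive


class TestPca:
    def test_collinear_points_have_all_variance_on_first_component(self):
        t = np.linspace(0, 1, 12)[:, None]
        direction = np.arange(1, 9)[None, :]
        res = pca_project(t @ direction + 5.0)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.explained_variance_ratio[1:] < 1e-9)

    def test_scores_are_centered_and_loadings_orthonormal(self):
        rng = np.random.default_rng(4)
        res = pca_project(rng.normal(size=(18, 8)))
        assert np.allclose(res.scores.mean(0), 0, atol=1e-9)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(3), atol=1e-9)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(18, 8)) * rng.uniform(0.1, 30, 8)
        got = pca_project(x).scores
        ref = pca_eigendecomposition_oracle(x)
        d_got = np.linalg.norm(got[:, None] - got[None, :], axis=2)
        d_ref = np.linalg.norm(ref[:, None] - ref[None, :], axis=2)
        assert np.max(np.abs(d_got - d_ref)) < 1e-8

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(12, 8))
        perm = rng.permutation(12)
        a = pca_project(x).scores
        b = pca_project(x[perm]).scores
        assert np.allclose(a[perm], b, atol=1e-9)

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(10, 8))
        x[:, 2] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_project(x)
        assert np.isfinite(res.scores).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="insufficient samples"):
            pca_project(np.zeros((3, 8)))

    def test_log_psd_transform_applies_to_band_columns_only(self):
        rng = np.random.default_rng(8)
        fm = pd.DataFrame(rng.uniform(0.1, 10, size=(10, 8)), columns=FEATURE_COLUMNS)
        manual = fm.copy()
        for c in FEATURE_COLUMNS[:5]:
            manual[c] = np.log10(manual[c])
        a = pca_project(fm, log_psd=True).scores
        b = pca_project(manual.to_numpy()).scores
        assert np.allclose(np.abs(a), np.abs(b), atol=1e-9)


class TestClustering:
    def test_two_well_separated_blobs(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 0.5, size=(6, 3))
            b = rng.normal(10, 0.5, size=(6, 3))
            pts = np.vstack([a, b])
            labels = ["a1", "a1", "a2", "a2", "a3", "a3",
                      "b1", "b1", "b2", "b2", "b3", "b3"]
            ca = cluster_conditions(pts, labels)
            assert ca.k == 2
            a_clusters = {ca.condition_to_cluster[c] for c in ("a1", "a2", "a3")}
            b_clusters = {ca.condition_to_cluster[c] for c in ("b1", "b2", "b3")}
            assert len(a_clusters) == 1 and len(b_clusters) == 1
            assert a_clusters != b_clusters

    def test_identical_points_flagged_degenerate(self):
        pts = np.ones((6, 3))
        ca = cluster_conditions(pts, ["x", "x", "x", "y", "y", "y"])
        assert ca.k == 1 and ca.degenerate and ca.silhouette is None

    def test_label_count_must_match(self):
        with pytest.raises(ValueError):
            cluster_conditions(np.zeros((4, 3)), ["a", "b"])

    def test_kmeans_variant_runs(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.3, (4, 3)), rng.normal(5, 0.3, (4, 3))])
        labels = ["a", "a", "a", "a", "b", "b", "b", "b"]
        ca = cluster_conditions(pts, labels, method="kmeans", seed=0)
        assert ca.k == 2


class TestThresholdResolution:
    @staticmethod
    def _conditions(tastant, concs):
        units = TASTANT_UNITS[tastant]
        return [StimulusLabel()] + [StimulusLabel(tastant, c, units) for c in concs]

    def test_lowest_non_control_cluster_wins(self):
        conds = self._conditions(Tastant.SWEET_SUCROSE, [0.125, 0.25, 0.5])
        ca = ClusterAssignment(
            labels=np.array([1, 1, 2, 3]),
            k=3,
            condition_to_cluster={
                ("none", 0.0): 1,
                ("sweet_sucrose", 0.125): 1,
                ("sweet_sucrose", 0.25): 2,
                ("sweet_sucrose", 0.5): 3,
            },
            silhouette=0.5,
        )
        assert resolve_detection_threshold(ca, conds) == 0.25

    def test_all_distinct_returns_lowest_tested(self):
        conds = self._conditions(Tastant.BITTER_PTC, [0.01, 0.1])
        ca = ClusterAssignment(
            labels=np.arange(1, 4), k=3,
            condition_to_cluster={("none", 0.0): 1, ("bitter_PTC", 0.01): 2,
                                  ("bitter_PTC", 0.1): 3},
            silhouette=0.4,
        )
        assert resolve_detection_threshold(ca, conds) == 0.01

    def test_nothing_detected(self):
        conds = self._conditions(Tastant.SALTY_NACL, [0.75, 1.5])
        ca = ClusterAssignment(
            labels=np.ones(3, int), k=1,
            condition_to_cluster={("none", 0.0): 1, ("salty_NaCl", 0.75): 1,
                                  ("salty_NaCl", 1.5): 1},
            silhouette=None,
        )
        assert resolve_detection_threshold(ca, conds) is None

    def test_missing_control_rejected(self):
        conds = [StimulusLabel(Tastant.SALTY_NACL, 3.0, TASTANT_UNITS[Tastant.SALTY_NACL])]
        ca = ClusterAssignment(np.array([1]), 1, {("salty_NaCl", 3.0): 1}, None)
        with pytest.raises(ValueError, match="no control"):
            resolve_detection_threshold(ca, conds)
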