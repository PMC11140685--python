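"""Feature catalog oracles, robust sigmoid closed forms, similarity,
network-pair aggregation against brute force, and homogeneity."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cortnet import features as feat
from cortnet.features import FeatureMatrix
from cortnet.types import ParcelLabeling, ParcelTimeSeries

from conftest import ar1


def _extract(x):
    return feat.extract_features(ParcelTimeSeries(x, 1.0))


class TestCatalog:
    def test_catalog_size(self):
        assert len(feat.feature_catalog()) >= 24

    def test_white_noise_ac1_near_zero(self, rng):
        fm = _extract(rng.standard_normal((5000, 3)))
        ac1 = fm.values[:, fm.feature_names.index("ac_1")]
        assert np.abs(ac1).max() < 0.05

    def test_ar1_ac1_matches_phi(self, rng):
        x = np.column_stack([ar1(0.6, 5000, rng) for _ in range(3)])
        fm = _extract(x)
        ac1 = fm.values[:, fm.feature_names.index("ac_1")]
        assert np.abs(ac1 - 0.6).max() < 0.05

    def test_constant_series_sd_zero(self):
        x = np.column_stack([np.ones(100), np.arange(100.0)])
        fm = _extract(x)
        assert fm.values[0, fm.feature_names.index("sd")] == 0.0

    def test_mean_sd_skew_exact(self, rng):
        x = rng.standard_normal((200, 2)) * 3.0 + 1.0
        fm = _extract(x)
        assert np.allclose(fm.values[:, 0], x.mean(axis=0))
        assert np.allclose(fm.values[:, 1], x.std(axis=0))

    def test_too_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="time points"):
            _extract(rng.standard_normal((10, 2)))

    def test_slow_series_has_lower_spectral_centroid(self, rng):
        x = np.column_stack([ar1(0.9, 2000, rng), rng.standard_normal(2000)])
        fm = _extract(x)
        cen = fm.values[:, fm.feature_names.index("spectral_centroid")]
        low = fm.values[:, fm.feature_names.index("power_low")]
        assert cen[0] < cen[1]
        assert low[0] > low[1]


class TestRobustSigmoid:
    def test_median_maps_to_half(self, rng):
        raw = FeatureMatrix(rng.standard_normal((11, 3)), ["a", "b", "c"])
        out = feat.robust_sigmoid_normalize(raw)
        for j in range(3):
            med = np.median(raw.values[:, j])
            k = np.argmin(np.abs(raw.values[:, j] - med))
            assert out.values[k, j] == pytest.approx(0.5, abs=1e-12)

    def test_iqr_offset_closed_form(self):
        col = np.arange(21.0)  # median 10, IQR 10
        raw = FeatureMatrix(col[:, None], ["a"])
        out = feat.robust_sigmoid_normalize(raw)
        value = 1.0 / (1.0 + np.exp(-(col - 10) / (1.35 * 10)))
        assert np.allclose(out.values[:, 0], value)
        assert 1.0 / (1.0 + np.exp(-1)) == pytest.approx(0.7310585786)

    def test_constant_feature_dropped(self, rng):
        v = np.column_stack([rng.standard_normal(10), np.full(10, 3.0)])
        out = feat.robust_sigmoid_normalize(FeatureMatrix(v, ["x", "const"]))
        assert out.feature_names == ["x"]
        assert out.dropped_features == ["const"]

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=30, unique=True))
    def test_monotone_order_preserved(self, values):
        col = np.asarray(values)
        out = feat.robust_sigmoid_normalize(FeatureMatrix(col[:, None], ["a"]))
        order = np.argsort(col, kind="stable")
        assert (np.diff(out.values[order, 0]) >= 0).all()
        assert (out.values >= 0).all() and (out.values <= 1).all()


class TestSimilarity:
    def test_fisher_z_closed_form(self):
        # construct two parcels with known feature correlation 0.5
        rng = np.random.default_rng(0)
        z = rng.standard_normal((2, 500))
        b = 0.5 * z[0] + np.sqrt(0.75) * z[1]
        v = np.vstack([z[0], b])
        v01 = (v - v.min(axis=1, keepdims=True))
        v01 = v01 / v01.max(axis=1, keepdims=True)
        fm = FeatureMatrix(v01, [f"f{i}" for i in range(500)], normalized=True)
        s = feat.feature_similarity(fm)
        r = np.corrcoef(v01)[0, 1]
        assert s.matrix[0, 1] == pytest.approx(np.arctanh(r))

    def test_identical_parcels_clipped_finite(self):
        v = np.tile(np.linspace(0, 1, 30), (2, 1))
        fm = FeatureMatrix(v, [f"f{i}" for i in range(30)], normalized=True)
        s = feat.feature_similarity(fm)
        assert np.isfinite(s.matrix[0, 1])
        assert s.matrix[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_requires_normalized(self, rng):
        fm = FeatureMatrix(rng.standard_normal((5, 4)), list("abcd"))
        with pytest.raises(ValueError, match="normalized"):
            feat.feature_similarity(fm)


class TestNetworkPairAverage:
    def test_block_constant_exact(self, labeling):
        net = labeling.parcel_network
        m = np.zeros((labeling.n_parcels, labeling.n_parcels))
        for a in range(1, 9):
            for b in range(1, 9):
                m[np.ix_(net == a, net == b)] = a * 10 + b
        m = 0.5 * (m + m.T)
        out = feat.network_pair_average(m, labeling)
        for a in range(1, 9):
            for b in range(1, 9):
                assert out[a - 1, b - 1] == pytest.approx(0.5 * (a * 10 + b + b * 10 + a))

    def test_brute_force_oracle(self, rng):
        lab = ParcelLabeling(
            np.arange(1, 9), np.array([1, 1, 1, 2, 2, 3, 3, 3]), ["A", "B", "C"]
        )
        m = rng.standard_normal((8, 8))
        m = 0.5 * (m + m.T)
        out = feat.network_pair_average(m, lab)
        for a in range(1, 4):
            for b in range(1, 4):
                vals = [
                    m[p, q]
                    for p in range(8) for q in range(8)
                    if p != q and lab.parcel_network[p] == a and lab.parcel_network[q] == b
                ]
                assert out[a - 1, b - 1] == pytest.approx(np.mean(vals))

    def test_permutation_invariance(self, rng, labeling):
        m = rng.standard_normal((68, 68))
        m = 0.5 * (m + m.T)
        perm = rng.permutation(68)
        lab2 = ParcelLabeling(
            np.argsort(perm)[labeling.vertex_parcel - 1] + 1,
            labeling.parcel_network[perm],
            labeling.network_names,
        )
        out1 = feat.network_pair_average(m, labeling)
        out2 = feat.network_pair_average(m[np.ix_(perm, perm)], lab2)
        assert np.allclose(out1, out2)

    def test_single_parcel_network_within_nan(self):
        lab = ParcelLabeling(np.array([1, 2, 3]), np.array([1, 1, 2]), ["A", "B"])
        m = np.ones((3, 3))
        out = feat.network_pair_average(m, lab)
        assert np.isnan(out[1, 1]) and out[0, 0] == 1.0


class TestHomogeneity:
    def test_shared_latent_gives_one(self, rng):
        lab = ParcelLabeling(np.array([1, 1, 1, 2, 2]), np.array([1, 1]), ["A"])
        sig = rng.standard_normal(100)
        x = np.column_stack([sig * a for a in (1.0, 2.0, 0.5, 1.0, 3.0)])
        rep = feat.parcel_homogeneity(x, lab)
        assert rep.per_parcel[0] == pytest.approx(1.0)
        assert rep.weighted_summary == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        lab = ParcelLabeling(np.repeat([1, 2], 10), np.array([1, 1]), ["A"])
        rep = feat.parcel_homogeneity(rng.standard_normal((4000, 20)), lab)
        assert abs(rep.weighted_summary) < 0.05

    def test_size_weighted_summary(self):
        # construct two parcels with known homogeneity by direct assembly
        rng = np.random.default_rng(1)
        lab = ParcelLabeling(
            np.concatenate([np.full(10, 1), np.full(30, 2)]),
            np.array([1, 1]), ["A"],
        )
        rep = feat.parcel_homogeneity(rng.standard_normal((200, 40)), lab)
        expected = (rep.per_parcel[0] * 10 + rep.per_parcel[1] * 30) / 40
        assert rep.weighted_summary == pytest.approx(expected)

    def test_single_vertex_parcel_excluded(self, rng):
        lab = ParcelLabeling(np.array([1, 2, 2, 2]), np.array([1, 1]), ["A"])
        rep = feat.parcel_homogeneity(rng.standard_normal((100, 4)), lab)
        assert np.isnan(rep.per_parcel[0])
        assert rep.weighted_summary == pytest.approx(rep.per_parcel[1])


def test_distinct_timescales_separate_in_feature_space(labeling):
    """Networks with distinct AR coefficients are closer within than
    between networks in normalized feature space (generator defaults)."""
    from cortnet import synthetic as syn
    from scipy.spatial.distance import pdist, squareform

    spec = syn.default_condition_spec(seed=13)
    runs, _ = syn.generate_timeseries(labeling, spec)
    fm = feat.robust_sigmoid_normalize(feat.extract_features(runs[0]))
    d = squareform(pdist(fm.values))
    net = labeling.parcel_network
    same = net[:, None] == net[None, :]
    off = ~np.eye(68, dtype=bool)
    assert d[same & off].mean() < d[~same].mean()
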