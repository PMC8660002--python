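"""Signal path: nuisance design, filtering, weighted Fisher-z connectivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from painconn.denoise import (
    build_nuisance_design,
    canonical_hrf,
    count_edges,
    denoise_and_filter,
    edge_list,
    weighted_connectivity,
)
from painconn.errors import ConfigurationError, ModelError

TR = 2.0
N = 200


def _motion(n=N, scale=0.01, seed=0):
    return np.random.default_rng(seed).normal(0, scale, (n, 6))


class TestCountEdges:
    @pytest.mark.parametrize(
        "n,expected", [(76, 2850), (2, 1), (10, 45), (20, 190)]
    )
    def test_edge_counts(self, n, expected):
        assert count_edges(n) == expected
        assert len(edge_list(n)) == expected

    def test_rejects_single_roi(self):
        with pytest.raises(ConfigurationError):
            count_edges(1)

    @pytest.mark.parametrize("n", [2, 5, 11, 20])
    def test_enumeration_bijection(self, n):
        """Edge order is a bijection onto {(i,j): i<j}, brute force."""
        edges = edge_list(n)
        assert edges == [(i, j) for i in range(n) for j in range(i + 1, n)]
        assert len(set(edges)) == n * (n - 1) // 2
        assert all(i < j for i, j in edges)


class TestNuisanceDesign:
    def test_scrub_columns_one_hot(self):
        flags = np.zeros(N, bool)
        flags[[10, 50, 120]] = True
        d = build_nuisance_design(_motion(), flags, None, None, TR)
        assert d.scrub.shape == (N, 3)
        np.testing.assert_array_equal(d.scrub.sum(axis=0), [1, 1, 1])
        np.testing.assert_array_equal(np.flatnonzero(d.scrub.any(axis=1)), [10, 50, 120])

    def test_constant_inputs_reduce_to_rest_block(self):
        """Zero motion and constant tissue leave only the rest regressors."""
        mot = np.zeros((N, 6))
        d = build_nuisance_design(mot, np.zeros(N, bool), None, None, TR)
        X = d.matrix
        assert all(n.startswith("rest") for n in d.column_names)
        assert X.shape[1] == 3

    def test_motion_derivatives_first_difference(self):
        mot = _motion(seed=3)
        d = build_nuisance_design(mot, np.zeros(N, bool), None, None, TR)
        np.testing.assert_allclose(d.motion_deriv[0], 0.0)
        np.testing.assert_allclose(d.motion_deriv[1:], np.diff(mot, axis=0))

    def test_compcor_recovers_planted_subspace(self):
        """First PCs match an independent eigendecomposition of the voxel pool."""
        rng = np.random.default_rng(1)
        latent = rng.standard_normal((N, 2))
        load = rng.standard_normal((2, 40)) * 5
        tissue = latent @ load + 0.01 * rng.standard_normal((N, 40))
        d = build_nuisance_design(_motion(), np.zeros(N, bool), tissue, None,
                                  TR, n_compcor=2)
        pcs = d.compcor_wm
        # oracle: eigendecomposition of the frame-space Gram matrix of the
        # voxel-centred pool (temporal PCs by an independent route)
        xc = tissue - tissue.mean(0)
        w, v = np.linalg.eigh(xc @ xc.T)
        oracle = v[:, ::-1][:, :2]
        # principal angles between the two 2-D subspaces
        qa, _ = np.linalg.qr(pcs)
        qb, _ = np.linalg.qr(oracle)
        sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
        angles = np.arccos(np.clip(sv, -1, 1))
        assert np.max(angles) < 1e-6

    def test_too_few_voxels_names_tissue(self):
        tissue = np.random.default_rng(0).standard_normal((N, 3))
        with pytest.raises(ModelError, match="CSF"):
            build_nuisance_design(_motion(), np.zeros(N, bool), None, tissue,
                                  TR, n_compcor=5)

    def test_frame_count_mismatch(self):
        with pytest.raises(ConfigurationError, match="flags"):
            build_nuisance_design(_motion(), np.zeros(N - 1, bool), None, None, TR)

    def test_hrf_shape(self):
        h = canonical_hrf(tr=0.5)
        t = np.arange(h.size) * 0.5
        assert h.max() == 1.0
        # gamma with delay 6 / dispersion 1 peaks at its mode, ~5 s
        assert 4.0 <= t[h.argmax()] <= 7.0
        assert h[(t > 12) & (t < 20)].min() < 0  # undershoot present


class TestDenoiseAndFilter:
    def test_inband_sinusoid_preserved(self):
        t = np.arange(300) * TR
        x = np.sin(2 * np.pi * 0.05 * t)[:, None]
        y, _ = denoise_and_filter(x, None, TR, to_percent=False)
        assert abs(y.std() / x.std() - 1) < 0.01

    def test_outofband_sinusoid_removed(self):
        t = np.arange(300) * TR
        x = np.sin(2 * np.pi * 0.2 * t)[:, None]
        y, _ = denoise_and_filter(x, None, TR, to_percent=False)
        assert np.sqrt((y**2).mean()) < 1e-6 * np.sqrt((x**2).mean())

    def test_design_column_projects_to_zero(self):
        mot = _motion(n=300, seed=2)
        d = build_nuisance_design(mot, np.zeros(300, bool), None, None, TR)
        col = d.matrix[:, 4].copy()
        y, _ = denoise_and_filter(col[:, None], d, TR, band=(0.008, 0.24),
                                  to_percent=False)
        assert np.abs(y).max() < 1e-10

    def test_percent_signal_conversion(self):
        rng = np.random.default_rng(4)
        x = 500.0 + rng.standard_normal((100, 3))
        y, _ = denoise_and_filter(x, None, TR, band=(0.008, 0.24))
        assert np.allclose(y.mean(axis=0), 0, atol=1e-10)
        with pytest.raises(ConfigurationError, match="percent"):
            denoise_and_filter(x - 500.0, None, TR)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ConfigurationError, match="Nyquist"):
            denoise_and_filter(np.ones((50, 2)), None, TR, band=(0.01, 0.3))

    def test_censoring_weights_binary(self):
        flags = np.zeros(100, bool)
        flags[7] = True
        x = 100 + np.random.default_rng(5).standard_normal((100, 2))
        _, w = denoise_and_filter(x, None, TR, outlier_flags=flags)
        assert w[7] == 0 and w.sum() == 99

    def test_connectivity_invariant_to_added_nuisance(self):
        """Adding design-column combinations leaves correlations unchanged."""
        rng = np.random.default_rng(6)
        x = 1000 + rng.standard_normal((300, 4))
        mot = _motion(n=300, seed=7)
        d = build_nuisance_design(mot, np.zeros(300, bool), None, None, TR)
        y0, _ = denoise_and_filter(x, d, TR)
        mix = d.matrix @ rng.standard_normal(d.matrix.shape[1])
        x2 = x.copy()
        x2[:, 0] += 0.001 * mix * 1000 / 100  # perturb in raw units
        y1, _ = denoise_and_filter(x2, d, TR)
        r0 = weighted_connectivity(y0).r
        r1 = weighted_connectivity(y1).r
        np.testing.assert_allclose(r0, r1, atol=1e-8)


class TestWeightedConnectivity:
    def test_uniform_weights_match_pearson(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((120, 6))
        c = weighted_connectivity(x, np.ones(120))
        np.testing.assert_allclose(c.r, np.corrcoef(x.T), atol=1e-12)

    def test_fisher_values(self):
        # construct two series with an exact correlation of 0.5
        rng = np.random.default_rng(9)
        a = rng.standard_normal(5000)
        b = 0.5 * a + np.sqrt(1 - 0.25) * rng.standard_normal(5000)
        c = weighted_connectivity(np.column_stack([a, b]))
        assert c.z[0, 1] == pytest.approx(np.arctanh(c.r[0, 1]), abs=1e-12)
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=5e-5)

    def test_zero_correlation_gives_zero_z(self):
        x = np.column_stack([np.ones(10), np.arange(10)])
        x[:, 0] = [1, -1] * 5  # orthogonal to linear trend
        c = weighted_connectivity(x.astype(float))
        assert c.z[0, 1] == pytest.approx(np.arctanh(c.r[0, 1]))

    def test_censored_frames_excluded(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((100, 3))
        w = np.ones(100)
        w[50:] = 0.0
        c = weighted_connectivity(x, w)
        np.testing.assert_allclose(c.r, np.corrcoef(x[:50].T), atol=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            weighted_connectivity(np.random.default_rng(0).standard_normal((10, 2)),
                                  np.zeros(10))

    def test_zero_variance_roi_marked_invalid(self):
        x = np.random.default_rng(1).standard_normal((50, 3))
        x[:, 1] = 7.0
        c = weighted_connectivity(x)
        assert np.isnan(c.r[0, 1]) and np.isnan(c.r[1, 2])
        assert np.isfinite(c.r[0, 2])

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    def test_fisher_monotone(self, r1, r2):
        """z = atanh(r) is strictly increasing on (-1, 1)."""
        if r1 == r2:
            return
        lo, hi = sorted([r1, r2])
        assert np.arctanh(lo) < np.arctanh(hi)
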