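"""TDC histogram, quantiles, EM mixture fit, z_f transform, IPv location."""

import numpy as np
import pytest
from scipy.stats import norm

import tdcperf as tp
from tdcperf.preprocessing import FirstPassWindow, TtpMap, smooth_curves, detect_first_pass_window, compute_ttp_map
from tdcperf.tdc import (
    build_tdc,
    empirical_quantile,
    fit_tdc_model,
    zf_transform,
    ipv_threshold,
    TdcModel,
    TdcMixtureModel,
    DegenerateMixtureError,
)


def _ttp_from_frames(frames, tr=1.0):
    frames = np.asarray(frames)
    return TtpMap(frames=frames, tr=tr, defined_mask=frames >= 0)


class TestHistogram:
    def test_constant_sample_single_bin(self):
        frames = np.full((10, 10, 1), 7)
        win = FirstPassWindow(5, 15, 3)
        h = build_tdc(_ttp_from_frames(frames, tr=2.0), win)
        assert h.counts.sum() == 100
        nz = np.nonzero(h.counts)[0]
        assert list(nz) == [2]  # bin of frame 7 relative to window start 5
        assert h.density[2] == 1.0
        assert h.density.sum() == pytest.approx(1.0)

    def test_bimodal_phantom_modes_at_construction_times(self, noiseless_phantom):
        series, truth = noiseless_phantom
        sm = smooth_curves(series, 3)
        win = detect_first_pass_window(sm, truth.brain_mask, baseline_frames=8)
        ttp = compute_ttp_map(sm, win, truth.brain_mask)
        h = build_tdc(ttp, win)
        centers = (h.bin_edges[:-1] + h.bin_edges[1:]) / 2
        main_mode = centers[np.argmax(h.counts)]
        normal = truth.true_ttp[truth.brain_mask.values & ~truth.lesion_mask.values]
        assert abs(main_mode - np.median(normal)) <= 2 * series.tr
        # the lesion forms a distinct late mode
        late = h.counts[centers > normal.max() + series.tr]
        assert late.sum() >= 0.8 * truth.lesion_mask.n_voxels

    def test_too_few_voxels_raises(self):
        frames = np.full((3, 3, 1), 7)
        with pytest.raises(ValueError, match="too few"):
            build_tdc(_ttp_from_frames(frames), FirstPassWindow(5, 15, 3))

    def test_empty_voi_raises(self):
        frames = np.full((10, 10, 2), 7)
        frames[:, :, 1] = -1
        with pytest.raises(ValueError, match="VOI"):
            build_tdc(_ttp_from_frames(frames), FirstPassWindow(5, 15, 3), voi=1)


class TestQuantile:
    def test_linear_interpolation_convention(self):
        values = np.arange(1.0, 101.0)
        assert empirical_quantile(values, 0.03) == pytest.approx(3.97)

    def test_constant_sample_any_p(self):
        values = np.full(50, 4.2)
        for p in (0.03, 0.2275, 0.5, 0.9):
            assert empirical_quantile(values, p) == 4.2

    def test_median_of_symmetric_sample(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert empirical_quantile(values, 0.5) == 3.0

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_out_of_range_probability(self, p):
        with pytest.raises(ValueError, match="probability"):
            empirical_quantile(np.arange(10.0), p)

    def test_brute_force_oracle(self):
        # oracle: manual order-statistic interpolation
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 30, size=137)
        for p in (0.03, 0.02275, 0.4):
            s = np.sort(x)
            h = (len(s) - 1) * p
            expected = s[int(h)] + (h - int(h)) * (s[int(h) + 1] - s[int(h)])
            assert empirical_quantile(x, p) == pytest.approx(expected)


class TestMixtureFit:
    def test_weights_sum_to_one_and_ordered(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(18, 3, 5000), rng.normal(30, 4, 1000)])
        m = fit_tdc_model(x, seed=0)
        assert m.k[0] + m.k[1] == pytest.approx(1.0, abs=1e-12)
        assert m.mu[0] < m.mu[1]
        assert all(s > 0 for s in m.sigma)

    def test_single_gaussian_sample_recovered_as_mixture(self):
        # on a pure Gaussian the two-component likelihood is flat along a
        # ridge of equivalent splits; what is identified is the mixture
        # itself, which must match the sample's distribution
        rng = np.random.default_rng(1)
        x = rng.normal(20, 2.5, 20000)
        m = fit_tdc_model(x, seed=1)
        mix_mean = m.k[0] * m.mu[0] + m.k[1] * m.mu[1]
        mix_var = sum(w * (s**2 + (mu - mix_mean) ** 2)
                      for mu, s, w in zip(m.mu, m.sigma, m.k))
        assert mix_mean == pytest.approx(x.mean(), abs=0.1)
        assert np.sqrt(mix_var) == pytest.approx(x.std(), abs=0.1)
        grid = np.linspace(10, 30, 201)
        assert np.abs(m.cdf(grid) - norm.cdf(grid, 20, 2.5)).max() < 0.01
        i = int(np.argmax(m.k))
        assert m.mu[i] == pytest.approx(20.0, abs=1.0)

    def test_loglik_nondecreasing_every_iteration(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(18, 3, 3000), rng.normal(30, 4, 600)])
        est = TdcMixtureModel(random_state=2).fit(x)
        assert np.all(np.diff(est.loglik_path_) >= -1e-8)
        assert est.converged_

    def test_agrees_with_sklearn_gaussian_mixture(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(18, 3, 8000), rng.normal(30, 4, 2000)])
        ours = fit_tdc_model(x, seed=3)
        ref = GaussianMixture(n_components=2, n_init=5, random_state=3, tol=1e-6).fit(x[:, None])
        order = np.argsort(ref.means_.ravel())
        assert np.allclose(np.sort(ours.mu), ref.means_.ravel()[order], rtol=0.02)
        assert np.allclose(ours.sigma, np.sqrt(ref.covariances_.ravel()[order]), rtol=0.05)
        assert np.allclose(ours.k, ref.weights_[order], rtol=0.05)

    def test_requires_enough_values(self):
        with pytest.raises(ValueError, match="100"):
            fit_tdc_model(np.arange(50.0))

    def test_fixed_two_components(self):
        with pytest.raises(ValueError, match="two"):
            fit_tdc_model(np.arange(200.0), n_components=3)


class TestZfTransform:
    def test_hand_evaluated_weighted_sum(self):
        m = TdcModel(mu=(10, 20), sigma=(2, 5), k=(0.6, 0.4))
        assert m.zf(15.0) == pytest.approx(0.6 * (5 / 2) + 0.4 * (-5 / 5))  # = 1.1

    def test_single_component_is_classical_zscore(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            mu, sigma = rng.uniform(5, 30), rng.uniform(0.5, 6)
            m = TdcModel(mu=(mu, mu + 10), sigma=(sigma, 1.0), k=(1.0, 0.0))
            t = rng.uniform(0, 40, size=11)
            assert np.array_equal(m.zf(t), (t - mu) / sigma)
        assert m.zf(mu) == 0.0
        assert m.zf(mu + 2 * sigma) == pytest.approx(2.0)

    def test_strictly_increasing_in_ttp(self):
        m = TdcModel(mu=(15, 27), sigma=(2, 4), k=(0.8, 0.2))
        t = np.linspace(0, 50, 300)
        assert np.all(np.diff(m.zf(t)) > 0)

    def test_map_level_transform_respects_sentinel(self):
        frames = np.array([[[10, -1], [12, 14]]])
        ttp = _ttp_from_frames(frames, tr=1.0)
        m = TdcModel(mu=(10, 20), sigma=(2, 5), k=(0.6, 0.4))
        zmap = zf_transform(ttp, m)
        assert zmap.name == "z_f"
        assert np.isnan(zmap.values[0, 0, 1])
        assert zmap.values[0, 1, 0] == pytest.approx(m.zf(12.0))

    def test_rejects_zero_sigma(self):
        with pytest.raises(ValueError, match="positive"):
            TdcModel(mu=(10, 20), sigma=(0.0, 5), k=(0.6, 0.4))


class TestIpv:
    def test_single_gaussian_inflection_at_mu_plus_sigma(self):
        m = TdcModel(mu=(18, 30), sigma=(3, 4), k=(1.0, 0.0))
        ipv = ipv_threshold(m, grid_step=0.139)
        assert ipv.ttp_at_ipv == pytest.approx(18 + 3, abs=1e-8)
        assert ipv.zf_at_ipv == pytest.approx(1.0, abs=1e-8)

    def test_mixture_matches_dense_grid_oracle(self):
        m = TdcModel(mu=(18, 30), sigma=(3, 4), k=(0.85, 0.15))
        step = 0.139
        ipv = ipv_threshold(m, grid_step=step)
        # oracle: exhaustive sign-change scan of the analytic second
        # derivative on a 1000x finer grid
        t = np.arange(m.mu[0], m.mu[1] + 4 * m.sigma[1], step / 1000)
        f2 = m.d2pdf(t)
        f1 = m.dpdf(t)
        flips = np.nonzero((np.sign(f2[:-1]) * np.sign(f2[1:]) < 0) & (f1[:-1] < 0))[0]
        oracle = t[flips[-1]]
        assert abs(ipv.ttp_at_ipv - oracle) <= step

    def test_ipv_nondecreasing_in_sigma2(self):
        vals = []
        for s2 in (2.0, 3.0, 4.0, 5.0):
            m = TdcModel(mu=(18, 30), sigma=(3, s2), k=(0.85, 0.15))
            vals.append(ipv_threshold(m, grid_step=0.1).ttp_at_ipv)
        assert np.all(np.diff(vals) >= -1e-9)

    def test_ipv_beyond_first_mean(self):
        m = TdcModel(mu=(18, 30), sigma=(3, 4), k=(0.85, 0.15))
        assert ipv_threshold(m, grid_step=0.1).ttp_at_ipv > m.mu[0]


class TestModelDensityAndSerialization:
    def test_lower_tail_at_zf_minus_two_is_2p275_percent(self):
        m = TdcModel(mu=(21.0, 30.0), sigma=(2.4, 1.0), k=(1.0, 0.0))
        ttp = m.zf_inverse(-2.0)
        assert m.cdf(ttp) == pytest.approx(norm.cdf(-2.0), abs=1e-12)
        assert 100 * m.cdf(ttp) == pytest.approx(2.275, abs=1e-3)

    def test_pdf_integrates_to_one(self):
        m = TdcModel(mu=(18, 30), sigma=(3, 4), k=(0.85, 0.15))
        t = np.linspace(-20, 80, 20001)
        assert np.trapezoid(m.pdf(t), t) == pytest.approx(1.0, abs=1e-6)

    def test_json_roundtrip(self, tmp_path):
        m = TdcModel(mu=(18, 30), sigma=(3, 4), k=(0.85, 0.15), loglik=-123.4, n_iter=17)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = TdcModel.from_json(path)
        assert back == m
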