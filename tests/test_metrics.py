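import numpy as np
import pytest
from scipy import ndimage

from latfuse import PhantomSpec, evaluate_all, make_structural_phantom, q_c, q_cb, q_g, q_te
from latfuse.metrics import _QG_PARAMS, q_g_max


def _phantom(seed, size=64):
    return make_structural_phantom(PhantomSpec(size=(size, size), seed=seed))


def brute_q_te(a, b, f, q=1.85):
    """Independent loop implementation over all 256x256 joint-histogram cells."""

    def quant(x):
        return np.clip(np.floor(np.asarray(x) * 255.0 + 0.5), 0, 255).astype(int)

    qa, qb, qf = quant(a), quant(b), quant(f)
    n = qa.size

    def marginal(img):
        p = np.bincount(img.ravel(), minlength=256) / n
        return p

    def tsallis_h(p):
        total = 0.0
        for v in p:
            if v > 0:
                total += v**q
        return (1.0 - total) / (q - 1.0)

    def tsallis_i(x, y):
        joint = np.zeros((256, 256))
        for xi, yi in zip(x.ravel(), y.ravel()):
            joint[xi, yi] += 1
        joint /= n
        px, py = marginal(x), marginal(y)
        total = 0.0
        for i in range(256):
            for j in range(256):
                if joint[i, j] > 0:
                    total += joint[i, j] ** q / (px[i] * py[j]) ** (q - 1.0)
        return (total - 1.0) / (q - 1.0)

    ha, hb, hf = tsallis_h(marginal(qa)), tsallis_h(marginal(qb)), tsallis_h(marginal(qf))
    return tsallis_i(qa, qf) / (ha + hf) + tsallis_i(qb, qf) / (hb + hf)


def brute_q_c(a, b, f, window=8):
    """Independent per-window loop implementation of the structural metric."""

    def quant(x):
        return np.clip(np.floor(np.asarray(x) * 255.0 + 0.5), 0, 255)

    qa, qb, qf = quant(a), quant(b), quant(f)
    C1 = (0.01 * 255) ** 2
    C2 = (0.03 * 255) ** 2
    h, w = qa.shape
    scores = []
    for y in range(h - window + 1):
        for x in range(w - window + 1):
            wa = qa[y : y + window, x : x + window].ravel()
            wb = qb[y : y + window, x : x + window].ravel()
            wf = qf[y : y + window, x : x + window].ravel()

            def stats(u, v):
                mu_u, mu_v = u.mean(), v.mean()
                var_u = ((u - mu_u) ** 2).sum() / (len(u) - 1)
                var_v = ((v - mu_v) ** 2).sum() / (len(v) - 1)
                cov = ((u - mu_u) * (v - mu_v)).sum() / (len(u) - 1)
                ssim = ((2 * mu_u * mu_v + C1) * (2 * cov + C2)) / (
                    (mu_u**2 + mu_v**2 + C1) * (var_u + var_v + C2)
                )
                return ssim, cov

            ssim_af, cov_af = stats(wa, wf)
            ssim_bf, cov_bf = stats(wb, wf)
            total = cov_af + cov_bf
            mu = cov_af / total if total != 0 else 0.5
            mu = min(max(mu, 0.0), 1.0)
            scores.append(mu * ssim_af + (1 - mu) * ssim_bf)
    return float(np.clip(np.mean(scores), 0.0, 1.0))


class TestQTE:
    def test_degenerate_constant_images_fall_back_to_zero(self):
        const = np.full((32, 32), 0.5)
        with pytest.warns(UserWarning):
            assert q_te(const, const, const) == 0.0

    def test_matches_brute_force_histogram_oracle(self, rng):
        img = rng.uniform(0, 1, (24, 24))
        assert q_te(img, img, img) == pytest.approx(brute_q_te(img, img, img), abs=1e-9)
        a, b, f = (rng.uniform(0, 1, (24, 24)) for _ in range(3))
        assert q_te(a, b, f) == pytest.approx(brute_q_te(a, b, f), abs=1e-9)

    def test_independent_noise_scores_below_identity(self, rng):
        a = _phantom(1)
        noise = rng.uniform(0, 1, a.shape)
        assert q_te(a, a, noise) < q_te(a, a, a)

    def test_invalid_order_rejected(self):
        a = _phantom(1)
        with pytest.raises(ValueError):
            q_te(a, a, a, q=1.0)


class TestQG:
    def test_identity_fusion_hits_closed_form_maximum(self):
        a = _phantom(2)
        expected = q_g_max()
        p = _QG_PARAMS
        direct = (
            p["gamma_g"] / (1 + np.exp(p["kappa_g"] * (1 - p["sigma_g"])))
            * p["gamma_a"] / (1 + np.exp(p["kappa_a"] * (1 - p["sigma_a"])))
        )
        assert expected == pytest.approx(direct, abs=1e-15)
        assert q_g(a, a, a) == pytest.approx(expected, abs=1e-9)

    def test_blurred_fusion_scores_strictly_lower(self):
        a = _phantom(3)
        assert q_g(a, a, ndimage.gaussian_filter(a, 1.5)) < q_g(a, a, a)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(5):
            a, b, f = (rng.uniform(0, 1, (32, 32)) for _ in range(3))
            assert 0.0 <= q_g(a, b, f) <= 1.0

    def test_flat_images_fall_back_to_zero(self):
        flat = np.full((32, 32), 0.25)
        with pytest.warns(UserWarning):
            assert q_g(flat, flat, flat) == 0.0


class TestQC:
    def test_identity_fusion_scores_one(self):
        a = _phantom(4)
        assert q_c(a, a, a) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_window_oracle(self, rng):
        a, b, f = (rng.uniform(0, 1, (16, 16)) for _ in range(3))
        assert q_c(a, b, f) == pytest.approx(brute_q_c(a, b, f), abs=1e-9)

    def test_source_identical_to_fusion_dominates(self, rng):
        a = _phantom(5)
        b = rng.uniform(0, 1, a.shape)
        assert q_c(a, b, a) > 0.5


class TestQCB:
    def test_identity_fusion_scores_one(self):
        a = _phantom(6)
        assert q_cb(a, a, a) == pytest.approx(1.0, abs=1e-6)

    def test_inverted_fusion_scores_strictly_lower(self):
        a = _phantom(7)
        assert q_cb(a, a, 1.0 - a) < q_cb(a, a, a)

    def test_finite_and_bounded_on_random_triples(self, rng):
        for _ in range(10):
            a, b, f = (rng.uniform(0, 1, (32, 32)) for _ in range(3))
            val = q_cb(a, b, f)
            assert np.isfinite(val) and val <= 1.0 + 1e-12


class TestSharedProperties:
    @pytest.mark.parametrize("metric", [q_te, q_g, q_c, q_cb])
    def test_source_swap_symmetry(self, metric):
        a, b = _phantom(8), _phantom(9)
        f = 0.5 * (a + b)
        assert metric(a, b, f) == pytest.approx(metric(b, a, f), abs=1e-12)

    @pytest.mark.parametrize("metric", [q_te, q_g, q_c, q_cb])
    def test_blur_degrades_every_metric(self, metric):
        a, b = _phantom(12), _phantom(13)
        blurred = ndimage.gaussian_filter(a, 1.5)
        assert metric(a, b, blurred) < metric(a, b, a)

    def test_evaluate_all_reports_params(self):
        a, b = _phantom(10), _phantom(11)
        report = evaluate_all(a, b, 0.5 * (a + b))
        assert set(report.as_dict()) == {"q_te", "q_g", "q_c", "q_cb"}
        assert report.params["tsallis_q"] == 1.85
        assert report.params["histogram_bins"] == 256
        assert 0.0 <= report.q_g <= 1.0
        assert 0.0 <= report.q_c <= 1.0
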