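import math

import numpy as np
import pytest

from kinprint.classify import (
    BivariateParams,
    CLOSE_RELATIONSHIPS,
    K_RATE_CAP,
    POParams,
    RelationshipModel,
    classify_pair,
    decision_boundaries,
    default_model,
    density,
    fit_model,
    read_model,
    write_model,
)
from kinprint.metrics import PairStats


def _stats(hgmr, agmr, n=10_000):
    """Synthetic PairStats with the requested rates."""
    n_both = n // 3
    return PairStats(
        "a", "b",
        n_compared=n,
        n_mismatch=int(round(agmr * n)),
        n_both_hom=n_both,
        n_DO=int(round(hgmr * n_both)),
    )


class TestDensity:
    def test_uncorrelated_peak_value(self):
        m = default_model()
        fs = BivariateParams(0.05, 0.01, 0.33, 0.02, 0.0)
        m2 = RelationshipModel(po=m.po, fs=fs, d2=m.d2, d3=m.d3)
        peak = density("FS", 0.05, 0.33, m2)
        assert peak == pytest.approx(1 / (2 * math.pi * 0.01 * 0.02))

    @pytest.mark.parametrize("rel", CLOSE_RELATIONSHIPS)
    def test_density_normalizes(self, rel):
        m = default_model()
        b = m.params(rel)
        if rel == "PO":
            xs = np.linspace(0, 0.01, 600)
            ys = np.linspace(b.mu_y - 6 * b.sd_y, b.mu_y + 6 * b.sd_y, 400)
        else:
            xs = np.linspace(b.mu_x - 6 * b.sd_x, b.mu_x + 6 * b.sd_x, 400)
            ys = np.linspace(b.mu_y - 6 * b.sd_y, b.mu_y + 6 * b.sd_y, 400)
        grid = np.array([[density(rel, x, y, m) for y in ys] for x in xs])
        integral = np.trapezoid(np.trapezoid(grid, ys, axis=1), xs)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_po_density_decreasing_in_hgmr(self):
        m = default_model()
        vals = [density("PO", x, m.po.mu_y, m) for x in (0.0, 0.001, 0.01)]
        assert vals == sorted(vals, reverse=True)


class TestClassify:
    def test_near_zero_agmr_is_identical(self):
        label, post = classify_pair(_stats(0.0, 0.001), default_model())
        assert label == "ID" and post is None

    def test_high_hgmr_is_unrelated(self):
        label, post = classify_pair(_stats(0.22, 0.54), default_model())
        assert label == "UN" and post is None

    @pytest.mark.parametrize(
        "hgmr,agmr,expected",
        [(0.0486, 0.3359, "FS"), (0.1732, 0.5107, "D3"), (0.1116, 0.4730, "D2"),
         (0.0004, 0.3948, "PO")],
    )
    def test_class_means_classified_confidently(self, hgmr, agmr, expected):
        label, post = classify_pair(_stats(hgmr, agmr), default_model())
        assert label == expected
        assert post[expected] > 0.99

    def test_posteriors_sum_to_one(self):
        _, post = classify_pair(_stats(0.08, 0.40), default_model())
        assert sum(post.values()) == pytest.approx(1.0)

    def test_prior_scaling_invariance(self):
        m = default_model()
        doubled = RelationshipModel(
            po=m.po, fs=m.fs, d2=m.d2, d3=m.d3,
            priors={r: 0.5 for r in CLOSE_RELATIONSHIPS},
        )
        for hgmr, agmr in [(0.05, 0.34), (0.12, 0.47), (0.17, 0.51)]:
            assert classify_pair(_stats(hgmr, agmr), m)[0] == classify_pair(
                _stats(hgmr, agmr), doubled
            )[0]

    def test_undefined_hgmr_is_unrelated_with_warning(self, caplog):
        st = PairStats("a", "b", n_compared=500, n_mismatch=300, n_both_hom=0, n_DO=0)
        label, post = classify_pair(st, default_model())
        assert label == "UN" and post is None


class TestFit:
    def test_parameter_recovery_from_sampled_pairs(self):
        """Moments of pairs drawn from the model are recovered within 3 SE."""
        rng = np.random.default_rng(17)
        m = default_model()
        n = 1_000
        labeled = []
        for rel in ("FS", "D2", "D3"):
            b = m.params(rel)
            cov = [
                [b.sd_x**2, b.rho * b.sd_x * b.sd_y],
                [b.rho * b.sd_x * b.sd_y, b.sd_y**2],
            ]
            xy = rng.multivariate_normal([b.mu_x, b.mu_y], cov, size=n)
            labeled += [(_stats(x, y), rel) for x, y in xy]
        po = m.po
        x = rng.exponential(1 / po.k_rate, size=n)
        y = rng.normal(po.mu_y, po.sd_y, size=n)
        labeled += [(_stats(xi, yi), "PO") for xi, yi in zip(x, y)]

        fit = fit_model(labeled)
        for rel in ("FS", "D2", "D3"):
            b, f = m.params(rel), fit.params(rel)
            assert abs(f.mu_x - b.mu_x) < 3 * b.sd_x / math.sqrt(n)
            assert abs(f.mu_y - b.mu_y) < 3 * b.sd_y / math.sqrt(n)
            # SE of a correlation estimate ~ (1-rho^2)/sqrt(n)
            assert abs(f.rho - b.rho) < 3 * (1 - b.rho**2) / math.sqrt(n)
        assert fit.po.k_rate == pytest.approx(po.k_rate, rel=0.15)

    def test_single_relationship_updates_only_that_entry(self):
        rng = np.random.default_rng(3)
        m = default_model()
        b = m.params("FS")
        xy = rng.multivariate_normal(
            [b.mu_x + 0.01, b.mu_y], [[b.sd_x**2, 0], [0, b.sd_y**2]], size=200
        )
        fit = fit_model([(_stats(x, y), "FS") for x, y in xy])
        assert fit.fs.mu_x != m.fs.mu_x
        assert fit.d2 == m.d2 and fit.d3 == m.d3 and fit.po == m.po

    def test_degenerate_po_rate_capped(self):
        labeled = [(_stats(0.0, 0.39), "PO") for _ in range(50)]
        fit = fit_model(labeled)
        assert fit.po.k_rate == K_RATE_CAP

    def test_no_pairs_returns_defaults(self):
        assert fit_model([]) == default_model()

    def test_model_tsv_roundtrip(self, tmp_path):
        m = default_model()
        write_model(m, tmp_path / "model.tsv")
        back = read_model(tmp_path / "model.tsv")
        assert back.fs == m.fs and back.d2 == m.d2 and back.d3 == m.d3
        assert back.po == m.po


class TestBoundaries:
    def test_equal_isotropic_densities_bisect(self):
        m = default_model()
        iso1 = BivariateParams(0.05, 0.01, 0.40, 0.01, 0.0)
        iso2 = BivariateParams(0.09, 0.01, 0.40, 0.01, 0.0)
        model = RelationshipModel(po=m.po, fs=iso1, d2=iso2, d3=m.d3)
        bounds = decision_boundaries(model, x_range=(0.03, 0.11), y_range=(0.35, 0.45),
                                     n_grid=81)
        pts = bounds[("FS", "D2")]
        assert len(pts) > 0
        assert np.allclose(pts[:, 0], 0.07, atol=1e-6)

    def test_boundary_points_have_equal_posteriors(self):
        m = default_model()
        bounds = decision_boundaries(m, n_grid=101)
        checked = 0
        for (r1, r2), pts in bounds.items():
            for x, y in pts[:50]:
                d1 = m.priors[r1] * density(r1, float(x), float(y), m)
                d2 = m.priors[r2] * density(r2, float(x), float(y), m)
                if d1 + d2 == 0:
                    continue
                assert abs(d1 - d2) / (d1 + d2) < 0.05  # grid-interpolation tolerance
                checked += 1
        assert checked > 10
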