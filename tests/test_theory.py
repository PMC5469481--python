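import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from kinprint import theory
from kinprint.theory import (
    PROFILES,
    FreqSpec,
    IBDProfile,
    ScanDesign,
    expected_agmr,
    expected_hgmr,
    kinship,
    p_ibs_given_ibd,
    quadratic_fn_rate,
    quadratic_fp_rate,
    sd_hgmr,
    separation_delta,
    subquadratic_sensitivity,
)


class TestIBSTable:
    def test_half_frequency_values(self):
        t = p_ibs_given_ibd(0.5)
        assert t[0, 0] == pytest.approx(2 * 0.25 * 0.25)
        # one shared allele: I=2 iff the two free alleles agree, so p^2 + q^2
        assert t[2, 1] == pytest.approx(self._enumerate_i2_z1(0.5))
        assert t[2, 1] == pytest.approx(0.5)
        assert t[2, 2] == 1.0

    @staticmethod
    def _enumerate_i2_z1(p):
        """Oracle: enumerate (shared, free, free) allele outcomes."""
        w = {0: p, 1: 1 - p}
        total = 0.0
        for shared in (0, 1):
            for y1 in (0, 1):
                for y2 in (0, 1):
                    if sorted((shared, y1)) == sorted((shared, y2)):
                        total += w[shared] * w[y1] * w[y2]
        return total

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(deadline=None, max_examples=50)
    def test_columns_are_distributions(self, p):
        t = p_ibs_given_ibd(p)
        assert np.allclose(t.sum(axis=0), 1.0)
        assert (t >= 0).all()

    def test_rejects_degenerate_frequency(self):
        with pytest.raises(ValueError):
            p_ibs_given_ibd(0.0)


class TestExpectations:
    def test_identical_pair_has_zero_agmr(self):
        assert expected_agmr(PROFILES["ID"]) == 0.0

    def test_uniform_matches_quadrature_oracle(self):
        # exact polynomial integration vs numerical quadrature
        prof = PROFILES["FS"]
        def integrand(p):
            q = 1 - p
            mz0 = p**4 + q**4 + 4 * p**2 * q**2
            mz1 = p**3 + q**3 + p**2 * q + p * q**2
            return prof.p0 * (1 - mz0) + prof.p1 * (1 - mz1)
        expected, _ = quad(integrand, 0.1, 0.9)
        assert expected_agmr(prof) == pytest.approx(expected / 0.8, abs=1e-10)

    def test_explicit_freqs_are_arithmetic_mean(self):
        # midpoint grid: O(h^2) quadrature error, far below the tolerance
        h = 0.8 / 20_000
        grid = FreqSpec.explicit(np.arange(0.1 + h / 2, 0.9, h))
        for rel in ("PO", "FS", "D2", "D3", "UN"):
            assert expected_agmr(PROFILES[rel], grid) == pytest.approx(
                expected_agmr(PROFILES[rel]), abs=1e-6
            )
            assert expected_hgmr(PROFILES[rel], grid) == pytest.approx(
                expected_hgmr(PROFILES[rel]), abs=1e-6
            )

    def test_po_hgmr_exactly_zero(self):
        assert expected_hgmr(PROFILES["PO"]) == 0.0

    def test_sd_vanishes_with_panel_size(self):
        prof = PROFILES["UN"]
        assert sd_hgmr(prof, S=10**12) == pytest.approx(0.0, abs=1e-4)
        assert sd_hgmr(prof, S=100) > sd_hgmr(prof, S=10_000)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            IBDProfile(0.5, 0.2, 0.2)


class TestScreenRates:
    def test_zero_error_gives_zero_fn(self):
        assert quadratic_fn_rate(ScanDesign(epsilon=0.0)) == 0.0

    def test_fn_is_binomial_upper_tail(self):
        # independent oracle: explicit summation of the binomial pmf
        m, k, eps = 64, 8, 0.0548
        tail = sum(
            math.comb(m, i) * eps**i * (1 - eps) ** (m - i) for i in range(k, m + 1)
        )
        assert quadratic_fn_rate(ScanDesign(m=m, k=k, epsilon=eps)) == pytest.approx(
            tail, rel=1e-12
        )

    def test_fp_negligible_for_unrelated_pairs(self):
        d = ScanDesign(m=64, k=8, eta=0.54)
        assert quadratic_fp_rate(d) < 1e-8

    def test_fp_zero_threshold(self):
        assert quadratic_fp_rate(ScanDesign(k=0, eta=0.5)) == 0.0

    def test_subquadratic_sensitivity(self):
        per, fn = subquadratic_sensitivity(ScanDesign(m=20, delta_rate=0.0))
        assert per == 1.0 and fn == 0.0
        per, _ = subquadratic_sensitivity(ScanDesign(m=20, delta_rate=0.01))
        assert per == pytest.approx(math.exp(-0.2))

    def test_fn_decreases_with_rounds(self):
        fns = [
            subquadratic_sensitivity(ScanDesign(m=20, delta_rate=0.05, r=r))[1]
            for r in range(1, 6)
        ]
        assert all(a > b for a, b in zip(fns, fns[1:]))


class TestKinshipAndSeparation:
    @pytest.mark.parametrize(
        "rel,expected",
        [("ID", 0.5), ("PO", 0.25), ("FS", 0.25), ("D2", 0.125), ("D3", 0.0625), ("UN", 0.0)],
    )
    def test_kinship_coefficients(self, rel, expected):
        assert kinship(PROFILES[rel]) == pytest.approx(expected)

    def test_equal_means_give_half_auc(self):
        delta, auc = separation_delta(0.1, 0.01, 0.1, 0.02)
        assert delta == 0.0 and auc == 0.5

    def test_auc_matches_overlap_integral(self):
        # oracle: P(X > Y) for X~N(2,1), Y~N(0,1) by numerical integration
        oracle, _ = quad(lambda y: norm.pdf(y) * norm.sf(y, loc=2), -10, 12)
        _, auc = separation_delta(2.0, 1.0, 0.0, 1.0)
        assert auc == pytest.approx(oracle, abs=1e-6)

    def test_delta_increases_with_mean_gap(self):
        deltas = [separation_delta(mu, 1.0, 0.0, 1.0)[0] for mu in (0.5, 1.0, 2.0)]
        assert deltas == sorted(deltas)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            separation_delta(1, 0, 0, 1)


def test_moment_helper_can_exceed_one():
    # the documented reason the classifier avoids IBD-probability estimates
    assert theory.p_z0_from_i0(0.2, 0.5) > 1.0
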