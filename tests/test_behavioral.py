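"""Questionnaire scoring and the correlation toolbox."""

import numpy as np
import pytest
from scipy import stats

from imagerylink import behavioral
from imagerylink.errors import DegenerateInputError, ValidationError


class TestScoring:
    @pytest.mark.parametrize(
        "viv, ctl, expected",
        [
            ([7] * 14, [7] * 14, (7.0, 7.0, 7.0)),
            ([4] * 14, [6] * 14, (4.0, 6.0, 5.0)),
            ([1] * 14, [1] * 14, (1.0, 1.0, 1.0)),
        ],
    )
    def test_bais_constant_items(self, viv, ctl, expected):
        assert behavioral.score_bais(viv, ctl) == expected

    def test_bais_matches_mean_oracle_and_item_order_invariance(self, rng):
        for _ in range(25):
            viv = rng.integers(1, 8, 14)
            ctl = rng.integers(1, 8, 14)
            v, c, tot = behavioral.score_bais(viv, ctl)
            assert v == pytest.approx(sum(viv) / 14)
            assert c == pytest.approx(sum(ctl) / 14)
            assert tot == pytest.approx((v + c) / 2)
            shuffled = behavioral.score_bais(rng.permutation(viv), rng.permutation(ctl))
            assert shuffled == pytest.approx((v, c, tot))

    @pytest.mark.parametrize(
        "items, expected",
        [([1] * 16, 5.0), ([5] * 16, 1.0), ([3] * 16, 3.0)],
    )
    def test_vviq_inversion_endpoints(self, items, expected):
        assert behavioral.score_vviq(items) == pytest.approx(expected)

    def test_vviq_matches_inverted_mean_oracle(self, rng):
        for _ in range(25):
            items = rng.integers(1, 6, 16)
            assert behavioral.score_vviq(items) == pytest.approx(6 - sum(items) / 16)

    @pytest.mark.parametrize(
        "viv, ctl, fragment",
        [
            ([8] + [4] * 13, [4] * 14, "item 0"),
            ([4] * 14, [4] * 6 + [0] + [4] * 7, "item 6"),
            ([4] * 13, [4] * 14, "expected 14"),
            ([4] * 13 + [None], [4] * 14, "item 13"),
        ],
    )
    def test_bais_rejects_bad_items_naming_index(self, viv, ctl, fragment):
        with pytest.raises(ValidationError, match=fragment):
            behavioral.score_bais(viv, ctl)

    def test_vviq_rejects_out_of_range(self):
        with pytest.raises(ValidationError, match="item 2"):
            behavioral.score_vviq([1, 2, 6] + [3] * 13)


class TestPearson:
    def test_identity_gives_unit_correlation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0, 8.0])
        res = behavioral.pearson_r(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.df == 3

    def test_orthogonal_to_centered_x_gives_zero(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, -1.0, 0.0, 1.0])  # orthogonal to centered x
        assert behavioral.pearson_r(x, y).r == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            behavioral.pearson_r([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_p_value_matches_permutation_oracle(self, rng):
        x = rng.standard_normal(12)
        y = 0.5 * x + rng.standard_normal(12)
        res = behavioral.pearson_r(x, y)
        n_mc = 20000
        count = 0
        for _ in range(n_mc):
            rp = np.corrcoef(x, rng.permutation(y))[0, 1]
            if abs(rp) >= abs(res.r) - 1e-12:
                count += 1
        p_mc = count / n_mc
        se = np.sqrt(max(p_mc * (1 - p_mc), 1e-6) / n_mc)
        assert res.p_two_sided == pytest.approx(p_mc, abs=max(5 * se, 0.01))


class TestFisherZ:
    def test_closed_form_values(self):
        assert behavioral.fisher_z(0.0) == 0.0
        assert behavioral.fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0))

    def test_odd_symmetry(self, rng):
        r = rng.uniform(-0.99, 0.99, 50)
        np.testing.assert_allclose(behavioral.fisher_z(-r), -behavioral.fisher_z(r))

    def test_clipping_keeps_perfect_correlation_finite(self):
        z = behavioral.fisher_z(1.0)
        assert np.isfinite(z) and z == pytest.approx(np.arctanh(1 - 1e-7))

    def test_unclipped_unit_correlation_raises(self):
        with pytest.raises(DegenerateInputError):
            behavioral.fisher_z(1.0, clip=None)


class TestPartialR:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 30))
        assert behavioral.partial_r(x, y).r == pytest.approx(behavioral.pearson_r(x, y).r)

    def test_covariate_orthogonal_to_both_leaves_r_unchanged(self, rng):
        x, y = rng.standard_normal((2, 40))
        q, _ = np.linalg.qr(np.column_stack([np.ones(40), x, y, rng.standard_normal(40)]))
        cov = q[:, 3]  # orthogonal to intercept, x and y by construction
        res = behavioral.partial_r(x, y, cov)
        assert res.r == pytest.approx(behavioral.pearson_r(x, y).r, abs=1e-10)
        assert res.df == 40 - 3

    def test_matches_explicit_residualization_oracle(self, rng):
        for _ in range(10):
            n, k = 35, 3
            cov = rng.standard_normal((n, k))
            x = cov @ rng.standard_normal(k) + rng.standard_normal(n)
            y = cov @ rng.standard_normal(k) + rng.standard_normal(n)
            design = np.column_stack([np.ones(n), cov])
            proj = design @ np.linalg.pinv(design)
            rx, ry = x - proj @ x, y - proj @ y
            expected = np.corrcoef(rx, ry)[0, 1]
            res = behavioral.partial_r(x, y, cov)
            assert res.r == pytest.approx(expected, abs=1e-10)
            assert res.df == n - 2 - k

    def test_matches_pingouin_cross_check(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n = 40
        cov = rng.standard_normal((n, 2))
        x = cov[:, 0] + rng.standard_normal(n)
        y = 0.4 * x + cov[:, 1] + rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        res = behavioral.partial_r(x, y, cov)
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.p_two_sided == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_y_linear_in_covariates_is_degenerate(self, rng):
        cov = rng.standard_normal((20, 2))
        x = rng.standard_normal(20)
        y = 2.0 * cov[:, 0] - cov[:, 1] + 3.0
        with pytest.raises(DegenerateInputError):
            behavioral.partial_r(x, y, cov)

    def test_collinear_covariates_rejected_with_column_indices(self, rng):
        c0 = rng.standard_normal(20)
        cov = np.column_stack([c0, 2 * c0])
        with pytest.raises(ValidationError, match="collinear"):
            behavioral.partial_r(rng.standard_normal(20), rng.standard_normal(20), cov)


def test_shapiro_wrapper_agrees_with_scipy(rng):
    x = rng.standard_normal(50)
    stat, p = behavioral.shapiro_wilk(x)
    ref = stats.shapiro(x)
    assert (stat, p) == pytest.approx((ref.statistic, ref.pvalue))


def test_cohort_roundtrip_and_validation(tmp_path, tiny_cohort):
    path = tmp_path / "cohort.csv"
    behavioral.save_cohort(tiny_cohort, path)
    loaded = behavioral.load_cohort(path)
    assert list(loaded["subject_id"]) == list(tiny_cohort["subject_id"])
    bad = tiny_cohort.drop(columns=["bais_total"])
    bad.to_csv(tmp_path / "bad.csv", index=False)
    with pytest.raises(ValidationError, match="bais_total"):
        behavioral.load_cohort(tmp_path / "bad.csv")
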