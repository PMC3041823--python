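"""Unit tests for the five statistics and their building blocks."""

import numpy as np
import pytest

from gti import (
    GroupAssignment,
    copa_score,
    gti_group_score,
    gti_score,
    ort_score,
    os_score,
    outlier_cutoff,
    robust_center_scale,
    score_all,
    t_statistic,
)
from gti.stats_core import OutlierCutoff, UndefinedInputError

from _oracle import ORACLES
from conftest import make_matrix, random_small_matrix, split


class TestRobustCenterScale:
    def test_hand_example(self):
        rs = robust_center_scale([1, 2, 3, 4, 5])
        assert rs.med == 3.0
        assert rs.mad == pytest.approx(1.4826, abs=0)

    def test_constant_vector(self):
        rs = robust_center_scale([7.5, 7.5, 7.5])
        assert rs.med == 7.5
        assert rs.mad == 0.0

    def test_mad_zero_iff_majority_at_median(self):
        # more than half the values equal the median -> mad 0
        assert robust_center_scale([2, 2, 2, 9, 0]).mad == 0.0
        assert robust_center_scale([2, 2, 9, 0]).mad > 0.0

    def test_normal_consistency(self):
        # scaled MAD estimates sd=1 for standard normal data
        v = np.random.default_rng(7).standard_normal(100_000)
        assert robust_center_scale(v).mad == pytest.approx(1.0, abs=0.02)

    def test_empty_raises(self):
        with pytest.raises(UndefinedInputError):
            robust_center_scale([])
        with pytest.raises(UndefinedInputError):
            robust_center_scale([np.nan, np.nan])

    def test_ignores_missing(self):
        rs = robust_center_scale([1, 2, np.nan, 3, 4, 5, np.nan])
        assert rs.med == 3.0


class TestOutlierCutoff:
    def test_one_to_eight(self):
        c = outlier_cutoff(np.arange(1, 9))
        assert c.b == pytest.approx(9.75, abs=1e-12)
        assert c.source == "all"

    def test_constant(self):
        assert outlier_cutoff([4.2] * 5).b == 4.2

    def test_normal_limit(self):
        # q75 + IQR of N(0,1): 0.67449 + 1.34898
        v = np.random.default_rng(11).standard_normal(100_000)
        assert outlier_cutoff(v).b == pytest.approx(2.02347, abs=0.03)

    def test_empty_raises(self):
        with pytest.raises(UndefinedInputError):
            outlier_cutoff([])


class TestTStatistic:
    def test_hand_example(self):
        matrix, groups = make_matrix([[1, 2, 3, 4, 6, 8]], [1, 1, 1, 2, 2, 2])
        t = t_statistic(matrix, groups)
        assert t[0] == pytest.approx(4 / (np.sqrt(2.5) * np.sqrt(2 / 3)), rel=1e-12)
        assert t[0] == pytest.approx(3.098, abs=1e-3)

    def test_identical_groups_zero(self):
        matrix, groups = make_matrix([[1, 2, 3, 1, 2, 3]], [1, 1, 1, 2, 2, 2])
        assert t_statistic(matrix, groups)[0] == 0.0

    def test_scipy_agreement(self, rng):
        from scipy import stats as sps

        matrix, groups = random_small_matrix(rng)
        t = t_statistic(matrix, groups)
        x = matrix.values
        ref = sps.ttest_ind(
            x[:, groups.disease_mask], x[:, groups.normal_mask], axis=1
        ).statistic
        np.testing.assert_allclose(t, ref, rtol=1e-10)

    def test_zero_variance_undefined(self):
        matrix, groups = make_matrix([[5, 5, 5, 5]], [1, 1, 2, 2])
        assert np.isnan(t_statistic(matrix, groups)[0])

    def test_small_group_undefined(self):
        matrix, groups = make_matrix([[1, 2, 3, 4]], [1, 2, 2, 2])
        assert np.isnan(t_statistic(matrix, groups)[0])


class TestCopa:
    def test_hand_example(self):
        matrix, groups = make_matrix(
            [[1, 2, 3, 4, 5, 1, 2, 3, 4, 20]], [1] * 5 + [2] * 5
        )
        s = copa_score(matrix, groups, r=90)
        # med 3, mad 1.4826; type-7 90th pct of standardized disease
        z = (np.array([1, 2, 3, 4, 20]) - 3) / 1.4826
        expected = np.quantile(z, 0.9, method="linear")
        assert s[0] == pytest.approx(expected, rel=1e-12)
        assert s[0] == pytest.approx(7.150, abs=1e-3)

    def test_disease_at_median_zero(self):
        matrix, groups = make_matrix([[1, 2, 3, 4, 5, 3, 3, 3]], [1] * 5 + [2] * 3)
        assert copa_score(matrix, groups, r=90)[0] == 0.0

    def test_normal_outlier_cannot_exceed_disease_max(self, rng):
        base = [[1, 2, 3, 4, 5, 1, 2, 3, 4, 20]]
        labels = [1] * 5 + [2] * 5
        matrix, groups = make_matrix(base, labels)
        boosted = [[1, 2, 3, 4, 500, 1, 2, 3, 4, 20]]
        matrix2, _ = make_matrix(boosted, labels)
        for m, g in ((matrix, groups), (matrix2, groups)):
            s = copa_score(m, g, r=95)[0]
            x = m.values[0]
            med = np.median(x)
            mad = 1.4826 * np.median(np.abs(x - med))
            zmax = (20 - med) / mad
            assert s <= zmax + 1e-12

    def test_bad_r_rejected(self):
        matrix, groups = make_matrix([[1, 2, 3, 4]], [1, 1, 2, 2])
        with pytest.raises(ValueError, match="75, 90 or 95"):
            copa_score(matrix, groups, r=80)

    def test_mad_zero_undefined(self):
        matrix, groups = make_matrix([[1, 1, 1, 1, 1, 9]], [1] * 3 + [2] * 3)
        assert np.isnan(copa_score(matrix, groups)[0])


class TestOutlierSum:
    def test_no_disease_above_cutoff(self):
        matrix, groups = make_matrix([[1, 2, 3, 4, 2, 3, 1, 4]], [1] * 4 + [2] * 4)
        assert os_score(matrix, groups)[0] == 0.0

    def test_chained_hand_example(self):
        # normal [1,2,1,2], disease [1,2,1,9]: b on all 8 values
        vals = [1, 2, 1, 2, 1, 2, 1, 9]
        matrix, groups = make_matrix([vals], [1] * 4 + [2] * 4)
        b = outlier_cutoff(vals).b
        rs = robust_center_scale(vals)
        assert b < 9 and rs.mad > 0
        expected = (9 - rs.med) / rs.mad
        assert os_score(matrix, groups)[0] == pytest.approx(expected, rel=1e-12)

    def test_degenerate_mad_flagged(self):
        # all-sample mad is 0 here: score must be undefined, not infinite
        matrix, groups = make_matrix([[1, 1, 1, 1, 1, 1, 1, 9]], [1] * 4 + [2] * 4)
        assert np.isnan(os_score(matrix, groups)[0])

    def test_extreme_normal_sample_gives_zero(self):
        matrix, groups = make_matrix(
            [[1, 2, 1, 50, 1, 2, 1, 2]], [1] * 4 + [2] * 4
        )
        assert os_score(matrix, groups)[0] == 0.0


class TestOrt:
    def test_all_disease_below_normal_fence(self):
        matrix, groups = make_matrix(
            [[1, 2, 3, 4, 5, 1, 2, 3, 4, 5]], [1] * 5 + [2] * 5
        )
        assert ort_score(matrix, groups)[0] == 0.0

    def test_hand_example(self):
        # normal [1,2,3,4,5]: q75=4, IQR=2 -> b_normal=6 (type 7); R={20}
        normal = [1, 2, 3, 4, 5]
        disease = [1, 2, 3, 4, 20]
        matrix, groups = make_matrix([normal + disease], [1] * 5 + [2] * 5)
        assert outlier_cutoff(normal).b == pytest.approx(6.0, abs=1e-12)
        centred = [v - 3 for v in normal] + [v - 3 for v in disease]
        mad_star = 1.4826 * np.median(np.abs(centred))
        expected = (20 - 3) / mad_star
        assert ort_score(matrix, groups)[0] == pytest.approx(expected, rel=1e-12)

    def test_scale_equivariance(self):
        matrix, groups = make_matrix(
            [[1, 2, 3, 4, 5, 1, 2, 3, 4, 20]], [1] * 5 + [2] * 5
        )
        scaled, _ = make_matrix(
            [[3.7 * v for v in [1, 2, 3, 4, 5, 1, 2, 3, 4, 20]]],
            [1] * 5 + [2] * 5,
        )
        assert ort_score(scaled, groups)[0] == pytest.approx(
            ort_score(matrix, groups)[0], rel=1e-12
        )


class TestGtiGroupScore:
    def test_no_value_above_cutoff(self):
        assert gti_group_score([1, 1, 2], OutlierCutoff(b=5.0)) == 0.0

    def test_hand_example(self):
        assert gti_group_score([1, 1, 1, 1, 9], OutlierCutoff(b=2.0)) == 70.0

    def test_values_equal_cutoff_strict(self):
        assert gti_group_score([2.0, 2.0, 2.0], OutlierCutoff(b=2.0)) == 0.0

    def test_nonpositive_cutoff_undefined(self):
        assert np.isnan(gti_group_score([1, 2, 3], OutlierCutoff(b=0.0)))
        assert np.isnan(gti_group_score([1, 2, 3], OutlierCutoff(b=-1.0)))

    def test_empty_group_raises(self):
        with pytest.raises(UndefinedInputError):
            gti_group_score([], OutlierCutoff(b=1.0))


class TestGtiScore:
    def test_nothing_above_cutoff(self):
        matrix, groups = make_matrix(
            [[1, 2, 3, 4, 1, 2, 3, 4]], [1] * 4 + [2] * 4
        )
        assert gti_score(matrix, groups)[0] == 0.0

    def test_hand_example(self):
        # all 8 values: b = q75 + IQR = 1; disease outlier {9}
        vals = [1, 1, 1, 1, 1, 1, 1, 9]
        assert outlier_cutoff(vals).b == pytest.approx(1.0, abs=1e-12)
        matrix, groups = make_matrix([vals], [1] * 4 + [2] * 4)
        assert gti_score(matrix, groups)[0] == pytest.approx(200.0, rel=1e-12)

    def test_antisymmetry_exact(self, rng):
        for _ in range(20):
            matrix, groups = random_small_matrix(rng)
            s = gti_score(matrix, groups)
            s_swap = gti_score(matrix, groups.swapped())
            np.testing.assert_array_equal(s, -s_swap)

    def test_negative_cutoff_flagged(self):
        matrix, groups = make_matrix(
            [[-5, -4, -3, -2, -5, -4, -3, -2.0]], [1] * 4 + [2] * 4
        )
        assert np.isnan(gti_score(matrix, groups)[0])


class TestOracleEquivalence:
    """Vectorized statistics vs literal per-gene transcriptions."""

    @pytest.mark.parametrize("missing_rate", [0.0, 0.15])
    def test_200_random_matrices(self, missing_rate):
        rng = np.random.default_rng(2024 + int(missing_rate * 100))
        checked = {m: 0 for m in ORACLES}
        for _ in range(200):
            matrix, groups = random_small_matrix(rng, missing_rate=missing_rate)
            scores = {
                "t": t_statistic(matrix, groups),
                "copa": copa_score(matrix, groups, r=90),
                "os": os_score(matrix, groups),
                "ort": ort_score(matrix, groups),
                "gti": gti_score(matrix, groups),
            }
            for gene in range(matrix.n_genes):
                normal, disease = split(matrix, groups, gene)
                for method, oracle in ORACLES.items():
                    if method == "copa":
                        expected = oracle(normal, disease, 90)
                    else:
                        expected = oracle(normal, disease)
                    got = scores[method][gene]
                    if expected is None:
                        assert np.isnan(got), (method, gene)
                    else:
                        assert got == pytest.approx(expected, rel=1e-10), (
                            method,
                            gene,
                        )
                        checked[method] += 1
        assert all(n > 100 for n in checked.values()), checked


class TestInvariants:
    def test_t_antisymmetry_exact(self, rng):
        for _ in range(20):
            matrix, groups = random_small_matrix(rng)
            np.testing.assert_array_equal(
                t_statistic(matrix, groups),
                -t_statistic(matrix, groups.swapped()),
            )

    @pytest.mark.parametrize("c", [0.5, 4.0, 1024.0])
    def test_scale_invariance_power_of_two_exact(self, rng, c):
        from gti.stats_core import _SCORE_FUNCS

        matrix, groups = random_small_matrix(rng)
        scaled, _ = make_matrix(matrix.values * c, groups.labels)
        for name, fn in _SCORE_FUNCS.items():
            np.testing.assert_array_equal(
                fn(matrix, groups), fn(scaled, groups), err_msg=name
            )
        np.testing.assert_array_equal(
            copa_score(matrix, groups), copa_score(scaled, groups)
        )

    def test_scale_invariance_arbitrary_c(self, rng):
        matrix, groups = random_small_matrix(rng)
        c = 2.718281828
        scaled, _ = make_matrix(matrix.values * c, groups.labels)
        for fn in (t_statistic, os_score, ort_score, gti_score):
            np.testing.assert_allclose(
                fn(matrix, groups), fn(scaled, groups), rtol=1e-12
            )

    def test_gti_not_shift_invariant(self):
        vals = [1, 1, 1, 1, 1, 1, 1, 9.0]
        matrix, groups = make_matrix([vals], [1] * 4 + [2] * 4)
        shifted, _ = make_matrix([[v + 10 for v in vals]], [1] * 4 + [2] * 4)
        a = gti_score(matrix, groups)[0]
        b = gti_score(shifted, groups)[0]
        assert a != b  # relative gap changes with the origin

    def test_strict_cutoff_semantics(self):
        # all-sample fence b = 8 equals the max disease value exactly
        vals = [0, 0, 0, 0, 4.0, 4.0, 4.0, 8.0]
        assert outlier_cutoff(vals).b == 8.0
        matrix, groups = make_matrix([vals], [1] * 4 + [2] * 4)
        assert os_score(matrix, groups)[0] == 0.0
        assert gti_score(matrix, groups)[0] == 0.0
        # ORT: normal fence = 4 equals the max disease value
        vals2 = [0, 0, 2, 2.0, 1, 4.0, 1, 1]
        assert outlier_cutoff(vals2[:4]).b == 4.0
        matrix2, groups2 = make_matrix([vals2], [1] * 4 + [2] * 4)
        assert ort_score(matrix2, groups2)[0] == 0.0

    def test_monotone_in_largest_disease_value(self, rng):
        for _ in range(50):
            matrix, groups = random_small_matrix(rng)
            x = matrix.values.copy()
            gene = int(rng.integers(matrix.n_genes))
            d_cols = np.flatnonzero(groups.disease_mask)
            jmax = d_cols[np.argmax(x[gene, d_cols])]
            b = outlier_cutoff(x[gene]).b
            if x[gene, jmax] <= b:
                continue  # need the max already above the fence
            before_os = os_score(matrix, groups)[gene]
            before_gti = gti_score(matrix, groups)[gene]
            x[gene, jmax] += rng.uniform(0.1, 5.0)
            bumped, _ = make_matrix(x, groups.labels)
            # bumping the max leaves q25/q75, median and mad unchanged
            assert outlier_cutoff(x[gene]).b == b
            assert os_score(bumped, groups)[gene] >= before_os
            assert gti_score(bumped, groups)[gene] >= before_gti


class TestScoreTable:
    def test_single_gene_all_methods(self):
        matrix, groups = make_matrix(
            [[1, 2, 3, 4, 5, 1, 2, 3, 4, 20]], [1] * 5 + [2] * 5
        )
        table = score_all(matrix, groups)
        assert len(table.table) == 1
        for m in table.methods:
            assert table.ranks(m).iloc[0] == 1

    def test_columns_match_single_statistics(self, rng):
        matrix, groups = random_small_matrix(rng)
        table = score_all(matrix, groups, copa_r=95)
        np.testing.assert_array_equal(
            table.scores("gti").to_numpy(), gti_score(matrix, groups)
        )
        np.testing.assert_array_equal(
            table.scores("copa").to_numpy(), copa_score(matrix, groups, r=95)
        )
        np.testing.assert_array_equal(
            table.scores("t").to_numpy(), t_statistic(matrix, groups)
        )

    def test_missing_cell_uses_informative_samples_only(self):
        vals = [
            [1, 2, 3, 4, 6, 8],
            [1, 2, 3, 4, 6, 8],
        ]
        matrix, groups = make_matrix(vals, [1, 1, 1, 2, 2, 2])
        matrix.values[1, 0] = np.nan
        matrix.missing[1, 0] = True
        sub, _ = make_matrix([[2, 3, 4, 6, 8]], [1, 1, 2, 2, 2])
        t = t_statistic(matrix, groups)
        assert t[1] == t_statistic(sub, GroupAssignment([1, 1, 2, 2, 2]))[0]
        assert t[0] != t[1]

    def test_ranks_descending_with_deterministic_ties(self):
        matrix, groups = make_matrix(
            [
                [1, 2, 3, 4, 6, 8],
                [5, 5, 5, 5, 5, 5],  # t undefined (sd 0)
                [1, 2, 3, 4, 6, 8],  # tie with gene 0, id later
            ],
            [1, 1, 1, 2, 2, 2],
            gene_ids=["b", "c", "a"],
        )
        table = score_all(matrix, groups, methods=["t"])
        # tie between 'a' and 'b' broken lexicographically; undefined last
        assert table.table.loc["a", "rank_t"] == 1
        assert table.table.loc["b", "rank_t"] == 2
        assert table.table.loc["c", "rank_t"] == 3
        assert "t:" in table.table.loc["c", "flags"]

    def test_no_methods_error(self, rng):
        matrix, groups = random_small_matrix(rng)
        with pytest.raises(ValueError, match="no methods"):
            score_all(matrix, groups, methods=[])
        with pytest.raises(ValueError, match="unknown"):
            score_all(matrix, groups, methods=["sam"])
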