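"""Per-site LOOCV classification and the exact binomial covariation test."""

import numpy as np
import pytest
from scipy.stats import binom, binomtest

from bundlekit.alignment import MSA, GroupAssignment, Selection, builtin_alphabets
from bundlekit.errors import GroupingError, InputError
from bundlekit.fixtures import PlantedMSASpec, make_planted_msa, two_motif_groups
from bundlekit.sites import (
    SiteScoreTable,
    binomial_covariation_test,
    detect_sites,
    marker_opacities,
)

_DNA = builtin_alphabets()["dna"]


class TestDetectSites:
    def test_fig1b_every_column_perfect(self, fig1b, fig1b_groups):
        table = detect_sites(fig1b, fig1b_groups)
        np.testing.assert_array_equal(table.loocv_error, 0.0)
        np.testing.assert_array_equal(table.marker_opacity, 1.0)
        assert table.n_used == 1000

    def test_constant_column_uninformative(self):
        # column 1 constant, column 2 separates the two balanced groups
        m = MSA(
            [f"s{i}" for i in range(8)],
            ["AC"] * 4 + ["AT"] * 4,
            _DNA,
        )
        ga = GroupAssignment(
            ["g1", "g2"], {}, {i: ("g1" if i <= 4 else "g2") for i in range(1, 9)}
        )
        table = detect_sites(m, ga)
        assert table.loocv_error[0] >= 0.5
        assert table.loocv_error[1] == 0.0

    def test_planted_site_is_argmin(self):
        spec = PlantedMSASpec(
            group_sizes={"G1": 10, "G2": 10},
            n_col=15,
            planted_sites=[(7, {"G1": "W", "G2": "C"})],
            seed=11,
        )
        msa, groups, truth = make_planted_msa(spec)
        table = detect_sites(msa, groups)
        assert table.best_column() == truth[0]

    def test_three_group_planted_site(self):
        spec = PlantedMSASpec(
            group_sizes={"G1": 6, "G2": 6, "G3": 6},
            n_col=10,
            planted_sites=[(4, {"G1": "W", "G2": "C", "G3": "H"})],
            seed=3,
        )
        msa, groups, truth = make_planted_msa(spec)
        table = detect_sites(msa, groups)
        assert table.best_column() == truth[0]
        assert table.loocv_error[truth[0] - 1] == 0.0

    def test_row_order_and_label_invariance(self):
        spec = PlantedMSASpec(
            group_sizes={"G1": 5, "G2": 5}, n_col=8,
            planted_sites=[(2, {"G1": "W", "G2": "C"})], seed=9,
        )
        msa, groups, _ = make_planted_msa(spec)
        table = detect_sites(msa, groups)
        perm = list(reversed(range(msa.n_seq)))
        shuffled = MSA(
            [msa.labels[p] for p in perm], [msa.rows[p] for p in perm], msa.alphabet
        )
        inv = {p: i for i, p in enumerate(perm)}
        remapped = GroupAssignment(
            ["renamedB", "renamedA"],
            {},
            {inv[i - 1] + 1: {"G1": "renamedB", "G2": "renamedA"}[g]
             for i, g in groups.membership.items()},
        )
        table2 = detect_sites(shuffled, remapped)
        np.testing.assert_allclose(table2.loocv_error, table.loocv_error)

    def test_single_group_rejected(self, fig1b):
        ga = GroupAssignment(["g"], {}, {1: "g", 2: "g"})
        with pytest.raises(GroupingError):
            detect_sites(fig1b, ga)

    def test_tiny_group_rejected(self, fig1b):
        ga = GroupAssignment(["g1", "g2"], {}, {1: "g1", 2: "g1", 3: "g2"})
        with pytest.raises(GroupingError):
            detect_sites(fig1b, ga)

    def test_ungrouped_sequences_do_not_participate(self, fig1b, fig1b_groups):
        partial = GroupAssignment(
            ["motifA", "motifB"], {},
            {i: fig1b_groups.membership[i] for i in list(range(1, 11)) + list(range(501, 511))},
        )
        table = detect_sites(fig1b, partial)
        assert table.n_used == 20
        np.testing.assert_array_equal(table.loocv_error, 0.0)


class TestMarkerOpacities:
    @pytest.mark.parametrize(
        "loocv,baseline,expected",
        [(0.0, 0.5, 1.0), (0.5, 0.5, 0.0), (0.25, 0.5, 0.5), (0.9, 0.5, 0.0)],
    )
    def test_clamped_linear_map(self, loocv, baseline, expected):
        table = SiteScoreTable(
            columns=np.array([1]),
            loocv_error=np.array([loocv]),
            baseline_error=baseline,
            marker_opacity=np.array([0.0]),
            n_used=10,
        )
        assert marker_opacities(table)[0] == pytest.approx(expected)

    def test_zero_baseline_gives_zero(self):
        table = SiteScoreTable(
            columns=np.array([1]),
            loocv_error=np.array([0.0]),
            baseline_error=0.0,
            marker_opacity=np.array([0.0]),
            n_used=10,
        )
        assert marker_opacities(table)[0] == 0.0


def _enumeration_oracle(k, n, p):
    """Exhaustive enumeration over all n+1 outcomes via the binomial pmf."""
    pmf = [binom.pmf(i, n, p) for i in range(n + 1)]
    less = sum(pmf[: k + 1])
    greater = sum(pmf[k:])
    two = sum(q for q in pmf if q <= pmf[k] * (1 + 1e-7))
    return less, greater, min(1.0, two)


class TestBinomialTest:
    def _msa_with_freq(self, n_total, n_t, n_cond, k_cond):
        """MSA where column 2 has n_t T's overall, and the first n_cond
        sequences (all with A at column 1) have k_cond T's at column 2."""
        rows = []
        for i in range(n_total):
            c1 = "A" if i < n_cond else "C"
            if i < n_cond:
                c2 = "T" if i < k_cond else "G"
            else:
                c2 = "T" if i < n_cond + (n_t - k_cond) else "G"
            rows.append(c1 + c2)
        return MSA([f"s{i}" for i in range(n_total)], rows, _DNA)

    def test_closed_form_all_misses(self):
        # k=0 of n=10 at p=0.5: lower tail = 0.5^10
        msa = self._msa_with_freq(20, 10, 10, 0)
        sel = Selection(seq_indices=frozenset(range(1, 11)))
        res = binomial_covariation_test(msa, sel, 2, "T")
        assert res.null_p == 0.5
        assert res.p_value_one_sided_less == pytest.approx(0.5 ** 10)

    def test_expected_count_two_sided_one(self):
        msa = self._msa_with_freq(20, 10, 10, 5)
        sel = Selection(seq_indices=frozenset(range(1, 11)))
        res = binomial_covariation_test(msa, sel, 2, "T")
        assert res.n_success == 5
        assert res.p_value_two_sided == pytest.approx(1.0)

    def test_one_sided_pair_identity(self):
        msa = self._msa_with_freq(20, 8, 10, 3)
        sel = Selection(seq_indices=frozenset(range(1, 11)))
        res = binomial_covariation_test(msa, sel, 2, "T")
        point = binom.pmf(res.n_success, res.n_trials, res.null_p)
        assert (
            res.p_value_one_sided_less + res.p_value_one_sided_greater
            == pytest.approx(1.0 + point)
        )

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_matches_enumeration_and_scipy(self, p):
        for n in range(1, 13):
            for k in range(n + 1):
                less, greater, two = _enumeration_oracle(k, n, p)
                sp = binomtest(k, n, p)
                from bundlekit.sites import _minlike_two_sided

                assert _minlike_two_sided(k, n, p) == pytest.approx(two, abs=1e-12)
                assert _minlike_two_sided(k, n, p) == pytest.approx(
                    sp.pvalue, rel=1e-9
                )
                assert binom.cdf(k, n, p) == pytest.approx(less, abs=1e-12)

    def test_complement_null(self):
        msa = self._msa_with_freq(20, 10, 10, 2)
        sel = Selection(seq_indices=frozenset(range(1, 11)))
        res = binomial_covariation_test(msa, sel, 2, "T", null_from="complement")
        assert res.null_p == 0.8  # 8 of the 10 unselected have T
        assert res.n_success == 2

    def test_degenerate_null_flagged(self):
        m = MSA(["a", "b", "c"], ["AT", "CG", "CG"], _DNA)
        sel = Selection(seq_indices=frozenset({1}))
        res = binomial_covariation_test(m, sel, 2, "T", null_from="complement")
        assert res.null_p == 0.0
        assert res.degenerate_null
        assert 0 <= res.p_value_two_sided <= 1

    def test_empty_condition_rejected(self, fig1b):
        with pytest.raises(InputError):
            binomial_covariation_test(fig1b, Selection(), 1, "A")

    def test_central_convention(self):
        msa = self._msa_with_freq(20, 8, 10, 3)
        sel = Selection(seq_indices=frozenset(range(1, 11)))
        res = binomial_covariation_test(msa, sel, 2, "T", two_sided="central")
        expected = min(
            1.0,
            2 * min(res.p_value_one_sided_less, res.p_value_one_sided_greater),
        )
        assert res.p_value_two_sided == pytest.approx(expected)
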