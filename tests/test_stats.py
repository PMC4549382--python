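import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import orseg as o
from orseg.dwi import ScalarMap, Tractogram
from orseg.exceptions import (DegenerateFitError, IncompleteDesignError,
                              InvalidArgumentError)
from orseg.stats import (bonferroni, paired_t, rm_anova, segment_mean_scalars,
                         visitation_map)


def _line_tractogram(n_points=50, y0=0.25):
    """One straight streamline along x through a row of voxels."""
    x = np.linspace(0.25, 9.75, n_points)
    s = np.column_stack([x, np.full_like(x, y0), np.full_like(x, 0.5)])
    return Tractogram([s], np.eye(4))


class TestVisitationMap:
    def test_straight_line_support(self):
        vm = visitation_map(_line_tractogram(), (10, 3, 3))
        assert vm.support.sum() == 10
        assert np.all(vm.counts[vm.support] == 1)

    def test_duplicate_streamline_doubles_counts(self):
        t = _line_tractogram()
        t2 = Tractogram(t.streamlines * 2, t.affine)
        vm1 = visitation_map(t, (10, 3, 3))
        vm2 = visitation_map(t2, (10, 3, 3))
        assert np.array_equal(vm1.support, vm2.support)
        assert np.array_equal(vm2.counts, 2 * vm1.counts)

    def test_empty_segment(self):
        vm = visitation_map(Tractogram([], np.eye(4)), (4, 4, 4))
        assert not vm.support.any()

    def test_support_invariant_to_densification(self):
        a = visitation_map(_line_tractogram(50), (10, 3, 3))
        b = visitation_map(_line_tractogram(200), (10, 3, 3))
        assert np.array_equal(a.support, b.support)


class TestSegmentScalars:
    def test_uniform_mean(self):
        vm = visitation_map(_line_tractogram(), (10, 3, 3))
        fa = ScalarMap(np.full((10, 3, 3), 0.5), np.eye(4))
        md = ScalarMap(np.full((10, 3, 3), 7e-4), np.eye(4))
        assert segment_mean_scalars(vm, fa, md) == (0.5, pytest.approx(7e-4))

    def test_two_value_mean(self):
        counts = np.zeros((4, 1, 1), dtype=int)
        counts[[0, 1], 0, 0] = 1
        vm = o.VisitationMap(counts, np.eye(4))
        data = np.zeros((4, 1, 1))
        data[0], data[1] = 0.2, 0.8
        m = ScalarMap(data, np.eye(4))
        assert segment_mean_scalars(vm, m, m)[0] == pytest.approx(0.5)

    def test_empty_support_rejected(self):
        vm = o.VisitationMap(np.zeros((2, 2, 2), dtype=int), np.eye(4))
        m = ScalarMap(np.zeros((2, 2, 2)), np.eye(4))
        with pytest.raises(InvalidArgumentError):
            segment_mean_scalars(vm, m, m)


class TestPairedT:
    def test_identical_samples(self):
        t, df, p = paired_t(np.arange(5.0), np.arange(5.0))
        assert (t, df, p) == (0.0, 4, 1.0)

    def test_closed_form(self):
        """Differences (1,2,3): t = mean / (sd/sqrt(3))."""
        a = np.array([2.0, 4.0, 6.0])
        b = np.array([1.0, 2.0, 3.0])
        d = a - b
        expect = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        t, df, _ = paired_t(a, b)
        assert t == pytest.approx(expect)
        assert df == 2

    def test_matches_scipy(self):
        from scipy import stats as sps
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1, 12)
        t, df, p = paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=6), rng.normal(size=6)
        t1, _, p1 = paired_t(a, b)
        t2, _, p2 = paired_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate(self):
        with pytest.raises(DegenerateFitError):
            paired_t(np.array([2.0, 3.0]), np.array([1.0, 2.0]))


class TestBonferroni:
    def test_examples(self):
        assert bonferroni(np.array([0.01]), 4)[0] == pytest.approx(0.04)
        assert bonferroni(np.array([0.5]), 4)[0] == 1.0
        assert np.array_equal(bonferroni(np.array([0.3, 0.9]), 1),
                              [0.3, 0.9])

    @given(st.floats(0.0, 1.0), st.integers(1, 50))
    def test_bounds(self, p, m):
        out = bonferroni(np.array([p]), m)[0]
        assert p <= out <= 1.0


def _make_table(Y, subjects, la, lb):
    rows = []
    for i, s in enumerate(subjects):
        for j, a in enumerate(la):
            for k, b in enumerate(lb):
                rows.append({"subject": s, "segment": a, "hemisphere": b,
                             "dv": Y[i, j, k]})
    return pd.DataFrame(rows)


def _brute_force_ss(Y):
    """Sums of squares by explicit loops over the 3-factor layout."""
    n, a, b = Y.shape
    gm = Y.mean()
    ss = dict(subject=0.0, A=0.0, B=0.0, AB=0.0, AS=0.0, BS=0.0, total=0.0)
    ss["subject"] = sum(a * b * (Y[i].mean() - gm) ** 2 for i in range(n))
    ss["A"] = sum(n * b * (Y[:, j].mean() - gm) ** 2 for j in range(a))
    ss["B"] = sum(n * a * (Y[:, :, k].mean() - gm) ** 2 for k in range(b))
    for j in range(a):
        for k in range(b):
            ss["AB"] += n * (Y[:, j, k].mean() - Y[:, j].mean()
                             - Y[:, :, k].mean() + gm) ** 2
    for i in range(n):
        for j in range(a):
            ss["AS"] += b * (Y[i, j].mean() - Y[:, j].mean()
                             - Y[i].mean() + gm) ** 2
        for k in range(b):
            ss["BS"] += a * (Y[i, :, k].mean() - Y[:, :, k].mean()
                             - Y[i].mean() + gm) ** 2
    ss["total"] = ((Y - gm) ** 2).sum()
    return ss


class TestRMAnova:
    def test_hand_worked_partition(self):
        """3 subjects x 2 x 2: SS partition matches explicit loops to 1e-9."""
        Y = np.array([[[4.0, 6.0], [5.0, 9.0]],
                      [[3.0, 5.0], [4.0, 8.0]],
                      [[5.0, 8.0], [6.0, 11.0]]])
        tab = _make_table(Y, [0, 1, 2], ["s1", "s2"], ["L", "R"])
        res = rm_anova(tab, "dv")
        ss = _brute_force_ss(Y)
        bya = res.set_index("effect")
        assert bya.loc["segment", "ss"] == pytest.approx(ss["A"], abs=1e-9)
        assert bya.loc["hemisphere", "ss"] == pytest.approx(ss["B"], abs=1e-9)
        assert bya.loc["segment:hemisphere", "ss"] == pytest.approx(
            ss["AB"], abs=1e-9)
        assert bya.loc["segment", "ss_error"] == pytest.approx(
            ss["AS"], abs=1e-9)
        assert res.attrs["ss_subject"] == pytest.approx(ss["subject"],
                                                        abs=1e-9)

    def test_ss_decomposition_identity(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(0, 1, (8, 3, 2))
        tab = _make_table(Y, range(8), ["V1", "V2", "V3"], ["L", "R"])
        res = rm_anova(tab, "dv")
        parts = (res.attrs["ss_subject"] + res["ss"].sum()
                 + res["ss_error"].sum())
        assert parts == pytest.approx(res.attrs["ss_total"], rel=1e-9)

    def test_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM
        rng = np.random.default_rng(6)
        Y = rng.normal(0, 1, (10, 3, 2)) + np.array([0.5, 0.0, -0.5])[:, None]
        tab = _make_table(Y, range(10), ["V1", "V2", "V3"], ["L", "R"])
        res = rm_anova(tab, "dv").set_index("effect")
        ref = AnovaRM(tab, "dv", "subject",
                      within=["segment", "hemisphere"]).fit().anova_table
        assert res.loc["segment", "F"] == pytest.approx(
            ref.loc["segment", "F Value"])
        assert res.loc["hemisphere", "p"] == pytest.approx(
            ref.loc["hemisphere", "Pr > F"])
        assert res.loc["segment:hemisphere", "F"] == pytest.approx(
            ref.loc["segment:hemisphere", "F Value"])

    def test_constant_dv_gives_zero_f(self):
        Y = np.full((4, 2, 2), 3.0)
        tab = _make_table(Y, range(4), ["a", "b"], ["L", "R"])
        res = rm_anova(tab, "dv")
        assert (res["F"] == 0.0).all()

    def test_missing_cell_rejected(self):
        Y = np.zeros((3, 2, 2))
        tab = _make_table(Y, range(3), ["a", "b"], ["L", "R"]).iloc[:-1]
        with pytest.raises(IncompleteDesignError):
            rm_anova(tab, "dv")

    def test_null_factor_type_one_error_calibrated(self):
        """Planted factor-A effect, null factor B: B rejects at ~5%."""
        rng = np.random.default_rng(12)
        n_rej = 0
        n_sim = 500
        for _ in range(n_sim):
            Y = rng.normal(0, 1, (10, 3, 2))
            Y += np.array([1.0, 0.0, -1.0])[None, :, None]   # A effect only
            tab = _make_table(Y, range(10), ["V1", "V2", "V3"], ["L", "R"])
            res = rm_anova(tab, "dv").set_index("effect")
            if res.loc["hemisphere", "p"] < 0.05:
                n_rej += 1
        assert 0.02 <= n_rej / n_sim <= 0.08
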