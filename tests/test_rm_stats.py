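"""Repeated-measures ANOVA engine, sphericity, decomposition, comparisons."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitlat as gl
from gaitlat.errors import ValidationError
from gaitlat.rm_stats import (WithinAnova, _orthonormal_contrasts, bh_adjust,
                              significance_glyph)
from tests.conftest import brute_force_rm_anova_2way, brute_force_rm_anova_3way

FACTORS_2 = {"sw": ("NB", "WB"), "sp": ("Normal", "Slow")}
FACTORS_3 = {"sw": ("NB", "WB"), "sp": ("Normal", "Slow"),
             "segment": ("head", "T4", "pelvis")}


class TestEngineAgainstBruteForce:
    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_two_way_matches_oracle(self, n):
        rng = np.random.default_rng(n)
        y = rng.normal(0, 1, (n, 2, 2))
        wa = WithinAnova(y, FACTORS_2)
        oracle = brute_force_rm_anova_2way(y)
        for source, key in (("sw", "A"), ("sp", "B"), ("sw x sp", "AB")):
            row = wa.omnibus().set_index("source").loc[source]
            ss, ss_err = oracle[key]
            assert row.ss == pytest.approx(ss, rel=1e-10)
            assert row.ss_error == pytest.approx(ss_err, rel=1e-10)

    @pytest.mark.parametrize("n", [3, 5])
    def test_three_way_matches_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        y = rng.normal(0, 1, (n, 2, 2, 3))
        wa = WithinAnova(y, FACTORS_3)
        oracle = brute_force_rm_anova_3way(y)
        keymap = {"sw": "A", "sp": "B", "segment": "C", "sw x sp": "AB",
                  "sw x segment": "AC", "sp x segment": "BC",
                  "sw x sp x segment": "ABC"}
        tab = wa.omnibus().set_index("source")
        for source, key in keymap.items():
            ss, ss_err = oracle[key]
            assert tab.loc[source].ss == pytest.approx(ss, rel=1e-10, abs=1e-12)
            assert tab.loc[source].ss_error == pytest.approx(ss_err, rel=1e-10)

    def test_pure_main_effect_shift_closed_form(self):
        rng = np.random.default_rng(1)
        n = 6
        base = rng.normal(0, 1, (n, 1, 2, 3))
        y = np.tile(base, (1, 2, 1, 1))
        delta = 1.7
        y[:, 1] += delta  # add delta to every WB cell
        wa = WithinAnova(y, FACTORS_3)
        tab = wa.omnibus().set_index("source")
        # balanced shift: SS = N * (levels of other factors) * delta^2 / 2
        assert tab.loc["sw"].ss == pytest.approx(n * 6 * delta ** 2 / 2, rel=1e-9)
        for source in ("sw x sp", "sw x segment", "sw x sp x segment"):
            assert tab.loc[source].ss == pytest.approx(0.0, abs=1e-18)

    def test_ss_decomposition_closure(self):
        rng = np.random.default_rng(17)
        y = rng.normal(0, 3, (8, 2, 2, 3))
        wa = WithinAnova(y, FACTORS_3)
        tab = wa.omnibus()
        ss_subject = 12 * np.sum((y.mean(axis=(1, 2, 3)) - y.mean()) ** 2)
        total = np.sum((y - y.mean()) ** 2)
        closure = tab.ss.sum() + tab.ss_error.sum() + ss_subject
        assert closure == pytest.approx(total, rel=1e-10)

    def test_constant_response_degenerate(self):
        y = np.full((5, 2, 2), 4.2)
        tab = WithinAnova(y, FACTORS_2).omnibus()
        assert (tab.ss == 0).all()
        assert (tab.F == 0).all()
        assert (tab.p == 1).all()

    def test_invariance_to_relabeling_and_subject_offsets(self):
        rng = np.random.default_rng(23)
        y = rng.normal(0, 1, (7, 2, 2, 3))
        tab = WithinAnova(y, FACTORS_3).omnibus()
        perm = rng.permutation(7)
        offsets = rng.normal(0, 10, 7)[:, None, None, None]
        tab2 = WithinAnova(y[perm] + offsets[perm], FACTORS_3).omnibus()
        np.testing.assert_allclose(tab.F, tab2.F, rtol=1e-9)


class TestSphericity:
    @staticmethod
    def one_way(y):
        return WithinAnova(y, {"bs": tuple("abc"[:y.shape[1]])})

    def test_matches_pingouin(self):
        rng = np.random.default_rng(42)
        y = rng.normal(0, 1, (12, 3)) * np.array([1.0, 1.5, 0.7])
        tab = self.one_way(y).omnibus().iloc[0]
        df = pd.DataFrame({"y": y.ravel(), "bs": np.tile(list("abc"), 12),
                           "s": np.repeat(np.arange(12), 3)})
        sph = pg.sphericity(df, dv="y", within="bs", subject="s")
        eps = pg.epsilon(df, dv="y", within="bs", subject="s", correction="gg")
        anova = pg.rm_anova(df, dv="y", within="bs", subject="s",
                            correction=True, detailed=True).iloc[0]
        assert tab.mauchly_w == pytest.approx(sph.W, rel=1e-9)
        assert tab.mauchly_chi2 == pytest.approx(sph.chi2, rel=1e-9)
        assert tab.mauchly_p == pytest.approx(sph.pval, rel=1e-9)
        assert tab.gg_epsilon == pytest.approx(float(eps), rel=1e-9)
        assert tab.F == pytest.approx(anova["F"], rel=1e-9)
        assert tab.gg_p == pytest.approx(anova["p_GG_corr"], rel=1e-9)

    def test_two_level_factor_not_applicable(self):
        rng = np.random.default_rng(0)
        tab = WithinAnova(rng.normal(0, 1, (6, 2)),
                          {"sw": ("NB", "WB")}).omnibus().iloc[0]
        assert np.isnan(tab.mauchly_w) and np.isnan(tab.gg_epsilon)

    def test_epsilon_bounds(self):
        # perfect sphericity: identity contrast covariance
        assert gl.gg_epsilon(np.eye(2)) == 1.0
        # rank-1 covariance: epsilon at its 1/k floor
        v = np.array([[1.0], [2.0]])
        assert gl.gg_epsilon(v @ v.T) == pytest.approx(0.5)

    def test_contrast_basis_invariance(self):
        # Mauchly W and epsilon must not depend on the orthonormal basis
        rng = np.random.default_rng(8)
        y = rng.normal(0, 1, (10, 3)) * np.array([1.0, 2.0, 0.5])
        C1 = _orthonormal_contrasts(3)
        q, _ = np.linalg.qr(rng.normal(0, 1, (2, 2)))
        C2 = q @ C1
        for C in (C1, C2):
            S = np.cov(y @ C.T, rowvar=False, ddof=1)
            W, _, _, _ = gl.mauchly_test(S, 10)
            assert W == pytest.approx(gl.mauchly_test(
                np.cov(y @ C1.T, rowvar=False, ddof=1), 10)[0], rel=1e-9)
            assert gl.gg_epsilon(S) == pytest.approx(
                gl.gg_epsilon(np.cov(y @ C1.T, rowvar=False, ddof=1)), rel=1e-9)

    def test_directional_w_below_one(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, (20, 3))
        y[:, 0] += rng.normal(0, 4, 20)  # one dominant contrast variance
        tab = self.one_way(y).omnibus().iloc[0]
        assert tab.mauchly_w < 1.0


class TestEffectSizeAndPower:
    def test_partial_eta_hand_values(self):
        assert gl.partial_eta_squared(3.0, 3.0) == 0.5
        assert gl.partial_eta_squared(0.0, 5.0) == 0.0
        assert np.isnan(gl.partial_eta_squared(0.0, 0.0))

    def test_one_df_identity_f_over_f_plus_df2(self):
        # eta_p^2 for a 1-df effect equals F/(F + df2)
        F, df2 = 444.89, 16
        assert F / (F + df2) == pytest.approx(0.9653, abs=1e-4)
        rng = np.random.default_rng(6)
        y = rng.normal(0, 1, (9, 2))
        y[:, 1] += 1.0
        row = WithinAnova(y, {"sw": ("NB", "WB")}).omnibus().iloc[0]
        assert row.partial_eta_sq == pytest.approx(row.F / (row.F + row.df2),
                                                   rel=1e-9)

    def test_power_limits_and_monotonicity(self):
        assert gl.observed_power(0.0, 1, 16) == pytest.approx(0.05, abs=1e-9)
        assert gl.observed_power(200.0, 1, 16) > 0.999999
        powers = [gl.observed_power(F, 2, 32) for F in (1, 3, 6, 12)]
        assert powers == sorted(powers)


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_monotone_and_never_decreases(self, ps):
        adj = bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()
        # the largest raw p is unchanged
        assert adj[np.argmax(ps)] == pytest.approx(max(ps))


class TestPairedComparisons:
    def test_identical_vectors(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        rows = gl.paired_comparisons({("x", "y"): (a, a.copy())})
        row = rows[0]
        assert row["t"] == 0.0 and row["cohens_d"] == 0.0
        assert row["p_adj"] == 1.0

    def test_mean_difference_equal_to_average_sd_gives_unit_d(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 2, 200)
        b = a - 0.5 * (a.std(ddof=1) + a.std(ddof=1))  # shift by the avg SD
        row = gl.paired_comparisons({("a", "b"): (a, b)})[0]
        assert row["cohens_d"] == pytest.approx(1.0, rel=1e-9)

    def test_dz_variant_uses_difference_sd(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 30)
        b = a + rng.normal(0.5, 0.3, 30)
        row_av = gl.paired_comparisons({("a", "b"): (a, b)})[0]
        row_z = gl.paired_comparisons({("a", "b"): (a, b)}, d_variant="z")[0]
        diff = a - b
        assert row_z["cohens_d"] == pytest.approx(diff.mean() /
                                                  diff.std(ddof=1), rel=1e-9)
        assert row_av["cohens_d"] != row_z["cohens_d"]


class TestDecomposition:
    @staticmethod
    def structured_cube(n=17, seed=5, three_way=2.0):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 1, (n, 2, 2, 3))
        y += rng.normal(0, 1.0, (n, 1, 1, 1))           # subject effect
        y[:, 1] += 3.0                                  # sw main effect
        y[:, :, 1] += 2.0                               # sp main effect
        y[:, 1, 1, 2] += three_way                      # breaks additivity
        return y

    def test_simple_interaction_strata_ss_sum_identity(self):
        wa = WithinAnova(self.structured_cube(), FACTORS_3)
        tab = wa.omnibus().set_index("source")
        total = sum(wa.simple_effect_ss(("sw", "sp"), {"segment": s})
                    for s in FACTORS_3["segment"])
        assert total == pytest.approx(tab.loc["sw x sp"].ss
                                      + tab.loc["sw x sp x segment"].ss,
                                      rel=1e-9)

    def test_simple_simple_ss_sum_identity(self):
        wa = WithinAnova(self.structured_cube(), FACTORS_3)
        tab = wa.omnibus().set_index("source")
        total = sum(wa.simple_effect_ss(("sw",), {"sp": sp, "segment": s})
                    for sp in FACTORS_3["sp"] for s in FACTORS_3["segment"])
        expected = (tab.loc["sw"].ss + tab.loc["sw x sp"].ss
                    + tab.loc["sw x segment"].ss
                    + tab.loc["sw x sp x segment"].ss)
        assert total == pytest.approx(expected, rel=1e-9)

    def test_simple_simple_df_match_design(self):
        # N=17: 2-level effects carry error df 16, the 3-level segment
        # effect 32, with one shared MSE per effect across strata
        wa = WithinAnova(self.structured_cube(), FACTORS_3)
        report = gl.decompose_interactions(wa)
        ss = report.simple_simple
        assert len(ss)
        seg_rows = ss[ss.source.str.startswith("segment")]
        assert (seg_rows.df1 == 2).all() and (seg_rows.df2 == 32).all()
        assert seg_rows.mse.nunique() == 1
        sw_rows = ss[ss.source.str.startswith("sw")]
        assert (sw_rows.df2 == 16).all() and sw_rows.mse.nunique() == 1

    def test_simple_effects_use_omnibus_error_terms(self):
        wa = WithinAnova(self.structured_cube(), FACTORS_3)
        omni = wa.omnibus().set_index("source")
        report = gl.decompose_interactions(wa)
        si = report.simple_interactions.set_index("source")
        assert si.loc["sw x sp at head"].mse == pytest.approx(
            omni.loc["sw x sp"].mse)
        ss = report.simple_simple.set_index("source")
        any_sw = next(s for s in ss.index if s.startswith("sw at"))
        assert ss.loc[any_sw].mse == pytest.approx(omni.loc["sw"].mse)

    def test_nonsignificant_omnibus_yields_empty_tiers_with_trace(self):
        rng = np.random.default_rng(77)
        y = rng.normal(0, 1, (10, 2, 2, 3))  # pure noise
        wa = WithinAnova(y, FACTORS_3)
        report = gl.decompose_interactions(wa)
        if report.omnibus.set_index("source").loc[
                "sw x sp x segment"].p_used >= 0.05:
            assert report.simple_interactions.empty
            assert report.pairwise.empty
            assert any("not significant" in t for t in report.trace)

    def test_constructed_effect_localised(self):
        # non-additivity only in sp x segment at NB
        rng = np.random.default_rng(31)
        y = rng.normal(0, 0.6, (17, 2, 2, 3))
        y[:, 0, 1, 2] += 2.0
        wa = WithinAnova(y, FACTORS_3)
        report = gl.decompose_interactions(wa)
        si = report.simple_interactions.set_index("source")
        assert si.loc["sp x segment at NB"].p_adj < 0.05

    def test_pairwise_triggered_by_segment_effect(self):
        y = self.structured_cube(three_way=0.0)
        y[:, :, :, 1] += 2.5  # strong segment separation everywhere
        y[:, 1, 1, 2] += 2.0  # and a three-way trigger
        wa = WithinAnova(y, FACTORS_3)
        report = gl.decompose_interactions(wa)
        if len(report.pairwise):
            assert set(report.pairwise.pair) <= {
                "head vs T4", "head vs pelvis", "T4 vs pelvis"}
            # BH within each condition's family of three
            for _, grp in report.pairwise.groupby("condition"):
                assert len(grp) == 3
                assert grp.p_adj.max() == pytest.approx(grp.p.max())

    def test_two_way_simple_main_effects(self):
        rng = np.random.default_rng(55)
        y = rng.normal(0, 0.5, (17, 2, 2))
        y[:, 1, 1] += 2.0  # interaction + main effects
        wa = WithinAnova(y, FACTORS_2)
        report = gl.decompose_two_way(wa)
        assert len(report.simple_interactions) == 4
        omni = report.omnibus.set_index("source")
        si = report.simple_interactions.set_index("source")
        assert si.loc["sw at Slow"].mse == pytest.approx(omni.loc["sw"].mse)
        assert si.loc["sw at Slow"].df2 == 16


class TestFromTable:
    def test_incomplete_design_rejected(self):
        rows = [{"participant": p, "sw": sw, "sp": sp, "value": 1.0}
                for p in "AB" for sw in ("NB", "WB") for sp in ("Normal", "Slow")]
        df = pd.DataFrame(rows[:-1])
        with pytest.raises(ValidationError, match="incomplete"):
            WithinAnova.from_table(df, within=["sw", "sp"])

    def test_table_and_cube_agree(self):
        rng = np.random.default_rng(10)
        y = rng.normal(0, 1, (5, 2, 2))
        rows = []
        for s in range(5):
            for i, sw in enumerate(FACTORS_2["sw"]):
                for j, sp in enumerate(FACTORS_2["sp"]):
                    rows.append({"participant": f"P{s}", "sw": sw, "sp": sp,
                                 "value": y[s, i, j]})
        wa = WithinAnova.from_table(pd.DataFrame(rows), within=["sw", "sp"],
                                    levels=FACTORS_2)
        np.testing.assert_allclose(wa.omnibus().F,
                                   WithinAnova(y, FACTORS_2).omnibus().F)


def test_glyphs():
    assert [significance_glyph(p) for p in (0.0005, 0.005, 0.03, 0.07, 0.5)] == \
        ["***", "**", "*", "#", "ns"]
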