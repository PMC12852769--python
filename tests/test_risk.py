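"""Deterministic exposure/risk equations and compliance screening."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from metalrisk import (
    ConcentrationRecord,
    GroupKey,
    aggregate_hi,
    classify_risk,
    compute_edi,
    compute_hq,
    compute_ilcr,
    pool_groups,
    screen_mrl,
    tissue_risk,
)
from metalrisk.risk import RiskUndefinedError, band_order, risk_table

IR_MEAT = 3.14 / 365  # kg/day


class TestEdi:
    def test_zero_concentration(self, params):
        assert compute_edi(0.0, IR_MEAT, 70) == 0.0

    def test_fe_muscle_pooled_mean(self):
        # hand arithmetic: 3.14/365 * 114.875 / 70
        assert compute_edi(114.875, IR_MEAT, 70) == pytest.approx(
            0.0141177, abs=5e-8)

    def test_pb_muscle_pooled_under_nd_zero(self):
        assert compute_edi(0.16, IR_MEAT, 70) == pytest.approx(1.96633e-5, rel=1e-4)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            compute_edi(-0.1, IR_MEAT, 70)


class TestHq:
    def test_fe_muscle_reproduces_published_mean(self, params, tox):
        c = (112.7 + 113.3 + 118.2 + 115.3) / 4
        hq = compute_hq(c, params, params.ir_muscle, tox["Fe"].rfd)
        assert round(hq, 4) == 0.0202

    def test_zero_concentration(self, params):
        assert compute_hq(0.0, params, IR_MEAT, 0.7) == 0.0

    def test_linearity(self, params):
        base = compute_hq(1.3, params, IR_MEAT, 0.02)
        assert compute_hq(2.6, params, IR_MEAT, 0.02) == pytest.approx(2 * base)

    def test_missing_rfd_signals_undefined(self, params):
        with pytest.raises(RiskUndefinedError):
            compute_hq(1.0, params, IR_MEAT, None)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c=st.floats(min_value=0, max_value=1e4),
           rfd=st.sampled_from([0.001, 0.02, 0.04, 0.7, 0.3]))
    def test_reduces_to_edi_over_rfd_under_defaults(self, params, c, rfd):
        # EF*ED == AT exactly, so the general formula collapses
        hq = compute_hq(c, params, params.ir_muscle, rfd)
        assert hq == compute_edi(c, params.ir_muscle, params.bw) / rfd


class TestIlcr:
    def test_zero_edi(self):
        assert compute_ilcr(0.0, 0.84) == 0.0

    def test_pb_muscle_deterministic(self):
        assert compute_ilcr(1.96633e-5, 0.0085) == pytest.approx(1.6714e-7, rel=1e-4)

    def test_ni_muscle_via_edi(self):
        edi = compute_edi(0.9075, IR_MEAT, 70)
        assert compute_ilcr(edi, 0.84) == pytest.approx(9.37e-5, rel=1e-3)

    def test_missing_csf_signals_undefined(self):
        with pytest.raises(RiskUndefinedError):
            compute_ilcr(1e-5, None)


class TestHiAggregation:
    MUSCLE_HQS = [0.009, 0.015, 0.070, 0.02261, 0.0018, 0.0330, 0.051]

    def test_published_muscle_column_sums_to_hi(self):
        assert aggregate_hi(self.MUSCLE_HQS) == pytest.approx(0.20241)
        assert round(aggregate_hi(self.MUSCLE_HQS), 2) == 0.20

    def test_empty_is_zero_and_none_skipped(self):
        assert aggregate_hi([]) == 0.0
        assert aggregate_hi([0.1, None, 0.2]) == pytest.approx(0.3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.permutations(MUSCLE_HQS))
    def test_permutation_invariant(self, perm):
        assert aggregate_hi(perm) == pytest.approx(
            aggregate_hi(self.MUSCLE_HQS), rel=0, abs=1e-15)


class TestRiskBands:
    @pytest.mark.parametrize("ilcr,band", [
        (0.0, "negligible"),
        (1.93e-7, "negligible"),
        (1e-6, "acceptable"),       # boundary in the closed middle band
        (2.5e-5, "acceptable"),
        (1e-4, "acceptable"),       # boundary in the closed middle band
        (2e-4, "unacceptable"),
    ])
    def test_band_assignment(self, ilcr, band):
        assert classify_risk(ilcr) == band

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=st.floats(min_value=0, max_value=1e-2),
           b=st.floats(min_value=0, max_value=1e-2))
    def test_monotone(self, a, b):
        lo, hi = min(a, b), max(a, b)
        assert band_order(classify_risk(lo)) <= band_order(classify_risk(hi))


class TestMrlScreening:
    def _rec(self, el, tissue, value, censored=False, lod=None):
        return ConcentrationRecord(
            group=GroupKey("goat", "female", tissue), element=el,
            value=None if censored else value, censored=censored, lod=lod)

    def test_ni_muscle_exceeds_who_limit(self, tox):
        assert screen_mrl(self._rec("Ni", "muscle", 1.2), tox["Ni"]) == "exceeds"

    def test_cd_liver_compliant(self, tox):
        assert screen_mrl(self._rec("Cd", "liver", 0.15), tox["Cd"]) == "compliant"

    def test_co_has_no_limit(self, tox):
        assert screen_mrl(self._rec("Co", "liver", 0.31), tox["Co"]) == "no_limit"

    def test_equality_complies(self, tox):
        assert screen_mrl(self._rec("Ni", "muscle", 0.5), tox["Ni"]) == "compliant"

    def test_all_fixture_ni_cells_exceed(self, study_records, tox):
        ni = [r for r in study_records if r.element == "Ni"]
        assert len(ni) == 8
        assert all(screen_mrl(r, tox["Ni"]) == "exceeds" for r in ni)

    def test_agrees_with_brute_force_over_fixture(self, study_records, tox):
        for rec in study_records:
            got = screen_mrl(rec, tox[rec.element])
            mrl = tox[rec.element].mrl_for(rec.group.tissue)
            if mrl is None:
                expected = "no_limit"
            else:
                v = 0.0 if rec.censored else rec.value
                expected = "exceeds" if v > mrl else "compliant"
            assert got == expected, (rec.element, rec.group)


class TestPooling:
    def test_ni_muscle_equal_weight_mean(self, study_records):
        pooled = pool_groups(study_records)
        row = pooled[(pooled.tissue == "muscle") & (pooled.element == "Ni")]
        assert row["concentration"].iloc[0] == pytest.approx((0.83 + 0.84 + 1.2 + 0.76) / 4)

    def test_ni_range_matches_published(self, study_records):
        vals = [r.value for r in study_records if r.element == "Ni"]
        assert (min(vals), max(vals)) == (0.76, 1.2)

    def test_equal_and_by_n_agree_under_balanced_design(self, study_records):
        eq = pool_groups(study_records, weights="equal")
        byn = pool_groups(study_records, weights="by_n")
        assert eq["concentration"].to_numpy() == pytest.approx(
            byn["concentration"].to_numpy())

    def test_nd_policy_changes_censored_cells_only(self, study_records):
        zero = pool_groups(study_records, nd_policy="zero").set_index(
            ["tissue", "element"])
        lod = pool_groups(study_records, nd_policy="lod").set_index(
            ["tissue", "element"])
        assert zero.loc[("muscle", "Cd"), "concentration"] == 0.0
        assert lod.loc[("muscle", "Cd"), "concentration"] == pytest.approx(0.000127)
        assert zero.loc[("liver", "Fe"), "concentration"] == lod.loc[
            ("liver", "Fe"), "concentration"]

    def test_single_group_returns_its_mean(self, lod_table):
        rec = ConcentrationRecord(
            group=GroupKey("sheep", "female", "liver"), element="Zn", value=86.26)
        pooled = pool_groups([rec])
        assert pooled["concentration"].iloc[0] == 86.26


class TestTissueRisk:
    def test_mg_excluded_from_hq_and_hi(self, study_records, tox, params):
        tr = tissue_risk(study_records, tox, params, "liver")
        by_el = {r.element: r for r in tr.results}
        assert by_el["Mg"].hq is None and by_el["Mg"].ilcr is None
        assert tr.hi == pytest.approx(
            sum(r.hq for r in tr.results if r.hq is not None), rel=0, abs=0)

    def test_ilcr_only_for_carcinogens(self, study_records, tox, params):
        tr = tissue_risk(study_records, tox, params, "muscle")
        for r in tr.results:
            assert (r.ilcr is not None) == (r.element in {"Cd", "Pb", "Ni"})

    def test_hq_ranks_are_dense_and_ordered(self, study_records, tox, params):
        tr = tissue_risk(study_records, tox, params, "liver")
        ranked = sorted((r for r in tr.results if r.hq_rank is not None),
                        key=lambda r: r.hq_rank)
        assert [r.hq_rank for r in ranked] == list(range(1, len(ranked) + 1))
        hqs = [r.hq for r in ranked]
        assert hqs == sorted(hqs, reverse=True)

    def test_homogeneity_in_concentration(self, study_records, tox, params):
        """Scaling every concentration by k scales HQ and ILCR by k."""
        base = tissue_risk(study_records, tox, params, "muscle")
        scaled_records = [
            ConcentrationRecord(
                group=r.group, element=r.element,
                value=None if r.censored else 3.0 * r.value,
                censored=r.censored, lod=r.lod, n=r.n, sd=r.sd)
            for r in study_records
        ]
        scaled = tissue_risk(scaled_records, tox, params, "muscle")
        for a, b in zip(base.results, scaled.results):
            if a.hq is not None:
                assert b.hq == pytest.approx(3.0 * a.hq, rel=1e-12)
            if a.ilcr is not None:
                assert b.ilcr == pytest.approx(3.0 * a.ilcr, rel=1e-12)
        assert scaled.hi == pytest.approx(3.0 * base.hi, rel=1e-12)

    def test_report_table_has_hi_per_tissue(self, study_records, tox, params):
        trs = [tissue_risk(study_records, tox, params, t)
               for t in ("muscle", "liver")]
        table = risk_table(trs)
        assert set(table["tissue"]) == {"muscle", "liver"}
        assert len(table) == 20  # 10 elements x 2 tissues
        assert table.groupby("tissue")["hi"].nunique().eq(1).all()
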