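"""Paired cohort statistics and the comparison Model/Results pair."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from planrisk import (Cohort, DoseVolumeHistogram, MetricPanel,
                      PairedPlanComparison, PlanRecord, StructurePanel,
                      default_panel, evaluate_plan, paired_t_test,
                      percent_reduction, ratio_summary)
from planrisk.errors import CohortMismatchError, ConfigError, DomainError


def sign_flip_pvalue(diffs, n_flips=100_000, seed=0):
    """Permutation oracle: two-sided p under random sign flips of the
    paired differences, comparing |t| (equivalently |mean/sd|)."""
    d = np.asarray(diffs, float)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_flips, d.size))
    flipped = signs * d
    def absstat(x):
        sd = x.std(ddof=1, axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(x.mean(axis=-1)) / (sd / np.sqrt(x.shape[-1]))
        return np.where(sd == 0, np.inf * np.sign(np.abs(x.mean(axis=-1))), t)
    return float(np.mean(absstat(flipped) >= absstat(d[None, :]) - 1e-12))


class TestPairedT:
    def test_hand_computed_example(self):
        res = paired_t_test([1, 2, 3], [2, 3, 5])
        assert res.t == pytest.approx(4.0)
        assert res.df == 2
        assert res.p == pytest.approx(0.0572, abs=2e-4)
        assert not res.degenerate

    def test_identical_arms_flagged(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p == 1.0 and res.mean_diff == 0.0

    def test_constant_shift_degenerate_p_zero(self):
        res = paired_t_test([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert res.degenerate and res.p == 0.0 and res.mean_diff == 100.0

    def test_large_shift_vs_noise_highly_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(10, 1, 12)
        b = a + 50 + rng.normal(0, 0.1, 12)
        assert paired_t_test(a, b).p < 1e-3

    def test_too_few_pairs(self):
        with pytest.raises(DomainError):
            paired_t_test([1.0], [2.0])

    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_agrees_with_sign_flip_permutation_oracle(self, seed):
        """Exact-test agreement within Monte-Carlo error on small samples."""
        rng = np.random.default_rng(seed)
        # n >= 15 so the t reference distribution matches the sign-flip law
        # (at very small n the permutation distribution is visibly discrete)
        n = int(rng.integers(15, 26))
        a = rng.normal(10, 2, n)
        b = a + rng.normal(0.8, 1.5, n)
        res = paired_t_test(a, b)
        p_perm = sign_flip_pvalue(b - a, n_flips=100_000, seed=seed)
        mc_err = 3 * np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / 100_000)
        assert res.p == pytest.approx(p_perm, abs=max(0.02, mc_err + 0.01))


class TestPercentReduction:
    def test_no_change(self):
        assert percent_reduction(100, 100) == 0.0

    def test_treatment_time_worked_example(self):
        assert percent_reduction(7.00, 2.00) == pytest.approx(71.43, abs=0.01)

    def test_mu_worked_example(self):
        assert percent_reduction(893, 611) == pytest.approx(31.58, abs=0.01)

    def test_nonpositive_reference(self):
        with pytest.raises(DomainError):
            percent_reduction(0, 5)


class TestRatioSummary:
    def test_identical_arms(self):
        m, sd = ratio_summary([1, 2, 3], [1, 2, 3])
        assert m == 1.0 and sd == 0.0

    def test_hand_values(self):
        m, sd = ratio_summary([2, 4], [1, 3])
        assert m == pytest.approx(0.625)
        assert sd == pytest.approx(0.1768, abs=1e-4)

    def test_constant_scaling(self):
        a = np.array([1.0, 2.0, 5.0])
        m, sd = ratio_summary(a, 0.9 * a)
        assert m == pytest.approx(0.9) and sd == pytest.approx(0.0, abs=1e-12)

    def test_zero_denominator_names_patient(self):
        with pytest.raises(DomainError, match="P002"):
            ratio_summary([1, 0], [1, 1], patient_ids=["P001", "P002"])

    def test_mean_of_ratios_is_not_ratio_of_means(self):
        # the risk-table convention: E[b/a] != E[b]/E[a] for varying metrics
        a = np.array([1.0, 10.0])
        b = np.array([2.0, 5.0])
        m, _ = ratio_summary(a, b)
        assert m == pytest.approx(1.25)
        assert m != pytest.approx(b.mean() / a.mean())


# -------------------------------------------------------- report construction

def _toy_record(pid, technique, scale, age=47.0, mu=900):
    lung = DoseVolumeHistogram(
        "ipsilateral_lung", np.array([0.0, 5.0, 20.0, 40.0]) * scale,
        np.array([1.0, 0.6, 0.25, 0.0]), 1000.0)
    heart = DoseVolumeHistogram(
        "heart", np.array([0.0, 3.0, 10.0, 30.0]) * scale,
        np.array([1.0, 0.5, 0.1, 0.0]), 600.0)
    return PlanRecord(pid, technique, age, {"ipsilateral_lung": lung, "heart": heart},
                      mu=mu, beam_on_min=1.5, treat_time_min=7.0)


def _toy_panel():
    return MetricPanel(
        prescription_gy=50.0,
        structures=[
            StructurePanel("ipsilateral_lung", v_gy=[5.0], dmean=True,
                           ntcp="lung_lkb_pneumonitis", sccp="sccp_lung",
                           ear="ear_lung"),
            StructurePanel("heart", dmean=True,
                           ntcp="heart_seriality_mortality"),
        ],
        efficiency=["MU"],
    )


def _toy_cohorts(scale_b=0.9):
    a = Cohort([_toy_record("P001", "IMRT", 1.00, mu=900),
                _toy_record("P002", "IMRT", 1.10, mu=880)])
    b = Cohort([_toy_record("P001", "VMAT", 1.00 * scale_b, mu=600),
                _toy_record("P002", "VMAT", 1.10 * scale_b, mu=650)])
    return a, b


class TestEvaluatePlan:
    def test_values_match_direct_calls(self):
        rec = _toy_record("P001", "IMRT", 1.0)
        vals = evaluate_plan(rec, _toy_panel())
        lung = rec.dvhs["ipsilateral_lung"]
        assert vals[("ipsilateral_lung", "V5Gy(%)")] == pytest.approx(
            lung.volume_at_dose(5.0))
        assert vals[("ipsilateral_lung", "Dmean(Gy)")] == pytest.approx(
            lung.mean_dose())
        assert vals[("ipsilateral_lung", "SCCP(%)")] == pytest.approx(
            lung.mean_dose() * 1.68)
        assert vals[("plan", "MU")] == 900.0

    def test_missing_structure_listed(self):
        rec = _toy_record("P001", "IMRT", 1.0)
        del rec.dvhs["heart"]
        with pytest.raises(ConfigError, match="heart"):
            evaluate_plan(rec, _toy_panel())

    def test_conformity_requires_volumes(self):
        rec = _toy_record("P001", "IMRT", 1.0)
        panel = _toy_panel()
        panel.conformity_structure = "ipsilateral_lung"
        with pytest.raises(ConfigError, match="conformity"):
            evaluate_plan(rec, panel)


class TestPairedPlanComparison:
    def test_two_patient_cells_match_hand_computation(self):
        a, b = _toy_cohorts()
        res = PairedPlanComparison(a, b, _toy_panel()).fit()
        va = [evaluate_plan(r, _toy_panel()) for r in a]
        vb = [evaluate_plan(r, _toy_panel()) for r in b]
        for row in res.rows:
            key = (row.structure, row.metric)
            xa = np.array([v[key] for v in va])
            xb = np.array([v[key] for v in vb])
            assert row.mean_a == pytest.approx(xa.mean())
            assert row.sd_a == pytest.approx(xa.std(ddof=1))
            assert row.diff == pytest.approx((xb - xa).mean())
            assert row.diff == pytest.approx(row.mean_b - row.mean_a, abs=1e-10)
            if row.metric in ("NTCP(%)", "SCCP(%)", "EAR"):
                assert row.ratio_mean == pytest.approx((xb / xa).mean())

    def test_identical_cohorts_degenerate(self):
        a, _ = _toy_cohorts()
        b = Cohort([_toy_record(r.patient_id, "VMAT", 1.0 if r.patient_id == "P001"
                                else 1.10, mu=r.mu) for r in a], "VMAT")
        panel = MetricPanel(structures=[StructurePanel("heart", dmean=True)])
        res = PairedPlanComparison(a, b, panel).fit()
        row = res.rows[0]
        assert row.degenerate and row.p == 1.0 and row.diff == 0.0

    def test_arm_swap_negates_differences_and_inverts_ratios(self):
        a, b = _toy_cohorts()
        fwd = PairedPlanComparison(a, b, _toy_panel()).fit()
        rev = PairedPlanComparison(b, a, _toy_panel()).fit()
        for rf, rr in zip(fwd.rows, rev.rows):
            assert rr.diff == pytest.approx(-rf.diff, abs=1e-10)
            assert rr.p == pytest.approx(rf.p, abs=1e-12)
            if rf.ratio_mean is not None:
                # per-patient reciprocal, sanity bound not exact inverse of mean
                assert 1.0 / rr.ratio_mean == pytest.approx(rf.ratio_mean, rel=0.1)

    def test_deterministic_row_order_and_count(self):
        a, b = _toy_cohorts()
        res1 = PairedPlanComparison(a, b, _toy_panel()).fit()
        res2 = PairedPlanComparison(a, b, _toy_panel()).fit()
        keys1 = [(r.structure, r.metric) for r in res1.rows]
        keys2 = [(r.structure, r.metric) for r in res2.rows]
        assert keys1 == keys2
        # lung: V5, Dmean, NTCP, SCCP, EAR; heart: Dmean, NTCP; plan: MU
        assert len(keys1) == 8

    def test_mismatched_cohorts_list_patients(self):
        a, b = _toy_cohorts()
        b = Cohort([r for r in b if r.patient_id != "P002"]
                   + [_toy_record("P099", "VMAT", 0.9)], "VMAT")
        with pytest.raises(CohortMismatchError, match="P099"):
            PairedPlanComparison(a, b, _toy_panel())

    def test_empty_panel_rejected(self):
        a, b = _toy_cohorts()
        with pytest.raises(ConfigError):
            PairedPlanComparison(a, b, MetricPanel(structures=[]))

    def test_summary_and_subtables(self):
        a, b = _toy_cohorts()
        res = PairedPlanComparison(a, b, _toy_panel()).fit()
        text = res.summary()
        assert "IMRT" in text and "VMAT" in text and "NTCP" in text
        assert len(res.risk_table()) == 4   # lung NTCP/SCCP/EAR + heart NTCP
        assert list(res.efficiency_table()["metric"]) == ["MU"]
        assert res.percent_reduction("plan", "MU") == pytest.approx(
            percent_reduction(890.0, 625.0))

    def test_default_panel_resolves_on_default_registry(self):
        panel = default_panel()
        names = {sp.ntcp for sp in panel.structures} | \
                {sp.sccp for sp in panel.structures} | \
                {sp.ear for sp in panel.structures}
        names.discard(None)
        from planrisk import DEFAULT_REGISTRY
        assert names <= set(DEFAULT_REGISTRY)
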