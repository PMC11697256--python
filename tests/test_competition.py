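"""Welch's t-test, competition ratios and the hit-calling filter cascade."""

import math

import numpy as np
import pytest
from scipy import stats

from covscreen.competition import (
    CompetitionParams,
    CompetitionScreen,
    call_hits,
    site_competition,
    welch_t,
)
from covscreen.io_model import Role, SampleMeta

from conftest import make_quant


class TestWelch:
    def test_identical_samples_give_p_one(self):
        r = welch_t([10, 12, 11, 13], [10, 12, 11, 13])
        assert r.t == 0.0
        assert r.p == 1.0

    def test_antisymmetry(self):
        a, b = [5.0, 5.2, 4.8, 5.4], [3.0, 3.1, 2.9]
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.t == pytest.approx(-r2.t, abs=1e-14)
        assert r1.p == pytest.approx(r2.p, abs=1e-14)
        assert r1.df == pytest.approx(r2.df, abs=1e-12)

    def test_textbook_example(self):
        # hand-computed from the Welch formulas:
        # mx=5.0, my=3.0, vx=0.04, vy=0.01, se2=0.04/3+0.01/3
        x, y = [5.0, 5.2, 4.8], [3.0, 3.1, 2.9]
        se2 = 0.04 / 3 + 0.01 / 3
        t_exp = 2.0 / math.sqrt(se2)
        df_exp = se2**2 / ((0.04 / 3) ** 2 / 2 + (0.01 / 3) ** 2 / 2)
        p_exp = 2 * stats.t.sf(t_exp, df_exp)
        r = welch_t(x, y)
        assert r.t == pytest.approx(t_exp, abs=1e-10)
        assert r.df == pytest.approx(df_exp, abs=1e-10)
        assert r.p == pytest.approx(p_exp, abs=1e-10)

    def test_zero_variance_unequal_means_degenerate(self):
        r = welch_t([5.0, 5.0], [3.0, 3.0])
        assert r.p == 0.0
        assert r.degenerate
        assert math.isinf(r.t)

    def test_requires_two_values_each(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestSiteCompetition:
    def test_quarter_intensity_gives_log2cr_two(self, single_dose_meta):
        intens = {s.sample_id: 100.0 for s in single_dose_meta
                  if s.role is Role.control}
        intens.update({s.sample_id: 25.0 for s in single_dose_meta
                       if s.role is Role.treated})
        q = make_quant(intens)
        rec = site_competition(q, single_dose_meta, "PP01")
        assert rec.mean_log2_cr == pytest.approx(2.0, abs=1e-12)
        assert rec.n_treated_detected == 4
        assert rec.n_control_detected == 16

    def test_no_change_is_not_a_hit(self, single_dose_meta):
        intens = {s.sample_id: 100.0 for s in single_dose_meta}
        rec = site_competition(make_quant(intens), single_dose_meta, "PP01")
        assert rec.mean_log2_cr == pytest.approx(0.0, abs=1e-12)
        assert not rec.is_hit

    def test_matches_bruteforce_on_lognormal_draws(self, single_dose_meta, rng):
        ctrl_ids = [s.sample_id for s in single_dose_meta if s.role is Role.control]
        trt_ids = [s.sample_id for s in single_dose_meta if s.role is Role.treated]
        sigma = math.sqrt(math.log(1 + 0.25**2))
        ctrl = np.exp(rng.normal(math.log(100), sigma, 16))
        trt = np.exp(rng.normal(math.log(100), sigma, 4)) * 0.25
        q = make_quant({**dict(zip(ctrl_ids, ctrl)), **dict(zip(trt_ids, trt))})
        rec = site_competition(q, single_dose_meta, "PP01")
        # brute-force recomputation from the same drawn numbers
        expected_cr = float(
            np.mean([math.log2(ctrl.mean()) - math.log2(t) for t in trt])
        )
        expected_p = stats.ttest_ind(
            np.log2(ctrl), np.log2(trt), equal_var=False
        ).pvalue
        assert rec.mean_log2_cr == pytest.approx(expected_cr, abs=1e-10)
        assert rec.p_value == pytest.approx(float(expected_p), abs=1e-10)

    def test_zero_treated_detections_yields_no_hit_record(self, single_dose_meta):
        intens = {s.sample_id: 100.0 for s in single_dose_meta
                  if s.role is Role.control}
        rec = site_competition(make_quant(intens), single_dose_meta, "PP01")
        assert rec.n_treated_detected == 0
        assert not rec.is_hit


class TestScalingInvariance:
    def test_common_factor_shifts_cr_and_preserves_p(self, single_dose_meta, rng):
        ctrl_ids = [s.sample_id for s in single_dose_meta if s.role is Role.control]
        trt_ids = [s.sample_id for s in single_dose_meta if s.role is Role.treated]
        base = {
            **{c: float(rng.lognormal(5, 0.3)) for c in ctrl_ids},
            **{t: float(rng.lognormal(4, 0.3)) for t in trt_ids},
        }
        scaled_trt = {k: (v * 8.0 if k in trt_ids else v) for k, v in base.items()}
        scaled_all = {k: v * 8.0 for k, v in base.items()}
        r1 = site_competition(make_quant(base), single_dose_meta, "PP01")
        r2 = site_competition(make_quant(scaled_trt), single_dose_meta, "PP01")
        r3 = site_competition(make_quant(scaled_all), single_dose_meta, "PP01")
        # scaling one group shifts the log ratio by exactly log2(factor)
        assert r2.mean_log2_cr == pytest.approx(r1.mean_log2_cr - 3.0, abs=1e-10)
        # a common factor on every sample changes neither CR nor the
        # log-scale test (pure location shift of all log intensities)
        assert r3.mean_log2_cr == pytest.approx(r1.mean_log2_cr, abs=1e-10)
        assert r3.p_value == pytest.approx(r1.p_value, abs=1e-12)


class TestFilterCascade:
    def _clean_quant(self, meta, treated_factor=0.25):
        intens = {
            s.sample_id: (100.0 if s.role is Role.control else 100.0 * treated_factor)
            for s in meta
        }
        # tiny jitter so variances are nonzero
        for i, k in enumerate(sorted(intens)):
            intens[k] *= 1 + 0.01 * ((i % 3) - 1)
        return intens

    def test_constructed_hit_is_called(self, single_dose_meta):
        q = make_quant(self._clean_quant(single_dose_meta))
        (rec,) = call_hits([q], single_dose_meta)
        assert rec.filter_flags == ""
        assert rec.is_hit

    def test_single_treated_detection_flags_low_treated_n(self, single_dose_meta):
        intens = self._clean_quant(single_dose_meta)
        for s in single_dose_meta:
            if s.role is Role.treated and s.sample_id != "T1":
                del intens[s.sample_id]
        (rec,) = call_hits([make_quant(intens)], single_dose_meta)
        assert "low_treated_n" in rec.flags
        assert not rec.is_hit

    def test_high_control_cv_flags(self, single_dose_meta):
        intens = self._clean_quant(single_dose_meta)
        # alternate control intensities 40/160: CV ~ 0.6 > 0.4
        for i, s in enumerate(s for s in single_dose_meta if s.role is Role.control):
            intens[s.sample_id] = 40.0 if i % 2 else 160.0
        (rec,) = call_hits([make_quant(intens)], single_dose_meta)
        assert "high_cv" in rec.flags
        assert not rec.is_hit

    def test_multi_dtb_flags(self, single_dose_meta):
        q = make_quant(
            self._clean_quant(single_dose_meta),
            sequence="ACDCEFK",
            dtb_positions=(2, 4),
        )
        (rec,) = call_hits([q], single_dose_meta)
        assert "multi_dtb" in rec.flags
        assert not rec.is_hit

    def test_redundant_form_flags(self, single_dose_meta):
        q = make_quant(self._clean_quant(single_dose_meta), redundant_form=True)
        (rec,) = call_hits([q], single_dose_meta)
        assert "redundant_form" in rec.flags
        assert not rec.is_hit

    def test_incomplete_detection_never_hits(self, single_dose_meta):
        intens = self._clean_quant(single_dose_meta)
        # drop 3 of 20 samples -> 85% completeness, below the 90% filter
        for sid in ["C01", "C02", "C03"]:
            del intens[sid]
        (rec,) = call_hits([make_quant(intens)], single_dose_meta)
        assert rec.frac_detected_all == pytest.approx(17 / 20)
        assert "low_completeness" in rec.flags
        assert not rec.is_hit


def test_multiple_compounds_and_concentrations_grouped():
    meta = [
        SampleMeta(sample_id=f"C{i}", role=Role.control, replicate_index=i)
        for i in range(1, 5)
    ]
    for comp in ("PP01", "PP02"):
        for conc in (5.0, 50.0):
            for j in (1, 2):
                meta.append(
                    SampleMeta(
                        sample_id=f"{comp}_{conc}_{j}",
                        role=Role.treated,
                        compound_id=comp,
                        concentration_um=conc,
                        replicate_index=j,
                    )
                )
    intens = {s.sample_id: 100.0 * (1 + 0.02 * (i % 5))
              for i, s in enumerate(meta)}
    recs = CompetitionScreen([make_quant(intens)], meta).fit().records
    assert len(recs) == 4
    assert {(r.compound_id, r.concentration_um) for r in recs} == {
        ("PP01", 5.0), ("PP01", 50.0), ("PP02", 5.0), ("PP02", 50.0)
    }
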