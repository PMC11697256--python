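"""Relative intensities, bounded 4PL fitting, quality filter, off-targets."""

import math

import numpy as np
import pytest

from covscreen.aggregate import SiteKey
from covscreen.dose_response import (
    DoseResponseFit,
    FourParamLogistic,
    QualityParams,
    assess_fit,
    count_off_targets,
    fit_4pl,
    logistic4,
    relative_intensities,
)
from covscreen.io_model import Role, SampleMeta
from covscreen.simulate import default_dose_series

from conftest import make_quant


def dr_meta(concs=(1.0, 10.0, 100.0), n_ctrl=4, n_reps=2):
    meta = [
        SampleMeta(sample_id=f"C{i}", role=Role.control, replicate_index=i)
        for i in range(1, n_ctrl + 1)
    ]
    for ci, c in enumerate(concs):
        for j in range(1, n_reps + 1):
            meta.append(
                SampleMeta(
                    sample_id=f"T{ci}_{j}",
                    role=Role.treated,
                    compound_id="PP01",
                    concentration_um=c,
                    replicate_index=j,
                )
            )
    return meta


class TestRelativeIntensities:
    def test_percent_of_control(self):
        meta = dr_meta()
        intens = {f"C{i}": 200.0 for i in range(1, 5)}
        for ci, y in enumerate((160.0, 100.0, 40.0)):
            intens[f"T{ci}_1"] = y
            intens[f"T{ci}_2"] = y
        pts = relative_intensities(make_quant(intens), meta, "PP01")
        assert [round(x, 6) for x, _ in pts] == [0.0, 1.0, 2.0]
        assert [y for _, y in pts] == pytest.approx([80.0, 50.0, 20.0])

    def test_equal_means_give_100(self):
        meta = dr_meta(concs=(10.0,))
        intens = {f"C{i}": 50.0 for i in range(1, 5)}
        intens.update({"T0_1": 40.0, "T0_2": 60.0})
        pts = relative_intensities(make_quant(intens), meta, "PP01")
        assert pts == [(1.0, pytest.approx(100.0))]

    def test_undetected_concentration_point_absent(self):
        meta = dr_meta()
        intens = {f"C{i}": 100.0 for i in range(1, 5)}
        intens.update({"T0_1": 90.0, "T2_1": 20.0})  # nothing at conc index 1
        pts = relative_intensities(make_quant(intens), meta, "PP01")
        assert [x for x, _ in pts] == [0.0, 2.0]

    def test_requires_two_controls(self):
        meta = dr_meta(n_ctrl=4)
        intens = {"C1": 100.0, "T0_1": 50.0}
        with pytest.raises(ValueError, match="control"):
            relative_intensities(make_quant(intens), meta, "PP01")


class TestFit4PL:
    X = np.log10(default_dose_series())

    def test_noiseless_recovery(self):
        y = logistic4(self.X, 100.0, 0.0, -1.0, 1.0)
        f = fit_4pl(list(zip(self.X, y)))
        assert f.converged
        assert f.e0 == pytest.approx(100.0, abs=1e-3)
        assert f.e_inf == pytest.approx(0.0, abs=1e-3)
        assert f.slope_n == pytest.approx(-1.0, abs=1e-3)
        assert f.log10_te50 == pytest.approx(1.0, abs=1e-3)
        assert f.r_squared >= 0.999999

    def test_midpoint_identity(self):
        y = logistic4(self.X, 95.0, 5.0, -1.4, 0.7)
        f = fit_4pl(list(zip(self.X, y)))
        mid = f.predict(f.log10_te50)
        assert mid == pytest.approx((f.e0 + f.e_inf) / 2, abs=1e-9)

    def test_pte50_unit_conversion(self):
        f = DoseResponseFit(log10_te50=1.0)
        assert f.pte50 == 5.0  # 10 uM == 1e-5 M

    def test_too_few_points_gives_no_fit(self):
        y = logistic4(self.X[:4], 100.0, 0.0, -1.0, 1.0)
        f = fit_4pl(list(zip(self.X[:4], y)))
        assert not f.converged
        assert math.isnan(f.log10_te50)
        assert f.n_conc_used == 4

    def test_bounds_honoured_with_at_bound_flags(self, rng):
        # flat noisy data pushes the slope/potency to their limits
        for _ in range(5):
            y = rng.normal(100.0, 2.0, size=self.X.size)
            f = fit_4pl(list(zip(self.X, y)))
            assert 60.0 <= f.e0 <= 140.0
            assert f.e_inf >= 0.0
            assert -50.0 <= f.slope_n <= 0.0
            assert self.X.min() - 3 <= f.log10_te50 <= self.X.max() + 3
        # an unreached bottom plateau pins e_inf at its bound
        y = logistic4(self.X, 100.0, 0.0, -1.0, 1.0)
        f = fit_4pl(list(zip(self.X, y)))
        assert set(f.at_bounds.split(",")) <= {"", "e_inf"}

    def test_curve_monotone_for_negative_slope(self):
        y = logistic4(self.X, 100.0, 0.0, -2.0, 1.0)
        f = FourParamLogistic(self.X, y).fit()
        xs = np.linspace(self.X.min() - 1, self.X.max() + 1, 100)
        pred = f.predict(xs)
        assert np.all(np.diff(pred) <= 1e-9)


class TestQuality:
    def _good_fit(self):
        x = np.log10(default_dose_series())
        y = logistic4(x, 100.0, 0.0, -1.0, 1.0)
        return fit_4pl(list(zip(x, y)))

    def test_noiseless_in_range_fit_passes(self):
        assert assess_fit(self._good_fit())

    def test_flat_curve_fails_on_span(self):
        f = self._good_fit()
        f.e0, f.e_inf = 80.0, 75.0
        assert not assess_fit(f)

    def test_out_of_range_potency_fails(self):
        f = self._good_fit()
        f.log10_te50 = f.x_max + 3.0
        assert not assess_fit(f)

    def test_uncertain_te50_fails(self):
        f = self._good_fit()
        f.stderr_log10_te50 = 1.5
        assert not assess_fit(f)


class TestOffTargets:
    def _fit(self, acc, pte50, passes=True):
        f = DoseResponseFit(
            compound_id="PP01",
            protein_accession=acc,
            residue_index=1,
            log10_te50=6.0 - pte50,
        )
        f.passes_quality = passes
        return f

    def test_window_counting(self):
        fits = [self._fit("REF", 5.4), self._fit("A", 5.2), self._fit("B", 4.0)]
        assert count_off_targets(fits, SiteKey("REF", 1), 0.5) == 1

    def test_sole_fit_has_zero_off_targets(self):
        fits = [self._fit("REF", 5.4)]
        assert count_off_targets(fits, SiteKey("REF", 1)) == 0

    def test_failing_fits_excluded(self):
        fits = [self._fit("REF", 5.4), self._fit("A", 5.3, passes=False)]
        assert count_off_targets(fits, SiteKey("REF", 1)) == 0

    def test_matches_bruteforce_on_random_pte50s(self, rng):
        pte50s = rng.uniform(4.0, 6.0, size=10)
        fits = [self._fit(f"P{i}", p) for i, p in enumerate(pte50s)]
        ref = SiteKey("P0", 1)
        expected = sum(
            1 for i, p in enumerate(pte50s) if i != 0 and p >= pte50s[0] - 0.5
        )
        assert count_off_targets(fits, ref, 0.5) == expected

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError):
            count_off_targets([self._fit("A", 5.0)], SiteKey("REF", 1))
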