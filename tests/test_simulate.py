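"""Simulator determinism, noise/occupancy model and ground-truth closure."""

import numpy as np
import pandas as pd
import pytest

from covscreen.pipeline import quants_from_frames, screen_from_frames
from covscreen.simulate import (
    DetectionModel,
    SimConfig,
    SpikeSpec,
    default_dose_series,
    occupancy,
    simulate_dose_response,
    simulate_screen,
)


class TestOccupancy:
    def test_midpoint(self):
        assert occupancy(10.0, 10.0) == 0.5

    def test_limits(self):
        assert occupancy(1e-9, 10.0) < 1e-9
        assert occupancy(1e12, 10.0) > 1 - 1e-9

    def test_three_times_te50(self):
        assert occupancy(30.0, 10.0) == pytest.approx(0.75)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            occupancy(0.0, 10.0)


class TestConfigValidation:
    def test_bad_cv_rejected(self):
        with pytest.raises(ValueError, match="cv"):
            SimConfig(cv=1.5)

    def test_spike_beyond_sites_rejected(self):
        with pytest.raises(ValueError, match="site_index"):
            SimConfig(n_sites=10, spikes=[SpikeSpec("PP01", 10, 5.0)])

    def test_spike_unknown_compound_rejected(self):
        with pytest.raises(ValueError, match="compound"):
            SimConfig(n_compounds=1, spikes=[SpikeSpec("PP09", 0, 5.0)])

    def test_design_defaults(self):
        assert SimConfig(design="single_dose").n_control_reps == 16
        dr = SimConfig(design="dose_response")
        assert dr.n_control_reps == 25
        assert dr.concentrations_um == pytest.approx(default_dose_series())
        assert dr.concentrations_um[0] == pytest.approx(0.4)
        assert dr.concentrations_um[-1] == pytest.approx(200.0)


class TestSimulateScreen:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SimConfig(n_proteins=5, n_sites=20, n_compounds=2, seed=9)
        a = simulate_screen(cfg).write(tmp_path / "a")
        b = simulate_screen(cfg).write(tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()

    def test_design_sample_counts(self):
        out = simulate_screen(SimConfig(n_proteins=5, n_sites=20, n_compounds=3))
        roles = [s.role.value for s in out.meta]
        assert roles.count("control") == 16
        assert roles.count("treated") == 3 * 4

    def test_charge_states_sum_to_peptide_intensity(self):
        cfg = SimConfig(n_proteins=2, n_sites=5, n_compounds=1, seed=3)
        out = simulate_screen(cfg)
        per_charge = out.report.groupby(
            ["sample_id", "modified_sequence"])["intensity"]
        assert (per_charge.count() == 2).all()
        # 70/30 split reassembles exactly
        sums = per_charge.sum()
        maxes = per_charge.max()
        assert np.allclose(maxes / sums, 0.7)

    def test_null_noiseless_screen_has_zero_cr_everywhere(self):
        cfg = SimConfig(
            n_proteins=4,
            n_sites=16,
            n_compounds=2,
            cv=0.0,
            detection=DetectionModel.always(),
            seed=5,
        )
        out = simulate_screen(cfg)
        res = screen_from_frames(out.report, out.meta, out.proteome)
        assert len(res.records) == 16 * 2
        for r in res.records:
            assert r.mean_log2_cr == pytest.approx(0.0, abs=1e-9)
            assert not r.is_hit

    def test_truth_closure_and_spike_effect(self):
        cfg = SimConfig(
            n_proteins=4,
            n_sites=16,
            n_compounds=2,
            cv=0.0,
            detection=DetectionModel.always(),
            spikes=[SpikeSpec("PP01", 0, te50_um=50.0 / 3.0)],  # occupancy 0.75
            seed=5,
        )
        out = simulate_screen(cfg)
        assert len(out.truth) == 1
        res = screen_from_frames(out.report, out.meta, out.proteome)
        spiked = [
            r
            for r in res.records
            if r.compound_id == "PP01"
            and r.protein_accession == out.truth.protein_accession[0]
            and r.residue_index == out.truth.residue_index[0]
        ]
        assert spiked[0].mean_log2_cr == pytest.approx(2.0, abs=1e-9)
        for r in res.records:
            if r not in spiked:
                assert r.mean_log2_cr == pytest.approx(0.0, abs=1e-9)

    def test_report_parses_through_full_pipeline(self):
        cfg = SimConfig(n_proteins=5, n_sites=20, n_compounds=2, seed=1)
        out = simulate_screen(cfg)
        quants = quants_from_frames(out.report, out.meta, out.proteome)
        mapped = [q for q in quants if q.site is not None]
        assert len(mapped) == len(quants)
        assert {q.site for q in mapped} <= set(out.sites)


class TestDoseResponse:
    def test_noiseless_relative_intensities_follow_occupancy(self):
        from covscreen.dose_response import relative_intensities

        cfg = SimConfig(
            n_proteins=2,
            n_sites=4,
            n_compounds=1,
            design="dose_response",
            cv=0.0,
            detection=DetectionModel.always(),
            spikes=[SpikeSpec("PP01", 0, te50_um=10.0)],
            seed=2,
        )
        out = simulate_dose_response(cfg)
        quants = quants_from_frames(out.report, out.meta, out.proteome)
        q = next(q for q in quants if q.site == out.sites[0])
        pts = relative_intensities(q, out.meta, "PP01")
        for x, y in pts:
            c = 10.0**x
            assert y == pytest.approx(100.0 * (1 - c / (c + 10.0)), abs=1e-9)

    def test_noiseless_series_recovers_te50(self):
        from covscreen.dose_response import fit_4pl, relative_intensities

        cfg = SimConfig(
            n_proteins=2,
            n_sites=4,
            n_compounds=1,
            design="dose_response",
            cv=0.0,
            detection=DetectionModel.always(),
            spikes=[SpikeSpec("PP01", 0, te50_um=10.0)],
            seed=2,
        )
        out = simulate_dose_response(cfg)
        quants = quants_from_frames(out.report, out.meta, out.proteome)
        q = next(q for q in quants if q.site == out.sites[0])
        fit = fit_4pl(relative_intensities(q, out.meta, "PP01"))
        assert fit.log10_te50 == pytest.approx(1.0, abs=1e-3)
        assert fit.pte50 == pytest.approx(5.0, abs=1e-3)


class TestDetectionCalibration:
    def test_marginal_detection_near_target(self):
        det = DetectionModel.calibrated()
        cfg = SimConfig(n_proteins=20, n_sites=300, n_compounds=1,
                        detection=det, seed=8)
        out = simulate_screen(cfg)
        assert out.detected.mean() == pytest.approx(0.9, abs=0.03)

    def test_spiked_engagement_reduces_detection(self):
        # MNAR: heavy engagement pushes intensities below the detection
        # midpoint, so spiked treated samples are detected less often
        cfg = SimConfig(
            n_proteins=20,
            n_sites=100,
            n_compounds=1,
            spikes=[SpikeSpec("PP01", i, te50_um=0.5) for i in range(50)],
            seed=4,
        )
        out = simulate_screen(cfg)
        treated_cols = [
            j for j, s in enumerate(out.meta) if s.role.value == "treated"
        ]
        spiked = out.detected[np.ix_(range(50), treated_cols)].mean()
        unspiked = out.detected[np.ix_(range(50, 100), treated_cols)].mean()
        assert spiked < unspiked - 0.2
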