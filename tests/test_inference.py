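"""Band-length estimation, product-vs-substrate OLS, parameter recovery,
and dose-response fitting."""

import math

import numpy as np
import pytest

from chirace.gel import GelParams, make_marker_ladder, render_lane
from chirace.inference import (
    FitError,
    estimate_band_lengths,
    fit_dose_response,
    fit_product_vs_substrate,
    product_band,
    recover_ratio_and_delay,
)
from chirace.kinetics import cheng_prusoff_ic50
from chirace.params import MotorKinetics, SubstrateSpec
from chirace.race import FragmentRecord, FragmentSet
from chirace.synthetic import generate_nuclease_assay, nuclease_assay_kinetics

GEL = GelParams(a_mm=120.0, b_mm=30.0, sigma_mm=0.8, min_length_nt=50, max_length_nt=5000)
MARKERS = make_marker_ladder([4350, 2270, 1340, 1000, 500, 250], GEL)


def lane_with(length_counts, substrate_len=4350, full=0):
    sub = SubstrateSpec("s", substrate_len)
    records = tuple(FragmentRecord(L, c, "end_stop") for L, c in length_counts)
    fs = FragmentSet(
        substrate=sub,
        inhibitor_uM=100.0,
        records=records,
        n_molecules=sum(c for _, c in length_counts) + full,
        full_length_count=full,
    )
    return render_lane(fs, GEL, MARKERS)


class TestEstimateBandLengths:
    def test_round_trip_single_fragment(self):
        lane = lane_with([(970, 2000)])
        bands = estimate_band_lengths(lane)
        assert len(bands) == 1
        assert bands[0].length_nt == pytest.approx(970, rel=0.005)
        assert not bands[0].is_full_length

    def test_full_length_band_flagged_not_dropped(self):
        lane = lane_with([(970, 1000)], full=1000)
        bands = estimate_band_lengths(lane)
        flags = sorted(b.is_full_length for b in bands)
        assert flags == [False, True]

    def test_empty_lane(self):
        lane = lane_with([(970, 1)])
        flat = lane.__class__(
            distance_mm=lane.distance_mm,
            intensity=np.zeros_like(lane.intensity),
            markers=lane.markers,
            metadata=lane.metadata,
        )
        assert estimate_band_lengths(flat) == []

    def test_band_outside_span_flagged(self):
        lane = lane_with([(120, 2000)])  # below the 250 nt bottom marker
        bands = estimate_band_lengths(lane)
        assert len(bands) == 1
        assert bands[0].length_nt is None and not bands[0].in_marker_span

    def test_product_band_picks_cut_product(self):
        lane = lane_with([(970, 1500)], full=500)
        band = product_band(lane)
        assert band is not None and band.length_nt == pytest.approx(970, rel=0.005)


class TestLinearFit:
    def test_exact_on_collinear_points(self):
        pts = [(1340, 152), (2270, 431), (4350, 1055)]  # 0.3·S − 250
        fit = fit_product_vs_substrate(pts)
        assert fit.slope == pytest.approx(0.300, abs=1e-9)
        assert fit.intercept == pytest.approx(-250.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_points_exact_with_nan_se(self):
        fit = fit_product_vs_substrate([(1000, 100), (2000, 400)])
        assert fit.slope == pytest.approx(0.3)
        assert math.isnan(fit.se_slope) and math.isnan(fit.se_intercept)

    def test_degenerate_x_rejected(self):
        with pytest.raises(FitError):
            fit_product_vs_substrate([(1000, 100), (1000, 200)])

    def test_ols_estimator_calibration(self):
        """Noisy synthetic triples: mean slope over replicates within 2 SE
        of the generating slope (σ = 30 nt, 100 replicates)."""
        rng = np.random.default_rng(0)
        slopes = []
        for _ in range(100):
            pts = [
                (S, 0.4 * S - 250 + rng.normal(0, 30))
                for S in (1340, 2270, 4350)
            ]
            slopes.append(fit_product_vs_substrate(pts).slope)
        slopes = np.asarray(slopes)
        se = slopes.std(ddof=1) / math.sqrt(slopes.size)
        assert abs(slopes.mean() - 0.4) < 2 * se


class TestRecoverRatioAndDelay:
    def test_definitional_inversion(self):
        fit = fit_product_vs_substrate([(1340, 152), (2270, 431), (4350, 1055)])
        rec = recover_ratio_and_delay(fit, v_b_nt_per_ms=1.0)
        assert rec.ratio == pytest.approx(0.7)
        assert rec.advance_nt == pytest.approx(250.0)
        assert rec.tau_ms == pytest.approx(250.0)

    def test_printed_400uM_delay(self):
        # slope 0.7, intercept −200 at ~1 nt/ms → ~200 ms swing
        pts = [(S, 0.7 * S - 200) for S in (1340, 2270, 4350)]
        rec = recover_ratio_and_delay(fit_product_vs_substrate(pts))
        assert rec.tau_ms == pytest.approx(200.0)

    def test_positive_intercept_clamped(self):
        pts = [(S, 0.5 * S + 10) for S in (1340, 2270, 4350)]
        rec = recover_ratio_and_delay(fit_product_vs_substrate(pts))
        assert rec.advance_nt == 0.0 and rec.intercept_clamped

    def test_zero_intercept(self):
        pts = [(S, 0.5 * S) for S in (1340, 2270, 4350)]
        rec = recover_ratio_and_delay(fit_product_vs_substrate(pts))
        assert rec.advance_nt == 0.0 and not rec.intercept_clamped

    def test_slope_outside_unit_interval_rejected(self):
        pts = [(S, 1.2 * S - 100) for S in (1340, 2270, 4350)]
        with pytest.raises(FitError):
            recover_ratio_and_delay(fit_product_vs_substrate(pts))


class TestDoseResponse:
    def test_noiseless_rate_law_recovers_cheng_prusoff(self):
        """On data generated exactly by the rate law the fitted IC50 matches
        the closed form within 2%."""
        kin = MotorKinetics(v_max=1.0, km_atp=3750 / 9, ki_inh=9.433962264150942)
        df = generate_nuclease_assay(
            kin, 25.0, [0, 1, 2.5, 5, 10, 20, 40, 80], replicates=1,
            noise_cv=0.0, seed=0,
        )
        fit = fit_dose_response(list(zip(df.inhibitor_uM, df.activity_fraction)))
        assert fit.ic50_uM == pytest.approx(
            cheng_prusoff_ic50(kin, 25.0), rel=0.02
        )
        assert fit.top == pytest.approx(1.0, abs=0.01)
        assert fit.bottom == pytest.approx(0.0, abs=0.01)

    def test_noiseless_logistic_recovers_exactly(self):
        conc = np.array([0, 1, 2, 4, 6.3, 10, 20, 40, 80])
        act = 1.0 / (1.0 + conc / 6.3)
        fit = fit_dose_response(list(zip(conc, act)))
        assert fit.ic50_uM == pytest.approx(6.3, rel=0.01)
        assert fit.hill == pytest.approx(1.0, rel=0.02)

    def test_constant_background_shifts_bottom_only(self):
        conc = np.array([0, 1, 2, 4, 6.3, 10, 20, 40, 80])
        act = 1.0 / (1.0 + conc / 6.3) + 0.1
        fit = fit_dose_response(list(zip(conc, act)))
        assert fit.bottom == pytest.approx(0.1, abs=0.02)
        assert fit.ic50_uM == pytest.approx(6.3, rel=0.05)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(FitError):
            fit_dose_response([(0, 1.0), (10, 0.5), (100, 0.1)])

    def test_missing_near_zero_anchor_rejected(self):
        with pytest.raises(FitError):
            fit_dose_response([(20, 0.9), (40, 0.5), (60, 0.3), (80, 0.2)])

    def test_assay_generator_settings_recovered(self):
        kin = nuclease_assay_kinetics(6.3, 25.0, 3750 / 9)
        assert cheng_prusoff_ic50(kin, 25.0) == pytest.approx(6.3, rel=1e-12)
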