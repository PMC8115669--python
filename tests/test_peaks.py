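"""Peak integration, S/N, QC checks and heavy/light quantification."""

import math

import numpy as np
import pytest

from mrmkit import simulate
from mrmkit.peaks import (
    CheckResult,
    Peak,
    Trace,
    TraceWindowError,
    bsa_normalize,
    coelution_check,
    integrate_peak,
    qualifier_ratio_check,
    quantify_batch,
    quantify_sample,
    snr,
)


class TestIntegratePeak:
    def test_noiseless_gaussian_matches_closed_form(self, make_gaussian_trace):
        trace = make_gaussian_trace(height=1000.0, sigma=0.05)
        peak = integrate_peak(trace, expected_rt=5.0, rt_tolerance=0.3)
        expected = 1000.0 * 0.05 * math.sqrt(2 * math.pi)  # ~125.3 counts*min
        assert peak.found
        assert peak.area == pytest.approx(expected, rel=0.02)
        assert peak.apex_rt == pytest.approx(5.0, abs=0.01)
        assert peak.apex_height == pytest.approx(1000.0, rel=0.01)

    def test_flat_zero_trace_not_found(self):
        t = np.arange(4.0, 6.0, 0.01)
        trace = Trace("s", "t", t, np.zeros_like(t))
        peak = integrate_peak(trace, 5.0, 0.3)
        assert not peak.found

    def test_area_closed_form_across_sigmas(self, make_gaussian_trace):
        # closed form holds whenever sigma >= 4 sampling intervals
        for sigma in (0.04, 0.08, 0.15):
            trace = make_gaussian_trace(height=500.0, sigma=sigma)
            peak = integrate_peak(trace, 5.0, max(0.3, 3 * sigma))
            assert peak.area == pytest.approx(
                500.0 * sigma * math.sqrt(2 * math.pi), rel=0.02
            )

    def test_baseline_offset_invariance(self, make_gaussian_trace):
        flat = make_gaussian_trace(height=100.0, noise_sd=10.0, seed=5)
        offset = Trace(
            "s", "t", flat.time, flat.intensity + 500.0
        )
        p0 = integrate_peak(flat, 5.0, 0.3)
        p1 = integrate_peak(offset, 5.0, 0.3)
        assert snr(p1) == pytest.approx(snr(p0), rel=1e-6)
        assert p1.baseline_level == pytest.approx(p0.baseline_level + 500.0, abs=1.0)

    def test_snr_monte_carlo(self, make_gaussian_trace):
        # apex 100 over noise SD 10 should report S/N ~ 10
        snrs = [
            snr(
                integrate_peak(
                    make_gaussian_trace(height=100.0, baseline=50.0, noise_sd=10.0, seed=s),
                    5.0,
                    0.3,
                )
            )
            for s in range(50)
        ]
        assert np.mean(snrs) == pytest.approx(10.0, rel=0.3)

    def test_expected_rt_outside_trace(self, make_gaussian_trace):
        trace = make_gaussian_trace()
        with pytest.raises(TraceWindowError):
            integrate_peak(trace, 99.0, 0.3)

    def test_trace_validation(self):
        with pytest.raises(ValueError, match="20 points"):
            Trace("s", "t", np.arange(5.0, 5.05, 0.01), np.zeros(5))
        t = np.arange(4.0, 6.0, 0.01)
        with pytest.raises(ValueError, match="increasing"):
            Trace("s", "t", t[::-1], np.zeros_like(t))


class TestSnr:
    def test_lod_boundary(self):
        peak = Peak(5.0, 30.0, 10.0, 0.0, 10.0, 3.0, True)
        assert snr(peak) == 3.0

    def test_loq_boundary(self):
        peak = Peak(5.0, 100.0, 10.0, 0.0, 10.0, 10.0, True)
        assert snr(peak) == 10.0

    def test_noise_floor(self):
        peak = Peak(5.0, 100.0, 10.0, 0.0, 0.0, 100.0, True)
        assert snr(peak) == 100.0  # noise floored at 1 count

    def test_undefined_when_not_found(self):
        peak = Peak(5.0, 1.0, 0.0, 0.0, 10.0, 0.1, False)
        with pytest.raises(ValueError):
            snr(peak)


class TestCoelution:
    def _peak(self, rt, found=True):
        return Peak(rt, 100.0, 10.0, 0.0, 1.0, 100.0, found)

    def test_close_apexes_pass(self):
        assert coelution_check(self._peak(6.40), self._peak(6.42), 0.1)

    def test_far_apexes_fail(self):
        assert not coelution_check(self._peak(6.40), self._peak(6.60), 0.1)

    def test_missing_labelled_fails_named(self):
        result = coelution_check(self._peak(6.4), None, 0.1)
        assert not result and "labelled" in result.reason


class TestQualifierRatio:
    def test_within_band(self):
        assert qualifier_ratio_check(100.0, 50.0, 2.0, 0.3)

    def test_outside_band(self):
        assert not qualifier_ratio_check(100.0, 20.0, 2.0, 0.3)

    def test_boundary_inclusive(self):
        assert qualifier_ratio_check(130.0, 50.0, 2.0, 0.3)  # ratio exactly 2.6

    def test_zero_qualifier_fails(self):
        assert not qualifier_ratio_check(100.0, 0.0, 2.0, 0.3)


class TestBsaNormalize:
    def test_identity_factor(self):
        normalized, factor, failure = bsa_normalize({"A": 10.0}, 1.0, 1.0)
        assert normalized == {"A": 10.0} and factor == 1.0 and not failure

    def test_half_efficiency_doubles_responses(self):
        normalized, factor, failure = bsa_normalize({"A": 10.0, "B": 4.0}, 0.5, 1.0)
        assert normalized == {"A": 20.0, "B": 8.0}
        assert factor == 0.5 and not failure

    def test_doubled_efficiency_removed_exactly(self):
        base = {"A": 10.0, "B": 4.0}
        doubled = {k: 2 * v for k, v in base.items()}
        normalized, factor, failure = bsa_normalize(doubled, 2.0, 1.0)
        assert normalized == base and factor == 2.0 and not failure

    def test_failed_digest_flagged(self):
        _, factor, failure = bsa_normalize({"A": 10.0}, 0.05, 1.0)
        assert failure and factor == 0.05

    def test_absent_bsa_signal(self):
        normalized, factor, failure = bsa_normalize({"A": 10.0}, 0.0, 1.0)
        assert failure and normalized == {"A": 10.0}


class TestQuantifySample:
    def test_unit_ratio_gives_spike_conc(self, opn_transitions):
        traces = simulate.simulate_sample(
            opn_transitions, {"OPN": 50.0},
            simulate.ChromSimParams(multiplicative_cv=0.0, noise_sd=0.0,
                                    rt_jitter_sd=0.0),
            seed=0,
        )
        sq = quantify_sample(traces, opn_transitions)[0]
        assert sq.raw_ratio == pytest.approx(1.0, rel=0.01)
        assert sq.relative_conc == pytest.approx(50.0, rel=0.01)

    def test_double_ratio(self, opn_transitions):
        traces = simulate.simulate_sample(
            opn_transitions, {"OPN": 100.0},
            simulate.ChromSimParams(multiplicative_cv=0.0, noise_sd=0.0,
                                    rt_jitter_sd=0.0),
            seed=0,
        )
        sq = quantify_sample(traces, opn_transitions)[0]
        assert sq.relative_conc == pytest.approx(100.0, rel=0.01)

    def test_missing_labelled_trace_flagged(self, opn_transitions):
        traces = simulate.simulate_sample(opn_transitions, {"OPN": 25.0}, seed=1)
        traces = {
            k: v for k, v in traces.items() if "labelled" not in k or "qualifier" in k
        }
        sq = quantify_sample(traces, opn_transitions)[0]
        assert "missing_trace" in sq.qc_flags
        assert math.isnan(sq.relative_conc)

    def test_round_trip_median_within_5pct(self, opn_transitions):
        for conc in (4.0, 25.0, 100.0):
            recovered = []
            for seed in range(200):
                traces = simulate.simulate_sample(
                    opn_transitions, {"OPN": conc}, seed=seed
                )
                sq = quantify_sample(traces, opn_transitions)[0]
                recovered.append(sq.relative_conc)
            assert np.median(recovered) == pytest.approx(conc, rel=0.05)

    def test_global_scaling_invariance(self, opn_bsa_transitions):
        params = simulate.ChromSimParams(
            multiplicative_cv=0.0, noise_sd=0.0, rt_jitter_sd=0.0
        )
        traces = simulate.simulate_sample(
            opn_bsa_transitions, {"OPN": 25.0}, params, seed=0
        )
        scaled = {
            k: Trace(v.sample_id, v.transition_id, v.time, v.intensity * 3.0)
            for k, v in traces.items()
        }
        sq0 = {s.protein: s for s in quantify_sample(traces, opn_bsa_transitions)}
        sq1 = {s.protein: s for s in quantify_sample(scaled, opn_bsa_transitions)}
        assert sq1["OPN"].relative_conc == pytest.approx(
            sq0["OPN"].relative_conc, rel=0.01
        )

    def test_digest_failure_suppresses_quantification(self, opn_bsa_transitions):
        traces = simulate.simulate_sample(
            opn_bsa_transitions, {"OPN": 25.0}, seed=2, digest_efficiency=0.05
        )
        results = {s.protein: s for s in quantify_sample(traces, opn_bsa_transitions)}
        assert "digest_failure" in results["OPN"].qc_flags
        assert math.isnan(results["OPN"].relative_conc)

    def test_bsa_normalization_removes_2x_digest_factor(self, opn_bsa_transitions):
        params = simulate.ChromSimParams(
            multiplicative_cv=0.0, noise_sd=0.0, rt_jitter_sd=0.0
        )
        nominal = simulate.simulate_sample(
            opn_bsa_transitions, {"OPN": 25.0}, params, seed=0
        )
        boosted = simulate.simulate_sample(
            opn_bsa_transitions, {"OPN": 25.0}, params, seed=0,
            digest_efficiency=2.0,
        )
        sq_nom = {s.protein: s for s in quantify_sample(nominal, opn_bsa_transitions)}
        sq_boost = {s.protein: s for s in quantify_sample(boosted, opn_bsa_transitions)}
        assert sq_boost["OPN"].bsa_factor == pytest.approx(2.0, rel=0.01)
        assert sq_boost["OPN"].relative_conc == pytest.approx(
            sq_nom["OPN"].relative_conc, rel=0.01
        )

    def test_below_loq_flag(self, opn_transitions):
        traces = simulate.simulate_sample(opn_transitions, {"OPN": 2.0}, seed=3)
        sq = quantify_sample(
            traces, opn_transitions, loq_by_protein={"OPN": 5.4}
        )[0]
        assert "below_loq" in sq.qc_flags


def test_quantify_batch_median_bsa_reference(opn_bsa_transitions):
    traces_by_sample = {
        f"u{i}": simulate.simulate_sample(
            opn_bsa_transitions, {"OPN": 25.0}, seed=100 + i
        )
        for i in range(5)
    }
    df = quantify_batch(traces_by_sample, opn_bsa_transitions)
    assert set(df.columns) == {
        "sample_id", "protein", "relative_conc_ng_ml", "raw_ratio",
        "bsa_factor", "snr", "qc_flags",
    }
    opn = df[df.protein == "OPN"]
    assert len(opn) == 5
    assert opn.relative_conc_ng_ml.median() == pytest.approx(25.0, rel=0.1)
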