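"""Normalization identities and halftime-fit accuracy for FRAP/FLIP traces."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nvjquant.photobleach import (
    IntensityTrace,
    OnePhaseModel,
    fit_one_phase,
    flip_normalize,
    frap_double_normalize,
    frap_full_normalize,
    halftime_summary,
)


def make_trace(roi, whole_cell=None, pre=0, bleach=1):
    roi = np.asarray(roi, dtype=float)
    times = np.arange(roi.size, dtype=float) * 0.5
    return IntensityTrace(times=times, roi=roi,
                          whole_cell=None if whole_cell is None else np.asarray(whole_cell, float),
                          pre_index=pre, bleach_index=bleach)


class TestDoubleNormalize:
    def test_hand_computed_example(self):
        """Worked three-frame trace: the whole-cell correction rescales the
        simple ROI normalization frame by frame."""
        trace = make_trace([100, 20, 60], [1000, 900, 900])
        out = frap_double_normalize(trace)
        np.testing.assert_allclose(out.values, [1.0, 0.2222, 0.6667], atol=1e-4)

    def test_pre_frame_is_one(self):
        trace = make_trace([80, 10, 30, 50], [500, 480, 470, 465])
        assert frap_double_normalize(trace).values[0] == pytest.approx(1.0)

    def test_constant_whole_cell_reduces_to_simple_normalization(self):
        trace = make_trace([100, 20, 60, 80], [700, 700, 700, 700])
        out = frap_double_normalize(trace)
        np.testing.assert_allclose(out.values, np.array([100, 20, 60, 80]) / 100.0)

    def test_requires_whole_cell(self):
        with pytest.raises(ValueError, match="whole_cell"):
            frap_double_normalize(make_trace([10, 5, 7]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        roi=st.lists(st.floats(1.0, 1e4), min_size=3, max_size=12),
        wc=st.lists(st.floats(1.0, 1e4), min_size=3, max_size=12),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, roi, wc, c):
        """Rescaling roi and whole_cell by any common factor leaves the
        double-normalized values unchanged."""
        n = min(len(roi), len(wc))
        trace = make_trace(roi[:n], wc[:n])
        scaled = make_trace([c * r for r in roi[:n]], [c * w for w in wc[:n]])
        np.testing.assert_allclose(
            frap_double_normalize(trace).values,
            frap_double_normalize(scaled).values,
            rtol=1e-9,
        )


class TestFullNormalize:
    def test_hand_computed_rescaling(self):
        trace = make_trace([100, 20, 60], [1000, 900, 900])
        out = frap_full_normalize(trace)
        np.testing.assert_allclose(out.values, [1.0, 0.0, 0.5714], atol=1e-4)

    def test_endpoint_identities(self):
        trace = make_trace([80, 10, 30, 50, 74], [500, 480, 470, 465, 464])
        out = frap_full_normalize(trace)
        assert out.values[out.pre_index] == pytest.approx(1.0, abs=1e-12)
        assert out.values[out.bleach_index] == pytest.approx(0.0, abs=1e-12)

    def test_full_recovery_trace_ends_at_one(self):
        trace = make_trace([100, 10, 60, 100], [600, 600, 600, 600])
        assert frap_full_normalize(trace).values[-1] == pytest.approx(1.0)

    def test_idempotent(self):
        trace = make_trace([100, 20, 60, 80], [1000, 900, 900, 880])
        once = frap_full_normalize(trace)
        twice = frap_full_normalize(once)
        np.testing.assert_allclose(once.values, twice.values, rtol=1e-12)

    def test_no_bleach_depth_rejected(self):
        trace = make_trace([100, 100, 100], [500, 500, 500])
        with pytest.raises(ValueError, match="bleach depth"):
            frap_full_normalize(trace)


class TestFlipNormalize:
    def test_hand_computed_example(self):
        out = flip_normalize(make_trace([200, 150, 100]))
        np.testing.assert_allclose(out.values, [1.0, 0.75, 0.5])

    def test_constant_roi_all_ones(self):
        out = flip_normalize(make_trace([300, 300, 300, 300]))
        np.testing.assert_allclose(out.values, 1.0)

    def test_whole_cell_ignored(self):
        a = flip_normalize(make_trace([200, 100]))
        b = flip_normalize(make_trace([200, 100], [900, 400]))
        np.testing.assert_allclose(a.values, b.values)

    def test_zero_pre_rejected(self):
        with pytest.raises(ValueError):
            flip_normalize(make_trace([0, 10, 10]))


class TestOnePhaseFit:
    def test_noise_free_association_halftime(self):
        t = np.arange(0, 25, 0.5)
        y = 0.8 * (1 - np.exp(-0.34657 * t))
        fit = fit_one_phase(t, y, "association")
        assert fit.converged
        assert fit.halftime == pytest.approx(np.log(2) / 0.34657, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.8, abs=1e-6)

    def test_noise_free_decay_halftime(self):
        t = np.arange(0, 300, 6.0)
        y = np.exp(-0.027726 * t)
        fit = fit_one_phase(t, y, "decay")
        assert fit.converged
        assert fit.halftime == pytest.approx(np.log(2) / 0.027726, abs=1e-6)

    def test_halftime_rate_identity(self):
        t = np.arange(0, 20, 0.5)
        fit = fit_one_phase(t, 0.5 * (1 - np.exp(-0.3 * t)), "association")
        assert fit.halftime * fit.rate_k == pytest.approx(np.log(2))

    def test_subsampled_fit_agrees(self):
        """Halving the frame rate moves the noise-free halftime by < 2%."""
        t = np.arange(0, 25, 0.5)
        y = 0.9 * (1 - np.exp(-0.4 * t))
        full = fit_one_phase(t, y, "association").halftime
        sub = fit_one_phase(t[::2], y[::2], "association").halftime
        assert sub == pytest.approx(full, rel=0.02)

    def test_monte_carlo_recovery(self):
        """Median fitted halftime over 200 noisy replicates lands within 5%
        of the true 2.0 s."""
        rng = np.random.default_rng(42)
        t = np.arange(0, 25, 0.5)
        k = np.log(2) / 2.0
        halftimes = []
        for _ in range(200):
            y = 0.8 * (1 - np.exp(-k * t)) + rng.normal(0, 0.02, t.size)
            halftimes.append(fit_one_phase(t, y, "association").halftime)
        assert np.median(halftimes) == pytest.approx(2.0, rel=0.05)

    def test_flat_data_reported_not_silent(self):
        fit = fit_one_phase(np.arange(6.0), np.ones(6), "decay")
        assert not fit.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5 post-bleach"):
            OnePhaseModel([0, 1, 2, 3], [0, 1, 2, 3], "association")

    def test_summary_mentions_halftime(self):
        t = np.arange(0, 25, 0.5)
        fit = fit_one_phase(t, 0.8 * (1 - np.exp(-0.3 * t)), "association")
        assert "halftime" in fit.summary()


class TestHalftimeSummary:
    def ok(self, halftime):
        from nvjquant.photobleach import ExpFitResult
        return ExpFitResult("decay", np.log(2) / halftime, 1.0, 0.0, halftime,
                            0.0, True)

    def bad(self):
        from nvjquant.photobleach import ExpFitResult
        return ExpFitResult("decay", float("nan"), float("nan"), 0.0,
                            float("nan"), float("nan"), False)

    def test_median(self):
        df = halftime_summary([self.ok(1), self.ok(2), self.ok(3)], ["g"] * 3)
        assert df.loc["g", "median_halftime_s"] == 2.0
        assert df.loc["g", "n"] == 3

    def test_nonconverged_excluded(self):
        df = halftime_summary([self.ok(1), self.ok(3), self.bad()], ["g"] * 3)
        assert df.loc["g", "n"] == 2
        assert df.loc["g", "excluded_count"] == 1

    def test_group_ordering_preserved(self):
        rng = np.random.default_rng(1)
        fits, groups = [], []
        for t_half, g in ((25.0, "free"), (100.0, "retained")):
            for _ in range(10):
                fits.append(self.ok(t_half * rng.uniform(0.9, 1.1)))
                groups.append(g)
        df = halftime_summary(fits, groups)
        assert df.loc["retained", "median_halftime_s"] > df.loc["free", "median_halftime_s"]

    def test_all_nonconverged_group_rejected(self):
        with pytest.raises(ValueError, match="no converged"):
            halftime_summary([self.bad()], ["g"])
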