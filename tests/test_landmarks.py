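"""Landmark anatomy and tent-fit tests against constructed geometry."""

import numpy as np
import pytest
from scipy import stats

import ocublink as ob
from ocublink.detect import PotentialBlink
from ocublink.landmarks import compute_landmarks, find_bases, find_zeros, fit_tent, locate_max

from conftest import filtered_from, triangle_trace

SRATE = 256.0


def make_triangle(apex=1000, rise=0.15, fall=0.15, amp=100.0, n=2560, baseline=0.0):
    return filtered_from(triangle_trace(n, SRATE, apex, rise, fall, amp, baseline), SRATE)


class TestLocateMax:
    def test_symmetric_triangle_apex(self):
        f = make_triangle()
        mf, mv = locate_max(f, PotentialBlink(900, 1100))
        assert mf == 1000
        assert mv == pytest.approx(100.0)

    def test_tie_resolves_to_first_frame(self):
        x = np.zeros(100)
        x[40:44] = 5.0
        mf, mv = locate_max(filtered_from(x, SRATE), PotentialBlink(30, 60))
        assert mf == 40 and mv == 5.0

    def test_single_frame_interval(self):
        x = np.arange(10.0)
        mf, mv = locate_max(filtered_from(x, SRATE), PotentialBlink(4, 4))
        assert mf == 4 and mv == 4.0


class TestFindZeros:
    def test_triangle_endpoints(self):
        # rise/fall of 0.125 s = exactly 32 frames, so the feet land on frames
        f = make_triangle(rise=0.125, fall=0.125)
        lz, rz = find_zeros(f, 1000)
        assert lz == 1000 - 32
        assert rz == 1000 + 32

    def test_offset_signal_falls_back_to_argmin(self):
        # trace never reaches zero between the two bumps: fallback = argmin
        x = np.full(2000, 1.0)
        x += triangle_trace(2000, SRATE, 500, 0.1, 0.1, 50.0)
        x += triangle_trace(2000, SRATE, 1500, 0.1, 0.1, 50.0)
        x[1000] = 0.2  # unique inter-blink minimum, still positive
        f = filtered_from(x, SRATE)
        lz, rz = find_zeros(f, 1500, left_limit=527)
        assert lz == 1000

    def test_first_blink_searches_from_signal_start(self):
        # positive ramp from frame 0: no zero crossing anywhere before apex
        x = np.linspace(1.0, 100.0, 500)
        f = filtered_from(x, SRATE)
        lz, _ = find_zeros(f, 499)
        assert lz == 0  # argmin of the full prefix

    def test_brute_force_oracle_on_random_traces(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x = rng.normal(0, 1, 300)
            mf = 150 + int(rng.integers(-30, 30))
            x[mf] = 10.0  # ensure a positive max
            f = filtered_from(x, SRATE)
            lz, rz = find_zeros(f, mf)
            # oracle: scan full prefix/suffix
            left = [i for i in range(0, mf) if x[i] <= 0]
            right = [i for i in range(mf + 1, 300) if x[i] <= 0]
            assert lz == (left[-1] if left else int(np.argmin(x[:mf])))
            assert rz == (right[0] if right else mf + 1 + int(np.argmin(x[mf + 1 :])))


class TestFindBases:
    def test_clean_triangle_bases_equal_zeros(self):
        f = make_triangle(rise=0.1, fall=0.1)
        lz, rz = find_zeros(f, 1000)
        lb, rb, mpv, mnv = find_bases(f, 1000, lz, rz)
        assert lb == lz and rb == rz
        assert lz <= lb < 1000 < rb <= rz

    def test_dip_before_rise_becomes_left_base(self):
        x = triangle_trace(2000, SRATE, 1000, 0.125, 0.125, 100.0)
        foot = 1000 - 32
        dip = foot - 8
        x[dip - 10 : dip + 1] = np.linspace(0.0, -2.0, 11)  # descend into the dip
        x[dip + 1 : foot] = np.linspace(-2.0, -0.1, foot - dip - 1)  # recover
        x[dip] = -2.2  # strict minimum at the dip
        f = filtered_from(x, SRATE)
        lz2, rz2 = find_zeros(f, 1000)
        lb, rb, mpv, _ = find_bases(f, 1000, lz2, rz2)
        # brute-force oracle: first strict local min left of max-velocity frame
        oracle = None
        for fr in range(mpv, 0, -1):
            if x[fr] < x[fr - 1] and x[fr] < x[fr + 1]:
                oracle = fr
                break
        assert oracle is not None and lb == oracle == dip

    def test_plateau_is_traversed(self):
        # plateau of equal samples in the stroke is not a strict local minimum
        x = np.concatenate([np.zeros(50), np.linspace(0, 50, 25), [50, 50, 50],
                            np.linspace(50, 100, 25), np.linspace(100, 0, 50), np.zeros(50)])
        f = filtered_from(x, SRATE)
        mf = int(np.argmax(x))
        lz, rz = find_zeros(f, mf)
        lb, rb, _, _ = find_bases(f, mf, lz, rz)
        assert lb == lz  # plateau skipped, fallback reached

    def test_invariant_ordering(self, default_evaluation):
        # bases flank the peak; they may precede/follow the zero crossings
        # only when a dip pushes them there, never beyond the blink region
        result, _ = default_evaluation
        for lm in result.landmarks:
            if lm.fittable:
                assert lm.leftBase < lm.maxFrame < lm.rightBase
                assert lm.leftZero < lm.maxFrame < lm.rightZero


class TestFitTent:
    def test_perfect_triangle_r2_one_peak_at_apex(self):
        f = make_triangle(rise=0.15, fall=0.15)
        lz, rz = find_zeros(f, 1000)
        tent = fit_tent(f, 1000, 100.0, lz, rz)
        assert tent["leftR2"] == pytest.approx(1.0, abs=1e-9)
        assert tent["rightR2"] == pytest.approx(1.0, abs=1e-9)
        assert tent["tentPeakFrame"] == pytest.approx(1000, abs=1.0)
        assert tent["tentPeakValue"] == pytest.approx(100.0, rel=0.02)

    def test_known_lines_intersection(self):
        # y = x up-stroke and y = -x + 10 down-stroke meet at (5, 5)
        x = np.minimum(np.arange(11.0), -np.arange(11.0) + 10.0)
        f = filtered_from(x, SRATE)
        tent = fit_tent(f, 5, 5.0, 0, 10)
        assert tent["tentPeakFrame"] == pytest.approx(5.0)
        assert tent["tentPeakValue"] == pytest.approx(5.0)
        assert tent["tentLeftXIntercept"] == pytest.approx(0.0)
        assert tent["tentRightXIntercept"] == pytest.approx(10.0)

    def test_half_cosine_matches_independent_ols_oracle(self):
        n = 129
        t = np.linspace(0, np.pi, n)
        bump = 100.0 * np.sin(t)  # rounded symmetric blink
        pad = np.zeros(100)
        x = np.concatenate([pad, bump, pad])
        f = filtered_from(x, SRATE)
        mf = int(np.argmax(x))
        tent = fit_tent(f, mf, float(x[mf]), 100, 100 + n - 1)
        # oracle: direct least-squares on the same inner-80% amplitude window
        up = np.arange(100, mf + 1)
        y = x[up]
        lo = y.min()
        keep = (y >= lo + 0.1 * (x[mf] - lo)) & (y <= lo + 0.9 * (x[mf] - lo))
        xs, ys = up[keep].astype(float), y[keep]
        sl, ic = np.polyfit(xs, ys, 1)
        r = np.corrcoef(xs, ys)[0, 1]
        assert tent["leftR2"] == pytest.approx(r**2, abs=1e-12)
        assert tent["leftFit"][0] == pytest.approx(sl, rel=1e-9)
        assert tent["leftFit"][1] == pytest.approx(ic, rel=1e-9)

    def test_symmetric_blink_has_symmetric_fit(self):
        n = 129
        bump = 100.0 * np.sin(np.linspace(0, np.pi, n))
        x = np.concatenate([np.zeros(100), bump, np.zeros(100)])
        f = filtered_from(x, SRATE)
        mf = int(np.argmax(x))
        tent = fit_tent(f, mf, float(x[mf]), 100, 100 + n - 1)
        assert abs(tent["leftR2"] - tent["rightR2"]) < 1e-6
        assert abs(tent["tentPeakFrame"] - mf) <= 0.5
        # tent circumscribes a concave blink: peak above the trajectory max
        assert tent["tentPeakValue"] >= float(x[mf])

    def test_unfittable_when_too_few_points(self):
        x = np.zeros(50)
        x[10:13] = [1.0, 5.0, 1.0]
        f = filtered_from(x, SRATE)
        tent = fit_tent(f, 11, 5.0, 9, 13)
        assert not tent["fittable"]
        assert tent["leftR2"] == 0.0 and tent["rightR2"] == 0.0

    def test_r2_invariant_under_scaling_and_shift(self):
        n = 129
        bump = np.sin(np.linspace(0, np.pi, n))
        rng = np.random.default_rng(3)
        bump += rng.normal(0, 0.02, n)
        bump[0] = bump[-1] = 0.0

        def r2s(amp, shift):
            x = np.concatenate([np.zeros(100 + shift), amp * bump, np.zeros(100 - shift)])
            f = filtered_from(x, SRATE)
            mf = 100 + shift + int(np.argmax(bump))
            tent = fit_tent(f, mf, float(x[mf]), 100 + shift, 100 + shift + n - 1)
            return tent["leftR2"], tent["rightR2"]

        base = r2s(1.0, 0)
        for amp, shift in [(3.0, 0), (0.5, 20), (100.0, -30)]:
            got = r2s(amp, shift)
            assert got[0] == pytest.approx(base[0], abs=1e-9)
            assert got[1] == pytest.approx(base[1], abs=1e-9)


class TestComputeLandmarks:
    def test_two_blinks_bound_each_other(self):
        x = triangle_trace(3000, SRATE, 800, 0.1, 0.1, 100.0) + triangle_trace(
            3000, SRATE, 2000, 0.1, 0.1, 80.0
        )
        f = filtered_from(x, SRATE)
        blinks = [PotentialBlink(780, 820), PotentialBlink(1980, 2020)]
        lms = compute_landmarks(f, blinks)
        assert len(lms) == 2
        assert lms[0].maxFrame == 800 and lms[1].maxFrame == 2000
        assert lms[0].rightZero <= lms[1].leftZero
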