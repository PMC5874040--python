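"""Count interpolation, temporal offsets, plateau detection, twitch stats."""

import itertools

import numpy as np
import pytest

from embryoalign.errors import PipelineError, ValidationError
from embryoalign.io import CountSeries
from embryoalign.synthetic import CountCurveParams, simulate_count_curve
from embryoalign.temporal import (
    TemporalOffset,
    count_rmse,
    detect_plateaus,
    interpolate_counts,
    temporal_offset,
    twitch_stats,
)


def series(counts, step=10.0, t0=0.0, factor=1):
    counts = np.asarray(counts, float)
    return CountSeries(t0 + step * np.arange(len(counts)), counts, factor)


class TestInterpolateCounts:
    def test_factor_one_identity(self):
        s = series([1, 5, 9])
        out = interpolate_counts(s, 1)
        assert np.array_equal(out.counts, s.counts)
        assert np.array_equal(out.times_min, s.times_min)

    def test_reproduces_raw_samples_and_density(self):
        s = series([60, 80, 120, 190, 194])
        out = interpolate_counts(s, 5)
        assert len(out) == 4 * (len(s) - 1) + len(s)
        assert np.allclose(out.counts[::5], s.counts)
        assert out.interpolation_factor == 5

    def test_monotone_preserving(self, rng):
        raw = np.sort(rng.integers(50, 350, size=20)).astype(float)
        out = interpolate_counts(series(raw), 5)
        assert np.all(np.diff(out.counts) >= -1e-12)
        # dense brute-force evaluation of the same interpolant stays in range
        from scipy.interpolate import PchipInterpolator

        dense = PchipInterpolator(np.arange(20) * 10.0, raw)(np.linspace(0, 190, 2000))
        assert dense.min() >= raw.min() - 1e-9 and dense.max() <= raw.max() + 1e-9

    def test_linear_data_reproduced(self):
        s = series([10, 20, 30, 40])
        out = interpolate_counts(s, 4)
        assert np.allclose(out.counts, 10 + out.times_min / 1.0 * 1.0)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValidationError):
            CountSeries(np.array([0.0, 10.0, 5.0]), np.array([1.0, 2.0, 3.0]))


def brute_force_offset(test, ref, max_offset_min=60.0, min_overlap_frac=0.25, normalized=True):
    """Exhaustive search oracle over integer-lattice offsets."""
    step = test.step_min
    k_max = int(np.floor(max_offset_min / step))
    min_overlap = max(1, int(np.ceil(min_overlap_frac * len(ref))))
    t0 = ref.times_min[0]
    best = None
    for k in range(-k_max, k_max + 1):
        sse, n = 0.0, 0
        for t, c in zip(test.times_min, test.counts):
            target = t + k * step
            j = np.where(np.isclose(ref.times_min - t0, target - t0))[0]
            if len(j):
                sse += (c - ref.counts[j[0]]) ** 2
                n += 1
        if n < min_overlap:
            continue
        score = sse / n if normalized else sse
        if best is None or score < best[0] - 1e-12:
            best = (score, k * step, n)
    return best


class TestTemporalOffset:
    def _interp(self, counts, **kw):
        return interpolate_counts(series(counts, **kw), 5)

    def test_self_offset_zero(self):
        s = self._interp([60, 90, 140, 190, 230, 280, 320, 330])
        off = temporal_offset(s, s)
        assert off.offset_min == 0.0
        assert off.normalized_sse == 0.0

    def test_known_shift_recovered_with_sign(self):
        base = np.array([60, 90, 140, 190, 230, 280, 320, 330, 335, 340], float)
        ref = self._interp(base)
        # test embryo = reference delayed by 4 min (2 interpolated steps)
        from scipy.interpolate import PchipInterpolator

        f = PchipInterpolator(np.arange(10) * 10.0, base)
        delayed = CountSeries(ref.times_min, f(np.maximum(ref.times_min - 4.0, 0)), 5)
        off = temporal_offset(delayed, ref)
        assert off.offset_min == -4.0

    def test_normalization_beats_edge_optimum(self):
        # near-flat curve with a constant count bias and one distinctive
        # bump: the per-point error is constant in the offset, so the raw
        # SSE shrinks with the overlap and runs to the maximal offset;
        # dividing by the overlap restores the true (zero) offset
        ref_counts = np.full(40, 150.0)
        ref_counts[5] = 155.0
        ref = CountSeries(2.0 * np.arange(40), ref_counts, 5)
        test = CountSeries(2.0 * np.arange(40), ref_counts + 2.0, 5)
        raw = brute_force_offset(test, ref, normalized=False)
        norm = brute_force_offset(test, ref, normalized=True)
        assert abs(raw[1]) >= 58.0  # unnormalized runs to the edge
        assert norm[1] == 0.0
        got = temporal_offset(test, ref)
        assert got.offset_min == 0.0
        assert got.overlap_points == norm[2]

    def test_matches_brute_force_oracle(self, rng):
        for i in range(5):
            ref = simulate_count_curve(CountCurveParams(noise_sd=2), seed=50 + i)
            tst = simulate_count_curve(
                CountCurveParams(noise_sd=2), seed=80 + i,
                offset_min=float(rng.integers(-8, 9)) * 2.0,
            )
            ri, ti = interpolate_counts(ref, 5), interpolate_counts(tst, 5)
            got = temporal_offset(ti, ri)
            exp = brute_force_offset(ti, ri)
            assert got.offset_min == exp[1]

    def test_antisymmetry_on_full_overlap(self):
        base = np.array([60, 90, 140, 190, 230, 280, 320, 330], float)
        a = self._interp(base)
        b = self._interp(base)
        assert temporal_offset(a, b).offset_min == -temporal_offset(b, a).offset_min

    def test_no_viable_offset(self):
        a = self._interp([60, 90, 140])
        b = CountSeries(a.times_min + 1000.0, a.counts, a.interpolation_factor)
        with pytest.raises(PipelineError):
            temporal_offset(b, a)


def brute_force_plateaus(s, increment=0.05, max_threshold=20.0):
    """Independent plateau search using itertools.groupby for run finding."""
    pct = [np.inf]
    for prev, cur in zip(s.counts[:-1], s.counts[1:]):
        pct.append(abs((cur - prev) / prev) * 100.0 if prev else np.inf)
    out = []
    for name, (lo, hi) in (("low", (120, 220)), ("high", (220, 350))):
        thr = 0.0
        found = None
        while thr <= max_threshold and found is None:
            flags = [
                (lo < c < hi) and p <= thr + 1e-12 for c, p in zip(s.counts, pct)
            ]
            i = 0
            for key, grp in itertools.groupby(range(len(flags)), key=lambda i: flags[i]):
                grp = list(grp)
                if key and len(grp) > 15:
                    found = (name, [s.times_min[j] for j in grp], thr)
                    break
            thr += increment
        if found:
            out.append(found)
    return out


class TestDetectPlateaus:
    def test_flat_run_at_zero_threshold(self):
        counts = np.concatenate([np.linspace(60, 180, 30), np.full(20, 194.0),
                                 np.linspace(210, 340, 30)])
        s = CountSeries(2.0 * np.arange(len(counts)), counts, 5)
        plats = detect_plateaus(s)
        low = [p for p in plats if p.window == "low"]
        assert len(low) == 1
        assert low[0].threshold_used == 0.0
        # the first flat point carries the jump's % change, so the run
        # starts one index into the flat stretch
        flat_times = 2.0 * np.arange(31, 50)
        assert np.allclose(low[0].member_times_min, flat_times)
        assert low[0].plateau_time_min == pytest.approx(np.mean(flat_times))

    def test_counts_outside_windows_empty(self):
        s = CountSeries(2.0 * np.arange(30), np.linspace(400, 500, 30), 5)
        assert detect_plateaus(s) == []

    def test_disjoint_runs_merge_at_higher_threshold(self):
        # two 10-point flat runs at 150 and 151, joined by a small step:
        # at 0% neither run exceeds 15 points; at a higher threshold the
        # step is tolerated and the merged 22-point run qualifies
        counts = np.concatenate([
            np.linspace(60, 140, 10), np.full(10, 150.0), [150.7], np.full(11, 151.0),
            np.linspace(170, 340, 10),
        ])
        s = CountSeries(2.0 * np.arange(len(counts)), counts, 5)
        plats = detect_plateaus(s)
        low = [p for p in plats if p.window == "low"][0]
        assert low.threshold_used > 0.0
        assert len(low.member_times_min) >= 21
        exp = brute_force_plateaus(s)
        got_exp = [e for e in exp if e[0] == "low"][0]
        assert np.allclose(low.member_times_min, got_exp[1])
        assert low.threshold_used == pytest.approx(got_exp[2])

    def test_matches_brute_force_on_simulated_curves(self):
        for seed in range(4):
            s = interpolate_counts(
                simulate_count_curve(CountCurveParams(noise_sd=2.0), seed=seed), 5
            )
            got = detect_plateaus(s)
            exp = brute_force_plateaus(s)
            assert [p.window for p in got] == [e[0] for e in exp]
            for p, e in zip(got, exp):
                assert np.allclose(p.member_times_min, e[1])
                assert p.threshold_used == pytest.approx(e[2])


class TestTwitchStats:
    def _off(self, vals):
        return [TemporalOffset(v, 0.0, 50) for v in vals]

    def test_equal_corrected_times_zero_sd(self):
        tw = np.array([100.0, 110.0, 120.0])
        st = twitch_stats(tw, self._off([-0.0, -10.0, -20.0]))
        assert st.sd_corrected_min == pytest.approx(0.0)
        assert st.sd_raw_min == pytest.approx(10.0)

    def test_perfect_anticorrelation(self):
        tw = np.array([100.0, 120.0, 140.0, 160.0])
        offs = self._off(list(-(tw - tw.mean())))
        st = twitch_stats(tw, offs)
        assert st.r_offset_twitch == pytest.approx(-1.0)

    def test_correction_reduces_sd_on_simulated_cohort(self, rng):
        true_clock = 270.0
        offsets = rng.uniform(-25, 25, size=12)
        noise = rng.normal(0, 1.0, size=12)
        tw = true_clock - offsets + noise
        st = twitch_stats(tw, self._off(list(offsets)))
        assert st.sd_corrected_min < st.sd_raw_min

    def test_too_few_embryos(self):
        with pytest.raises(ValidationError):
            twitch_stats(np.array([100.0]), self._off([0.0]))


class TestCountRmse:
    def test_offset_correction_reduces_rmse(self):
        ref = interpolate_counts(simulate_count_curve(CountCurveParams(noise_sd=0), seed=1), 5)
        tests, offs = [], []
        for i, true in enumerate([-10.0, 6.0, 14.0]):
            t = interpolate_counts(
                simulate_count_curve(CountCurveParams(noise_sd=0), seed=2 + i, offset_min=true), 5
            )
            tests.append(t)
            offs.append(temporal_offset(t, ref))
        before = count_rmse(tests, ref)
        after = count_rmse(tests, ref, offs)
        assert after < before
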