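"""Temporal registration of embryos from nuclear-count curves.

Developmental clocks of different embryos are offset by imaging start time
and (mildly) by rate differences.  Counts over the slow-imaging window are
interpolated with a monotone piecewise-cubic Hermite polynomial, and a
test embryo is shifted onto the reference by the integer-lattice offset
minimizing the summed squared count difference *normalized by the number
of overlapping points* — without the normalization, the maximal offset
usually wins by shrinking the overlap.

Sign convention: the offset is the value added to the test embryo's clock
to land on the reference clock, i.e. c_test(tau) ~ c_ref(tau + offset).
A test embryo whose curve is a delayed copy of the reference gets a
negative offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import pearsonr

from .errors import PipelineError, ValidationError
from .io import CountSeries

LOW_WINDOW = (120.0, 220.0)  # ~200-cell-stage plateau
HIGH_WINDOW = (220.0, 350.0)  # ball-stage plateau
MIN_RUN_POINTS = 15  # a plateau is a connected run of MORE than this many points


@dataclass(frozen=True)
class TemporalOffset:
    offset_min: float
    normalized_sse: float
    overlap_points: int

    def __post_init__(self) -> None:
        if self.overlap_points < 1:
            raise ValidationError("overlap must contain at least one point")


@dataclass(frozen=True)
class Plateau:
    window: str  # "low" | "high"
    member_times_min: np.ndarray
    threshold_used: float  # |% change| threshold, percentage points

    @property
    def plateau_time_min(self) -> float:
        return float(np.mean(self.member_times_min))


def interpolate_counts(series: CountSeries, factor: int = 5) -> CountSeries:
    """Monotone-preserving cubic Hermite interpolation at factor-x density.

    ``factor - 1`` new samples are inserted between consecutive raw frames;
    original samples are reproduced exactly.
    """
    if factor < 1:
        raise ValidationError("factor must be >= 1")
    if len(series) < 2:
        raise ValidationError("need at least 2 points to interpolate")
    if factor == 1:
        return CountSeries(series.times_min.copy(), series.counts.copy(),
                           series.interpolation_factor)
    interp = PchipInterpolator(series.times_min, series.counts)
    n = len(series)
    times = np.concatenate(
        [
            np.linspace(series.times_min[i], series.times_min[i + 1], factor, endpoint=False)
            for i in range(n - 1)
        ]
        + [series.times_min[-1:]]
    )
    counts = interp(times)
    # exact reproduction of raw samples (guard against round-off)
    counts[::factor] = series.counts
    return CountSeries(times, counts, series.interpolation_factor * factor)


def temporal_offset(
    test: CountSeries,
    ref: CountSeries,
    max_offset_min: float = 60.0,
    min_overlap_frac: float = 0.25,
) -> TemporalOffset:
    """Least-squares temporal offset of a test embryo onto the reference.

    Both series must be sampled on the same lattice step.  Candidate
    offsets are integer multiples of that step within +/-``max_offset_min``;
    for each, SSE over the overlapping lattice points is divided by the
    overlap size, and the minimizing offset returned.  Candidates whose
    overlap is below ``min_overlap_frac`` of the reference window are
    excluded to keep degenerate edge optima out.
    """
    step = test.step_min
    if not np.isclose(step, ref.step_min):
        raise ValidationError(f"lattice steps differ: test {step}, ref {ref.step_min}")
    min_overlap = max(1, int(np.ceil(min_overlap_frac * len(ref))))
    k_max = int(np.floor(max_offset_min / step))

    # integer lattice positions (robust to float times)
    t0 = ref.times_min[0]
    test_idx = np.round((test.times_min - t0) / step).astype(int)
    ref_idx = np.round((ref.times_min - t0) / step).astype(int)
    ref_map = {int(i): c for i, c in zip(ref_idx, ref.counts)}

    best = None
    for k in range(-k_max, k_max + 1):
        # offset = k*step added to test clock: test point at lattice i aligns with ref at i + k
        shifted = test_idx + k
        mask = np.array([i in ref_map for i in shifted])
        overlap = int(mask.sum())
        if overlap < min_overlap:
            continue
        refc = np.array([ref_map[int(i)] for i in shifted[mask]])
        sse = float(np.sum((test.counts[mask] - refc) ** 2))
        score = sse / overlap
        if best is None or score < best[0] - 1e-12:
            best = (score, k, overlap)
    if best is None:
        raise PipelineError("no candidate offset with sufficient overlap")
    score, k, overlap = best
    return TemporalOffset(offset_min=k * step, normalized_sse=score, overlap_points=overlap)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) index ranges of consecutive True runs."""
    runs = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(flags)))
    return runs


def detect_plateaus(
    series: CountSeries,
    threshold_increment: float = 0.05,
    max_threshold: float = 20.0,
) -> list[Plateau]:
    """Find the ~200-cell and ball-stage count plateaus.

    For each count window (120-220 and 220-350 nuclei): restrict to
    in-window interpolated points, flag points whose absolute percentage
    change from the previous interpolated point is <= a threshold, and
    raise the threshold from 0 in small increments until a connected run of
    more than 15 points appears.  That run is the plateau; its time is the
    mean of the member times.
    """
    counts = series.counts
    times = series.times_min
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.abs(np.diff(counts) / counts[:-1]) * 100.0
    pct = np.concatenate([[np.inf], pct])  # first point has no previous
    plateaus: list[Plateau] = []
    for name, (lo, hi) in (("low", LOW_WINDOW), ("high", HIGH_WINDOW)):
        in_win = (counts > lo) & (counts < hi)
        if not np.any(in_win):
            continue
        found = None
        thr = 0.0
        while thr <= max_threshold:
            flags = in_win & (pct <= thr + 1e-12)
            run = next(((a, b) for a, b in _runs(flags) if b - a > MIN_RUN_POINTS), None)
            if run is not None:
                found = (run, thr)
                break
            thr += threshold_increment
        if found is not None:
            (a, b), thr = found
            plateaus.append(
                Plateau(window=name, member_times_min=times[a:b].copy(), threshold_used=thr)
            )
    return plateaus


@dataclass(frozen=True)
class TwitchStats:
    sd_raw_min: float
    sd_corrected_min: float
    r_offset_twitch: float
    r_plateau_twitch: float | None


def twitch_stats(
    twitch_times_min: np.ndarray,
    offsets: list[TemporalOffset],
    plateau_times_min: np.ndarray | None = None,
) -> TwitchStats:
    """Dispersion of twitch-onset times before/after temporal correction.

    The corrected twitch time of an embryo is its raw twitch time plus its
    offset (placing it on the reference clock).  Also reports the Pearson
    correlation between offsets and raw twitch times (strong negative when
    offsets capture true staging differences), and optionally between
    plateau times and twitch times.
    """
    tw = np.asarray(twitch_times_min, dtype=float)
    off = np.array([o.offset_min for o in offsets], dtype=float)
    if len(tw) != len(off):
        raise ValidationError("twitch times and offsets must have equal length")
    if len(tw) < 2:
        raise ValidationError("need at least 2 embryos")
    corrected = tw + off
    r_ot = float(pearsonr(off, tw)[0]) if np.std(off) > 0 and np.std(tw) > 0 else np.nan
    r_pt = None
    if plateau_times_min is not None:
        pt = np.asarray(plateau_times_min, dtype=float)
        if len(pt) != len(tw):
            raise ValidationError("plateau times must match twitch times in length")
        r_pt = float(pearsonr(pt, tw)[0]) if np.std(pt) > 0 and np.std(tw) > 0 else np.nan
    return TwitchStats(
        sd_raw_min=float(np.std(tw, ddof=1)),
        sd_corrected_min=float(np.std(corrected, ddof=1)),
        r_offset_twitch=r_ot,
        r_plateau_twitch=r_pt,
    )


def count_rmse(
    tests: list[CountSeries],
    ref: CountSeries,
    offsets: list[TemporalOffset] | None = None,
) -> float:
    """RMS count error of test embryos vs the reference, normalized per point.

    With ``offsets`` given, each test series is shifted onto the reference
    clock first; the RMSE is computed over all overlapping points of all
    embryos.
    """
    step = ref.step_min
    t0 = ref.times_min[0]
    ref_idx = np.round((ref.times_min - t0) / step).astype(int)
    ref_map = {int(i): c for i, c in zip(ref_idx, ref.counts)}
    sq, n = 0.0, 0
    for j, test in enumerate(tests):
        k = 0 if offsets is None else int(round(offsets[j].offset_min / step))
        shifted = np.round((test.times_min - t0) / step).astype(int) + k
        for i, c in zip(shifted, test.counts):
            if int(i) in ref_map:
                sq += (c - ref_map[int(i)]) ** 2
                n += 1
    if n == 0:
        raise PipelineError("no overlapping points")
    return float(np.sqrt(sq / n))
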