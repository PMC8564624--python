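"""Temperature rate-of-change profiles, rapid-episode detection and overlap tests.

The chain mirrors ice-core-based analyses of climate instability: a series of
temperature (anomalies) against age BP is subsampled to a fixed interval
(default 1000 years), converted to a percent rate of change

    ROC_t = (T_t - T_{t-1}) / T_{t-1} * 100,

where ``t-1`` is the previous (older) sample, optionally smoothed with a
loess-style local linear regression, thresholded into rapid-change episodes,
and compared with inferred split-time intervals by a circular-shift
permutation test.

The percent ROC divides by the lagged value; on anomaly series the
denominator crosses zero, so samples with ``|T_{t-1}|`` below a guard value
are flagged non-finite (NaN) rather than propagated. An absolute-difference
mode (degrees per interval) is provided as a labeled alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ClimateSeries:
    """Ages (years BP, strictly monotone) with temperatures (deg C)."""

    age_bp: np.ndarray
    temp: np.ndarray
    label: str = "temp_c"

    def __post_init__(self) -> None:
        self.age_bp = np.asarray(self.age_bp, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        if self.age_bp.ndim != 1 or self.age_bp.shape != self.temp.shape:
            raise ValueError("age_bp and temp must be 1-D arrays of equal length")
        if len(self.age_bp) == 0:
            raise ValueError("empty climate series")
        d = np.diff(self.age_bp)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ages must be strictly monotone with no duplicates")

    def sorted_past_to_present(self) -> "ClimateSeries":
        """Return a copy ordered oldest-first (descending age BP)."""
        order = np.argsort(-self.age_bp, kind="stable")
        return ClimateSeries(self.age_bp[order], self.temp[order], self.label)

    @property
    def step(self) -> float:
        """Median absolute spacing between consecutive samples."""
        return float(np.median(np.abs(np.diff(self.age_bp))))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.age_bp.min()), float(self.age_bp.max())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age_bp": self.age_bp, self.label: self.temp}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "ClimateSeries":
        df = pd.read_csv(path)
        if "age_bp" not in df.columns or len(df.columns) < 2:
            raise ValueError("climate CSV needs columns age_bp and a value column")
        value_col = [c for c in df.columns if c != "age_bp"][0]
        return cls(df["age_bp"].to_numpy(), df[value_col].to_numpy(), label=value_col)


@dataclass
class EpisodeSet:
    """Rapid-change intervals (start_bp > end_bp), with detection context."""

    intervals: list[tuple[float, float]]
    threshold: float
    source: str
    step: float
    axis_span: tuple[float, float]
    peaks: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end in self.intervals:
            if start <= end:
                raise ValueError("episode intervals must have start_bp > end_bp")

    def total_width(self) -> float:
        return sum(s - e for s, e in self.intervals)

    def covered_fraction(self, lo: float, hi: float) -> float:
        """Fraction of [lo, hi] (ages BP, lo < hi) covered by episodes."""
        if hi <= lo:
            raise ValueError("need lo < hi")
        cov = 0.0
        for start, end in self.intervals:
            cov += max(0.0, min(hi, start) - max(lo, end))
        return cov / (hi - lo)

    def to_tsv(self, path) -> None:
        peaks = self.peaks if self.peaks else [math.nan] * len(self.intervals)
        pd.DataFrame(
            {
                "start_bp": [s for s, _ in self.intervals],
                "end_bp": [e for _, e in self.intervals],
                "peak_roc": peaks,
            }
        ).to_csv(path, sep="\t", index=False)


def resample_series(
    series: ClimateSeries, interval: float = 1000.0, mode: str = "nearest"
) -> ClimateSeries:
    """Subsample to ages at multiples of ``interval`` (default every 1000 years).

    ``nearest`` picks the closest original sample (ties: older); ``linear``
    interpolates between neighbours.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    s = series.sorted_past_to_present()
    lo, hi = s.span
    if hi - lo < 2 * interval:
        raise ValueError("series must span at least two resampling intervals")
    targets = np.arange(math.floor(hi / interval), math.ceil(lo / interval) - 1, -1.0)
    targets *= interval
    targets = targets[(targets >= lo) & (targets <= hi)]
    if mode == "nearest":
        # ages descending; for each target find the closest sample, older on ties
        idx = np.searchsorted(-s.age_bp, -targets)
        idx = np.clip(idx, 1, len(s.age_bp) - 1)
        older = s.age_bp[idx - 1] - targets
        younger = targets - s.age_bp[idx]
        pick = np.where(older <= younger, idx - 1, idx)
        vals = s.temp[pick]
    elif mode == "linear":
        vals = np.interp(targets[::-1], s.age_bp[::-1], s.temp[::-1])[::-1]
    else:
        raise ValueError(f"unknown resampling mode {mode!r}")
    return ClimateSeries(targets, vals, label=series.label)


def rate_of_change(
    series: ClimateSeries, eps_guard: float = 0.1, mode: str = "percent"
) -> ClimateSeries:
    """Rate of change per interval; first (oldest) point is dropped.

    ``percent``: (T_t - T_{t-1}) / T_{t-1} * 100 with the previous, older
    sample as lag; lagged values with magnitude below ``eps_guard`` yield NaN.
    ``absolute``: plain difference T_t - T_{t-1} per interval.
    """
    s = series.sorted_past_to_present()
    if len(s.temp) < 2:
        raise ValueError("rate of change needs at least two points")
    lag = s.temp[:-1]
    cur = s.temp[1:]
    if mode == "percent":
        with np.errstate(divide="ignore", invalid="ignore"):
            roc = (cur - lag) / lag * 100.0
        roc = np.where(np.abs(lag) < eps_guard, np.nan, roc)
        label = "roc_pct"
    elif mode == "absolute":
        roc = cur - lag
        label = "roc_abs"
    else:
        raise ValueError(f"unknown ROC mode {mode!r}")
    return ClimateSeries(s.age_bp[1:], roc, label=label)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def smooth_series(series: ClimateSeries, span: float = 0.05) -> ClimateSeries:
    """Loess-style smoothing: local linear regression with tricube weights.

    For each age, the ``k = max(3, ceil(span * n))`` nearest samples are
    weighted by tricube of distance scaled to the window radius and a
    weighted straight line is evaluated at that age. Exact equivalence with
    any particular statistics package is not claimed; constants and straight
    lines are reproduced to round-off.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    s = series.sorted_past_to_present()
    n = len(s.age_bp)
    k = max(3, math.ceil(span * n))
    if n < max(5, k):
        raise ValueError(f"too few points ({n}) for span {span}")
    x, y = s.age_bp, s.temp
    out = np.empty(n)
    for j in range(n):
        d = np.abs(x - x[j])
        nbr = np.argpartition(d, k - 1)[:k]
        h = d[nbr].max()
        if h == 0:
            out[j] = y[nbr].mean()
            continue
        w = _tricube(d[nbr] / h)
        if w.sum() == 0 or np.count_nonzero(w) < 2:
            w = np.ones_like(w)
        xc = x[nbr] - x[j]
        sw, swx = w.sum(), (w * xc).sum()
        swxx, swy, swxy = (w * xc * xc).sum(), (w * y[nbr]).sum(), (w * xc * y[nbr]).sum()
        denom = sw * swxx - swx * swx
        if denom <= 1e-12 * max(sw * swxx, 1.0):
            out[j] = swy / sw
        else:
            beta = (sw * swxy - swx * swy) / denom
            alpha = (swy - beta * swx) / sw
            out[j] = alpha
    return ClimateSeries(x, out, label=f"{series.label}_smooth")


def detect_episodes(
    roc_series: ClimateSeries,
    quantile_threshold: float = 0.90,
    merge_gap: int = 1,
) -> EpisodeSet:
    """Flag |ROC| exceeding a quantile and merge nearby runs into episodes.

    Runs of flagged samples separated by at most ``merge_gap`` sub-threshold
    samples are merged. Interval edges extend half a step beyond the flagged
    samples so a single-sample episode has width one step.
    """
    s = roc_series.sorted_past_to_present()
    finite = np.isfinite(s.temp)
    if not finite.any():
        raise ValueError("no finite rate-of-change values")
    mag = np.abs(s.temp)
    thr = float(np.quantile(mag[finite], quantile_threshold))
    flagged = finite & (mag > thr)
    step = s.step
    intervals, peaks = [], []
    idx = np.flatnonzero(flagged)
    if idx.size:
        run_start = idx[0]
        prev = idx[0]
        groups = []
        for i in idx[1:]:
            if i - prev - 1 <= merge_gap:
                prev = i
            else:
                groups.append((run_start, prev))
                run_start = prev = i
        groups.append((run_start, prev))
        for a, b in groups:
            intervals.append((s.age_bp[a] + step / 2.0, s.age_bp[b] - step / 2.0))
            seg = mag[a : b + 1]
            peaks.append(float(np.nanmax(seg)))
    lo, hi = s.span
    return EpisodeSet(
        intervals=intervals,
        threshold=thr,
        source=s.label,
        step=step,
        axis_span=(lo - step / 2.0, hi + step / 2.0),
        peaks=peaks,
    )


def interval_episode_overlap(
    split_interval: tuple[float, float],
    episodes: EpisodeSet,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Episode coverage of a split-time interval, with a circular-shift p-value.

    The observed statistic is the fraction of the interval's width covered by
    episodes. The null redistributes the episode mask by a uniform circular
    shift of the time axis; the p-value is the fraction of shifted masks
    whose coverage is at least the observed one. Deterministic under a fixed
    seed.
    """
    lo, hi = sorted(split_interval)
    axis_lo, axis_hi = episodes.axis_span
    if lo < axis_lo or hi > axis_hi:
        raise ValueError("split interval lies outside the climate series span")
    observed = episodes.covered_fraction(lo, hi)
    if not episodes.intervals:
        return 0.0, 1.0
    span = axis_hi - axis_lo
    rng = np.random.default_rng(seed)
    shifts = rng.uniform(0.0, span, size=n_permutations)
    count = 0
    for u in shifts:
        cov = 0.0
        for start, end in episodes.intervals:
            # shift toward the past, wrapping around the axis
            s_ = axis_lo + (start - axis_lo + u) % span
            e_ = s_ - (start - end)
            pieces = [(s_, max(e_, axis_lo))]
            if e_ < axis_lo:  # wrapped
                pieces.append((axis_hi, axis_hi - (axis_lo - e_)))
            for ps, pe in pieces:
                cov += max(0.0, min(hi, ps) - max(lo, pe))
        if cov / (hi - lo) >= observed - 1e-12:
            count += 1
    return observed, count / n_permutations
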