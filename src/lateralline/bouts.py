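"""Per-bout statistics of afferent activity around fictive swimming.

The central quantity is the relative spike rate: the rate during a swim
bout divided by the rate in the immediately preceding, duration-matched
"pre-swim" window.  Inhibition is one minus the relative rate, so a bout
with no afferent spikes at all (quiescence) has inhibition 1 and a bout
whose rate rose during swimming has negative inhibition.  Only bouts with
at least one pre-swim spike are retained for aggregation — a zero pre-swim
rate leaves the ratio undefined.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .containers import BoutRates, SpikeTrain, SwimBout
from .detect import _as_times, instantaneous_rate


@dataclass(frozen=True)
class BoutWindows:
    """Duration-matched pre-swim / swim / post-swim windows of one bout."""

    pre: tuple[float, float]
    swim: tuple[float, float]
    post: tuple[float, float]
    usable: bool


def bout_windows(
    bout: SwimBout,
    recording_start: float = 0.0,
    recording_duration: float = np.inf,
) -> BoutWindows:
    """The three analysis windows of a bout, each of the bout's duration.

    Pre-swim is ``[onset - duration, onset)``, swim ``[onset, offset)``,
    post-swim ``[offset, offset + duration)``.  If the pre- or post-swim
    window would extend beyond the recording, the bout is flagged unusable
    rather than clipped, so retained bouts always have three equal-width
    windows.
    """
    d = bout.duration
    pre = (bout.onset - d, bout.onset)
    swim = (bout.onset, bout.offset)
    post = (bout.offset, bout.offset + d)
    usable = pre[0] >= recording_start and post[1] <= recording_start + recording_duration
    return BoutWindows(pre, swim, post, usable)


def window_rate(spike_train, interval: tuple[float, float]) -> float:
    """Spike count in the half-open interval divided by its width."""
    a, b = interval
    if not b > a:
        raise ValueError(f"zero-width interval [{a}, {b})")
    return _count_in(spike_train, interval) / (b - a)


def _count_in(spike_train, interval: tuple[float, float]) -> int:
    times = _as_times(spike_train)
    a, b = interval
    return int(
        np.searchsorted(times, b, side="left")
        - np.searchsorted(times, a, side="left")
    )


def score_bout(
    spike_train,
    bout: SwimBout,
    recording_duration: float = np.inf,
    recording_start: float = 0.0,
) -> BoutRates:
    """Windowed rates, relative rate, inhibition and class label of one bout.

    The label is ``quiescent`` when no spike fell in the swim window,
    otherwise ``reduced`` when the swim rate is strictly below the pre-swim
    rate, otherwise ``non_reduced`` (ties count as non-reduced).  For
    non-retained bouts (no pre-swim spike) relative rate and inhibition are
    NaN and the label is None.
    """
    w = bout_windows(bout, recording_start, recording_duration)
    if not w.usable:
        raise ValueError("bout windows extend beyond the recording; bout unusable")
    d = bout.duration
    pre_n = _count_in(spike_train, w.pre)
    swim_n = _count_in(spike_train, w.swim)
    post_n = _count_in(spike_train, w.post)
    pre_rate, swim_rate, post_rate = pre_n / d, swim_n / d, post_n / d
    retained = pre_n >= 1
    if retained:
        relative = swim_rate / pre_rate
        inhibition = 1.0 - relative
        if swim_n == 0:
            label = "quiescent"
        elif swim_rate < pre_rate:
            label = "reduced"
        else:
            label = "non_reduced"
    else:
        relative = np.nan
        inhibition = np.nan
        label = None
    return BoutRates(
        bout=bout,
        pre_count=pre_n, swim_count=swim_n, post_count=post_n,
        pre_rate=pre_rate, swim_rate=swim_rate, post_rate=post_rate,
        relative_rate=relative, inhibition=inhibition,
        label=label, retained=retained,
    )


def score_bouts(
    spike_train,
    bouts: list[SwimBout],
    recording_duration: float = np.inf,
    recording_start: float = 0.0,
    exclude_intervals=None,
) -> list[BoutRates]:
    """Score every usable bout, skipping flagged and stimulus-overlapping ones.

    Bouts whose windows reach beyond the recording are dropped, as are
    bouts overlapping any interval in ``exclude_intervals`` (stimulus
    epochs are analysed separately from spontaneous swimming).
    """
    exclude = (
        np.asarray(exclude_intervals, dtype=float).reshape(-1, 2)
        if exclude_intervals is not None
        else np.empty((0, 2))
    )
    out = []
    for bout in bouts:
        w = bout_windows(bout, recording_start, recording_duration)
        if not w.usable:
            continue
        if exclude.size and np.any(
            (bout.onset < exclude[:, 1]) & (bout.offset > exclude[:, 0])
        ):
            continue
        out.append(score_bout(spike_train, bout, recording_duration,
                              recording_start))
    return out


@dataclass(frozen=True)
class ClassificationCounts:
    """Bout-class tallies over retained bouts.

    ``n_reduced`` counts every bout whose swim rate fell below its pre-swim
    rate — including fully quiescent bouts, which are also tallied
    separately in ``n_quiescent`` — so the reduced percentage is always at
    least the quiescent percentage.
    """

    n_retained: int
    n_reduced: int
    n_quiescent: int
    n_non_reduced: int
    pct_reduced: float
    pct_quiescent: float


def classify_counts(bout_rates: list[BoutRates]) -> ClassificationCounts:
    """Tally reduced / quiescent / non-reduced bouts among retained ones."""
    if not bout_rates:
        raise ValueError("empty bout list")
    retained = [b for b in bout_rates if b.retained]
    n = len(retained)
    if n == 0:
        raise ValueError("no retained bouts; percentages undefined")
    n_reduced = sum(1 for b in retained if b.swim_rate < b.pre_rate)
    n_quiescent = sum(1 for b in retained if b.swim_count == 0)
    return ClassificationCounts(
        n_retained=n,
        n_reduced=n_reduced,
        n_quiescent=n_quiescent,
        n_non_reduced=n - n_reduced,
        pct_reduced=100.0 * n_reduced / n,
        pct_quiescent=100.0 * n_quiescent / n,
    )


def mean_inhibition(bout_rates: list[BoutRates], method: str = "per_bout") -> float:
    """Aggregate inhibition over retained bouts.

    ``per_bout`` averages the per-bout inhibition values over retained
    bouts (the descriptive statistic reported per fish); ``pooled``
    computes one minus the ratio of total swim spikes to total pre-swim
    spikes, which is the preferred estimator of the underlying suppression
    fraction: the per-bout ratio is biased when pre-swim counts are small
    (the expectation of 1/count, conditioned on count >= 1, exceeds
    1/expected-count), whereas a ratio of totals needs no retention filter
    at all and so uses every scored bout.
    """
    if method == "per_bout":
        retained = [b for b in bout_rates if b.retained]
        if not retained:
            raise ValueError("no retained bouts")
        return float(np.mean([b.inhibition for b in retained]))
    if method == "pooled":
        pre = sum(b.pre_count for b in bout_rates)
        swim = sum(b.swim_count for b in bout_rates)
        if pre == 0:
            raise ValueError("no pre-swim spikes in any bout")
        return 1.0 - swim / pre
    raise ValueError(f"unknown method {method!r}")


def event_aligned_rate(
    spike_trains,
    bouts,
    span_before_s: float = 1.0,
    span_after_s: float = 1.0,
    window_s: float = 0.100,
    grid_step: float = 0.001,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Bout-onset-aligned average firing rate.

    For every bout the moving-average rate of its fish's spike train is
    evaluated on a grid relative to the bout onset (time 0); curves are
    averaged across bouts.  Every bout contributes to every grid point —
    what changes across the grid is the rate modulation, not the number of
    contributing bouts.  Returns (grid, mean rate, number of bouts).
    """
    if not span_before_s > 0 or not span_after_s > 0:
        raise ValueError("spans must be positive")
    if isinstance(spike_trains, (SpikeTrain, np.ndarray)):
        spike_trains = [spike_trains]
        bouts = [bouts]
    grid = np.arange(-span_before_s, span_after_s + 0.5 * grid_step, grid_step)
    total = np.zeros_like(grid)
    n_bouts = 0
    for train, fish_bouts in zip(spike_trains, bouts):
        times = _as_times(train)
        for bout in fish_bouts:
            onset = bout.onset if isinstance(bout, SwimBout) else float(bout)
            centers = onset + grid
            lo = np.searchsorted(times, centers - window_s / 2, side="left")
            hi = np.searchsorted(times, centers + window_s / 2, side="left")
            total += (hi - lo) / window_s
            n_bouts += 1
    if n_bouts == 0:
        raise ValueError("no bouts to align on")
    return grid, total / n_bouts, n_bouts


def relative_rate_density(
    relative_rates,
    bandwidth: float | None = None,
    grid_size: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of relative swim rates on [0, max(2, data max)].

    Relative rates are nonnegative, so kernel mass below zero is reflected
    back across the boundary and the curve is renormalized to integrate to
    one on the grid.  Bandwidth defaults to Silverman's rule.
    """
    v = np.asarray(relative_rates, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least two values for a density estimate")
    if not np.all(np.isfinite(v)) or np.any(v < 0):
        raise ValueError("relative rates must be finite and nonnegative")
    hi = max(2.0, float(v.max()))
    grid = np.linspace(0.0, hi, grid_size)
    if np.ptp(v) == 0:
        # degenerate sample: a narrow Gaussian bump at the common value
        sd = max(hi / 100.0, 1e-3)
        dens = sps.norm.pdf(grid, v[0], sd) + sps.norm.pdf(-grid, v[0], sd)
    else:
        kde = sps.gaussian_kde(v, bw_method=bandwidth or "silverman")
        dens = kde(grid) + kde(-grid)
    dens = dens / np.trapezoid(dens, grid)
    return grid, dens
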