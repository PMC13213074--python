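"""Conformational-state assignment and population statistics.

Frames are classified into inactive-like, active-like and intermediate-like
states by joint strict thresholds on the two collective variables (the
K745-E762 salt-bridge distance d1 and the E762-D855 distance d2):

* inactive-like:  d1 > 13 A  and  d2 > 12 A
* active-like:    d1 < 7 A   and  d2 < 7 A
* intermediate-like: everything else (including frames exactly on a
  threshold, since the inequalities are strict)

Populations are fractions of frames per state over a half-open time window,
with confidence intervals from the normal approximation to the binomial.
By default n is the raw frame count; an optional effective-sample-size
correction by the integrated autocorrelation time is available for
autocorrelated trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cv import CVFrameSeries, time_window_mask

__all__ = [
    "StateThresholds",
    "PopulationEstimate",
    "ChannelSummary",
    "classify_frames",
    "population_fractions",
    "band_populations",
    "summarize_channel",
    "effective_sample_size",
    "integrated_autocorrelation_time",
    "STATE_LABELS",
]

INACTIVE = "inactive-like"
ACTIVE = "active-like"
INTERMEDIATE = "intermediate-like"
STATE_LABELS = (INACTIVE, INTERMEDIATE, ACTIVE)


@dataclass(frozen=True)
class StateThresholds:
    """Joint 2D cutoffs and 1D band cutpoints defining the states (A)."""

    inactive_d1_gt: float = 13.0
    inactive_d2_gt: float = 12.0
    active_d1_lt: float = 7.0
    active_d2_lt: float = 7.0
    band_cutpoints_1d: tuple[float, ...] = (7.0, 13.0)

    def __post_init__(self) -> None:
        if not (self.active_d1_lt < self.inactive_d1_gt
                and self.active_d2_lt < self.inactive_d2_gt):
            raise ValueError("active thresholds must lie below inactive thresholds")
        cp = tuple(float(c) for c in self.band_cutpoints_1d)
        if any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError("band cutpoints must be strictly increasing")
        object.__setattr__(self, "band_cutpoints_1d", cp)


@dataclass
class PopulationEstimate:
    """Fraction of frames in one state over one time window."""

    state: str
    fraction: float
    ci_half_width: float
    n_frames: int
    window: tuple[float, float] | None = None
    confidence_level: float = 0.95


@dataclass
class ChannelSummary:
    mean: float
    min: float
    max: float
    n_frames: int
    window: tuple[float, float] | None = None


def classify_frames(series: CVFrameSeries, thresholds: StateThresholds | None = None,
                    channels: tuple[str, str] = ("d_K745_E762", "d_E762_D855")) -> np.ndarray:
    """Per-frame state labels from joint strict 2D thresholds."""
    thr = thresholds or StateThresholds()
    d1 = series.channel(channels[0])
    d2 = series.channel(channels[1])
    labels = np.full(len(series), INTERMEDIATE, dtype=object)
    labels[(d1 > thr.inactive_d1_gt) & (d2 > thr.inactive_d2_gt)] = INACTIVE
    labels[(d1 < thr.active_d1_lt) & (d2 < thr.active_d2_lt)] = ACTIVE
    return labels


def population_fractions(labels, confidence_level: float = 0.95,
                         states: tuple[str, ...] | None = None,
                         window: tuple[float, float] | None = None,
                         correct_autocorrelation: bool = False) -> list[PopulationEstimate]:
    """Per-state fractions with normal-approximation binomial intervals.

    ``ci_half_width = z * sqrt(p (1 - p) / n)`` with z from the two-sided
    *confidence_level*.  With ``correct_autocorrelation=True`` n is the
    effective sample size of each state's indicator series (raw count
    divided by the integrated autocorrelation time) instead of the raw
    frame count.
    """
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    if n == 0:
        raise ValueError("cannot estimate populations from an empty label sequence")
    if not 0 < confidence_level < 1:
        raise ValueError("confidence_level must be in (0, 1)")
    if states is None:
        known = [s for s in STATE_LABELS if s in labels]
        extra = [s for s in dict.fromkeys(labels) if s not in STATE_LABELS]
        states = tuple(known + extra)
    z = stats.norm.ppf(0.5 + confidence_level / 2.0)
    out = []
    for state in states:
        indicator = (labels == state)
        p = indicator.mean()
        n_eff = float(n)
        if correct_autocorrelation and 0.0 < p < 1.0:
            n_eff = effective_sample_size(indicator.astype(float))
        half = z * np.sqrt(p * (1.0 - p) / n_eff)
        out.append(PopulationEstimate(state, float(p), float(half), n,
                                      window=window, confidence_level=confidence_level))
    return out


def band_populations(values, cutpoints, times_ns=None,
                     window: tuple[float, float] | None = None) -> dict[str, float]:
    """Fractions of frames in 1D distance bands over a time window.

    Bands are ``(-inf, c1), [c1, c2), ..., [ck, inf)`` for strictly
    increasing cutpoints; the window is half-open ``[start, end)`` ns.
    Fractions sum to 1.
    """
    values = np.asarray(values, dtype=float)
    cutpoints = [float(c) for c in np.atleast_1d(cutpoints)]
    if any(b <= a for a, b in zip(cutpoints, cutpoints[1:])):
        raise ValueError("cutpoints must be strictly increasing")
    if window is not None:
        if times_ns is None:
            raise ValueError("times_ns required when a window is given")
        mask = time_window_mask(times_ns, window)
        values = values[mask]
    if values.size == 0:
        raise ValueError("no frames in the requested window")
    edges = [-np.inf] + cutpoints + [np.inf]
    counts, _ = np.histogram(values, bins=edges)
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        lo_s = "-inf" if np.isinf(lo) else f"{lo:g}"
        hi_s = "inf" if np.isinf(hi) else f"{hi:g}"
        left = "(" if np.isinf(lo) else "["
        labels.append(f"{left}{lo_s}, {hi_s})")
    return {lab: c / values.size for lab, c in zip(labels, counts)}


def summarize_channel(values, times_ns=None,
                      window: tuple[float, float] | None = None) -> ChannelSummary:
    """Mean and extrema of a channel over a half-open time window."""
    values = np.asarray(values, dtype=float)
    if window is not None:
        if times_ns is None:
            raise ValueError("times_ns required when a window is given")
        values = values[time_window_mask(times_ns, window)]
    if values.size == 0:
        raise ValueError("no frames in the requested window")
    return ChannelSummary(mean=float(values.mean()), min=float(values.min()),
                          max=float(values.max()), n_frames=int(values.size),
                          window=window)


# ---------------------------------------------------------------------------
# autocorrelation utilities


def integrated_autocorrelation_time(x) -> float:
    """Integrated autocorrelation time via Geyer's initial positive sequence.

    ``tau = -1 + 2 * sum_m max(Gamma_m, 0)`` where
    ``Gamma_m = rho(2m) + rho(2m + 1)``, truncated at the first
    non-positive pair sum.  For an uncorrelated series tau ~= 1.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 1.0
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return 1.0
    # autocovariance by FFT
    f = np.fft.rfft(x, 2 * n)
    acov = np.fft.irfft(f * np.conj(f))[:n] / n
    rho = acov / acov[0]
    tau = -1.0
    for m in range(n // 2):
        gamma = rho[2 * m] + (rho[2 * m + 1] if 2 * m + 1 < n else 0.0)
        if gamma <= 0:
            break
        tau += 2.0 * gamma
    return max(tau, 1.0)


def effective_sample_size(x) -> float:
    """n / tau -- the number of effectively independent samples."""
    x = np.asarray(x, dtype=float)
    return x.size / integrated_autocorrelation_time(x)
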