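"""Block-averaging convergence statistics for CV time series.

A time-series window is split into contiguous blocks of equal frame count
(remainder frames joining the final block); the spread of the block means
is the convergence diagnostic.  The reported uncertainty is the sample
standard deviation of the block means -- deliberately the conservative
choice, not the standard error; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cv import time_window_mask

__all__ = ["BlockStats", "block_average", "window_compare", "WindowComparison"]


@dataclass
class BlockStats:
    channel: str
    window: tuple[float, float] | None
    n_blocks: int
    block_means: np.ndarray
    mean: float
    uncertainty: float  # sample SD of block means; NaN when n_blocks == 1
    n_frames: int


def block_average(values, n_blocks: int = 5, times_ns=None,
                  window: tuple[float, float] | None = None,
                  channel: str = "") -> BlockStats:
    """Contiguous equal-count block averages of a (windowed) channel.

    With ``n_blocks=1`` the mean is the plain mean and the uncertainty is
    NaN (a single block has no spread).
    """
    values = np.asarray(values, dtype=float)
    if window is not None:
        if times_ns is None:
            raise ValueError("times_ns required when a window is given")
        values = values[time_window_mask(times_ns, window)]
    n = values.size
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if n < n_blocks:
        raise ValueError(f"n_blocks={n_blocks} exceeds the {n} frames available")
    per = n // n_blocks
    block_means = np.array([
        values[k * per: (k + 1) * per if k < n_blocks - 1 else n].mean()
        for k in range(n_blocks)
    ])
    mean = float(block_means.mean()) if n % n_blocks == 0 else float(values.mean())
    unc = float(block_means.std(ddof=1)) if n_blocks > 1 else float("nan")
    return BlockStats(channel=channel, window=window, n_blocks=n_blocks,
                      block_means=block_means, mean=mean, uncertainty=unc,
                      n_frames=n)


@dataclass
class WindowComparison:
    stats_a: BlockStats
    stats_b: BlockStats
    mean_difference: float  # mean(b) - mean(a)
    windows_overlap: bool


def window_compare(values, times_ns, window_a: tuple[float, float],
                   window_b: tuple[float, float], n_blocks: int = 5,
                   channel: str = "") -> WindowComparison:
    """Side-by-side block statistics for two time windows (drift check).

    Overlapping windows are permitted but flagged.
    """
    a = block_average(values, n_blocks=n_blocks, times_ns=times_ns,
                      window=window_a, channel=channel)
    b = block_average(values, n_blocks=n_blocks, times_ns=times_ns,
                      window=window_b, channel=channel)
    overlap = (window_a[0] < window_b[1]) and (window_b[0] < window_a[1])
    return WindowComparison(stats_a=a, stats_b=b,
                            mean_difference=b.mean - a.mean,
                            windows_overlap=bool(overlap))
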