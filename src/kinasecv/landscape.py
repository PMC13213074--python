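"""Free-energy surfaces and kernel-density distance distributions.

A 2D free-energy surface over a pair of collective variables is obtained
by Boltzmann inversion of the binned empirical probability,
``G = -kB T ln P``, shifted so the global minimum is 0 and with empty bins
masked.  1D kernel-density estimates of single distances use a Gaussian
kernel with Silverman's rule bandwidth by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cv import CVFrameSeries

__all__ = ["FES2D", "DensityCurve", "free_energy_surface", "kde_density",
           "BOLTZMANN_KCAL"]

#: Boltzmann constant in kcal mol^-1 K^-1
BOLTZMANN_KCAL = 0.0019872041


@dataclass
class FES2D:
    """Binned 2D free-energy surface.

    ``free_energy`` is in kcal/mol, NaN on empty bins; ``mask`` is True
    exactly where the occupancy count is 0; the finite minimum is 0.
    """

    edges_x: np.ndarray
    edges_y: np.ndarray
    counts: np.ndarray
    free_energy: np.ndarray
    mask: np.ndarray
    temperature: float
    boltzmann_constant: float = BOLTZMANN_KCAL
    channel_names: tuple[str, str] = ("d1", "d2")
    metadata: dict = field(default_factory=dict)

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def centers_x(self) -> np.ndarray:
        return 0.5 * (self.edges_x[:-1] + self.edges_x[1:])

    @property
    def centers_y(self) -> np.ndarray:
        return 0.5 * (self.edges_y[:-1] + self.edges_y[1:])

    def minimum_location(self) -> tuple[float, float]:
        """CV coordinates of the bin with the lowest free energy."""
        g = np.where(self.mask, np.inf, self.free_energy)
        i, j = np.unravel_index(np.argmin(g), g.shape)
        return float(self.centers_x[i]), float(self.centers_y[j])

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: bin_i, bin_j, centers, count, G, masked."""
        nx, ny = self.counts.shape
        ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        return pd.DataFrame({
            "bin_i": ii.ravel(),
            "bin_j": jj.ravel(),
            f"{self.channel_names[0]}_center": self.centers_x[ii.ravel()],
            f"{self.channel_names[1]}_center": self.centers_y[jj.ravel()],
            "count": self.counts.ravel().astype(int),
            "G_kcal_mol": self.free_energy.ravel(),
            "masked": self.mask.ravel(),
        })


def free_energy_surface(series: CVFrameSeries,
                        channels: tuple[str, str] | None = None,
                        n_bins: int | tuple[int, int] = 100,
                        temperature: float = 300.0,
                        padding: float = 0.5,
                        ranges: tuple[tuple[float, float], tuple[float, float]] | None = None,
                        ) -> FES2D:
    """Boltzmann-inverted free-energy surface of two CV channels.

    Bins span the data min/max padded by *padding* angstrom unless
    explicit *ranges* are given.  Occupied bins get
    ``G = -kB T ln(count / total)`` shifted to a zero minimum; empty bins
    are masked (NaN).  A zero-variance channel still yields a defined
    surface (all frames in one column of bins).
    """
    if channels is None:
        names = series.channel_names
        if len(names) < 2:
            raise ValueError("series must have at least two channels for a 2D surface")
        channels = (names[0], names[1])
    if isinstance(n_bins, int):
        n_bins = (n_bins, n_bins)
    if min(n_bins) < 2:
        raise ValueError("n_bins must be >= 2 per axis")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    x = series.channel(channels[0])
    y = series.channel(channels[1])
    if ranges is None:
        ranges = ((x.min() - padding, x.max() + padding),
                  (y.min() - padding, y.max() + padding))
    counts, ex, ey = np.histogram2d(x, y, bins=n_bins, range=ranges)
    total = counts.sum()
    mask = counts == 0
    kT = BOLTZMANN_KCAL * temperature
    with np.errstate(divide="ignore"):
        g = -kT * np.log(np.where(mask, np.nan, counts / total))
    g = g - np.nanmin(g)
    g[mask] = np.nan
    return FES2D(edges_x=ex, edges_y=ey, counts=counts, free_energy=g, mask=mask,
                 temperature=temperature, channel_names=channels,
                 metadata={"n_bins": n_bins, "padding": padding,
                           "n_frames": int(total)})


@dataclass
class DensityCurve:
    """Gaussian-kernel density estimate on an evaluation grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def local_maxima(self) -> np.ndarray:
        """Grid locations of interior local maxima of the density."""
        d = self.density
        idx = np.nonzero((d[1:-1] > d[:-2]) & (d[1:-1] > d[2:]))[0] + 1
        return self.grid[idx]


def _silverman_bandwidth(values: np.ndarray) -> float:
    n = values.size
    sd = values.std(ddof=1)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * scale * n ** (-1.0 / 5.0)


def kde_density(values, bandwidth="silverman", grid=None,
                gridsize: int = 512) -> DensityCurve:
    """Gaussian KDE of a distance sample.

    *bandwidth* is either a rule name (``"silverman"``) or an explicit
    kernel standard deviation in angstrom.  A rule that evaluates to a
    non-positive bandwidth (e.g. Silverman on a zero-variance sample) is
    an error; pass an explicit bandwidth for degenerate samples.  The
    default grid spans the data range extended by 4 bandwidths, so the
    curve integrates to ~1.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("kde_density requires at least 2 values")
    if isinstance(bandwidth, str):
        if bandwidth != "silverman":
            raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
        h = _silverman_bandwidth(values)
    else:
        h = float(bandwidth)
    if h <= 0:
        raise ValueError(
            f"bandwidth must be positive, got {h}; pass an explicit bandwidth "
            "for zero-variance samples"
        )
    if grid is None:
        grid = np.linspace(values.min() - 4 * h, values.max() + 4 * h, gridsize)
    else:
        grid = np.asarray(grid, dtype=float)
    sd = values.std(ddof=1)
    if sd > 0:
        kde = stats.gaussian_kde(values, bw_method=h / sd)
        density = kde(grid)
    else:
        # all values identical: the KDE is a single Gaussian at that value
        density = stats.norm.pdf(grid, loc=values[0], scale=h)
    return DensityCurve(grid=grid, density=density, bandwidth=h)
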