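"""Core data model for full-spectral FLIM photon-count cubes.

A full-spectral FLIM (FS-FLIM) acquisition produces, for every image pixel, a
time-correlated single-photon-counting (TCSPC) histogram in each of many
spectral channels.  The central object is therefore a 4-D non-negative integer
cube indexed ``(row, col, spectral_channel, time_bin)``, together with the axis
metadata needed to interpret channel indices as wavelengths and bin indices as
arrival delays.

Conventions
-----------
* Channels and bins are half-open intervals, 0-based: channel ``k`` covers
  ``[lambda_min + k*dl, lambda_min + (k+1)*dl)`` and bin ``j`` covers
  ``[t0 + j*dt, t0 + (j+1)*dt)``.  Centers sit at the interval midpoints.
* Arrays are row-major ``(row, col, channel, bin)``.
* Counts are stored as unsigned 32-bit words regardless of the on-sensor bit
  depth, so 10-bit (raw) and 20-bit (chained) cubes share one layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralAxis",
    "TimeAxis",
    "SensorConfig",
    "FlimCube",
    "make_spectral_axis",
    "wavelength_to_channel",
    "cube_storage_bits",
    "default_pde_curve",
]


@dataclass(frozen=True)
class SpectralAxis:
    """Uniform channel-to-wavelength mapping.

    Parameters
    ----------
    n_channels : int
        Number of spectral channels (512 on the line sensor).
    lambda_min, lambda_max : float
        Wavelength range in nm covered by the sensor (default 500-760 nm).
        ``lambda_min`` is the lower *edge* of channel 0 and ``lambda_max`` the
        upper edge of the last channel.
    """

    n_channels: int = 512
    lambda_min: float = 500.0
    lambda_max: float = 760.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if not self.lambda_max > self.lambda_min:
            raise ValueError(
                f"inverted wavelength range: [{self.lambda_min}, {self.lambda_max}]"
            )

    @property
    def delta(self) -> float:
        """Channel width in nm (constant across channels)."""
        return (self.lambda_max - self.lambda_min) / self.n_channels

    @property
    def edges(self) -> np.ndarray:
        """``n_channels + 1`` channel edges in nm."""
        return np.linspace(self.lambda_min, self.lambda_max, self.n_channels + 1)

    @property
    def centers(self) -> np.ndarray:
        """Channel center wavelengths in nm."""
        return self.lambda_min + (np.arange(self.n_channels) + 0.5) * self.delta


@dataclass(frozen=True)
class TimeAxis:
    """Uniform time-bin axis of the on-chip TCSPC histogram.

    ``n_bins`` is 32 in raw mode and 16 after pairwise bin chaining.  The
    default 50 ns laser period corresponds to 20 MHz pulsed excitation.
    """

    n_bins: int = 32
    bin_width: float = 1.5625  # ns; 32 bins spanning the 50 ns period
    t0_offset: float = 0.0
    laser_period: float = 50.0

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be > 0, got {self.bin_width}")
        span = self.n_bins * self.bin_width
        if span > self.laser_period * (1 + 1e-12):
            raise ValueError(
                f"time window {span} ns exceeds laser period {self.laser_period} ns"
            )

    @property
    def edges(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.n_bins + 1) * self.bin_width

    @property
    def centers(self) -> np.ndarray:
        return self.t0_offset + (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def span(self) -> float:
        """Total observation window in ns."""
        return self.n_bins * self.bin_width


@dataclass(frozen=True)
class SensorConfig:
    """SPAD line-sensor characteristics.

    Parameters
    ----------
    bit_depth : int
        Bits per per-bin counter (10 on-chip; chaining pairs gives 20).
    dark_count_rate : float or ndarray
        Dark counts per second per spectral channel.  A scalar applies the
        same rate to every channel; an array gives per-channel rates.
    pde_curve : ndarray or None
        Photon detection efficiency per spectral channel, in [0, 1].  ``None``
        means a flat curve at ``pde_peak``.
    pde_peak : float
        Peak detection efficiency (0.17 for this sensor).
    irf_fwhm : float
        Instrument-response FWHM in ps (laser pulse + timing jitter; <100 ps).
    """

    bit_depth: int = 10
    dark_count_rate: float | np.ndarray = 0.0
    pde_curve: np.ndarray | None = None
    pde_peak: float = 0.17
    irf_fwhm: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pde_peak <= 1.0:
            raise ValueError(f"pde_peak must be in (0, 1], got {self.pde_peak}")
        if np.any(np.asarray(self.dark_count_rate) < 0):
            raise ValueError("dark_count_rate must be >= 0")
        if self.pde_curve is not None:
            pde = np.asarray(self.pde_curve, dtype=float)
            if np.any(pde < 0) or np.any(pde > self.pde_peak + 1e-12):
                raise ValueError("pde_curve must satisfy 0 <= pde <= pde_peak")
        if self.irf_fwhm < 0:
            raise ValueError("irf_fwhm must be >= 0")

    @property
    def counter_capacity(self) -> int:
        """Maximum count a single per-bin counter can hold (2^bits - 1)."""
        return 2**self.bit_depth - 1

    def pde_at(self, n_channels: int) -> np.ndarray:
        """Per-channel PDE array, materializing the flat default."""
        if self.pde_curve is None:
            return np.full(n_channels, self.pde_peak)
        pde = np.asarray(self.pde_curve, dtype=float)
        if pde.shape != (n_channels,):
            raise ValueError(
                f"pde_curve has {pde.shape} entries, expected ({n_channels},)"
            )
        return pde

    def dark_rate_at(self, n_channels: int) -> np.ndarray:
        """Per-channel dark-count rate array (counts/s)."""
        rate = np.asarray(self.dark_count_rate, dtype=float)
        if rate.ndim == 0:
            return np.full(n_channels, float(rate))
        if rate.shape != (n_channels,):
            raise ValueError(
                f"dark_count_rate has {rate.shape} entries, expected ({n_channels},)"
            )
        return rate


# Counter capacities: a raw cube uses 10-bit per-bin counters; chaining merges
# counter pairs into a single 20-bit word.
CHAINED_BIT_DEPTH = 20


@dataclass
class FlimCube:
    """4-D photon-count cube ``(row, col, spectral_channel, time_bin)``.

    ``chained`` marks a cube whose time bins are merged counter pairs and are
    therefore bounded by 2^20 - 1 rather than 2^10 - 1.
    ``dwell_time`` is the per-pixel exposure in µs.
    """

    counts: np.ndarray
    spectral_axis: SpectralAxis = field(default_factory=SpectralAxis)
    time_axis: TimeAxis = field(default_factory=TimeAxis)
    chained: bool = False
    dwell_time: float = 500.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.counts.shape

    @property
    def capacity(self) -> int:
        """Per-bin counter bound: 2^10 - 1 raw, 2^20 - 1 chained."""
        bits = CHAINED_BIT_DEPTH if self.chained else 10
        return 2**bits - 1

    def validate(self) -> None:
        """Check structural invariants, raising ``ValueError`` on violation."""
        c = self.counts
        if c.ndim != 4:
            raise ValueError(f"counts must be 4-D (row, col, channel, bin), got {c.ndim}-D")
        if not np.issubdtype(c.dtype, np.integer):
            raise ValueError(f"counts must be integer-typed, got {c.dtype}")
        if np.any(c < 0):
            raise ValueError("negative photon counts")
        if c.shape[2] != self.spectral_axis.n_channels:
            raise ValueError(
                f"spectral extent {c.shape[2]} != axis n_channels "
                f"{self.spectral_axis.n_channels}"
            )
        if c.shape[3] != self.time_axis.n_bins:
            raise ValueError(
                f"time extent {c.shape[3]} != axis n_bins {self.time_axis.n_bins}"
            )
        if c.size and int(c.max()) > self.capacity:
            raise ValueError(
                f"count {int(c.max())} exceeds "
                f"{'20-bit chained' if self.chained else '10-bit'} "
                f"capacity {self.capacity}"
            )
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be > 0")


def make_spectral_axis(
    n_channels: int = 512, lambda_min: float = 500.0, lambda_max: float = 760.0
) -> SpectralAxis:
    """Build a uniform spectral axis.

    The instrument configuration (512 channels over 500-760 nm) gives a channel
    width of 260/512 ≈ 0.508 nm, i.e. ~0.5 nm spectral resolution.
    """
    return SpectralAxis(n_channels=n_channels, lambda_min=lambda_min, lambda_max=lambda_max)


def wavelength_to_channel(axis: SpectralAxis, wavelength: float) -> int:
    """Channel index whose half-open interval contains ``wavelength`` (nm).

    Raises
    ------
    ValueError
        If the wavelength lies outside ``[lambda_min, lambda_max)``.
    """
    if not (axis.lambda_min <= wavelength < axis.lambda_max):
        raise ValueError(
            f"wavelength {wavelength} nm outside axis range "
            f"[{axis.lambda_min}, {axis.lambda_max}) nm"
        )
    k = int((wavelength - axis.lambda_min) / axis.delta)
    # guard against floating-point landing exactly on an upper edge
    return min(k, axis.n_channels - 1)


def cube_storage_bits(
    rows: int, cols: int, n_channels: int, n_bins: int, word_bits: int = 32
) -> int:
    """Total storage, in bits, of a dense count cube at a given word size.

    For the full acquisition geometry (256 × 256 pixels, 512 channels, 16
    chained bins, 32-bit words) this is 2^34 bits = 16 Gib — the theoretical
    maximum transfer per frame.
    """
    for name, v in (
        ("rows", rows),
        ("cols", cols),
        ("n_channels", n_channels),
        ("n_bins", n_bins),
        ("word_bits", word_bits),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return rows * cols * n_channels * n_bins * word_bits


def default_pde_curve(axis: SpectralAxis, peak: float = 0.17) -> np.ndarray:
    """Smooth silicon-SPAD-like detection-efficiency curve.

    A Gaussian in wavelength peaking at ``peak`` near 550 nm with a 300 nm
    FWHM, floored at 20% of peak so every channel stays correctable.  This is
    a documented synthetic stand-in for the (unpublished) measured sensor
    response; its only load-bearing properties are positivity and a peak of
    ``peak``.
    """
    centers = axis.centers
    sigma = 300.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    curve = peak * np.exp(-0.5 * ((centers - 550.0) / sigma) ** 2)
    return np.maximum(curve, 0.2 * peak)
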