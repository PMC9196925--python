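"""Core data containers for multispectral FLIM (maFLIM) analysis.

A maFLIM acquisition records, at every pixel, one fluorescence decay per
emission channel (390, 452 and >496 nm bands, referred to as 390/452/500),
sampled on a common time base.  The instrument response function (IRF) is
recorded per channel on the same time base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Emission channel labels in concatenation order (nm).
CHANNELS: tuple[int, int, int] = (390, 452, 500)

BENIGN = "benign"
MALIGNANT = "malignant"


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry and timing of the maFLIM dermoscope.

    Parameters
    ----------
    rows, cols : int
        Pixel grid size (default 140x140).
    dt : float
        Temporal sample spacing in ns.  Must equal ``1e9 / sampling_rate``.
    n_samples_per_channel : int
        Decay length per emission channel (149 samples -> 59.6 ns at 0.4 ns).
    sampling_rate : float
        Digitizer rate in Hz (2.5 GHz).
    pixel_rate : float
        Scan rate in pixels per second (10 kHz).
    channels : tuple of int
        Ordered emission-band labels; exactly three.
    """

    rows: int = 140
    cols: int = 140
    dt: float = 0.4
    n_samples_per_channel: int = 149
    sampling_rate: float = 2.5e9
    pixel_rate: float = 1.0e4
    channels: tuple[int, ...] = CHANNELS

    def __post_init__(self) -> None:
        if len(self.channels) != 3:
            raise ValueError("exactly three emission channels are required")
        if self.n_samples_per_channel < 1:
            raise ValueError("n_samples_per_channel must be >= 1")
        if not np.isclose(self.dt, 1e9 / self.sampling_rate, rtol=1e-9):
            raise ValueError("dt must equal 1/sampling_rate expressed in ns")

    @property
    def time_ns(self) -> np.ndarray:
        """Sample times of one channel, in ns (starting at 0)."""
        return np.arange(self.n_samples_per_channel) * self.dt

    @property
    def channel_duration_ns(self) -> float:
        """Duration of one channel's acquisition window in ns."""
        return self.n_samples_per_channel * self.dt

    @property
    def acquisition_time_s(self) -> float:
        """Time to scan one full image, in seconds."""
        return self.rows * self.cols / self.pixel_rate


@dataclass
class InstrumentResponse:
    """Per-channel instrument response functions on a shared time base.

    ``gaussian_params`` optionally records the analytic (fwhm_ns, t0_ns) of
    each channel's pulse when the IRF is a known Gaussian; fitting and
    simulation then use exact continuous-time convolution instead of a
    discrete approximation.
    """

    channels: dict[int, np.ndarray]
    dt: float
    gaussian_params: dict[int, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        lengths = {len(u) for u in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channel IRFs must share one time base")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


@dataclass
class TimeResolvedImage:
    """Three-channel per-pixel fluorescence decay cube.

    ``channels`` maps emission band -> array of shape (rows, cols, T).
    Channels may have different native lengths T (zero padding harmonises
    them at concatenation time); all share the pixel grid and ``dt``.
    """

    channels: dict[int, np.ndarray]
    dt: float
    adc_max: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {arr.shape[:2] for arr in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share the pixel grid")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[:2]

    @property
    def channel_order(self) -> tuple[int, ...]:
        return tuple(sorted(self.channels))

    def copy(self) -> "TimeResolvedImage":
        return TimeResolvedImage(
            channels={c: a.copy() for c, a in self.channels.items()},
            dt=self.dt,
            adc_max=self.adc_max,
            meta=dict(self.meta),
        )


@dataclass
class ConcatenatedImage:
    """Channel-concatenated decay cube of shape (rows, cols, 3*M).

    Each channel is zero padded at its tail to the longest channel length M
    and the three are laid end to end in channel order, mirroring the
    concatenated-signal representation used for clustering and for
    frequency-domain deconvolution.
    """

    data: np.ndarray
    dt: float
    segment_length: int
    channel_order: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.data.shape[-1] != 3 * self.segment_length:
            raise ValueError("concatenated length must be 3*M")

    def segment(self, channel: int) -> np.ndarray:
        """Slice out one channel's padded segment (inverse of concatenation)."""
        i = self.channel_order.index(channel)
        M = self.segment_length
        return self.data[..., i * M : (i + 1) * M]


@dataclass
class RegionMasks:
    """Validity mask plus two exclusive cluster masks over a pixel grid.

    ``region1 & region2`` is empty and ``region1 | region2`` equals ``valid``.
    Region numbering is arbitrary (K-means label order); every global feature
    downstream is invariant to swapping the two.
    """

    valid: np.ndarray
    region1: np.ndarray
    region2: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.region1 & self.region2):
            raise ValueError("region masks must be exclusive")
        if not np.array_equal(self.region1 | self.region2, self.valid):
            raise ValueError("region masks must partition the valid mask")

    def swapped(self) -> "RegionMasks":
        return RegionMasks(self.valid, self.region2.copy(), self.region1.copy())


def harmonic_label(k: int) -> str:
    """Display label (MHz) of harmonic ``k`` on the nominal 5.6 MHz grid."""
    return f"{k * 5.6:.1f}"
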