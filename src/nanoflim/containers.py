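"""Core data containers shared by the simulation and analysis modules.

The containers are deliberately thin: calibrated numpy arrays plus the
metadata needed to interpret them (pixel size, frame interval, TCSPC channel
width, repetition rate).  File round-trips live in :mod:`nanoflim.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameStack",
    "GaussianIRF",
    "DecayCube",
    "FRAPTrace",
    "BleachTrace",
]


@dataclass
class FrameStack:
    """Calibrated 2-D fluorescence image time series.

    Parameters
    ----------
    data:
        Array of shape ``(n_frames, ny, nx)`` holding intensities in camera
        units (a.u.).
    pixel_size_nm:
        Lateral pixel size in nanometres.
    frame_interval_ms:
        Time between successive frames in milliseconds.
    meta:
        Free-form metadata (seed, simulation parameters, ...), serialised to
        the JSON sidecar on write.
    """

    data: np.ndarray
    pixel_size_nm: float
    frame_interval_ms: float = 100.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("FrameStack data must be 2-D or 3-D")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def pixel_area_um2(self) -> float:
        return (self.pixel_size_nm / 1000.0) ** 2

    @property
    def field_area_um2(self) -> float:
        ny, nx = self.shape
        return ny * nx * self.pixel_area_um2


@dataclass
class GaussianIRF:
    """Parametric Gaussian instrument response function.

    ``center_ps`` is the position of the IRF peak on the TCSPC time axis and
    ``fwhm_ps`` its full width at half maximum.  A FWHM of 300 ps is typical
    for a hybrid detector with ~100 ps single-photon timing resolution.
    """

    center_ps: float = 976.5625
    fwhm_ps: float = 300.0

    _FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    @property
    def sigma_ps(self) -> float:
        return self.fwhm_ps * self._FWHM_TO_SIGMA


@dataclass
class DecayCube:
    """Per-pixel TCSPC photon-arrival histograms.

    ``counts`` has shape ``(ny, nx, n_channels)``; each channel spans
    ``channel_width_ps`` picoseconds and the laser repetition period is
    ``1e6 / rep_rate_mhz`` ps (25 ns at 40 MHz).
    """

    counts: np.ndarray
    channel_width_ps: float
    rep_rate_mhz: float = 40.0
    irf: GaussianIRF | np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("DecayCube counts must have shape (ny, nx, channels)")
        if self.channel_width_ps <= 0:
            raise ValueError("channel_width_ps must be positive")

    @property
    def n_channels(self) -> int:
        return self.counts.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def period_ps(self) -> float:
        return 1e6 / self.rep_rate_mhz

    def photon_image(self) -> np.ndarray:
        """Total photons per pixel (the FLIM intensity image)."""
        return self.counts.sum(axis=2)


@dataclass
class FRAPTrace:
    """Intensity traces of a FRAP experiment.

    ``bleach_index`` is the index of the first post-bleach sample; all
    samples before it are pre-bleach scans.
    """

    times_s: np.ndarray
    bleach: np.ndarray
    reference: np.ndarray
    background: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.bleach = np.asarray(self.bleach, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = self.times_s.size
        if not (self.bleach.size == self.reference.size == self.background.size == n):
            raise ValueError("all FRAP trace columns must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0 < self.bleach_index < n:
            raise ValueError("bleach_index out of range")

    @property
    def n_pre(self) -> int:
        return self.bleach_index


@dataclass
class BleachTrace:
    """Single-cluster intensity trace used for photobleaching step counting."""

    values: np.ndarray
    frame_interval_ms: float = 100.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("BleachTrace values must be 1-D")

    @property
    def n_frames(self) -> int:
        return self.values.size
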