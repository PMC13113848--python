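"""Conventional delay-and-sum (DAS) reconstruction.

The reference path: delay every channel trace to each focal point using the
known time-of-flight map, sum across channels, envelope-detect with the
analytic signal, and log-compress to a fixed dynamic range.  No apodization
or aperture growth — plain summation over all channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .curvature import FocalGrid, ToFMap, compute_tof, sample_traces
from .geometry import ArrayShape, TransducerSpec, element_positions
from .phantom import SPEED_OF_SOUND, RFChannelData

__all__ = [
    "DelayedRFCube",
    "BModeImage",
    "delay_rf",
    "sum_channels",
    "envelope_log",
    "das_reconstruct",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DelayedRFCube:
    """Per-focal-point delayed RF, shape (n_focal, n_channels, n_scanlines).

    Summing over the channel axis yields the beamformed RF image.
    ``radius_tag`` records the originating geometry: a radius in mm, or
    ``"flat"``.
    """

    values: np.ndarray
    radius_tag: float | str = "flat"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError("values must be 3-D (focal, channel, scanline)")
        if not np.all(np.isfinite(v)):
            raise ValueError("delayed RF cube must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BModeImage:
    """Log-compressed brightness image in dB, shape (n_focal, n_scanlines).

    Normalized so the maximum pixel is 0 dB; pixels are clipped at
    ``-dynamic_range``.
    """

    pixels: np.ndarray
    dynamic_range: float = 60.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=float))


def delay_rf(rf: RFChannelData, tof: ToFMap) -> DelayedRFCube:
    """Interpolate each channel trace at its per-focal-point travel times.

    Reads beyond the recorded window are zero-filled; their count is logged.
    """
    cube, n_out = sample_traces(rf, tof.times, count_out_of_window=True)
    if n_out:
        logger.info(
            "delay_rf: %d of %d reads fell outside the recorded window",
            n_out,
            tof.times.size,
        )
    tag = tof.geometry_tag if tof.geometry_tag else "flat"
    return DelayedRFCube(cube, radius_tag=tag)


def sum_channels(cube: DelayedRFCube) -> np.ndarray:
    """Coherent sum over the channel axis -> RF image (n_focal, n_scanlines)."""
    return np.asarray(cube.values).sum(axis=1)


def envelope_log(rf_image: np.ndarray, dynamic_range: float = 60.0) -> BModeImage:
    """Envelope detection and log compression of a beamformed RF image.

    Per scanline, the envelope is the magnitude of the analytic signal along
    the focal (axial) axis; the image is normalized to its global maximum and
    mapped to ``20 log10``, clipped at ``-dynamic_range`` dB.
    """
    img = np.asarray(rf_image, dtype=float)
    env = np.abs(hilbert(img, axis=0))
    peak = env.max()
    if peak <= 0:
        raise ValueError("all-zero image: log compression undefined")
    db = 20.0 * np.log10(np.maximum(env / peak, 10.0 ** (-dynamic_range / 20.0 - 1)))
    return BModeImage(np.clip(db, -dynamic_range, 0.0), dynamic_range)


def das_reconstruct(
    rf: RFChannelData,
    shape: ArrayShape,
    spec: TransducerSpec,
    grid: FocalGrid,
    c: float = SPEED_OF_SOUND,
    dynamic_range: float = 60.0,
) -> BModeImage:
    """Full DAS pipeline: ToF -> delay -> channel sum -> envelope/log."""
    tof = compute_tof(element_positions(spec, shape), grid, c)
    cube = delay_rf(rf, tof)
    return envelope_log(sum_channels(cube), dynamic_range)


def brightest_point(image: BModeImage, grid: FocalGrid) -> tuple[float, float]:
    """(lateral mm, depth mm) of the brightest pixel — point-target locator."""
    f, s = np.unravel_index(np.argmax(image.pixels), image.pixels.shape)
    return float(grid.lateral[s]), float(grid.depths[f])
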