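"""Synthetic flat-array RF acquisition simulator.

Emulates repeated phantom acquisitions with a point-scatterer model: each
scanline fires a single element (walking aperture), every channel records the
sum of Gaussian-modulated echoes at their two-way times of flight, scaled by a
voltage-dependent gain, with additive white Gaussian system noise.  Series of
acquisitions share one repositioning-jitter draw; only the noise varies
within a series, mimicking consecutive frames of a stationary probe.

No attenuation, multiple scattering, or element directivity is modelled — the
simulator exists to exercise delay logic with closed-form oracle math, not to
reproduce tissue realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import gausspulse

from .geometry import ArrayShape, ElementLayout, TransducerSpec, element_positions

__all__ = [
    "PointPhantom",
    "PulseSpec",
    "AcquisitionConfig",
    "RFChannelData",
    "cirs_like_phantom",
    "simulate_acquisition",
    "emulate_experiment_series",
]

#: Conventional tissue-mimicking phantom sound speed, mm/µs.
SPEED_OF_SOUND = 1.540


@dataclass(frozen=True)
class PointPhantom:
    """A set of point scatterers in a homogeneous medium.

    ``scatterers`` has shape ``(n, 3)``: (lateral mm, depth mm, reflectivity).
    """

    scatterers: np.ndarray
    speed_of_sound: float = SPEED_OF_SOUND

    def __post_init__(self) -> None:
        sc = np.atleast_2d(np.asarray(self.scatterers, dtype=float))
        if sc.size and sc.shape[1] != 3:
            raise ValueError("scatterers must be (n, 3): lateral, depth, reflectivity")
        if sc.size and (np.any(sc[:, 1] <= 0) or np.any(sc[:, 2] <= 0)):
            raise ValueError("scatterer depths and reflectivities must be positive")
        object.__setattr__(self, "scatterers", sc.reshape(-1, 3))

    def shifted(self, d_lateral: float, d_depth: float) -> "PointPhantom":
        """Rigidly translate every scatterer (repositioning jitter)."""
        sc = self.scatterers.copy()
        sc[:, 0] += d_lateral
        sc[:, 1] += d_depth
        return PointPhantom(sc, self.speed_of_sound)


@dataclass(frozen=True)
class PulseSpec:
    """Transmit pulse: Gaussian-modulated sinusoid.

    ``fractional_bandwidth`` is the -6 dB bandwidth over the center frequency.
    """

    center_frequency: float = 5.0  # MHz
    fractional_bandwidth: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 < self.fractional_bandwidth < 2.0:
            raise ValueError("fractional_bandwidth must be in (0, 2)")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the pulse at times ``t`` (µs) centered on t = 0."""
        return gausspulse(t, fc=self.center_frequency, bw=self.fractional_bandwidth)


@dataclass(frozen=True)
class AcquisitionConfig:
    """One acquisition event's settings.

    ``voltage_gain`` scales all echo amplitudes (numerically equal to the
    transmit voltage in the emulated experiments); ``noise_sigma`` is the
    white-noise std as a fraction of the peak echo amplitude, so the additive
    noise has std ``noise_sigma * voltage_gain``; ``reposition_jitter`` is the
    std (mm) of the rigid lateral/depth offset applied to the whole phantom.
    """

    voltage_gain: float = 30.0
    noise_sigma: float = 0.0
    reposition_jitter: float = 0.0
    seed: int = 0
    pulse: PulseSpec = field(default_factory=PulseSpec)

    def __post_init__(self) -> None:
        if not self.voltage_gain > 0:
            raise ValueError("voltage_gain must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not isinstance(self.seed, (int, np.integer)):
            raise TypeError("seed must be an integer")


@dataclass
class RFChannelData:
    """Raw per-channel echo recordings for one acquisition.

    ``samples`` has shape (n_axial_samples, n_receive_channels, n_scanlines);
    sample ``k`` of any trace was recorded at time ``t0 + k / sampling_rate``.
    """

    samples: np.ndarray
    sampling_rate: float  # MHz
    t0: float = 0.0  # µs

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 3:
            raise ValueError("samples must be 3-D (axial, channel, scanline)")

    @property
    def n_axial(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def n_scanlines(self) -> int:
        return self.samples.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Recording times of the axial samples, µs."""
        return self.t0 + np.arange(self.n_axial) / self.sampling_rate


def cirs_like_phantom(max_depth: float = 40.0,
                      lateral_span: float = 40.0) -> PointPhantom:
    """Deterministic small-parts point-target layout.

    A vertical column of five targets between ``max_depth / 4`` and
    ``max_depth`` on the array axis plus a lateral row of four targets at
    ``5/8 max_depth`` spanning ``lateral_span``, all with unit reflectivity,
    in a medium with c = 1.540 mm/µs.  The defaults fill the full array's
    field of view (3712 samples at 62.5 MHz reach ~45 mm); pass smaller
    extents for reduced desk-scale arrays.  Stands in for a physical
    small-parts calibration phantom; the layout is generic by design.
    """
    column = [(0.0, z, 1.0) for z in np.linspace(max_depth / 4, max_depth, 5)]
    row_z = 5.0 * max_depth / 8.0
    row = [(x * lateral_span / 2, row_z, 1.0) for x in (-0.5, -0.25, 0.25, 0.5)]
    return PointPhantom(np.array(column + row))


def _two_way_tof(layout: ElementLayout, scatterers: np.ndarray, c: float) -> np.ndarray:
    """Times of flight tx-element -> scatterer -> rx-element.

    Returns shape (n_scatterers, n_channels, n_scanlines) under the walking
    single-element transmit convention (transmit element == scanline index).
    """
    pos = layout.positions  # (n_el, 2)
    diff = scatterers[:, None, :2] - pos[None, :, :]  # (n_sc, n_el, 2)
    dist = np.linalg.norm(diff, axis=-1)  # (n_sc, n_el)
    # d_tx over scanlines (axis s) + d_rx over channels (axis ch)
    return (dist[:, None, :] + dist[:, :, None]) / c


def simulate_acquisition(
    phantom: PointPhantom,
    spec: TransducerSpec,
    shape: ArrayShape,
    acq: AcquisitionConfig,
    *,
    rng: np.random.Generator | None = None,
) -> RFChannelData:
    """Simulate one walking-aperture acquisition.

    For scanline ``s`` the single element ``s`` transmits; receive channel
    ``ch`` records ``sum_i a_i * pulse(t - tof_i)`` with
    ``tof_i = (|p_s - q_i| + |q_i - p_ch|) / c``, scaled by
    ``acq.voltage_gain``, plus white Gaussian noise of std
    ``noise_sigma * voltage_gain``.  The phantom is rigidly offset by one
    jitter draw before simulation.  Echoes whose centers fall outside the
    recorded window contribute only their in-window tails.
    """
    if rng is None:
        rng = np.random.default_rng(acq.seed)
    jitter = (
        rng.normal(0.0, acq.reposition_jitter, size=2)
        if acq.reposition_jitter > 0
        else np.zeros(2)
    )
    ph = phantom.shifted(*jitter) if jitter.any() else phantom

    n = spec.n_elements
    out = np.zeros((spec.n_axial_samples, n, n), dtype=np.float32)
    t = np.arange(spec.n_axial_samples) / spec.sampling_rate  # t0 = 0

    if ph.scatterers.size:
        layout = element_positions(spec, shape)
        tof = _two_way_tof(layout, ph.scatterers, ph.speed_of_sound)
        pulse = acq.pulse
        refl = ph.scatterers[:, 2]
        # scanline-by-scanline to bound temporary memory at full array size
        for s in range(n):
            # (n_axial, n_scatterers, n_channels)
            dt = t[:, None, None] - tof[None, :, :, s]
            echo = pulse.waveform(dt) * refl[None, :, None]
            out[:, :, s] = echo.sum(axis=1).astype(np.float32)

    out *= np.float32(acq.voltage_gain)
    if acq.noise_sigma > 0:
        out += rng.normal(
            0.0, acq.noise_sigma * acq.voltage_gain, size=out.shape
        ).astype(np.float32)
    return RFChannelData(out, spec.sampling_rate, t0=0.0)


def emulate_experiment_series(
    phantom: PointPhantom,
    spec: TransducerSpec,
    n_acquisitions: int,
    acq_template: AcquisitionConfig,
    seed: int,
    *,
    shape: ArrayShape | None = None,
) -> list[RFChannelData]:
    """Simulate one experiment: repeated acquisitions of a stationary probe.

    The phantom is repositioned (jitter drawn) once per series; within the
    series only the system noise differs between acquisitions, so consecutive
    frames are identical when ``noise_sigma == 0``.  Deterministic under
    ``seed``.
    """
    if n_acquisitions < 1:
        raise ValueError("n_acquisitions must be >= 1")
    if shape is None:
        shape = ArrayShape.flat()
    rng = np.random.default_rng(seed)
    jitter = (
        rng.normal(0.0, acq_template.reposition_jitter, size=2)
        if acq_template.reposition_jitter > 0
        else np.zeros(2)
    )
    ph = phantom.shifted(*jitter) if jitter.any() else phantom
    base = replace(acq_template, reposition_jitter=0.0)

    series: list[RFChannelData] = []
    signal: RFChannelData | None = None
    for _ in range(n_acquisitions):
        if signal is None:
            noiseless = replace(base, noise_sigma=0.0)
            signal = simulate_acquisition(ph, spec, shape, noiseless, rng=rng)
        samples = signal.samples.copy()
        if base.noise_sigma > 0:
            samples = samples + rng.normal(
                0.0, base.noise_sigma * base.voltage_gain, size=samples.shape
            ).astype(np.float32)
        series.append(RFChannelData(samples, signal.sampling_rate, signal.t0))
    return series
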