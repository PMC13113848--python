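"""Time-of-flight maps and artificial-curvature simulation.

A flexible array that bends onto an arc records echoes at different times
than the same array lying flat.  Given RF data acquired flat, the curved
acquisition can be synthesized by time-warping each channel trace with the
curved-minus-flat time-of-flight difference, producing paired
(curved pre-delay RF, ground-truth delayed RF) datasets without physically
deforming the probe.

Steps, per channel/scanline:

1. true ToF of every focal point for the flat array geometry;
2. curved ToF of every focal point for a chosen arc radius;
3. warp the flat trace so that reading it at the curved ToF reproduces what
   reading the original at the flat ToF gives — i.e. the properly delayed
   ground truth.

Fractional delays use linear interpolation with zero fill outside the
recorded window; the warp is a monotone time remap defined on the focal-time
axis and edge-extrapolated beyond it, which makes the infinite-radius limit
an exact identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import (
    ArrayShape,
    ElementLayout,
    InvalidShapeError,
    TransducerSpec,
    element_positions,
)
from .phantom import SPEED_OF_SOUND, RFChannelData

__all__ = [
    "FocalGrid",
    "ToFMap",
    "DelayMap",
    "default_focal_grid",
    "compute_tof",
    "delay_map",
    "apply_artificial_curvature",
    "curvature_sweep",
    "sample_traces",
]

#: Mechanically feasible bending radii of the prototype, mm.
FEASIBLE_RADIUS_RANGE = (300.0, 800.0)


@dataclass(frozen=True)
class FocalGrid:
    """Focal points of the reconstruction.

    All scanlines share the same strictly increasing depth vector ``depths``
    (mm); scanline ``s``'s beam runs vertically at lateral position
    ``lateral[s]`` (mm) — the flat-array element positions, kept fixed across
    curvatures so paired data live on a common grid.
    """

    depths: np.ndarray  # (n_focal,), mm
    lateral: np.ndarray  # (n_scanlines,), mm

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        la = np.asarray(self.lateral, dtype=float)
        if d.ndim != 1 or d.size < 2 or np.any(np.diff(d) <= 0) or d[0] <= 0:
            raise ValueError("depths must be strictly increasing and positive")
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "lateral", la)

    @property
    def n_focal(self) -> int:
        return self.depths.size

    @property
    def n_scanlines(self) -> int:
        return self.lateral.size


@dataclass(frozen=True)
class ToFMap:
    """Two-way travel times, µs, shape (n_focal, n_channels, n_scanlines)."""

    times: np.ndarray
    geometry_tag: str

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 3:
            raise ValueError("times must be 3-D (focal, channel, scanline)")
        if np.any(t <= 0):
            raise ValueError("all travel times must be positive")
        object.__setattr__(self, "times", t)


@dataclass(frozen=True)
class DelayMap:
    """Curved-minus-flat ToF difference in samples, same shape as ToFMap."""

    delta_samples: np.ndarray
    geometry_tag: str = ""


def default_focal_grid(
    spec: TransducerSpec,
    n_focal: int = 1024,
    c: float = SPEED_OF_SOUND,
) -> FocalGrid:
    """Focal grid spanning the recorded window.

    Depths ``z_k = c * t_k / 2`` for ``n_focal`` uniformly spaced round-trip
    times from the first usable sample time (one sampling period, keeping
    depths positive) to the end of the recorded window.  Scanline beams sit
    at the flat-array element lateral positions.
    """
    if n_focal < 2:
        raise ValueError("n_focal must be >= 2")
    t_start = spec.dt
    t_end = spec.record_duration
    t = np.linspace(t_start, t_end, n_focal)
    depths = c * t / 2.0
    lateral = element_positions(spec, ArrayShape.flat()).lateral
    return FocalGrid(depths, lateral)


def compute_tof(
    layout: ElementLayout,
    grid: FocalGrid,
    c: float = SPEED_OF_SOUND,
) -> ToFMap:
    """Two-way ToF for every (focal point, receive channel, scanline).

    ``times[f, ch, s] = (|p_tx(s) - q(f,s)| + |q(f,s) - p_ch|) / c`` with the
    walking-transmit convention (transmit element index == scanline index)
    and ``q(f, s) = (grid.lateral[s], grid.depths[f])``.
    """
    if c <= 0:
        raise ValueError("speed of sound must be positive")
    ex = layout.lateral  # (n_el,)
    ez = layout.depth
    lat = grid.lateral  # (n_s,)
    z = grid.depths  # (n_f,)
    dx2 = (lat[None, :] - ex[:, None]) ** 2  # (n_el, n_s)
    dz = z[:, None, None] - ez[None, :, None]  # (n_f, n_el, 1)
    dist = np.sqrt(dx2[None, :, :] + dz**2)  # (n_f, n_el, n_s)
    n_s = lat.size
    d_tx = dist[:, np.arange(n_s), np.arange(n_s)]  # (n_f, n_s)
    times = (dist + d_tx[:, None, :]) / c
    return ToFMap(times, layout.shape.tag)


def delay_map(
    tof_curved: ToFMap,
    tof_flat: ToFMap,
    sampling_rate: float,
) -> DelayMap:
    """Elementwise ToF difference converted to samples."""
    if tof_curved.times.shape != tof_flat.times.shape:
        raise ValueError("ToF maps must share shape and grid")
    if tof_curved.geometry_tag == tof_flat.geometry_tag:
        warnings.warn(
            "delay map between identical geometries is identically zero",
            stacklevel=2,
        )
    delta = (tof_curved.times - tof_flat.times) * sampling_rate
    return DelayMap(delta, tof_curved.geometry_tag)


#: Reads this many samples past the window edge still count as inside
#: (guards against float round-off at the boundary).
_EDGE_TOL = 1e-6


def _fractional_read(x: np.ndarray, idx: np.ndarray, axis0_take) -> tuple:
    """Catmull-Rom cubic read of ``x`` along axis 0 at fractional indices.

    Returns ``(values, inside_mask)``; outside reads are zeroed.  The cubic
    kernel interpolates (passes through the samples), so integer indices
    reproduce sample values exactly; its error on band-limited signals is
    two orders below linear interpolation at ultrasound sampling ratios.
    Edge taps are clamped.
    """
    n = x.shape[0]
    inside = (idx >= -_EDGE_TOL) & (idx <= n - 1 + _EDGE_TOL)
    i1 = np.clip(np.floor(idx).astype(np.int64), 0, n - 2)
    t = np.clip(idx - i1, 0.0, 1.0)
    p0 = axis0_take(x, np.maximum(i1 - 1, 0))
    p1 = axis0_take(x, i1)
    p2 = axis0_take(x, i1 + 1)
    p3 = axis0_take(x, np.minimum(i1 + 2, n - 1))
    val = 0.5 * (
        2.0 * p1
        + t * (p2 - p0)
        + t**2 * (2.0 * p0 - 5.0 * p1 + 4.0 * p2 - p3)
        + t**3 * (3.0 * (p1 - p2) + p3 - p0)
    )
    return np.where(inside, val, 0.0), inside


def sample_traces(
    rf: RFChannelData,
    times: np.ndarray,
    *,
    count_out_of_window: bool = False,
):
    """Interpolate every channel trace at per-focal-point times.

    ``times`` has shape (n_focal, n_channels, n_scanlines); reads outside the
    recorded window return zero.  Returns the sampled cube, plus the
    out-of-window read count when requested.
    """
    x = np.asarray(rf.samples, dtype=np.float64)
    idx = (np.asarray(times) - rf.t0) * rf.sampling_rate
    out, inside = _fractional_read(
        x, idx, lambda arr, i: np.take_along_axis(arr, i, axis=0)
    )
    if count_out_of_window:
        return out, int(np.size(inside) - np.count_nonzero(inside))
    return out


def _tof_scanline(
    layout: ElementLayout,
    beam_lateral: float,
    depths: np.ndarray,
    tx_index: int,
    c: float,
) -> np.ndarray:
    """Two-way ToF (µs) for one scanline: shape (n_depths, n_channels)."""
    dx2 = (beam_lateral - layout.lateral) ** 2  # (n_el,)
    dist = np.sqrt(dx2[None, :] + (depths[:, None] - layout.depth[None, :]) ** 2)
    return (dist + dist[:, tx_index][:, None]) / c


def _warp_trace(
    trace: np.ndarray,
    t_uniform: np.ndarray,
    t_target: np.ndarray,
    t_source: np.ndarray,
    fs: float,
    t0: float,
) -> np.ndarray:
    """Resample ``trace`` so that its value at time ``t_target[f]`` equals the
    original's value at ``t_source[f]``.

    The delay curve ``t_source - t_target``, parameterized by ``t_target``, is
    linearly interpolated onto the uniform sample grid and edge-extrapolated
    beyond the focal-time range; the original trace is then read at the
    shifted times with zero outside the window.

    Only the monotone branch of ``t_target`` is used: for a bent array the
    curved ToF *decreases* over depths above the element plane, so times in
    that fold map to two depths and no single-valued remap exists there.
    The warp is defined from the ToF minimum onward (the physically imageable
    region).
    """
    imin = int(np.argmin(t_target))
    tt = t_target[imin:]
    delta = np.interp(t_uniform, tt, (t_source - t_target)[imin:])
    idx = (t_uniform + delta - t0) * fs
    out, _ = _fractional_read(trace, idx, lambda arr, i: arr[i])
    return out


def apply_artificial_curvature(
    flat_rf: RFChannelData,
    radius: float,
    spec: TransducerSpec,
    grid: FocalGrid | None = None,
    c: float = SPEED_OF_SOUND,
):
    """Synthesize the curved-array acquisition and its delayed ground truth.

    Returns ``(curved_rf, gt_cube)``:

    * ``gt_cube[f, ch, s]`` — the flat RF sampled at the flat ToF of focal
      point ``f``: the properly delayed ground truth;
    * ``curved_rf`` — a time-warped copy of the flat RF such that sampling it
      at the *curved* ToF reproduces ``gt_cube`` (within interpolation
      error): the RF a bent array would have recorded.

    A radius outside the mechanically feasible 300–800 mm range triggers a
    warning; a non-positive radius is an error.
    """
    from .beamform import DelayedRFCube  # local import: beamform builds on this module

    if not radius > 0:
        raise InvalidShapeError("curvature radius must be positive")
    if not FEASIBLE_RADIUS_RANGE[0] <= radius <= FEASIBLE_RADIUS_RANGE[1]:
        warnings.warn(
            f"radius {radius:g} mm outside the mechanically feasible "
            f"{FEASIBLE_RADIUS_RANGE[0]:g}-{FEASIBLE_RADIUS_RANGE[1]:g} mm range",
            stacklevel=2,
        )
    if grid is None:
        grid = default_focal_grid(spec, c=c)

    layout_flat = element_positions(spec, ArrayShape.flat())
    layout_curved = element_positions(spec, ArrayShape.convex(radius))
    tof_flat = compute_tof(layout_flat, grid, c)

    gt = sample_traces(flat_rf, tof_flat.times)

    # Dense focal-time nodes (one per RF sample) for the warp's delay curve:
    # a coarse grid leaves kinks at shallow depths where the delay varies fast.
    t_uniform = flat_rf.times
    dense_depths = c * t_uniform[1:] / 2.0
    fs = flat_rf.sampling_rate
    n_ch, n_s = flat_rf.n_channels, flat_rf.n_scanlines
    curved = np.empty_like(np.asarray(flat_rf.samples, dtype=np.float64))
    src = np.asarray(flat_rf.samples, dtype=np.float64)
    for s in range(n_s):
        tf_d = _tof_scanline(layout_flat, grid.lateral[s], dense_depths, s, c)
        tc_d = _tof_scanline(layout_curved, grid.lateral[s], dense_depths, s, c)
        for ch in range(n_ch):
            curved[:, ch, s] = _warp_trace(
                src[:, ch, s],
                t_uniform,
                tc_d[:, ch],
                tf_d[:, ch],
                fs,
                flat_rf.t0,
            )

    curved_rf = RFChannelData(
        curved.astype(np.float32), flat_rf.sampling_rate, flat_rf.t0
    )
    return curved_rf, DelayedRFCube(gt, radius_tag=radius)


def sweep_radii(r_min: float, r_max: float, step: float) -> np.ndarray:
    """Inclusive arithmetic radius sweep, e.g. 300..800 by 5 -> 101 values."""
    if r_min > r_max or step <= 0:
        raise ValueError("need r_min <= r_max and step > 0")
    n = int(round((r_max - r_min) / step)) + 1
    radii = r_min + step * np.arange(n)
    return radii[radii <= r_max + 1e-9]


def curvature_sweep(
    flat_rf: RFChannelData,
    r_min: float,
    r_max: float,
    step: float,
    spec: TransducerSpec,
    grid: FocalGrid | None = None,
    c: float = SPEED_OF_SOUND,
    meta: dict | None = None,
) -> list:
    """Generate one paired training sample per radius in the sweep.

    Radii run from ``r_min`` to ``r_max`` inclusive in ``step`` increments
    (300–800 mm in 5 mm steps gives 101 pairs).  Each pair holds the curved
    pre-delay RF (axially resized to the focal-grid length and normalized to
    [0, 1]) and the normalized ground-truth delayed cube, tagged with its
    radius.
    """
    from .dataset import PairedSample, normalize01, resize_axial

    if grid is None:
        grid = default_focal_grid(spec, c=c)
    base_meta = dict(meta or {})
    pairs = []
    for r in sweep_radii(r_min, r_max, step):
        curved_rf, gt = apply_artificial_curvature(flat_rf, float(r), spec, grid, c)
        pre_resized = resize_axial(curved_rf, grid.n_focal)
        pre, pre_lo, pre_hi = normalize01(pre_resized.samples, return_range=True)
        post, post_lo, post_hi = normalize01(gt.values, return_range=True)
        m = dict(base_meta)
        m.update(
            radius_mm=float(r),
            pre_range=(pre_lo, pre_hi),
            post_range=(post_lo, post_hi),
        )
        pairs.append(PairedSample(pre.astype(np.float32), post.astype(np.float32), m))
    return pairs
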