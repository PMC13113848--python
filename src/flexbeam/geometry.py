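"""Flexible-array transducer geometry.

The array is a 1-D row of elements that can lie flat (linear array) or bend
onto a circular arc of radius ``R`` (a convex shape bowing toward the imaged
medium).  Physical bending preserves the inter-element spacing *along the
array surface*, so curved layouts place elements with arc-length spacing
equal to the pitch.

Coordinate convention: lateral ``x`` in mm, depth ``z`` in mm with ``z >= 0``
into the medium, array centered at ``x = 0``.  Elements are treated as points;
element width/kerf are retained as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransducerSpec",
    "ArrayShape",
    "ElementLayout",
    "default_spec",
    "element_positions",
]


class InvalidShapeError(ValueError):
    """Raised for a geometrically invalid array shape (e.g. radius <= 0)."""


@dataclass(frozen=True)
class TransducerSpec:
    """Physical parameters of the flexible linear array.

    Defaults describe a 128-element, 1-mm-pitch, 5-MHz prototype sampled at
    62.5 MHz with 3712 recorded axial samples per channel.

    Attributes
    ----------
    n_elements : int
        Number of array elements (also the number of receive channels and,
        under the walking single-element transmit sequence, of scanlines).
    pitch : float
        Element center-to-center spacing in mm, measured along the array
        surface.
    element_width, kerf : float
        Element width and inter-element gap in mm; ``width + kerf == pitch``.
    element_length : float
        Elevational element length in mm (metadata only; no 3-D geometry).
    center_frequency : float
        Pulse center frequency in MHz.
    sampling_rate : float
        RF sampling rate in MHz.
    n_axial_samples : int
        Number of recorded samples per channel per transmit event.
    """

    n_elements: int = 128
    pitch: float = 1.0
    element_width: float = 0.8
    kerf: float = 0.2
    element_length: float = 10.0
    center_frequency: float = 5.0
    sampling_rate: float = 62.5
    n_axial_samples: int = 3712

    def __post_init__(self) -> None:
        if self.n_elements <= 0:
            raise ValueError("n_elements must be positive")
        if not np.isclose(self.element_width + self.kerf, self.pitch):
            raise ValueError(
                f"element_width + kerf ({self.element_width + self.kerf}) "
                f"must equal pitch ({self.pitch})"
            )
        if self.sampling_rate <= 2 * self.center_frequency:
            raise ValueError("sampling_rate must exceed twice the center frequency")
        if self.n_axial_samples < 2:
            raise ValueError("n_axial_samples must be >= 2")

    @property
    def dt(self) -> float:
        """Sampling period in µs."""
        return 1.0 / self.sampling_rate

    @property
    def record_duration(self) -> float:
        """Duration of the recorded window in µs, ``(n-1) * dt``."""
        return (self.n_axial_samples - 1) * self.dt

    def to_dict(self) -> dict:
        return {
            "n_elements": self.n_elements,
            "pitch": self.pitch,
            "element_width": self.element_width,
            "kerf": self.kerf,
            "element_length": self.element_length,
            "center_frequency": self.center_frequency,
            "sampling_rate": self.sampling_rate,
            "n_axial_samples": self.n_axial_samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransducerSpec":
        return cls(**d)


def default_spec() -> TransducerSpec:
    """Return the prototype flexible-array parameters.

    128 elements, 1 mm pitch (0.8 mm width + 0.2 mm kerf), 10 mm element
    length, 5 MHz center frequency, sampled at 62.5 MHz over 3712 axial
    samples.
    """
    return TransducerSpec()


def desk_spec(n_elements: int = 16, n_axial_samples: int = 464) -> TransducerSpec:
    """A reduced-size array used for fast tests and desk-scale studies.

    Same pitch, frequency and sampling rate as :func:`default_spec`; only the
    element count and record length shrink (464 = 3712 / 8, so the axial
    resize ratio matches the full system).
    """
    return TransducerSpec(n_elements=n_elements, n_axial_samples=n_axial_samples)


@dataclass(frozen=True)
class ArrayShape:
    """Flat or convex-arc array shape.

    ``kind`` is ``"flat"`` or ``"convex"``; ``radius`` (mm) is required for
    convex shapes and ignored for flat ones.
    """

    kind: str
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "convex"):
            raise InvalidShapeError(f"unknown shape kind {self.kind!r}")
        if self.kind == "convex":
            if self.radius is None or not self.radius > 0:
                raise InvalidShapeError("convex shape requires radius > 0")

    @classmethod
    def flat(cls) -> "ArrayShape":
        return cls("flat")

    @classmethod
    def convex(cls, radius: float) -> "ArrayShape":
        return cls("convex", radius)

    @property
    def tag(self) -> str:
        return "flat" if self.kind == "flat" else f"convex({self.radius:g}mm)"


@dataclass(frozen=True)
class ElementLayout:
    """Per-element 2-D positions of the (possibly bent) array.

    ``positions`` has shape ``(n_elements, 2)`` with columns (lateral mm,
    depth mm).  Consecutive elements are separated by the pitch along the
    array surface (arc length for convex shapes) and the layout is symmetric
    about lateral 0.
    """

    positions: np.ndarray
    shape: ArrayShape = field(default_factory=ArrayShape.flat)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must have shape (n_elements, 2)")
        object.__setattr__(self, "positions", pos)

    @property
    def n_elements(self) -> int:
        return self.positions.shape[0]

    @property
    def lateral(self) -> np.ndarray:
        return self.positions[:, 0]

    @property
    def depth(self) -> np.ndarray:
        return self.positions[:, 1]


def element_positions(spec: TransducerSpec, shape: ArrayShape) -> ElementLayout:
    """Compute element positions for a flat or convex-arc array.

    Flat: elements on the ``z == 0`` line at ``x_i = (i - (N-1)/2) * pitch``.

    Convex radius ``R``: elements on a circular arc of radius ``R`` whose apex
    touches the origin tangent to the ``z == 0`` line, bowing toward positive
    depth (into the medium).  Spacing is ``pitch`` measured along the arc, so
    element ``i`` sits at arc angle ``theta_i = s_i / R`` with
    ``s_i = (i - (N-1)/2) * pitch``:

    .. math:: x_i = R \\sin\\theta_i, \\qquad z_i = R (1 - \\cos\\theta_i).

    Raises
    ------
    InvalidShapeError
        If the shape carries a non-positive radius.
    """
    n = spec.n_elements
    s = (np.arange(n) - (n - 1) / 2.0) * spec.pitch  # signed arc length, mm
    if shape.kind == "flat":
        pos = np.column_stack([s, np.zeros(n)])
    else:
        r = float(shape.radius)  # validated > 0 by ArrayShape
        theta = s / r
        pos = np.column_stack([r * np.sin(theta), r * (1.0 - np.cos(theta))])
    return ElementLayout(pos, shape)
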