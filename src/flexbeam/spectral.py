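"""Frequency-domain evaluation of RF signal variation.

Curvature warping and acquisition noise change RF data in ways that envelope
detection and log compression largely hide from B-mode images.  Comparing
zero-frequency-centered 2-D spectra of the RF sections — via log-scaled
magnitude maps and pairwise absolute-difference maps — makes that variation
visible, and the image-domain mean squared error quantifies reconstruction
accuracy against the delay-and-sum reference.

Conventions: differences are taken between complex spectra first, then the
magnitude, then (for display) ``log1p``; the log-scale map of a single
spectrum is ``log(1 + |F|)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "DiffMap",
    "MetricReport",
    "fft2_shifted",
    "log_scale",
    "freq_difference",
    "mse",
    "variation_report",
]


@dataclass(frozen=True)
class Spectrum:
    """Zero-frequency-centered complex 2-D spectrum."""

    values: np.ndarray
    source_tag: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("spectrum must be 2-D")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class DiffMap:
    """Non-negative spectral difference magnitudes, linear or log1p scale."""

    values: np.ndarray
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log1p"):
            raise ValueError("scale must be 'linear' or 'log1p'")


@dataclass
class MetricReport:
    """Per-sample MSE values keyed by (group, sample) labels."""

    mse_values: dict = field(default_factory=dict)

    def add(self, key, value: float) -> None:
        if value < 0:
            raise ValueError("MSE must be non-negative")
        self.mse_values[key] = float(value)


def fft2_shifted(f: np.ndarray, source_tag: str = "") -> Spectrum:
    """2-D DFT with the zero-frequency bin moved to the array center."""
    f = np.asarray(f)
    if f.ndim != 2:
        raise ValueError("input must be 2-D")
    if not np.all(np.isfinite(f)):
        raise ValueError("input contains NaN or Inf")
    return Spectrum(np.fft.fftshift(np.fft.fft2(f)), source_tag)


def log_scale(spectrum: Spectrum) -> np.ndarray:
    """``log(1 + |F_shifted|)`` — the displayable log-magnitude map."""
    return np.log1p(np.abs(spectrum.values))


def freq_difference(s1: Spectrum, s2: Spectrum, scale: str = "linear") -> DiffMap:
    """Magnitude of the complex spectral difference, optionally log1p-scaled."""
    if s1.shape != s2.shape:
        raise ValueError("spectra must share shape")
    d = np.abs(s1.values - s2.values)
    if scale == "log1p":
        d = np.log1p(d)
    return DiffMap(d, scale)


def mse(image_i: np.ndarray, image_k: np.ndarray) -> float:
    """Mean squared pixel difference ``(1/mn) sum (I - K)^2``."""
    i = np.asarray(image_i, dtype=float)
    k = np.asarray(image_k, dtype=float)
    if i.shape != k.shape:
        raise ValueError("images must share shape")
    return float(np.mean((i - k) ** 2))


def center_scanline_section(rf_samples: np.ndarray, scanline: int | None = None) -> np.ndarray:
    """2-D (axial x channel) section of an RF tensor at one scanline
    (default: the center scanline) — the unit the spectral comparisons use."""
    x = np.asarray(rf_samples)
    if x.ndim != 3:
        raise ValueError("expected a 3-D RF tensor")
    s = x.shape[2] // 2 if scanline is None else scanline
    return x[:, :, s]


def variation_report(
    sections: dict,
    pairings: list[tuple] | None = None,
    scale: str = "log1p",
) -> tuple[MetricReport, dict]:
    """Pairwise spectral difference panels and MSE table for grouped data.

    Parameters
    ----------
    sections : dict
        Label -> 2-D array (RF section or reconstructed image).
    pairings : list of (label, label), optional
        Which pairs to compare; defaults to consecutive pairs plus the
        first-vs-last closure when more than two groups are given (the
        layout used for curvature triplets and the four-experiment panels).
    scale : str
        Scale of the difference maps.

    Returns
    -------
    (MetricReport, dict)
        MSE per pairing, and a dict of ``DiffMap`` panels keyed by pairing.
    """
    if not sections:
        raise ValueError("no groups given")
    labels = list(sections)
    if pairings is None:
        pairings = [(labels[i], labels[i + 1]) for i in range(len(labels) - 1)]
        if len(labels) > 2:
            pairings.append((labels[0], labels[-1]))
    spectra = {k: fft2_shifted(v, source_tag=str(k)) for k, v in sections.items()}
    report = MetricReport()
    panels: dict = {}
    for a, b in pairings:
        panels[(a, b)] = freq_difference(spectra[a], spectra[b], scale)
        report.add((a, b), mse(sections[a], sections[b]))
    return report, panels
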