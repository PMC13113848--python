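"""Data plumbing: axial resize, [0, 1] normalization, noise augmentation,
experiment-aware train/val/test splitting, and the HDF5 container.

The processed unit is the *paired sample*: one curved pre-delay RF tensor and
its ground-truth delayed cube, both resized to the focal-grid length and
normalized to [0, 1] (per tensor, with the original range recorded so the
map can be inverted), tagged with experiment / acquisition / voltage /
curvature-radius metadata.

The split rule holds out whole acquisitions: per experiment, one acquisition
(expanded over the full curvature sweep) goes to the test set and another to
validation; everything else trains.  With 4 experiments x 24 acquisitions
x 101 curvatures this yields 404 test and 404 validation pairs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction

import h5py
import numpy as np
from scipy.signal import resample_poly

from .geometry import TransducerSpec
from .phantom import RFChannelData

__all__ = [
    "PairedSample",
    "SampleRef",
    "DatasetSplit",
    "NoiseConfig",
    "resize_axial",
    "normalize01",
    "add_gaussian_noise",
    "build_split",
    "RFContainer",
]

logger = logging.getLogger(__name__)


@dataclass
class PairedSample:
    """One (pre-delay RF, ground-truth delayed cube) training pair.

    Both tensors have shape (n_focal, n_channels, n_scanlines) and live in
    [0, 1].  ``meta`` carries at least ``radius_mm`` and usually
    ``experiment_id``, ``acquisition_id``, ``voltage`` and the pre/post
    normalization ranges.
    """

    pre_delay: np.ndarray
    post_delay: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pre = np.asarray(self.pre_delay)
        post = np.asarray(self.post_delay)
        if pre.ndim != 3 or post.ndim != 3:
            raise ValueError("pre/post tensors must be 3-D")
        if pre.shape[2] != post.shape[2]:
            raise ValueError("pre/post scanline counts must match")
        for name, x in (("pre_delay", pre), ("post_delay", post)):
            if x.size and (x.min() < -1e-6 or x.max() > 1 + 1e-6):
                raise ValueError(f"{name} must be normalized to [0, 1]")
        self.pre_delay = pre
        self.post_delay = post

    @property
    def n_scanlines(self) -> int:
        return self.pre_delay.shape[2]

    def scanline(self, s: int) -> tuple[np.ndarray, np.ndarray]:
        """(input, target) 2-D slices for scanline ``s``, each
        (n_channels, n_focal) — one network sample."""
        return self.pre_delay[:, :, s].T, self.post_delay[:, :, s].T


@dataclass(frozen=True)
class SampleRef:
    """Lightweight handle used for splitting without loading tensors."""

    experiment_id: int
    acquisition_id: int
    radius_mm: float


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partitions of sample references."""

    train: list
    val: list
    test: list
    held_out: dict = field(default_factory=dict)  # experiment -> (test_acq, val_acq)

    def __post_init__(self) -> None:
        keys = [set(map(_ref_key, part)) for part in (self.train, self.val, self.test)]
        if keys[0] & keys[1] or keys[0] & keys[2] or keys[1] & keys[2]:
            raise ValueError("split partitions must be disjoint")


def _ref_key(sample) -> tuple:
    meta = sample.meta if isinstance(sample, PairedSample) else None
    if meta is not None:
        return (meta["experiment_id"], meta["acquisition_id"], meta["radius_mm"])
    return (sample.experiment_id, sample.acquisition_id, sample.radius_mm)


@dataclass(frozen=True)
class NoiseConfig:
    """Input-noise augmentation variant.

    ``mode`` is ``"INO"`` (intrinsic noise only: no injected noise) or
    ``"GN"`` (additive Gaussian noise of std ``sigma`` on the normalized
    pre-delay input).  The studied presets are GN with sigma 0.001 and 0.01.
    """

    mode: str = "INO"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("INO", "GN"):
            raise ValueError("mode must be 'INO' or 'GN'")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.mode == "INO" and self.sigma != 0:
            raise ValueError("INO mode implies sigma == 0")

    @classmethod
    def ino(cls, seed: int = 0) -> "NoiseConfig":
        return cls("INO", 0.0, seed)

    @classmethod
    def gn(cls, sigma: float, seed: int = 0) -> "NoiseConfig":
        return cls("GN", sigma, seed)

    @property
    def label(self) -> str:
        return "INO" if self.mode == "INO" else f"GN{self.sigma:g}"


def resize_axial(rf: RFChannelData, target_len: int) -> RFChannelData:
    """Anti-aliased polyphase resampling along the axial axis only.

    3712 -> 1024 is the rational ratio 8/29; the sampling-rate metadata is
    rescaled accordingly so sample times stay physical.
    """
    if target_len < 2:
        raise ValueError("target_len must be >= 2")
    n = rf.n_axial
    if target_len == n:
        return rf
    ratio = Fraction(target_len, n)
    y = resample_poly(np.asarray(rf.samples, dtype=np.float64), ratio.numerator,
                      ratio.denominator, axis=0, padtype="line")
    assert y.shape[0] == target_len
    return RFChannelData(
        y.astype(rf.samples.dtype, copy=False),
        rf.sampling_rate * target_len / n,
        rf.t0,
    )


def normalize01(x: np.ndarray, *, return_range: bool = False):
    """Affine map of a tensor onto [0, 1]: ``(x - min) / (max - min)``.

    A constant tensor maps to all zeros (logged).  Returns
    ``(normalized, min, max)`` when ``return_range`` so the map can be
    inverted.  Non-finite input is rejected.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains NaN or Inf")
    lo = float(x.min())
    hi = float(x.max())
    if hi == lo:
        logger.info("normalize01: constant input mapped to zeros")
        y = np.zeros_like(x)
    else:
        y = (x - lo) / (hi - lo)
    if return_range:
        return y, lo, hi
    return y


def denormalize01(y: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Invert :func:`normalize01` given the recorded range."""
    return np.asarray(y) * (hi - lo) + lo


def add_gaussian_noise(
    x: np.ndarray,
    cfg: NoiseConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply the configured input perturbation.

    INO returns the input unchanged; GN adds elementwise N(0, sigma^2) noise,
    seeded by ``cfg.seed`` unless an explicit generator is passed.
    """
    x = np.asarray(x)
    if cfg.mode == "INO" or cfg.sigma == 0:
        return x
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return x + rng.normal(0.0, cfg.sigma, size=x.shape)


def build_split(samples, n_experiments: int, seed: int = 0) -> DatasetSplit:
    """Hold out one acquisition per experiment for test and one for val.

    ``samples`` is a sequence of :class:`PairedSample` or :class:`SampleRef`.
    Every experiment must contribute at least 3 acquisitions; each held-out
    acquisition carries its whole curvature sweep into its partition.
    Selection is seeded and logged.
    """
    by_exp: dict = {}
    for s in samples:
        e, a, _ = _ref_key(s)
        by_exp.setdefault(e, {}).setdefault(a, []).append(s)
    if len(by_exp) != n_experiments:
        raise ValueError(
            f"expected {n_experiments} experiments, found {len(by_exp)}"
        )
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    held = {}
    for e in sorted(by_exp):
        acqs = sorted(by_exp[e])
        if len(acqs) < 3:
            raise ValueError(
                f"experiment {e} has {len(acqs)} acquisitions; need >= 3 to split"
            )
        pick = rng.choice(len(acqs), size=2, replace=False)
        test_acq, val_acq = acqs[pick[0]], acqs[pick[1]]
        held[e] = (test_acq, val_acq)
        logger.info(
            "split: experiment %s -> test acquisition %s, val acquisition %s",
            e, test_acq, val_acq,
        )
        for a in acqs:
            dest = test if a == test_acq else val if a == val_acq else train
            dest.extend(by_exp[e][a])
    return DatasetSplit(train, val, test, held)


class RFContainer:
    """HDF5 container for raw acquisitions and paired curvature samples.

    Layout::

        /transducer                 (attrs: Table-style array parameters)
        /experiments/<e>/acquisitions/<a>/raw_rf   (n_axial, n_ch, n_scan)
        /pairs/e<e>_a<a>/r<radius>/pre_delay
        /pairs/e<e>_a<a>/r<radius>/post_delay

    with voltage, seed, sampling metadata and normalization ranges stored as
    attributes.  Tensors round-trip bitwise.
    """

    def __init__(self, path, mode: str = "r"):
        self._h5 = h5py.File(path, mode)

    # -- lifecycle -----------------------------------------------------
    def close(self) -> None:
        self._h5.close()

    def __enter__(self) -> "RFContainer":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- transducer metadata -------------------------------------------
    def set_spec(self, spec: TransducerSpec) -> None:
        g = self._h5.require_group("transducer")
        for k, v in spec.to_dict().items():
            g.attrs[k] = v

    def get_spec(self) -> TransducerSpec:
        g = self._h5["transducer"]
        return TransducerSpec.from_dict({k: v.item() if hasattr(v, "item") else v
                                         for k, v in g.attrs.items()})

    # -- raw acquisitions ----------------------------------------------
    def add_acquisition(
        self,
        experiment_id: int,
        acquisition_id: int,
        rf: RFChannelData,
        *,
        voltage: float,
        seed: int,
    ) -> None:
        g = self._h5.require_group(
            f"experiments/{experiment_id}/acquisitions/{acquisition_id}"
        )
        d = g.create_dataset("raw_rf", data=rf.samples)
        d.attrs["sampling_rate"] = rf.sampling_rate
        d.attrs["t0"] = rf.t0
        g.attrs["voltage"] = voltage
        g.attrs["seed"] = seed

    def get_acquisition(
        self, experiment_id: int, acquisition_id: int
    ) -> tuple[RFChannelData, dict]:
        g = self._h5[f"experiments/{experiment_id}/acquisitions/{acquisition_id}"]
        d = g["raw_rf"]
        rf = RFChannelData(d[...], float(d.attrs["sampling_rate"]), float(d.attrs["t0"]))
        return rf, {"voltage": float(g.attrs["voltage"]), "seed": int(g.attrs["seed"])}

    def iter_acquisitions(self):
        exps = self._h5.get("experiments")
        if exps is None:
            return
        for e in sorted(exps, key=int):
            for a in sorted(exps[e]["acquisitions"], key=int):
                yield int(e), int(a)

    # -- paired samples -------------------------------------------------
    def add_pair(self, sample: PairedSample) -> None:
        m = sample.meta
        g = self._h5.require_group(
            f"pairs/e{m['experiment_id']}_a{m['acquisition_id']}/r{m['radius_mm']:g}"
        )
        g.create_dataset("pre_delay", data=sample.pre_delay)
        g.create_dataset("post_delay", data=sample.post_delay)
        g.attrs["meta"] = json.dumps(m, default=float)

    def get_pair(self, ref: SampleRef) -> PairedSample:
        g = self._h5[
            f"pairs/e{ref.experiment_id}_a{ref.acquisition_id}/r{ref.radius_mm:g}"
        ]
        meta = json.loads(g.attrs["meta"])
        return PairedSample(g["pre_delay"][...], g["post_delay"][...], meta)

    def iter_pair_refs(self):
        pairs = self._h5.get("pairs")
        if pairs is None:
            return
        for acq_key in sorted(pairs):
            e, a = acq_key[1:].split("_a")
            for r_key in sorted(pairs[acq_key], key=lambda k: float(k[1:])):
                yield SampleRef(int(e), int(a), float(r_key[1:]))
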