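"""Desk-scale study orchestration: simulate -> curvature sweep -> split ->
train the three noise variants -> reconstruct -> evaluate.

Each stage writes its artifacts under the run directory and is skipped on
rerun when its output already exists (unless forced); a manifest records the
configuration, derived seeds, counts, and content hashes so a run can be
audited and reproduced.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from .config import RunConfig
from .curvature import curvature_sweep, default_focal_grid, sweep_radii
from .dataset import (
    DatasetSplit,
    NoiseConfig,
    PairedSample,
    RFContainer,
    build_split,
)
from .dnpad import (
    DiscriminatorConfig,
    DNPADModel,
    GeneratorConfig,
    TrainConfig,
    pair_reconstruction_mse,
)
from .phantom import AcquisitionConfig, cirs_like_phantom, emulate_experiment_series
from .spectral import center_scanline_section, variation_report

__all__ = ["run_study", "simulate_experiments", "generate_pairs", "train_variants"]

logger = logging.getLogger(__name__)

VARIANT_NOISE = {
    "INO": NoiseConfig.ino(),
    "GN0.001": NoiseConfig.gn(0.001),
    "GN0.01": NoiseConfig.gn(0.01),
}


def _sha(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def simulate_experiments(cfg: RunConfig, container: RFContainer) -> list[dict]:
    """Emulate the multi-experiment acquisition design into the container.

    Experiments enumerate (voltage x repositioned repeat); each holds
    ``acquisitions_per_experiment`` consecutive frames differing only by
    system noise.
    """
    spec = cfg.spec()
    phantom = cirs_like_phantom(**cfg.phantom)
    e = cfg.experiments
    container.set_spec(spec)
    records = []
    exp_id = 0
    for voltage in e["voltages"]:
        for repeat in range(int(e.get("repeats_per_voltage", 1))):
            exp_id += 1
            seed = cfg.stage_seed("simulate", exp_id)
            acq = AcquisitionConfig(
                voltage_gain=float(voltage),
                noise_sigma=float(e.get("noise_sigma", 0.0)),
                reposition_jitter=float(e.get("reposition_jitter", 0.0)),
                seed=seed,
            )
            series = emulate_experiment_series(
                phantom, spec, int(e["acquisitions_per_experiment"]), acq, seed
            )
            for acq_id, rf in enumerate(series, start=1):
                container.add_acquisition(exp_id, acq_id, rf,
                                          voltage=float(voltage), seed=seed)
            records.append({"experiment_id": exp_id, "voltage": float(voltage),
                            "repeat": repeat + 1, "seed": seed,
                            "n_acquisitions": len(series)})
    return records


def generate_pairs(cfg: RunConfig, container: RFContainer) -> list[PairedSample]:
    """Curvature-sweep every stored acquisition into paired samples."""
    spec = cfg.spec()
    sw = cfg.sweep
    n_focal = int(cfg.training.get("n_focal", 1024))
    grid = default_focal_grid(spec, n_focal)
    pairs: list[PairedSample] = []
    for exp_id, acq_id in container.iter_acquisitions():
        rf, meta = container.get_acquisition(exp_id, acq_id)
        ps = curvature_sweep(
            rf, sw["r_min"], sw["r_max"], sw["step"], spec, grid,
            meta={"experiment_id": exp_id, "acquisition_id": acq_id,
                  "voltage": meta["voltage"]},
        )
        for p in ps:
            container.add_pair(p)
        pairs.extend(ps)
    return pairs


def train_variants(cfg: RunConfig, split: DatasetSplit, outdir: Path) -> dict:
    """Fit the INO / GN0.001 / GN0.01 variants with identical settings.

    The variants share architecture, seeds and schedule; only the input-noise
    augmentation differs.  Trained generator weights and histories are saved
    per variant.
    """
    tr = cfg.training
    gcfg = GeneratorConfig(base_channels=int(tr.get("base_channels", 64)))
    dcfg = DiscriminatorConfig(base_channels=int(tr.get("base_channels", 64)))
    base_tc = TrainConfig(
        lr=float(tr.get("lr", 1e-4)),
        batch_size=int(tr.get("batch_size", 4)),
        epochs=int(tr.get("epochs", 100)),
        lambda_l1=float(tr.get("lambda_l1", 10.0)),
        seed=cfg.stage_seed("train"),
    )
    results = {}
    for name in tr.get("variants", list(VARIANT_NOISE)):
        noise = VARIANT_NOISE[name]
        model = DNPADModel(split, gcfg, dcfg,
                           train_config=base_tc).with_noise(noise)
        logger.info("training variant %s (%d epochs)", name, base_tc.epochs)
        res = model.fit()
        vdir = outdir / f"variant_{name.replace('.', '_')}"
        vdir.mkdir(parents=True, exist_ok=True)
        save_weights(res.generator, vdir / "generator.npz")
        with open(vdir / "history.json", "w") as fh:
            json.dump({k: getattr(res.history, k)
                       for k in ("g_total", "g_l1", "g_adv", "d_loss",
                                 "val_mse", "lr")}, fh, indent=1)
        (vdir / "summary.txt").write_text(res.summary() + "\n")
        results[name] = res
    return results


def save_weights(net, path) -> None:
    np.savez(path, **{f"p{i}": p.value for i, p in enumerate(net.params())})


def load_weights(net, path) -> None:
    with np.load(path) as data:
        for i, p in enumerate(net.params()):
            p.value[...] = data[f"p{i}"]


def evaluate_variants(cfg: RunConfig, results: dict, split: DatasetSplit,
                      outdir: Path) -> dict:
    """Image-domain MSE per (variant, test sample) plus spectral panels."""
    dyn = float(cfg.evaluation.get("dynamic_range", 60.0))
    rows = []
    for name, res in results.items():
        for p in split.test:
            rows.append({
                "variant": name,
                "experiment_id": p.meta["experiment_id"],
                "acquisition_id": p.meta["acquisition_id"],
                "radius_mm": p.meta["radius_mm"],
                "mse": pair_reconstruction_mse(res.generator, p, dyn),
            })
    with open(outdir / "mse_report.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)

    if cfg.evaluation.get("save_panels", True):
        _spectral_panels(split, outdir)

    summary: dict = {}
    for name in results:
        vals = [r["mse"] for r in rows if r["variant"] == name]
        summary[name] = {
            "mean_mse": float(np.mean(vals)),
            "var_mse": float(np.var(vals)),
            "n": len(vals),
        }
    return {"rows": rows, "summary": summary}


def _spectral_panels(split: DatasetSplit, outdir: Path) -> None:
    """Curvature-triplet and cross-experiment difference panels (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    test = split.test
    # curvature triplet from one acquisition
    by_acq: dict = {}
    for p in test:
        by_acq.setdefault(
            (p.meta["experiment_id"], p.meta["acquisition_id"]), []
        ).append(p)
    first = sorted(by_acq)[0]
    triplet = sorted(by_acq[first], key=lambda p: p.meta["radius_mm"])[:3]
    if len(triplet) >= 2:
        sections = {f"R{p.meta['radius_mm']:g}":
                    center_scanline_section(p.pre_delay) for p in triplet}
        _, panels = variation_report(sections)
        _save_panels(panels, outdir / "curvature_panels.png", plt)

    # one fixed radius across experiments
    by_exp: dict = {}
    for p in test:
        by_exp.setdefault(p.meta["experiment_id"], []).append(p)
    radius = min(p.meta["radius_mm"] for p in test)
    sections = {}
    for e in sorted(by_exp):
        match = [p for p in by_exp[e] if p.meta["radius_mm"] == radius]
        if match:
            sections[f"exp{e}"] = center_scanline_section(match[0].pre_delay)
    if len(sections) >= 2:
        _, panels = variation_report(sections)
        _save_panels(panels, outdir / "experiment_panels.png", plt)


def _save_panels(panels: dict, path: Path, plt) -> None:
    n = len(panels)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    for ax, ((a, b), dm) in zip(axes[0], panels.items()):
        ax.imshow(dm.values, aspect="auto", cmap="magma")
        ax.set_title(f"{a} vs {b}")
        ax.set_xlabel("lateral frequency")
        ax.set_ylabel("axial frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def run_study(cfg: RunConfig, outdir, force: bool = False) -> dict:
    """Run the full pipeline; returns the manifest dictionary.

    Artifacts: ``dataset.h5`` (raw acquisitions + pairs), ``split.json``,
    per-variant weight/history directories, ``mse_report.csv``, spectral
    panels, and ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h5_path = outdir / "dataset.h5"

    if h5_path.exists() and not force:
        logger.info("dataset stage: reusing %s", h5_path)
        container = RFContainer(h5_path, "r")
        pairs = [container.get_pair(ref) for ref in container.iter_pair_refs()]
        exp_records = None
    else:
        container = RFContainer(h5_path, "w")
        exp_records = simulate_experiments(cfg, container)
        pairs = generate_pairs(cfg, container)

    split = build_split(pairs, cfg.n_experiments(),
                        seed=cfg.stage_seed("split"))
    split_info = {
        "n_train": len(split.train),
        "n_val": len(split.val),
        "n_test": len(split.test),
        "held_out": {str(k): list(v) for k, v in split.held_out.items()},
    }
    with open(outdir / "split.json", "w") as fh:
        json.dump(split_info, fh, indent=1)

    results = train_variants(cfg, split, outdir)
    evaluation = evaluate_variants(cfg, results, split, outdir)

    radii = sweep_radii(cfg.sweep["r_min"], cfg.sweep["r_max"],
                        cfg.sweep["step"])
    manifest = {
        "config": cfg.to_dict(),
        "seeds": {"global": cfg.seed,
                  "split": cfg.stage_seed("split"),
                  "train": cfg.stage_seed("train")},
        "experiments": exp_records,
        "n_curvatures": int(radii.size),
        "curvature_radii_mm": [float(r) for r in radii],
        "split": split_info,
        "dataset_hash": _sha(np.concatenate(
            [p.pre_delay.ravel()[:256] for p in pairs])),
        "evaluation": evaluation["summary"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    container.close()
    return manifest
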