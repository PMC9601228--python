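"""End-to-end wiring: phantoms (or images on disk) -> enriched multichannel
objects -> patches -> HDF5 tensor-dataset containers -> repeated training.

This module is the library face of the three-stage pipeline; the CLI is a
thin shell over these functions.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .annotations import N_CLASSES
from .config import ExperimentConfig
from .enrichment import (
    BreastMask,
    GrayscaleImage,
    MultichannelImage,
    apply_filter_bank,
    tissue_bounding_box,
)
from .evaluation import ExperimentReport, run_repetitions
from .phantoms import Phantom, generate_cohort
from .rankr_fnn import ModelDims, count_parameters
from .sampling import Patch, extract_patches, sample_by_class, split_dataset, stack_samples, tensorize_patch

__all__ = [
    "enrich_phantom",
    "cohort_to_patches",
    "write_container",
    "read_patches",
    "train_eval",
    "write_report",
]

logger = logging.getLogger(__name__)


def enrich_phantom(
    image: GrayscaleImage, breast_mask: BreastMask, label_mask: np.ndarray,
) -> tuple[MultichannelImage, np.ndarray]:
    """Peripheral-crop an annotated image and build its 10-channel object.

    The known tissue mask and the label mask are cropped with the same box
    as the image, so lesion annotations are never lost to the crop.
    """
    r0, r1, c0, c1 = tissue_bounding_box(image)
    if label_mask[..., :].any():
        kept = label_mask[r0:r1, c0:c1].sum()
        if kept != label_mask.sum():
            raise RuntimeError("peripheral crop discarded annotated lesion pixels")
    cropped = GrayscaleImage(image.pixels[r0:r1, c0:c1])
    cmask = BreastMask(breast_mask.mask[r0:r1, c0:c1])
    mci = apply_filter_bank(cropped, cmask)
    return mci, label_mask[r0:r1, c0:c1]


def cohort_to_patches(cohort: list[Phantom], config: ExperimentConfig) -> list[Patch]:
    """Run enrichment and criterion-based patch extraction over a cohort."""
    patches: list[Patch] = []
    for i, ph in enumerate(cohort):
        mci, labels = enrich_phantom(ph.image, ph.breast_mask, ph.label_mask)
        got = extract_patches(
            mci, labels, sps=config.sps, scan_step=config.scan_step,
            max_patches=config.max_patches, coverage_min=config.coverage_min,
            source_id=f"phantom_{i:03d}",
        )
        logger.info("image %d: %d patches accepted", i, len(got))
        patches.extend(got)
    return patches


def write_container(path, patches: list[Patch], config: ExperimentConfig) -> None:
    """Write the prepared dataset to an HDF5 container.

    Stores the accepted patches (so later runs can re-draw tensor samples)
    plus one realized tensor dataset at the config seed: X, one-hot t,
    provenance (source image, patch origin, dominant pixel) and the 30/70
    split indices.

    Raises a descriptive error when zero patches were accepted.
    """
    if not patches:
        raise ValueError(
            "zero patches accepted; check tissue coverage (criterion: "
            f"> {config.coverage_min:.0%} of the patch area) and ROI "
            "intersection for lesion images"
        )
    samples = []
    for pid, p in enumerate(patches):
        samples.extend(tensorize_patch(p, tws=config.tws, tss=config.tss, patch_id=pid))
    chosen = sample_by_class(samples, spc=config.spc, rng_seed=config.seed)
    ds = split_dataset(chosen, train_fraction=config.train_fraction,
                       rng_seed=config.seed, spc=config.spc, tws=config.tws,
                       tss=config.tss, sps=config.sps)
    X, t = stack_samples(chosen)
    with h5py.File(path, "w") as f:
        g = f.create_group("patches")
        g.create_dataset("blocks", data=np.stack([p.block for p in patches]).astype(np.float32))
        g.create_dataset("labels", data=np.stack([p.labels for p in patches]).astype(np.uint8))
        g.create_dataset("origins", data=np.array([p.origin for p in patches], dtype=np.int64))
        g.create_dataset(
            "source_ids",
            data=np.array([p.source_id for p in patches], dtype=h5py.string_dtype()),
        )
        f.create_dataset("X", data=X)
        f.create_dataset("t", data=t)
        prov = f.create_group("provenance")
        prov.create_dataset("source_patch", data=np.array([s.source_patch for s in chosen]))
        prov.create_dataset("dominant_pixel", data=np.array([s.dominant_pixel for s in chosen]))
        f.create_dataset("train_idx", data=ds.train_idx)
        f.create_dataset("test_idx", data=ds.test_idx)
        f.attrs["config"] = config.to_json()


def read_patches(path) -> tuple[list[Patch], ExperimentConfig]:
    with h5py.File(path, "r") as f:
        blocks = f["patches/blocks"][...].astype(np.float64)
        labels = f["patches/labels"][...]
        origins = f["patches/origins"][...]
        sources = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in f["patches/source_ids"][...]]
        config = ExperimentConfig.from_dict(json.loads(f.attrs["config"]))
    patches = [
        Patch(block=blocks[i], labels=labels[i],
              origin=(int(origins[i][0]), int(origins[i][1])), source_id=sources[i])
        for i in range(blocks.shape[0])
    ]
    return patches, config


def train_eval(patches: list[Patch], config: ExperimentConfig) -> ExperimentReport:
    """Repeated train/evaluate runs on prepared patches (see
    :func:`mammotensor.evaluation.run_repetitions`)."""
    cfg = config.train
    cfg.seed = config.seed
    report = run_repetitions(
        patches,
        dims_template={"Q": config.Q, "R": config.R},
        train_cfg=cfg,
        tws=config.tws, tss=config.tss, spc=config.spc,
        train_fraction=config.train_fraction, n_classes=config.C,
    )
    report.config = config.to_dict()
    return report


def write_report(report: ExperimentReport, out_dir, make_plots: bool = True) -> dict:
    """Write metrics CSV, aggregate JSON, confusion CSVs and learning curves.

    Returns the aggregate dictionary (including the parameter-count
    summary)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "repetition": i,
            "seed": r.seed,
            "accuracy": f"{r.accuracy:.10f}",
            "macro_f1": f"{r.f1:.10f}",
            "final_train_loss": f"{r.history.train_loss[-1]:.10f}" if r.history and r.history.train_loss else "",
            "diverged": bool(r.history.diverged) if r.history else False,
        }
        for i, r in enumerate(report.per_repetition)
    ]
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
    for i, r in enumerate(report.per_repetition):
        np.savetxt(out / f"confusion_rep{i:02d}.csv", r.confusion, fmt="%d", delimiter=",")

    cfg = report.config
    aggregate = dict(report.aggregate)
    if cfg:
        dims = ModelDims(s=cfg["tws"], b=10, C=cfg["C"], Q=cfg["Q"], R=cfg["R"])
        fact, dense = count_parameters(dims)
        aggregate["parameters_factorized"] = fact
        aggregate["parameters_dense_equivalent"] = dense
    with open(out / "aggregate.json", "w") as f:
        json.dump(aggregate, f, indent=2, sort_keys=True)

    if make_plots:
        _plot_learning_curves(report, out / "learning_curves.png")
    return aggregate


def _plot_learning_curves(report: ExperimentReport, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for r in report.per_repetition:
        if r.history is None:
            continue
        axes[0].plot(range(1, len(r.history.train_loss) + 1), r.history.train_loss,
                     alpha=0.5, lw=1)
        axes[1].plot(r.history.eval_epochs, r.history.test_accuracy, alpha=0.6,
                     marker="o", ms=3, lw=1)
    axes[0].set(xlabel="epoch", ylabel="training cross-entropy")
    axes[1].set(xlabel="epoch", ylabel="test accuracy", ylim=(0, 1))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_default_experiment(
    seed: int = 0, repetitions: int | None = None, config: ExperimentConfig | None = None,
) -> ExperimentReport:
    """The package's reference small-sample experiment.

    Generates the default 12-phantom cohort, extracts 64 x 64 x 10 patches,
    and runs the repeated 21 x 21 x 10 tensor protocol (SPC = 60, TSS = 2,
    Q = 25, R = 4, 70 epochs, 10 repetitions) end to end.
    """
    cfg = config or ExperimentConfig(seed=seed)
    cfg.seed = seed
    cfg.train.seed = seed
    if repetitions is not None:
        cfg.train.repetitions = repetitions
    cohort = generate_cohort(cfg.n_images, cfg.phantom_spec(), cfg.class_mix,
                             seed=cfg.seed)
    patches = cohort_to_patches(cohort, cfg)
    return train_eval(patches, cfg)


def simulate_to_disk(config: ExperimentConfig, out_dir) -> pd.DataFrame:
    """Generate a phantom cohort and write it as 16-bit PNGs plus a manifest.

    Writes per image: the phantom (``*_image.png``), the breast mask
    (``*_breastmask.png``, 0/1) and the label mask (``*_labels.png``,
    codes 0/1/2). The manifest CSV mirrors clinical per-image indices:
    image id, lesion (mass) existence flag, calcification existence flag.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config.n_images, config.phantom_spec(),
                             config.class_mix, seed=config.seed)
    rows = []
    for i, ph in enumerate(cohort):
        stem = f"phantom_{i:03d}"
        iio.imwrite(out / f"{stem}_image.png",
                    np.round(ph.image.pixels * 65535).astype(np.uint16))
        iio.imwrite(out / f"{stem}_breastmask.png", ph.breast_mask.mask)
        iio.imwrite(out / f"{stem}_labels.png", ph.label_mask)
        rows.append({"image_id": stem, "has_mass": int(ph.has_mass),
                     "has_calc": int(ph.has_calc)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def prepare_from_disk(image_dir, config: ExperimentConfig):
    """Load a simulated cohort from disk and extract patches."""
    import imageio.v3 as iio

    image_dir = Path(image_dir)
    manifest = pd.read_csv(image_dir / "manifest.csv")
    patches: list[Patch] = []
    for _, row in manifest.iterrows():
        stem = row["image_id"]
        img = iio.imread(image_dir / f"{stem}_image.png").astype(np.float64) / 65535.0
        bmask = BreastMask(iio.imread(image_dir / f"{stem}_breastmask.png"))
        labels = np.asarray(iio.imread(image_dir / f"{stem}_labels.png"), dtype=np.uint8)
        mci, clabels = enrich_phantom(GrayscaleImage(img), bmask, labels)
        patches.extend(
            extract_patches(mci, clabels, sps=config.sps, scan_step=config.scan_step,
                            max_patches=config.max_patches,
                            coverage_min=config.coverage_min, source_id=str(stem))
        )
    return patches
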