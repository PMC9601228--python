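"""Patch extraction, tensorization, class-balanced sampling and splitting.

This stage turns a 10-channel image into the dataset D = {(X_i, t_i)}: fixed
size patches are extracted under tissue-coverage and lesion-inclusion
criteria, every *dominant pixel* inside a patch spawns a TWS x TWS x 10
window labeled by that pixel's class, the samples-per-class (SPC) cap limits
how many windows each patch contributes per class, and the pooled samples
are split 30/70 into training and testing with the training order permuted.

Hyper-parameters follow the pipeline's naming: SPS (selected patch size),
TWS (tensor window size), TSS (tensor step size), SPC (samples per class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotations import N_CLASSES
from .enrichment import MultichannelImage, N_CHANNELS

__all__ = [
    "Patch",
    "TensorSample",
    "Dataset",
    "extract_patches",
    "tensorize_patch",
    "sample_by_class",
    "split_dataset",
    "stack_samples",
]

logger = logging.getLogger(__name__)

SPS_MIN, SPS_MAX = 32, 512
SPC_MIN = 10
TWS_MIN_EXCLUSIVE = 3
DEFAULT_COVERAGE_MIN = 0.9
DEFAULT_TRAIN_FRACTION = 0.30


@dataclass(frozen=True)
class Patch:
    """An SPS x SPS x 10 block with its per-pixel class mask and origin."""

    block: np.ndarray
    labels: np.ndarray
    origin: tuple[int, int]
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.block.ndim != 3 or self.block.shape[2] != N_CHANNELS:
            raise ValueError(f"block must be SPS x SPS x {N_CHANNELS}")
        if self.labels.shape != self.block.shape[:2]:
            raise ValueError("labels must match block spatial shape")

    @property
    def sps(self) -> int:
        return self.block.shape[0]


@dataclass(frozen=True)
class TensorSample:
    """One training pair (X_i, t_i): a centered window plus a one-hot label."""

    X: np.ndarray
    t: np.ndarray
    dominant_pixel: tuple[int, int]
    source_patch: int = 0

    def __post_init__(self) -> None:
        if self.t.sum() != 1 or not np.isin(self.t, (0, 1)).all():
            raise ValueError("t must be one-hot")

    @property
    def class_code(self) -> int:
        return int(np.argmax(self.t))


@dataclass
class Dataset:
    """Ordered samples plus disjoint train/test index lists and hyper-params."""

    samples: list[TensorSample]
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    spc: int | None = None
    tws: int | None = None
    tss: int | None = None
    sps: int | None = None

    def __post_init__(self) -> None:
        train, test = set(self.train_idx.tolist()), set(self.test_idx.tolist())
        if train & test:
            raise ValueError("train and test indices overlap")
        if train | test != set(range(len(self.samples))):
            raise ValueError("split does not cover all samples")

    @property
    def n(self) -> int:
        return len(self.samples)


def extract_patches(
    mci: MultichannelImage,
    label_mask: np.ndarray | None,
    sps: int = 64,
    scan_step: int = 32,
    max_patches: int = 10,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
    source_id: str = "",
) -> list[Patch]:
    """Raster-scan a multichannel image and keep windows meeting the criteria.

    Candidate windows are visited row-major with stride ``scan_step``. A
    window is accepted iff

    1. the fraction of breast-tissue pixels in its footprint strictly
       exceeds ``coverage_min`` (default 0.9), and
    2. when the image's label mask contains any lesion pixel, the window
       intersects at least one nonzero label pixel (images with lesions
       only contribute lesion-bearing patches).

    Scanning stops after ``max_patches`` acceptances. A patch size larger
    than the image yields an empty list with a warning rather than an error.
    """
    if not SPS_MIN <= sps <= SPS_MAX:
        raise ValueError(f"sps must lie in [{SPS_MIN}, {SPS_MAX}]")
    if scan_step < 1:
        raise ValueError("scan_step must be >= 1")
    h, w = mci.shape
    if sps > h or sps > w:
        logger.warning(
            "patch size %d exceeds image size %dx%d; no patches extracted", sps, h, w
        )
        return []
    if label_mask is None:
        label_mask = np.zeros((h, w), dtype=np.uint8)
    if label_mask.shape != (h, w):
        raise ValueError("label_mask shape must match image")
    require_roi = bool(label_mask.any())
    tissue = mci.mask.mask
    area = sps * sps
    patches: list[Patch] = []
    n_rej_coverage = n_rej_roi = 0
    for r in range(0, h - sps + 1, scan_step):
        for c in range(0, w - sps + 1, scan_step):
            cov = tissue[r : r + sps, c : c + sps].sum() / area
            if cov <= coverage_min:
                n_rej_coverage += 1
                continue
            lab = label_mask[r : r + sps, c : c + sps]
            if require_roi and not lab.any():
                n_rej_roi += 1
                continue
            patches.append(
                Patch(
                    block=mci.channels[r : r + sps, c : c + sps, :],
                    labels=lab.copy(),
                    origin=(r, c),
                    source_id=source_id,
                )
            )
            if len(patches) >= max_patches:
                logger.debug(
                    "patch cap reached (%d); rejected %d by coverage, %d by ROI",
                    max_patches, n_rej_coverage, n_rej_roi,
                )
                return patches
    logger.debug(
        "accepted %d patches; rejected %d by coverage, %d by ROI",
        len(patches), n_rej_coverage, n_rej_roi,
    )
    return patches


def tensorize_patch(
    patch: Patch, tws: int, tss: int = 1, patch_id: int = 0
) -> list[TensorSample]:
    """Emit one tensor window per dominant pixel of a patch.

    Dominant pixels are visited every ``tss`` pixels along both axes, at
    positions whose centered ``tws x tws`` window lies fully inside the
    patch (no padding; windows never cross patch borders). Each sample's X
    is the window across all 10 channels and its label is the one-hot class
    of the dominant pixel. The emitted X arrays are views into the patch
    block; stack or copy before mutating.

    The window count per axis is ``floor((sps - tws) / tss) + 1``. An odd
    ``tws`` centers exactly; for an even ``tws`` the dominant pixel is the
    top-left element of the central 2 x 2 block.
    """
    if tws <= TWS_MIN_EXCLUSIVE:
        raise ValueError(f"tws must exceed {TWS_MIN_EXCLUSIVE}")
    if tws > patch.sps:
        raise ValueError("tws cannot exceed the patch size")
    if tss < 1:
        raise ValueError("tss must be >= 1")
    half = (tws - 1) // 2
    samples: list[TensorSample] = []
    for r0 in range(0, patch.sps - tws + 1, tss):
        for c0 in range(0, patch.sps - tws + 1, tss):
            dr, dc = r0 + half, c0 + half
            code = int(patch.labels[dr, dc])
            t = np.zeros(N_CLASSES, dtype=np.uint8)
            t[code] = 1
            samples.append(
                TensorSample(
                    X=patch.block[r0 : r0 + tws, c0 : c0 + tws, :],
                    t=t,
                    dominant_pixel=(dr, dc),
                    source_patch=patch_id,
                )
            )
    return samples


def sample_by_class(
    samples: list[TensorSample], spc: int, rng_seed: int
) -> list[TensorSample]:
    """Cap each patch's contribution at ``spc`` samples per class.

    Within every (source patch, class) group, min(spc, available) samples
    are drawn uniformly without replacement. Output order is deterministic
    given the seed: groups in first-appearance order, selections in
    original sample order.
    """
    if spc < SPC_MIN:
        raise ValueError(f"spc must be >= {SPC_MIN}")
    rng = np.random.default_rng(rng_seed)
    groups: dict[tuple[int, int], list[int]] = {}
    for i, s in enumerate(samples):
        groups.setdefault((s.source_patch, s.class_code), []).append(i)
    kept: list[int] = []
    for key in groups:
        idx = groups[key]
        if len(idx) <= spc:
            kept.extend(idx)
        else:
            pick = rng.choice(len(idx), size=spc, replace=False)
            kept.extend(idx[j] for j in sorted(pick))
    return [samples[i] for i in kept]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(
    samples: list[TensorSample],
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    rng_seed: int = 0,
    spc: int | None = None,
    tws: int | None = None,
    tss: int | None = None,
    sps: int | None = None,
) -> Dataset:
    """Stratified random 30/70 split with a permuted training order.

    The train size is round-half-up of ``train_fraction * N``, apportioned
    across classes by largest remainder so every class keeps its share.
    Training indices are then permuted with the same seeded generator (the
    unbiasing permutation); test order is left as constructed. A class with
    fewer than 2 samples goes entirely to training with a warning.
    """
    if not 0.0 <= train_fraction <= 1.0:
        raise ValueError("train_fraction must lie in [0, 1]")
    n = len(samples)
    rng = np.random.default_rng(rng_seed)
    labels = np.array([s.class_code for s in samples])
    target_total = _round_half_up(train_fraction * n)

    class_codes = [int(c) for c in np.unique(labels)]
    forced: list[int] = []      # classes too small to split
    splittable: list[int] = []
    for c in class_codes:
        if (labels == c).sum() < 2:
            logger.warning("class %d has < 2 samples; placed entirely in training", c)
            forced.append(c)
        else:
            splittable.append(c)

    train_parts: list[np.ndarray] = []
    forced_idx = np.flatnonzero(np.isin(labels, forced)) if forced else np.empty(0, int)
    train_parts.append(forced_idx)
    remaining = max(target_total - forced_idx.size, 0)

    # largest-remainder apportionment of the remaining train quota
    sizes = np.array([(labels == c).sum() for c in splittable], dtype=float)
    if sizes.size and remaining > 0:
        quotas = remaining * sizes / sizes.sum()
        take = np.floor(quotas).astype(int)
        short = remaining - take.sum()
        order = np.argsort(-(quotas - np.floor(quotas)), kind="stable")
        take[order[:short]] += 1
        take = np.minimum(take, sizes.astype(int))
    else:
        take = np.zeros(len(splittable), dtype=int)

    test_parts: list[np.ndarray] = []
    for c, k in zip(splittable, take):
        idx = np.flatnonzero(labels == c)
        perm = rng.permutation(idx.size)
        train_parts.append(idx[perm[:k]])
        test_parts.append(idx[perm[k:]])

    train_idx = np.concatenate(train_parts) if train_parts else np.empty(0, int)
    train_idx = train_idx[rng.permutation(train_idx.size)]
    if test_parts:
        test_idx = np.sort(np.concatenate(test_parts))
    else:
        test_idx = np.empty(0, dtype=int)
    return Dataset(
        samples=samples,
        train_idx=train_idx.astype(int),
        test_idx=test_idx.astype(int),
        seed=rng_seed,
        spc=spc, tws=tws, tss=tss, sps=sps,
    )


def stack_samples(samples: list[TensorSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into dense arrays X (N, tws, tws, 10) and t (N, C)."""
    if not samples:
        raise ValueError("no samples to stack")
    X = np.stack([s.X for s in samples]).astype(np.float32)
    t = np.stack([s.t for s in samples]).astype(np.float32)
    return X, t
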