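"""Image enrichment: peripheral cropping, breast-tissue masking and the
nine-filter low-level feature bank.

A raw grayscale mammogram is turned into a 10-channel *multichannel object*:
channel 0 is the cropped raw image, channels 1-9 are training-free filter
responses (Sobel variants, Canny, difference of Gaussians, gamma correction,
histogram equalization and two Gabor orientations). All channels live on the
[0, 1] intensity scale and share the crop's spatial extent.

Coordinates are row-major, 0-based ``(row, col)`` with half-open ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, feature, filters, measure

__all__ = [
    "GrayscaleImage",
    "BreastMask",
    "MultichannelImage",
    "FilterSpec",
    "default_filter_bank",
    "compute_breast_mask",
    "tissue_bounding_box",
    "peripheral_crop",
    "apply_filter_bank",
    "save_multichannel",
    "load_multichannel",
    "load_grayscale",
    "EmptyTissueError",
    "FilterConfigError",
]

N_CHANNELS = 10
DEFAULT_TISSUE_THRESHOLD = 0.05
DEFAULT_CROP_MARGIN = 8


class EmptyTissueError(ValueError):
    """Raised when no breast tissue can be located in an image."""


class FilterConfigError(ValueError):
    """Raised when the filter configuration does not define exactly 9 channels."""


@dataclass(frozen=True)
class GrayscaleImage:
    """A 2-D grayscale image with intensities normalized to [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("image must be a nonempty 2-D array")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BreastMask:
    """Binary tissue mask (1 = breast tissue, 0 = background)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "mask", m.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def coverage(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True)
class MultichannelImage:
    """H x W x 10 stack: raw image plus nine filter responses, with tissue mask."""

    channels: np.ndarray
    channel_names: tuple[str, ...]
    mask: BreastMask

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=np.float64)
        if ch.ndim != 3 or ch.shape[2] != N_CHANNELS:
            raise ValueError(f"channels must be H x W x {N_CHANNELS}")
        if len(self.channel_names) != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} channel names")
        if ch.shape[:2] != self.mask.shape:
            raise ValueError("mask shape must match channel spatial shape")
        object.__setattr__(self, "channels", ch)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[:2]

    @property
    def raw(self) -> np.ndarray:
        return self.channels[:, :, 0]


# ---------------------------------------------------------------------------
# Tissue mask and peripheral crop
# ---------------------------------------------------------------------------

def compute_breast_mask(
    image: GrayscaleImage, threshold: float = DEFAULT_TISSUE_THRESHOLD
) -> BreastMask:
    """Estimate the breast-tissue mask by intensity thresholding.

    Pixels brighter than ``threshold`` are candidate tissue; the largest
    connected component is kept and its holes are filled, discarding
    isolated bright specks and scanner artifacts. May return an all-zero
    mask if nothing exceeds the threshold.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    fg = image.pixels > threshold
    if not fg.any():
        return BreastMask(np.zeros(image.shape, dtype=np.uint8))
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = labels == counts.argmax()
    filled = ndi.binary_fill_holes(largest)
    return BreastMask(filled.astype(np.uint8))


def tissue_bounding_box(
    image: GrayscaleImage,
    threshold: float = DEFAULT_TISSUE_THRESHOLD,
    margin: int = DEFAULT_CROP_MARGIN,
) -> tuple[int, int, int, int]:
    """Half-open crop box (r0, r1, c0, c1) around the estimated tissue region,
    expanded symmetrically by ``margin`` and clipped to the image bounds."""
    mask = compute_breast_mask(image, threshold)
    rows = np.flatnonzero(mask.mask.any(axis=1))
    cols = np.flatnonzero(mask.mask.any(axis=0))
    if rows.size == 0:
        raise EmptyTissueError("no breast tissue found above threshold")
    r0 = max(int(rows[0]) - margin, 0)
    r1 = min(int(rows[-1]) + 1 + margin, image.height)
    c0 = max(int(cols[0]) - margin, 0)
    c1 = min(int(cols[-1]) + 1 + margin, image.width)
    return r0, r1, c0, c1


def peripheral_crop(
    image: GrayscaleImage,
    threshold: float = DEFAULT_TISSUE_THRESHOLD,
    margin: int = DEFAULT_CROP_MARGIN,
) -> tuple[GrayscaleImage, BreastMask]:
    """Crop an image to the bounding box of its estimated tissue region.

    The tightest axis-aligned box around the tissue mask is expanded
    symmetrically by ``margin`` pixels and clipped to the image bounds; the
    returned mask is the tissue mask restricted to the same crop.

    Raises
    ------
    EmptyTissueError
        If no pixel exceeds the tissue threshold.
    """
    mask = compute_breast_mask(image, threshold)
    r0, r1, c0, c1 = tissue_bounding_box(image, threshold, margin)
    cropped = GrayscaleImage(image.pixels[r0:r1, c0:c1])
    return cropped, BreastMask(mask.mask[r0:r1, c0:c1])


# ---------------------------------------------------------------------------
# Filter bank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """One filter channel: a name and a pure function of the image array."""

    name: str
    fn: Callable[[np.ndarray], np.ndarray]
    params: dict[str, Any] = field(default_factory=dict)

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        return np.asarray(self.fn(pixels, **self.params), dtype=np.float64)


def _sobel_binary(pixels: np.ndarray, threshold: float) -> np.ndarray:
    return (filters.sobel(pixels) > threshold).astype(np.float64)


def _canny(pixels: np.ndarray, sigma: float) -> np.ndarray:
    return feature.canny(pixels, sigma=sigma).astype(np.float64)


def _dog(pixels: np.ndarray, low_sigma: float, high_sigma: float) -> np.ndarray:
    return filters.difference_of_gaussians(pixels, low_sigma, high_sigma)


def _gabor_magnitude(pixels: np.ndarray, frequency: float, theta: float) -> np.ndarray:
    real, imag = filters.gabor(pixels, frequency=frequency, theta=theta)
    return np.hypot(real, imag)


def default_filter_bank() -> list[FilterSpec]:
    """The default nine-channel filter configuration.

    The channel families are Sobel (raw magnitude plus two binarizations at
    different thresholds), Canny, difference of Gaussians, gamma correction,
    histogram equalization, and Gabor magnitude at two orientations. Every
    parameter lives here, so any other nine-channel assignment is one
    config edit away.
    """
    return [
        FilterSpec("sobel_magnitude", filters.sobel),
        FilterSpec("sobel_binary_low", _sobel_binary, {"threshold": 0.1}),
        FilterSpec("sobel_binary_high", _sobel_binary, {"threshold": 0.3}),
        FilterSpec("canny", _canny, {"sigma": 1.0}),
        FilterSpec("dog", _dog, {"low_sigma": 1.0, "high_sigma": 3.0}),
        FilterSpec("gamma_0.5", exposure.adjust_gamma, {"gamma": 0.5}),
        FilterSpec("hist_equalize", exposure.equalize_hist),
        FilterSpec("gabor_0deg", _gabor_magnitude, {"frequency": 0.2, "theta": 0.0}),
        FilterSpec("gabor_90deg", _gabor_magnitude, {"frequency": 0.2, "theta": np.pi / 2}),
    ]


def _rescale_unit(channel: np.ndarray) -> np.ndarray:
    """Min-max rescale a channel onto [0, 1] when it strays outside.

    Channels already inside [0, 1] are returned unchanged so identity-like
    filters (e.g. gamma with exponent 1) stay exact; rescaling is
    rank-preserving either way. A constant out-of-range channel maps to 0.
    """
    lo, hi = float(channel.min()), float(channel.max())
    if 0.0 <= lo and hi <= 1.0:
        return channel
    if hi == lo:
        return np.zeros_like(channel)
    return (channel - lo) / (hi - lo)


def apply_filter_bank(
    image: GrayscaleImage,
    mask: BreastMask,
    filter_config: Sequence[FilterSpec] | None = None,
) -> MultichannelImage:
    """Stack the (already cropped) raw image with its nine filter responses.

    All filters are training-free and deterministic: identical input and
    configuration give bit-identical output. Channel 0 is the raw image.

    Raises
    ------
    FilterConfigError
        If the configuration does not define exactly nine filters.
    """
    if filter_config is None:
        filter_config = default_filter_bank()
    if len(filter_config) != N_CHANNELS - 1:
        raise FilterConfigError(
            f"filter_config must define exactly {N_CHANNELS - 1} channels, "
            f"got {len(filter_config)}"
        )
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    stack = np.empty(image.shape + (N_CHANNELS,), dtype=np.float64)
    stack[:, :, 0] = image.pixels
    names = ["raw"]
    for i, spec in enumerate(filter_config, start=1):
        response = spec(image.pixels)
        if response.shape != image.shape:
            raise FilterConfigError(f"filter {spec.name!r} changed the image shape")
        if not np.isfinite(response).all():
            raise FilterConfigError(f"filter {spec.name!r} produced non-finite values")
        stack[:, :, i] = _rescale_unit(response)
        names.append(spec.name)
    return MultichannelImage(stack, tuple(names), mask)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_multichannel(path, mci: MultichannelImage, source: str = "", filter_repr: str = "") -> None:
    """Write a multichannel object to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("channels", data=mci.channels.astype(np.float32))
        f.create_dataset("mask", data=mci.mask.mask)
        f.attrs["channel_names"] = list(mci.channel_names)
        f.attrs["source"] = source
        f.attrs["filter_config"] = filter_repr


def load_multichannel(path) -> MultichannelImage:
    import h5py

    with h5py.File(path, "r") as f:
        channels = f["channels"][...].astype(np.float64)
        mask = BreastMask(f["mask"][...])
        names = tuple(str(n) for n in f.attrs["channel_names"])
    return MultichannelImage(channels, names, mask)


def load_grayscale(path) -> GrayscaleImage:
    """Read a PNG/TIFF (8/16-bit) or single-frame DICOM as a [0,1] grayscale image.

    Integer images are divided by their dtype maximum; float images are
    assumed to already sit in [0, 1].
    """
    spath = str(path)
    if spath.lower().endswith((".dcm", ".dicom")):
        import pydicom

        ds = pydicom.dcmread(spath)
        arr = ds.pixel_array.astype(np.float64)
        arr = arr / max(arr.max(), 1.0)
        return GrayscaleImage(arr)
    import imageio.v3 as iio

    arr = iio.imread(spath)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return GrayscaleImage(np.clip(arr.astype(np.float64), 0.0, 1.0))
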