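"""Synthetic mammogram-like phantoms with pixel-level class masks.

Real screening mammograms show a breast-shaped tissue region against a dark
detector background, slowly varying parenchymal texture, occasional bright
roughly-Gaussian masses, and clusters of tiny very bright calcification
speckles. The generator emulates exactly those structures — enough to
exercise every stage of the pipeline (cropping, filter bank, patch
criteria, tensorization, training) offline — with per-pixel labels:
0 = healthy tissue, 1 = calcification, 2 = mass.

Everything is seeded and bit-reproducible. See the methods note for what
these phantoms deliberately do not emulate about clinical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .annotations import CLASS_CALCIFICATION, CLASS_MASS
from .enrichment import BreastMask, GrayscaleImage

__all__ = ["PhantomSpec", "ClassMix", "Phantom", "generate_phantom", "generate_cohort"]

# half-maximum of the flat-top mass profile: labeled pixels average an
# elevation of ~1.44x mass_contrast, so the configured contrast is a
# guaranteed mean elevation, not just the peak
_PLACEMENT_ATTEMPTS = 100


class PlacementError(RuntimeError):
    """Raised when a structure cannot be placed inside the breast region."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic mammogram.

    Intensities are on the [0, 1] scale; sizes in pixels. The breast is a
    half-ellipse attached to the left image edge (chest wall), as in a
    standard mammographic projection.
    """

    image_size: tuple[int, int] = (192, 192)
    breast_semiaxes: tuple[float, float] = (0.42, 0.88)  # fractions of (H, W)
    tissue_base: float = 0.45
    texture_correlation: float = 6.0   # px, smoothing length of the texture
    texture_amplitude: float = 0.08
    n_masses: int = 2
    mass_radius_range: tuple[float, float] = (6.0, 12.0)
    mass_contrast: float = 0.25
    n_calc_clusters: int = 2
    speckles_per_cluster: int = 8
    speckle_size: tuple[int, int] = (1, 3)  # pixels per speckle
    speckle_contrast: float = 0.45
    cluster_spread: float = 8.0
    noise_sd: float = 0.05
    placement_margin: int = 16  # keep structures this far inside the breast
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass_contrast <= 0 or self.speckle_contrast <= 0:
            raise ValueError("contrasts must be positive")
        if min(self.image_size) < 32:
            raise ValueError("image too small")


@dataclass(frozen=True)
class ClassMix:
    """Fractions of cohort images containing masses / calcification clusters."""

    mass_fraction: float = 1.0 / 3.0
    calc_fraction: float = 1.0 / 3.0


@dataclass(frozen=True)
class Phantom:
    image: GrayscaleImage
    breast_mask: BreastMask
    label_mask: np.ndarray
    seed: int = 0
    has_mass: bool = False
    has_calc: bool = False


def _breast_region(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.image_size
    rr, cc = np.mgrid[0:h, 0:w]
    ar = spec.breast_semiaxes[0] * h
    ac = spec.breast_semiaxes[1] * w
    cy = h / 2.0
    return (((rr - cy) / ar) ** 2 + (cc / ac) ** 2) <= 1.0


def _interior(region: np.ndarray, margin: int) -> np.ndarray:
    if margin <= 0:
        return region
    return ndi.binary_erosion(region, iterations=margin)


def _place_center(
    rng: np.random.Generator, allowed: np.ndarray, taken: list[tuple[float, float, float]],
    radius: float,
) -> tuple[int, int]:
    rows, cols = np.nonzero(allowed)
    if rows.size == 0:
        raise PlacementError("no admissible placement region inside the breast")
    for _ in range(_PLACEMENT_ATTEMPTS):
        i = int(rng.integers(rows.size))
        r, c = int(rows[i]), int(cols[i])
        if all(np.hypot(r - tr, c - tc) > radius + trad + 4 for tr, tc, trad in taken):
            return r, c
    raise PlacementError(
        f"could not place structure after {_PLACEMENT_ATTEMPTS} attempts"
    )


def generate_phantom(spec: PhantomSpec) -> tuple[GrayscaleImage, BreastMask, np.ndarray]:
    """Render one phantom: (image, breast mask, per-pixel label mask).

    The breast half-ellipse is filled with low-frequency smoothed-noise
    texture around a base intensity; masses are flat-topped Gaussian blobs
    (labeled class 2 where the profile is at or above half its peak);
    calcifications are clusters of 1-3 px bright speckles (labeled class 1);
    additive Gaussian pixel noise covers the whole frame. Same seed, same
    output, bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    region = _breast_region(spec)
    labels = np.zeros((h, w), dtype=np.uint8)

    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), spec.texture_correlation)
    sd = texture.std()
    if sd > 0:
        texture *= spec.texture_amplitude / sd
    image = np.where(region, spec.tissue_base + texture, 0.0)

    taken: list[tuple[float, float, float]] = []
    rr, cc = np.mgrid[0:h, 0:w]

    for _ in range(spec.n_masses):
        radius = float(rng.uniform(*spec.mass_radius_range))
        allowed = _interior(region, spec.placement_margin + int(np.ceil(radius)))
        r0, c0 = _place_center(rng, allowed, taken, radius)
        taken.append((r0, c0, radius))
        sigma = radius / 2.0
        d2 = (rr - r0) ** 2.0 + (cc - c0) ** 2.0
        profile = np.exp(-d2 / (2.0 * sigma**2))
        # flat top at 2x contrast so labeled pixels average >= the contrast
        peak = 2.0 * spec.mass_contrast
        image += peak * np.minimum(profile * 2.0, 1.0) * region
        labels[(profile >= 0.5) & region] = CLASS_MASS

    for _ in range(spec.n_calc_clusters):
        reach = int(np.ceil(2.0 * spec.cluster_spread)) + spec.speckle_size[1]
        allowed = _interior(region, spec.placement_margin + reach)
        r0, c0 = _place_center(rng, allowed, taken, spec.cluster_spread)
        taken.append((r0, c0, spec.cluster_spread))
        for _ in range(spec.speckles_per_cluster):
            dr, dc = rng.normal(0.0, spec.cluster_spread, 2)
            sr = int(np.clip(round(r0 + dr), 0, h - 1))
            sc = int(np.clip(round(c0 + dc), 0, w - 1))
            n_px = int(rng.integers(spec.speckle_size[0], spec.speckle_size[1] + 1))
            px = [(sr, sc)]
            while len(px) < n_px:
                pr, pc = px[-1]
                step = rng.integers(-1, 2, 2)
                cand = (int(np.clip(pr + step[0], 0, h - 1)),
                        int(np.clip(pc + step[1], 0, w - 1)))
                if cand not in px:
                    px.append(cand)
            for pr, pc in px:
                if region[pr, pc]:
                    image[pr, pc] += spec.speckle_contrast
                    labels[pr, pc] = CLASS_CALCIFICATION

    image += rng.normal(0.0, spec.noise_sd, (h, w))
    image = np.clip(image, 0.0, 1.0)
    return (
        GrayscaleImage(image),
        BreastMask(region.astype(np.uint8)),
        labels,
    )


def generate_cohort(
    n_images: int,
    spec_template: PhantomSpec | None = None,
    class_mix: ClassMix | None = None,
    seed: int = 0,
) -> list[Phantom]:
    """Generate a deterministic cohort of phantoms.

    Exactly ``round(mass_fraction * n)`` images (the first ones) contain
    masses and ``round(calc_fraction * n)`` (the last ones) contain
    calcification clusters; images in between are healthy. Per-image seeds
    derive from the master seed, so disjoint master seeds give disjoint
    cohorts.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    spec_template = spec_template or PhantomSpec()
    class_mix = class_mix or ClassMix()
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_images)
    n_mass = int(np.floor(class_mix.mass_fraction * n_images + 0.5))
    n_calc = int(np.floor(class_mix.calc_fraction * n_images + 0.5))
    cohort: list[Phantom] = []
    for i in range(n_images):
        has_mass = i < n_mass
        has_calc = i >= n_images - n_calc
        spec = replace(
            spec_template,
            seed=int(child_seeds[i]),
            n_masses=spec_template.n_masses if has_mass else 0,
            n_calc_clusters=spec_template.n_calc_clusters if has_calc else 0,
        )
        image, bmask, labels = generate_phantom(spec)
        cohort.append(Phantom(image, bmask, labels, seed=spec.seed,
                              has_mass=has_mass, has_calc=has_calc))
    return cohort
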