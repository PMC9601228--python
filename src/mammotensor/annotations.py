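"""Lesion annotations: contour rasterization and label-image loading.

Label masks use per-pixel class codes: 0 = healthy tissue, 1 = calcification,
2 = malignant mass. Contours arrive either as pre-rasterized label images or
as polygon point lists (e.g. parsed from clinical annotation XML), given in
(row, col) image coordinates.
"""

from __future__ import annotations

from typing import Iterable, Sequence
import xml.etree.ElementTree as ET

import numpy as np
from skimage import draw

CLASS_HEALTHY = 0
CLASS_CALCIFICATION = 1
CLASS_MASS = 2
N_CLASSES = 3

# annotation names commonly used for the two abnormality families
_NAME_TO_CLASS = {
    "calcification": CLASS_CALCIFICATION,
    "calcifications": CLASS_CALCIFICATION,
    "cluster": CLASS_CALCIFICATION,
    "mass": CLASS_MASS,
    "masses": CLASS_MASS,
    "tumor": CLASS_MASS,
}


def rasterize_contours(
    shape: tuple[int, int],
    contours: Iterable[tuple[int, Sequence[tuple[float, float]]]],
) -> np.ndarray:
    """Fill polygon contours into a label mask.

    Parameters
    ----------
    shape
        (height, width) of the target mask.
    contours
        Iterable of ``(class_code, points)`` with points as (row, col) pairs.
        Single-point contours mark individual pixels (typical for
        calcification annotations).
    """
    mask = np.zeros(shape, dtype=np.uint8)
    for code, points in contours:
        pts = np.asarray(points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("contour points must be (row, col) pairs")
        if len(pts) < 3:
            rr = np.clip(np.round(pts[:, 0]).astype(int), 0, shape[0] - 1)
            cc = np.clip(np.round(pts[:, 1]).astype(int), 0, shape[1] - 1)
        else:
            rr, cc = draw.polygon(pts[:, 0], pts[:, 1], shape=shape)
        mask[rr, cc] = code
    return mask


def parse_contour_xml(path) -> list[tuple[int, list[tuple[float, float]]]]:
    """Parse a plist-style annotation XML into (class_code, points) contours.

    Understands the nested dict/array layout used by clinical contouring
    tools: each ROI dict carries a ``Name`` string and a ``Point_px`` array
    of "(x, y)" strings. Points are returned as (row, col).
    """
    root = ET.parse(str(path)).getroot()
    contours: list[tuple[int, list[tuple[float, float]]]] = []
    for roi in root.iter("dict"):
        name, points = None, None
        children = list(roi)
        for key_el, val_el in zip(children, children[1:]):
            if key_el.tag != "key":
                continue
            if key_el.text == "Name":
                name = (val_el.text or "").strip().lower()
            elif key_el.text == "Point_px":
                points = [
                    _parse_point(s.text or "") for s in val_el if s.tag == "string"
                ]
        if name is not None and points:
            code = _NAME_TO_CLASS.get(name)
            if code is not None:
                contours.append((code, points))
    return contours


def _parse_point(text: str) -> tuple[float, float]:
    x, y = text.strip().strip("()").split(",")
    return float(y), float(x)  # (x, y) on disk -> (row, col)


def load_label_image(path) -> np.ndarray:
    """Read a pre-rasterized label image with pixel codes {0, 1, 2}."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    codes = np.unique(arr)
    if not np.isin(codes, (CLASS_HEALTHY, CLASS_CALCIFICATION, CLASS_MASS)).all():
        raise ValueError(f"label image contains unexpected codes {codes}")
    return arr.astype(np.uint8)
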