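"""Condensate image quantification.

Three primitives operationalize the microscopy analyses: ROI-restricted
Pearson colocalization between two channels, threshold/connected-component
focus detection with size measurement, and a pixel-distance contact test
("no empty space observable between two foci" read as a boundary distance
of at most ``tol_px``).  On top of these sits the tri-condensate
arrangement taxonomy for E/P/Z germ-granule compartments.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage.filters import threshold_otsu

ARRANGEMENT_CATEGORIES = ("EP_only", "EPZ", "multiE_P", "other")

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def pearson_coloc(img_a: np.ndarray, img_b: np.ndarray, roi_mask: np.ndarray) -> float:
    """Pearson's R between two channels over the ROI pixels (no thresholding)."""
    a, b = np.asarray(img_a, dtype=float), np.asarray(img_b, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("channel images and ROI mask must share dimensions")
    x, y = a[mask], b[mask]
    if x.size < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson's R undefined: zero variance within ROI")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class Focus:
    """A segmented fluorescent focus (4-connected pixel component)."""

    pixels: np.ndarray  # (n, 2) integer row/col coordinates
    centroid: tuple[float, float]
    area: int
    channel: str = ""

    @classmethod
    def from_pixels(cls, pixels: np.ndarray, channel: str = "") -> "Focus":
        pixels = np.asarray(pixels, dtype=int)
        return cls(
            pixels=pixels,
            centroid=tuple(pixels.mean(axis=0)),
            area=len(pixels),
            channel=channel,
        )


def detect_foci(
    image: np.ndarray,
    threshold: float | str = "otsu",
    min_area: int = 4,
    channel: str = "",
) -> list[Focus]:
    """Segment foci: pixels above threshold grouped by 4-connectivity.

    ``threshold`` is a fixed intensity or ``"otsu"``.  Components smaller
    than ``min_area`` are discarded; an empty list is returned when nothing
    passes.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if threshold == "otsu":
        if np.ptp(img) == 0:
            return []
        thr = float(threshold_otsu(img))
    else:
        thr = float(threshold)
    binary = img > thr
    labels, n = ndimage.label(binary, structure=_FOUR_CONN)
    foci = []
    for i in range(1, n + 1):
        pix = np.argwhere(labels == i)
        if len(pix) >= min_area:
            foci.append(Focus.from_pixels(pix, channel=channel))
    return foci


def contact(focus_a: Focus, focus_b: Focus, tol_px: float = 1.0) -> bool:
    """True iff the minimum pixel-to-pixel distance between the two foci is
    at most ``tol_px``."""
    return bool(cdist(focus_a.pixels, focus_b.pixels).min() <= tol_px)


@dataclass(frozen=True)
class ArrangementCall:
    """Contact-topology category of one germ granule plus its contact graph."""

    category: str
    contacts: tuple[tuple[str, str], ...]  # edges as (label_a, label_b)


def classify_arrangement(
    p_focus: Focus,
    e_foci: Sequence[Focus],
    z_foci: Sequence[Focus],
    tol_px: float = 1.0,
) -> ArrangementCall:
    """Assign the granule's E/P/Z contact arrangement.

    With the P granule as anchor: exactly one E in contact with P and no
    E-Z contact is ``EP_only``; one E in contact with P that also touches a
    Z is ``EPZ``; two or more E on the same P is ``multiE_P``; anything
    else (including no E contacting P) is ``other``.  Z foci not contacting
    anything are ignored.
    """
    if p_focus is None:
        raise ValueError("a P focus is required to anchor the granule")
    edges: list[tuple[str, str]] = []
    e_on_p: list[int] = []
    for i, e in enumerate(e_foci):
        if contact(e, p_focus, tol_px):
            e_on_p.append(i)
            edges.append((f"E{i}", "P"))
    e_z_pairs: set[tuple[int, int]] = set()
    for i, e in enumerate(e_foci):
        for j, z in enumerate(z_foci):
            if contact(e, z, tol_px):
                e_z_pairs.add((i, j))
                edges.append((f"E{i}", f"Z{j}"))
    for j, z in enumerate(z_foci):
        if contact(z, p_focus, tol_px):
            edges.append((f"Z{j}", "P"))
    if len(e_on_p) == 1:
        i = e_on_p[0]
        category = "EPZ" if any(p[0] == i for p in e_z_pairs) else "EP_only"
    elif len(e_on_p) >= 2:
        category = "multiE_P"
    else:
        category = "other"
    return ArrangementCall(category=category, contacts=tuple(edges))


def arrangement_from_images(
    images: dict[str, np.ndarray],
    threshold: float | str = "otsu",
    min_area: int = 4,
    tol_px: float = 1.0,
) -> ArrangementCall:
    """Segment one granule field (channels 'E', 'P', 'Z') and classify it.

    The largest P component anchors the granule; raises when no P focus is
    detected.
    """
    p_foci = detect_foci(images["P"], threshold, min_area, channel="P")
    if not p_foci:
        raise ValueError("no P focus detected in field")
    p_focus = max(p_foci, key=lambda f: f.area)
    e_foci = detect_foci(images.get("E", np.zeros_like(images["P"])), threshold, min_area, "E")
    z_foci = detect_foci(images.get("Z", np.zeros_like(images["P"])), threshold, min_area, "Z")
    return classify_arrangement(p_focus, e_foci, z_foci, tol_px)


def category_percentages(calls: Sequence[ArrangementCall]) -> dict[str, float]:
    """Per-cohort summary: percentage of granules in each category."""
    n = len(calls)
    out = {}
    for cat in ARRANGEMENT_CATEGORIES:
        out[cat] = 100.0 * sum(c.category == cat for c in calls) / n if n else 0.0
    return out
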