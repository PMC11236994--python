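"""Synthetic multi-channel foci fields with known contact topology.

Each focus is rendered as a flat-topped radial profile
``intensity * exp(-(d/r)**4)`` — bright and nearly uniform inside the
radius, falling off sharply at the edge — so that threshold segmentation
recovers a disc of approximately the nominal radius.  The ground-truth
contact graph is computed analytically from centers and radii with the
same boundary-distance tolerance the imaging contact test uses, so
generator truth and re-segmented calls share one contact contract.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .genome import largest_remainder
from .imaging import ARRANGEMENT_CATEGORIES


@dataclass(frozen=True)
class FocusSpec:
    channel: str  # 'E', 'P' or 'Z'
    center: tuple[float, float]  # (row, col)
    radius: float
    intensity: float = 1000.0


def truth_contact(a: FocusSpec, b: FocusSpec, tol_px: float = 1.0) -> bool:
    """Analytic contact: boundary distance (center distance minus both radii)
    at most ``tol_px``."""
    d = float(np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1]))
    return d - a.radius - b.radius <= tol_px


def truth_contact_graph(
    layout: Sequence[FocusSpec], tol_px: float = 1.0
) -> list[tuple[int, int]]:
    return [
        (i, j)
        for i in range(len(layout))
        for j in range(i + 1, len(layout))
        if truth_contact(layout[i], layout[j], tol_px)
    ]


def simulate_foci_image(
    layout: Sequence[FocusSpec],
    image_size: tuple[int, int] = (48, 48),
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    contact_tol: float = 1.0,
    min_same_channel_gap: float = 1.0,
) -> tuple[dict[str, np.ndarray], list[tuple[int, int]]]:
    """Render a layout into per-channel images plus its truth contact graph.

    Raises when a focus does not fit inside the image or when two
    same-channel foci sit closer than the resolvable limit
    (boundary distance < ``min_same_channel_gap``).
    """
    h, w = image_size
    for f in layout:
        r0, c0 = f.center
        if not (f.radius <= r0 <= h - 1 - f.radius and f.radius <= c0 <= w - 1 - f.radius):
            raise ValueError(f"focus at {f.center} (r={f.radius}) does not fit in {image_size}")
    for i, a in enumerate(layout):
        for b in layout[i + 1 :]:
            if a.channel == b.channel:
                d = float(np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1]))
                if d - a.radius - b.radius < min_same_channel_gap:
                    raise ValueError(
                        f"unresolvable same-channel ({a.channel}) foci at "
                        f"{a.center} and {b.center}"
                    )
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0:h, 0:w]
    channels = sorted({f.channel for f in layout})
    images = {ch: np.zeros((h, w)) for ch in channels}
    for f in layout:
        d = np.hypot(rows - f.center[0], cols - f.center[1])
        images[f.channel] += f.intensity * np.exp(-((d / f.radius) ** 4))
    if noise_sd > 0:
        for ch in channels:
            images[ch] = np.clip(images[ch] + rng.normal(0.0, noise_sd, size=(h, w)), 0.0, None)
    return images, truth_contact_graph(layout, contact_tol)


@dataclass(frozen=True)
class GranuleScene:
    """One germ granule: its foci layout and intended arrangement category."""

    layout: tuple[FocusSpec, ...]
    category: str


# default geometry (px): a P granule anchor with E and Z satellites
_R_P, _R_E, _R_Z = 4.5, 3.0, 3.0
_TOUCH = -0.5  # boundary overlap for 'in contact' placements
_APART = 4.0   # boundary gap for 'not in contact' placements


def _polar(center: tuple[float, float], angle: float, dist: float) -> tuple[float, float]:
    return (center[0] + dist * np.sin(angle), center[1] + dist * np.cos(angle))


def make_granule_scene(category: str, angle: float, center=(24.0, 24.0)) -> GranuleScene:
    """Deterministic layout realizing one arrangement category.

    ``EP_only``: one E on P; a Z on P at a far angle (touching P, not E).
    ``EPZ``: one E on P with a Z docked on the E's far side.
    ``multiE_P``: two E on P, one of them also touching a Z.
    """
    p = FocusSpec("P", center, _R_P)
    d_ep = _R_P + _R_E + _TOUCH
    d_ez = _R_E + _R_Z + _TOUCH
    e1 = FocusSpec("E", _polar(center, angle, d_ep), _R_E)
    if category == "EP_only":
        z = FocusSpec("Z", _polar(center, angle + 2.6, _R_P + _R_Z + _TOUCH), _R_Z)
        layout = (p, e1, z)
    elif category == "EPZ":
        z = FocusSpec("Z", _polar(center, angle, d_ep + d_ez), _R_Z)
        layout = (p, e1, z)
    elif category == "multiE_P":
        e2 = FocusSpec("E", _polar(center, angle + 2.1, d_ep), _R_E)
        z = FocusSpec("Z", _polar(center, angle, d_ep + d_ez), _R_Z)
        layout = (p, e1, e2, z)
    else:
        raise ValueError(f"unknown category {category!r}")
    return GranuleScene(layout=layout, category=category)


def make_granule_cohort(
    n: int = 210,
    weights: Sequence[float] = (0.32, 0.48, 0.20),
    seed: int = 0,
) -> list[GranuleScene]:
    """A cohort of granules with category composition ``weights``.

    Category counts are allocated by largest remainder (the observed
    composition of a fixed-size cohort), the order shuffled and each
    granule given a random orientation.
    """
    cats = ("EP_only", "EPZ", "multiE_P")
    counts = largest_remainder(dict(zip(cats, weights)), n)
    rng = np.random.default_rng(seed)
    scenes = [cat for cat in cats for _ in range(counts[cat])]
    scenes = [scenes[i] for i in rng.permutation(n)]
    return [make_granule_scene(cat, angle=float(rng.uniform(0, 2 * np.pi))) for cat in scenes]
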