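"""Axon degeneration index (DI) on images, and a threshold-onset model.

The DI operator follows the standard particle-shape convention: binarize a
brightfield-like image, run connected-component analysis, and classify
particles with circularity 4*pi*area/perimeter^2 above a threshold as
fragments.  DI is fragmented particle area over total foreground area, so
intact (elongated, low-circularity) axons score near 0 and fully
fragmented fields of round blebs score near 1.  DI > 0.3 marks a
degenerated field.

``threshold_onset_model`` links simulated NAD+ trajectories to DI time
courses: degeneration begins once axonal NAD+ falls below a critical
fraction of its pre-injury baseline, then DI rises logistically.  It is an
artifact-level construct (the quantitative NAD+ -> fragmentation mapping is
not an experimentally measured curve) and requires the SARM1 executioner:
SARM1-deficient axons cross the NAD+ threshold without degenerating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import draw as _draw
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label, regionprops

__all__ = [
    "AxonImage",
    "DegenerationRecord",
    "synth_axon_image",
    "degeneration_index",
    "threshold_onset_model",
    "DEGENERATION_DEFAULTS",
]

DEGENERATION_DEFAULTS = {
    "circularity_threshold": 0.2,
    "threshold_fraction": 0.5,
    "lag_h": 5.0,
    "rate_h": 1.0,
    "n_fields": 6,
}


@dataclass
class AxonImage:
    """A 2-D grayscale field of simulated axons, intensities in [0, 1]."""

    pixels: np.ndarray
    pixel_size_um: float = 0.65  # 20x objective scale
    true_di: float | None = None
    seed: int | None = None


@dataclass
class DegenerationRecord:
    scenario_id: str
    well_id: str
    time_h: float
    di: float
    n_fields: int

    def __post_init__(self):
        if not 0.0 <= self.di <= 1.0:
            raise ValueError("DI must lie in [0, 1]")


def _fiber_path(rng: np.random.Generator, shape) -> np.ndarray:
    """A smooth curvilinear path across the field (random quadratic Bezier)."""
    h, w = shape
    side = rng.integers(0, 2)
    if side == 0:  # left-to-right
        p0 = np.array([rng.uniform(0.1, 0.9) * h, 0.0])
        p2 = np.array([rng.uniform(0.1, 0.9) * h, w - 1.0])
    else:  # top-to-bottom
        p0 = np.array([0.0, rng.uniform(0.1, 0.9) * w])
        p2 = np.array([h - 1.0, rng.uniform(0.1, 0.9) * w])
    p1 = np.array([rng.uniform(0.2, 0.8) * h, rng.uniform(0.2, 0.8) * w])
    s = np.linspace(0.0, 1.0, 400)[:, None]
    pts = (1 - s) ** 2 * p0 + 2 * s * (1 - s) * p1 + s**2 * p2
    return pts


def synth_axon_image(
    true_di: float,
    density: int = 6,
    seed: int = 0,
    *,
    shape: tuple = (256, 256),
    fiber_radius: int = 1,
    fragment_radius: int = 3,
) -> AxonImage:
    """Render a synthetic axon field with a known ground-truth fragmentation.

    A fraction ``true_di`` of each fiber's path length is replaced by round
    fragment blobs; the remainder is drawn as a continuous curvilinear
    fiber.  Deterministic for a fixed seed.
    """
    if not 0.0 <= true_di <= 1.0:
        raise ValueError("true_di must lie in [0, 1]")
    if density <= 0:
        raise ValueError("density must be > 0")
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=float)
    for _ in range(density):
        pts = _fiber_path(rng, shape)
        n = len(pts)
        n_intact = int(round((1.0 - true_di) * n))
        intact = pts[:n_intact]
        for a, b in zip(intact[:-1], intact[1:]):
            rr, cc = _draw.line(
                int(round(a[0])), int(round(a[1])), int(round(b[0])), int(round(b[1]))
            )
            for dr in range(-fiber_radius, fiber_radius + 1):
                for dc in range(-fiber_radius, fiber_radius + 1):
                    r = np.clip(rr + dr, 0, shape[0] - 1)
                    c = np.clip(cc + dc, 0, shape[1] - 1)
                    img[r, c] = 1.0
        frag = pts[n_intact:]
        if len(frag):
            # fragments: well-separated disks along the broken stretch
            spacing = max(3 * fragment_radius, 9)
            step = max(int(round(n / ((n * true_di) / spacing))) if true_di > 0 else n, 1)
            for p in frag[::step]:
                r0, c0 = p + rng.normal(0.0, 1.5, 2)
                rr, cc = _draw.disk(
                    (float(r0), float(c0)), fragment_radius, shape=shape
                )
                img[rr, cc] = 1.0
    img = gaussian_filter(img, sigma=0.6)
    if img.max() > 0:
        img = img / img.max()
    return AxonImage(pixels=img, true_di=true_di, seed=seed)


def degeneration_index(
    image: AxonImage | np.ndarray,
    *,
    circularity_threshold: float = DEGENERATION_DEFAULTS["circularity_threshold"],
    min_area: int = 5,
) -> float:
    """Degeneration index: fragmented particle area / total foreground area.

    Contrast-stretches, Otsu-binarizes, labels connected components and
    classifies particles with circularity 4*pi*A/P^2 above the threshold as
    fragments.  Raises on an empty foreground.
    """
    px = image.pixels if isinstance(image, AxonImage) else np.asarray(image, float)
    lo, hi = float(px.min()), float(px.max())
    if hi <= lo:
        raise ValueError("undefined DI: image has no foreground")
    px = (px - lo) / (hi - lo)
    binary = px > threshold_otsu(px)
    if not binary.any():
        raise ValueError("undefined DI: empty foreground after binarization")
    labels = _cc_label(binary, connectivity=2)
    total = 0.0
    fragmented = 0.0
    for region in regionprops(labels):
        if region.area < min_area:
            continue
        # Crofton perimeter: robust on diagonal fibers, where the weighted
        # pixel-count estimator collapses and inflates circularity
        perim = region.perimeter_crofton
        circ = 4.0 * np.pi * region.area / perim**2 if perim > 0 else 1.0
        total += region.area
        if circ > circularity_threshold:
            fragmented += region.area
    if total == 0:
        raise ValueError("undefined DI: no particles above the size floor")
    return float(fragmented / total)


def threshold_onset_model(
    t: np.ndarray,
    nad: np.ndarray,
    *,
    threshold_fraction: float = DEGENERATION_DEFAULTS["threshold_fraction"],
    lag_h: float = DEGENERATION_DEFAULTS["lag_h"],
    rate_h: float = DEGENERATION_DEFAULTS["rate_h"],
    baseline: float | None = None,
    t_onset_from: float = 0.0,
    sarm1_present: bool = True,
) -> np.ndarray:
    """DI(t) from an NAD+ trajectory: zero until NAD+ crosses the threshold,
    then a logistic rise toward 1 with the given lag and rate.

    ``baseline`` defaults to NAD+ at ``t_onset_from`` (the moment of injury).
    If the trajectory never crosses ``threshold_fraction * baseline``, or if
    the SARM1 executioner is absent, the axon is protected and DI stays 0.
    """
    t = np.asarray(t, dtype=float)
    nad = np.asarray(nad, dtype=float)
    if t.shape != nad.shape:
        raise ValueError("t and nad must have matching shapes")
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    di = np.zeros_like(t)
    if not sarm1_present:
        return di
    if baseline is None:
        i0 = int(np.searchsorted(t, t_onset_from))
        i0 = min(i0, len(t) - 1)
        baseline = float(nad[i0])
    if baseline <= 0:
        return di
    below = (nad < threshold_fraction * baseline) & (t >= t_onset_from)
    if not below.any():
        return di
    t_cross = float(t[np.argmax(below)])
    after = t >= t_cross
    di[after] = 1.0 / (1.0 + np.exp(-(t[after] - t_cross - lag_h) / rate_h))
    return di
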