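"""Virtual detectors: scan-space images reconstructed from diffraction space.

At each scan position the recorded pattern is integrated over an annular
(or disc) region of the detector, exactly as a physical annular dark-field
detector would — except the "detector" is applied after the fact, so any
geometry can be chosen.  The transmitted-intensity map combines the raw
central-beam signal (hybrid counting saturates there through coincidence)
with hybrid counts integrated at Bragg peak positions, both in electron
units, for downstream thickness estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import tifffile

from .frame_io import FrameStack4D

logger = logging.getLogger(__name__)

__all__ = [
    "VirtualDetector", "VirtualImage",
    "virtual_image", "transmitted_intensity_map",
    "estimate_beam_radius", "default_adf_detector", "write_virtual_image",
]


@dataclass
class VirtualDetector:
    """Annular integration region on the detector.

    ``outer_radius_px`` may be ``np.inf`` to run to the detector edge; a
    disc is ``inner_radius_px = 0``.
    """

    centre: tuple[float, float]
    inner_radius_px: float
    outer_radius_px: float

    def __post_init__(self) -> None:
        if not 0 <= self.inner_radius_px < self.outer_radius_px:
            raise ValueError(
                f"need 0 <= inner < outer, got inner={self.inner_radius_px} "
                f"outer={self.outer_radius_px}")

    def mask(self, det_shape: tuple[int, int]) -> np.ndarray:
        yy = np.arange(det_shape[0])[:, None] - self.centre[0]
        xx = np.arange(det_shape[1])[None, :] - self.centre[1]
        rr = np.sqrt(yy * yy + xx * xx)
        return (rr >= self.inner_radius_px) & (rr < self.outer_radius_px)


@dataclass
class VirtualImage:
    """Scan-space image produced by a virtual detector."""

    values: np.ndarray
    detector: VirtualDetector | None
    source_tag: str = "raw_adu"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("virtual image must be 2D (scan space)")


def virtual_image(stack: FrameStack4D, det: VirtualDetector) -> VirtualImage:
    """Integrate every frame over the annulus: one value per scan position."""
    mask = det.mask(stack.det_shape)
    if not mask.any():
        raise ValueError("virtual detector annulus does not intersect the "
                         f"frame (det_shape={stack.det_shape})")
    vals = stack.data[:, :, mask].sum(axis=2)
    return VirtualImage(vals, det, stack.dtype_tag)


def estimate_beam_radius(stack: FrameStack4D,
                         bg_factor: float = 2.0) -> float:
    """Radius (px) where the central beam sinks into the background.

    The aggregate pattern over all scan positions is centred on its
    brightest pixel and reduced to azimuthal ring medians (medians, so a
    ring grazed by a few Bragg-spot arcs still reads as background);
    walking outward from the centre, the beam radius is the first ring
    whose median drops to within ``bg_factor`` times the background level
    (median of the outer-half ring medians, floored at half a count for
    sparse data).
    """
    agg = stack.data.sum(axis=(0, 1)).astype(float)
    if agg.max() <= 0:
        raise ValueError("aggregate pattern is empty")
    centre = np.unravel_index(np.argmax(agg), agg.shape)
    yy = np.arange(agg.shape[0])[:, None] - centre[0]
    xx = np.arange(agg.shape[1])[None, :] - centre[1]
    rr = np.rint(np.sqrt(yy * yy + xx * xx)).astype(int).ravel()
    vals = agg.ravel()
    r_max = rr.max()
    order = np.argsort(rr, kind="stable")
    bounds = np.searchsorted(rr[order], np.arange(r_max + 2))
    ring_median = np.array([
        np.median(vals[order[bounds[r]:bounds[r + 1]]])
        if bounds[r + 1] > bounds[r] else 0.0
        for r in range(r_max + 1)])
    bg = float(np.median(ring_median[r_max // 2:]))
    threshold = bg_factor * max(bg, 0.5)
    for r in range(1, r_max + 1):
        if ring_median[r] <= threshold:
            return float(r)
    return float(r_max)


def default_adf_detector(stack: FrameStack4D,
                         inner_scale: float = 1.5) -> VirtualDetector:
    """Annular dark-field detector: inner radius 1.5x the beam disc radius,
    outer radius at the detector edge."""
    r = estimate_beam_radius(stack)
    centre = ((stack.det_shape[0] - 1) / 2.0, (stack.det_shape[1] - 1) / 2.0)
    return VirtualDetector(centre, inner_scale * r, np.inf)


def transmitted_intensity_map(stack_raw: FrameStack4D,
                              beam: VirtualDetector,
                              gain_adu_per_electron: float,
                              peaks=None,
                              hybrid_stack: FrameStack4D | None = None,
                              peak_radius_px: float = 3.0) -> VirtualImage:
    """Total transmitted electrons per scan position.

    ``I_xy`` is the raw central-beam integral converted to electron units by
    the gain (the beam saturates hybrid counting through coincidence, so raw
    ADU after dark subtraction is the honest estimator there) plus the
    hybrid counts integrated in discs of ``peak_radius_px`` at each Bragg
    peak (elastically scattered electrons are transmitted electrons too;
    dropping them overstates the apparent inelastic loss and hence the
    thickness).  Without a peak list only the central-beam term is computed,
    with a warning.
    """
    if not gain_adu_per_electron > 0:
        raise ValueError("gain_adu_per_electron must be > 0")
    beam_img = virtual_image(stack_raw, beam)
    vals = beam_img.values.astype(float) / gain_adu_per_electron

    if peaks is None or getattr(peaks, "n_peaks", len(peaks) if
                                hasattr(peaks, "__len__") else 0) == 0:
        logger.warning("transmitted_intensity_map: no Bragg peak list — "
                       "central-beam-only transmission will overestimate "
                       "thickness")
        return VirtualImage(vals, beam, "electrons")

    if hybrid_stack is None:
        raise ValueError("a hybrid-count stack is required to integrate "
                         "Bragg-peak intensity")
    det_shape = hybrid_stack.det_shape
    peak_mask = np.zeros(det_shape, dtype=bool)
    positions = peaks.positions if hasattr(peaks, "positions") \
        else np.asarray(peaks, dtype=float).reshape(-1, 2)
    yy = np.arange(det_shape[0])[:, None]
    xx = np.arange(det_shape[1])[None, :]
    for r, c in positions:
        peak_mask |= ((yy - r) ** 2 + (xx - c) ** 2) <= peak_radius_px ** 2
    # keep the two terms disjoint: the beam disc wins where they overlap
    peak_mask &= ~beam.mask(det_shape)
    vals = vals + hybrid_stack.data[:, :, peak_mask].sum(axis=2)
    return VirtualImage(vals, beam, "electrons")


def write_virtual_image(img: VirtualImage, path) -> None:
    """Write a virtual image as 32-bit float TIFF."""
    tifffile.imwrite(path, img.values.astype(np.float32))
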