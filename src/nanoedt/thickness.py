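"""Log-ratio thickness mapping and tilt-image preparation.

Crystal thickness per scan position follows the log-ratio model familiar
from energy-loss spectroscopy: ``Z_xy = lambda * ln(I0 / I_xy)`` with
``lambda`` the inelastic mean free path through the crystal (332 nm for
these peptide crystals) and ``I_xy`` the transmitted intensity — central
beam plus elastically scattered Bragg intensity, both in electrons.  The
incident intensity ``I0`` is taken from vacuum (a hole in the support
film) as the mean transmitted value minus two standard deviations, a
conservative estimate that absorbs beam-current fluctuation.

``prepare_tilt_images`` turns per-tilt thickness maps into the aligned,
cropped, background-subtracted stack a tomographic reconstruction would
consume; the reconstruction itself is out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import tifffile
from skimage.registration import phase_cross_correlation

from .segmentation import RegionMask
from .virtual_imaging import VirtualImage

logger = logging.getLogger(__name__)

__all__ = [
    "ThicknessModel", "ThicknessMap",
    "estimate_i0", "thickness_map", "prepare_tilt_images",
    "write_thickness_map", "write_tilt_stack",
]

#: Inelastic mean free path through the peptide crystal, nm.
DEFAULT_LAMBDA_MFP_NM = 332.0


@dataclass
class ThicknessModel:
    """Mean free path (nm) and incident intensity (electrons)."""

    lambda_mfp_nm: float = DEFAULT_LAMBDA_MFP_NM
    i0_e: float = 1.0

    def __post_init__(self) -> None:
        if not self.lambda_mfp_nm > 0:
            raise ValueError("lambda_mfp_nm must be > 0")
        if not self.i0_e > 0:
            raise ValueError("i0_e must be > 0")


@dataclass
class ThicknessMap:
    """Per-scan-position thickness (nm) with a validity mask."""

    z_nm: np.ndarray
    valid: np.ndarray
    model: ThicknessModel

    def __post_init__(self) -> None:
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.z_nm.shape != self.valid.shape:
            raise ValueError("z and valid must share shape")
        if np.any(self.z_nm[self.valid] < 0):
            raise ValueError("thickness must be >= 0 where valid")


def estimate_i0(transmitted: VirtualImage,
                vacuum_region: RegionMask) -> float:
    """Incident intensity from vacuum: mean minus two standard deviations.

    The 2-sigma margin makes I0 a lower bound robust to shot-to-shot beam
    fluctuation; the resulting small negative bias in thickness is the
    accepted trade-off of the estimator.
    """
    if transmitted.values.shape != vacuum_region.mask.shape:
        raise ValueError("vacuum region shape must match the image")
    vals = transmitted.values[vacuum_region.mask].astype(float)
    if vals.size == 0:
        raise ValueError("vacuum region is empty")
    i0 = float(vals.mean() - 2.0 * vals.std())
    if i0 <= 0:
        raise ValueError(
            f"non-positive I0 estimate ({i0:.3g}); vacuum region too noisy "
            "or mislocated")
    return i0


def thickness_map(transmitted: VirtualImage,
                  model: ThicknessModel) -> ThicknessMap:
    """Z_xy = lambda * ln(I0 / I_xy), elementwise over the scan.

    Pixels with non-positive transmitted intensity are flagged invalid;
    pixels brighter than I0 (possible over vacuum, where the estimator's
    2-sigma margin puts I0 below the mean) clamp to zero thickness, with
    the clamp count logged.
    """
    i_xy = transmitted.values.astype(float)
    valid = i_xy > 0
    z = np.zeros_like(i_xy)
    z[valid] = model.lambda_mfp_nm * np.log(model.i0_e / i_xy[valid])
    n_clamped = int(np.count_nonzero(z[valid] < 0))
    if n_clamped:
        logger.info("thickness_map: %d pixels brighter than I0 clamped to "
                    "zero thickness", n_clamped)
    z[valid & (z < 0)] = 0.0
    z[~valid] = 0.0
    return ThicknessMap(z, valid, model)


def prepare_tilt_images(maps: list[ThicknessMap], tilts_deg,
                        background_strip_px: int = 3) -> np.ndarray:
    """Align, crop and background-correct thickness maps for reconstruction.

    Consecutive maps are registered by integer-pixel cross-correlation and
    the cumulative shifts applied relative to the first map; the stack is
    cropped to the field of view common to all tilts.  A flat background
    (the mean over a ``background_strip_px``-wide strip along the leading
    columns, which the acquisition keeps over vacuum/support) is subtracted
    per image and negatives are clipped to zero.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps to prepare a tilt stack")
    tilts = np.asarray(tilts_deg, dtype=float)
    if tilts.size != len(maps):
        raise ValueError("one tilt angle per map required")

    imgs = [np.nan_to_num(m.z_nm, nan=0.0) for m in maps]
    shape = imgs[0].shape
    if any(im.shape != shape for im in imgs):
        raise ValueError("all maps must share scan shape")

    # cumulative integer shifts of each map relative to the first
    shifts = [np.zeros(2, dtype=int)]
    for prev, cur in zip(imgs, imgs[1:]):
        if np.ptp(prev) == 0 and np.ptp(cur) == 0:
            rel = np.zeros(2)
        else:
            rel, _, _ = phase_cross_correlation(prev, cur,
                                                upsample_factor=1)
        shifts.append(shifts[-1] + np.rint(rel).astype(int))
    shifts_arr = np.array(shifts)

    # common field of view after applying the shifts
    r0 = max(0, int(shifts_arr[:, 0].max()))
    r1 = shape[0] + min(0, int(shifts_arr[:, 0].min()))
    c0 = max(0, int(shifts_arr[:, 1].max()))
    c1 = shape[1] + min(0, int(shifts_arr[:, 1].min()))
    if r1 - r0 <= 0 or c1 - c0 <= 0:
        raise ValueError("no common field of view after alignment")

    out = np.empty((len(imgs), r1 - r0, c1 - c0), dtype=float)
    for i, (im, sh) in enumerate(zip(imgs, shifts_arr)):
        shifted = np.roll(im, tuple(sh), axis=(0, 1))
        crop = shifted[r0:r1, c0:c1]
        strip = crop[:, :max(1, background_strip_px)]
        out[i] = np.clip(crop - strip.mean(), 0.0, None)
    return out


def write_thickness_map(tm: ThicknessMap, path) -> None:
    """Write thickness (nm) as 32-bit float TIFF; invalid pixels are NaN."""
    z = tm.z_nm.astype(np.float32).copy()
    z[~tm.valid] = np.nan
    tifffile.imwrite(path, z)


def write_tilt_stack(stack: np.ndarray, path) -> None:
    """Write an aligned tilt stack as multi-page 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
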