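"""Hybrid electron counting for sparse integrating-detector frames.

Order of operations: align frames to a common centre using the centre of
mass of the primary beam, estimate and subtract the detector dark level,
fit a Gaussian noise model to the dark-subtracted residuals, then convert
each pixel to an estimated electron count.  A pixel below the threshold
(``k_sigma`` read-noise widths, default 4) counts zero; above it, the value
is quantized by the single-electron gain as ``max(1, round(v / gain))`` —
the "hybrid" count that keeps the multiplicity binary counting throws away
when electrons coincide in one pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

from .frame_io import FrameStack4D, read_keyvalue, write_keyvalue

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseModel", "AlignmentResult",
    "align_to_common_centre", "estimate_dark", "fit_noise_model",
    "hybridize", "binarize", "hybridize_stack", "binarize_stack",
]

MIN_DARK_FRAMES = 16


@dataclass
class NoiseModel:
    """Detector noise description used for counting.

    dark_map : per-pixel ADU offset (scalar broadcastable array allowed)
    sigma_adu : Gaussian read-noise width in ADU
    gain_adu_per_electron : single-electron response in ADU
    threshold_adu : counting threshold (k_sigma * sigma_adu)
    """

    dark_map: np.ndarray
    sigma_adu: float
    gain_adu_per_electron: float
    threshold_adu: float

    def __post_init__(self) -> None:
        self.dark_map = np.asarray(self.dark_map, dtype=float)
        if not self.sigma_adu > 0:
            raise ValueError("sigma_adu must be > 0")
        if not self.gain_adu_per_electron > 0:
            raise ValueError("gain_adu_per_electron must be > 0")
        if not self.threshold_adu > 0:
            raise ValueError("threshold_adu must be > 0")

    def save(self, path: str | Path) -> None:
        write_keyvalue({
            "sigma_adu": self.sigma_adu,
            "gain_adu_per_electron": self.gain_adu_per_electron,
            "threshold_adu": self.threshold_adu,
            "dark_mean_adu": float(np.mean(self.dark_map)),
        }, path)
        np.savetxt(str(path) + ".dark.txt", np.atleast_2d(self.dark_map))

    @classmethod
    def load(cls, path: str | Path) -> "NoiseModel":
        d = read_keyvalue(path)
        dark = np.loadtxt(str(path) + ".dark.txt")
        return cls(dark_map=dark, sigma_adu=float(d["sigma_adu"]),
                   gain_adu_per_electron=float(d["gain_adu_per_electron"]),
                   threshold_adu=float(d["threshold_adu"]))


@dataclass
class AlignmentResult:
    """Integer per-frame shifts applied to centre the primary beam."""

    shifts: np.ndarray          # (scan_rows, scan_cols, 2) applied (d_row, d_col)
    common_centre: tuple[int, int]
    unalignable: np.ndarray     # boolean (scan_rows, scan_cols)


def _beam_com(frame: np.ndarray, window_radius: int,
              floor: float) -> tuple[float, float] | None:
    """Centre of mass in a window around the brightest pixel.

    Returns None when no pixel clears ``floor`` (no discernible beam).
    """
    idx = np.unravel_index(np.argmax(frame), frame.shape)
    if frame[idx] <= floor:
        return None
    r0 = max(idx[0] - window_radius, 0)
    r1 = min(idx[0] + window_radius + 1, frame.shape[0])
    c0 = max(idx[1] - window_radius, 0)
    c1 = min(idx[1] + window_radius + 1, frame.shape[1])
    win = np.clip(frame[r0:r1, c0:c1] - floor, 0, None)
    tot = win.sum()
    if tot <= 0:
        return None
    rr = np.arange(r0, r1, dtype=float)
    cc = np.arange(c0, c1, dtype=float)
    return (float((win.sum(axis=1) * rr).sum() / tot),
            float((win.sum(axis=0) * cc).sum() / tot))


def align_to_common_centre(stack: FrameStack4D, beam_window_radius_px: int,
                           dark_map: np.ndarray | None = None,
                           sigma_adu: float = 0.0
                           ) -> tuple[FrameStack4D, AlignmentResult]:
    """Shift every frame by integer pixels so the beam lands on the centre.

    The beam seed is the per-frame maximum; it must exceed the dark level by
    more than 5 sigma, else the frame is flagged unalignable and left in
    place.  Vacated pixels are filled with the dark value where a dark map
    is supplied, otherwise 0.
    """
    if beam_window_radius_px <= 0:
        raise ValueError("beam_window_radius_px must be > 0")
    det_r, det_c = stack.det_shape
    centre = (det_r // 2, det_c // 2)
    dark = np.zeros((det_r, det_c)) if dark_map is None \
        else np.broadcast_to(np.asarray(dark_map, float), (det_r, det_c))
    rows, cols = stack.scan_shape
    shifts = np.zeros((rows, cols, 2), dtype=int)
    unalignable = np.zeros((rows, cols), dtype=bool)
    out = np.empty_like(stack.data)

    for r in range(rows):
        for c in range(cols):
            frame = stack.data[r, c].astype(float)
            com = _beam_com(frame - dark, beam_window_radius_px,
                            floor=5.0 * sigma_adu)
            if com is None:
                unalignable[r, c] = True
                out[r, c] = stack.data[r, c]
                logger.warning("frame (%d, %d) has no discernible beam; "
                               "left unshifted", r, c)
                continue
            d_row = centre[0] - int(round(com[0]))
            d_col = centre[1] - int(round(com[1]))
            shifts[r, c] = (d_row, d_col)
            shifted = np.full(frame.shape, np.nan)
            src_r = slice(max(0, -d_row), min(det_r, det_r - d_row))
            dst_r = slice(max(0, d_row), min(det_r, det_r + d_row))
            src_c = slice(max(0, -d_col), min(det_c, det_c - d_col))
            dst_c = slice(max(0, d_col), min(det_c, det_c + d_col))
            shifted[dst_r, dst_c] = stack.data[r, c][src_r, src_c]
            fill = dark if dark_map is not None else 0.0
            vac = np.isnan(shifted)
            shifted[vac] = np.broadcast_to(fill, shifted.shape)[vac] \
                if dark_map is not None else 0.0
            out[r, c] = shifted.astype(stack.data.dtype)

    return (stack.with_data(out),
            AlignmentResult(shifts=shifts, common_centre=centre,
                            unalignable=unalignable))


def estimate_dark(stack: FrameStack4D, method: str = "temporal",
                  outlier_sigma: float | None = 5.0) -> np.ndarray:
    """Per-pixel dark level from the stack itself.

    Because diffraction signal is sparse, the temporal median over frames at
    each pixel is dominated by dark current and read noise.  Pixels that see
    signal in most frames — the central beam sits on the same pixels at
    every scan position — would leak signal into a plain temporal median, so
    pixels whose median deviates from the bulk by more than
    ``outlier_sigma`` robust widths are replaced with the bulk median (this
    assumes the true dark map is smooth at the scale of the beam disc; pass
    ``outlier_sigma=None`` to disable, e.g. for a genuine dark acquisition).
    ``method="spatial"`` applies a per-frame median filter instead and
    averages — a variant for dense data, off by default.
    """
    n = stack.n_frames
    if n < MIN_DARK_FRAMES:
        raise ValueError(
            f"dark estimation needs >= {MIN_DARK_FRAMES} frames, got {n}")
    frames = stack.frames()
    if method == "temporal":
        dark = np.median(frames, axis=0).astype(float)
    elif method == "spatial":
        from scipy.ndimage import median_filter
        acc = np.zeros(stack.det_shape, dtype=float)
        for f in frames:
            acc += median_filter(f.astype(float), size=5)
        dark = acc / n
    else:
        raise ValueError(f"unknown dark method {method!r}")
    if outlier_sigma is not None:
        bulk = np.median(dark)
        # integer ADU can collapse the MAD to zero; floor at 1 ADU
        mad = max(1.4826 * float(np.median(np.abs(dark - bulk))), 1.0)
        hot = np.abs(dark - bulk) > outlier_sigma * mad
        if hot.any():
            logger.info("estimate_dark: %d persistent-signal pixels "
                        "replaced with the bulk dark level", int(hot.sum()))
            dark[hot] = bulk
    return dark


def _gauss(x, a, mu, sigma):
    return a * np.exp(-(x - mu) ** 2 / (2.0 * sigma ** 2))


def fit_noise_model(stack: FrameStack4D, dark_map: np.ndarray,
                    k_sigma: float = 4.0,
                    gain_adu_per_electron: float | None = None) -> NoiseModel:
    """Fit the read-noise Gaussian and derive the counting threshold.

    The histogram of dark-subtracted values has a dominant zero-electron
    mode plus a sparse positive electron tail; a Gaussian is fitted to the
    central mode only (bins within a robust-sigma window around the mode).
    ``threshold_adu = k_sigma * sigma_adu``.  If the gain is not supplied it
    is estimated as the mode of the above-threshold residuals — the
    single-electron peak.
    """
    if not k_sigma > 0:
        raise ValueError("k_sigma must be > 0")
    resid = (stack.frames().astype(float) - dark_map).ravel()
    if np.ptp(resid) == 0:
        raise ValueError("degenerate histogram: all residuals identical")

    med = np.median(resid)
    mad_sigma = 1.4826 * np.median(np.abs(resid - med))
    if mad_sigma == 0:
        raise ValueError("degenerate histogram: zero spread in central mode")

    lo, hi = med - 5 * mad_sigma, med + 3 * mad_sigma
    core = resid[(resid >= lo) & (resid <= hi)]
    hist, edges = np.histogram(core, bins=min(101, max(11, core.size // 50)))
    centres = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = curve_fit(
            _gauss, centres, hist,
            p0=[hist.max(), centres[np.argmax(hist)], mad_sigma])
        sigma = abs(float(popt[2]))
    except RuntimeError:  # fall back to the robust estimate
        sigma = float(mad_sigma)
    if not sigma > 0:
        sigma = float(mad_sigma)
    threshold = k_sigma * sigma

    gain = gain_adu_per_electron
    if gain is None:
        tail = resid[resid > threshold]
        if tail.size < 10:
            raise ValueError("too few above-threshold pixels to estimate "
                             "gain; pass gain_adu_per_electron explicitly")
        # histogram at ~sigma/2 resolution; mode = single-electron peak
        binw = max(sigma / 2.0, 1e-6)
        nb = int(np.ceil((tail.max() - threshold) / binw)) + 1
        h, e = np.histogram(tail, bins=min(nb, 4096),
                            range=(threshold, threshold + binw * min(nb, 4096)))
        gain = float(0.5 * (e[np.argmax(h)] + e[np.argmax(h) + 1]))

    return NoiseModel(dark_map=np.asarray(dark_map, float),
                      sigma_adu=sigma,
                      gain_adu_per_electron=float(gain),
                      threshold_adu=float(threshold))


def hybridize(frame: np.ndarray, model: NoiseModel) -> np.ndarray:
    """Convert a dark-subtracted frame to hybrid electron counts.

    v <= threshold -> 0; otherwise max(1, round(v / gain)).
    """
    if not model.gain_adu_per_electron > 0:
        raise ValueError("gain must be positive")
    frame = np.asarray(frame, dtype=float)
    quant = np.maximum(1, np.rint(frame / model.gain_adu_per_electron))
    counts = np.where(frame > model.threshold_adu, quant, 0)
    return counts.astype(np.int64)


def binarize(frame: np.ndarray, model: NoiseModel) -> np.ndarray:
    """Binary counting baseline: every above-threshold pixel counts one."""
    frame = np.asarray(frame, dtype=float)
    return (frame > model.threshold_adu).astype(np.int64)


def _convert_stack(stack: FrameStack4D, model: NoiseModel,
                   fn) -> FrameStack4D:
    resid = stack.data.astype(float) - model.dark_map
    out = fn(resid, model)
    return FrameStack4D(out, stack.geometry, "hybrid_counts")


def hybridize_stack(stack: FrameStack4D, model: NoiseModel) -> FrameStack4D:
    """Dark-subtract and hybridize a whole raw stack."""
    return _convert_stack(stack, model, hybridize)


def binarize_stack(stack: FrameStack4D, model: NoiseModel) -> FrameStack4D:
    """Dark-subtract and binary-count a whole raw stack."""
    return _convert_stack(stack, model, binarize)
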