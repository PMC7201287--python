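"""Bragg peak localization by binning and circular-template matching.

Summed patterns are first binned (factor 5 by default) to boost contrast,
then scanned with a circular template six binned pixels in diameter using
normalized cross-correlation; local NCC maxima above a threshold, after
non-maximum suppression, are the peaks.  Coordinates are reported in
unbinned detector pixels.  For multi-crystal fields of view, peaks found in
the full-field pattern are labelled by matching against the per-region peak
lists, which separates the overlapping reciprocal lattices without any
multi-lattice indexing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import fftconvolve
from skimage.feature import peak_local_max

logger = logging.getLogger(__name__)

__all__ = [
    "PeakList", "bin_pattern", "ncc_map", "disc_template",
    "gaussian_template", "find_peaks", "assign_peaks_to_regions",
    "write_peaks", "read_peaks",
]

DEFAULT_BIN_FACTOR = 5
DEFAULT_TEMPLATE_DIAMETER = 6


@dataclass
class PeakList:
    """Located Bragg peaks in unbinned detector coordinates.

    ``peaks`` rows are (det_row, det_col, ncc_score, integrated_counts);
    ``labels`` holds one list of region labels per peak (empty until
    :func:`assign_peaks_to_regions` runs).
    """

    peaks: np.ndarray
    bin_factor: int
    template_diameter_binned_px: int
    labels: list[list] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 4)
        if self.peaks.size and (np.abs(self.peaks[:, 2]) > 1 + 1e-9).any():
            raise ValueError("NCC scores must lie in [-1, 1]")
        if not self.labels:
            self.labels = [[] for _ in range(len(self.peaks))]

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (det_row, det_col), unbinned pixels."""
        return self.peaks[:, :2]


def bin_pattern(pattern: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping factor x factor block sums.

    Dimensions not divisible by the factor are edge-cropped (warning);
    counts on the cropped field are conserved exactly.
    """
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    pattern = np.asarray(pattern)
    if factor == 1:
        return pattern.copy()
    rows, cols = pattern.shape
    r, c = rows - rows % factor, cols - cols % factor
    if (r, c) != (rows, cols):
        logger.warning("bin_pattern: cropping %s to %s for factor %d",
                       (rows, cols), (r, c), factor)
    cropped = pattern[:r, :c]
    return cropped.reshape(r // factor, factor, c // factor, factor) \
                  .sum(axis=(1, 3))


def disc_template(diameter_px: float, pad_px: int = 2) -> np.ndarray:
    """Flat circular template in an odd window with background margin.

    The margin gives the template contrast against the surrounding
    background — a disc that fills its entire window has zero variance and
    a degenerate NCC.
    """
    n = int(np.ceil(diameter_px)) + 2 * pad_px
    if n % 2 == 0:
        n += 1
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[:n, :n]
    return (((yy - c) ** 2 + (xx - c) ** 2)
            <= (diameter_px / 2.0) ** 2).astype(float)


def gaussian_template(diameter_px: float, pad_px: int = 2) -> np.ndarray:
    """Gaussian alternative (sigma = diameter / 4, i.e. FWHM ~ diameter/1.7)."""
    n = int(np.ceil(diameter_px)) + 2 * pad_px
    if n % 2 == 0:
        n += 1
    c = (n - 1) / 2.0
    sigma = diameter_px / 4.0
    yy, xx = np.mgrid[:n, :n]
    return np.exp(-((yy - c) ** 2 + (xx - c) ** 2) / (2 * sigma ** 2))


def ncc_map(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of ``image`` with ``template``.

    Scores are invariant to affine rescaling of the image intensities.
    Windows with (near-)zero variance score 0 rather than dividing by
    noise-level denominators.
    """
    image = np.asarray(image, dtype=float)
    if template.shape[0] > image.shape[0] or \
            template.shape[1] > image.shape[1]:
        raise ValueError(
            f"template {template.shape} larger than pattern {image.shape}")
    n = template.size
    tz = template - template.mean()
    tnorm = np.sqrt((tz ** 2).sum())
    local_mean = uniform_filter(image, size=template.shape, mode="reflect")
    local_sq = uniform_filter(image * image, size=template.shape,
                              mode="reflect")
    local_var = np.clip(local_sq - local_mean ** 2, 0.0, None)
    corr = fftconvolve(image, tz[::-1, ::-1], mode="same")
    denom = tnorm * np.sqrt(n * local_var)
    floor = 1e-9 * max(tnorm, 1.0) * n
    out = np.where(denom > floor, corr / np.maximum(denom, floor), 0.0)
    out = np.clip(out, -1.0, 1.0)
    # NCC is undefined where the window hangs off the edge; zero the border
    k = template.shape[0] // 2
    if k:
        out[:k] = out[-k:] = 0.0
        out[:, :k] = 0.0
        out[:, -k:] = 0.0
    return out


def find_peaks(pattern: np.ndarray,
               bin_factor: int = DEFAULT_BIN_FACTOR,
               template_diameter_binned_px: int = DEFAULT_TEMPLATE_DIAMETER,
               ncc_min: float = 0.5,
               min_separation_binned_px: int | None = None,
               central_exclusion_radius_px: float | None = None,
               template_kind: str = "disc",
               integration_radius_px: float | None = None) -> PeakList:
    """Locate Bragg peaks in a summed pattern.

    The pattern is binned, correlated with a circular template
    (``template_kind``: ``"disc"`` or ``"gaussian"``), and local NCC maxima
    above ``ncc_min`` are kept with non-maximum suppression at
    ``min_separation_binned_px`` (default: the template diameter).
    Coordinates are mapped back to unbinned pixels at the bin centre
    (``unbinned = binned * factor + (factor - 1) / 2``).  Peaks within
    ``central_exclusion_radius_px`` (unbinned) of the pattern centre — the
    direct beam — are discarded.  Integrated counts are summed in an
    unbinned disc of ``integration_radius_px`` (default: half the template
    diameter, unbinned) around each peak.
    """
    pattern = np.asarray(pattern)
    if not 0 < ncc_min < 1:
        raise ValueError("ncc_min must lie in (0, 1)")
    binned = bin_pattern(pattern, bin_factor)
    make = disc_template if template_kind == "disc" else gaussian_template
    if template_kind not in ("disc", "gaussian"):
        raise ValueError(f"unknown template_kind {template_kind!r}")
    template = make(template_diameter_binned_px)
    score = ncc_map(binned, template)
    sep = min_separation_binned_px or template_diameter_binned_px
    coords = peak_local_max(score, min_distance=int(sep),
                            threshold_abs=ncc_min, exclude_border=False)

    centre = ((pattern.shape[0] - 1) / 2.0, (pattern.shape[1] - 1) / 2.0)
    int_r = integration_radius_px if integration_radius_px is not None \
        else template_diameter_binned_px * bin_factor / 2.0
    yy = np.arange(pattern.shape[0])[:, None]
    xx = np.arange(pattern.shape[1])[None, :]

    rows = []
    for br, bc in coords:
        ur = br * bin_factor + (bin_factor - 1) / 2.0
        uc = bc * bin_factor + (bin_factor - 1) / 2.0
        if central_exclusion_radius_px is not None:
            if np.hypot(ur - centre[0], uc - centre[1]) \
                    < central_exclusion_radius_px:
                continue
        disc = ((yy - ur) ** 2 + (xx - uc) ** 2) <= int_r ** 2
        rows.append((ur, uc, float(score[br, bc]),
                     float(pattern[disc].sum())))
    rows.sort(key=lambda t: -t[2])
    return PeakList(np.array(rows, dtype=float).reshape(-1, 4),
                    bin_factor, template_diameter_binned_px)


def assign_peaks_to_regions(full_field: PeakList,
                            per_region: list[tuple[int, PeakList]],
                            match_radius_px: float) -> PeakList:
    """Label each full-field peak with the regions that also found it.

    ``per_region`` pairs each region label with the peak list found from
    that region's summed pattern alone.  A full-field peak is labelled with
    every region owning a peak within ``match_radius_px`` (unbinned); peaks
    matched by no region are labelled ``"unassigned"``.
    """
    if not per_region:
        raise ValueError("need at least one per-region peak list")
    labels: list[list] = []
    for pos in full_field.positions:
        mine: list = []
        for region_label, plist in per_region:
            if plist.n_peaks == 0:
                continue
            d = np.hypot(plist.positions[:, 0] - pos[0],
                         plist.positions[:, 1] - pos[1])
            if match_radius_px > 0 and (d <= match_radius_px).any():
                mine.append(region_label)
        labels.append(mine or ["unassigned"])
    return PeakList(full_field.peaks.copy(), full_field.bin_factor,
                    full_field.template_diameter_binned_px, labels)


def write_peaks(plist: PeakList, path) -> None:
    """Tab-separated peak table: row, col, score, counts, labels."""
    with open(path, "w") as fh:
        fh.write("# det_row\tdet_col\tncc_score\tintegrated_counts\tlabels\n")
        for (r, c, s, n), lab in zip(plist.peaks, plist.labels):
            lab_s = ",".join(str(x) for x in lab) if lab else "-"
            fh.write(f"{r:.2f}\t{c:.2f}\t{s:.4f}\t{n:.1f}\t{lab_s}\n")


def read_peaks(path, bin_factor: int = DEFAULT_BIN_FACTOR,
               template_diameter_binned_px: int = DEFAULT_TEMPLATE_DIAMETER
               ) -> PeakList:
    rows, labels = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            rows.append([float(x) for x in parts[:4]])
            lab = parts[4] if len(parts) > 4 else "-"
            labels.append([] if lab == "-" else lab.split(","))
    return PeakList(np.array(rows, dtype=float).reshape(-1, 4),
                    bin_factor, template_diameter_binned_px, labels)
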