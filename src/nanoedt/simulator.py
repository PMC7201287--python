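"""Synthetic 4D-STEM tilt-series generator with ground truth.

Emulates a scanning nanobeam electron-diffraction tomography acquisition: a
focused probe (FWHM ~12 nm) raster-scanned over a needle-shaped nanocrystal
resting on a support film with a vacuum hole, one 4D scan per goniometer
tilt, recorded on a noisy integrating direct detector at ~1 e/A^2 per frame.

The diffraction model is a kinematic projection.  Each crystal carries three
reciprocal basis vectors expressed in detector-pixel units plus an
out-of-plane component; at tilt angle theta (rotation about the scan-row
axis) a reflection (h,k,l) is "excited" when the rotated reciprocal vector's
out-of-plane component falls below a tolerance, and is rendered as a 2D
Gaussian spot at the rotated in-plane position, weighted by its structure
factor.  Both the direct beam and the diffracted spots are attenuated by the
transmission factor exp(-thickness / lambda_mfp), so the log-ratio thickness
model downstream is exactly invertible up to counting noise.  Electron
arrivals are Poisson; the detector adds gain, a dark offset and Gaussian
read noise.  Multiple arrivals in one pixel simply sum in the analog value —
the coincidence that hybrid counting must recover.

Everything is driven by a single integer seed: identical configs give
bit-identical stacks and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from skimage.draw import polygon2mask

from .frame_io import (FrameStack4D, ScanGeometry, WAVELENGTH_300KV_A,
                       read_keyvalue, write_keyvalue)

__all__ = [
    "CrystalSpec", "SimulationConfig", "GroundTruth",
    "simulate_tilt_series", "default_sf_table",
    "write_ground_truth", "read_ground_truth",
    "save_config", "load_config",
]


def default_sf_table(hk_max: int = 3, l_max: int = 1,
                     scale: float = 1000.0) -> dict[tuple[int, int, int], float]:
    """Smoothly decaying relative intensities on a small (h,k,l) block.

    A stand-in structure-factor table (synthetic, not from any real crystal):
    intensity falls off with resolution like a Debye-Waller envelope so inner
    reflections dominate, as in real peptide nanocrystal patterns.
    """
    table: dict[tuple[int, int, int], float] = {}
    for h in range(-hk_max, hk_max + 1):
        for k in range(-hk_max, hk_max + 1):
            for l in range(-l_max, l_max + 1):
                if (h, k, l) == (0, 0, 0):
                    continue
                table[(h, k, l)] = scale * math.exp(
                    -0.15 * (h * h + k * k) - 0.3 * l * l)
    return table


@dataclass
class CrystalSpec:
    """One crystal: a scan-space footprint plus its reciprocal lattice.

    polygon
        Vertices (row, col) in scan coordinates, 0-based.
    lattice
        3x3 array, rows = reciprocal basis vectors a*, b*, c* in
        (det_row_px, det_col_px, out_of_plane_px) components.
    sf_table
        Map (h,k,l) -> relative intensity.
    """

    polygon: np.ndarray
    lattice: np.ndarray
    sf_table: dict[tuple[int, int, int], float] = field(
        default_factory=default_sf_table)

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        self.lattice = np.asarray(self.lattice, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 \
                or len(self.polygon) < 3:
            raise ValueError("crystal polygon needs >= 3 (row, col) vertices")
        if self.lattice.shape != (3, 3):
            raise ValueError("lattice must be 3 reciprocal basis 3-vectors")
        if not self.sf_table:
            raise ValueError("sf_table must be non-empty")


@dataclass
class SimulationConfig:
    """Stated world for one synthetic acquisition.

    Defaults follow the real experiment where values are on record: 40 nm
    scan step, ~12 nm probe FWHM, 1 e/A^2 per frame, 1 deg tilt increments
    over +/-40 deg (the 81-pattern reduced range), 300 kV wavelength.  The
    detector is 256 px square — a desk-scale stand-in for the ~1792 px
    K2-IS — and gain / read noise / dark level / background rate are
    realistic free parameters the experiment does not pin down.
    """

    scan_shape: tuple[int, int] = (30, 70)
    step_nm: float = 40.0
    probe_fwhm_nm: float = 12.0
    tilt_min_deg: float = -40.0
    tilt_max_deg: float = 40.0
    tilt_step_deg: float = 1.0
    det_shape: tuple[int, int] = (256, 256)
    gain_adu_per_electron: float = 32.0
    read_noise_sigma_adu: float = 5.0
    dark_level_adu: float = 100.0
    dose_e_per_A2_per_frame: float = 1.0
    bg_rate_e_per_px: float = 0.005
    crystals: list[CrystalSpec] = field(default_factory=list)
    vacuum_polygon: np.ndarray | None = None
    thickness_profile: np.ndarray | None = None
    support_thickness_nm: float = 30.0
    crystal_thickness_nm: tuple[float, float] = (100.0, 300.0)
    lambda_mfp_nm: float = 332.0
    diffracted_fraction: float = 0.1
    beam_sigma_px: float = 2.0
    spot_sigma_px: float = 1.5
    excitation_tol_px: float = 0.8
    beam_jitter_px: int = 0
    wavelength_A: float = WAVELENGTH_300KV_A
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tilt_step_deg > 0:
            raise ValueError("tilt_step_deg must be > 0")
        if self.tilt_max_deg < self.tilt_min_deg:
            raise ValueError("tilt_max_deg must be >= tilt_min_deg")
        if not self.gain_adu_per_electron > 0:
            raise ValueError("gain_adu_per_electron must be > 0")
        if self.dose_e_per_A2_per_frame < 0:
            raise ValueError("dose_e_per_A2_per_frame must be >= 0")
        if self.bg_rate_e_per_px < 0:
            raise ValueError("bg_rate_e_per_px must be >= 0")
        if self.read_noise_sigma_adu < 0:
            raise ValueError("read_noise_sigma_adu must be >= 0")
        if not (0 <= self.diffracted_fraction < 1):
            raise ValueError("diffracted_fraction must lie in [0, 1)")
        if not self.lambda_mfp_nm > 0:
            raise ValueError("lambda_mfp_nm must be > 0")
        if self.beam_jitter_px < 0:
            raise ValueError("beam_jitter_px must be >= 0")
        rows, cols = self.scan_shape
        for i, c in enumerate(self.crystals):
            p = c.polygon
            if p[:, 0].min() < 0 or p[:, 1].min() < 0 \
                    or p[:, 0].max() > rows or p[:, 1].max() > cols:
                raise ValueError(
                    f"crystals[{i}].polygon extends outside scan_shape "
                    f"{self.scan_shape}")
        if self.thickness_profile is not None:
            tp = np.asarray(self.thickness_profile, dtype=float)
            if tp.shape != tuple(self.scan_shape):
                raise ValueError(
                    "thickness_profile shape must equal scan_shape")
            self.thickness_profile = tp

    # -- derived quantities -------------------------------------------------

    @property
    def tilts_deg(self) -> np.ndarray:
        n = int(round((self.tilt_max_deg - self.tilt_min_deg)
                      / self.tilt_step_deg)) + 1
        return self.tilt_min_deg + self.tilt_step_deg * np.arange(n)

    @property
    def probe_area_A2(self) -> float:
        """Illuminated area pi*(FWHM/2)^2 in square angstroms."""
        r_A = self.probe_fwhm_nm * 10.0 / 2.0
        return math.pi * r_A * r_A

    @property
    def incident_electrons_per_frame(self) -> float:
        """Expected electrons delivered into the probe per frame."""
        return self.dose_e_per_A2_per_frame * self.probe_area_A2

    def geometry(self, tilt_deg: float) -> ScanGeometry:
        return ScanGeometry(step_nm=self.step_nm,
                            probe_fwhm_nm=self.probe_fwhm_nm,
                            tilt_deg=tilt_deg,
                            dose_e_per_A2_per_frame=self.dose_e_per_A2_per_frame,
                            wavelength_A=self.wavelength_A)

    @classmethod
    def default(cls, scan_shape: tuple[int, int] = (30, 70),
                det_shape: tuple[int, int] = (256, 256),
                lattice_spacing_px: float | None = None,
                c_star_z_px: float | None = None,
                two_crystals: bool = False,
                **kwargs) -> "SimulationConfig":
        """Build a config with a needle crystal, support film and vacuum hole.

        Footprints are placed at fixed fractions of the scan so any scan
        shape yields the same layout: a needle running across the upper half
        of the field and a vacuum hole in the lower-right corner.  With
        ``two_crystals`` a second, in-plane-rotated needle is added below the
        first (disjoint lattices, as in a polycrystalline field of view).
        """
        rows, cols = scan_shape
        if lattice_spacing_px is None:
            lattice_spacing_px = 0.1875 * det_shape[0]  # 48 px on a 256 det
        if c_star_z_px is None:
            c_star_z_px = lattice_spacing_px / 12.0
        needle = np.array([(0.18, 0.10), (0.12, 0.88),
                           (0.32, 0.90), (0.38, 0.12)]) * (rows, cols)
        # c* carries an in-plane row offset so higher-layer reflections land
        # at distinct detector positions once a tilt excites them
        lat = np.array([[lattice_spacing_px, 0.0, 0.0],
                        [0.0, lattice_spacing_px, 0.0],
                        [0.4 * lattice_spacing_px, 0.0, c_star_z_px]])
        crystals = [CrystalSpec(needle, lat)]
        if two_crystals:
            # 20 deg keeps the two reciprocal lattices well separated on the
            # detector (no near-coincident reflections at low order)
            ang = math.radians(20.0)
            rot = np.array([[math.cos(ang), -math.sin(ang), 0.0],
                            [math.sin(ang), math.cos(ang), 0.0],
                            [0.0, 0.0, 1.0]])
            lat2 = lat @ rot.T
            needle2 = np.array([(0.50, 0.12), (0.46, 0.60),
                                (0.62, 0.62), (0.66, 0.14)]) * (rows, cols)
            crystals.append(CrystalSpec(needle2, lat2))
        vacuum = np.array([(0.72, 0.68), (0.72, 1.0),
                           (1.0, 1.0), (1.0, 0.68)]) * (rows, cols)
        return cls(scan_shape=scan_shape, det_shape=det_shape,
                   crystals=crystals, vacuum_polygon=vacuum, **kwargs)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    #: per tilt, true Poisson arrivals (r, c, det_r, det_c)
    electron_counts: list[np.ndarray]
    #: (n_crystals, scan_rows, scan_cols) boolean footprints
    crystal_masks: np.ndarray
    #: records (tilt_index, tilt_deg, det_row, det_col, h, k, l, crystal)
    peak_positions: list[tuple]
    #: (scan_rows, scan_cols) thickness in nm
    thickness_nm: np.ndarray
    #: (scan_rows, scan_cols) boolean vacuum footprint
    vacuum_mask: np.ndarray
    #: per tilt, (scan_rows, scan_cols, 2) integer beam offsets applied
    beam_offsets: list[np.ndarray]
    tilts_deg: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def peaks_at_tilt(self, tilt_index: int,
                      crystal: int | None = None) -> np.ndarray:
        """(det_row, det_col) positions of true peaks at one tilt."""
        out = [(p[2], p[3]) for p in self.peak_positions
               if p[0] == tilt_index and (crystal is None or p[7] == crystal)]
        return np.asarray(out, dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# rendering internals
# ---------------------------------------------------------------------------

def _gaussian_image(det_shape, centre, sigma) -> np.ndarray:
    rows, cols = det_shape
    yy = np.arange(rows)[:, None] - centre[0]
    xx = np.arange(cols)[None, :] - centre[1]
    img = np.exp(-(yy * yy + xx * xx) / (2.0 * sigma * sigma))
    s = img.sum()
    return img / s if s > 0 else img


def _rotate_about_row_axis(g: np.ndarray, tilt_deg: float) -> np.ndarray:
    """Rotate reciprocal vectors (row, col, z) about the scan-row axis."""
    th = math.radians(tilt_deg)
    c, s = math.cos(th), math.sin(th)
    out = g.copy()
    out[..., 1] = g[..., 1] * c - g[..., 2] * s
    out[..., 2] = g[..., 1] * s + g[..., 2] * c
    return out


def excited_reflections(crystal: CrystalSpec, tilt_deg: float,
                        det_shape: tuple[int, int],
                        excitation_tol_px: float,
                        margin_px: float = 2.0) -> list[tuple]:
    """Reflections excited at this tilt that land on the detector.

    Returns (h, k, l, det_row, det_col, weight) tuples; weight is the
    sf_table intensity (not yet normalized).
    """
    centre = (det_shape[0] // 2, det_shape[1] // 2)
    hkl = np.array(list(crystal.sf_table.keys()), dtype=float)
    weights = np.array(list(crystal.sf_table.values()), dtype=float)
    g = hkl @ crystal.lattice  # (n, 3) in (row, col, z) det-px units
    gr = _rotate_about_row_axis(g, tilt_deg)
    sel = np.abs(gr[:, 2]) < excitation_tol_px
    out = []
    for (h, k, l), w, vec in zip(hkl[sel], weights[sel], gr[sel]):
        r = centre[0] + vec[0]
        c = centre[1] + vec[1]
        if margin_px <= r <= det_shape[0] - 1 - margin_px \
                and margin_px <= c <= det_shape[1] - 1 - margin_px:
            out.append((int(h), int(k), int(l), r, c, w))
    return out


def expected_electron_image(config: SimulationConfig, tilt_deg: float,
                            scan_pos: tuple[int, int],
                            _cache: dict | None = None) -> np.ndarray:
    """Analytic expectation of electron arrivals for one frame.

    Exposed separately so tests can compare empirical Poisson means against
    the exact rate map the generator uses.
    """
    masks, thickness, _ = _scan_fields(config)
    beam = _gaussian_image(
        config.det_shape,
        (config.det_shape[0] // 2, config.det_shape[1] // 2),
        config.beam_sigma_px)
    r, c = scan_pos
    t = thickness[r, c]
    trans = math.exp(-t / config.lambda_mfp_nm)
    n0 = config.incident_electrons_per_frame
    img = np.full(config.det_shape, config.bg_rate_e_per_px, dtype=float)
    ci = next((i for i in range(len(config.crystals)) if masks[i, r, c]), None)
    if ci is None:
        img += n0 * trans * beam
        return img
    spots = _spot_image(config, config.crystals[ci], tilt_deg)
    f = config.diffracted_fraction if spots is not None else 0.0
    img += n0 * trans * (1.0 - f) * beam
    if spots is not None:
        img += n0 * trans * f * spots
    return img


def _spot_image(config: SimulationConfig, crystal: CrystalSpec,
                tilt_deg: float) -> np.ndarray | None:
    refl = excited_reflections(crystal, tilt_deg, config.det_shape,
                               config.excitation_tol_px)
    if not refl:
        return None
    img = np.zeros(config.det_shape, dtype=float)
    wsum = sum(r[5] for r in refl)
    for h, k, l, rr, cc, w in refl:
        img += (w / wsum) * _gaussian_image(config.det_shape, (rr, cc),
                                            config.spot_sigma_px)
    s = img.sum()
    return img / s if s > 0 else None


def _scan_fields(config: SimulationConfig):
    """Crystal masks, thickness map and vacuum mask on the scan grid."""
    rows, cols = config.scan_shape
    masks = np.zeros((len(config.crystals), rows, cols), dtype=bool)
    for i, cr in enumerate(config.crystals):
        masks[i] = polygon2mask((rows, cols), cr.polygon)
    vacuum = np.zeros((rows, cols), dtype=bool)
    if config.vacuum_polygon is not None:
        vacuum = polygon2mask((rows, cols),
                              np.asarray(config.vacuum_polygon, dtype=float))
    if config.thickness_profile is not None:
        thickness = config.thickness_profile.copy()
    else:
        thickness = np.full((rows, cols), config.support_thickness_nm)
        t0, t1 = config.crystal_thickness_nm
        ramp = np.linspace(t0, t1, cols)[None, :]  # wedge along scan cols
        any_xtal = masks.any(axis=0)
        thickness = np.where(any_xtal, ramp, thickness)
        thickness[vacuum & ~any_xtal] = 0.0
    return masks, thickness, vacuum


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------

def simulate_tilt_series(config: SimulationConfig
                         ) -> tuple[list[FrameStack4D], GroundTruth]:
    """Generate one FrameStack4D per tilt angle plus full ground truth.

    Per frame the expected electron image is the attenuated central-beam
    disc, a uniform background and — inside a crystal footprint — the
    excited Bragg spots; arrivals are Poisson draws and the detector value
    is ``arrivals * gain + dark_level + N(0, read_noise_sigma)``, rounded to
    integer ADU.  The returned ground truth records the actual Poisson
    arrivals, the rasterized crystal/vacuum footprints, the thickness map
    and every excited on-detector reflection per tilt.
    """
    rng = np.random.default_rng(config.seed)
    masks, thickness, vacuum = _scan_fields(config)
    rows, cols = config.scan_shape
    det_shape = tuple(config.det_shape)
    # integer centre pixel: matches the common centre integer alignment uses
    centre = (det_shape[0] // 2, det_shape[1] // 2)
    beam = _gaussian_image(det_shape, centre, config.beam_sigma_px)
    n0 = config.incident_electrons_per_frame
    trans = np.exp(-thickness / config.lambda_mfp_nm)
    # first crystal wins where footprints overlap (they should not)
    crystal_index = np.full((rows, cols), -1, dtype=int)
    for i in range(len(config.crystals) - 1, -1, -1):
        crystal_index[masks[i]] = i

    tilts = config.tilts_deg
    stacks: list[FrameStack4D] = []
    counts_per_tilt: list[np.ndarray] = []
    offsets_per_tilt: list[np.ndarray] = []
    peak_records: list[tuple] = []

    for ti, tilt in enumerate(tilts):
        spot_imgs: dict[int, np.ndarray | None] = {}
        for ci, cr in enumerate(config.crystals):
            spot_imgs[ci] = _spot_image(config, cr, tilt)
            for h, k, l, rr, cc, _w in excited_reflections(
                    cr, tilt, det_shape, config.excitation_tol_px):
                peak_records.append((ti, float(tilt), rr, cc, h, k, l, ci))

        counts = np.zeros((rows, cols) + det_shape, dtype=np.uint32)
        data = np.empty((rows, cols) + det_shape, dtype=np.int32)
        offsets = np.zeros((rows, cols, 2), dtype=np.int64)
        if config.beam_jitter_px > 0:
            offsets = rng.integers(-config.beam_jitter_px,
                                   config.beam_jitter_px + 1,
                                   size=(rows, cols, 2))
        lam = np.empty(det_shape, dtype=np.float64)
        for r in range(rows):
            for c in range(cols):
                ci = crystal_index[r, c]
                spots = spot_imgs.get(ci) if ci >= 0 else None
                f = config.diffracted_fraction if spots is not None else 0.0
                np.multiply(beam, n0 * trans[r, c] * (1.0 - f), out=lam)
                if spots is not None:
                    lam += n0 * trans[r, c] * f * spots
                lam += config.bg_rate_e_per_px
                if config.beam_jitter_px > 0:
                    lam = np.roll(lam, tuple(offsets[r, c]), axis=(0, 1))
                arr = rng.poisson(lam)
                counts[r, c] = arr
                adu = arr * config.gain_adu_per_electron \
                    + config.dark_level_adu
                if config.read_noise_sigma_adu > 0:
                    adu += rng.normal(0.0, config.read_noise_sigma_adu,
                                      size=det_shape)
                data[r, c] = np.rint(adu)
        stacks.append(FrameStack4D(data, config.geometry(float(tilt)),
                                   "raw_adu"))
        counts_per_tilt.append(counts)
        offsets_per_tilt.append(offsets)

    gt = GroundTruth(electron_counts=counts_per_tilt,
                     crystal_masks=masks,
                     peak_positions=peak_records,
                     thickness_nm=thickness,
                     vacuum_mask=vacuum,
                     beam_offsets=offsets_per_tilt,
                     tilts_deg=tilts)
    return stacks, gt


# ---------------------------------------------------------------------------
# ground-truth round trip
# ---------------------------------------------------------------------------

def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Write ground truth to an HDF5 file; lossless with the paired reader."""
    with h5py.File(path, "w") as f:
        if gt.electron_counts:
            f.create_dataset("electron_counts",
                             data=np.stack(gt.electron_counts))
        f.create_dataset("crystal_masks",
                         data=gt.crystal_masks.astype(np.uint8))
        f.create_dataset("thickness_nm",
                         data=np.asarray(gt.thickness_nm, dtype=np.float64))
        f.create_dataset("vacuum_mask", data=gt.vacuum_mask.astype(np.uint8))
        if gt.beam_offsets:
            f.create_dataset("beam_offsets", data=np.stack(gt.beam_offsets))
        f.create_dataset("tilts_deg", data=np.asarray(gt.tilts_deg))
        pk = np.array([(p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7])
                       for p in gt.peak_positions], dtype=np.float64)
        f.create_dataset("peaks", data=pk.reshape(-1, 8))


def read_ground_truth(path: str | Path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        counts = [np.array(a) for a in f["electron_counts"]] \
            if "electron_counts" in f else []
        offsets = [np.array(a) for a in f["beam_offsets"]] \
            if "beam_offsets" in f else []
        pk = f["peaks"][()]
        peaks = [(int(p[0]), float(p[1]), float(p[2]), float(p[3]),
                  int(p[4]), int(p[5]), int(p[6]), int(p[7])) for p in pk]
        return GroundTruth(
            electron_counts=counts,
            crystal_masks=f["crystal_masks"][()].astype(bool),
            peak_positions=peaks,
            thickness_nm=f["thickness_nm"][()],
            vacuum_mask=f["vacuum_mask"][()].astype(bool),
            beam_offsets=offsets,
            tilts_deg=f["tilts_deg"][()])


# ---------------------------------------------------------------------------
# config round trip (flat key=value text, documented schema)
# ---------------------------------------------------------------------------

_SCALAR_FIELDS = (
    "step_nm", "probe_fwhm_nm", "tilt_min_deg", "tilt_max_deg",
    "tilt_step_deg", "gain_adu_per_electron", "read_noise_sigma_adu",
    "dark_level_adu", "dose_e_per_A2_per_frame", "bg_rate_e_per_px",
    "support_thickness_nm", "lambda_mfp_nm", "diffracted_fraction",
    "beam_sigma_px", "spot_sigma_px", "excitation_tol_px", "wavelength_A",
)


def _fmt_polygon(p: np.ndarray) -> str:
    return ";".join(f"{r}:{c}" for r, c in np.asarray(p, dtype=float))


def _parse_polygon(s: str) -> np.ndarray:
    return np.array([[float(x) for x in v.split(":")]
                     for v in s.split(";") if v])


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Serialize a config as flat key=value text.

    Schema: scalar fields by name; ``scan_shape``/``det_shape`` as
    ``rows,cols``; per-crystal keys ``crystalN_polygon`` (``row:col`` pairs
    joined by ``;``), ``crystalN_lattice`` (three ``r,c,z`` triplets joined
    by ``|``) and ``crystalN_sf`` (``h,k,l,I`` quadruplets joined by ``;``);
    ``vacuum_polygon`` like a crystal polygon.  Explicit thickness-profile
    arrays are not representable in this flat format.
    """
    if config.thickness_profile is not None:
        raise ValueError("flat config files cannot carry an explicit "
                         "thickness_profile array")
    d: dict[str, object] = {
        "scan_shape": f"{config.scan_shape[0]},{config.scan_shape[1]}",
        "det_shape": f"{config.det_shape[0]},{config.det_shape[1]}",
        "seed": config.seed,
        "beam_jitter_px": config.beam_jitter_px,
        "crystal_thickness_nm": (f"{config.crystal_thickness_nm[0]},"
                                 f"{config.crystal_thickness_nm[1]}"),
    }
    for k in _SCALAR_FIELDS:
        d[k] = getattr(config, k)
    for i, cr in enumerate(config.crystals):
        d[f"crystal{i}_polygon"] = _fmt_polygon(cr.polygon)
        d[f"crystal{i}_lattice"] = "|".join(
            ",".join(str(x) for x in row) for row in cr.lattice)
        d[f"crystal{i}_sf"] = ";".join(
            f"{h},{k},{l},{v}" for (h, k, l), v in cr.sf_table.items())
    if config.vacuum_polygon is not None:
        d["vacuum_polygon"] = _fmt_polygon(config.vacuum_polygon)
    write_keyvalue(d, path)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a config written by :func:`save_config`; unknown keys rejected."""
    raw = read_keyvalue(path)
    known = set(_SCALAR_FIELDS) | {
        "scan_shape", "det_shape", "seed", "beam_jitter_px",
        "crystal_thickness_nm", "vacuum_polygon"}
    crystals: dict[int, dict] = {}
    for k in list(raw):
        for suffix in ("polygon", "lattice", "sf"):
            if k.startswith("crystal") and k.endswith("_" + suffix):
                idx = int(k[len("crystal"):-len("_" + suffix)])
                crystals.setdefault(idx, {})[suffix] = raw.pop(k)
                break
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    kwargs: dict = {}
    for k in _SCALAR_FIELDS:
        if k in raw:
            kwargs[k] = float(raw[k])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "beam_jitter_px" in raw:
        kwargs["beam_jitter_px"] = int(raw["beam_jitter_px"])
    for k in ("scan_shape", "det_shape"):
        if k in raw:
            kwargs[k] = tuple(int(x) for x in raw[k].split(","))
    if "crystal_thickness_nm" in raw:
        kwargs["crystal_thickness_nm"] = tuple(
            float(x) for x in raw["crystal_thickness_nm"].split(","))
    if "vacuum_polygon" in raw:
        kwargs["vacuum_polygon"] = _parse_polygon(raw["vacuum_polygon"])

    specs = []
    for idx in sorted(crystals):
        entry = crystals[idx]
        poly = _parse_polygon(entry["polygon"])
        lattice = np.array([[float(x) for x in row.split(",")]
                            for row in entry["lattice"].split("|")])
        sf = {}
        for quad in entry["sf"].split(";"):
            h, k, l, v = quad.split(",")
            sf[(int(h), int(k), int(l))] = float(v)
        specs.append(CrystalSpec(poly, lattice, sf))
    kwargs["crystals"] = specs
    return SimulationConfig(**kwargs)
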