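"""Data model and I/O for 4D diffraction stacks and exported still images.

A 4D-STEM acquisition at one tilt angle is a ``FrameStack4D``: a
``(scan_rows, scan_cols, det_rows, det_cols)`` array of detector values
together with the scan geometry (step size, probe size, tilt angle, dose,
wavelength).  Three on-disk dialects are supported:

``container``
    One HDF5 file per tilt with a ``/data`` dataset and the geometry stored
    as attributes.  A tilt series is then simply a directory of per-angle
    files, mirroring the per-scan acquisition.
``raw_binary``
    A flat little-endian payload plus a plain-text sidecar header
    (``<path>.hdr``) giving shape, dtype, byte order and geometry.  The
    sidecar schema is our own invention (the key=value lines documented in
    :data:`RAW_SIDECAR_KEYS`); it exists so stacks remain readable without
    any binary-aware tooling.
``tiff_stack``
    A multi-page TIFF with one detector frame per page in row-major scan
    order, plus the same sidecar for scan shape and geometry.

Summed diffraction patterns destined for crystallographic indexing are
exported as SMV stills (512-byte ASCII header + unsigned 16-bit payload),
the dialect consumed by XDS/DIALS-style software.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Electron wavelength at 300 kV accelerating voltage, in angstroms.
WAVELENGTH_300KV_A = 0.0197

DIALECTS = ("container", "raw_binary", "tiff_stack")

#: Keys of the raw-binary / TIFF sidecar header (one ``key = value`` per line).
RAW_SIDECAR_KEYS = (
    "scan_rows", "scan_cols", "det_rows", "det_cols",
    "dtype", "byte_order", "dtype_tag",
    "step_nm", "probe_fwhm_nm", "tilt_deg",
    "dose_e_per_A2_per_frame", "wavelength_A",
)


@dataclass
class ScanGeometry:
    """Scan and beam geometry for one 4D scan (one tilt angle).

    Parameters
    ----------
    step_nm : float
        Scan step (grid pitch) in nm.
    probe_fwhm_nm : float
        Full width at half maximum of the focused probe, nm.
    tilt_deg : float
        Goniometer tilt angle of this scan, degrees, in [-90, 90].
    dose_e_per_A2_per_frame : float
        Fluence delivered per frame, electrons per square angstrom.
    wavelength_A : float
        Electron wavelength in angstroms (0.0197 at 300 kV).
    """

    step_nm: float
    probe_fwhm_nm: float
    tilt_deg: float = 0.0
    dose_e_per_A2_per_frame: float = 1.0
    wavelength_A: float = WAVELENGTH_300KV_A

    def __post_init__(self) -> None:
        if not self.step_nm > 0:
            raise ValueError(f"step_nm must be > 0, got {self.step_nm}")
        if not self.probe_fwhm_nm > 0:
            raise ValueError(
                f"probe_fwhm_nm must be > 0, got {self.probe_fwhm_nm}")
        if not -90.0 <= self.tilt_deg <= 90.0:
            raise ValueError(
                f"tilt_deg must lie in [-90, 90], got {self.tilt_deg}")
        if self.dose_e_per_A2_per_frame < 0:
            raise ValueError("dose_e_per_A2_per_frame must be >= 0")
        if not self.wavelength_A > 0:
            raise ValueError("wavelength_A must be > 0")


@dataclass
class FrameStack4D:
    """One tilt angle's 4D scan: (scan_rows, scan_cols, det_rows, det_cols).

    ``dtype_tag`` records what the pixel values mean: ``"raw_adu"`` for
    detector output (possibly dark-subtracted, possibly float) or
    ``"hybrid_counts"`` for non-negative integer electron counts.
    """

    data: np.ndarray
    geometry: ScanGeometry
    dtype_tag: str = "raw_adu"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be 4D, got shape {self.data.shape}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(
                f"all four dimensions must be >= 1, got {self.data.shape}")
        if self.dtype_tag not in ("raw_adu", "hybrid_counts"):
            raise ValueError(f"unknown dtype_tag {self.dtype_tag!r}")
        if self.dtype_tag == "hybrid_counts":
            if not np.issubdtype(self.data.dtype, np.integer):
                raise ValueError("hybrid_counts data must be integer-typed")
            if self.data.size and self.data.min() < 0:
                raise ValueError("hybrid_counts data must be non-negative")

    @property
    def scan_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def det_shape(self) -> tuple[int, int]:
        return self.data.shape[2:]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def frames(self) -> np.ndarray:
        """View of the stack as (n_frames, det_rows, det_cols), row-major."""
        return self.data.reshape(self.n_frames, *self.det_shape)

    def with_data(self, data: np.ndarray, dtype_tag: str | None = None):
        return FrameStack4D(data, replace(self.geometry),
                            dtype_tag or self.dtype_tag)


# ---------------------------------------------------------------------------
# geometry <-> flat key/value helpers
# ---------------------------------------------------------------------------

def _geometry_to_dict(geom: ScanGeometry) -> dict:
    return {
        "step_nm": geom.step_nm,
        "probe_fwhm_nm": geom.probe_fwhm_nm,
        "tilt_deg": geom.tilt_deg,
        "dose_e_per_A2_per_frame": geom.dose_e_per_A2_per_frame,
        "wavelength_A": geom.wavelength_A,
    }


def _geometry_from_dict(d: dict) -> ScanGeometry:
    return ScanGeometry(
        step_nm=float(d["step_nm"]),
        probe_fwhm_nm=float(d["probe_fwhm_nm"]),
        tilt_deg=float(d["tilt_deg"]),
        dose_e_per_A2_per_frame=float(d["dose_e_per_A2_per_frame"]),
        wavelength_A=float(d["wavelength_A"]),
    )


def write_keyvalue(d: dict, path: str | Path) -> None:
    """Write a flat ``key = value`` text file (one pair per line)."""
    with open(path, "w") as fh:
        for k, v in d.items():
            fh.write(f"{k} = {v}\n")


def read_keyvalue(path: str | Path) -> dict:
    """Read a flat ``key = value`` text file; values stay as strings."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed sidecar line: {line!r}")
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out


# ---------------------------------------------------------------------------
# stack writers / readers
# ---------------------------------------------------------------------------

def write_stack(stack: FrameStack4D, path: str | Path,
                dialect: str = "container") -> None:
    """Write a 4D stack to ``path`` in the given dialect.

    All dialects round-trip integer data bit-exactly.  ``raw_binary`` always
    writes little-endian and pairs the payload with a ``<path>.hdr`` text
    sidecar; ``tiff_stack`` writes one page per frame in row-major scan order
    plus the same sidecar.
    """
    path = Path(path)
    if path.is_dir():
        raise IsADirectoryError(f"{path} is a directory, not a target file")
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected {DIALECTS}")

    if dialect == "container":
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("data", data=stack.data)
            for k, v in _geometry_to_dict(stack.geometry).items():
                ds.attrs[k] = v
            ds.attrs["dtype_tag"] = stack.dtype_tag
    elif dialect == "raw_binary":
        arr = np.ascontiguousarray(stack.data)
        le = arr.astype(arr.dtype.newbyteorder("<"), copy=False)
        le.tofile(path)
        hdr = {
            "scan_rows": arr.shape[0], "scan_cols": arr.shape[1],
            "det_rows": arr.shape[2], "det_cols": arr.shape[3],
            "dtype": arr.dtype.name, "byte_order": "little_endian",
            "dtype_tag": stack.dtype_tag,
        }
        hdr.update(_geometry_to_dict(stack.geometry))
        write_keyvalue(hdr, str(path) + ".hdr")
    else:  # tiff_stack
        tifffile.imwrite(path, stack.frames())
        hdr = {
            "scan_rows": stack.data.shape[0], "scan_cols": stack.data.shape[1],
            "det_rows": stack.data.shape[2], "det_cols": stack.data.shape[3],
            "dtype": stack.data.dtype.name, "byte_order": "little_endian",
            "dtype_tag": stack.dtype_tag,
        }
        hdr.update(_geometry_to_dict(stack.geometry))
        write_keyvalue(hdr, str(path) + ".hdr")


def read_stack(path: str | Path, dialect: str = "container") -> FrameStack4D:
    """Read a 4D stack written by :func:`write_stack`.

    For ``raw_binary`` the payload byte count is checked against the sidecar
    shape and a mismatch raises with both expected and actual counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected {DIALECTS}")

    if dialect == "container":
        with h5py.File(path, "r") as f:
            ds = f["data"]
            data = ds[()]
            attrs = dict(ds.attrs)
        geom = _geometry_from_dict(attrs)
        return FrameStack4D(data, geom, str(attrs.get("dtype_tag", "raw_adu")))

    hdr = read_keyvalue(str(path) + ".hdr")
    shape = tuple(int(hdr[k]) for k in
                  ("scan_rows", "scan_cols", "det_rows", "det_cols"))
    dtype = np.dtype(hdr["dtype"]).newbyteorder("<")
    geom = _geometry_from_dict(hdr)
    tag = hdr.get("dtype_tag", "raw_adu")

    if dialect == "raw_binary":
        expected = int(np.prod(shape)) * dtype.itemsize
        actual = os.path.getsize(path)
        if actual != expected:
            raise ValueError(
                f"raw_binary payload size mismatch for {path}: header implies "
                f"{expected} bytes ({shape}, {dtype.name}), file has {actual}")
        data = np.fromfile(path, dtype=dtype).reshape(shape)
        return FrameStack4D(data.astype(data.dtype.newbyteorder("=")),
                            geom, tag)

    pages = tifffile.imread(path)
    pages = np.atleast_3d(pages)
    if pages.ndim == 2:
        pages = pages[None]
    n = shape[0] * shape[1]
    if pages.shape[0] != n:
        raise ValueError(
            f"tiff_stack page count mismatch for {path}: header implies "
            f"{n} pages, file has {pages.shape[0]}")
    return FrameStack4D(pages.reshape(shape), geom, tag)


# ---------------------------------------------------------------------------
# SMV still-image export
# ---------------------------------------------------------------------------

SMV_HEADER_BYTES = 512


def write_smv(pattern: np.ndarray, geometry: ScanGeometry,
              osc_start_deg: float, osc_range_deg: float,
              path: str | Path, *, pedestal: int = 0,
              pixel_size_mm: float = 0.014, distance_mm: float = 1000.0,
              beam_center_mm: tuple[float, float] | None = None) -> int:
    """Write a 2D pattern as an SMV still image.

    The payload is row-major unsigned 16-bit; ``pedestal`` is added to every
    pixel before clipping to [0, 65535] so that genuinely-zero background can
    be distinguished from clipped negatives downstream.  Returns the number
    of pixels clipped at 65535 (also logged as a warning when non-zero).
    """
    pattern = np.asarray(pattern)
    if pattern.ndim != 2:
        raise ValueError(f"pattern must be 2D, got shape {pattern.shape}")
    if pattern.size and pattern.min() < 0:
        raise ValueError("pattern must be non-negative before pedestal")
    rows, cols = pattern.shape
    shifted = np.rint(pattern.astype(np.float64)) + pedestal
    n_clipped = int(np.count_nonzero(shifted > 65535))
    if n_clipped:
        logger.warning("write_smv: %d pixels clipped to 65535 in %s",
                       n_clipped, path)
    payload = np.clip(shifted, 0, 65535).astype("<u2")

    if beam_center_mm is None:
        beam_center_mm = (cols / 2.0 * pixel_size_mm,
                          rows / 2.0 * pixel_size_mm)
    fields = [
        ("HEADER_BYTES", SMV_HEADER_BYTES),
        ("DIM", 2),
        ("BYTE_ORDER", "little_endian"),
        ("TYPE", "unsigned_short"),
        ("SIZE1", cols),
        ("SIZE2", rows),
        ("PIXEL_SIZE", pixel_size_mm),
        ("DISTANCE", distance_mm),
        ("WAVELENGTH", geometry.wavelength_A),
        ("PHI", osc_start_deg),
        ("OSC_START", osc_start_deg),
        ("OSC_RANGE", osc_range_deg),
        ("BEAM_CENTER_X", beam_center_mm[0]),
        ("BEAM_CENTER_Y", beam_center_mm[1]),
        ("IMAGE_PEDESTAL", pedestal),
    ]
    header = "{\n" + "".join(f"{k}={v};\n" for k, v in fields) + "}\n"
    raw = header.encode("ascii")
    if len(raw) > SMV_HEADER_BYTES:
        raise ValueError("SMV header overflow")
    raw += b" " * (SMV_HEADER_BYTES - len(raw))

    with open(path, "wb") as fh:
        fh.write(raw)
        fh.write(payload.tobytes())
    return n_clipped


def read_smv(path: str | Path) -> tuple[np.ndarray, dict]:
    """Parse an SMV still: returns (uint16 array, header dict of strings)."""
    with open(path, "rb") as fh:
        raw = fh.read(SMV_HEADER_BYTES)
        header: dict[str, str] = {}
        for line in raw.decode("ascii", errors="replace").splitlines():
            line = line.strip().rstrip(";")
            if "=" in line:
                k, v = line.split("=", 1)
                header[k.strip()] = v.strip()
        if int(header.get("HEADER_BYTES", SMV_HEADER_BYTES)) != SMV_HEADER_BYTES:
            fh.seek(int(header["HEADER_BYTES"]))
        rows = int(header["SIZE2"])
        cols = int(header["SIZE1"])
        payload = fh.read(rows * cols * 2)
    if len(payload) != rows * cols * 2:
        raise ValueError(
            f"SMV payload size mismatch for {path}: header implies "
            f"{rows * cols * 2} bytes, file has {len(payload)}")
    dt = "<u2" if header.get("BYTE_ORDER", "little_endian") == "little_endian" \
        else ">u2"
    data = np.frombuffer(payload, dtype=dt).reshape(rows, cols)
    return data.astype(np.uint16), header
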