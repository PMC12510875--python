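"""File I/O: HDF5 datacubes, MRC/TIFF images and TOML run configuration.

The datacube container is HDF5 (group ``/datacube`` holding the counts and
calibration attributes), with a raw-binary + JSON-sidecar fallback for
interchange.  Images are written either as 32-bit-float MRC (mode 2,
MRC2014 layout with the pixel size in the cell header) or 16-bit TIFF with
the linear rescale recorded in the image description.
"""

from __future__ import annotations

import json
import struct
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .parallax import DataCube4D

__all__ = [
    "FormatError",
    "RunConfig",
    "write_datacube",
    "read_datacube",
    "write_mrc",
    "read_mrc",
    "write_tiff",
    "read_tiff",
    "write_image",
    "read_image",
]


class FormatError(ValueError):
    """A file does not follow the expected container layout."""


# ---------------------------------------------------------------------------
# datacube container

_OPTIONAL_ATTR_DEFAULTS = {"scan_step_A": 1.0, "det_pixel_mrad": 1.0}


def write_datacube(cube: DataCube4D, path) -> None:
    """Write a datacube to HDF5 (or raw + JSON sidecar for ``.raw`` paths)."""
    path = Path(path)
    if path.suffix == ".raw":
        _write_raw_datacube(cube, path)
        return
    with h5py.File(path, "w") as f:
        g = f.create_group("datacube")
        g.create_dataset("counts", data=cube.counts, compression="gzip",
                         compression_opts=4)
        g.attrs["scan_step_A"] = float(cube.scan_step)
        g.attrs["det_pixel_mrad"] = float(cube.det_pixel * 1e3)
        g.attrs["det_center"] = np.asarray(cube.det_center, dtype=float)
        if cube.optics is not None:
            g.attrs["kV"] = float(cube.optics.voltage_kv)
            g.attrs["alpha_mrad"] = float(cube.optics.alpha * 1e3)
        for key in ("dose", "seed"):
            if cube.metadata.get(key) is not None:
                g.attrs[key] = cube.metadata[key]


def read_datacube(path) -> DataCube4D:
    """Read a datacube container; missing optional attrs warn and default.

    A missing counts dataset (or group) raises :class:`FormatError` naming
    the member; missing calibration attributes produce a warning, a default
    value and a ``defaulted_attrs`` entry in the cube metadata.
    """
    path = Path(path)
    if path.suffix == ".raw":
        return _read_raw_datacube(path)
    from .optics import OpticalConfig

    with h5py.File(path, "r") as f:
        if "datacube" not in f:
            raise FormatError(f"{path}: missing group '/datacube'")
        g = f["datacube"]
        if "counts" not in g:
            raise FormatError(f"{path}: missing dataset '/datacube/counts'")
        counts = g["counts"][...]
        attrs = dict(g.attrs)
    defaulted = []
    for key, default in _OPTIONAL_ATTR_DEFAULTS.items():
        if key not in attrs:
            warnings.warn(f"{path}: attribute {key!r} missing, "
                          f"defaulting to {default}", stacklevel=2)
            attrs[key] = default
            defaulted.append(key)
    optics = None
    if "kV" in attrs and "alpha_mrad" in attrs:
        optics = OpticalConfig(voltage_kv=float(attrs["kV"]),
                               alpha=float(attrs["alpha_mrad"]) * 1e-3)
    center = attrs.get("det_center")
    meta = {"dose": attrs.get("dose"), "seed": attrs.get("seed"),
            "defaulted_attrs": defaulted}
    return DataCube4D(
        counts=counts,
        scan_step=float(attrs["scan_step_A"]),
        det_pixel=float(attrs["det_pixel_mrad"]) * 1e-3,
        det_center=None if center is None else (float(center[0]), float(center[1])),
        optics=optics,
        metadata={k: (v.item() if isinstance(v, np.generic) else v)
                  for k, v in meta.items()},
    )


def _write_raw_datacube(cube: DataCube4D, path: Path) -> None:
    arr = np.ascontiguousarray(cube.counts, dtype="<f4")
    arr.tofile(path)
    sidecar = {
        "shape": list(arr.shape), "dtype": "<f4",
        "scan_step_A": float(cube.scan_step),
        "det_pixel_mrad": float(cube.det_pixel * 1e3),
        "det_center": list(map(float, cube.det_center)),
    }
    if cube.optics is not None:
        sidecar["kV"] = float(cube.optics.voltage_kv)
        sidecar["alpha_mrad"] = float(cube.optics.alpha * 1e3)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def _read_raw_datacube(path: Path) -> DataCube4D:
    from .optics import OpticalConfig

    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"{path}: missing JSON sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("shape", "dtype"):
        if key not in meta:
            raise FormatError(f"{sidecar_path}: missing key {key!r}")
    counts = np.fromfile(path, dtype=meta["dtype"])
    expected = int(np.prod(meta["shape"]))
    if counts.size != expected:
        raise FormatError(f"{path}: expected {expected} samples for shape "
                          f"{meta['shape']}, found {counts.size}")
    optics = None
    if "kV" in meta and "alpha_mrad" in meta:
        optics = OpticalConfig(voltage_kv=meta["kV"],
                               alpha=meta["alpha_mrad"] * 1e-3)
    center = meta.get("det_center")
    return DataCube4D(counts=counts.reshape(meta["shape"]),
                      scan_step=meta.get("scan_step_A", 1.0),
                      det_pixel=meta.get("det_pixel_mrad", 1.0) * 1e-3,
                      det_center=None if center is None else tuple(center),
                      optics=optics)


# ---------------------------------------------------------------------------
# MRC (MRC2014, mode 2 = 32-bit float)

_MRC_HEADER_BYTES = 1024


def write_mrc(image: np.ndarray, path, pixel_size: float = 1.0) -> None:
    """Write a 2-D image as MRC2014 mode 2 with the pixel size (A) in the
    cell dimensions."""
    img = np.ascontiguousarray(_check_image(image), dtype="<f4")
    ny, nx = img.shape
    header = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<10i", header, 0, nx, ny, 1, 2, 0, 0, 0, nx, ny, 1)
    struct.pack_into("<6f", header, 40, nx * pixel_size, ny * pixel_size,
                     pixel_size, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into("<3f", header, 76, float(img.min()), float(img.max()),
                     float(img.mean()))
    struct.pack_into("<2i", header, 88, 0, 0)          # ispg, nsymbt
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian stamp
    struct.pack_into("<f", header, 216, float(img.std()))
    struct.pack_into("<i", header, 220, 0)             # nlabl
    with open(path, "wb") as f:
        f.write(header)
        f.write(img.tobytes())


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read a mode-2 MRC image; returns ``(image, pixel_size_A)``."""
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER_BYTES:
        raise FormatError(f"{path}: shorter than the 1024-byte MRC header")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise FormatError(f"{path}: missing MRC 'MAP ' signature")
    if mode != 2:
        raise FormatError(f"{path}: unsupported MRC mode {mode} (expected 2)")
    if nz != 1:
        raise FormatError(f"{path}: expected a single section, got nz={nz}")
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    cella_x = struct.unpack_from("<f", raw, 40)[0]
    mx = struct.unpack_from("<i", raw, 28)[0]
    pixel = cella_x / mx if mx else 1.0
    start = _MRC_HEADER_BYTES + nsymbt
    n = nx * ny
    data = np.frombuffer(raw, dtype="<f4", count=n, offset=start)
    if data.size < n:
        raise FormatError(f"{path}: truncated data section")
    return data.reshape(ny, nx).astype(np.float64), float(pixel)


# ---------------------------------------------------------------------------
# TIFF (16-bit with linear rescale metadata)


def write_tiff(image: np.ndarray, path, pixel_size: float = 1.0) -> None:
    """Write a 16-bit TIFF; the linear rescale (scale, offset) mapping
    uint16 back to physical values is stored in the image description."""
    img = _check_image(image)
    lo, hi = float(img.min()), float(img.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    coded = np.round((img - lo) / scale).astype(np.uint16)
    desc = json.dumps({"rescale_slope": scale, "rescale_intercept": lo,
                       "pixel_size_A": pixel_size})
    tifffile.imwrite(path, coded, description=desc)


def read_tiff(path) -> tuple[np.ndarray, float]:
    """Read a TIFF written by :func:`write_tiff`, undoing the rescale."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        coded = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    slope = meta.get("rescale_slope", 1.0)
    intercept = meta.get("rescale_intercept", 0.0)
    return coded.astype(np.float64) * slope + intercept, meta.get("pixel_size_A", 1.0)


def _check_image(image, sanitize: str = "fail") -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        if sanitize == "mask":
            finite = img[np.isfinite(img)]
            fill = float(finite.mean()) if finite.size else 0.0
            img = np.where(np.isfinite(img), img, fill)
        else:
            raise ValueError("image contains non-finite pixels "
                             "(pass sanitize='mask' to replace them)")
    return img


def write_image(image, path, pixel_size: float = 1.0,
                sanitize: str = "fail") -> None:
    """Write MRC or TIFF depending on the file extension."""
    img = _check_image(image, sanitize)
    suffix = Path(path).suffix.lower()
    if suffix == ".mrc":
        write_mrc(img, path, pixel_size)
    elif suffix in (".tif", ".tiff"):
        write_tiff(img, path, pixel_size)
    else:
        raise ValueError(f"unsupported image extension {suffix!r} "
                         "(use .mrc, .tif or .tiff)")


def read_image(path) -> tuple[np.ndarray, float]:
    """Read MRC or TIFF depending on the file extension."""
    suffix = Path(path).suffix.lower()
    if suffix == ".mrc":
        return read_mrc(path)
    if suffix in (".tif", ".tiff"):
        return read_tiff(path)
    raise ValueError(f"unsupported image extension {suffix!r}")


# ---------------------------------------------------------------------------
# run configuration

_KNOWN_SECTIONS = {
    "simulate": {"phantom", "kv", "alpha_mrad", "defocus_nm",
                 "scan_step_angstrom", "scan_shape", "detector_shape",
                 "dose", "inelastic_sigma_mrad", "phantom_size",
                 "pixel_size_angstrom"},
    "reconstruct": {"upsample", "max_iter", "edge_margin", "regularize",
                    "upsample_factor"},
    "ctf": {"kv", "alpha_mrad", "defocus_nm", "mode", "omega_max_mrad",
            "n_points"},
    "dqe": {"kv", "alpha_mrad", "defocus_nm", "omega_max_mrad", "n_points"},
    "thickness": {"lambda_in_nm", "a_ha", "corrected", "incident"},
    "design": {"kv", "alpha_mrad", "det_pixel_mrad", "defocus_nm",
               "scan_step_angstrom"},
}
_KNOWN_TOP = {"seed", "out_dir", "log_level"}


@dataclass
class RunConfig:
    """TOML-backed configuration mirroring the CLI flags."""

    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"
    sections: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_toml(cls, text: str) -> "RunConfig":
        data = tomllib.loads(text)
        top = {}
        sections = {}
        for key, value in data.items():
            if key in _KNOWN_TOP:
                top[key] = value
            elif key in _KNOWN_SECTIONS:
                if not isinstance(value, dict):
                    raise ValueError(f"config section {key!r} must be a table")
                unknown = set(value) - _KNOWN_SECTIONS[key]
                if unknown:
                    raise ValueError(
                        f"unknown key {sorted(unknown)[0]!r} in config "
                        f"section [{key}]")
                sections[key] = dict(value)
            else:
                raise ValueError(f"unknown top-level config key {key!r}")
        return cls(sections=sections, **top)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_toml(Path(path).read_text())

    def to_toml(self) -> str:
        def fmt(v):
            if isinstance(v, bool):
                return "true" if v else "false"
            if isinstance(v, str):
                return json.dumps(v)
            if isinstance(v, (list, tuple)):
                return "[" + ", ".join(fmt(x) for x in v) + "]"
            return repr(v)

        lines = [f"seed = {fmt(self.seed)}",
                 f"out_dir = {fmt(self.out_dir)}",
                 f"log_level = {fmt(self.log_level)}"]
        for name in sorted(self.sections):
            lines.append(f"\n[{name}]")
            for key in sorted(self.sections[name]):
                lines.append(f"{key} = {fmt(self.sections[name][key])}")
        return "\n".join(lines) + "\n"
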