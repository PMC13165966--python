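"""File formats, configuration and manifest handling.

Interchange formats are all open and text-friendly: float TIFF for lossless
holograms and complex fields (two pages: real, imaginary), 16-bit TIFF/PNG
export for viewers, CSV manifests, JSON sidecars/reports and YAML configs.
Human-facing files use mm/um/nm; everything is converted to SI metres on
ingest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .optics import ComplexField, OpticalConfig
from .simulate import Hologram

__all__ = [
    "Manifest",
    "read_image",
    "read_hologram",
    "write_hologram",
    "write_field",
    "read_field",
    "load_config",
    "dump_config",
    "DEFAULT_CONFIG",
]

MANIFEST_COLUMNS = [
    "file", "grid_row", "grid_col", "stage_x_mm", "stage_y_mm", "z_index", "z_mm",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale TIFF/PNG as float64 scaled to [0, 1].

    8-/16-bit integer images are divided by their dtype maximum; float
    images are taken as-is.  Color images are rejected.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim == 3 and data.shape[0] in (1,):
        data = data[0]
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a grayscale image, got shape {data.shape}")
    if data.dtype.kind == "u" or data.dtype.kind == "i":
        return data.astype(np.float64) / np.iinfo(data.dtype).max
    return data.astype(np.float64)


def read_hologram(
    path: str | Path,
    as_amplitude: bool = True,
    pitch: float = 1.0,
    z: float = 0.0,
    **meta,
) -> Hologram:
    """Load one hologram tile.

    With ``as_amplitude=False`` the file is treated as recorded intensity
    and the square root is applied, covering both recording conventions.
    Extra keyword metadata (grid_row, stage_x, ...) is attached verbatim.
    """
    values = read_image(path)
    if not as_amplitude:
        values = np.sqrt(values)
    return Hologram(amplitude=values, pitch=pitch, z=z, **meta)


def write_hologram(path: str | Path, amplitude: np.ndarray, bits: str = "float") -> None:
    """Write an amplitude image as float32 TIFF (lossless default), or as a
    16-bit TIFF/PNG export (rescaled to the dtype range; lossy)."""
    path = Path(path)
    amplitude = np.asarray(amplitude, dtype=np.float64)
    if bits == "float":
        tifffile.imwrite(path, amplitude.astype(np.float32))
        return
    if bits == "uint16":
        peak = amplitude.max()
        scaled = (amplitude / peak * 65535.0 if peak > 0 else amplitude)
        data = np.round(scaled).astype(np.uint16)
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, data)
        else:
            iio.imwrite(path, data)
        return
    raise ValueError(f"unknown bit depth {bits!r}")


def write_field(path: str | Path, fld: ComplexField) -> None:
    """Store a complex field as a two-page float TIFF (real, imaginary)
    plus a JSON sidecar with wavelength, pitch and z."""
    path = Path(path)
    pages = np.stack([fld.values.real, fld.values.imag]).astype(np.float32)
    tifffile.imwrite(path, pages)
    sidecar = {
        "wavelength_nm": fld.wavelength * 1e9,
        "pitch_um": fld.pitch * 1e6,
        "z_mm": fld.z * 1e3,
        "pages": ["real", "imag"],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_field(path: str | Path) -> ComplexField:
    path = Path(path)
    pages = tifffile.imread(path).astype(np.float64)
    if pages.ndim != 3 or pages.shape[0] != 2:
        raise ValueError(f"{path}: expected a two-page (real, imag) TIFF")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return ComplexField(
        pages[0] + 1j * pages[1],
        pitch=sidecar["pitch_um"] * 1e-6,
        wavelength=sidecar["wavelength_nm"] * 1e-9,
        z=sidecar["z_mm"] * 1e-3,
    )


@dataclass
class Manifest:
    """Stage-coordinate manifest for a scanned multi-depth dataset."""

    records: pd.DataFrame
    root: Path | None = None

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        keys = self.records[["grid_row", "grid_col", "z_index"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].values.tolist()
            raise ValueError(f"duplicate (grid_row, grid_col, z_index): {dup}")

    @classmethod
    def load(cls, path: str | Path, check_files: bool = True) -> "Manifest":
        path = Path(path)
        records = pd.read_csv(path)
        m = cls(records=records, root=path.parent)
        if check_files:
            for f in records["file"]:
                if not (m.root / str(f)).exists():
                    raise FileNotFoundError(f"manifest references missing file {f}")
        return m

    def save(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    def plane(self, z_index: int) -> pd.DataFrame:
        sub = self.records[self.records["z_index"] == z_index]
        if sub.empty:
            raise ValueError(f"no tiles for z plane {z_index}")
        return sub

    def check_complete(self) -> tuple[int, int, int]:
        """Verify a full rows x cols x K lattice; returns (rows, cols, K).

        Raises naming every missing (row, col, z_index) cell.
        """
        rows = int(self.records["grid_row"].max()) + 1
        cols = int(self.records["grid_col"].max()) + 1
        planes = int(self.records["z_index"].max()) + 1
        have = set(
            map(tuple, self.records[["grid_row", "grid_col", "z_index"]].values)
        )
        missing = [
            (r, c, z)
            for z in range(planes)
            for r in range(rows)
            for c in range(cols)
            if (r, c, z) not in have
        ]
        if missing:
            raise ValueError(f"manifest missing tiles (row, col, z): {missing}")
        return rows, cols, planes

    def load_holograms(
        self, z_index: int, pitch: float, as_amplitude: bool = True
    ) -> list[Hologram]:
        out = []
        for rec in self.plane(z_index).itertuples():
            out.append(
                read_hologram(
                    (self.root or Path(".")) / str(rec.file),
                    as_amplitude=as_amplitude,
                    pitch=pitch,
                    z=rec.z_mm * 1e-3,
                    z_index=int(rec.z_index),
                    grid_row=int(rec.grid_row),
                    grid_col=int(rec.grid_col),
                    stage_x=rec.stage_x_mm * 1e-3,
                    stage_y=rec.stage_y_mm * 1e-3,
                )
            )
        return out


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict = {
    "optics": {
        "wavelength_nm": 632.8,
        "pitch_um": 2.0,
        "z1_mm": 114.0,
        "spacing_mm": 1.0,
        "num_planes": 5,
        "z_planes_mm": None,      # explicit list overrides z1/spacing
        "reference_plane": 3,     # 1-based in config files
        "band_limited": True,     # the full-scale geometry needs it
    },
    "simulate": {
        "grid_rows": 3,
        "grid_cols": 3,
        "step_mm": 3.0,
        "tile_px": 3552,
        "noise_sigma": 0.0,
        "seed": 0,
        "phase_delay_rad": 0.0,
        "elements": None,         # list of [group, element, [row, col]]
        "phase_elements": None,   # same format; drawn as phase bars
    },
    "stitch": {
        "margin": 0.10,
        "bin_px": 1,
        "min_support": 0.2,
        "matcher": "xcorr",
        "patch_size": 96,
    },
    "retrieve": {
        "iterations": 10,
        "tol": 1e-6,
    },
    "analyze": {
        "threshold": 0.10,
        "intensity": False,
    },
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, base in defaults.items():
        here = f"{path}.{key}" if path else key
        if key in user:
            val = user[key]
            if isinstance(base, dict) and isinstance(val, dict):
                out[key] = _merge(base, val, here)
            else:
                out[key] = val
        else:
            out[key] = {**base} if isinstance(base, dict) else base
    unknown = set(user) - set(defaults)
    if unknown:
        where = path or "top level"
        raise ValueError(f"unknown config keys at {where}: {sorted(unknown)}")
    return out


def resolve_optics(cfg: dict) -> OpticalConfig:
    """Turn the ``optics`` config section into an :class:`OpticalConfig`."""
    o = cfg["optics"]
    if o.get("z_planes_mm"):
        z = [float(v) * 1e-3 for v in o["z_planes_mm"]]
        if o.get("num_planes") and len(z) != int(o["num_planes"]):
            raise ValueError(
                f"z_planes_mm lists {len(z)} planes but num_planes is "
                f"{o['num_planes']}"
            )
    else:
        k = int(o["num_planes"])
        z = [(o["z1_mm"] + i * o["spacing_mm"]) * 1e-3 for i in range(k)]
    return OpticalConfig(
        wavelength=o["wavelength_nm"] * 1e-9,
        pitch=o["pitch_um"] * 1e-6,
        z_planes=tuple(z),
        reference_index=int(o["reference_plane"]) - 1,
    )


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load and validate a YAML config, filling unset keys with defaults.

    An empty or missing file yields the default full-scale acquisition
    geometry (632.8 nm, 2 um pitch, five planes from 114 mm at 1 mm
    spacing, reference plane 3, 10 iterations, 10% search margin).
    Unknown keys are rejected with their key path.
    """
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a mapping")
    cfg = _merge(DEFAULT_CONFIG, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    resolve_optics(cfg)  # validates the optics section eagerly
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
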