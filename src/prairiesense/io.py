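"""File formats: ENVI spectral cubes, single-band rasters, CSV tables.

Spectral cubes are stored as ENVI band-interleaved-by-line (BIL) rasters —
a raw float32 payload next to a text header carrying the wavelength list
in nanometers, the units tag and the local metric grid.  Single-band
rasters are float32 TIFFs with a JSON sidecar for the grid and units
(coordinates are local scene meters; no map projection).  Tables are
UTF-8 CSV with a header row and '.' decimals.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cube import SpectralCube, UNITS_RADIANCE
from .errors import FormatError
from .grids import Grid
from .thermal import AtmosphericState

# ---------------------------------------------------------------------------
# ENVI cubes
# ---------------------------------------------------------------------------


def write_cube(cube: SpectralCube, path: str | Path) -> Path:
    """Write a cube as ENVI BIL (<path>.bil + <path>.hdr); returns the .bil path."""
    path = Path(path)
    if path.suffix == ".bil":
        path = path.with_suffix("")
    bil = path.with_suffix(".bil")
    hdr = path.with_suffix(".hdr")
    values = np.ascontiguousarray(
        cube.values.astype(np.float32).transpose(0, 2, 1)  # (line, band, sample)
    )
    values.tofile(bil)
    g = cube.grid
    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
    hdr_text = (
        "ENVI\n"
        f"samples = {g.ncols}\n"
        f"lines = {g.nrows}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bil\n"
        "byte order = 0\n"
        f"map info = {{Arbitrary, 1, 1, {g.x0}, {g.y1}, {g.gsd}, {g.gsd}}}\n"
        "wavelength units = Nanometers\n"
        f"units = {cube.units}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr.write_text(hdr_text)
    return bil


def _parse_envi_header(text: str) -> dict:
    """Minimal ENVI header parser: `key = value` with {}-wrapped lists."""
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("not an ENVI header (missing ENVI magic)")
    fields: dict[str, str] = {}
    body = text.split("\n", 1)[1]
    i = 0
    while i < len(body):
        line = body[i:].split("\n", 1)[0]
        i += len(line) + 1
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        key, val = key.strip().lower(), val.strip()
        if val.startswith("{") and "}" not in val:
            while i < len(body) and "}" not in val:
                nxt = body[i:].split("\n", 1)[0]
                i += len(nxt) + 1
                val += " " + nxt.strip()
        fields[key] = val.strip("{} ")
    return fields


def read_cube(path: str | Path) -> SpectralCube:
    path = Path(path)
    if path.suffix == ".hdr":
        hdr, bil = path, path.with_suffix(".bil")
    else:
        bil, hdr = path.with_suffix(".bil"), path.with_suffix(".hdr")
    if not hdr.exists():
        raise FormatError(f"missing ENVI header {hdr}")
    fields = _parse_envi_header(hdr.read_text())
    for key in ("samples", "lines", "bands", "interleave", "data type"):
        if key not in fields:
            raise FormatError(f"ENVI header missing '{key}'")
    if "wavelength" not in fields:
        raise FormatError("ENVI header missing wavelength list")
    if fields["interleave"].lower() != "bil" or fields["data type"] != "4":
        raise FormatError("only float32 BIL cubes are supported")
    ncols = int(fields["samples"])
    nrows = int(fields["lines"])
    nbands = int(fields["bands"])
    wavelengths = np.array(
        [float(w) for w in fields["wavelength"].split(",")], dtype=float
    )
    raw = np.fromfile(bil, dtype=np.float32)
    if raw.size != nrows * ncols * nbands:
        raise FormatError(
            f"{bil}: expected {nrows * ncols * nbands} values, got {raw.size}"
        )
    values = raw.reshape(nrows, nbands, ncols).transpose(0, 2, 1)
    if "map info" not in fields:
        raise FormatError("ENVI header missing map info (grid)")
    parts = [p.strip() for p in fields["map info"].split(",")]
    x0, y_top, gsd = float(parts[3]), float(parts[4]), float(parts[5])
    grid = Grid(x0=x0, y0=y_top - nrows * gsd, gsd=gsd, nrows=nrows, ncols=ncols)
    units = fields.get("units")
    if units is None:
        raise FormatError("ENVI header missing units tag")
    return SpectralCube(values=values, wavelengths=wavelengths, grid=grid, units=units)


# ---------------------------------------------------------------------------
# single-band rasters
# ---------------------------------------------------------------------------


def write_raster(
    values: np.ndarray, grid: Grid, path: str | Path, units: str = UNITS_RADIANCE
) -> Path:
    """Float32 TIFF plus a .grid.json sidecar with grid and units."""
    path = Path(path)
    if path.suffix != ".tif":
        path = path.with_suffix(".tif")
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    sidecar = path.with_suffix(".grid.json")
    sidecar.write_text(json.dumps({"units": units, **grid.to_meta()}, indent=1))
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, Grid, str]:
    path = Path(path)
    sidecar = path.with_suffix(".grid.json")
    if not sidecar.exists():
        raise FormatError(f"missing grid sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "units" not in meta:
        raise FormatError(f"{sidecar}: missing units tag")
    values = tifffile.imread(path).astype(np.float32)
    grid = Grid.from_meta(meta)
    if values.shape != grid.shape:
        raise FormatError(
            f"{path}: raster shape {values.shape} != sidecar grid {grid.shape}"
        )
    return values, grid, meta["units"]


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_table(
    path: str | Path, numeric_columns: tuple[str, ...] = ()
) -> pd.DataFrame:
    """Read a CSV, validating '.'-decimal numeric columns.

    A value like '1,5' in a numeric column raises :class:`FormatError`
    naming the first offending row.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    for col in numeric_columns:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
        if frame[col].dtype == object:
            for i, v in enumerate(frame[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric value {v!r} in column "
                        f"'{col}' at row {i + 2}"  # 1-based incl. header
                    ) from None
            frame[col] = frame[col].astype(float)
    return frame


# ---------------------------------------------------------------------------
# atmosphere + small JSON structures
# ---------------------------------------------------------------------------


def write_atmosphere(
    atm: AtmosphericState, path: str | Path, provenance: str = ""
) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "tau": atm.tau,
                "l_down": atm.l_down,
                "l_up": atm.l_up,
                "units": "W m-2 sr-1 um-1 (band-effective)",
                "provenance": provenance,
            },
            indent=1,
        )
    )
    return path


def read_atmosphere(path: str | Path) -> AtmosphericState:
    meta = json.loads(Path(path).read_text())
    for key in ("tau", "l_down", "l_up"):
        if key not in meta:
            raise FormatError(f"{path}: missing '{key}'")
    return AtmosphericState(
        tau=float(meta["tau"]),
        l_down=float(meta["l_down"]),
        l_up=float(meta["l_up"]),
    )


def write_json_atomic(obj: dict, path: str | Path) -> Path:
    """Write JSON via a temp file + rename (atomic on POSIX)."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(obj, indent=1, default=str))
    os.replace(tmp, path)
    return path
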