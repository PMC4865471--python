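"""ESRI ASCII grid reading and writing.

The interchange format is the plain-text ``.asc`` grid: a header of
``ncols``, ``nrows``, ``xllcorner``, ``yllcorner``, ``cellsize`` and
optionally ``NODATA_value``, followed by ``nrows`` rows of integer codes
(row 0 is the top of the map).  The fixed-cell mask travels as a companion
``.asc`` of 0/1 values on the same grid.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .raster import LandscapeRaster

__all__ = ["read_ascii_grid", "write_ascii_grid", "GridParseError"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


class GridParseError(ValueError):
    """Malformed ASCII grid; carries the offending line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def read_ascii_grid(
    path: str | Path, fixed_mask: str | Path | None = None
) -> LandscapeRaster:
    """Read an ESRI ASCII grid as a :class:`LandscapeRaster`.

    Codes must be integers; NODATA cells (matching the header's
    ``NODATA_value``) are marked fixed.  An optional companion 0/1 grid
    marks additional fixed cells.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for lineno, line in enumerate(lines, start=1):
        tok = line.split()
        if not tok:
            body_start = lineno
            continue
        key = tok[0].lower()
        if key in _HEADER_KEYS + ("nodata_value",):
            if len(tok) != 2:
                raise GridParseError(lineno, f"header key {tok[0]} needs one value")
            try:
                header[key] = float(tok[1])
            except ValueError as exc:
                raise GridParseError(lineno, f"bad header value {tok[1]!r}") from exc
            body_start = lineno
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GridParseError(body_start, f"missing header key {key}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = int(header.get("nodata_value", -1))
    rows = []
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        tok = line.split()
        if not tok:
            continue
        if len(tok) != ncols:
            raise GridParseError(
                lineno, f"expected {ncols} values per row, found {len(tok)}"
            )
        try:
            rows.append([int(t) for t in tok])
        except ValueError as exc:
            raise GridParseError(lineno, f"non-integer cell value in {tok}") from exc
    if len(rows) != nrows:
        raise GridParseError(len(lines), f"expected {nrows} rows, found {len(rows)}")
    codes = np.array(rows, dtype=np.int32)
    fixed = None
    if fixed_mask is not None:
        mask_raster = read_ascii_grid(fixed_mask)
        if mask_raster.shape != codes.shape:
            raise GridParseError(0, "fixed mask shape differs from the grid")
        fixed = mask_raster.codes.astype(bool)
    return LandscapeRaster(
        codes, fixed=fixed, cell_size=float(header["cellsize"]), nodata_code=nodata
    )


def write_ascii_grid(raster: LandscapeRaster, path: str | Path) -> None:
    """Write the raster's codes as an ESRI ASCII grid (integers, row 0 on top)."""
    lines = [
        f"ncols {raster.cols}",
        f"nrows {raster.rows}",
        "xllcorner 0",
        "yllcorner 0",
        f"cellsize {raster.cell_size:g}",
        f"NODATA_value {raster.nodata_code}",
    ]
    for row in raster.codes:
        lines.append(" ".join(str(int(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixed_mask(raster: LandscapeRaster, path: str | Path) -> None:
    """Write the fixed-cell flags as a companion 0/1 ASCII grid."""
    out = LandscapeRaster(
        raster.fixed.astype(np.int32),
        cell_size=raster.cell_size,
        nodata_code=-9999,
    )
    write_ascii_grid(out, path)
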