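"""Landscape fragmentation metrics on categorical land-use rasters.

Six covariates are extracted per monitoring station from the land-use grid
inside a circular buffer (3 km by default elsewhere in the package):
edge density (ED) and landscape shape index (LSI) for the industrial and
public classes, plus the landscape-level aggregation index (AI) and number
of patches (NP) over all developed classes.

Conventions (FRAGSTATS-style unless noted):

* rook (4-neighbour) adjacency for edge lengths and like adjacencies;
* 8-connectivity for patch labelling;
* the ED and LSI denominator is the *class* area — ED in metres of edge per
  hectare of class area, LSI dimensionless with the area in square metres so
  that a solid square patch scores exactly 1 (a ``landscape`` denominator is
  available via ``ed_denominator``);
* cell sides on the buffer/raster boundary count as edge by default
  (outside-buffer treated as background), switchable with
  ``boundary_as_edge=False``;
* background (code 0) is excluded from AI and NP;
* a class reduced to patches with no possible like adjacency (single cells)
  contributes a fully-aggregated ratio of 1 to AI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: land-use class codes used throughout the package
CLASS_CODES = {
    "background": 0,
    "residential": 1,
    "commercial": 2,
    "industrial": 3,
    "transportation": 4,
    "public": 5,
}
BACKGROUND = 0
INDUSTRIAL = CLASS_CODES["industrial"]
PUBLIC = CLASS_CODES["public"]
DEVELOPED_CODES = (1, 2, 3, 4, 5)

#: 8-connectivity structuring element for patch labelling
_STRUCTURE_8 = np.ones((3, 3), dtype=int)


class RasterError(ValueError):
    """Raised for invalid rasters or metric preconditions."""


@dataclass
class LandUseRaster:
    """A rectangular categorical land-use grid with square cells.

    Parameters
    ----------
    grid
        2-D integer array of class codes 0-5; ``nodata`` marks cells outside
        the analysis region (e.g. outside a circular buffer).
    cell_size
        Side length of a cell in metres.
    nodata
        Integer code for missing cells; must not collide with class codes.
    """

    grid: np.ndarray
    cell_size: float
    nodata: int = -1

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        if self.grid.ndim != 2:
            raise RasterError("raster grid must be 2-D")
        if self.cell_size <= 0:
            raise RasterError("cell_size must be positive")
        if self.nodata in CLASS_CODES.values():
            raise RasterError("nodata code collides with a class code")
        valid = set(CLASS_CODES.values()) | {self.nodata}
        present = set(np.unique(self.grid).tolist())
        if not present <= valid:
            raise RasterError(f"unknown class codes in raster: {sorted(present - valid)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def class_cells(self, class_code: int) -> int:
        return int(np.count_nonzero(self.grid == class_code))


@dataclass
class FragmentationProfile:
    """The six fragmentation covariates for one station buffer.

    Missing metrics (class absent from the buffer) are NaN and the class is
    listed in ``missing``.
    """

    ind_ed: float
    pub_ed: float
    ind_lsi: float
    pub_lsi: float
    uf_ai: float
    uf_np: float
    missing: tuple[str, ...] = field(default_factory=tuple)

    COLUMNS = ("ind_ed", "pub_ed", "ind_lsi", "pub_lsi", "uf_ai", "uf_np")

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in self.COLUMNS}

    @property
    def complete(self) -> bool:
        return not self.missing


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text dialect)
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: LandUseRaster, path) -> None:
    """Write a raster as an ESRI ASCII grid with integer class codes."""
    rows, cols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        for row in raster.grid:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_ascii_grid(path) -> LandUseRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([int(v) for v in parts])
    grid = np.array(rows, dtype=int)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if grid.shape != (nrows, ncols):
        raise RasterError(
            f"grid shape {grid.shape} does not match header ({nrows}, {ncols}) in {path}"
        )
    return LandUseRaster(
        grid=grid,
        cell_size=header["cellsize"],
        nodata=int(header.get("nodata_value", -1)),
    )


# ---------------------------------------------------------------------------
# Buffer masking
# ---------------------------------------------------------------------------

def circular_mask(
    raster: LandUseRaster, center: tuple[int, int], radius: float
) -> LandUseRaster:
    """Retain cells whose centre lies within ``radius`` metres of the centre
    of the station cell; everything else becomes nodata.

    ``center`` is (row, col) in cell coordinates. A radius smaller than half
    a cell degenerates to the single centre cell.
    """
    rows, cols = raster.shape
    r0, c0 = center
    if not (0 <= r0 < rows and 0 <= c0 < cols):
        raise RasterError(f"center {center} outside grid of shape {raster.shape}")
    if radius <= 0:
        raise RasterError("radius must be positive")
    rr, cc = np.ogrid[:rows, :cols]
    dist = np.hypot(rr - r0, cc - c0) * raster.cell_size
    masked = np.where(dist <= radius, raster.grid, raster.nodata)
    # the station cell itself is always inside (distance 0)
    return LandUseRaster(grid=masked, cell_size=raster.cell_size, nodata=raster.nodata)


# ---------------------------------------------------------------------------
# Edge-based metrics
# ---------------------------------------------------------------------------

def _edge_sides(raster: LandUseRaster, class_code: int, boundary_as_edge: bool) -> int:
    """Count cell sides where a ``class_code`` cell abuts anything else.

    With ``boundary_as_edge`` the raster border and nodata cells count as
    edge (outside-buffer treated as background); without it only contacts
    with a *different class* (including background) count.
    """
    grid = raster.grid
    pad_value = raster.nodata
    padded = np.pad(grid, 1, constant_values=pad_value)
    is_class = padded == class_code
    sides = 0
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = np.roll(np.roll(padded, dr, axis=0), dc, axis=1)
        contact = is_class & (neigh != class_code)
        if not boundary_as_edge:
            contact &= neigh != raster.nodata
        sides += int(np.count_nonzero(contact))
    return sides


def edge_density(
    raster: LandUseRaster,
    class_code: int,
    *,
    boundary_as_edge: bool = True,
    ed_denominator: str = "class",
) -> float:
    """Edge density of one class: total edge length / area, in m per hectare.

    The denominator is the class area (``ed_denominator='class'``, default) or
    the total non-nodata landscape area (``'landscape'``). Returns NaN when
    the class is absent.
    """
    a_cells = raster.class_cells(class_code)
    if a_cells == 0:
        return float("nan")
    e_m = _edge_sides(raster, class_code, boundary_as_edge) * raster.cell_size
    if ed_denominator == "class":
        denom_cells = a_cells
    elif ed_denominator == "landscape":
        denom_cells = int(np.count_nonzero(raster.grid != raster.nodata))
    else:
        raise ValueError(f"unknown ed_denominator {ed_denominator!r}")
    a_ha = denom_cells * raster.cell_size**2 / 10_000.0
    return e_m / a_ha


def landscape_shape_index(
    raster: LandUseRaster, class_code: int, *, boundary_as_edge: bool = True
) -> float:
    """LSI = 0.25 * edge length / sqrt(class area), edge in m and area in m².

    Equals exactly 1 for a solid square patch and grows with shape complexity
    and fragmentation. NaN when the class is absent.
    """
    a_cells = raster.class_cells(class_code)
    if a_cells == 0:
        return float("nan")
    e_m = _edge_sides(raster, class_code, boundary_as_edge) * raster.cell_size
    a_m2 = a_cells * raster.cell_size**2
    return 0.25 * e_m / math.sqrt(a_m2)


# ---------------------------------------------------------------------------
# Adjacency-based metrics
# ---------------------------------------------------------------------------

def max_like_adjacencies(cell_count: int) -> int:
    """Maximum possible number of like adjacencies (each pair counted once)
    for a class occupying ``cell_count`` cells, attained by the most compact
    arrangement (largest square plus a partial row).

    With n = floor(sqrt(A)) and m = A - n²:
    2n(n-1) if m = 0; 2n(n-1) + 2m - 1 if 0 < m <= n; 2n(n-1) + 2m - 2 if m > n.
    """
    if cell_count < 1:
        raise ValueError("cell_count must be >= 1")
    a = int(cell_count)
    n = math.isqrt(a)
    m = a - n * n
    base = 2 * n * (n - 1)
    if m == 0:
        return base
    if m <= n:
        return base + 2 * m - 1
    return base + 2 * m - 2


def _like_adjacencies(grid: np.ndarray, class_code: int) -> int:
    """Rook-adjacent same-class cell pairs, each counted once."""
    is_class = grid == class_code
    horiz = np.count_nonzero(is_class[:, :-1] & is_class[:, 1:])
    vert = np.count_nonzero(is_class[:-1, :] & is_class[1:, :])
    return int(horiz + vert)


def aggregation_index(raster: LandUseRaster) -> float:
    """Aggregation index over the developed classes, in percent.

    AI = 100 * Σ_i (g_ii / max g_ii) P_i with g_ii the realised like
    adjacencies of class i, max g_ii from :func:`max_like_adjacencies` and
    P_i the class share of total developed area. Classes whose maximum is 0
    (single cells) contribute ratio 1. Background and nodata are excluded.
    """
    counts = {c: raster.class_cells(c) for c in DEVELOPED_CODES}
    total = sum(counts.values())
    if total == 0:
        raise RasterError("aggregation_index: no developed cells in raster")
    ai = 0.0
    for c, a in counts.items():
        if a == 0:
            continue
        g_max = max_like_adjacencies(a)
        ratio = 1.0 if g_max == 0 else _like_adjacencies(raster.grid, c) / g_max
        ai += ratio * (a / total)
    return ai * 100.0


def count_patches(raster: LandUseRaster) -> int:
    """Number of patches: connected components per developed class
    (8-connectivity), summed over classes."""
    if not any(raster.class_cells(c) for c in DEVELOPED_CODES):
        raise RasterError("count_patches: no developed cells in raster")
    total = 0
    for c in DEVELOPED_CODES:
        mask = raster.grid == c
        if mask.any():
            _, n = ndimage.label(mask, structure=_STRUCTURE_8)
            total += int(n)
    return total


# ---------------------------------------------------------------------------
# Station profile
# ---------------------------------------------------------------------------

def fragmentation_profile(
    raster: LandUseRaster,
    center: tuple[int, int] | None = None,
    radius: float | None = None,
    *,
    boundary_as_edge: bool = True,
    ed_denominator: str = "class",
) -> FragmentationProfile:
    """Apply the circular buffer (when given) and compute the six covariates.

    Industrial or public metrics are NaN (and the class is flagged in
    ``missing``) when the class does not occur inside the buffer.
    """
    if center is not None:
        if radius is None:
            raise ValueError("radius required when center is given")
        raster = circular_mask(raster, center, radius)

    missing: list[str] = []
    values: dict[str, float] = {}
    for name, code in (("industrial", INDUSTRIAL), ("public", PUBLIC)):
        ed = edge_density(
            raster, code, boundary_as_edge=boundary_as_edge, ed_denominator=ed_denominator
        )
        lsi = landscape_shape_index(raster, code, boundary_as_edge=boundary_as_edge)
        if math.isnan(ed):
            missing.append(name)
        prefix = "ind" if name == "industrial" else "pub"
        values[f"{prefix}_ed"] = ed
        values[f"{prefix}_lsi"] = lsi
    return FragmentationProfile(
        ind_ed=values["ind_ed"],
        pub_ed=values["pub_ed"],
        ind_lsi=values["ind_lsi"],
        pub_lsi=values["pub_lsi"],
        uf_ai=aggregation_index(raster),
        uf_np=float(count_patches(raster)),
        missing=tuple(missing),
    )
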