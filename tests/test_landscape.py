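"""Fragmentation metrics: hand fixtures, independent oracles, invariances."""

import itertools

import numpy as np
import pytest

from fragno2.landscape import (
    INDUSTRIAL,
    PUBLIC,
    LandUseRaster,
    RasterError,
    aggregation_index,
    circular_mask,
    count_patches,
    edge_density,
    fragmentation_profile,
    landscape_shape_index,
    max_like_adjacencies,
    read_ascii_grid,
    write_ascii_grid,
)

CELL = 100.0


def raster(grid, cell_size=CELL):
    return LandUseRaster(np.asarray(grid, dtype=int), cell_size)


def block_2x2(code=INDUSTRIAL, size=6):
    g = np.zeros((size, size), int)
    g[2:4, 2:4] = code
    return raster(g)


def scattered_4(code=INDUSTRIAL, size=6):
    g = np.zeros((size, size), int)
    for r, c in ((0, 0), (0, 2), (2, 0), (2, 2)):
        g[r, c] = code
    return raster(g)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def flood_fill_patches(grid: np.ndarray) -> int:
    """Recursive 8-connectivity flood fill, per developed class, summed."""
    rows, cols = grid.shape
    seen = np.zeros_like(grid, dtype=bool)
    total = 0
    for r0 in range(rows):
        for c0 in range(cols):
            code = grid[r0, c0]
            if code <= 0 or seen[r0, c0]:
                continue
            total += 1
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = r + dr, c + dc
                        if (0 <= nr < rows and 0 <= nc < cols and not seen[nr, nc]
                                and grid[nr, nc] == code):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
    return total


def polyomino_max_adjacencies(n: int) -> int:
    """Max rook adjacencies over all polyominoes of n cells, by exhaustive
    growth enumeration (translation-normalised)."""

    def normalise(cells):
        rmin = min(r for r, _ in cells)
        cmin = min(c for _, c in cells)
        return frozenset((r - rmin, c - cmin) for r, c in cells)

    def adjacencies(cells):
        return sum(1 for (r, c) in cells if (r + 1, c) in cells) + sum(
            1 for (r, c) in cells if (r, c + 1) in cells
        )

    shapes = {normalise({(0, 0)})}
    for _ in range(n - 1):
        grown = set()
        for shape in shapes:
            for r, c in shape:
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    cand = (r + dr, c + dc)
                    if cand not in shape:
                        grown.add(normalise(shape | {cand}))
        shapes = grown
    return max(adjacencies(s) for s in shapes)


# ---------------------------------------------------------------------------
# hand fixtures
# ---------------------------------------------------------------------------

def test_edge_density_compact_block():
    # 2x2 block: 8 exposed sides of 100 m over 4 ha of class area
    assert edge_density(block_2x2(), INDUSTRIAL) == pytest.approx(200.0)


def test_edge_density_scattered_cells_doubles():
    # 4 isolated cells: 16 sides over the same 4 ha
    assert edge_density(scattered_4(), INDUSTRIAL) == pytest.approx(400.0)


def test_lsi_square_is_one():
    assert landscape_shape_index(block_2x2(), INDUSTRIAL) == pytest.approx(1.0)
    g = np.zeros((10, 10), int)
    g[1:6, 1:6] = PUBLIC  # 5x5 square, different size
    assert landscape_shape_index(raster(g), PUBLIC) == pytest.approx(1.0)


def test_lsi_scattered_cells():
    assert landscape_shape_index(scattered_4(), INDUSTRIAL) == pytest.approx(2.0)


def test_edge_density_boundary_config():
    g = np.full((6, 6), INDUSTRIAL)
    assert edge_density(raster(g), INDUSTRIAL, boundary_as_edge=False) == 0.0
    assert edge_density(raster(g), INDUSTRIAL, boundary_as_edge=True) > 0.0


def test_edge_density_landscape_denominator():
    r = block_2x2()
    by_class = edge_density(r, INDUSTRIAL, ed_denominator="class")
    by_landscape = edge_density(r, INDUSTRIAL, ed_denominator="landscape")
    assert by_landscape == pytest.approx(by_class * 4 / 36)


def test_absent_class_is_nan():
    assert np.isnan(edge_density(block_2x2(), PUBLIC))
    assert np.isnan(landscape_shape_index(block_2x2(), PUBLIC))


def test_aggregation_index_extremes():
    assert aggregation_index(raster(np.ones((8, 8), int))) == pytest.approx(100.0)
    checker = np.indices((8, 8)).sum(axis=0) % 2 + 1  # two developed classes
    assert aggregation_index(raster(checker)) == pytest.approx(0.0)


def test_aggregation_index_single_block_weighted():
    assert aggregation_index(block_2x2()) == pytest.approx(100.0)


def test_count_patches_cases():
    assert count_patches(raster(np.ones((5, 5), int))) == 1
    checker = np.indices((8, 8)).sum(axis=0) % 2 + 1
    assert count_patches(raster(checker)) == 2  # each class diagonally connected
    assert count_patches(scattered_4()) == 4


def test_all_background_raises():
    with pytest.raises(RasterError):
        count_patches(raster(np.zeros((5, 5), int)))
    with pytest.raises(RasterError):
        aggregation_index(raster(np.zeros((5, 5), int)))


# ---------------------------------------------------------------------------
# max_like_adjacencies vs exhaustive polyomino search
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n", range(1, 10))
def test_max_like_adjacencies_matches_polyomino_search(n):
    assert max_like_adjacencies(n) == polyomino_max_adjacencies(n)


def test_max_like_adjacencies_rejects_zero():
    with pytest.raises(ValueError):
        max_like_adjacencies(0)


# ---------------------------------------------------------------------------
# patch counting vs flood-fill oracle
# ---------------------------------------------------------------------------

def test_count_patches_matches_flood_fill_on_random_rasters():
    rng = np.random.default_rng(42)
    for _ in range(100):
        shape = (int(rng.integers(3, 17)), int(rng.integers(3, 17)))
        grid = rng.integers(0, 6, size=shape)
        if not (grid > 0).any():
            grid[0, 0] = 1
        assert count_patches(raster(grid)) == flood_fill_patches(grid)


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("metric", [edge_density, landscape_shape_index])
def test_translation_and_rotation_invariance(metric, rng):
    base = np.zeros((12, 12), int)
    base[2:6, 3:8] = INDUSTRIAL
    base[7:9, 1:4] = INDUSTRIAL
    value = metric(raster(base), INDUSTRIAL)
    assert metric(raster(np.roll(base, (2, 3), axis=(0, 1))), INDUSTRIAL) == pytest.approx(value)
    assert metric(raster(np.rot90(base).copy()), INDUSTRIAL) == pytest.approx(value)


# ---------------------------------------------------------------------------
# circular buffer
# ---------------------------------------------------------------------------

def test_circular_mask_superset_radius_keeps_everything():
    g = np.ones((9, 9), int)
    r = raster(g)
    masked = circular_mask(r, (4, 4), radius=100.0 * 20)
    assert (masked.grid == g).all()


def test_circular_mask_point_buffer():
    r = raster(np.ones((9, 9), int))
    masked = circular_mask(r, (4, 4), radius=0.4 * CELL)
    assert (masked.grid != masked.nodata).sum() == 1
    assert masked.grid[4, 4] == 1


def test_circular_mask_matches_per_cell_distance_oracle():
    r = raster(np.ones((15, 15), int))
    center, radius = (7, 7), 2.0 * CELL
    masked = circular_mask(r, center, radius)
    for i in range(15):
        for j in range(15):
            inside = np.hypot(i - 7, j - 7) * CELL <= radius
            assert (masked.grid[i, j] != masked.nodata) == inside


# ---------------------------------------------------------------------------
# profile assembly
# ---------------------------------------------------------------------------

def test_profile_flags_missing_class():
    g = np.full((8, 8), INDUSTRIAL)
    prof = fragmentation_profile(raster(g))
    assert np.isfinite(prof.ind_ed) and np.isfinite(prof.ind_lsi)
    assert np.isnan(prof.pub_ed) and np.isnan(prof.pub_lsi)
    assert prof.missing == ("public",)


def test_compact_vs_scattered_profiles():
    compact = np.zeros((12, 12), int)
    compact[0:4, 0:4] = INDUSTRIAL
    compact[8:12, 8:12] = PUBLIC
    scattered = np.zeros((12, 12), int)
    scattered[::3, ::3] = INDUSTRIAL
    scattered[1::3, 1::3] = PUBLIC
    p_compact = fragmentation_profile(raster(compact))
    p_scattered = fragmentation_profile(raster(scattered))
    assert p_scattered.uf_np > p_compact.uf_np
    assert p_scattered.uf_ai < p_compact.uf_ai


def test_profile_on_masked_equals_profile_of_mask():
    rng = np.random.default_rng(8)
    g = rng.integers(0, 6, size=(21, 21))
    r = raster(g)
    center, radius = (10, 10), 5.2 * CELL
    via_args = fragmentation_profile(r, center, radius)
    via_mask = fragmentation_profile(circular_mask(r, center, radius))
    for col in via_args.COLUMNS:
        a, b = getattr(via_args, col), getattr(via_mask, col)
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)


# ---------------------------------------------------------------------------
# ASCII grid round trip
# ---------------------------------------------------------------------------

def test_ascii_grid_round_trip(tmp_path, rng):
    grid = rng.integers(0, 6, size=(13, 17))
    r = LandUseRaster(grid, cell_size=30.0)
    path = tmp_path / "station.asc"
    write_ascii_grid(r, path)
    back = read_ascii_grid(path)
    assert (back.grid == grid).all()
    assert back.cell_size == 30.0
    assert back.nodata == r.nodata
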