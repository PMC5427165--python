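"""Synthetic multi-channel well images with exported ground truth.

Emulates the screen's imaging read-out — Hoechst-stained nuclei plus
cytoplasmic mCherry and YFP reporter signal — with the simplest geometry
that admits exact ground-truth masks: a circular nucleus and a concentric
annular cytoplasm per cell. Per-cell reporter intensity is log-normal
around the well mean so that averaging is non-trivial; pixel noise is
additive Gaussian truncated at zero. Point-spread functions, illumination
gradients and autofluorescence are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cellcounts import DEFAULT_MEAN, DEFAULT_SD, sample_cell_counts
from .errors import CellOutOfBoundsError, InputError, PlacementError
from .image_quant import CHANNELS, WellImageStack, write_well_tiff

GROUND_TRUTH_COLUMNS = [
    "cell_id", "center_row", "center_col", "nucleus_radius",
    "cytoplasm_radius", "true_mcherry_mean", "true_yfp_mean",
]


@dataclass
class CellGroundTruth:
    """One simulated cell: geometry plus true mean reporter intensities."""

    cell_id: int
    center_row: float
    center_col: float
    nucleus_radius: float
    cytoplasm_radius: float
    true_mcherry_mean: float
    true_yfp_mean: float

    def __post_init__(self) -> None:
        if not (self.cytoplasm_radius > self.nucleus_radius > 0):
            raise InputError(
                "need cytoplasm_radius > nucleus_radius > 0, got "
                f"{self.cytoplasm_radius}, {self.nucleus_radius}")
        if self.true_mcherry_mean < 0 or self.true_yfp_mean < 0:
            raise InputError("true intensities must be >= 0")


@dataclass
class ImageSimParams:
    """Simulation parameters for one well image.

    ``background`` and ``noise_sd`` are per-channel (hoechst, yfp, mcherry)
    fluorescence units. ``mcherry_mean``/``yfp_mean`` set the well-level true
    mean around which per-cell intensities scatter log-normally with
    coefficient of variation ``intensity_cv``. Identical parameters and seed
    give bit-identical images and ground truth.
    """

    image_size: tuple[int, int] = (1024, 1024)
    nucleus_radius: float = 6.0
    cytoplasm_radius: float = 13.0
    overlap_allowed: bool = False
    background: tuple[float, float, float] = (8.0, 15.0, 15.0)
    noise_sd: tuple[float, float, float] = (3.0, 4.0, 4.0)
    nucleus_intensity: float = 160.0
    mcherry_mean: float = 500.0
    yfp_mean: float = 300.0
    intensity_cv: float = 0.3
    cellcount_mean: float = DEFAULT_MEAN
    cellcount_sd: float = DEFAULT_SD
    max_attempts_per_cell: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.noise_sd):
            raise InputError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if any(b < 0 for b in self.background):
            raise InputError(f"background must be >= 0, got {self.background}")
        if self.intensity_cv < 0:
            raise InputError("intensity_cv must be >= 0")
        if not (self.cytoplasm_radius > self.nucleus_radius > 0):
            raise InputError("need cytoplasm_radius > nucleus_radius > 0")


def nucleus_mask(cell: CellGroundTruth, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the cell's nucleus disc (exact ground truth)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - cell.center_row) ** 2 + (cc - cell.center_col) ** 2
    return d2 <= cell.nucleus_radius ** 2


def cytoplasm_mask(cell: CellGroundTruth, shape: tuple[int, int]
                   ) -> np.ndarray:
    """Boolean mask of the cell's annular cytoplasm (exact ground truth)."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - cell.center_row) ** 2 + (cc - cell.center_col) ** 2
    return (d2 > cell.nucleus_radius ** 2) & (d2 <= cell.cytoplasm_radius ** 2)


def sample_well_layout(
    n_cells: int,
    params: ImageSimParams,
    rng: np.random.Generator | None = None,
) -> list[CellGroundTruth]:
    """Place ``n_cells`` cells in the image, non-overlapping by default.

    Placement is rejection sampling on a spatial hash: a candidate centre is
    accepted when no accepted centre lies within two cytoplasm radii (so the
    full cell discs are disjoint). Per-cell true means are log-normal around
    the well means with CV ``params.intensity_cv``.
    """
    if n_cells < 0:
        raise InputError(f"n_cells must be >= 0, got {n_cells}")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    h, w = params.image_size
    margin = params.cytoplasm_radius
    if 2 * margin >= h or 2 * margin >= w:
        raise CellOutOfBoundsError(
            f"image {params.image_size} too small for cytoplasm radius "
            f"{params.cytoplasm_radius}")

    min_dist = 2.0 * params.cytoplasm_radius
    bin_size = min_dist
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    centers: list[tuple[float, float]] = []
    budget = params.max_attempts_per_cell * max(n_cells, 1)
    attempts = 0
    while len(centers) < n_cells:
        if attempts >= budget:
            raise PlacementError(
                f"placed {len(centers)}/{n_cells} cells within the attempt "
                f"budget ({budget} = {params.max_attempts_per_cell} per cell)")
        attempts += 1
        r = rng.uniform(margin, h - 1 - margin)
        c = rng.uniform(margin, w - 1 - margin)
        if params.overlap_allowed:
            ok = True
        else:
            key = (int(r // bin_size), int(c // bin_size))
            ok = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    for (pr, pc) in grid.get((key[0] + dr, key[1] + dc), ()):
                        if (pr - r) ** 2 + (pc - c) ** 2 < min_dist ** 2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
        if ok:
            centers.append((r, c))
            key = (int(r // bin_size), int(c // bin_size))
            grid.setdefault(key, []).append((r, c))

    cells = []
    for i, (r, c) in enumerate(centers, start=1):
        cells.append(CellGroundTruth(
            cell_id=i,
            center_row=r,
            center_col=c,
            nucleus_radius=params.nucleus_radius,
            cytoplasm_radius=params.cytoplasm_radius,
            true_mcherry_mean=_lognormal_around(
                params.mcherry_mean, params.intensity_cv, rng),
            true_yfp_mean=_lognormal_around(
                params.yfp_mean, params.intensity_cv, rng),
        ))
    return cells


def _lognormal_around(mean: float, cv: float, rng: np.random.Generator
                      ) -> float:
    if cv == 0 or mean == 0:
        return float(mean)
    s2 = np.log1p(cv ** 2)
    return float(rng.lognormal(np.log(mean) - s2 / 2, np.sqrt(s2)))


#: Area fraction up to which non-overlapping discs place quickly; random
#: sequential placement jams near ~0.547, so stay comfortably below it.
PACKING_FRACTION = 0.45


def max_placeable_cells(params: ImageSimParams) -> int:
    """Largest cell count the non-overlap placement accepts reliably."""
    h, w = params.image_size
    cell_area = np.pi * params.cytoplasm_radius ** 2
    return int(np.floor(PACKING_FRACTION * h * w / cell_area))


def draw_cell_count(params: ImageSimParams, rng: np.random.Generator) -> int:
    """One analyzable-cell count from the screen-wide calibration.

    Draws are capped at the image's packing limit: crowded wells above the
    limit cannot be rendered with disjoint ground-truth masks. The
    intensity-level screen simulator uses the uncapped distribution.
    """
    count = int(sample_cell_counts(
        1, rng, mean=params.cellcount_mean, sd=params.cellcount_sd)[0])
    if params.overlap_allowed:
        return count
    return min(count, max_placeable_cells(params))


def render_well(
    params: ImageSimParams,
    cells: list[CellGroundTruth],
    rng: np.random.Generator | None = None,
    well_id: str = "",
) -> tuple[WellImageStack, list[CellGroundTruth]]:
    """Render a 3-channel well image from a cell layout.

    Nucleus discs appear in the Hoechst channel at ``nucleus_intensity``
    above background; each cell's annular cytoplasm carries its true mean in
    the mCherry and YFP channels. Additive Gaussian noise (per-channel SD)
    is applied last and the result is clipped at zero. Ground truth is
    returned unchanged alongside the image.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    h, w = params.image_size
    for cell in cells:
        r_out = cell.cytoplasm_radius
        if (cell.center_row - r_out < 0 or cell.center_row + r_out > h - 1
                or cell.center_col - r_out < 0
                or cell.center_col + r_out > w - 1):
            raise CellOutOfBoundsError(
                f"cell {cell.cell_id} at ({cell.center_row:.1f}, "
                f"{cell.center_col:.1f}) exceeds image bounds {params.image_size}")

    channels = {
        name: np.full((h, w), bg, dtype=np.float64)
        for name, bg in zip(CHANNELS, params.background)
    }
    for cell in cells:
        sl, local = _footprint_window(cell, (h, w))
        rr, cc = local
        d2 = rr ** 2 + cc ** 2
        nuc = d2 <= cell.nucleus_radius ** 2
        annulus = (d2 > cell.nucleus_radius ** 2) & (
            d2 <= cell.cytoplasm_radius ** 2)
        channels["hoechst"][sl][nuc] = params.background[0] + params.nucleus_intensity
        channels["yfp"][sl][annulus] = params.background[1] + cell.true_yfp_mean
        channels["mcherry"][sl][annulus] = params.background[2] + cell.true_mcherry_mean

    for name, sd in zip(CHANNELS, params.noise_sd):
        if sd > 0:
            channels[name] += rng.normal(0.0, sd, size=(h, w))
            np.clip(channels[name], 0.0, None, out=channels[name])

    stack = WellImageStack(well_id=well_id, **channels)
    return stack, cells


def _footprint_window(cell: CellGroundTruth, shape: tuple[int, int]):
    r0 = int(np.floor(cell.center_row - cell.cytoplasm_radius))
    r1 = int(np.ceil(cell.center_row + cell.cytoplasm_radius)) + 1
    c0 = int(np.floor(cell.center_col - cell.cytoplasm_radius))
    c1 = int(np.ceil(cell.center_col + cell.cytoplasm_radius)) + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, shape[0]), min(c1, shape[1])
    rows = np.arange(r0, r1)[:, None] - cell.center_row
    cols = np.arange(c0, c1)[None, :] - cell.center_col
    return (slice(r0, r1), slice(c0, c1)), (rows, cols)


def simulate_well(
    params: ImageSimParams,
    n_cells: int | None = None,
    well_id: str = "",
    rng: np.random.Generator | None = None,
) -> tuple[WellImageStack, list[CellGroundTruth]]:
    """Layout + render in one call; ``n_cells=None`` draws the count from
    the calibrated per-well distribution."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if n_cells is None:
        n_cells = draw_cell_count(params, rng)
    cells = sample_well_layout(n_cells, params, rng=rng)
    return render_well(params, cells, rng=rng, well_id=well_id)


def ground_truth_table(cells: list[CellGroundTruth]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in cells],
                        columns=GROUND_TRUTH_COLUMNS)


def write_well(stack: WellImageStack, cells: list[CellGroundTruth],
               out_dir: str | Path) -> dict[str, Path]:
    """Write one well's TIFF, channel sidecar, and ground-truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff = write_well_tiff(stack, out_dir / f"{stack.well_id}.tiff")
    truth = out_dir / f"{stack.well_id}.ground_truth.csv"
    ground_truth_table(cells).to_csv(truth, index=False)
    return {"tiff": tiff, "ground_truth": truth}
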