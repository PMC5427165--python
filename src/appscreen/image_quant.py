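"""Per-cell fluorescence quantification from multi-channel well images.

Reimplements the screen's automated image read-out: nuclei are segmented
from the Hoechst channel, each cell is grown from its nucleus by a bounded
nearest-seed expansion, and the mean cytoplasmic mCherry/YFP intensity per
cell is measured after subtracting a per-image background estimate. The
per-well summary is the analyzable cell count and the unweighted mean of
the per-cell means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import expand_labels, relabel_sequential, watershed

from .errors import InputError

CHANNELS = ("hoechst", "yfp", "mcherry")


@dataclass
class WellImageStack:
    """Registered multi-channel image of one well.

    All three channels share the same 2-D shape; intensities are arbitrary
    fluorescence units and non-negative.
    """

    hoechst: np.ndarray
    yfp: np.ndarray
    mcherry: np.ndarray
    well_id: str = ""

    def __post_init__(self) -> None:
        shapes = {self.hoechst.shape, self.yfp.shape, self.mcherry.shape}
        if len(shapes) != 1:
            raise InputError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hoechst.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise InputError(f"unknown channel {name!r}; expected {CHANNELS}")
        return getattr(self, name)


@dataclass
class SegmentationResult:
    """Label images from one well: nuclei, whole cells, and cytoplasm rings.

    Label 0 is background; the cytoplasm mask of each cell is disjoint from
    its nucleus and shares its label id.
    """

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    cytoplasm_labels: np.ndarray


@dataclass
class CellMeasurement:
    cell_id: int
    mcherry_mean: float
    yfp_mean: float
    cytoplasm_area: int


@dataclass
class QuantConfig:
    """Tunable knobs of the quantification stage.

    smooth_sigma      Gaussian blur (px) applied to Hoechst before Otsu.
    min_nucleus_area  objects smaller than this (px) are discarded.
    peak_min_distance minimum separation (px) of watershed seed peaks.
    ring_inner_margin px between the nucleus boundary and the inner edge of
                      the cytoplasm ring; keeps perinuclear pixels out of
                      the cytoplasmic measurement.
    ring_width        radial width (px) of the cytoplasm ring.
    exclude_border    drop cells whose footprint touches the image border.
    """

    smooth_sigma: float = 2.0
    min_nucleus_area: int = 30
    peak_min_distance: int = 7
    ring_inner_margin: int = 1
    ring_width: int = 4
    exclude_border: bool = True


def segment_nuclei(
    hoechst: np.ndarray,
    sigma: float = 2.0,
    min_area: int = 30,
    peak_min_distance: int = 7,
) -> np.ndarray:
    """Label nuclei in a Hoechst image.

    Otsu threshold on the Gaussian-smoothed image, followed by a
    distance-transform watershed to split touching nuclei and removal of
    sub-threshold specks. A blank (constant) image yields zero labels.
    """
    hoechst = np.asarray(hoechst, dtype=np.float64)
    if hoechst.size == 0:
        raise InputError("empty image")
    labels = np.zeros(hoechst.shape, dtype=np.int32)
    if np.ptp(hoechst) == 0:
        return labels

    smoothed = gaussian(hoechst, sigma=sigma, preserve_range=True)
    mask = smoothed > threshold_otsu(smoothed)
    comps = cc_label(mask)
    areas = np.bincount(comps.ravel())
    specks = np.flatnonzero(areas < min_area)
    mask &= ~np.isin(comps, specks[specks > 0])
    if not mask.any():
        return labels

    distance = ndi.distance_transform_edt(mask)
    coords = peak_local_max(
        distance,
        min_distance=peak_min_distance,
        labels=cc_label(mask),
        exclude_border=False,
    )
    if len(coords) == 0:
        return labels
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-distance, markers, mask=mask)

    # watershed fragments below the area floor are noise, not nuclei
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < min_area)
    labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_cells(
    nucleus_labels: np.ndarray,
    hoechst: np.ndarray | None = None,
    ring_width: int = 4,
    inner_margin: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Grow cell and cytoplasm-ring labels from nucleus seeds.

    Each cell is its nucleus expanded by ``inner_margin + ring_width``
    pixels, clipped where neighbouring cells meet (nearest-seed partition).
    The cytoplasm ring excludes both the nucleus and an ``inner_margin``
    guard band around it, so nucleus-boundary pixels never contaminate the
    cytoplasmic mean. ``hoechst`` is accepted for interface symmetry; the
    expansion is purely geometric.
    """
    del hoechst
    if ring_width < 0 or inner_margin < 0:
        raise InputError("ring_width and inner_margin must be >= 0")
    nucleus_labels = np.asarray(nucleus_labels)
    if ring_width == 0:
        warnings.warn(
            "ring_width=0 gives empty cytoplasm masks", stacklevel=2)
        cells = expand_labels(nucleus_labels, distance=inner_margin)
        return cells, np.zeros_like(nucleus_labels)
    cells = expand_labels(nucleus_labels, distance=inner_margin + ring_width)
    inner = expand_labels(nucleus_labels, distance=inner_margin)
    cytoplasm = np.where(inner == 0, cells, 0)
    return cells, cytoplasm


def segment_well(stack: WellImageStack, config: QuantConfig | None = None
                 ) -> SegmentationResult:
    """Full segmentation of one well from its Hoechst channel."""
    config = config or QuantConfig()
    nuclei = segment_nuclei(
        stack.hoechst,
        sigma=config.smooth_sigma,
        min_area=config.min_nucleus_area,
        peak_min_distance=config.peak_min_distance,
    )
    cells, cyto = segment_cells(
        nuclei,
        ring_width=config.ring_width,
        inner_margin=config.ring_inner_margin,
    )
    return SegmentationResult(nuclei, cells, cyto)


def _border_labels(labels: np.ndarray) -> set[int]:
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    return set(np.unique(edge[edge > 0]).tolist())


def estimate_background(channel: np.ndarray, cell_labels: np.ndarray) -> float:
    """Median intensity of pixels outside every cell footprint."""
    outside = channel[cell_labels == 0]
    if outside.size == 0:
        return 0.0
    return float(np.median(outside))


def quantify_well(
    stack: WellImageStack,
    seg: SegmentationResult,
    config: QuantConfig | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Measure per-cell cytoplasmic means and the per-well summary.

    Returns ``(well_record, measurements)``. ``well_record`` carries
    ``well_id``, ``cell_count`` and the unweighted mean over cells of the
    per-cell background-subtracted means (NaN when no cell is measurable).
    Background per channel is the median of non-cell pixels; per-cell means
    are floored at 0 after subtraction.
    """
    config = config or QuantConfig()
    if seg.cell_labels.shape != stack.shape:
        raise InputError("segmentation and stack dimensions differ")

    drop = _border_labels(seg.cell_labels) if config.exclude_border else set()
    cyto = seg.cytoplasm_labels
    ids = [int(i) for i in np.unique(cyto) if i > 0 and i not in drop]

    backgrounds = {
        name: estimate_background(stack.channel(name), seg.cell_labels)
        for name in ("mcherry", "yfp")
    }

    rows = []
    if ids:
        index = np.asarray(ids)
        area = ndi.sum_labels(np.ones_like(cyto), cyto, index)
        means = {}
        for name in ("mcherry", "yfp"):
            raw = ndi.mean(stack.channel(name), labels=cyto, index=index)
            means[name] = np.maximum(raw - backgrounds[name], 0.0)
        for k, cid in enumerate(ids):
            rows.append(CellMeasurement(
                cell_id=cid,
                mcherry_mean=float(means["mcherry"][k]),
                yfp_mean=float(means["yfp"][k]),
                cytoplasm_area=int(area[k]),
            ))

    measurements = pd.DataFrame(
        [vars(m) for m in rows],
        columns=["cell_id", "mcherry_mean", "yfp_mean", "cytoplasm_area"],
    )
    n = len(measurements)
    record = {
        "well_id": stack.well_id,
        "cell_count": n,
        "mcherry_mean": float(measurements["mcherry_mean"].mean()) if n else float("nan"),
        "yfp_mean": float(measurements["yfp_mean"].mean()) if n else float("nan"),
    }
    return record, measurements


# ---------------------------------------------------------------------------
# TIFF input/output

def write_well_tiff(stack: WellImageStack, path: str | Path) -> Path:
    """Write a well as a 3-page TIFF (hoechst, yfp, mcherry) with a sidecar
    ``<stem>.channels.csv`` recording the page-to-channel mapping."""
    path = Path(path)
    pages = np.stack([stack.channel(c) for c in CHANNELS]).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = path.with_suffix(".channels.csv")
    pd.DataFrame({
        "page": range(len(CHANNELS)),
        "channel": CHANNELS,
        "well_id": stack.well_id,
    }).to_csv(sidecar, index=False)
    return path


def read_well_tiff(path: str | Path, well_id: str | None = None
                   ) -> WellImageStack:
    """Read a well written by :func:`write_well_tiff`.

    The sidecar channel table is honoured when present; otherwise pages are
    assumed to follow the canonical (hoechst, yfp, mcherry) order.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        raise InputError(f"{path} has a single page; expected 3 channels")
    order = list(CHANNELS)
    sidecar = path.with_suffix(".channels.csv")
    if sidecar.exists():
        meta = pd.read_csv(sidecar).sort_values("page")
        order = [str(c) for c in meta["channel"]]
        if well_id is None and "well_id" in meta:
            well_id = str(meta["well_id"].iloc[0])
    arrays = dict(zip(order, np.asarray(pages, dtype=np.float64)))
    return WellImageStack(
        hoechst=arrays["hoechst"],
        yfp=arrays["yfp"],
        mcherry=arrays["mcherry"],
        well_id=well_id or path.stem,
    )
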