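"""Nuclei segmentation and per-cell measurement.

Cells are detected from the haematoxylin OD map (brightfield) or the DAPI
channel (fluorescence): threshold, fill holes, drop sub-nuclear debris,
then split touching nuclei with a distance-transform watershed.  Each
labelled nucleus becomes one row of a cell table (a pandas DataFrame) with
its centroid, area in px and um^2, and mean per-stain OD (or per-channel
intensity) over the nucleus mask and over a thin cytoplasmic ring.

The cell table is the package's canonical container; downstream phenotyping
and scoring operate on its columns.  Stable column order: ``id, x, y,
area_um2, area_px``, then ``od_nuc_* / od_cyt_*`` (brightfield) or
``int_nuc_* / int_cyt_*`` (fluorescence), then phenotype columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.morphology import remove_small_objects
from skimage.segmentation import expand_labels, watershed

from .geometry import FovGeometry
from .stain import OdImage

__all__ = ["SegmentationParams", "segment_nuclei", "measure_cells", "CELL_BASE_COLUMNS"]

CELL_BASE_COLUMNS = ["id", "x", "y", "area_um2", "area_px"]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables for nuclei segmentation.

    ``od_threshold=None`` selects a data-driven threshold on the OD
    histogram — ``method='triangle'`` (default; robust when nuclei of
    very different darkness share a dominant cytoplasm background) or
    ``method='otsu'``; a float fixes the threshold.  ``min_od`` guards
    against thresholding blank or near-blank images.  ``min_area_um2`` drops debris below a plausible
    nuclear cross-section at 20x.  ``split_min_distance_um`` is the minimum
    peak separation of the watershed marker search, roughly one small
    nuclear radius.
    """

    od_threshold: float | None = None
    method: str = "triangle"
    min_od: float = 0.1
    min_area_um2: float = 10.0
    split_min_distance_um: float = 3.0


def _threshold(od: np.ndarray, params: SegmentationParams) -> float | None:
    """Pick the foreground OD cut; None means nothing to segment."""
    if params.od_threshold is not None:
        return params.od_threshold
    if od.max() < params.min_od:
        return None
    if params.method == "triangle":
        thr = threshold_triangle(od)
    elif params.method == "otsu":
        thr = threshold_otsu(od)
    else:
        raise ValueError(f"unknown threshold method {params.method!r}")
    # a near-empty histogram can push the cut below the noise floor
    return max(thr, params.min_od / 2)


def segment_nuclei(
    nuclear_signal: OdImage | np.ndarray,
    geometry: FovGeometry,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment nuclei from a haematoxylin-OD (or DAPI-intensity) map.

    Returns ``(labels, cells)`` where ``labels`` is an int32 image with
    background 0 and nuclei 1..N, and ``cells`` is a cell table with the
    base columns filled (measurement columns are added by
    :func:`measure_cells`).  Deterministic for fixed input and params.
    """
    params = params or SegmentationParams()
    od = nuclear_signal.values if isinstance(nuclear_signal, OdImage) else np.asarray(
        nuclear_signal, dtype=float
    )
    if od.shape != geometry.shape:
        raise ValueError(f"image shape {od.shape} != geometry shape {geometry.shape}")
    if not np.all(np.isfinite(od)):
        raise ValueError("nuclear signal must be finite")

    thr = _threshold(od, params)
    if thr is None:
        return np.zeros(geometry.shape, dtype=np.int32), _empty_cells()

    fg = od > thr
    fg = ndi.binary_fill_holes(fg)
    min_area_px = max(1, int(round(params.min_area_um2 / geometry.um2_per_px)))
    fg = remove_small_objects(fg, max_size=min_area_px - 1)
    if not fg.any():
        return np.zeros(geometry.shape, dtype=np.int32), _empty_cells()

    labels = _watershed_split(fg, geometry, params)
    sizes = np.bincount(labels.ravel())
    labels[sizes[labels] < min_area_px] = 0
    labels = _renumber(labels)

    cells = _base_table(labels, geometry)
    return labels, cells


def _watershed_split(
    fg: np.ndarray, geometry: FovGeometry, params: SegmentationParams
) -> np.ndarray:
    """Split touching nuclei by watershed on the negated distance transform."""
    dist = ndi.distance_transform_edt(fg)
    min_dist_px = max(1, int(round(geometry.um_to_px(params.split_min_distance_um))))
    # deterministic marker detection: local maxima of the smoothed EDT
    smooth = ndi.gaussian_filter(dist, sigma=1.0)
    footprint = np.ones((2 * min_dist_px + 1,) * 2, dtype=bool)
    maxima = (smooth == ndi.maximum_filter(smooth, footprint=footprint)) & fg
    # collapse maxima plateaus to single markers
    markers, n_markers = ndi.label(maxima)
    if n_markers == 0:
        markers, _ = ndi.label(fg)
        return markers.astype(np.int32)
    return watershed(-dist, markers=markers, mask=fg).astype(np.int32)


def _renumber(labels: np.ndarray) -> np.ndarray:
    """Relabel to a dense 1..N range, preserving order."""
    ids, inverse = np.unique(labels, return_inverse=True)
    lut = np.zeros(ids.size, dtype=np.int32)
    lut[ids > 0] = np.arange(1, int((ids > 0).sum()) + 1, dtype=np.int32)
    return lut[inverse].reshape(labels.shape)


def _empty_cells() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": pd.Series(dtype=np.int64),
            "x": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
            "area_um2": pd.Series(dtype=float),
            "area_px": pd.Series(dtype=np.int64),
        }
    )


def _base_table(labels: np.ndarray, geometry: FovGeometry) -> pd.DataFrame:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return _empty_cells()
    # centroids in (y, x); convert to x-rightward / y-downward columns
    centroids = ndi.center_of_mass(labels > 0, labels, ids)
    areas_px = ndi.sum_labels(np.ones_like(labels), labels, ids).astype(np.int64)
    cy = np.array([c[0] for c in centroids])
    cx = np.array([c[1] for c in centroids])
    return pd.DataFrame(
        {
            "id": ids.astype(np.int64),
            "x": cx,
            "y": cy,
            "area_um2": areas_px * geometry.um2_per_px,
            "area_px": areas_px,
        }
    )


def measure_cells(
    labels: np.ndarray,
    cells: pd.DataFrame,
    signal_maps: dict[str, OdImage | np.ndarray],
    geometry: FovGeometry,
    ring_radius_px: int = 3,
    prefix: str = "od",
    nucleus_erode_px: int = 2,
) -> pd.DataFrame:
    """Fill per-cell measurement columns from stain OD maps or channels.

    For every named map, adds ``{prefix}_nuc_{name}`` (mean over the
    nucleus mask, shrunk by ``nucleus_erode_px`` to avoid partial-volume
    boundary pixels) and ``{prefix}_cyt_{name}`` (mean over a cytoplasmic
    ring: dilation of the nucleus by ``ring_radius_px``, minus all nuclei,
    clipped at neighbouring cells' rings).  Use ``prefix='int'`` for
    fluorescence channel intensities.
    """
    if ring_radius_px < 0:
        raise ValueError("ring_radius_px must be >= 0")
    cells = cells.copy()
    ids = cells["id"].to_numpy()
    expanded = expand_labels(labels, distance=ring_radius_px)
    ring = np.where(labels == 0, expanded, 0)
    nuc_labels = labels
    if nucleus_erode_px > 0:
        interior = ndi.binary_erosion(labels > 0, iterations=nucleus_erode_px)
        eroded = np.where(interior, labels, 0)
        # cells erased entirely by the erosion keep their full mask
        kept = np.unique(eroded)
        lost = np.setdiff1d(ids, kept)
        if lost.size:
            eroded = np.where(np.isin(labels, lost), labels, eroded)
        nuc_labels = eroded
    for name, img in signal_maps.items():
        values = img.values if isinstance(img, OdImage) else np.asarray(img, dtype=float)
        if values.shape != labels.shape:
            raise ValueError(
                f"map {name!r} shape {values.shape} != label shape {labels.shape}"
            )
        if ids.size == 0:
            cells[f"{prefix}_nuc_{name}"] = pd.Series(dtype=float)
            cells[f"{prefix}_cyt_{name}"] = pd.Series(dtype=float)
            continue
        nuc_mean = ndi.mean(values, nuc_labels, ids)
        with np.errstate(invalid="ignore"):
            cyt_mean = ndi.mean(values, ring, ids)
        # cells whose ring is fully occluded by neighbours: fall back to nucleus
        cyt_mean = np.where(np.isfinite(cyt_mean), cyt_mean, nuc_mean)
        cells[f"{prefix}_nuc_{name}"] = nuc_mean
        cells[f"{prefix}_cyt_{name}"] = cyt_mean
    return cells
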