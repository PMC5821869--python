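"""Synthetic stained-liver FOV generator with complete ground truth.

Renders 20x-magnification fields of view the way the analysis modules
expect to see them — brightfield IHC (DAB + haematoxylin), H&E, Sirius
Red, and 3-channel immunofluorescence — with every rendered cell and
region recorded in a truth table before rasterisation.  The generator is
the package's benchmark substrate: detection, phenotyping, region and
scoring claims are all validated against its ground truth.

Scene model
-----------
* Nuclei are hard-core (minimum-distance) random disks: hepatocytes,
  small presumptive progenitors (HPCs), large dark ductal cells ringing
  portal tracts, and small CD45+ inflammatory cells (singles and
  clustered foci).
* Marker expression is painted as a cytoplasmic DAB annulus with
  per-population OD distributions (positive vs negative populations are
  two Gaussians).
* Confluent necrosis is an irregular low-haematoxylin blob, steatosis a
  set of round unstained vacuoles, collagen a set of Sirius-Red ribbons.
* Per-stain OD maps are mildly blurred, given Gaussian OD noise inside
  tissue, composed through the stain matrix and converted to 8-bit RGB.

All randomness flows through one seeded generator; identical spec + seed
yields bit-identical truth tables and images.  Placement counts are
deterministic functions of the densities (``round(density * area)``), so
the severity ladder's planted measures are monotone by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from .geometry import FovGeometry
from .scoring import surrogate_measures
from .stain import default_stain_matrix, od_to_rgb, compose
from .regions import RegionParams, area_fraction

__all__ = [
    "SceneSpec",
    "SyntheticFovTruth",
    "GenerationError",
    "generate_brightfield",
    "generate_if",
    "severity_ladder",
    "replicate_specs",
    "POPULATIONS",
]


class GenerationError(RuntimeError):
    """Raised when a scene cannot be packed within the retry budget."""


#: Per-population nuclear morphology and staining (means; sds below).
#: Areas in um^2, ODs dimensionless.
POPULATIONS: dict[str, dict[str, float]] = {
    "hepatocyte": {"area_um2": 40.0, "haem": 0.55, "haem_sd": 0.05},
    "hpc": {"area_um2": 25.0, "haem": 0.40, "haem_sd": 0.04},
    "ductal": {"area_um2": 60.0, "haem": 0.80, "haem_sd": 0.06},
    "cd45": {"area_um2": 20.0, "haem": 0.60, "haem_sd": 0.05},
}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic FOV.

    Defaults emulate a 20x liver-biopsy field: 512 x 512 px at 0.5 um/px
    (0.066 mm^2), about 1500 nuclei/mm^2 of parenchyma, one portal tract
    ringed by ductal cells.  ``severity`` (integer >= 0) jointly scales
    the three necroinflammatory drivers: CD45 density
    (+``sev_cd45``/unit), focus rate (+``sev_focus``/unit) and necrotic
    fraction (+``sev_necrosis``/unit).
    """

    geometry: FovGeometry = field(default_factory=lambda: FovGeometry(512, 512, 0.5))
    seed: int = 0
    stain_system: str = "ihc_dab"  # ihc_dab | he | sirius_red
    marker: str = "pck"  # which population carries DAB: pck | cd45

    hepatocyte_density: float = 1500.0  # nuclei per mm^2
    portal_tracts: int = 1
    portal_radius_um: float = 60.0
    hpc_fraction: float = 0.1  # fraction of parenchymal cells that are HPC
    cd45_density: float = 0.0  # single inflammatory cells per mm^2
    focus_rate: float = 0.0  # inflammatory foci per mm^2
    focus_size_range: tuple[int, int] = (5, 9)
    focus_radius_um: float = 18.0
    fat_vacuole_count: int = 0
    fat_diameter_um: tuple[float, float] = (15.0, 40.0)
    necrosis_patches: int = 1
    necrosis_fraction: float = 0.0
    collagen_fraction: float = 0.0
    tissue_fraction: float = 1.0

    severity: int = 0
    sev_cd45: float = 75.0
    sev_focus: float = 3.0
    sev_necrosis: float = 0.006

    # marker OD distributions (DAB annulus), per population
    dab_neg_mean: float = 0.10
    dab_hpc_mean: float = 0.60
    dab_ductal_mean: float = 0.70
    dab_cd45_mean: float = 0.65
    dab_sd: float = 0.05

    # rendering
    cytoplasm_haem_od: float = 0.15
    necrosis_haem_od: float = 0.02
    cytoplasm_eosin_od: float = 0.25
    necrosis_eosin_od: float = 0.30
    sirius_background_od: float = 0.08
    collagen_od: float = 0.70
    collagen_width_um: float = 15.0
    noise_od_sd: float = 0.02
    blur_sigma_px: float = 1.0

    # immunofluorescence (three channels: DAPI, green, red)
    if_fraction_green: float = 0.3
    if_fraction_red: float = 0.2
    if_fraction_double: float = 0.1
    if_pos_mean: float = 0.7
    if_pos_sd: float = 0.08
    if_neg_mean: float = 0.05
    if_neg_sd: float = 0.02
    dapi_mean: float = 0.8
    dapi_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "hepatocyte_density", "cd45_density", "focus_rate",
            "portal_radius_um", "focus_radius_um",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "hpc_fraction", "necrosis_fraction", "collagen_fraction",
            "tissue_fraction", "if_fraction_green", "if_fraction_red",
            "if_fraction_double",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.severity < 0 or int(self.severity) != self.severity:
            raise ValueError("severity must be a non-negative integer")
        total_if = self.if_fraction_green + self.if_fraction_red + self.if_fraction_double
        if total_if > 1.0 + 1e-12:
            raise ValueError("IF positivity fractions sum above 1")
        if self.marker not in ("pck", "cd45"):
            raise ValueError("marker must be 'pck' or 'cd45'")

    # severity-scaled effective drivers
    @property
    def cd45_density_eff(self) -> float:
        return self.cd45_density + self.sev_cd45 * self.severity

    @property
    def focus_rate_eff(self) -> float:
        return self.focus_rate + self.sev_focus * self.severity

    @property
    def necrosis_fraction_eff(self) -> float:
        return min(1.0, self.necrosis_fraction + self.sev_necrosis * self.severity)


@dataclass(frozen=True)
class SyntheticFovTruth:
    """Ground truth of one rendered FOV.

    ``cells``: one row per rendered cell (position, population, radius,
    painted ODs/intensities, marker status).  ``masks``: boolean region
    masks (tissue, portal, periportal, necrosis, fat, collagen).
    ``measures``: per-FOV true summary quantities, recomputable from the
    tables.
    """

    cells: pd.DataFrame
    masks: dict[str, np.ndarray]
    measures: dict[str, float]
    spec: SceneSpec


# ---------------------------------------------------------------------------
# placement helpers

_MAX_TRIES_PER_POINT = 300


class _HardCore:
    """Incremental hard-core dart board: centres with per-point radii."""

    def __init__(self) -> None:
        self.xy = np.empty((0, 2))
        self.r = np.empty(0)

    def fits(self, x: float, y: float, r: float, gap: float = 1.0) -> bool:
        if self.xy.shape[0] == 0:
            return True
        d2 = (self.xy[:, 0] - x) ** 2 + (self.xy[:, 1] - y) ** 2
        lim = (self.r + r + gap) ** 2
        return bool(np.all(d2 > lim))

    def add(self, x: float, y: float, r: float) -> None:
        self.xy = np.vstack([self.xy, [x, y]])
        self.r = np.append(self.r, r)


def _dart(
    rng: np.random.Generator,
    n: int,
    r_of: "callable",
    allowed_dist: np.ndarray,
    board: _HardCore,
    geometry: FovGeometry,
) -> list[tuple[float, float, float]]:
    """Throw n hard-core darts; ``allowed_dist[y, x]`` is the clearance
    (px) to forbidden regions and image border.  Raises
    :class:`GenerationError` when the retry budget is exhausted."""
    placed = []
    h, w = geometry.shape
    tries = 0
    budget = _MAX_TRIES_PER_POINT * max(n, 1)
    while len(placed) < n:
        if tries > budget:
            raise GenerationError(
                f"could not place {n} cells (packed {len(placed)}) within budget"
            )
        tries += 1
        x = rng.uniform(0, w)
        y = rng.uniform(0, h)
        r = r_of()
        if allowed_dist[int(y), int(x)] <= r + 1:
            continue
        if not board.fits(x, y, r):
            continue
        board.add(x, y, r)
        placed.append((x, y, r))
    return placed


def _clearance(forbidden: np.ndarray) -> np.ndarray:
    """Distance (px) to forbidden pixels and to the image border."""
    pad = np.pad(forbidden, 1, constant_values=True)
    return ndi.distance_transform_edt(~pad)[1:-1, 1:-1]


def _radius_px(rng: np.random.Generator, pop: str, geometry: FovGeometry) -> float:
    area = POPULATIONS[pop]["area_um2"]
    area = max(5.0, rng.normal(area, 0.1 * area))
    return geometry.um_to_px(np.sqrt(area / np.pi))


def _paint_disk(arr: np.ndarray, x: float, y: float, r: float, value: float) -> None:
    rr, cc = draw_disk((y, x), r, shape=arr.shape)
    arr[rr, cc] = value


def _paint_annulus(
    arr: np.ndarray, x: float, y: float, r_in: float, r_out: float, value: float
) -> None:
    rr, cc = draw_disk((y, x), r_out, shape=arr.shape)
    keep = (rr - y) ** 2 + (cc - x) ** 2 >= r_in**2
    rr, cc = rr[keep], cc[keep]
    arr[rr, cc] = np.maximum(arr[rr, cc], value)


def _blob_mask(
    rng: np.random.Generator,
    center: tuple[float, float],
    target_px: int,
    shape: tuple[int, int],
    clip: np.ndarray,
) -> np.ndarray:
    """Irregular, elongated blob of approximately target_px area.

    A chain of jittered disks along a meandering walk (confluent necrosis
    spreads along plates and zones rather than as a round drop), scaled in
    a second pass to hit the target area.  The elongation keeps the shape
    well below the circularity of a steatotic vacuole.
    """
    cx, cy = center
    n_steps = 10
    # a gently curving arc with jitter: elongated for every seed (a
    # straighter walk cannot fold back into a vacuole-like clump)
    curvature = rng.uniform(-0.18, 0.18)
    turns = curvature + rng.normal(0.0, 0.08, size=n_steps)
    theta0 = rng.uniform(0, 2 * np.pi)
    radii = rng.uniform(0.32, 0.45, size=n_steps)

    # walk in a unit frame, then recentre its bounding box on the target
    # centre so the blob stays in view and the area scaling is exact
    ox = np.zeros(n_steps)
    oy = np.zeros(n_steps)
    theta = theta0
    for k in range(1, n_steps):
        theta += turns[k - 1]
        ox[k] = ox[k - 1] + 0.5 * np.cos(theta)
        oy[k] = oy[k - 1] + 0.5 * np.sin(theta)
    ox -= (ox.min() + ox.max()) / 2
    oy -= (oy.min() + oy.max()) / 2

    h, w = shape

    def rasterise(scale: float) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        bx = float(np.clip(cx, (ox.max() + radii.max()) * scale + 1,
                           w - (ox.max() + radii.max()) * scale - 1))
        by = float(np.clip(cy, (oy.max() + radii.max()) * scale + 1,
                           h - (oy.max() + radii.max()) * scale - 1))
        for k in range(n_steps):
            _paint_disk_bool(m, bx + ox[k] * scale, by + oy[k] * scale,
                             radii[k] * scale)
        return m & clip

    # iterate the area scaling: clipping and recentring make a single
    # rescale inexact
    scale = np.sqrt(target_px / np.pi)
    m = rasterise(scale)
    for _ in range(6):
        a = m.sum()
        if a == 0 or abs(a - target_px) / target_px < 0.02:
            break
        scale *= np.sqrt(target_px / a)
        m = rasterise(scale)
    return m


def _paint_disk_bool(mask: np.ndarray, x: float, y: float, r: float) -> None:
    rr, cc = draw_disk((y, x), max(r, 1.0), shape=mask.shape)
    mask[rr, cc] = True


def _ribbon_mask(
    rng: np.random.Generator,
    target_px: int,
    width_px: float,
    shape: tuple[int, int],
    clip: np.ndarray,
) -> np.ndarray:
    """Collagen ribbons: thick random-walk curves painted until the
    target area is reached (bounded number of ribbons)."""
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    half = width_px / 2.0
    for _ in range(64):
        if mask.sum() >= target_px:
            break
        x = rng.uniform(0, w)
        y = rng.uniform(0, h)
        theta = rng.uniform(0, 2 * np.pi)
        for _ in range(int(2.5 * max(h, w) / 3)):
            _paint_disk_bool(mask, x, y, half)
            theta += rng.normal(0, 0.25)
            x += 3.0 * np.cos(theta)
            y += 3.0 * np.sin(theta)
            if not (0 <= x < w and 0 <= y < h):
                break
            if mask.sum() >= target_px:
                break
    return mask & clip


# ---------------------------------------------------------------------------
# brightfield generation

def generate_brightfield(spec: SceneSpec) -> tuple[np.ndarray, SyntheticFovTruth]:
    """Render a brightfield FOV (IHC, H&E or Sirius Red) with truth.

    Returns ``(rgb, truth)`` where ``rgb`` is an (H, W, 3) uint8 image.
    Truth (cell table, region masks, per-FOV measures) is recorded before
    rendering noise is applied.
    """
    if spec.stain_system not in ("ihc_dab", "he", "sirius_red"):
        raise ValueError(f"not a brightfield stain system: {spec.stain_system!r}")
    rng = np.random.default_rng(spec.seed)
    geom = spec.geometry
    h, w = geom.shape

    # --- regions -----------------------------------------------------------
    tissue = np.zeros((h, w), dtype=bool)
    tissue[:, : int(round(w * spec.tissue_fraction))] = True

    portal = np.zeros((h, w), dtype=bool)
    portal_centres: list[tuple[float, float]] = []
    r_portal = geom.um_to_px(spec.portal_radius_um)
    for _ in range(spec.portal_tracts):
        # tracts may be partially clipped by the FOV edge, as in real crops
        for _try in range(200):
            x = rng.uniform(0.3 * r_portal, w * spec.tissue_fraction - 0.3 * r_portal)
            y = rng.uniform(0.3 * r_portal, h - 0.3 * r_portal)
            if all((x - px) ** 2 + (y - py) ** 2 > (2.2 * r_portal) ** 2
                   for px, py in portal_centres):
                portal_centres.append((x, y))
                _paint_disk_bool(portal, x, y, r_portal)
                break
        else:
            raise GenerationError("could not place portal tracts")

    tissue_px = int(tissue.sum())
    necrosis = np.zeros((h, w), dtype=bool)
    frac_necro = spec.necrosis_fraction_eff
    if frac_necro > 0 and spec.necrosis_patches > 0:
        # confluent necrosis may involve portal areas; clipping only at
        # the tissue border keeps each patch a single elongated component
        clip = tissue
        target_each = int(round(frac_necro * tissue_px / spec.necrosis_patches))
        for _ in range(spec.necrosis_patches):
            cx = rng.uniform(0.15 * w, 0.85 * w * spec.tissue_fraction)
            cy = rng.uniform(0.15 * h, 0.85 * h)
            necrosis |= _blob_mask(rng, (cx, cy), target_each, (h, w), clip)

    fat = np.zeros((h, w), dtype=bool)
    fat_centres: list[tuple[float, float, float]] = []
    lo_d, hi_d = spec.fat_diameter_um
    # clearance to necrosis and portal tracts so components stay separate
    avoid_dist = _clearance(necrosis | portal)
    # large vacuoles first: easier hard-core packing
    diameters = np.sort(rng.uniform(lo_d, hi_d, size=spec.fat_vacuole_count))[::-1]
    gap_px = geom.um_to_px(8)
    for d_um in diameters:
        r = geom.um_to_px(d_um / 2.0)
        for _try in range(300):
            x = rng.uniform(r + 2, w * spec.tissue_fraction - r - 2)
            y = rng.uniform(r + 2, h - r - 2)
            clear = all(
                (x - fx) ** 2 + (y - fy) ** 2 > (r + fr + gap_px) ** 2
                for fx, fy, fr in fat_centres
            )
            if clear and avoid_dist[int(y), int(x)] > r + gap_px:
                fat_centres.append((x, y, r))
                _paint_disk_bool(fat, x, y, r)
                break
        else:
            raise GenerationError("could not place fat vacuoles")
    fat &= tissue & ~necrosis

    collagen = np.zeros((h, w), dtype=bool)
    if spec.collagen_fraction > 0:
        target = int(round(spec.collagen_fraction * tissue_px))
        collagen = _ribbon_mask(
            rng, target, geom.um_to_px(spec.collagen_width_um), (h, w), tissue
        )

    # --- cells -------------------------------------------------------------
    board = _HardCore()
    rows: list[dict] = []
    marker = spec.marker

    def dab_for(pop: str) -> float:
        positive = (
            (marker == "pck" and pop in ("hpc", "ductal"))
            or (marker == "cd45" and pop == "cd45")
        )
        if positive:
            mean = {
                "hpc": spec.dab_hpc_mean,
                "ductal": spec.dab_ductal_mean,
                "cd45": spec.dab_cd45_mean,
            }[pop]
        else:
            mean = spec.dab_neg_mean
        return max(0.0, rng.normal(mean, spec.dab_sd)), positive

    def record(x: float, y: float, r: float, pop: str) -> None:
        dab, positive = dab_for(pop)
        haem = max(
            0.05, rng.normal(POPULATIONS[pop]["haem"], POPULATIONS[pop]["haem_sd"])
        )
        rows.append(
            {
                "id": len(rows) + 1,
                "x": x,
                "y": y,
                "radius_px": r,
                "area_um2": np.pi * geom.px_to_um(r) ** 2,
                "population": pop,
                "haem_od": haem,
                "dab_od": dab,
                "marker_positive": positive,
                "cd45": pop == "cd45",
            }
        )

    # ductal rings around portal tracts
    if spec.portal_tracts > 0:
        r_duct = geom.um_to_px(np.sqrt(POPULATIONS["ductal"]["area_um2"] / np.pi))
        for px, py in portal_centres:
            ring_r = r_portal - r_duct - 2
            n_ring = max(1, int(np.floor(2 * np.pi * ring_r / (2.6 * r_duct))))
            offset = rng.uniform(0, 2 * np.pi)
            for k in range(n_ring):
                ang = offset + 2 * np.pi * k / n_ring
                x = px + ring_r * np.cos(ang)
                y = py + ring_r * np.sin(ang)
                if (
                    0 <= x < w and 0 <= y < h
                    and tissue[int(y), int(x)]
                    and not necrosis[int(y), int(x)]
                ):
                    board.add(x, y, r_duct)
                    record(x, y, r_duct, "ductal")

    # parenchymal cells (hepatocytes + scattered HPCs) outside portal tracts
    forbidden_par = ~tissue | necrosis | fat | portal
    clear_par = _clearance(forbidden_par)
    avail_mm2 = geom.px_area_to_mm2(int((~forbidden_par).sum()))
    n_par = int(round(spec.hepatocyte_density * avail_mm2))
    n_hpc = int(round(spec.hpc_fraction * n_par))
    n_hep = n_par - n_hpc
    for x, y, r in _dart(rng, n_hep, lambda: _radius_px(rng, "hepatocyte", geom),
                         clear_par, board, geom):
        record(x, y, r, "hepatocyte")
    for x, y, r in _dart(rng, n_hpc, lambda: _radius_px(rng, "hpc", geom),
                         clear_par, board, geom):
        record(x, y, r, "hpc")

    # inflammatory cells: singles anywhere in viable tissue, foci lobular
    forbidden_cd45 = ~tissue | necrosis | fat
    clear_cd45 = _clearance(forbidden_cd45)
    tissue_mm2 = geom.px_area_to_mm2(tissue_px)
    n_singles = int(round(spec.cd45_density_eff * tissue_mm2))
    for x, y, r in _dart(rng, n_singles, lambda: _radius_px(rng, "cd45", geom),
                         clear_cd45, board, geom):
        record(x, y, r, "cd45")

    n_foci = int(round(spec.focus_rate_eff * tissue_mm2))
    r_focus = geom.um_to_px(spec.focus_radius_um)
    forbidden_focus = forbidden_cd45 | portal
    clear_focus = _clearance(forbidden_focus)
    for _ in range(n_foci):
        centre = _dart(rng, 1, lambda: r_focus, clear_focus, _HardCore(), geom)
        cx, cy, _r = centre[0]
        size = int(rng.integers(spec.focus_size_range[0], spec.focus_size_range[1] + 1))
        placed = 0
        tries = 0
        while placed < size and tries < 500:
            tries += 1
            ang = rng.uniform(0, 2 * np.pi)
            rad = r_focus * np.sqrt(rng.uniform())
            x, y = cx + rad * np.cos(ang), cy + rad * np.sin(ang)
            if not (0 <= x < w and 0 <= y < h):
                continue
            r = _radius_px(rng, "cd45", geom)
            if clear_cd45[int(y), int(x)] <= r + 1 or not board.fits(x, y, r, gap=0.5):
                continue
            board.add(x, y, r)
            record(x, y, r, "cd45")
            placed += 1
        if placed < spec.focus_size_range[0]:
            raise GenerationError("could not pack an inflammatory focus")

    cells = pd.DataFrame(
        rows,
        columns=[
            "id", "x", "y", "radius_px", "area_um2", "population",
            "haem_od", "dab_od", "marker_positive", "cd45",
        ],
    )

    # --- painting ----------------------------------------------------------
    haem = np.zeros((h, w))
    haem[tissue] = spec.cytoplasm_haem_od
    haem[necrosis] = spec.necrosis_haem_od
    haem[fat] = 0.0
    maps: dict[str, np.ndarray] = {"haematoxylin": haem}
    if spec.stain_system == "ihc_dab":
        maps["dab"] = np.zeros((h, w))
    elif spec.stain_system == "he":
        eosin = np.zeros((h, w))
        eosin[tissue] = spec.cytoplasm_eosin_od
        eosin[necrosis] = spec.necrosis_eosin_od
        eosin[fat] = 0.0
        maps["eosin"] = eosin
    else:  # sirius_red
        sirius = np.zeros((h, w))
        sirius[tissue] = spec.sirius_background_od
        sirius[collagen] = spec.collagen_od
        sirius[fat] = 0.0
        maps["sirius_red"] = sirius

    for row in rows:
        _paint_disk(haem, row["x"], row["y"], row["radius_px"], row["haem_od"])
    if spec.stain_system == "ihc_dab" and rows:
        # cytoplasmic DAB: each cell's territory (nucleus + 6 px, clipped
        # at neighbours' territories) carries its own DAB OD, so adjacent
        # positive/negative cells do not contaminate each other
        from skimage.segmentation import expand_labels

        nuc_labels = np.zeros((h, w), dtype=np.int32)
        for row in rows:
            _paint_disk(nuc_labels, row["x"], row["y"], row["radius_px"], row["id"])
        territory = expand_labels(nuc_labels, distance=6.0)
        dab_lut = np.zeros(len(rows) + 1)
        for row in rows:
            dab_lut[row["id"]] = row["dab_od"]
        maps["dab"] = dab_lut[territory]

    matrix = default_stain_matrix(spec.stain_system)
    stack = []
    for name in matrix.names:
        m = ndi.gaussian_filter(maps[name], sigma=spec.blur_sigma_px)
        noise = rng.normal(0.0, spec.noise_od_sd, size=m.shape)
        m = np.where(tissue, np.maximum(m + noise, 0.0), m)
        stack.append(m)
    od = compose(np.stack(stack, axis=-1), matrix)
    rgb = od_to_rgb(od, 255.0)

    # --- truth masks & measures -------------------------------------------
    masks = {
        "tissue": tissue,
        "portal": portal,
        "necrosis": necrosis,
        "fat": fat,
        "collagen": collagen,
    }
    measures = _truth_measures(spec, cells, masks)
    return rgb, SyntheticFovTruth(cells=cells, masks=masks, measures=measures, spec=spec)


def _truth_measures(
    spec: SceneSpec, cells: pd.DataFrame, masks: dict[str, np.ndarray]
) -> dict[str, float]:
    geom = spec.geometry
    tissue = masks["tissue"]
    n_cells = len(cells)
    n_pos = int(cells["marker_positive"].sum()) if n_cells else 0
    measures = {
        "n_cells": float(n_cells),
        "n_marker_positive": float(n_pos),
        "percent_positive": 100.0 * n_pos / n_cells if n_cells else 0.0,
        "cd45_count": float(cells["cd45"].sum()) if n_cells else 0.0,
        "necrosis_fraction": area_fraction(masks["necrosis"], tissue),
        "fat_fraction": area_fraction(masks["fat"], tissue),
        "collagen_fraction": area_fraction(masks["collagen"], tissue),
        "tissue_fraction": float(tissue.mean()),
    }
    tissue_mm2 = geom.px_area_to_mm2(int(tissue.sum()))
    measures["cd45_density"] = (
        measures["cd45_count"] / tissue_mm2 if tissue_mm2 else 0.0
    )
    # surrogate necroinflammatory measures from the truth tables, using the
    # same definitions the scoring module applies to pipeline output
    truth_cells = cells.copy()
    truth_cells["phenotype_cd45"] = np.where(truth_cells["cd45"], "positive", "negative")
    truth_scores = surrogate_measures(
        truth_cells, masks, geom, RegionParams(band_width_um=25.0)
    )
    measures.update(
        {
            "piecemeal": truth_scores.piecemeal_measure,
            "confluent": truth_scores.confluent_measure,
            "lobular": truth_scores.lobular_measure,
            "portal": truth_scores.portal_measure,
        }
    )
    return measures


# ---------------------------------------------------------------------------
# immunofluorescence generation

def generate_if(spec: SceneSpec) -> tuple[np.ndarray, SyntheticFovTruth]:
    """Render a 3-channel IF FOV (DAPI, green, red) with truth.

    Cells are assigned one of four labels (green+, red+, double+,
    negative) by a multinomial draw with the spec's fractions; channel
    intensities come from the positive/negative population distributions
    and the truth table records the drawn label per cell.  Channels are
    float arrays in [0, 1], stacked (H, W, 3) as DAPI/green/red.
    """
    rng = np.random.default_rng(spec.seed)
    geom = spec.geometry
    h, w = geom.shape
    tissue = np.ones((h, w), dtype=bool)

    board = _HardCore()
    clear = _clearance(np.zeros((h, w), dtype=bool))
    n = int(round(spec.hepatocyte_density * geom.area_mm2))
    placed = _dart(rng, n, lambda: _radius_px(rng, "hepatocyte", geom),
                   clear, board, geom)

    probs = [
        spec.if_fraction_green, spec.if_fraction_red, spec.if_fraction_double,
        1.0 - spec.if_fraction_green - spec.if_fraction_red - spec.if_fraction_double,
    ]
    label_names = np.array(["green+", "red+", "double+", "negative"])
    draws = rng.choice(4, size=len(placed), p=probs)

    def channel_value(positive: bool) -> float:
        mean, sd = (
            (spec.if_pos_mean, spec.if_pos_sd)
            if positive
            else (spec.if_neg_mean, spec.if_neg_sd)
        )
        return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))

    dapi = np.zeros((h, w))
    green = np.zeros((h, w))
    red = np.zeros((h, w))
    rows = []
    for i, ((x, y, r), lab_idx) in enumerate(zip(placed, draws), start=1):
        lab = label_names[lab_idx]
        g_pos = lab in ("green+", "double+")
        r_pos = lab in ("red+", "double+")
        d_val = float(np.clip(rng.normal(spec.dapi_mean, spec.dapi_sd), 0.0, 1.0))
        g_val = channel_value(g_pos)
        r_val = channel_value(r_pos)
        _paint_disk(dapi, x, y, r, d_val)
        _paint_annulus(green, x, y, 0.0, r + 4.0, g_val)
        _paint_annulus(red, x, y, 0.0, r + 4.0, r_val)
        rows.append(
            {
                "id": i,
                "x": x,
                "y": y,
                "radius_px": r,
                "area_um2": np.pi * geom.px_to_um(r) ** 2,
                "if_label": lab,
                "green_int": g_val,
                "red_int": r_val,
                "green_positive": g_pos,
                "red_positive": r_pos,
            }
        )

    channels = []
    for m in (dapi, green, red):
        m = ndi.gaussian_filter(m, sigma=spec.blur_sigma_px)
        m = np.clip(m + rng.normal(0.0, spec.noise_od_sd, size=m.shape), 0.0, 1.0)
        channels.append(m)
    image = np.stack(channels, axis=-1)

    cells = pd.DataFrame(
        rows,
        columns=[
            "id", "x", "y", "radius_px", "area_um2", "if_label",
            "green_int", "red_int", "green_positive", "red_positive",
        ],
    )
    n_total = len(cells)
    counts = {lab: int((cells["if_label"] == lab).sum()) for lab in label_names}
    measures = {
        "n_cells": float(n_total),
        "n_green_only": float(counts["green+"]),
        "n_red_only": float(counts["red+"]),
        "n_double": float(counts["double+"]),
        "n_negative": float(counts["negative"]),
        "double_fraction": counts["double+"] / n_total if n_total else 0.0,
    }
    masks = {"tissue": tissue}
    return image, SyntheticFovTruth(cells=cells, masks=masks, measures=measures, spec=spec)


# ---------------------------------------------------------------------------
# severity ladder

def severity_ladder(
    base: SceneSpec, levels: int, seed: int | None = None
) -> list[SceneSpec]:
    """Specs with severity 0..levels-1, all else equal.

    Per-level seeds derive deterministically from ``seed`` (default: the
    base spec's seed), so the ladder is reproducible as a whole.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    root = base.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(root).generate_state(levels) % (2**31)
    return [
        dataclasses.replace(base, severity=s, seed=int(child_seeds[s]))
        for s in range(levels)
    ]


def replicate_specs(base: SceneSpec, n: int, seed: int | None = None) -> list[SceneSpec]:
    """n FOV specs identical to ``base`` except for derived seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    root = base.seed if seed is None else seed
    child_seeds = np.random.SeedSequence((root, 1)).generate_state(n) % (2**31)
    return [dataclasses.replace(base, seed=int(child_seeds[i])) for i in range(n)]
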