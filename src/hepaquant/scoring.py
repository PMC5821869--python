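"""Surrogate Ishak-Knodell necroinflammatory scoring.

The Ishak modification of Knodell's hepatic activity index (HAI) grades
necroinflammation in four categories — piecemeal (interface) necrosis,
confluent necrosis, lobular (focal) necrosis/inflammation and portal
inflammation — each on an ordinal scale, summed into a composite.  This
module computes continuous *surrogate measures* for the four categories
from a cell table and region masks, bins each to its ordinal with an
explicit, configurable :class:`BinningScheme`, and sums the ordinals:

* piecemeal — CD45+ cell density (cells/mm^2) inside the periportal
  (limiting-plate) band;
* confluent — necrotic area as a fraction of tissue area;
* lobular  — inflammatory-focus density (foci/mm^2) in lobular tissue;
* portal   — CD45+ cell density inside portal regions.

Default ordinal ranges follow the Ishak scheme (0-4, 0-6, 0-4, 0-4;
composite 0-18).  Default bin thresholds ship as package data
(``data/default_bins.yaml``), calibrated once against the synthetic
severity ladder — they are explicit configuration, not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .geometry import FovGeometry
from .regions import RegionParams, area_fraction, detect_foci, periportal_band

__all__ = [
    "CATEGORIES",
    "CATEGORY_MAX",
    "BinningScheme",
    "SurrogateScores",
    "surrogate_measures",
    "bin_scores",
    "score_sample",
    "default_binning_scheme",
    "lobular_mask",
]

CATEGORIES = ("piecemeal", "confluent", "lobular", "portal")
CATEGORY_MAX = {"piecemeal": 4, "confluent": 6, "lobular": 4, "portal": 4}


@dataclass(frozen=True)
class BinningScheme:
    """Ascending thresholds mapping each surrogate measure to an ordinal.

    For each category the ordinal is the number of thresholds *strictly*
    below the measure, so a measure exactly at a threshold falls in the
    lower bin (conservative scoring).  Threshold list length equals the
    category's maximum score.
    """

    thresholds: dict[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        norm = {}
        for cat in CATEGORIES:
            if cat not in self.thresholds:
                raise ValueError(f"binning scheme missing category {cat!r}")
            ts = tuple(float(t) for t in self.thresholds[cat])
            if len(ts) != CATEGORY_MAX[cat]:
                raise ValueError(
                    f"{cat}: expected {CATEGORY_MAX[cat]} thresholds, got {len(ts)}"
                )
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError(f"{cat}: thresholds must be strictly increasing")
            norm[cat] = ts
        object.__setattr__(self, "thresholds", norm)

    def bin(self, category: str, measure: float) -> int:
        return int(sum(measure > t for t in self.thresholds[category]))


@dataclass(frozen=True)
class SurrogateScores:
    """The four surrogate measures, their ordinal bins, and the composite."""

    piecemeal_measure: float
    confluent_measure: float
    lobular_measure: float
    portal_measure: float
    ordinal: dict[str, int] = field(default_factory=dict)
    composite: int = 0

    @property
    def measures(self) -> dict[str, float]:
        return {
            "piecemeal": self.piecemeal_measure,
            "confluent": self.confluent_measure,
            "lobular": self.lobular_measure,
            "portal": self.portal_measure,
        }

    def to_dict(self) -> dict:
        return {
            "measures": self.measures,
            "ordinal": dict(self.ordinal),
            "composite": self.composite,
        }


def default_binning_scheme() -> BinningScheme:
    """Load the shipped default thresholds (YAML package data)."""
    text = resources.files("hepaquant.data").joinpath("default_bins.yaml").read_text()
    payload = yaml.safe_load(text)
    return BinningScheme({k: tuple(v) for k, v in payload["thresholds"].items()})


def lobular_mask(
    tissue_mask: np.ndarray, portal_mask: np.ndarray, band_mask: np.ndarray
) -> np.ndarray:
    """Lobular processing region: tissue minus portal tracts and band."""
    return tissue_mask & ~portal_mask & ~band_mask


def _in_mask(mask: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xi = np.clip(np.round(x).astype(int), 0, mask.shape[1] - 1)
    yi = np.clip(np.round(y).astype(int), 0, mask.shape[0] - 1)
    return mask[yi, xi]


def surrogate_measures(
    cells: pd.DataFrame,
    masks: dict[str, np.ndarray],
    geometry: FovGeometry,
    params: RegionParams | None = None,
) -> SurrogateScores:
    """Compute the four surrogate measures for one FOV.

    ``cells`` must carry a ``phenotype_cd45`` column; ``masks`` must hold
    ``tissue``, ``necrosis`` and ``portal`` (the ``periportal`` band is
    derived from the portal mask when absent).  Densities are 0 when the
    corresponding processing region is empty.
    """
    params = params or RegionParams()
    if "phenotype_cd45" not in cells.columns:
        raise KeyError("cell table lacks 'phenotype_cd45' column")
    for key in ("tissue", "necrosis", "portal"):
        if key not in masks:
            raise KeyError(f"masks missing {key!r}")
    tissue = np.asarray(masks["tissue"], dtype=bool)
    necrosis = np.asarray(masks["necrosis"], dtype=bool)
    portal = np.asarray(masks["portal"], dtype=bool)
    if "periportal" in masks:
        band = np.asarray(masks["periportal"], dtype=bool)
    elif portal.any():
        band = periportal_band(portal, params.band_width_um, geometry, tissue)
    else:
        band = np.zeros_like(portal)
    lobular = lobular_mask(tissue, portal, band)

    cd45 = cells[cells["phenotype_cd45"] == "positive"]
    x = cd45["x"].to_numpy(dtype=float) if len(cd45) else np.empty(0)
    y = cd45["y"].to_numpy(dtype=float) if len(cd45) else np.empty(0)

    def density(mask: np.ndarray) -> float:
        area = geometry.px_area_to_mm2(int(mask.sum()))
        if area == 0:
            return 0.0
        if x.size == 0:
            return 0.0
        return float(_in_mask(mask, x, y).sum()) / area

    piecemeal = density(band)
    portal_measure = density(portal)
    confluent = area_fraction(necrosis, tissue)

    foci, _ = detect_foci(
        cd45, geometry, params.linking_distance_um, params.min_focus_size
    )
    lob_area = geometry.px_area_to_mm2(int(lobular.sum()))
    if lob_area == 0 or not foci:
        lobular_measure = 0.0
    else:
        fx = np.array([f.centroid[0] for f in foci])
        fy = np.array([f.centroid[1] for f in foci])
        lobular_measure = float(_in_mask(lobular, fx, fy).sum()) / lob_area

    return SurrogateScores(
        piecemeal_measure=piecemeal,
        confluent_measure=confluent,
        lobular_measure=lobular_measure,
        portal_measure=portal_measure,
    )


def bin_scores(
    scores: SurrogateScores | dict[str, float], scheme: BinningScheme
) -> SurrogateScores:
    """Bin the surrogate measures to ordinals and sum the composite.

    The composite is the exact integer sum of the four ordinals; binning
    is monotone (a larger measure never lowers an ordinal).
    """
    measures = scores.measures if isinstance(scores, SurrogateScores) else dict(scores)
    ordinal = {cat: scheme.bin(cat, measures[cat]) for cat in CATEGORIES}
    return SurrogateScores(
        piecemeal_measure=measures["piecemeal"],
        confluent_measure=measures["confluent"],
        lobular_measure=measures["lobular"],
        portal_measure=measures["portal"],
        ordinal=ordinal,
        composite=int(sum(ordinal.values())),
    )


def score_sample(
    fov_scores: list[SurrogateScores],
    scheme: BinningScheme,
    fov_areas_mm2: list[float] | None = None,
) -> SurrogateScores:
    """Aggregate per-FOV measures to a sample score.

    Measures are combined as area-weighted means across FOVs (a plain
    mean for equal-size FOVs), then binned as in :func:`bin_scores`.
    """
    if not fov_scores:
        raise ValueError("score_sample requires at least one FOV")
    if fov_areas_mm2 is None:
        weights = np.ones(len(fov_scores))
    else:
        if len(fov_areas_mm2) != len(fov_scores):
            raise ValueError("fov_areas_mm2 length must match fov_scores")
        weights = np.asarray(fov_areas_mm2, dtype=float)
        if np.any(weights <= 0):
            raise ValueError("FOV areas must be positive")
    weights = weights / weights.sum()
    agg = {
        cat: float(sum(w * s.measures[cat] for w, s in zip(weights, fov_scores)))
        for cat in CATEGORIES
    }
    return bin_scores(agg, scheme)
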