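"""Batch orchestration: per-FOV analysis and per-sample scoring.

``run_fov`` executes the full stain -> detect -> phenotype -> regions
chain on one TIFF field of view and writes a result bundle (cell CSV,
mask TIFFs, label TIFF, summary JSON); ``run_sample`` aggregates FOV
results into a sample-level surrogate necroinflammatory score.  Outputs
are written atomically and are byte-identical on re-run with the same
inputs — the open analogue of a semi-automated batch workflow in which
a stored algorithm is applied unattended to every extracted FOV.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import regions as reg
from .config import RunConfig
from .detect import measure_cells, segment_nuclei
from .geometry import FovGeometry
from .phenotype import (
    DuctalDiscriminant,
    classify_double_if,
    classify_fov_ductality,
    classify_marker,
)
from .scoring import SurrogateScores, score_sample, surrogate_measures
from .stain import default_stain_matrix, deconvolve, read_stain_matrix, rgb_to_od

__all__ = ["run_fov", "run_sample", "DataError", "read_fov_image"]

log = logging.getLogger("hepaquant")


class DataError(RuntimeError):
    """Unreadable or inconsistent input data."""


def read_fov_image(path, assay: str) -> np.ndarray:
    """Read a FOV TIFF: (H, W, 3) uint8 RGB or (H, W, 3) float IF stack."""
    path = Path(path)
    if not path.is_file():
        raise DataError(f"no such image: {path}")
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # tifffile raises various types
        raise DataError(f"could not read TIFF {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[0] == 3 and arr.shape[-1] != 3:
        arr = np.moveaxis(arr, 0, -1)  # page-per-channel layout
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise DataError(f"{path}: expected a 3-channel image, got shape {arr.shape}")
    if assay == "if" and arr.dtype.kind == "u":
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    return arr


def _read_mask(path, shape) -> np.ndarray:
    mask = tifffile.imread(str(path))
    if mask.shape != shape:
        raise DataError(f"annotation mask {path} shape {mask.shape} != image {shape}")
    return mask > 0


def _atomic_write(path: Path, data: bytes) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_bytes(data)
    os.replace(tmp, path)


def _write_json(path: Path, payload: dict) -> None:
    _atomic_write(path, (json.dumps(payload, indent=2, sort_keys=True) + "\n").encode())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_fov(
    config: RunConfig,
    image_path,
    out_dir=None,
    portal_mask_path=None,
    write_outputs: bool = True,
) -> dict:
    """Analyse one FOV and (optionally) write its result bundle.

    Returns a dict with the cell table (``cells``), region masks
    (``masks``), nucleus label image (``labels``), geometry and the
    summary payload (``summary``).  When a portal annotation mask is
    supplied and a CD45 rule is configured, the surrogate
    necroinflammatory measures are included.
    """
    image_path = Path(image_path)
    image = read_fov_image(image_path, config.assay)
    geometry = config.geometry_for(image.shape[:2])
    rp = config.regions

    if config.assay == "if":
        result = _analyse_if(config, image, geometry)
    else:
        result = _analyse_brightfield(config, image, geometry)
    cells, labels, masks, summary = (
        result["cells"], result["labels"], result["masks"], result["summary"],
    )

    if portal_mask_path is not None:
        masks["portal"] = _read_mask(portal_mask_path, geometry.shape)
    if "portal" in masks and masks["portal"].any():
        masks["periportal"] = reg.periportal_band(
            masks["portal"], rp.band_width_um, geometry, masks["tissue"]
        )
    if (
        "phenotype_cd45" in cells.columns
        and "necrosis" in masks
        and "portal" in masks
    ):
        scores = surrogate_measures(cells, masks, geometry, rp)
        summary["surrogate_measures"] = scores.measures
    summary["n_cells"] = int(len(cells))
    summary["fov"] = image_path.name
    summary["geometry"] = {
        "width": geometry.width,
        "height": geometry.height,
        "microns_per_pixel": geometry.microns_per_pixel,
    }

    bundle = {
        "cells": cells,
        "labels": labels,
        "masks": masks,
        "geometry": geometry,
        "summary": summary,
    }
    if write_outputs:
        out_dir = Path(out_dir if out_dir is not None else config.output_dir) / image_path.stem
        _write_bundle(bundle, out_dir)
    return bundle


def _analyse_brightfield(config: RunConfig, image: np.ndarray, geometry: FovGeometry) -> dict:
    rp = config.regions
    matrix = (
        read_stain_matrix(config.stain_matrix_path)
        if config.stain_matrix_path
        else default_stain_matrix(config.assay)
    )
    od_triple = rgb_to_od(image, 255.0)
    stain_maps = {im.stain_name: im for im in deconvolve(od_triple, matrix)}
    if "haematoxylin" not in stain_maps:
        raise DataError("stain system lacks a haematoxylin channel")

    labels, cells = segment_nuclei(
        stain_maps["haematoxylin"], geometry, config.segmentation
    )
    cells = measure_cells(labels, cells, stain_maps, geometry, prefix="od")

    summary: dict = {"phenotypes": {}}
    for rule in config.phenotype_rules:
        if rule.feature not in cells.columns:
            continue
        cells, pheno_summary = classify_marker(cells, rule)
        summary["phenotypes"][rule.marker] = pheno_summary

    tissue = reg.detect_tissue(od_triple, geometry, rp)
    masks: dict[str, np.ndarray] = {"tissue": tissue}
    fractions: dict[str, float] = {}
    candidate = reg.detect_low_haematoxylin(
        stain_maps["haematoxylin"], tissue, geometry, rp
    )
    fat, necrosis = reg.split_fat_vs_necrosis(candidate, geometry, rp)
    masks["fat"], masks["necrosis"] = fat, necrosis
    fractions["fat"] = reg.area_fraction(fat, tissue)
    fractions["necrosis"] = reg.area_fraction(necrosis, tissue)
    if "sirius_red" in stain_maps:
        collagen, frac = reg.detect_collagen(stain_maps["sirius_red"], tissue, geometry, rp)
        masks["collagen"] = collagen
        fractions["collagen"] = frac
    summary["area_fractions"] = fractions

    if "phenotype_cd45" in cells.columns:
        cd45 = cells[cells["phenotype_cd45"] == "positive"]
        foci, singles = reg.detect_foci(
            cd45, geometry, rp.linking_distance_um, rp.min_focus_size
        )
        summary["foci"] = {
            "n_foci": len(foci),
            "n_single_cells": len(singles),
            "focus_sizes": [f.cell_count for f in foci],
        }

    if config.ductal_model_path and "phenotype_pck" in cells.columns:
        model = DuctalDiscriminant.from_json(config.ductal_model_path)
        positive = cells[cells["phenotype_pck"] == "positive"]
        summary["fov_ductality"] = _jsonable(classify_fov_ductality(positive, model))

    return {"cells": cells, "labels": labels, "masks": masks, "summary": summary}


def _analyse_if(config: RunConfig, image: np.ndarray, geometry: FovGeometry) -> dict:
    channels = {"dapi": image[..., 0], "green": image[..., 1], "red": image[..., 2]}
    # exposure-invariant normalisation: each channel scaled by its 99.9th
    # percentile (floor 1 keeps already-normalised data unchanged)
    for name in ("green", "red"):
        p = np.percentile(channels[name], 99.9)
        if p > 1.0:
            channels[name] = channels[name] / p
    labels, cells = segment_nuclei(channels["dapi"], geometry, config.segmentation)
    cells = measure_cells(labels, cells, channels, geometry, prefix="int")

    summary: dict = {"phenotypes": {}}
    rules = {r.marker: r for r in config.phenotype_rules}
    if "green" in rules and "red" in rules and len(cells):
        cells, counts = classify_double_if(cells, rules["green"], rules["red"])
        summary["if_counts"] = counts
    masks = {"tissue": np.ones(geometry.shape, dtype=bool)}
    return {"cells": cells, "labels": labels, "masks": masks, "summary": summary}


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cells_path = out_dir / "cells.csv"
    bundle["cells"].to_csv(cells_path, index=False, float_format="%.6g")
    labels = bundle["labels"]
    tifffile.imwrite(out_dir / "labels.tif", labels.astype(np.uint16))
    manifest = ["cells.csv", "labels.tif"]
    for name, mask in bundle["masks"].items():
        fname = f"mask_{name}.tif"
        tifffile.imwrite(out_dir / fname, (mask.astype(np.uint8) * 255))
        manifest.append(fname)
    summary = dict(bundle["summary"])
    summary["manifest"] = sorted(manifest + ["summary.json"])
    _write_json(out_dir / "summary.json", _jsonable(summary))
    log.info("FOV %s: %d cells", summary.get("fov", "?"), summary.get("n_cells", 0))


def run_sample(
    config: RunConfig,
    image_paths: list,
    out_dir=None,
    portal_mask_paths: list | None = None,
    sample_name: str = "sample",
) -> dict:
    """Analyse a list of FOVs and aggregate a sample-level score.

    All FOVs must share one geometry.  Measures are area-weighted means
    across FOVs, binned with the configured scheme; the report (JSON +
    CSV) carries per-category measure, ordinal and the composite.
    """
    if not image_paths:
        raise DataError("run_sample requires at least one FOV")
    if portal_mask_paths is not None and len(portal_mask_paths) != len(image_paths):
        raise DataError("portal_mask_paths length must match image_paths")
    out_dir = Path(out_dir if out_dir is not None else config.output_dir)

    fov_scores: list[SurrogateScores] = []
    fov_areas: list[float] = []
    geometries = set()
    summaries = []
    for i, path in enumerate(image_paths):
        mask_path = portal_mask_paths[i] if portal_mask_paths else None
        bundle = run_fov(config, path, out_dir=out_dir, portal_mask_path=mask_path)
        geom = bundle["geometry"]
        geometries.add((geom.width, geom.height, geom.microns_per_pixel))
        if len(geometries) > 1:
            raise DataError("mixed FOV geometries within one sample")
        summaries.append(bundle["summary"])
        if "surrogate_measures" in bundle["summary"]:
            m = bundle["summary"]["surrogate_measures"]
            fov_scores.append(
                SurrogateScores(
                    piecemeal_measure=m["piecemeal"],
                    confluent_measure=m["confluent"],
                    lobular_measure=m["lobular"],
                    portal_measure=m["portal"],
                )
            )
            fov_areas.append(geom.area_mm2)

    report: dict = {
        "sample": sample_name,
        "n_fovs": len(image_paths),
        "fovs": [s.get("fov") for s in summaries],
    }
    if fov_scores:
        sample_scores = score_sample(fov_scores, config.binning, fov_areas)
        report["scores"] = sample_scores.to_dict()
    sample_dir = out_dir / sample_name
    sample_dir.mkdir(parents=True, exist_ok=True)
    _write_json(sample_dir / "sample_report.json", _jsonable(report))
    if fov_scores:
        rows = [
            {
                "category": cat,
                "measure": sample_scores.measures[cat],
                "ordinal": sample_scores.ordinal[cat],
            }
            for cat in sample_scores.measures
        ]
        pd.DataFrame(rows).to_csv(
            sample_dir / "sample_scores.csv", index=False, float_format="%.6g"
        )
    return report
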