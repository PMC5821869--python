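"""Ground-truth validation benchmarks.

Each function re-runs one of the package's validation designs end to end
on freshly generated synthetic FOVs and returns the resulting metrics:

* :func:`stain_roundtrip` — compose/deconvolve consistency of the stain
  model on random two-stain scenes.
* :func:`count_recovery` — marker-positive percentage vs truth across a
  15-FOV IHC batch spanning 0-60% positive fraction, plus nucleus
  detection precision/recall.
* :func:`if_double_label` — per-channel and double-positive counts vs
  truth across a 12-FOV double-immunofluorescence batch.
* :func:`ductal_discrimination` — single-cell and FOV-level separation
  of ductal from non-ductal marker-positive cells (16 portal-seeded vs
  16 central-seeded FOVs).
* :func:`region_detection` — necrosis/fat/collagen area recovery and an
  exact check of focus clustering against a brute-force linkage oracle.
* :func:`severity_scoring` — Spearman correlation between planted
  severity and the surrogate composite across an 11-sample ladder,
  repeated over seeded replicates.
* :func:`determinism_check` — bit-identity of repeated generation and
  byte-identity of repeated pipeline runs.

The designs mirror the validation layout of the semi-automated scoring
study the package reimplements, with synthetic ground truth standing in
for the human counter.
"""

from __future__ import annotations

import dataclasses
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import regions as reg
from .detect import measure_cells, segment_nuclei
from .geometry import FovGeometry
from .metrics import match_detections, precision_recall, r_squared
from .phenotype import (
    DuctalDiscriminant,
    MarkerClassifier,
    PhenotypeRule,
    classify_double_if,
    classify_fov_ductality,
    classify_marker,
)
from .scoring import (
    CATEGORIES,
    bin_scores,
    default_binning_scheme,
    score_sample,
    surrogate_measures,
)
from .stain import (
    StainMatrix,
    STAIN_VECTORS,
    compose,
    deconvolve,
    default_stain_matrix,
    rgb_to_od,
)
from .synth import SceneSpec, generate_brightfield, generate_if, replicate_specs, severity_ladder

__all__ = [
    "stain_roundtrip",
    "count_recovery",
    "if_double_label",
    "ductal_discrimination",
    "region_detection",
    "severity_scoring",
    "determinism_check",
    "analyse_scene",
]


def _seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def analyse_scene(spec: SceneSpec):
    """Generate one brightfield FOV and run detection + measurement.

    Returns ``(cells, truth, stain_maps, od_triple, labels)`` — the common
    front half of every brightfield benchmark.
    """
    rgb, truth = generate_brightfield(spec)
    geom = spec.geometry
    od = rgb_to_od(rgb)
    maps = {im.stain_name: im for im in deconvolve(od, default_stain_matrix(spec.stain_system))}
    labels, cells = segment_nuclei(maps["haematoxylin"], geom)
    cells = measure_cells(labels, cells, maps, geom)
    return cells, truth, maps, od, labels


def stain_roundtrip(seed: int, n_scenes: int = 10, size: int = 64) -> dict:
    """Compose random non-negative two-stain OD scenes and deconvolve.

    Reports the maximum per-pixel concentration error over all scenes
    (float pipeline, no quantisation).
    """
    rng = np.random.default_rng(seed)
    matrix = StainMatrix(
        (("haematoxylin", STAIN_VECTORS["haematoxylin"]), ("dab", STAIN_VECTORS["dab"]))
    )
    max_err = 0.0
    for _ in range(n_scenes):
        conc = rng.uniform(0.0, 2.0, size=(size, size, 2))
        od = compose(conc, matrix)
        rec = np.stack([m.values for m in deconvolve(od, matrix)], axis=-1)
        max_err = max(max_err, float(np.abs(rec - conc).max()))
    return {"max_concentration_error": max_err, "n_scenes": n_scenes}


def count_recovery(seed: int, n_fovs: int = 15, size: int = 512) -> dict:
    """Marker-positive percentage vs truth over an IHC FOV batch.

    FOVs span 0-60% planted positive fraction; one Otsu threshold is
    fitted on the pooled cells of the batch (the single trained
    algorithm applied to every FOV), then per-FOV percent-positive is
    compared with ground truth (squared Pearson correlation).  Also
    reports nucleus detection precision/recall (match = centroid within
    one mean nucleus radius).
    """
    base = SceneSpec(geometry=FovGeometry(size, size, 0.5), seed=seed)
    fractions = np.linspace(0.0, 0.6, n_fovs)
    fovs = []
    pooled = []
    for frac, spec in zip(fractions, replicate_specs(base, n_fovs, seed=seed)):
        spec = dataclasses.replace(spec, hpc_fraction=float(frac), portal_tracts=0)
        cells, truth, *_ = analyse_scene(spec)
        fovs.append((cells, truth))
        pooled.append(cells["od_cyt_dab"].to_numpy())
    clf = MarkerClassifier(mode="otsu").fit(np.concatenate(pooled))

    pipeline_pct, truth_pct, precs, recs = [], [], [], []
    for cells, truth in fovs:
        pos = clf.predict(cells["od_cyt_dab"].to_numpy())
        pipeline_pct.append(100.0 * pos.mean() if pos.size else 0.0)
        truth_pct.append(truth.measures["percent_positive"])
        radius = float(truth.cells["radius_px"].mean())
        p, r = precision_recall(
            truth.cells[["x", "y"]].to_numpy(), cells[["x", "y"]].to_numpy(), radius
        )
        precs.append(p)
        recs.append(r)
    return {
        "r2": r_squared(pipeline_pct, truth_pct),
        "precision": float(np.mean(precs)),
        "recall": float(np.mean(recs)),
        "min_precision": float(np.min(precs)),
        "min_recall": float(np.min(recs)),
        "n_fovs": n_fovs,
    }


def if_double_label(seed: int, n_fovs: int = 12, size: int = 512) -> dict:
    """Double-IF counting vs truth over a 12-FOV batch.

    Positivity fractions vary across FOVs; per-FOV green, red and
    double-positive counts are compared with the generator's truth.
    """
    base = SceneSpec(geometry=FovGeometry(size, size, 0.5), seed=seed)
    rows = []
    for i, spec in enumerate(replicate_specs(base, n_fovs, seed=seed)):
        spec = dataclasses.replace(
            spec,
            if_fraction_green=0.15 + 0.03 * i,
            if_fraction_red=0.35 - 0.02 * i,
            if_fraction_double=0.1,
        )
        image, truth = generate_if(spec)
        geom = spec.geometry
        channels = {"dapi": image[..., 0], "green": image[..., 1], "red": image[..., 2]}
        labels, cells = segment_nuclei(channels["dapi"], geom)
        cells = measure_cells(labels, cells, channels, geom, prefix="int")
        cells, counts = classify_double_if(
            cells,
            PhenotypeRule("green", "int_cyt_green", "otsu"),
            PhenotypeRule("red", "int_cyt_red", "otsu"),
        )
        rows.append((counts, truth.measures))
    green = r_squared(
        [c["green_only"] + c["double"] for c, _ in rows],
        [m["n_green_only"] + m["n_double"] for _, m in rows],
    )
    red = r_squared(
        [c["red_only"] + c["double"] for c, _ in rows],
        [m["n_red_only"] + m["n_double"] for _, m in rows],
    )
    double = r_squared(
        [c["double"] for c, _ in rows], [m["n_double"] for _, m in rows]
    )
    frac_err = max(
        abs(c["double"] / max(c["n_total"], 1) - m["double_fraction"])
        for c, m in rows
    )
    return {
        "green_r2": green,
        "red_r2": red,
        "double_r2": double,
        "max_double_fraction_error": float(frac_err),
        "n_fovs": n_fovs,
    }


def _cells_with_truth_labels(spec: SceneSpec) -> pd.DataFrame:
    """Measured cells of one FOV, annotated with their true population."""
    cells, truth, *_ = analyse_scene(spec)
    ti, di = match_detections(
        truth.cells[["x", "y"]].to_numpy(), cells[["x", "y"]].to_numpy(),
        float(truth.cells["radius_px"].mean()),
    )
    cells = cells.iloc[di].copy()
    cells["population"] = truth.cells["population"].to_numpy()[ti]
    return cells


def ductal_discrimination(
    seed: int, n_exemplars_per_class: int = 50, n_fovs_per_group: int = 16,
    size: int = 512,
) -> dict:
    """Train the ductal discriminant and classify portal vs central FOVs.

    Exemplars come from measured cells matched to truth labels (the
    programmatic analogue of cropping single cells for algorithm
    verification).  A held-out exemplar set from an independent scene
    gives single-cell accuracy; 16 portal-seeded and 16 central-seeded
    FOVs give the FOV-level score.
    """
    s_train, s_test, s_portal, s_central = _seeds(seed, 4)
    geom = FovGeometry(size, size, 0.5)

    def exemplars(scene_seed: int) -> pd.DataFrame:
        frames = []
        counts = {"ductal": 0, "hpc": 0}
        for spec in replicate_specs(
            SceneSpec(geometry=geom, seed=scene_seed, portal_tracts=2, hpc_fraction=0.15),
            6, seed=scene_seed,
        ):
            cells = _cells_with_truth_labels(spec)
            frames.append(cells[cells["population"].isin(["ductal", "hpc"])])
            counts = pd.concat(frames)["population"].value_counts().to_dict()
            if (counts.get("ductal", 0) >= n_exemplars_per_class
                    and counts.get("hpc", 0) >= n_exemplars_per_class):
                break
        pool = pd.concat(frames)
        d = pool[pool["population"] == "ductal"].head(n_exemplars_per_class).copy()
        h = pool[pool["population"] == "hpc"].head(n_exemplars_per_class).copy()
        d["ductal_label"] = "ductal"
        h["ductal_label"] = "non_ductal"
        return pd.concat([d, h], ignore_index=True)

    train = exemplars(s_train)
    model = DuctalDiscriminant().fit(train, train["ductal_label"].to_numpy())
    test = exemplars(s_test)
    cell_accuracy = float(
        (model.predict(test) == test["ductal_label"].to_numpy()).mean()
    )

    correct = 0
    portal_spec = SceneSpec(geometry=geom, seed=s_portal, portal_tracts=2, hpc_fraction=0.02)
    for spec in replicate_specs(portal_spec, n_fovs_per_group, seed=s_portal):
        cells = _cells_with_truth_labels(spec)
        pos = cells[cells["population"].isin(["ductal", "hpc"])]
        correct += classify_fov_ductality(pos, model)["label"] == "portal-like"
    central_spec = SceneSpec(geometry=geom, seed=s_central, portal_tracts=0, hpc_fraction=0.15)
    for spec in replicate_specs(central_spec, n_fovs_per_group, seed=s_central):
        cells = _cells_with_truth_labels(spec)
        pos = cells[cells["population"].isin(["ductal", "hpc"])]
        correct += classify_fov_ductality(pos, model)["label"] == "central-like"
    n_total = 2 * n_fovs_per_group
    return {
        "cell_accuracy": cell_accuracy,
        "n_exemplars": int(len(train)),
        "fov_correct": int(correct),
        "n_fovs": n_total,
        "fov_accuracy": correct / n_total,
    }


def _brute_force_foci(
    xy: np.ndarray, link_px: float, min_size: int
) -> list[tuple[int, ...]]:
    """O(n^2) union-find single-linkage oracle (independent of the
    KD-tree/graph path used by the package)."""
    n = xy.shape[0]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(xy[i] - xy[j])) <= link_px:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(
        tuple(sorted(g)) for g in groups.values() if len(g) >= min_size
    )


def region_detection(seed: int, size: int = 512) -> dict:
    """Necrosis / fat / collagen area recovery and focus-oracle check.

    A fatty-necrotic H&E scene (20 vacuoles + one confluent patch) and a
    Sirius Red scene (12% collagen) give relative area errors against
    planted truth; focus clustering on random CD45 point sets is compared
    exactly with a brute-force single-linkage oracle.
    """
    geom = FovGeometry(size, size, 0.5)
    s_he, s_sr, s_foci = _seeds(seed, 3)

    spec = SceneSpec(
        geometry=geom, seed=s_he, stain_system="he", portal_tracts=0,
        hpc_fraction=0.0, fat_vacuole_count=20, necrosis_fraction=0.04,
    )
    rgb, truth = generate_brightfield(spec)
    od = rgb_to_od(rgb)
    maps = {im.stain_name: im for im in deconvolve(od, default_stain_matrix("he"))}
    tissue = reg.detect_tissue(od, geom)
    cand = reg.detect_low_haematoxylin(maps["haematoxylin"], tissue, geom)
    fat, nec = reg.split_fat_vs_necrosis(cand, geom)
    nec_err = abs(
        reg.area_fraction(nec, tissue) / truth.measures["necrosis_fraction"] - 1
    )
    fat_err = abs(reg.area_fraction(fat, tissue) / truth.measures["fat_fraction"] - 1)

    spec_sr = SceneSpec(
        geometry=geom, seed=s_sr, stain_system="sirius_red", portal_tracts=0,
        hpc_fraction=0.0, collagen_fraction=0.12,
    )
    rgb_sr, truth_sr = generate_brightfield(spec_sr)
    od_sr = rgb_to_od(rgb_sr)
    maps_sr = {
        im.stain_name: im for im in deconvolve(od_sr, default_stain_matrix("sirius_red"))
    }
    tissue_sr = reg.detect_tissue(od_sr, geom)
    _, col_frac = reg.detect_collagen(maps_sr["sirius_red"], tissue_sr, geom)
    col_err = abs(col_frac / truth_sr.measures["collagen_fraction"] - 1)

    # focus detection vs brute-force oracle on random point sets
    rng = np.random.default_rng(s_foci)
    oracle_match = True
    for _ in range(10):
        n = int(rng.integers(20, 200))
        xy = rng.uniform(0, size, size=(n, 2))
        cells = pd.DataFrame({"id": np.arange(1, n + 1), "x": xy[:, 0], "y": xy[:, 1]})
        foci, _singles = reg.detect_foci(cells, geom, 30.0, 5)
        got = sorted(tuple(i - 1 for i in f.member_cell_ids) for f in foci)
        expected = _brute_force_foci(xy, geom.um_to_px(30.0), 5)
        oracle_match &= got == expected
    return {
        "necrosis_rel_error": float(nec_err),
        "fat_rel_error": float(fat_err),
        "collagen_rel_error": float(col_err),
        "focus_oracle_match": bool(oracle_match),
    }


def severity_scoring(
    seed: int, n_samples: int = 11, n_replicates: int = 20,
    fovs_per_sample: int = 2, size: int = 512,
) -> dict:
    """Severity ladder -> surrogate composite, over seeded replicates.

    Each replicate builds an 11-sample ladder (severity 0..10 jointly
    scaling CD45 density, focus rate and necrotic fraction), runs the
    full pipeline on every FOV using the generator's portal annotations,
    aggregates per-sample composites and computes Spearman's rho against
    planted severity.  Also verifies the composite identity and ordinal
    monotonicity on the binned results.
    """
    scheme = default_binning_scheme()
    rhos = []
    composite_identity = True
    ordinal_monotone = True
    rule = PhenotypeRule("cd45", "od_cyt_dab", "otsu")
    for rep_seed in _seeds(seed, n_replicates):
        base = SceneSpec(
            geometry=FovGeometry(size, size, 0.5), seed=rep_seed,
            marker="cd45", hpc_fraction=0.0, cd45_density=25.0, focus_rate=2.0,
        )
        sevs, comps = [], []
        per_sample_scores = []
        for spec in severity_ladder(base, n_samples, seed=rep_seed):
            fov_scores, areas = [], []
            for fspec in replicate_specs(spec, fovs_per_sample):
                cells, truth, maps, od, _labels = analyse_scene(fspec)
                cells, _ = classify_marker(cells, rule)
                tissue = reg.detect_tissue(od, fspec.geometry)
                cand = reg.detect_low_haematoxylin(
                    maps["haematoxylin"], tissue, fspec.geometry
                )
                _fat, nec = reg.split_fat_vs_necrosis(cand, fspec.geometry)
                masks = {"tissue": tissue, "necrosis": nec, "portal": truth.masks["portal"]}
                fov_scores.append(surrogate_measures(cells, masks, fspec.geometry))
                areas.append(fspec.geometry.area_mm2)
            scores = score_sample(fov_scores, scheme, areas)
            composite_identity &= scores.composite == sum(scores.ordinal.values())
            sevs.append(spec.severity)
            comps.append(scores.composite)
            per_sample_scores.append(scores)
        rhos.append(float(spearmanr(sevs, comps).statistic))
        # binning monotonicity: re-bin sorted measures, ordinals must follow
        for cat in CATEGORIES:
            ms = sorted(s.measures[cat] for s in per_sample_scores)
            ords = [bin_scores(dict.fromkeys(CATEGORIES, 0.0) | {cat: m}, scheme).ordinal[cat]
                    for m in ms]
            ordinal_monotone &= all(a <= b for a, b in zip(ords, ords[1:]))
    return {
        "spearman_mean": float(np.mean(rhos)),
        "spearman_min": float(np.min(rhos)),
        "n_replicates": n_replicates,
        "composite_identity": bool(composite_identity),
        "ordinal_monotone": bool(ordinal_monotone),
    }


def determinism_check(seed: int, size: int = 256) -> dict:
    """Bit-identity of regeneration and byte-identity of pipeline re-runs."""
    import tifffile

    from .config import RunConfig
    from .pipeline import run_fov

    spec = SceneSpec(
        geometry=FovGeometry(size, size, 0.5), seed=seed,
        marker="cd45", cd45_density=150.0, hpc_fraction=0.0, necrosis_fraction=0.02,
    )
    rgb1, truth1 = generate_brightfield(spec)
    rgb2, truth2 = generate_brightfield(spec)
    images_identical = bool(np.array_equal(rgb1, rgb2))
    truth_identical = truth1.cells.equals(truth2.cells)

    config = RunConfig(
        assay="ihc_dab",
        phenotype_rules=(PhenotypeRule("cd45", "od_cyt_dab", "otsu"),),
        seed=seed,
    )
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        img_path = tmp / "fov.tif"
        tifffile.imwrite(img_path, rgb1)
        run_fov(config, img_path, out_dir=tmp / "a")
        run_fov(config, img_path, out_dir=tmp / "b")
        s_a = (tmp / "a" / "fov" / "summary.json").read_bytes()
        s_b = (tmp / "b" / "fov" / "summary.json").read_bytes()
        rerun_identical = s_a == s_b
        # re-running into the same directory must also reproduce bytes
        run_fov(config, img_path, out_dir=tmp / "a")
        rerun_identical &= (tmp / "a" / "fov" / "summary.json").read_bytes() == s_a
    return {
        "images_identical": images_identical,
        "truth_identical": bool(truth_identical),
        "rerun_identical": bool(rerun_identical),
        "all_deterministic": bool(images_identical and truth_identical and rerun_identical),
    }
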