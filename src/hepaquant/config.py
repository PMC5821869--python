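"""Run configuration: a single human-readable YAML file with strict keys.

A :class:`RunConfig` captures everything a batch run needs — assay type,
stain system, pixel calibration, segmentation and region parameters,
phenotype rules, an optional trained ductal model, the ordinal binning
scheme and the output directory.  Unknown keys are rejected so typos fail
loudly; referenced files are checked at validation time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import FovGeometry, MPP_MAX, MPP_MIN
from .phenotype import PhenotypeRule
from .regions import RegionParams
from .detect import SegmentationParams
from .scoring import BinningScheme, default_binning_scheme

__all__ = ["RunConfig", "ConfigError", "load_config"]

ASSAYS = ("ihc_dab", "he", "sirius_red", "if")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass(frozen=True)
class RunConfig:
    assay: str = "ihc_dab"
    microns_per_pixel: float = 0.5
    stain_matrix_path: str | None = None
    seed: int = 0
    output_dir: str = "results"
    log_level: str = "INFO"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    phenotype_rules: tuple[PhenotypeRule, ...] = ()
    ductal_model_path: str | None = None
    regions: RegionParams = field(default_factory=RegionParams)
    binning: BinningScheme = field(default_factory=default_binning_scheme)

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ConfigError(f"unknown assay {self.assay!r}; choose from {ASSAYS}")
        if not (MPP_MIN < self.microns_per_pixel < MPP_MAX):
            raise ConfigError(
                f"microns_per_pixel={self.microns_per_pixel} outside ({MPP_MIN}, {MPP_MAX})"
            )
        for attr in ("stain_matrix_path", "ductal_model_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).is_file():
                raise ConfigError(f"{attr}: no such file: {p}")

    def geometry_for(self, shape: tuple[int, int]) -> FovGeometry:
        return FovGeometry(
            width=shape[1], height=shape[0], microns_per_pixel=self.microns_per_pixel
        )


_TOP_KEYS = {
    "assay", "microns_per_pixel", "stain_matrix", "seed", "output_dir",
    "log_level", "segmentation", "phenotype", "ductal_model", "regions",
    "binning",
}
_RULE_KEYS = {"marker", "feature", "mode", "threshold"}


def _check_keys(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(f"{context}: unknown keys {unknown}")


def _sub_params(cls, payload: dict | None, context: str):
    payload = payload or {}
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(payload, fields, context)
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"no such config file: {path}")
    payload = yaml.safe_load(path.read_text()) or {}
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    _check_keys(payload, _TOP_KEYS, str(path))

    rules = []
    for i, rule in enumerate(payload.get("phenotype") or []):
        _check_keys(rule, _RULE_KEYS, f"{path}: phenotype[{i}]")
        try:
            rules.append(PhenotypeRule(**rule))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: phenotype[{i}]: {exc}") from exc

    binning = default_binning_scheme()
    bin_payload = payload.get("binning")
    if bin_payload is not None:
        if isinstance(bin_payload, str):
            bin_path = Path(bin_payload)
            if not bin_path.is_file():
                raise ConfigError(f"binning: no such file: {bin_path}")
            bin_payload = yaml.safe_load(bin_path.read_text())
        if not isinstance(bin_payload, dict) or "thresholds" not in bin_payload:
            raise ConfigError("binning: expected a mapping with a 'thresholds' block")
        try:
            binning = BinningScheme(
                {k: tuple(v) for k, v in bin_payload["thresholds"].items()}
            )
        except ValueError as exc:
            raise ConfigError(f"binning: {exc}") from exc

    try:
        return RunConfig(
            assay=payload.get("assay", "ihc_dab"),
            microns_per_pixel=float(payload.get("microns_per_pixel", 0.5)),
            stain_matrix_path=payload.get("stain_matrix"),
            seed=int(payload.get("seed", 0)),
            output_dir=str(payload.get("output_dir", "results")),
            log_level=str(payload.get("log_level", "INFO")),
            segmentation=_sub_params(
                SegmentationParams, payload.get("segmentation"), f"{path}: segmentation"
            ),
            phenotype_rules=tuple(rules),
            ductal_model_path=payload.get("ductal_model"),
            regions=_sub_params(RegionParams, payload.get("regions"), f"{path}: regions"),
            binning=binning,
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc
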