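"""Beer-Lambert optical density and linear colour deconvolution.

Brightfield histology quantification keys on per-stain optical density
(OD): the transmitted intensity ``I`` of a pixel relates to the amount of
absorbing stain by ``OD = -log10(I / I0)`` with ``I0`` the blank-glass
(background) intensity.  ODs of co-localised stains add, so an RGB pixel's
OD vector is (approximately) a non-negative linear combination of per-stain
unit absorption vectors.  Deconvolution inverts that mixture to recover a
concentration map per stain (Ruifrok & Johnston's scheme).

The module provides the forward transform (:func:`rgb_to_od`), its inverse
(:func:`od_to_rgb`), stain systems (:class:`StainMatrix`) and the
(de)composition between OD triples and per-stain concentration maps
(:func:`deconvolve`, :func:`compose`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OdImage",
    "StainMatrix",
    "DegenerateStainMatrixError",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "compose",
    "default_stain_matrix",
    "read_stain_matrix",
    "STAIN_VECTORS",
]

#: Published unit absorption vectors (Ruifrok-Johnston) for the common
#: brightfield stains, plus a Sirius Red vector estimated from synthetic
#: pure-stain swatches (a red stain absorbs green and blue, transmits red).
#: All are normalised to unit Euclidean norm on construction.
STAIN_VECTORS: dict[str, tuple[float, float, float]] = {
    "haematoxylin": (0.650, 0.704, 0.286),
    "dab": (0.268, 0.570, 0.776),
    "eosin": (0.072, 0.990, 0.105),
    "sirius_red": (0.140, 0.770, 0.620),
}

#: Named stain systems for the assay types handled by the pipeline.
STAIN_SYSTEMS: dict[str, tuple[str, ...]] = {
    "ihc_dab": ("haematoxylin", "dab"),
    "he": ("haematoxylin", "eosin"),
    "sirius_red": ("sirius_red", "haematoxylin"),
}

_COND_LIMIT = 1e6


class DegenerateStainMatrixError(ValueError):
    """Raised when stain vectors are (near-)linearly dependent."""


@dataclass(frozen=True)
class OdImage:
    """A per-stain (or per-channel) optical-density map.

    ``values`` is a 2-D array of non-negative, finite, dimensionless OD
    values with the spatial shape of the source image.
    """

    values: np.ndarray
    stain_name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("OdImage values must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("OdImage values must be finite")
        if v.min() < 0:
            raise ValueError("OdImage values must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class StainMatrix:
    """An ordered stain system: per-stain unit OD absorption vectors.

    Holds 1-3 linearly independent unit 3-vectors, one per stain.  Rows of
    :attr:`matrix` are stains, columns RGB channels.
    """

    stains: tuple[tuple[str, tuple[float, float, float]], ...]
    matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not 1 <= len(self.stains) <= 3:
            raise ValueError("StainMatrix requires 1-3 stains")
        rows = []
        norm_stains = []
        for name, vec in self.stains:
            v = np.asarray(vec, dtype=float)
            if v.shape != (3,) or np.any(v < 0) or not np.all(np.isfinite(v)):
                raise ValueError(f"stain {name!r}: vector must be 3 non-negative reals")
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError(f"stain {name!r}: zero vector")
            v = v / n
            rows.append(v)
            norm_stains.append((name, tuple(v)))
        m = np.vstack(rows)
        if np.linalg.matrix_rank(m, tol=1e-9) < len(rows):
            raise DegenerateStainMatrixError("stain vectors are linearly dependent")
        if len(rows) > 1 and np.linalg.cond(m @ m.T) > _COND_LIMIT:
            raise DegenerateStainMatrixError(
                "stain system is near-singular (condition number > 1e6)"
            )
        object.__setattr__(self, "stains", tuple(norm_stains))
        object.__setattr__(self, "matrix", m)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.stains)

    def __contains__(self, name: str) -> bool:
        return name in self.names


def default_stain_matrix(system: str = "ihc_dab") -> StainMatrix:
    """Return the shipped stain system for an assay type.

    ``system`` is one of ``ihc_dab`` (haematoxylin + DAB), ``he``
    (haematoxylin + eosin) or ``sirius_red`` (Sirius Red + haematoxylin
    counterstain).
    """
    try:
        names = STAIN_SYSTEMS[system]
    except KeyError:
        raise ValueError(
            f"unknown stain system {system!r}; choose from {sorted(STAIN_SYSTEMS)}"
        ) from None
    return StainMatrix(tuple((n, STAIN_VECTORS[n]) for n in names))


def read_stain_matrix(path) -> StainMatrix:
    """Read a stain matrix from a plain-text config.

    One stain per line: ``name r g b`` (whitespace separated); blank lines
    and ``#`` comments ignored.  Vectors are normalised on load.
    """
    stains = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'name r g b'")
            name = parts[0]
            try:
                vec = tuple(float(p) for p in parts[1:])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric stain vector") from None
            stains.append((name, vec))
    return StainMatrix(tuple(stains))


def rgb_to_od(
    image: np.ndarray, background_intensity: float = 255.0
) -> tuple[OdImage, OdImage, OdImage]:
    """Convert an RGB image to per-channel optical density.

    ``od = -log10(max(I, eps) / I0)`` per channel, with ``eps = I0 / 255``
    so saturated-dark pixels map to a finite OD (about 2.4) rather than
    infinity.  Background (``I = I0``) maps to OD 0 exactly.
    """
    if background_intensity <= 0:
        raise ValueError("background_intensity must be positive")
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    eps = background_intensity / 255.0
    od = -np.log10(np.maximum(img, eps) / background_intensity)
    od = np.maximum(od, 0.0)
    return tuple(OdImage(od[..., c], stain_name=ch) for c, ch in enumerate("RGB"))


def od_to_rgb(
    od_triple, background_intensity: float = 255.0, dtype=np.uint8
) -> np.ndarray:
    """Invert :func:`rgb_to_od`: ``I = I0 * 10**(-od)``, clipped to [0, I0].

    Accepts a triple of :class:`OdImage` / 2-D arrays or an (H, W, 3) OD
    array.  ``dtype=None`` returns the float image without quantisation.
    """
    if background_intensity <= 0:
        raise ValueError("background_intensity must be positive")
    od = _stack_od(od_triple, n=3)
    if od.min() < 0:
        raise ValueError("OD values must be non-negative")
    rgb = background_intensity * np.power(10.0, -od)
    rgb = np.clip(rgb, 0.0, background_intensity)
    if dtype is None:
        return rgb
    return np.round(rgb).astype(dtype)


def _stack_od(od_images, n: int | None = None) -> np.ndarray:
    """Stack OdImages/arrays into an (H, W, k) float array."""
    if isinstance(od_images, np.ndarray) and od_images.ndim == 3:
        arr = np.asarray(od_images, dtype=float)
    else:
        planes = [
            im.values if isinstance(im, OdImage) else np.asarray(im, dtype=float)
            for im in od_images
        ]
        arr = np.stack(planes, axis=-1)
    if not np.all(np.isfinite(arr)):
        raise ValueError("OD values must be finite")
    if n is not None and arr.shape[-1] != n:
        raise ValueError(f"expected {n} OD planes, got {arr.shape[-1]}")
    return arr


def deconvolve(od_triple, matrix: StainMatrix) -> list[OdImage]:
    """Unmix a 3-channel OD image into per-stain concentration maps.

    Per pixel, solves ``od = M.T @ c`` for the concentration vector ``c``
    by least squares (pseudo-inverse of the stacked stain matrix); negative
    solutions are clipped to zero.  Returns one :class:`OdImage` per stain,
    in the matrix's stain order.
    """
    od = _stack_od(od_triple, n=3)
    m = matrix.matrix  # (k, 3)
    pinv = np.linalg.pinv(m.T)  # (k, 3)
    conc = od @ pinv.T  # (H, W, k)
    conc = np.maximum(conc, 0.0)
    return [
        OdImage(conc[..., i], stain_name=name) for i, name in enumerate(matrix.names)
    ]


def compose(concentrations, matrix: StainMatrix) -> np.ndarray:
    """Mix per-stain concentration maps into an (H, W, 3) OD image.

    The adjoint of :func:`deconvolve`: ``od = M.T @ c`` per pixel.  For
    non-negative inputs ``deconvolve(compose(c)) == c`` up to float error.
    """
    conc = _stack_od(concentrations, n=len(matrix.names))
    if conc.min() < 0:
        raise ValueError("stain concentrations must be non-negative")
    return conc @ matrix.matrix
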