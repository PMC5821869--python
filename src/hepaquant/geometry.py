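"""Field-of-view geometry: pixel grid plus physical calibration.

All spatial quantities in the package are convertible between pixels and
microns through a :class:`FovGeometry`.  The valid ``microns_per_pixel``
range corresponds to 20x slide scanners (roughly 0.25-1 um/px plus margin).
"""

from __future__ import annotations

from dataclasses import dataclass

MPP_MIN = 0.1
MPP_MAX = 2.0


@dataclass(frozen=True)
class FovGeometry:
    """Geometry of one field of view.

    Parameters
    ----------
    width, height : int
        Image size in pixels (x rightward, y downward, 0-based, pixel-centre
        convention).
    microns_per_pixel : float
        Physical pixel pitch.  Must lie in the open interval (0.1, 2.0),
        the plausible range for a 20x scan.
    """

    width: int
    height: int
    microns_per_pixel: float = 0.5

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("FOV dimensions must be positive")
        if not (MPP_MIN < self.microns_per_pixel < MPP_MAX):
            raise ValueError(
                f"microns_per_pixel={self.microns_per_pixel} outside the "
                f"20x scanner range ({MPP_MIN}, {MPP_MAX})"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) array shape."""
        return (self.height, self.width)

    @property
    def um2_per_px(self) -> float:
        return self.microns_per_pixel**2

    @property
    def area_mm2(self) -> float:
        return self.width * self.height * self.um2_per_px / 1e6

    def um_to_px(self, microns: float) -> float:
        return microns / self.microns_per_pixel

    def px_to_um(self, pixels: float) -> float:
        return pixels * self.microns_per_pixel

    def px_area_to_mm2(self, n_pixels: float) -> float:
        return n_pixels * self.um2_per_px / 1e6
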