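"""Screen geometry and pixel/degree conversions.

All gaze coordinates are screen pixels with the origin at the top-left
corner and y increasing downward. Visual angles use a flat-screen
small-angle mapping evaluated at the screen centre: a pixel subtends
``atan(px_size_cm / viewing_distance_cm)`` degrees, so conversions are
linear in pixel distance. This is accurate to well under 1% within the
central ~20 deg that free-viewing fixations occupy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display layout and viewing distance.

    Parameters
    ----------
    width_px, height_px
        Display resolution in pixels.
    width_cm, height_cm
        Physical panel size in centimetres.
    viewing_distance_cm
        Eye-to-screen distance in centimetres.
    """

    width_px: int
    height_px: int
    width_cm: float
    height_cm: float
    viewing_distance_cm: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm",
                     "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def px_per_cm(self) -> float:
        # horizontal and vertical pitch averaged; panels are square-pixel
        return 0.5 * (self.width_px / self.width_cm
                      + self.height_px / self.height_cm)

    @property
    def px_per_deg(self) -> float:
        """Pixels per degree of visual angle at the screen centre."""
        cm_per_deg = self.viewing_distance_cm * math.tan(math.radians(1.0))
        return self.px_per_cm * cm_per_deg

    def px_to_deg(self, px: float) -> float:
        return px / self.px_per_deg

    def deg_to_px(self, deg: float) -> float:
        return deg * self.px_per_deg


#: Geometry of the study-style setup: 24" 1920x1080 panel viewed at 70 cm.
DEFAULT_GEOMETRY = ScreenGeometry(
    width_px=1920, height_px=1080,
    width_cm=53.1, height_cm=29.9,
    viewing_distance_cm=70.0,
)
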