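"""Field-of-view geometry shared by every stage of the pipeline.

All physical coordinates are in micrometres; the pixel grid uses the
image-processing convention: origin at the centre of the top-left pixel,
x rightward, y downward, 0-based indices.  The default pixel size of
0.078 um/pixel corresponds to a 100x objective with an intensified CCD
camera at 78 nm/pixel magnification.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

DEFAULT_PIXEL_SIZE = 0.078  # um/pixel (78 nm/pixel camera magnification)
DEFAULT_FRAME_INTERVAL = 0.05  # s (20 frames/s video rate)
DEFAULT_SAMPLING_DISTANCE = 0.625  # um (8 pixels at 78 nm/pixel)


@dataclass(frozen=True)
class FieldSpec:
    """A bounded rectangular 2-D field of view.

    Parameters
    ----------
    width, height : float
        Physical extent in micrometres.
    pixel_size : float
        Sampling of the camera, um/pixel.
    seed : int
        Root seed for any stochastic generator that draws into this field.
        Identical seed and parameters give bit-identical output.
    """

    width: float
    height: float
    pixel_size: float = DEFAULT_PIXEL_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("field width and height must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def area(self) -> float:
        """Field area in um^2."""
        return self.width * self.height

    @property
    def shape(self) -> tuple[int, int]:
        """Pixel-grid shape (rows, cols) covering the field."""
        return (
            max(1, int(round(self.height / self.pixel_size))),
            max(1, int(round(self.width / self.pixel_size))),
        )

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Deterministic generator; ``stream`` separates independent draws."""
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of points (N, 2) inside the field."""
        xy = np.asanyarray(xy, dtype=float)
        return (
            (xy[..., 0] >= 0.0)
            & (xy[..., 0] <= self.width)
            & (xy[..., 1] >= 0.0)
            & (xy[..., 1] <= self.height)
        )

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "pixel_size": self.pixel_size,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FieldSpec":
        return cls(**{k: d[k] for k in ("width", "height", "pixel_size", "seed") if k in d})


__all__ = [
    "FieldSpec",
    "DEFAULT_PIXEL_SIZE",
    "DEFAULT_FRAME_INTERVAL",
    "DEFAULT_SAMPLING_DISTANCE",
]
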