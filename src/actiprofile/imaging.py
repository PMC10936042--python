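"""Movement-behavior images.

A participant's labelled week becomes a 168 x 60 categorical grid
(rows = 7 days x 24 h, Monday first; columns = minute within hour) and is
rendered as an RGB raster with non-wear in black. Rasters are resized with
nearest-neighbour resampling (categories must never blend) for model input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .preprocess import (
    DailySummary,
    DataError,
    IntensitySeries,
    LIGHT,
    MINUTES_PER_DAY,
    MVPA,
    NONWEAR,
    SEDENTARY,
)

N_ROWS = 168  # 7 days x 24 hours
N_COLS = 60  # minutes per hour


@dataclass
class Palette:
    """Category -> RGB (floats in [0,1]); non-wear is fixed at black."""

    colors: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: {
            NONWEAR: (0.0, 0.0, 0.0),
            SEDENTARY: (0.9, 0.15, 0.1),
            LIGHT: (0.1, 0.8, 0.2),
            MVPA: (0.1, 0.2, 0.95),
        }
    )

    def __post_init__(self) -> None:
        if self.colors.get(NONWEAR) != (0.0, 0.0, 0.0):
            raise ValueError("non-wear must be black")
        quantized = {tuple(int(round(c * 255)) for c in rgb) for rgb in self.colors.values()}
        if len(quantized) != 4:
            raise ValueError("palette colors must stay distinct after 8-bit quantization")

    def as_array(self) -> np.ndarray:
        return np.array([self.colors[c] for c in (NONWEAR, SEDENTARY, LIGHT, MVPA)])


DEFAULT_PALETTE = Palette()


def build_matrix(
    series: IntensitySeries,
    daily: list[DailySummary] | None = None,
    valid_only: bool = True,
) -> np.ndarray:
    """Place labelled minutes on the 168 x 60 grid.

    Cell (row, col) with row = (weekday-1)*24 + hour, col = minute within
    hour. Minutes on invalid days (when ``valid_only``) and days absent
    from the trace are non-wear.
    """
    key = series.weekday * MINUTES_PER_DAY + series.minute_of_day
    if len(np.unique(key)) != len(key):
        raise DataError("duplicate (weekday, minute) entries")
    grid = np.full((N_ROWS, N_COLS), NONWEAR, dtype=np.int8)
    keep = np.ones(len(series.category), dtype=bool)
    if valid_only and daily is not None:
        valid_days = {d.weekday for d in daily if d.valid}
        keep = np.isin(series.weekday, list(valid_days))
    rows = (series.weekday - 1) * 24 + series.minute_of_day // 60
    cols = series.minute_of_day % 60
    grid[rows[keep], cols[keep]] = series.category[keep]
    return grid


def render(matrix: np.ndarray, palette: Palette = DEFAULT_PALETTE) -> np.ndarray:
    """Categorical grid -> native-resolution RGB raster (168, 60, 3)."""
    return palette.as_array()[matrix]


def decode(image: np.ndarray, palette: Palette = DEFAULT_PALETTE) -> np.ndarray:
    """Inverse of :func:`render` at native resolution (nearest palette color)."""
    pal = palette.as_array()  # (4, 3)
    d2 = ((image[..., None, :] - pal) ** 2).sum(axis=-1)
    return d2.argmin(axis=-1).astype(np.int8)


def prepare_for_model(image: np.ndarray, side: int = 224) -> np.ndarray:
    """Nearest-neighbour resize to (side, side, 3); values stay in [0,1]."""
    if side < 8:
        raise ValueError("model input side must be >= 8")
    h, w = image.shape[:2]
    ri = np.minimum((np.arange(side) * h) // side, h - 1)
    ci = np.minimum((np.arange(side) * w) // side, w - 1)
    return image[np.ix_(ri, ci)]


def save_png(image: np.ndarray, path) -> None:
    arr = np.clip(np.round(image * 255), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def load_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64)
    return arr / 255.0


def mvpa_pixel_fraction(matrix: np.ndarray) -> float:
    """Fraction of MVPA cells; equals MVPA minutes / 10,080 at native size."""
    return float(np.mean(matrix == MVPA))
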