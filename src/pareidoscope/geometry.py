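"""Stimulus geometry: canvas, target region, elliptical frame, fixation cross.

All arrays are row-major luminance grids indexed ``[row, col]`` with 0-based,
half-open rectangles.  The reference geometry is a 300 (w) x 350 (h) noise
canvas with a 200 x 220 target region centred on it, enclosed by a 238 x 294
elliptical frame with a 12 x 12 central cross.  ``StimulusGeometry.scaled``
produces proportionally reduced geometries for fast desk-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AOISpec:
    """Area of interest: an axis-aligned rectangle, 0-based, half-open.

    ``x_offset``/``y_offset`` are the column/row of the top-left corner;
    the AOI spans ``[y_offset, y_offset + height) x [x_offset, x_offset + width)``.
    """

    x_offset: int
    y_offset: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("AOI dimensions must be positive")
        if self.x_offset < 0 or self.y_offset < 0:
            raise ValueError("AOI offsets must be non-negative")

    @property
    def row_slice(self) -> slice:
        return slice(self.y_offset, self.y_offset + self.height)

    @property
    def col_slice(self) -> slice:
        return slice(self.x_offset, self.x_offset + self.width)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    def fits_inside(self, shape: tuple[int, int]) -> bool:
        h, w = shape
        return (self.y_offset + self.height <= h) and (self.x_offset + self.width <= w)


@dataclass(frozen=True)
class StimulusGeometry:
    """Dimensions (pixels) of one oddity stimulus and its annotations."""

    canvas_width: int = 300
    canvas_height: int = 350
    target_width: int = 200
    target_height: int = 220
    ellipse_width: int = 238
    ellipse_height: int = 294
    cross_size: int = 12
    frame_stroke: int = 2

    def __post_init__(self) -> None:
        if self.target_width > self.canvas_width or self.target_height > self.canvas_height:
            raise ValueError("target region must fit inside the canvas")

    @property
    def canvas_shape(self) -> tuple[int, int]:
        return (self.canvas_height, self.canvas_width)

    @property
    def target_shape(self) -> tuple[int, int]:
        return (self.target_height, self.target_width)

    @property
    def target_col_offset(self) -> int:
        return (self.canvas_width - self.target_width) // 2

    @property
    def target_row_offset(self) -> int:
        return (self.canvas_height - self.target_height) // 2

    @property
    def aoi(self) -> AOISpec:
        """Default AOI: the centred target-sized rectangle."""
        return AOISpec(
            x_offset=self.target_col_offset,
            y_offset=self.target_row_offset,
            width=self.target_width,
            height=self.target_height,
        )

    @classmethod
    def scaled(cls, factor: float) -> "StimulusGeometry":
        """Proportionally reduced geometry (e.g. factor=0.1 for tiny fixtures)."""
        if not 0 < factor <= 1:
            raise ValueError("scale factor must be in (0, 1]")
        r = lambda v: max(1, int(round(v * factor)))  # noqa: E731
        return cls(
            canvas_width=r(300),
            canvas_height=r(350),
            target_width=r(200),
            target_height=r(220),
            ellipse_width=r(238),
            ellipse_height=r(294),
            cross_size=max(2, int(round(12 * factor))),
            frame_stroke=max(1, int(round(2 * factor))),
        )


#: The study's full-scale geometry.
DEFAULT_GEOMETRY = StimulusGeometry()
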