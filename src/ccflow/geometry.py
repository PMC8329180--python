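"""Field geometry: the physical extent and sampling of the imaged region.

Coordinates follow the package convention: pixel indices are 0-based,
row-major with the origin at the top-left; physical positions are in
millimetres measured from the top-left corner of the field. The optic-disc
centre may lie outside the field (the scan is centred on the fovea, the disc
sits nasal of it).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class FieldGeometry:
    """Physical and grid geometry of an en-face field.

    Parameters
    ----------
    width_mm, height_mm : float
        Physical field size. The default 3 x 3 mm matches a macular
        OCTA scan centred over the fovea.
    grid_nx, grid_ny : int
        Grid samples along x (columns) and y (rows).
    disc_center_mm : (float, float)
        Optic-disc centre ``(x_mm, y_mm)``; may lie outside the field.
    """

    width_mm: float = 3.0
    height_mm: float = 3.0
    grid_nx: int = 256
    grid_ny: int = 256
    disc_center_mm: tuple[float, float] = (-1.0, 1.5)

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.height_mm <= 0:
            raise ValueError("field dimensions must be positive")
        if self.grid_nx < 16 or self.grid_ny < 16:
            raise ValueError("grid must be at least 16 x 16")

    @property
    def pixel_pitch_um(self) -> float:
        """Pixel pitch in micrometres (derived from width and grid_nx)."""
        return 1000.0 * self.width_mm / self.grid_nx

    @property
    def pixel_pitch_mm(self) -> float:
        return self.width_mm / self.grid_nx

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape as (rows, cols) = (grid_ny, grid_nx)."""
        return (self.grid_ny, self.grid_nx)

    def pixel_centers_mm(self):
        """Return (X, Y) grids of pixel-centre positions in mm."""
        import numpy as np

        px = self.pixel_pitch_mm
        py = self.height_mm / self.grid_ny
        x = (np.arange(self.grid_nx) + 0.5) * px
        y = (np.arange(self.grid_ny) + 0.5) * py
        return np.meshgrid(x, y)

    def mm_to_pixel(self, pos_mm) -> tuple[int, int]:
        """Nearest pixel (row, col) for a physical position (x_mm, y_mm)."""
        x_mm, y_mm = pos_mm
        col = int(round(x_mm / self.pixel_pitch_mm - 0.5))
        row = int(round(y_mm / (self.height_mm / self.grid_ny) - 0.5))
        col = min(max(col, 0), self.grid_nx - 1)
        row = min(max(row, 0), self.grid_ny - 1)
        return row, col
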