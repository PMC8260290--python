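"""Assembly and image I/O of the 6x6 grayscale health map.

One day's standardized measurements are laid out on a fixed 6x6 grid of
8-bit gray values — a 36-pixel image small enough for a phone to build and
upload, and shaped for a tiny CNN to consume:

    row 1: SP1  DP1  HR1   APP1  MAP1  ARPP1   (morning BP session)
    row 2: SP2  DP2  HR2   APP2  MAP2  ARPP2   (evening BP session)
    row 3: Weight  Fat     --    --    --  --
    row 4: Steps Distance FastT FastD Sleep Awake
    row 5: Temp1  --  --  --  --  --
    row 6: Temp2  --  --  --  --  --

Unassigned cells are zero-filled. Canonical lossless serialization is PGM
(P5); 8-bit grayscale PNG is accepted for interchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from PIL import Image

from .features import DEFAULT_TABLE, ExpandedRecord, StandardizationTable, standardize

__all__ = ["MAP_SHAPE", "LAYOUT", "HealthMap", "build_map", "to_image", "from_image"]

MAP_SHAPE = (6, 6)

# (row, col) 1-based -> (index name in the standardization table,
#                        accessor into an ExpandedRecord)
LAYOUT: dict[tuple[int, int], tuple[str, Callable[[ExpandedRecord], float]]] = {
    (1, 1): ("sp", lambda r: r.session1.sp),
    (1, 2): ("dp", lambda r: r.session1.dp),
    (1, 3): ("hr", lambda r: r.session1.hr),
    (1, 4): ("app", lambda r: r.session1.app),
    (1, 5): ("map", lambda r: r.session1.map),
    (1, 6): ("arpp", lambda r: r.session1.arpp),
    (2, 1): ("sp", lambda r: r.session2.sp),
    (2, 2): ("dp", lambda r: r.session2.dp),
    (2, 3): ("hr", lambda r: r.session2.hr),
    (2, 4): ("app", lambda r: r.session2.app),
    (2, 5): ("map", lambda r: r.session2.map),
    (2, 6): ("arpp", lambda r: r.session2.arpp),
    (3, 1): ("weight", lambda r: r.weight),
    (3, 2): ("fat", lambda r: r.fat),
    (4, 1): ("step_num", lambda r: r.activity.step_num),
    (4, 2): ("distance", lambda r: r.activity.distance),
    (4, 3): ("fast_motion_time", lambda r: r.activity.fast_motion_time),
    (4, 4): ("fast_motion_distance", lambda r: r.activity.fast_motion_distance),
    (4, 5): ("sleep_len", lambda r: r.activity.sleep_len),
    (4, 6): ("awake_len", lambda r: r.activity.awake_len),
    (5, 1): ("body_temperature", lambda r: r.temp1),
    (6, 1): ("body_temperature", lambda r: r.temp2),
}


@dataclass(frozen=True)
class HealthMap:
    """6x6 grid of gray values 0..255, row 1 at the image top."""

    grid: np.ndarray = field(default_factory=lambda: np.zeros(MAP_SHAPE, dtype=np.uint8))

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.shape != MAP_SHAPE:
            raise ValueError(f"health map must be {MAP_SHAPE}, got {grid.shape}")
        if grid.dtype != np.uint8:
            if np.any((grid < 0) | (grid > 255)) or np.any(grid != np.round(grid)):
                raise ValueError("health-map cells must be integers in 0..255")
            grid = grid.astype(np.uint8)
        object.__setattr__(self, "grid", grid)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HealthMap):
            return NotImplemented
        return bool(np.array_equal(self.grid, other.grid))

    def __hash__(self) -> int:
        return hash(self.grid.tobytes())

    def cell(self, row: int, col: int) -> int:
        """Gray value at 1-based (row, col)."""
        if not (1 <= row <= 6 and 1 <= col <= 6):
            raise IndexError(f"cell coordinates out of range: ({row}, {col})")
        return int(self.grid[row - 1, col - 1])


def build_map(record: ExpandedRecord, table: StandardizationTable = DEFAULT_TABLE) -> HealthMap:
    """Standardize an expanded record into its health map.

    Every laid-out cell holds the gray value of its quantity; the cells the
    layout leaves unassigned are zero. Pure function: identical inputs give a
    bit-identical map.
    """
    missing = [
        name
        for name, value in (
            ("session1", record.session1),
            ("session2", record.session2),
            ("temp1", record.temp1),
            ("temp2", record.temp2),
            ("activity", record.activity),
        )
        if value is None
    ]
    if missing:
        raise ValueError(f"incomplete record, missing: {missing}")

    grid = np.zeros(MAP_SHAPE, dtype=np.uint8)
    for (row, col), (index, getter) in LAYOUT.items():
        grid[row - 1, col - 1] = standardize(getter(record), index, table)
    return HealthMap(grid=grid)


def to_image(health_map: HealthMap, path) -> None:
    """Write the map as an 8-bit single-channel image (PGM/P5 or PNG by suffix)."""
    Image.fromarray(health_map.grid, mode="L").save(path)


def from_image(path) -> HealthMap:
    """Read a 6x6 8-bit grayscale image back into a health map."""
    with Image.open(path) as img:
        if img.mode != "L":
            raise ValueError(f"expected 8-bit grayscale image, got mode {img.mode!r}")
        arr = np.asarray(img, dtype=np.uint8)
    if arr.shape != MAP_SHAPE:
        raise ValueError(f"expected a {MAP_SHAPE} image, got {arr.shape}")
    return HealthMap(grid=arr)
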