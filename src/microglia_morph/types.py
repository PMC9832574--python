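"""Shared containers for two-channel microglia imaging data.

Conventions used throughout the package:

* images are 2-D ``float`` arrays indexed ``[row, col]``;
* the red channel carries the cytoplasmic microglia reporter, the green
  channel carries SYTOX-stained nucleic-acid debris;
* a *label mask* is a non-negative integer image in which 0 is background
  and ``k > 0`` identifies cell ``k``;
* physical lengths are micrometres, areas square micrometres, converted
  through the acquisition pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default lateral pixel size of the acquisition, in micrometres.
DEFAULT_PIXEL_SIZE_UM = 0.758


@dataclass
class Field:
    """One acquisition: per-channel pixel arrays plus calibration.

    Attributes
    ----------
    red, green :
        2-D intensity images (microglia reporter / SYTOX debris).
    pixel_size_um :
        Lateral pixel size in micrometres.
    time_index :
        Position of this field in a time-lapse (0 for single frames).
    """

    red: np.ndarray
    green: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    time_index: int = 0

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if self.red.ndim != 2 or self.green.ndim != 2:
            raise ValueError("channel images must be 2-D")
        if self.red.shape != self.green.shape:
            raise ValueError(
                f"channel shapes differ: red {self.red.shape}, green {self.green.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape


def as_label_mask(mask: np.ndarray) -> np.ndarray:
    """Validate and return ``mask`` as an integer label mask."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("label mask must be 2-D")
    if not np.issubdtype(mask.dtype, np.integer):
        if not np.array_equal(mask, np.round(mask)):
            raise ValueError("label mask must hold integers")
        mask = mask.astype(np.int32)
    if mask.min() < 0:
        raise ValueError("label mask must be non-negative")
    return mask
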