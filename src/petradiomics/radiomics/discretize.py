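"""Gray-level discretization of the in-mask SUV distribution.

Texture matrices operate on integer gray levels 1..Ng.  Two schemes are
supported:

* fixed-bin-size (``"fbs"``): ``level = floor((SUV - min) / w) + 1`` with a
  bin width ``w`` in SUV; Ng follows from the in-mask range.  The package
  default is w = 0.5 SUV, a common choice for FDG PET.
* fixed-bin-number (``"fbn"``): ``Nb`` equal-width bins spanning the in-mask
  [min, max]; texture becomes invariant to affine intensity shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..petio import PETVolume, ROIMask

__all__ = ["DiscretizedROI", "discretize"]


@dataclass
class DiscretizedROI:
    """Integer gray levels on the ROI grid; 0 marks out-of-mask voxels."""

    levels: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    ng: int
    method: str
    param: float
    flags: list[str] = field(default_factory=list)

    @property
    def inmask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize(vol: PETVolume, mask: ROIMask, method: str = "fbs", param: float = 0.5) -> DiscretizedROI:
    """Discretize in-mask SUVs to gray levels 1..Ng.

    ``param`` is the bin width w (SUV) for ``"fbs"`` or the bin count Nb for
    ``"fbn"``.  A constant ROI collapses to a single level and is flagged.
    """
    mask.check_grid(vol)
    if param <= 0:
        raise ValueError(f"discretization parameter must be > 0, got {param}")
    m = mask.values
    x = vol.values[m]
    flags: list[str] = []
    levels = np.zeros(vol.shape, dtype=np.int64)
    xmin, xmax = float(x.min()), float(x.max())
    if method == "fbs":
        lv = np.floor((x - xmin) / param).astype(np.int64) + 1
        ng = int(lv.max())
    elif method == "fbn":
        nb = int(param)
        if nb < 1:
            raise ValueError(f"fixed-bin-number requires Nb >= 1, got {param}")
        if xmax == xmin:
            lv = np.ones(x.shape, dtype=np.int64)
        else:
            lv = np.floor(nb * (x - xmin) / (xmax - xmin)).astype(np.int64) + 1
            lv[lv > nb] = nb  # the maximum falls on the closed upper edge
        ng = int(lv.max())
    else:
        raise ValueError(f"unknown discretization method {method!r}; use 'fbs' or 'fbn'")
    if xmax == xmin:
        flags.append("constant in-mask intensity: single gray level")
    levels[m] = lv
    return DiscretizedROI(levels, m, mask.spacing, ng, method, float(param), flags)
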