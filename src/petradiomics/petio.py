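"""Image and table I/O with grid-consistency enforcement.

PET volumes are carried in SUV units (body-weight normalized, dimensionless)
on a regular 3D grid with physical voxel spacing in mm.  All downstream
geometry (morphology, spatial autocorrelation, SUVpeak) is computed in world
units from ``spacing``, so grid agreement between image and mask is enforced
at read time rather than trusted.

Clinical tables are plain CSV with a fixed column dictionary (see
:data:`CLINICAL_COLUMNS`); marker columns may be blank, which is preserved as
the explicit level ``"missing"`` and never imputed.  The binary response
label is derived here, once: pathologic complete response (γpCR) is Mandard
tumor-regression grade 1, everything else (TRG 2-5) is non-γpCR.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "PETVolume",
    "ROIMask",
    "GridMismatchError",
    "EmptyMaskError",
    "read_pet_pair",
    "write_pet_pair",
    "read_clinical",
    "RESPONSE_COLUMN",
    "MARKER_COLUMNS",
    "CLINICAL_COLUMNS",
]

#: spacing agreement tolerance between image and mask, mm
SPACING_TOL_MM = 1e-3
#: affine agreement tolerance, mm
AFFINE_TOL_MM = 1e-3

RESPONSE_COLUMN = "response"

MARKER_COLUMNS = ("her2", "cd44", "hif1a_nucleus", "hif1a_cytosol", "ptch1", "shh")

#: required clinical columns and their admissible levels (None = free/numeric)
CLINICAL_COLUMNS: dict[str, tuple | None] = {
    "id": None,
    "histology": ("adenocarcinoma", "squamous"),
    "cT": ("T1-2", "T3-4a"),
    "cN": ("N0-1", "N2-3"),
    "chemo_cycles": (4, 5),
    "mandard": (1, 2, 3, 4, 5),
    "her2": ("negative", "positive", "missing"),
    "cd44": ("negative", "positive", "missing"),
    "hif1a_nucleus": ("negative", "positive", "missing"),
    "hif1a_cytosol": ("negative", "positive", "missing"),
    "ptch1": ("negative", "positive", "missing"),
    "shh": ("negative", "positive", "missing"),
}


class GridMismatchError(ValueError):
    """Image and mask do not live on the same grid."""


class EmptyMaskError(ValueError):
    """Mask contains no foreground voxel."""


@dataclass
class PETVolume:
    """A 3D SUV grid.

    Parameters
    ----------
    values
        3D float array of SUV, axis order (x, y, z) internally.
    spacing
        Voxel spacing per axis in mm, all > 0.
    origin
        World coordinate of the first voxel centre, mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"PETVolume requires a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PETVolume values must be finite")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class ROIMask:
    """A binary region of interest on the same grid as its paired volume."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values) > 0
        if self.values.ndim != 3:
            raise ValueError(f"ROIMask requires a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not self.values.any():
            raise EmptyMaskError("mask contains no foreground voxel")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def check_grid(self, vol: PETVolume) -> None:
        """Raise :class:`GridMismatchError` unless self and ``vol`` share a grid."""
        if self.shape != vol.shape:
            raise GridMismatchError(
                f"mask shape {self.shape} != image shape {vol.shape}"
            )
        ds = np.abs(np.asarray(self.spacing) - np.asarray(vol.spacing))
        if np.any(ds > SPACING_TOL_MM):
            raise GridMismatchError(
                f"mask spacing {self.spacing} mm != image spacing {vol.spacing} mm "
                f"(tolerance {SPACING_TOL_MM} mm)"
            )


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_pet_pair(vol: PETVolume, mask: ROIMask, image_path, mask_path) -> None:
    """Write an image/mask pair as NIfTI-1 files."""
    mask.check_grid(vol)
    nib.save(nib.Nifti1Image(vol.values.astype(np.float64), _affine(vol.spacing, vol.origin)), str(image_path))
    nib.save(
        nib.Nifti1Image(mask.values.astype(np.uint8), _affine(mask.spacing, mask.origin)),
        str(mask_path),
    )


def read_pet_pair(image_path, mask_path) -> tuple[PETVolume, ROIMask]:
    """Read a NIfTI image/mask pair and verify they share one grid.

    The mask is binarized at > 0.  Shape must match exactly; spacing within
    1e-3 mm; the affines within 1e-3 mm elementwise.  An all-zero mask and any
    grid disagreement are hard errors naming both grids.
    """
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    ivals = np.asanyarray(img.dataobj, dtype=float)
    mvals = np.asanyarray(msk.dataobj)
    izoom = tuple(float(z) for z in img.header.get_zooms()[:3])
    mzoom = tuple(float(z) for z in msk.header.get_zooms()[:3])
    if ivals.shape != mvals.shape:
        raise GridMismatchError(
            f"image grid {ivals.shape} @ {izoom} mm vs mask grid {mvals.shape} @ {mzoom} mm"
        )
    if np.any(np.abs(np.asarray(izoom) - np.asarray(mzoom)) > SPACING_TOL_MM):
        raise GridMismatchError(
            f"image spacing {izoom} mm vs mask spacing {mzoom} mm exceeds {SPACING_TOL_MM} mm"
        )
    if np.any(np.abs(img.affine - msk.affine) > AFFINE_TOL_MM):
        raise GridMismatchError("image and mask affines disagree beyond tolerance")
    if not (mvals > 0).any():
        raise EmptyMaskError(f"mask {mask_path} has no foreground voxel")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    vol = PETVolume(ivals, izoom, origin)
    mask = ROIMask(mvals > 0, mzoom, origin, provenance=str(mask_path))
    return vol, mask


def read_clinical(csv_path) -> pd.DataFrame:
    """Read and validate a per-patient clinical table.

    Returns the table with a derived binary ``response`` column
    (1 = γpCR = Mandard TRG 1, 0 = non-γpCR = TRG 2-5).  Blank marker cells
    become the explicit level ``"missing"`` and the row is retained; analyses
    that use a marker are expected to do complete-case exclusion themselves.
    """
    df = pd.read_csv(csv_path)
    return validate_clinical(df)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate levels of an in-memory clinical table and derive the response."""
    df = df.copy()
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"clinical table lacks required columns: {missing_cols}")
    for col in MARKER_COLUMNS:
        df[col] = df[col].fillna("missing").replace("", "missing")
    for col, levels in CLINICAL_COLUMNS.items():
        if levels is None:
            continue
        if col in ("chemo_cycles", "mandard"):
            df[col] = df[col].astype(int)
        bad = ~df[col].isin(levels)
        if bad.any():
            row = df.loc[bad].iloc[0]
            raise ValueError(
                f"unknown level {row[col]!r} in column {col!r} (patient id {row['id']!r})"
            )
    df[RESPONSE_COLUMN] = (df["mandard"] == 1).astype(int)
    return df
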