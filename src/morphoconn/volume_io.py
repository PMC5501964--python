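"""Volume and parcellation I/O, Gaussian smoothing, and regional sampling.

Gray-matter (GM) density volumes are NIfTI images whose voxel values are
tissue probabilities/densities, nominally in [0, 1] (modulated VBM output may
exceed 1 slightly; such values are kept and logged, not clipped, unless the
caller asks for clamping).  A parcellation is an integer label volume on the
same grid plus a table naming each region of interest (ROI) and assigning it
a hemisphere and a role (seed / target / ignore).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: FWHM -> Gaussian sigma conversion constant, 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

ROI_TABLE_COLUMNS = ("id", "name", "hemisphere", "role")
ROI_ROLES = ("seed", "target", "ignore")


@dataclass
class GMVolume:
    """One subject's 3-D gray-matter density map with grid geometry."""

    data: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3-D volume, got {self.data.ndim}-D array of shape "
                f"{self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite voxel value at index {tuple(int(i) for i in bad)}"
            )
        out_of_range = int(np.count_nonzero((self.data < 0) | (self.data > 1)))
        if out_of_range:
            logger.warning(
                "volume %s: %d voxel(s) outside [0, 1]; kept as-is",
                self.subject_id or "<unnamed>",
                out_of_range,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def clamped(self) -> "GMVolume":
        """Copy with values clipped to [0, 1] (opt-in; never automatic)."""
        return GMVolume(np.clip(self.data, 0.0, 1.0), self.affine, self.subject_id)


@dataclass
class Parcellation:
    """Integer label volume plus the ROI table describing each label.

    Label 0 is background.  ``roi_table`` has columns id, name, hemisphere,
    role; every id listed must occur in ``labels``.
    """

    labels: np.ndarray
    roi_table: pd.DataFrame
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("parcellation labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("parcellation labels must be integers")
            self.labels = as_int
        if self.labels.min() < 0:
            raise ValueError("parcellation labels must be non-negative")
        missing_cols = set(ROI_TABLE_COLUMNS) - set(self.roi_table.columns)
        if missing_cols:
            raise ValueError(f"roi_table missing columns: {sorted(missing_cols)}")
        bad_roles = set(self.roi_table["role"]) - set(ROI_ROLES)
        if bad_roles:
            raise ValueError(f"unknown ROI roles: {sorted(bad_roles)}")
        present = set(np.unique(self.labels).tolist()) - {0}
        listed = set(int(i) for i in self.roi_table["id"])
        if 0 in listed:
            raise ValueError("ROI id 0 is reserved for background")
        absent = listed - present
        if absent:
            raise ValueError(f"ROI ids absent from label volume: {sorted(absent)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def rois(self, role: str | None = None, hemisphere: str | None = None) -> pd.DataFrame:
        """ROI table rows filtered by role and/or hemisphere."""
        t = self.roi_table
        if role is not None:
            t = t[t["role"] == role]
        if hemisphere is not None:
            t = t[t["hemisphere"] == hemisphere]
        return t

    def roi_name(self, roi_id: int) -> str:
        row = self.roi_table[self.roi_table["id"] == roi_id]
        return str(row["name"].iloc[0]) if len(row) else f"roi_{roi_id}"


@dataclass
class RegionalSample:
    """Multiset of GM density values drawn from one ROI's voxels."""

    roi_id: int
    values: np.ndarray
    roi_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size == 0:
            raise ValueError(f"ROI {self.roi_id} has no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_gm_volume(path: str | Path, subject_id: str | None = None) -> GMVolume:
    """Read a 3-D NIfTI gray-matter density volume.

    Raises ``ValueError`` for non-3-D images or non-finite voxels; squeezes
    nothing — a 4-D file is an error, not a silent first-frame read.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D file: {path}")
    sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
    return GMVolume(data.astype(np.float64), np.asarray(img.affine), sid)


def write_gm_volume(vol: GMVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (float32 preserves GM densities adequately;
    float64 is used so the round trip is exact)."""
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    nib.save(img, str(path))


def read_parcellation(labels_path: str | Path, roi_table_path: str | Path) -> Parcellation:
    """Read a label NIfTI plus its ROI table CSV (id,name,hemisphere,role)."""
    img = nib.load(str(labels_path))
    labels = np.asanyarray(img.dataobj)
    if labels.ndim != 3:
        raise ValueError(f"expected 3-D label volume, got {labels.ndim}-D")
    labels = np.rint(labels).astype(np.int64)
    table = pd.read_csv(roi_table_path)
    return Parcellation(labels, table, np.asarray(img.affine))


def write_parcellation(parc: Parcellation, labels_path: str | Path, roi_table_path: str | Path) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int16), parc.affine)
    nib.save(img, str(labels_path))
    parc.roi_table.to_csv(roi_table_path, index=False)


# ---------------------------------------------------------------------------
# Smoothing


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm: np.ndarray | float) -> np.ndarray:
    """Per-axis Gaussian sigma (in voxels) for a given FWHM in mm."""
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    vox = np.atleast_1d(np.asarray(voxel_size_mm, dtype=np.float64))
    if np.any(vox <= 0):
        raise ValueError("voxel sizes must be positive")
    return fwhm_mm / FWHM_TO_SIGMA / vox


def smooth_gaussian(vol: GMVolume, fwhm_mm: float) -> GMVolume:
    """Gaussian-smooth a volume with an isotropic FWHM given in mm.

    Anisotropic voxels are handled by converting the FWHM to a per-axis sigma
    in voxel units.  The filter has unit DC gain, so mean intensity is
    conserved away from the boundary (reflect padding at edges).
    """
    sigma_vox = fwhm_to_sigma_voxels(fwhm_mm, vol.voxel_size_mm)
    smoothed = ndimage.gaussian_filter(vol.data, sigma=sigma_vox, mode="reflect")
    return GMVolume(smoothed, vol.affine, vol.subject_id)


# ---------------------------------------------------------------------------
# Regional sampling


def extract_regional_samples(
    vol: GMVolume,
    parc: Parcellation,
    inclusion_threshold: float = 0.0,
    mask: np.ndarray | None = None,
) -> list[RegionalSample]:
    """Collect each non-ignored ROI's voxel values from a GM volume.

    Voxels enter a region's sample when their GM value is strictly greater
    than ``inclusion_threshold`` (default 0: zero-density voxels carry no
    morphological signal).  An optional boolean ``mask`` further restricts
    sampling (e.g. a group GM mask).  An ROI left empty after filtering is an
    error naming the ROI, never a silent skip.
    """
    if vol.shape != parc.shape:
        raise ValueError(
            f"volume shape {vol.shape} does not match parcellation shape {parc.shape}"
        )
    if mask is not None and mask.shape != vol.shape:
        raise ValueError(f"mask shape {mask.shape} does not match volume {vol.shape}")

    keep = vol.data > inclusion_threshold
    if mask is not None:
        keep &= mask.astype(bool)

    samples: list[RegionalSample] = []
    for row in parc.roi_table.itertuples(index=False):
        if row.role == "ignore":
            continue
        roi_id = int(row.id)
        sel = (parc.labels == roi_id) & keep
        values = vol.data[sel]
        if values.size == 0:
            raise ValueError(
                f"ROI {roi_id} ({row.name}) is empty after filtering at "
                f"threshold {inclusion_threshold} for subject "
                f"{vol.subject_id or '<unnamed>'}"
            )
        logger.debug(
            "subject %s ROI %s (%s): %d voxels sampled",
            vol.subject_id, roi_id, row.name, values.size,
        )
        samples.append(RegionalSample(roi_id, values, str(row.name)))
    return samples
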