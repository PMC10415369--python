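"""Grey-matter mask construction and voxel feature extraction.

The mask keeps a voxel iff the grey-matter tissue probability is strictly
above ``gm_threshold`` (default 0.40) AND the white-matter probability is
strictly below ``wm_threshold`` (default 0.60). Strict inequalities are
deliberate: boundary voxels differ between conventions, and this package pins
the convention down. Masked voxels are linearized in ascending flat (C-order)
index, and that ordering defines the feature-matrix columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

VOXEL_ORDER_NOTE = "voxel_order=ascending C-order flat index of true voxels"


@dataclass(frozen=True)
class MaskConfig:
    """Thresholds and smoothing width for mask construction."""

    gm_threshold: float = 0.40
    wm_threshold: float = 0.60
    fwhm_mm: float = 8.0

    def __post_init__(self) -> None:
        for name in ("gm_threshold", "wm_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be non-negative")


@dataclass
class GreyMatterMask:
    """Boolean voxel mask plus the affine and linearization rule."""

    volume: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=bool)
        if self.volume.ndim != 3:
            raise ValueError("mask volume must be 3D")
        if not self.volume.any():
            raise ValueError("mask contains no voxels")

    @property
    def voxel_order(self) -> np.ndarray:
        """Flat C-order indices of masked voxels; defines feature columns."""
        return np.flatnonzero(self.volume.ravel())

    @property
    def n_voxels(self) -> int:
        return int(self.volume.sum())


@dataclass
class FeatureMatrix:
    """Subjects x masked-voxels GMD values with stable orderings."""

    values: np.ndarray
    subject_ids: list
    mask: GreyMatterMask

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = list(self.subject_ids)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2D (subjects x voxels)")
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("row count must match subject_ids")
        if self.values.shape[1] != self.mask.n_voxels:
            raise ValueError("column count must match mask voxel count")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix must not contain missing values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def build_gm_mask(
    gm_prob: np.ndarray,
    wm_prob: np.ndarray,
    config: MaskConfig = MaskConfig(),
    affine: np.ndarray | None = None,
) -> GreyMatterMask:
    """Apply the strict two-threshold rule to the tissue-probability templates."""
    gm = np.asarray(gm_prob, dtype=float)
    wm = np.asarray(wm_prob, dtype=float)
    if gm.shape != wm.shape:
        raise ValueError(
            f"tissue volumes must share a shape, got {gm.shape} vs {wm.shape}"
        )
    if affine is None:
        affine = np.eye(4)
    volume = (gm > config.gm_threshold) & (wm < config.wm_threshold)
    if not volume.any():
        raise ValueError(
            "empty grey-matter mask: no voxel has grey-matter probability "
            f"> {config.gm_threshold} and white-matter probability "
            f"< {config.wm_threshold}"
        )
    return GreyMatterMask(volume=volume, affine=np.asarray(affine, dtype=float))


def smooth_volume(vol: np.ndarray, fwhm_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Gaussian-smooth a volume at the given FWHM (mm).

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, converted to voxel units.
    Boundary handling is reflective, so constant volumes are preserved; in the
    interior (kernel support away from edges) this equals plain convolution
    with the 3D Gaussian kernel.
    """
    if voxel_size_mm <= 0:
        raise ValueError("voxel_size_mm must be positive")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    vol = np.asarray(vol, dtype=float)
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    return ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="reflect")


def extract_features(
    images: dict | np.ndarray,
    mask: GreyMatterMask,
    subject_ids: list | None = None,
) -> FeatureMatrix:
    """Read masked voxel values into a subjects x voxels matrix.

    ``images`` is either a mapping subject_id -> 3D array, or a 4D stack with
    ``subject_ids`` giving row order. Row order follows ``subject_ids``;
    column order follows the mask's voxel linearization.
    """
    if isinstance(images, dict):
        if subject_ids is None:
            subject_ids = list(images.keys())
        missing = [sid for sid in subject_ids if sid not in images]
        if missing:
            raise ValueError(f"missing image for subjects: {missing}")
        stack = [np.asarray(images[sid]) for sid in subject_ids]
    else:
        stack = np.asarray(images)
        if subject_ids is None:
            raise ValueError("subject_ids required with an image stack")
        if stack.shape[0] != len(subject_ids):
            raise ValueError("image stack length must match subject_ids")
    order = mask.voxel_order
    shape = mask.volume.shape
    rows = []
    for sid, img in zip(subject_ids, stack):
        img = np.asarray(img)
        if img.shape != shape:
            raise ValueError(
                f"image for subject {sid!r} has shape {img.shape}, mask is {shape}"
            )
        rows.append(img.ravel()[order])
    return FeatureMatrix(values=np.asarray(rows, dtype=float), subject_ids=subject_ids, mask=mask)


# ---------------------------------------------------------------------------
# persistence


def save_mask(mask: GreyMatterMask, path) -> None:
    """Write the mask as a uint8 NIfTI; the header descrip records voxel order."""
    img = nib.Nifti1Image(mask.volume.astype(np.uint8), mask.affine)
    img.header["descrip"] = VOXEL_ORDER_NOTE.encode()[:79]
    nib.save(img, str(path))


def load_mask(path) -> GreyMatterMask:
    img = nib.load(str(path))
    return GreyMatterMask(volume=np.asarray(img.dataobj) > 0, affine=img.affine)


def save_features(fm: FeatureMatrix, path) -> None:
    """Persist matrix + ids + mask in one compressed npz archive."""
    np.savez_compressed(
        str(path),
        values=fm.values.astype(np.float32),
        subject_ids=np.asarray(fm.subject_ids, dtype=str),
        mask_volume=fm.mask.volume,
        affine=fm.mask.affine,
    )


def load_features(path) -> FeatureMatrix:
    with np.load(str(path), allow_pickle=False) as archive:
        mask = GreyMatterMask(volume=archive["mask_volume"], affine=archive["affine"])
        return FeatureMatrix(
            values=archive["values"].astype(float),
            subject_ids=[str(s) for s in archive["subject_ids"]],
            mask=mask,
        )


def save_volume(vol: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine
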