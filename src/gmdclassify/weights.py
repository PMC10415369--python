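"""Aggregate per-iteration model weights into voxel-wise importance maps.

Two maps summarize each binary model across iterations: the voxel-wise *mean
weight* and the *sign consistency* — the fraction of iterations whose weight
at that voxel has the same sign as the mean. A voxel that receives +w on half
of the iterations and -w on the other half has mean ~0 and consistency ~0.5;
a voxel the model relies on in the same direction every time has consistency
1. Both maps are written back into image space at the mask coordinates, zero
elsewhere. This aggregation is a reconstruction: it summarizes stored models
and supports qualitative comparison of how diffusely and consistently each
model spreads its weights, but it is not a statistical threshold, and single
voxels should not be interpreted in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .masking import GreyMatterMask


@dataclass
class WeightMapSet:
    """Mean-weight and sign-consistency volumes for one model."""

    mean_weight: np.ndarray
    sign_consistency: np.ndarray
    n_iterations: int
    model: str


def aggregate_weights(
    weights: np.ndarray, mask: GreyMatterMask, model: str = ""
) -> WeightMapSet:
    """Reduce an (iterations x voxels) weight array to importance maps."""
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2:
        raise ValueError("weights must be 2D (iterations x voxels)")
    if W.shape[1] != mask.n_voxels:
        raise ValueError(
            f"weight length {W.shape[1]} does not match mask population {mask.n_voxels}"
        )
    mean = W.mean(axis=0)
    consistency = np.mean(np.sign(W) == np.sign(mean)[None, :], axis=0)

    order = mask.voxel_order
    mean_vol = np.zeros(mask.volume.size)
    mean_vol[order] = mean
    cons_vol = np.zeros(mask.volume.size)
    cons_vol[order] = consistency
    shape = mask.volume.shape
    return WeightMapSet(
        mean_weight=mean_vol.reshape(shape),
        sign_consistency=cons_vol.reshape(shape),
        n_iterations=W.shape[0],
        model=model,
    )


def pooled_magnitude_cutoff(
    map_sets: list, mask: GreyMatterMask, quantile: float = 0.95
) -> float:
    """Common |mean-weight| cutoff: a quantile of the pooled in-mask values.

    Comparing how diffusely models spread strong weights requires one scale
    for all of them; a per-model cutoff would equalize the counts by
    construction.
    """
    order = mask.voxel_order
    pooled = np.concatenate([np.abs(m.mean_weight.ravel()[order]) for m in map_sets])
    return float(np.quantile(pooled, quantile))


def high_consistency_count(
    map_set: WeightMapSet,
    mask: GreyMatterMask,
    magnitude_cutoff: float,
    consistency_threshold: float = 0.9,
) -> int:
    """Count mask voxels that are both sign-consistent and strongly weighted."""
    order = mask.voxel_order
    mean = map_set.mean_weight.ravel()[order]
    cons = map_set.sign_consistency.ravel()[order]
    return int(np.sum((cons > consistency_threshold) & (np.abs(mean) > magnitude_cutoff)))


def write_map_nifti(map_set: WeightMapSet, mask: GreyMatterMask, out_dir) -> dict:
    """Write one NIfTI per map (float32, mask affine); returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    label = map_set.model or "model"
    paths = {}
    for name, vol in (
        ("mean_weight", map_set.mean_weight),
        ("sign_consistency", map_set.sign_consistency),
    ):
        path = out_dir / f"{label}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), mask.affine), str(path))
        paths[name] = path
    return paths
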