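"""Voxelwise model selection over 4D images.

Each in-mask voxel's time course is fitted independently with the same
engine as single-curve fits, so results are identical regardless of voxel
order or partitioning.  Frame times are supplied explicitly (a sidecar
JSON in the CLI) because a NIfTI repetition time alone cannot express
shifted or variable sampling.  Output maps use NaN as the missing value
for out-of-mask voxels and for parameters of voxels where the full model
was not preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from numpy.typing import NDArray

from .inference import PriorSpec, QuadratureFitter
from .model import DoseSchedule

__all__ = ["VoxelwiseJob", "fit_voxelwise", "save_maps"]

#: map name -> (estimate key, needs acceptance)
MAP_SPEC = {
    "prob_full": (None, False),
    "ec50": ("ec50", True),
    "e_max": ("e_max", True),
    "ts": ("ts", True),
    "t_half": ("t_half", True),
    "residual_sd": (None, False),
}


@dataclass
class VoxelwiseJob:
    """A voxelwise fitting job over a 4D image and a 3D mask."""

    image: "nib.Nifti1Image | str | Path"
    mask: "nib.Nifti1Image | str | Path"
    frame_times: NDArray[np.float64]
    schedule: DoseSchedule
    prior: PriorSpec = field(default_factory=lambda: PriorSpec(t_half=(2.0, 60.0)))
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if isinstance(self.image, (str, Path)):
            self.image = nib.load(str(self.image))
        if isinstance(self.mask, (str, Path)):
            self.mask = nib.load(str(self.mask))
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        ishape = self.image.shape
        if len(ishape) != 4:
            raise ValueError(f"image must be 4D, got shape {ishape}")
        if tuple(self.mask.shape) != tuple(ishape[:3]):
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image grid {ishape[:3]}"
            )
        if self.frame_times.size != ishape[3]:
            raise ValueError(
                f"{self.frame_times.size} frame times for {ishape[3]} image frames"
            )


def fit_voxelwise(job: VoxelwiseJob) -> dict[str, NDArray[np.float64]]:
    """Fit every in-mask voxel; return 3D parameter maps (NaN = missing)."""
    data = np.asarray(job.image.get_fdata(), dtype=float)
    mask = np.asarray(job.mask.get_fdata()) > 0
    shape3 = data.shape[:3]
    maps = {name: np.full(shape3, np.nan) for name in MAP_SPEC}
    idx = np.argwhere(mask)
    if idx.size == 0:
        return maps
    fitter = QuadratureFitter(
        job.frame_times, job.schedule, job.prior, threshold=job.threshold
    )
    for i, j, k in idx:
        res = fitter.fit(data[i, j, k, :])
        maps["prob_full"][i, j, k] = res.prob_full
        maps["residual_sd"][i, j, k] = res.residual_sd
        if res.estimates is not None:
            for name, (key, needs) in MAP_SPEC.items():
                if key is not None:
                    maps[name][i, j, k] = res.estimates[key]["ml"]
    return maps


def save_maps(
    maps: dict[str, NDArray[np.float64]],
    like: "nib.Nifti1Image",
    outdir: str | Path,
    prefix: str = "",
) -> list[Path]:
    """Write each map as a NIfTI-1 volume with the reference image's affine."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, vol in maps.items():
        img = nib.Nifti1Image(vol.astype(np.float64), like.affine)
        path = outdir / f"{prefix}{name}.nii"
        nib.save(img, str(path))
        written.append(path)
    return written
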