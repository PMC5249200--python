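"""Toy-scale CT stage: parallel-beam forward projection and filtered
back-projection (FBP), slice by slice.

A real metrological micro-CT uses a cone beam, but reconstruction enters
the wear method only as a black box producing a gray-value volume; a
parallel-beam FBP preserves that structure at desk scale.  Angles span
180 degrees with uniform spacing (sufficient for parallel geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon, radon

from .phantom import VoxelVolume

__all__ = ["Sinogram", "forward_project", "fbp_reconstruct", "nrmse"]

_FILTERS = {"ramp": "ramp", "hann": "hann"}


class ReconstructError(ValueError):
    pass


@dataclass
class Sinogram:
    """Stack of per-slice parallel-beam sinograms.

    ``projections`` has shape (n_slices, n_angles, n_detector_bins); the
    angles are uniform over [0, pi).  ``slice_shape`` remembers the
    original in-plane grid so reconstruction restores it exactly.
    """

    projections: np.ndarray
    angles: np.ndarray
    detector_spacing: float
    slice_shape: tuple[int, int]
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.detector_spacing <= 0:
            raise ReconstructError("detector_spacing must be positive")
        if self.projections.ndim != 3:
            raise ReconstructError("projections must be (slices, angles, bins)")
        if self.projections.shape[1] != len(self.angles):
            raise ReconstructError("angle count mismatch")

    @property
    def n_angles(self) -> int:
        return len(self.angles)


def forward_project(volume: VoxelVolume, n_angles: int) -> Sinogram:
    """Parallel-beam line integrals of each axial (z) slice.

    Linear in the input gray values; ``n_angles`` uniform angles over
    [0, 180) degrees.
    """
    if n_angles < 1:
        raise ReconstructError("n_angles must be >= 1")
    nx, ny, nz = volume.grid.shape
    if nx != ny:
        raise ReconstructError("axial slices must be square for this projector")
    theta = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    sinos = []
    for k in range(nz):
        # radon returns (detector bins, angles); store as (angles, bins)
        sinos.append(radon(volume.grid[:, :, k], theta=theta, circle=False).T)
    return Sinogram(
        projections=np.stack(sinos, axis=0),
        angles=np.deg2rad(theta),
        detector_spacing=volume.voxel_size,
        slice_shape=(nx, ny),
        voxel_size=volume.voxel_size,
        origin=volume.origin.copy(),
    )


def fbp_reconstruct(sino: Sinogram, filter: str = "ramp") -> VoxelVolume:
    """Slice-wise filtered back-projection onto the original grid.

    ``filter`` is ``"ramp"`` (Ram-Lak, default) or ``"hann"`` (stronger
    high-frequency roll-off for noisy projections).
    """
    if filter not in _FILTERS:
        raise ReconstructError(
            f"unknown filter {filter!r}; choose from {sorted(_FILTERS)}"
        )
    if sino.n_angles < 2:
        raise ReconstructError("need at least 2 angles for reconstruction")
    theta = np.rad2deg(sino.angles)
    out = np.empty(sino.slice_shape + (sino.projections.shape[0],), dtype=float)
    for k in range(sino.projections.shape[0]):
        out[:, :, k] = iradon(
            sino.projections[k].T,
            theta=theta,
            filter_name=_FILTERS[filter],
            circle=False,
            output_size=sino.slice_shape[0],
        )
    return VoxelVolume(
        out,
        voxel_size=sino.voxel_size,
        origin=sino.origin.copy(),
        metadata={"reconstruction": "parallel-beam FBP", "filter": filter,
                  "n_angles": sino.n_angles},
    )


def nrmse(estimate: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Normalized RMS error: RMS(estimate - truth) / RMS span of truth,
    optionally restricted to ``mask`` (e.g. the phantom support)."""
    e = np.asarray(estimate, dtype=float)
    t = np.asarray(truth, dtype=float)
    span = t.max() - t.min()  # span of the full truth, even when masked
    if span == 0:
        span = 1.0
    if mask is not None:
        e, t = e[mask], t[mask]
    return float(np.sqrt(np.mean((e - t) ** 2)) / span)
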