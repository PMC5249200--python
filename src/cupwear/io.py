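"""Volume and mesh file I/O.

Volumes round-trip through MHD+RAW or NRRD (via SimpleITK) preserving the
grid values, voxel size and origin bit-exactly; meshes are written as STL
or PLY.  MHD headers are pre-validated so that malformed files produce an
error naming the offending field instead of an opaque reader failure.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh

from .phantom import VoxelVolume
from .reconstruct import Sinogram
from .surface import SurfaceModel

__all__ = [
    "read_volume", "write_volume", "read_mesh", "write_mesh",
    "read_sinogram", "write_sinogram", "VolumeIOError",
]


class VolumeIOError(ValueError):
    pass


_MHD_DTYPES = {
    "MET_UCHAR": 1, "MET_CHAR": 1, "MET_USHORT": 2, "MET_SHORT": 2,
    "MET_UINT": 4, "MET_INT": 4, "MET_FLOAT": 4, "MET_DOUBLE": 8,
}


def _validate_mhd(path: Path) -> None:
    fields: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip()] = val.strip()
    for required in ("NDims", "DimSize", "ElementType", "ElementDataFile"):
        if required not in fields:
            raise VolumeIOError(f"MHD header missing required field '{required}'")
    try:
        ndims = int(fields["NDims"])
    except ValueError:
        raise VolumeIOError(f"MHD field 'NDims' is not an integer: {fields['NDims']!r}")
    try:
        dims = [int(x) for x in fields["DimSize"].split()]
    except ValueError:
        raise VolumeIOError(f"MHD field 'DimSize' is not a list of integers: "
                            f"{fields['DimSize']!r}")
    if len(dims) != ndims:
        raise VolumeIOError(
            f"MHD field 'DimSize' has {len(dims)} entries but NDims = {ndims}"
        )
    etype = fields["ElementType"]
    if etype not in _MHD_DTYPES:
        raise VolumeIOError(f"MHD field 'ElementType' unknown: {etype!r}")
    datafile = fields["ElementDataFile"]
    if datafile not in ("LOCAL", "LIST"):
        raw = path.parent / datafile
        if not raw.exists():
            raise VolumeIOError(f"MHD field 'ElementDataFile' points to missing "
                                f"file {datafile!r}")
        expected = int(np.prod(dims)) * _MHD_DTYPES[etype]
        actual = os.path.getsize(raw)
        if actual != expected:
            raise VolumeIOError(
                f"RAW payload size mismatch for 'ElementDataFile' {datafile!r}: "
                f"expected {expected} bytes from DimSize x ElementType, found {actual}"
            )


def read_volume(path) -> VoxelVolume:
    """Read an MHD or NRRD volume; voxel size must be isotropic."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    if path.suffix.lower() == ".mhd":
        _validate_mhd(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise VolumeIOError(f"cannot read volume {path}: {exc}") from exc
    spacing = img.GetSpacing()
    if not np.allclose(spacing, spacing[0]):
        raise VolumeIOError(f"anisotropic voxels not supported: spacing {spacing}")
    # SimpleITK arrays are (z, y, x); our grids are (x, y, z)
    grid = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelVolume(
        grid,
        voxel_size=float(spacing[0]),
        origin=np.asarray(img.GetOrigin(), dtype=float),
        metadata={"path": str(path)},
    )


def write_volume(volume: VoxelVolume, path) -> None:
    """Write a volume as MHD+RAW or NRRD, chosen by file extension."""
    path = Path(path)
    if path.suffix.lower() not in (".mhd", ".nrrd"):
        raise VolumeIOError(f"unsupported volume format {path.suffix!r} "
                            "(use .mhd or .nrrd)")
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.grid.transpose(2, 1, 0)))
    img.SetSpacing((volume.voxel_size,) * 3)
    img.SetOrigin(tuple(float(x) for x in volume.origin))
    sitk.WriteImage(img, str(path), useCompression=False)


def write_sinogram(sino: Sinogram, path) -> None:
    """Write a sinogram stack as NRRD, with the angles and grid geometry in
    the header metadata."""
    path = Path(path)
    if path.suffix.lower() != ".nrrd":
        raise VolumeIOError("sinograms are stored as .nrrd")
    img = sitk.GetImageFromArray(np.ascontiguousarray(sino.projections))
    img.SetMetaData("angles_rad", " ".join(repr(float(a)) for a in sino.angles))
    img.SetMetaData("detector_spacing_mm", repr(float(sino.detector_spacing)))
    img.SetMetaData("slice_shape", f"{sino.slice_shape[0]} {sino.slice_shape[1]}")
    img.SetMetaData("voxel_size_mm", repr(float(sino.voxel_size)))
    img.SetMetaData("origin_mm", " ".join(repr(float(x)) for x in sino.origin))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_sinogram(path) -> Sinogram:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    img = sitk.ReadImage(str(path))
    keys = set(img.GetMetaDataKeys())
    for required in ("angles_rad", "detector_spacing_mm", "slice_shape",
                     "voxel_size_mm", "origin_mm"):
        if required not in keys:
            raise VolumeIOError(f"sinogram NRRD missing metadata field '{required}'")
    shape = tuple(int(x) for x in img.GetMetaData("slice_shape").split())
    return Sinogram(
        projections=sitk.GetArrayFromImage(img),
        angles=np.array([float(a) for a in img.GetMetaData("angles_rad").split()]),
        detector_spacing=float(img.GetMetaData("detector_spacing_mm")),
        slice_shape=shape,
        voxel_size=float(img.GetMetaData("voxel_size_mm")),
        origin=np.array([float(x) for x in img.GetMetaData("origin_mm").split()]),
    )


def write_mesh(mesh: SurfaceModel, path) -> None:
    """Write a mesh as STL (binary) or PLY, chosen by file extension."""
    path = Path(path)
    if path.suffix.lower() not in (".stl", ".ply"):
        raise VolumeIOError(f"unsupported mesh format {path.suffix!r} (use .stl or .ply)")
    mesh.to_trimesh().export(str(path))


def read_mesh(path) -> SurfaceModel:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    tm = trimesh.load_mesh(str(path), process=False)
    # STL stores an unindexed triangle soup; re-weld shared vertices so the
    # mesh is watertight again
    tm.merge_vertices()
    return SurfaceModel(tm.vertices.view(np.ndarray), tm.faces.view(np.ndarray),
                        metadata={"path": str(path)})
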