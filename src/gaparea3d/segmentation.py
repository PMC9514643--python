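"""Bone extraction and fragment meshing from CT volumes.

The pipeline mirrors the manual clinical workflow: threshold the CT at a
Hounsfield-unit cut-off to isolate bone, keep the connected components the
user seeds (discarding noise and adjacent bones), split the remaining bone
into fracture fragments, and turn each fragment label into a triangle mesh
in physical (mm) coordinates.

All masks are voxel-indexed with half-open extents; all meshes and
measurements downstream are in mm in the volume's physical space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure as _skmeasure
import trimesh

logger = logging.getLogger("gaparea3d")

#: Default Hounsfield-unit threshold separating bone from soft tissue.
DEFAULT_HU_THRESHOLD = 225.0

#: Slice thickness (mm) above which input volumes trigger a resolution warning.
MAX_RECOMMENDED_SLICE_MM = 1.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CTVolume:
    """A scalar CT volume in Hounsfield units on a regular axis-aligned grid.

    Parameters
    ----------
    voxels
        3D array of HU values, indexed ``[x, y, z]``.
    spacing
        Voxel size in mm per axis.
    origin
        Physical coordinate (mm) of the corner of voxel ``(0, 0, 0)``; the
        voxel's center sits at ``origin + spacing / 2``.
    orientation
        Axis orientation descriptor (informational).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("CT volume must be a non-empty 3D grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if self.spacing[2] > MAX_RECOMMENDED_SLICE_MM:
            warnings.warn(
                f"slice thickness {self.spacing[2]:.2f} mm exceeds the "
                f"recommended {MAX_RECOMMENDED_SLICE_MM:.0f} mm for articular "
                "fracture assessment",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelMask:
    """Integer fragment labels (0 = background) on the same grid as a CTVolume."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.labels.ndim != 3:
            raise ValueError("label mask must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label mask must be integer-typed")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def label_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(v) for v in ids if v > 0]

    def binarize(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class FragmentMesh:
    """A closed triangle mesh (mm coordinates) for one labeled fracture fragment."""

    mesh: trimesh.Trimesh
    fragment_id: int

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices

    @property
    def triangles(self) -> np.ndarray:
        return self.mesh.faces

    @property
    def area(self) -> float:
        return float(self.mesh.area)

    @property
    def volume(self) -> float:
        return float(abs(self.mesh.volume))

    @property
    def watertight(self) -> bool:
        return bool(self.mesh.is_watertight)


# ---------------------------------------------------------------------------
# volume IO
# ---------------------------------------------------------------------------

def load_volume(path: str | Path) -> CTVolume:
    """Load a CT volume from NIfTI (.nii/.nii.gz) or a DICOM series directory."""
    path = Path(path)
    if path.is_dir():
        return _load_dicom_series(path)
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(data, tuple(float(z) for z in zooms), origin)


def _load_dicom_series(directory: Path) -> CTVolume:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise ValueError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    # SimpleITK arrays come back [z, y, x]; transpose to [x, y, z].
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float32)
    return CTVolume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def load_label_mask(path: str | Path) -> LabelMask:
    """Load an integer fragment-label mask from NIfTI."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise ValueError("label mask contains non-integer values")
        data = rounded.astype(np.int32)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return LabelMask(data.astype(np.int32), tuple(float(z) for z in zooms), origin)


def save_nifti(data: np.ndarray, spacing: Sequence[float],
               origin: Sequence[float], path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def threshold_bone(volume: CTVolume,
                   hu_threshold: float = DEFAULT_HU_THRESHOLD) -> LabelMask:
    """Binary bone mask: voxels strictly above ``hu_threshold`` HU.

    Cortical bone sits far above soft tissue on the Hounsfield scale, so a
    single global threshold isolates the skeleton; the strict inequality
    means a voxel at exactly the threshold is background.
    """
    fg = volume.voxels > hu_threshold
    if not fg.any():
        warnings.warn("no bone voxels above threshold", stacklevel=2)
    return LabelMask(fg.astype(np.int32), volume.spacing, volume.origin)


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def region_grow(mask: LabelMask,
                seeds: Sequence[Sequence[int]]) -> LabelMask:
    """Keep only the 26-connected components that contain a seed.

    Seeds landing in the same component collapse onto one label; output
    labels are contiguous ``1..F`` in order of first seed. Used to strip
    isolated noise voxels and bones adjacent to the radius.
    """
    seeds = [tuple(int(c) for c in s) for s in seeds]
    fg = mask.binarize()
    for s in seeds:
        if not fg[s]:
            raise ValueError(f"seed {s} is not on a foreground voxel")
    comps, _ = ndimage.label(fg, structure=_CONN26)
    out = np.zeros_like(comps, dtype=np.int32)
    next_label = 1
    comp_to_label: dict[int, int] = {}
    for s in seeds:
        cid = int(comps[s])
        if cid not in comp_to_label:
            comp_to_label[cid] = next_label
            next_label += 1
    for cid, lab in comp_to_label.items():
        out[comps == cid] = lab
    return LabelMask(out, mask.spacing, mask.origin)


def split_fragments(mask: LabelMask,
                    seeds: Sequence[Sequence[Sequence[int]]]) -> LabelMask:
    """Partition foreground into fragments from per-fragment seed groups.

    ``seeds`` is one voxel-coordinate list per fragment. Connected
    components holding exactly one seed group (fragments already separated
    by the fracture gap) go to that group wholesale; components contested
    by several groups -- fragments still touching along the fracture -- are
    divided by distance-transform watershed, so every voxel joins the group
    whose seeds are nearest. Supplying a full label mask upstream bypasses
    this entirely.
    """
    if len(seeds) < 2:
        raise ValueError("split_fragments needs at least 2 seed groups")
    fg = mask.binarize()
    markers = np.zeros(mask.shape, dtype=np.int32)
    for gi, group in enumerate(seeds, start=1):
        for s in group:
            s = tuple(int(c) for c in s)
            if not fg[s]:
                raise ValueError(f"seed {s} is not on a foreground voxel")
            markers[s] = gi

    comps, _ = ndimage.label(fg, structure=_CONN26)
    labels = np.zeros(mask.shape, dtype=np.int32)
    contested: list[int] = []
    for cid in range(1, comps.max() + 1):
        inside = comps == cid
        groups = np.unique(markers[inside])
        groups = groups[groups > 0]
        if len(groups) == 1:
            labels[inside] = groups[0]
        elif len(groups) > 1:
            contested.append(cid)
    if contested:
        # nearest-seed-group partition: each group's Euclidean distance
        # field decides, flooded as a watershed of the minimum field
        dists = np.full((len(seeds),) + mask.shape, np.inf)
        for gi in range(1, len(seeds) + 1):
            if not (markers == gi).any():
                continue
            dists[gi - 1] = ndimage.distance_transform_edt(
                markers != gi, sampling=mask.spacing)
        nearest = np.argmin(dists, axis=0).astype(np.int32) + 1
        for cid in contested:
            inside = comps == cid
            labels[inside] = nearest[inside]
    # any seedless component joins its globally nearest seed group
    orphan = fg & (labels == 0)
    if orphan.any():
        dists = np.stack([
            ndimage.distance_transform_edt(markers != gi,
                                           sampling=mask.spacing)
            for gi in range(1, len(seeds) + 1)])
        nearest = np.argmin(dists, axis=0).astype(np.int32) + 1
        labels[orphan] = nearest[orphan]
    for gi in range(1, len(seeds) + 1):
        if not (labels == gi).any():
            raise ValueError(f"seed group {gi} produced an empty region")
    return LabelMask(labels, mask.spacing, mask.origin)


def mesh_fragment(mask: LabelMask, label: int,
                  smooth: bool = False) -> FragmentMesh:
    """Isosurface one fragment label into a watertight mm-coordinate mesh.

    Marching cubes at the 0.5 level of the binary label, vertices scaled by
    the voxel spacing and shifted so they live in the volume's physical
    space. No smoothing by default: smoothing shrinks surface area and would
    bias the gap-area metric; an optional Taubin pass is available for
    visualization exports.
    """
    if label not in mask.label_ids:
        raise ValueError(f"label {label} not present in mask")
    binary = (mask.labels == label).astype(np.uint8)
    padded = np.pad(binary, 1)
    sp = np.asarray(mask.spacing, dtype=float)
    verts, faces, _, _ = _skmeasure.marching_cubes(padded, level=0.5, spacing=tuple(sp))
    # padded sample i sits at i*spacing; our voxel i center is origin+(i+0.5)*s
    verts = verts + np.asarray(mask.origin) - 0.5 * sp
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    if smooth:
        trimesh.smoothing.filter_taubin(mesh)
    out = FragmentMesh(mesh=mesh, fragment_id=int(label))
    if not out.watertight:
        logger.warning("fragment %d mesh is not watertight", label)
    return out


def mesh_all_fragments(mask: LabelMask, smooth: bool = False) -> list[FragmentMesh]:
    return [mesh_fragment(mask, lab, smooth=smooth) for lab in mask.label_ids]
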