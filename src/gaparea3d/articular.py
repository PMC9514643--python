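"""Marking the distal radial articular surface on fragment meshes.

In the manual workflow an observer paints the cartilage-bearing joint
surface on each 3D fragment; fragments carrying part of it are
intra-articular, the rest extra-articular. Here the marking comes from a
proxy: an explicit face list, a binary ROI volume (faces whose centroid
falls inside), or a fitted sphere (faces near the sphere whose outward
normal points away from its center -- a good model for the gently concave
carpal-facing surface).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .segmentation import FragmentMesh, LabelMask

logger = logging.getLogger("gaparea3d")

#: Minimum marked area (mm^2) for a fragment to count as intra-articular.
DEFAULT_MIN_AREA_MM2 = 5.0


@dataclass
class RoiMask:
    """Binary region-of-interest volume on a regular grid (mm geometry).

    If ``direction`` is set, face selection additionally requires the face
    normal to satisfy ``normal . direction >= min_cos`` -- the articular
    surface faces the carpus, so an orientation gate cleanly rejects side
    walls and fracture surfaces whose centroids graze the ROI.
    """

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] | None = None
    min_cos: float = 0.3

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership test for mm-coordinate ``points`` (N, 3)."""
        idx = np.floor((np.asarray(points) - np.asarray(self.origin))
                       / np.asarray(self.spacing)).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(self.mask.shape)), axis=1)
        out = np.zeros(len(points), dtype=bool)
        if ok.any():
            ii = idx[ok]
            out[ok] = self.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


@dataclass
class FittedSphere:
    """Sphere proxy: faces within ``tolerance`` mm of the sphere surface."""

    center: tuple[float, float, float]
    radius: float
    tolerance: float = 1.0


@dataclass
class ArticularProxy:
    """One of: explicit per-fragment face lists, an ROI volume, or a sphere."""

    kind: str  # "face_list" | "roi_mask" | "fitted_sphere"
    face_lists: dict[int, list[int]] | None = None
    roi: RoiMask | None = None
    sphere: FittedSphere | None = None

    def __post_init__(self) -> None:
        payloads = {"face_list": self.face_lists, "roi_mask": self.roi,
                    "fitted_sphere": self.sphere}
        if self.kind not in payloads:
            raise ValueError(f"unknown proxy kind {self.kind!r}")
        if payloads[self.kind] is None:
            raise ValueError(f"proxy kind {self.kind!r} has no payload")
        if sum(p is not None for p in payloads.values()) != 1:
            raise ValueError("exactly one proxy payload must be populated")


@dataclass
class ArticularPatch:
    """The marked articular faces of one fragment mesh."""

    fragment_id: int
    mesh: FragmentMesh
    faces: np.ndarray  # indices into mesh.triangles
    patch_area: float
    classification: str  # "intra" | "extra"
    n_components: int = 0

    @property
    def is_intra(self) -> bool:
        return self.classification == "intra"


# ---------------------------------------------------------------------------
# proxies from volumes
# ---------------------------------------------------------------------------

def top_surface_roi(mask: LabelMask, axis: int = 2) -> RoiMask:
    """ROI covering the top-exposed surface of every fragment.

    For each grid column along ``axis``, the highest foreground voxel and
    the background voxel directly above it are included. On a phantom whose
    articular surface faces +axis this captures exactly the articular faces
    (including the half-voxel chamfer ring that marching cubes places on
    sharp edges) while excluding side walls and fracture surfaces.
    """
    lab = np.moveaxis(mask.labels, axis, -1)
    fg = lab > 0
    roi = np.zeros_like(fg)
    has = fg.any(axis=-1)
    # index of highest foreground voxel per column
    top = fg.shape[-1] - 1 - np.argmax(fg[..., ::-1], axis=-1)
    ii, jj = np.nonzero(has)
    tt = top[ii, jj]
    roi[ii, jj, tt] = True
    roi[ii, jj, np.minimum(tt + 1, fg.shape[-1] - 1)] = True
    direction = [0.0, 0.0, 0.0]
    direction[axis] = 1.0
    return RoiMask(np.moveaxis(roi, -1, axis), mask.spacing, mask.origin,
                   direction=tuple(direction))


def load_proxy(path: str | Path, mask: LabelMask | None = None) -> ArticularProxy:
    """Read a proxy description from JSON.

    ``face_list``: ``{"kind": "face_list", "faces": {"<frag>": [i, ...]}}``;
    ``fitted_sphere``: center/radius/tolerance fields;
    ``roi_mask``: ``{"kind": "roi_mask", "path": "roi.nii.gz"}`` or
    ``{"kind": "roi_mask", "top_surface": true}`` (requires ``mask``).
    """
    with open(path) as fh:
        spec = json.load(fh)
    kind = spec["kind"]
    if kind == "face_list":
        faces = {int(k): list(map(int, v)) for k, v in spec["faces"].items()}
        return ArticularProxy(kind="face_list", face_lists=faces)
    if kind == "fitted_sphere":
        return ArticularProxy(kind="fitted_sphere", sphere=FittedSphere(
            center=tuple(spec["center"]), radius=float(spec["radius"]),
            tolerance=float(spec.get("tolerance", 1.0))))
    if kind == "roi_mask":
        if spec.get("top_surface"):
            if mask is None:
                raise ValueError("top_surface ROI proxy needs a label mask")
            return ArticularProxy(kind="roi_mask", roi=top_surface_roi(mask))
        from .segmentation import load_label_mask
        roi_lm = load_label_mask(spec["path"])
        return ArticularProxy(kind="roi_mask", roi=RoiMask(
            roi_lm.labels > 0, roi_lm.spacing, roi_lm.origin))
    raise ValueError(f"unknown proxy kind {kind!r}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def mark_articular(mesh: FragmentMesh, proxy: ArticularProxy,
                   min_area: float = DEFAULT_MIN_AREA_MM2) -> ArticularPatch:
    """Select the articular faces of one fragment and classify it.

    ROI membership is tested at the triangle centroid (not its vertices) so
    boundary triangles are assigned deterministically. An empty selection,
    or one below ``min_area``, classifies the fragment extra-articular.
    """
    tm = mesh.mesh
    centroids = tm.triangles_center
    if proxy.kind == "face_list":
        wanted = proxy.face_lists.get(mesh.fragment_id, [])
        faces = np.asarray(sorted(set(int(i) for i in wanted)), dtype=int)
        if faces.size and (faces.min() < 0 or faces.max() >= len(tm.faces)):
            raise IndexError(
                f"face index out of range for fragment {mesh.fragment_id}")
    elif proxy.kind == "roi_mask":
        sel = proxy.roi.contains(centroids)
        if proxy.roi.direction is not None:
            d = np.asarray(proxy.roi.direction, dtype=float)
            d = d / np.linalg.norm(d)
            sel &= (tm.face_normals @ d) >= proxy.roi.min_cos
        faces = np.nonzero(sel)[0]
    else:  # fitted_sphere
        sph = proxy.sphere
        c = np.asarray(sph.center, dtype=float)
        dist = np.linalg.norm(centroids - c, axis=1)
        near = np.abs(dist - sph.radius) <= sph.tolerance
        outward = np.einsum("ij,ij->i", tm.face_normals, centroids - c) > 0
        faces = np.nonzero(near & outward)[0]

    area = float(tm.area_faces[faces].sum()) if faces.size else 0.0
    n_comp = _count_face_components(tm, faces) if faces.size else 0
    patch = ArticularPatch(
        fragment_id=mesh.fragment_id, mesh=mesh, faces=faces,
        patch_area=area,
        classification=classify_fragment_area(area, min_area),
        n_components=n_comp)
    if n_comp > 3:
        logger.warning("articular patch of fragment %d has %d components",
                       mesh.fragment_id, n_comp)
    return patch


def _count_face_components(tm, faces: np.ndarray) -> int:
    """Connected components of a face subset via shared edges."""
    sub = tm.submesh([faces], append=True)
    return len(sub.split(only_watertight=False))


def classify_fragment_area(patch_area: float,
                           min_area: float = DEFAULT_MIN_AREA_MM2) -> str:
    """``intra`` iff the marked area reaches ``min_area`` mm^2."""
    return "intra" if patch_area >= min_area else "extra"


def classify_fragment(patch: ArticularPatch,
                      min_area: float = DEFAULT_MIN_AREA_MM2) -> str:
    return classify_fragment_area(patch.patch_area, min_area)


def mark_all(meshes: list[FragmentMesh], proxy: ArticularProxy,
             min_area: float = DEFAULT_MIN_AREA_MM2) -> list[ArticularPatch]:
    return [mark_articular(m, proxy, min_area=min_area) for m in meshes]
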