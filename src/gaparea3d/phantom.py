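"""Synthetic fractured-articular-surface phantoms with analytic ground truth.

A phantom is an idealized distal-radius articular block: either a flat
rectangular plate (the analytic workhorse -- its articular surface is the
flat top face) or a spherical cap (exercises curvature). Oriented cut
planes slice it into fragments, each of which may be rigidly displaced.
The phantom is voxelized into an HU volume plus a fragment label mask, and
the expected gap areas / step-offs are computed in closed form, so every
downstream stage can be validated without any patient data.

For a straight cut whose articular edge has length ``L`` and whose two
fragments are separated by a pure relative translation ``t``, the minimal
ruled surface between the two displaced copies of the edge is a
parallelogram of area ``L * ||t_perp||`` where ``t_perp`` is the component
of ``t`` perpendicular to the edge direction. Ground truth is exact for
per-fragment translations; for nonzero rotations the analytic gap fields
are ``None``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon, box as _shapely_box

from .segmentation import CTVolume, LabelMask

logger = logging.getLogger("gaparea3d")

#: HU value assigned to bone voxels; comfortably above the 225 HU threshold.
BONE_HU = 700.0
#: HU value assigned to background (air) voxels.
BACKGROUND_HU = -1000.0

_BIG = 1e4  # half-plane clipping extent, mm


@dataclass(frozen=True)
class CutPlane:
    """An oriented fracture plane: point ``origin`` and unit ``normal`` (mm)."""

    origin: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("cut plane normal must be non-zero")
        object.__setattr__(self, "normal", tuple(n / nn))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - np.asarray(self.origin)) @ np.asarray(self.normal)


@dataclass(frozen=True)
class RigidDisplacement:
    """Rigid transform of one fragment: translation plus optional rotation.

    Rotation is ``rotation_deg`` degrees about the axis through
    ``rotation_center`` (fragment centroid if None) along ``rotation_axis``.
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: float = 0.0
    rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rotation_center: tuple[float, float, float] | None = None

    @property
    def is_pure_translation(self) -> bool:
        return self.rotation_deg == 0.0

    def matrix(self, default_center: np.ndarray) -> np.ndarray:
        """4x4 homogeneous transform."""
        t = np.asarray(self.translation, dtype=float)
        m = np.eye(4)
        if self.rotation_deg != 0.0:
            axis = np.asarray(self.rotation_axis, dtype=float)
            axis = axis / np.linalg.norm(axis)
            c = (np.asarray(self.rotation_center, dtype=float)
                 if self.rotation_center is not None else np.asarray(default_center))
            th = np.deg2rad(self.rotation_deg)
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
            m[:3, :3] = R
            m[:3, 3] = c - R @ c + t
        else:
            m[:3, 3] = t
        return m


@dataclass
class PhantomSpec:
    """Geometry, fracture pattern and imaging parameters of one phantom.

    Exactly one of ``plate_dims`` (W, D, T in mm) or ``cap_radius`` must be
    set. Fragments are the non-empty sign-regions of the cut arrangement,
    labeled 1..F in lexicographic order of their sign vectors (the negative
    side of each cut first); ``displacements`` is indexed in that order.
    """

    plate_dims: tuple[float, float, float] | None = None
    cap_radius: float | None = None
    cap_height: float | None = None
    cuts: list[CutPlane] = field(default_factory=list)
    displacements: list[RigidDisplacement] = field(default_factory=list)
    spacing: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.plate_dims is None) == (self.cap_radius is None):
            raise ValueError("set exactly one of plate_dims or cap_radius")
        if self.plate_dims is not None:
            if any(d <= 0 for d in self.plate_dims):
                raise ValueError("plate dimensions must be positive")
        else:
            if self.cap_radius <= 0:
                raise ValueError("cap radius must be positive")
            if self.cap_height is None:
                self.cap_height = 0.5 * self.cap_radius
            if not 0 < self.cap_height <= self.cap_radius:
                raise ValueError("cap height must lie in (0, radius]")
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        self.cuts = [c if isinstance(c, CutPlane) else CutPlane(**c) for c in self.cuts]
        self.displacements = [
            d if isinstance(d, RigidDisplacement) else RigidDisplacement(**d)
            for d in self.displacements
        ]

    # -- geometry helpers ---------------------------------------------------

    @property
    def top_z(self) -> float:
        """Height of the articular surface (plate top / cap apex), mm."""
        if self.plate_dims is not None:
            return float(self.plate_dims[2])
        return float(self.cap_height)

    def _base_footprint(self) -> Polygon:
        if self.plate_dims is not None:
            return _shapely_box(0.0, 0.0, self.plate_dims[0], self.plate_dims[1])
        # cap footprint at its base circle (z = 0 plane of the cap solid)
        r_base = np.sqrt(self.cap_radius**2
                         - (self.cap_radius - self.cap_height) ** 2)
        from shapely.geometry import Point
        return Point(0.0, 0.0).buffer(float(r_base), quad_segs=128)

    def _cut_halfplane_2d(self, cut: CutPlane, sign: int) -> Polygon:
        """The 2D half-plane induced by a cut at the articular level."""
        n = np.asarray(cut.normal)
        nz_inplane = np.linalg.norm(n[:2])
        if nz_inplane < 1e-9:
            raise ValueError("cut plane is parallel to the articular surface")
        # line on the z = top_z plane: (p - o).n = 0 with p_z fixed
        o = np.asarray(cut.origin)
        n2 = n[:2] / nz_inplane
        # shift of the line due to the z offset of the evaluation plane
        offset = (n[2] * (self.top_z - o[2])) / nz_inplane
        line_pt = o[:2] - offset * n2
        d = np.array([-n2[1], n2[0]])
        half = Polygon([
            line_pt + _BIG * d,
            line_pt - _BIG * d,
            line_pt - _BIG * d + sign * _BIG * n2,
            line_pt + _BIG * d + sign * _BIG * n2,
        ])
        return half

    def fragment_sign_vectors(self) -> list[tuple[int, ...]]:
        """Non-empty fragment regions as cut-plane sign vectors, label order."""
        base = self._base_footprint()
        out = []
        for signs in itertools.product((-1, 1), repeat=len(self.cuts)):
            poly = base
            for cut, s in zip(self.cuts, signs):
                poly = poly.intersection(self._cut_halfplane_2d(cut, s))
            if poly.area > 1e-6:
                out.append(signs)
        if not out:
            out = [()] if not self.cuts else out
        return out

    def fragment_footprints(self) -> list[Polygon]:
        base = self._base_footprint()
        polys = []
        for signs in self.fragment_sign_vectors():
            poly = base
            for cut, s in zip(self.cuts, signs):
                poly = poly.intersection(self._cut_halfplane_2d(cut, s))
            polys.append(poly)
        return polys

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_sign_vectors())

    def validate(self) -> None:
        base = self._base_footprint()
        for i, cut in enumerate(self.cuts):
            n2 = np.linalg.norm(np.asarray(cut.normal)[:2])
            if n2 < 1e-9:
                raise ValueError(f"cut {i} is parallel to the articular surface")
            line = self._cut_line_2d(cut)
            if not line.intersects(base.buffer(-1e-9)):
                raise ValueError(f"cut {i} misses the phantom")
        nfrag = self.n_fragments
        if self.displacements and len(self.displacements) != nfrag:
            raise ValueError(
                f"{len(self.displacements)} displacements given for {nfrag} fragments")

    def _cut_line_2d(self, cut: CutPlane) -> LineString:
        n = np.asarray(cut.normal)
        n2 = n[:2] / np.linalg.norm(n[:2])
        o = np.asarray(cut.origin)
        offset = (n[2] * (self.top_z - o[2])) / np.linalg.norm(n[:2])
        line_pt = o[:2] - offset * n2
        d = np.array([-n2[1], n2[0]])
        return LineString([line_pt - _BIG * d, line_pt + _BIG * d])

    @property
    def articular_area(self) -> float:
        """Analytic intact articular surface area, mm^2."""
        if self.plate_dims is not None:
            return float(self.plate_dims[0] * self.plate_dims[1])
        return float(2.0 * np.pi * self.cap_radius * self.cap_height)


@dataclass
class GroundTruth:
    """Analytic expectations for a phantom: gap areas, maxima, labels."""

    expected_gap_area_per_cut: list[float | None]
    expected_gap_area_total: float | None
    expected_max_gap: float | None
    expected_max_stepoff: float | None
    fragment_labels: list[int]
    articular_area: float
    fragment_volumes: list[float] | None = None


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------

def _interface_segments(spec: PhantomSpec):
    """Articular-edge interface segments between fragment pairs.

    Yields ``(cut_index, label_a, label_b, length, direction_3d)`` for every
    pair of fragments whose sign vectors differ in exactly one cut and whose
    undisplaced footprints share a boundary segment at that cut.
    """
    signs = spec.fragment_sign_vectors()
    polys = spec.fragment_footprints()
    for (ia, sa), (ib, sb) in itertools.combinations(enumerate(signs), 2):
        diff = [k for k in range(len(spec.cuts)) if sa[k] != sb[k]]
        if len(diff) != 1:
            continue
        cut_idx = diff[0]
        line2 = spec._cut_line_2d(spec.cuts[cut_idx])
        d2 = np.asarray(line2.coords[1]) - np.asarray(line2.coords[0])
        d2 = d2 / np.linalg.norm(d2)
        direction = np.array([d2[0], d2[1], 0.0])
        # interface = overlap of the two footprints' extents along the cut line
        proj_a = _projected_interval(polys[ia], line2)
        proj_b = _projected_interval(polys[ib], line2)
        lo = max(proj_a[0], proj_b[0])
        hi = min(proj_a[1], proj_b[1])
        if hi - lo < 1e-6:
            continue
        yield cut_idx, ia + 1, ib + 1, float(hi - lo), direction


def _projected_interval(poly: Polygon, line: LineString) -> tuple[float, float]:
    p0 = np.asarray(line.coords[0])
    d = np.asarray(line.coords[1]) - p0
    d = d / np.linalg.norm(d)
    pts = np.asarray(poly.exterior.coords)
    proj = (pts - p0) @ d
    # only boundary points actually on the cut line bound the interface
    rel = pts - p0
    dist = np.abs(d[0] * rel[:, 1] - d[1] * rel[:, 0])
    on_line = dist < 1e-6
    if on_line.sum() >= 2:
        return float(proj[on_line].min()), float(proj[on_line].max())
    return float(proj.min()), float(proj.max())


def compute_ground_truth(spec: PhantomSpec,
                         fragment_volumes: list[float] | None = None) -> GroundTruth:
    """Closed-form expected gap areas and displacement maxima.

    Exact for per-fragment translations; with any rotation present the gap
    fields are ``None`` (no closed form is claimed).
    """
    labels = list(range(1, spec.n_fragments + 1))
    disps = spec.displacements or [RigidDisplacement() for _ in labels]
    if any(not d.is_pure_translation for d in disps):
        return GroundTruth([None] * len(spec.cuts), None, None, None, labels,
                           spec.articular_area, fragment_volumes)
    per_cut = [0.0] * len(spec.cuts)
    max_gap = 0.0
    max_step = 0.0
    for cut_idx, la, lb, length, u in _interface_segments(spec):
        t_rel = (np.asarray(disps[la - 1].translation, dtype=float)
                 - np.asarray(disps[lb - 1].translation, dtype=float))
        t_perp = t_rel - (t_rel @ u) * u
        per_cut[cut_idx] += length * float(np.linalg.norm(t_perp))
        inplane = t_perp.copy()
        inplane[2] = 0.0
        max_gap = max(max_gap, float(np.linalg.norm(inplane)))
        max_step = max(max_step, abs(float(t_rel[2])))
    return GroundTruth(per_cut, float(sum(per_cut)), max_gap, max_step,
                       labels, spec.articular_area, fragment_volumes)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def _fragment_membership(spec: PhantomSpec, signs: tuple[int, ...],
                         points: np.ndarray) -> np.ndarray:
    """Inside-test for the undisplaced fragment region at mm ``points``."""
    if spec.plate_dims is not None:
        W, D, T = spec.plate_dims
        inside = ((points[:, 0] >= 0) & (points[:, 0] <= W)
                  & (points[:, 1] >= 0) & (points[:, 1] <= D)
                  & (points[:, 2] >= 0) & (points[:, 2] <= T))
    else:
        R, h = spec.cap_radius, spec.cap_height
        center = np.array([0.0, 0.0, h - R])
        inside = (np.linalg.norm(points - center, axis=1) <= R) & (points[:, 2] >= 0)
    for cut, s in zip(spec.cuts, signs):
        sd = cut.signed_distance(points)
        inside &= (sd >= 0) if s > 0 else (sd < 0)
    return inside


def make_fracture_phantom(spec: PhantomSpec
                          ) -> tuple[CTVolume, LabelMask, GroundTruth]:
    """Voxelize a phantom into an HU volume, label mask and ground truth.

    Bone voxels get ~700 HU (cortical-bone contrast, cleanly above the
    225 HU segmentation threshold), background -1000 HU, plus optional
    Gaussian noise. Fragments that would interpenetrate after displacement
    raise an error.
    """
    spec.validate()
    signs_list = spec.fragment_sign_vectors()
    disps = spec.displacements or [RigidDisplacement() for _ in signs_list]
    s = spec.spacing

    # base solid bounding box
    if spec.plate_dims is not None:
        lo = np.zeros(3)
        hi = np.asarray(spec.plate_dims, dtype=float)
    else:
        r_base = np.sqrt(spec.cap_radius**2
                         - (spec.cap_radius - spec.cap_height) ** 2)
        lo = np.array([-r_base, -r_base, 0.0])
        hi = np.array([r_base, r_base, spec.cap_height])
    corners = np.array(list(itertools.product(*zip(lo, hi))))
    center0 = 0.5 * (lo + hi)
    all_pts = []
    mats = []
    for d in disps:
        m = d.matrix(default_center=center0)
        mats.append(m)
        pc = (m[:3, :3] @ corners.T).T + m[:3, 3]
        all_pts.append(pc)
    all_pts = np.vstack(all_pts)
    margin = 3 * s
    gmin = np.floor((all_pts.min(axis=0) - margin) / s) * s
    gmax = np.ceil((all_pts.max(axis=0) + margin) / s) * s
    shape = np.maximum(np.round((gmax - gmin) / s).astype(int), 1)

    idx = np.indices(shape).reshape(3, -1).T
    centers = gmin + (idx + 0.5) * s

    labels = np.zeros(shape, dtype=np.int32)
    flat = labels.reshape(-1)
    for f, (signs, m) in enumerate(zip(signs_list, mats), start=1):
        inv = np.linalg.inv(m)
        local = (inv[:3, :3] @ centers.T).T + inv[:3, 3]
        inside = _fragment_membership(spec, signs, local)
        clash = inside & (flat > 0)
        if clash.any():
            raise ValueError("fragments interpenetrate")
        flat[inside] = f
    labels = flat.reshape(shape)

    rng = np.random.default_rng(spec.seed)
    hu = np.where(labels > 0, BONE_HU, BACKGROUND_HU).astype(np.float32)
    if spec.noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape).astype(np.float32)

    spacing3 = (s, s, s)
    origin = tuple(float(v) for v in gmin)
    vol = CTVolume(hu, spacing3, origin)
    mask = LabelMask(labels, spacing3, origin)

    vols = None
    if spec.plate_dims is not None:
        T = spec.plate_dims[2]
        vols = [p.area * T for p in spec.fragment_footprints()]
    truth = compute_ground_truth(spec, fragment_volumes=vols)
    return vol, mask, truth


# ---------------------------------------------------------------------------
# observer-table simulation
# ---------------------------------------------------------------------------

def simulate_observer_table(n_cases: int, n_observers: int,
                            subject_sd: float, observer_bias_sd: float,
                            error_sd: float, seed: int,
                            mean: float = 50.0, kind: str = "gap_area_mm2"):
    """Two-way crossed measurement table with known variance components.

    ``y_ij = mean + subject_i + observer_j + e_ij`` with independent
    zero-mean Gaussian components. The generative intraclass correlation
    ``subject_sd^2 / (subject_sd^2 + observer_bias_sd^2 + error_sd^2)`` is
    recorded on the returned table, so reliability estimators can be
    validated by parameter recovery.
    """
    from .agreement import ObserverTable

    if n_cases < 2 or n_observers < 2:
        raise ValueError("need at least 2 cases and 2 observers")
    for name, sd in (("subject_sd", subject_sd),
                     ("observer_bias_sd", observer_bias_sd),
                     ("error_sd", error_sd)):
        if sd < 0:
            raise ValueError(f"{name} must be non-negative")
    rng = np.random.default_rng(seed)
    subj = rng.normal(0.0, subject_sd, size=n_cases)
    obs = rng.normal(0.0, observer_bias_sd, size=n_observers)
    eps = rng.normal(0.0, error_sd, size=(n_cases, n_observers))
    values = mean + subj[:, None] + obs[None, :] + eps

    import pandas as pd

    df = pd.DataFrame(values,
                      index=pd.RangeIndex(1, n_cases + 1, name="case_id"),
                      columns=[f"observer_{j + 1}" for j in range(n_observers)])
    total_var = subject_sd**2 + observer_bias_sd**2 + error_sd**2
    gen_icc = subject_sd**2 / total_var if total_var > 0 else float("nan")
    return ObserverTable(data=df, kind=kind, generative_icc=float(gen_icc))
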