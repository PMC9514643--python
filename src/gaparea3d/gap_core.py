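"""3D gap-area computation between articular fracture lines.

The displacement metric is the total area (mm^2) of the surface spanning
the fracture lines of opposing intra-articular fragments:

1. the boundary of each fragment's articular patch is chained into
   contours; boundary edges lying close to another fragment's patch
   boundary are fracture edges, the rest is peripheral rim;
2. maximal runs of fracture edges become fracture lines (open polylines);
3. fracture lines of distinct fragments are matched greedily by symmetric
   mean closest-point distance;
4. each matched pair is stitched with the minimal-area monotone
   triangulation (dynamic programming over the advance lattice -- the
   classic two-contour surface-from-planar-contours construction);
5. per-pair areas are summed into the case total.

Both lines are resampled to a uniform <=0.5 mm step before stitching, so
the area is insensitive to mesh tessellation density, and the whole
computation is invariant under rigid motion of the assembly.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .articular import ArticularPatch

logger = logging.getLogger("gaparea3d")

#: Max distance (mm) from a boundary-edge midpoint to another fragment's
#: patch boundary for the edge to count as a fracture edge rather than rim.
DEFAULT_FRACTURE_TOL_MM = 3.0

#: Max symmetric mean gap (mm) for two fracture lines to be paired.
DEFAULT_MATCH_LIMIT_MM = 10.0

#: Resampling step (mm) applied to polylines before distance/DP evaluation.
RESAMPLE_STEP_MM = 0.5

#: Fracture lines shorter than this (mm) are sub-voxel slivers left over at
#: fragment junctions and are discarded.
MIN_LINE_LENGTH_MM = 1.0

#: Minimum cosine between a boundary edge's outward normal and the direction
#: to the opposing boundary for the edge to count as facing that fragment.
#: Facing edges score near 1, lateral (rim) edges near 0; corner chamfers
#: produced by voxelization land around 0.5.
FACING_MIN_COS = 0.25


@dataclass
class FractureLine:
    """Ordered open polyline along a fracture edge of an articular patch."""

    fragment_id: int
    points: np.ndarray  # (N, 3) mm
    index: int = 0  # per-fragment line index, for deterministic tie-breaks

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValueError("fracture line needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if (seg == 0).any():
            keep = np.r_[True, seg > 0]
            self.points = self.points[keep]
        if self.points.shape[0] < 2:
            raise ValueError("fracture line degenerates to a point")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class CurvePair:
    """Two matched fracture lines from distinct fragments."""

    line_a: FractureLine
    line_b: FractureLine
    mean_gap: float

    def __post_init__(self) -> None:
        if self.line_a.fragment_id == self.line_b.fragment_id:
            raise ValueError("matched lines must come from distinct fragments")


@dataclass
class GapSurface:
    """Triangulated surface spanning one CurvePair."""

    pair: CurvePair
    triangles: np.ndarray  # (M, 3, 3) mm vertex coordinates
    area: float


@dataclass
class GapAreaResult:
    """Per-case 3D gap-area summary."""

    case_id: str
    observer_id: str
    surfaces: list[GapSurface]
    unmatched: list[FractureLine] = field(default_factory=list)

    @property
    def per_pair_areas(self) -> list[float]:
        return [s.area for s in self.surfaces]

    @property
    def total_area(self) -> float:
        return float(sum(self.per_pair_areas))

    @property
    def no_displacement(self) -> bool:
        return len(self.surfaces) == 0


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def resample_polyline(points: np.ndarray,
                      step: float = RESAMPLE_STEP_MM) -> np.ndarray:
    """Resample to uniform arc-length spacing <= ``step``, keeping endpoints."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = seg.sum()
    if total == 0:
        return points[:1].repeat(2, axis=0)
    n = max(int(np.ceil(total / step)), 1)
    t_target = np.linspace(0.0, total, n + 1)
    t_orig = np.r_[0.0, np.cumsum(seg)]
    out = np.empty((n + 1, 3))
    for k in range(3):
        out[:, k] = np.interp(t_target, t_orig, points[:, k])
    return out


def _nearest_on_segments(points: np.ndarray, segs_a: np.ndarray,
                         segs_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance and closest point from each point to a set of segments."""
    d = segs_b - segs_a  # (S, 3)
    L2 = np.einsum("ij,ij->i", d, d)
    L2 = np.where(L2 == 0, 1.0, L2)
    # (P, S, 3) differences
    w = points[:, None, :] - segs_a[None, :, :]
    t = np.clip(np.einsum("psk,sk->ps", w, d) / L2, 0.0, 1.0)
    proj = segs_a[None, :, :] + t[..., None] * d[None, :, :]
    dist = np.linalg.norm(points[:, None, :] - proj, axis=2)
    best = dist.argmin(axis=1)
    rows = np.arange(len(points))
    return dist[rows, best], proj[rows, best]


def _point_to_segments_dist(points: np.ndarray, segs_a: np.ndarray,
                            segs_b: np.ndarray) -> np.ndarray:
    """Min distance from each point to a set of segments (vectorized)."""
    return _nearest_on_segments(points, segs_a, segs_b)[0]


def polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Distance from each of ``points`` to an (N, 3) polyline."""
    return _point_to_segments_dist(np.asarray(points, float),
                                   polyline[:-1], polyline[1:])


def mean_closest_distance(line_a: FractureLine, line_b: FractureLine,
                          step: float = RESAMPLE_STEP_MM) -> float:
    """Symmetric mean closest-point distance between two polylines (mm)."""
    pa = resample_polyline(line_a.points, step)
    pb = resample_polyline(line_b.points, step)
    d_ab = polyline_distance(pa, pb).mean()
    d_ba = polyline_distance(pb, pa).mean()
    return float(0.5 * (d_ab + d_ba))


# ---------------------------------------------------------------------------
# fracture-line extraction
# ---------------------------------------------------------------------------

def patch_boundary_loops(patch: ArticularPatch) -> list[np.ndarray]:
    """Ordered vertex-index loops of the patch boundary.

    A boundary edge is incident to exactly one selected face. Loops are
    walked deterministically (lowest vertex index first); open chains can
    occur on non-manifold slivers and are returned as-is.
    """
    tm = patch.mesh.mesh
    faces = tm.faces[patch.faces]
    edge_count: dict[tuple[int, int], int] = defaultdict(int)
    for tri in faces:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            edge_count[(min(a, b), max(a, b))] += 1
    boundary = [e for e, c in edge_count.items() if c == 1]
    if not boundary:
        raise ValueError("patch has no boundary")
    adj: dict[int, list[int]] = defaultdict(list)
    for a, b in boundary:
        adj[a].append(b)
        adj[b].append(a)
    unused = set(boundary)

    def _take(a: int, b: int) -> None:
        unused.discard((min(a, b), max(a, b)))

    loops: list[list[int]] = []
    while unused:
        start_edge = min(unused)
        a, b = start_edge
        chain = [a, b]
        _take(a, b)
        # extend forward until we close or dead-end
        while True:
            cur, prev = chain[-1], chain[-2]
            nxt = [v for v in sorted(adj[cur])
                   if (min(cur, v), max(cur, v)) in unused]
            if not nxt:
                break
            v = nxt[0]
            chain.append(v)
            _take(cur, v)
            if v == chain[0]:
                break
        # if open, try extending backwards
        if chain[0] != chain[-1]:
            while True:
                cur, prev = chain[0], chain[1]
                nxt = [v for v in sorted(adj[cur])
                       if (min(cur, v), max(cur, v)) in unused]
                if not nxt:
                    break
                v = nxt[0]
                chain.insert(0, v)
                _take(cur, v)
        loops.append(chain)
    return [np.asarray(c, dtype=int) for c in loops]


def _boundary_points(patch: ArticularPatch) -> np.ndarray:
    """All boundary polyline points of a patch, concatenated (for distance tests)."""
    tm = patch.mesh.mesh
    loops = patch_boundary_loops(patch)
    return np.vstack([tm.vertices[lp] for lp in loops])


def extract_fracture_lines(patch: ArticularPatch,
                           all_patches: list[ArticularPatch],
                           tol: float = DEFAULT_FRACTURE_TOL_MM,
                           min_line: float = MIN_LINE_LENGTH_MM
                           ) -> list[FractureLine]:
    """Fracture lines of one intra-articular patch.

    Each boundary edge is classified *fracture* if its midpoint lies within
    ``tol`` mm of the patch boundary of any other fragment, else *rim*;
    maximal runs of consecutive fracture edges along each boundary loop
    become FractureLines. Runs are additionally split where the nearest
    opposing fragment changes, so at junctions where three or more
    fragments meet each pairwise fracture border yields its own line (the
    pairwise decomposition of the gap surface).
    """
    if not patch.is_intra:
        raise ValueError("fracture lines are defined on intra-articular patches")
    tm = patch.mesh.mesh
    loops = patch_boundary_loops(patch)
    others = [p for p in all_patches
              if p.fragment_id != patch.fragment_id and p.is_intra
              and len(p.faces)]
    other_segments = []  # (frag_id, seg_starts, seg_ends)
    for p in others:
        ptm = p.mesh.mesh
        for lp in patch_boundary_loops(p):
            pts = ptm.vertices[lp]
            other_segments.append((p.fragment_id, pts[:-1], pts[1:]))

    # boundary-edge -> selected face, for outward in-plane edge normals
    sel_tris = tm.faces[patch.faces]
    sel_normals = tm.face_normals[patch.faces]
    edge_to_face: dict[tuple[int, int], list[int]] = defaultdict(list)
    for row, tri in enumerate(sel_tris):
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            edge_to_face[(min(a, b), max(a, b))].append(row)

    lines: list[FractureLine] = []
    idx = 0
    for loop in loops:
        pts = tm.vertices[loop]
        closed = loop[0] == loop[-1]
        if closed:
            pts = pts[:-1]
            n_edges = len(pts)
            edge_vs = [(loop[i], loop[(i + 1) % n_edges]) for i in range(n_edges)]
            mids = 0.5 * (pts + np.roll(pts, -1, axis=0))
        else:
            n_edges = len(pts) - 1
            edge_vs = [(loop[i], loop[i + 1]) for i in range(n_edges)]
            mids = 0.5 * (pts[:-1] + pts[1:])
        if n_edges == 0 or not other_segments:
            continue

        outward, _ = _edge_outward_normals(tm, edge_vs, mids, edge_to_face,
                                           sel_tris, sel_normals)
        # articular-plane frame: the patch's area-weighted mean normal; all
        # facing/step-off geometry is resolved against this plane so the
        # half-voxel chamfer faces at mesh edges do not tilt the test
        w = tm.area_faces[patch.faces]
        pnorm = (sel_normals * w[:, None]).sum(axis=0)
        pnorm = pnorm / max(np.linalg.norm(pnorm), 1e-12)
        out_h = outward - np.outer(outward @ pnorm, pnorm)
        out_h = out_h / np.maximum(np.linalg.norm(out_h, axis=1,
                                                  keepdims=True), 1e-12)
        edge_len = np.linalg.norm(
            tm.vertices[[b for _, b in edge_vs]]
            - tm.vertices[[a for a, _ in edge_vs]], axis=1)
        contact_eps = 1.5 * float(np.median(edge_len))

        edge_dir = (tm.vertices[[b for _, b in edge_vs]]
                    - tm.vertices[[a for a, _ in edge_vs]])
        edge_dir = edge_dir / np.maximum(
            np.linalg.norm(edge_dir, axis=1, keepdims=True), 1e-12)

        # nearest *facing* fragment per edge: the opposing boundary must lie
        # ahead of the edge's outward normal, or directly above/below it (a
        # pure step-off), or be in coincident contact. Offsets running along
        # the edge itself are lateral -- a neighbouring border at a junction,
        # not an opposing fragment -- and never qualify.
        best_d = np.full(n_edges, np.inf)
        nearest = np.full(n_edges, -1, dtype=int)
        for fid, sa, sb in other_segments:
            d, q = _nearest_on_segments(mids, sa, sb)
            vec = q - mids
            vn = np.linalg.norm(vec, axis=1)
            safe_vn = np.where(vn > 0, vn, 1.0)
            vert_signed = vec @ pnorm
            vert_comp = np.abs(vert_signed)
            lat_comp = np.abs(np.einsum("ij,ij->i", vec, edge_dir))
            vecp = vec - vert_signed[:, None] * pnorm
            vpn = np.linalg.norm(vecp, axis=1)
            cosang = np.einsum("ij,ij->i", vecp, out_h) / np.where(
                vpn > 0, vpn, 1.0)
            facing = cosang >= FACING_MIN_COS
            stepoff = (vert_comp >= 0.7 * vn) & (lat_comp <= 0.3 * vert_comp)
            coincident = vn <= 1e-6
            lateral_contact = (d <= contact_eps) & (lat_comp >= 0.9 * safe_vn)
            valid = (coincident | ((facing | stepoff) & ~lateral_contact)
                     | ((d <= contact_eps) & ~lateral_contact))
            closer = valid & (d < best_d)
            best_d[closer] = d[closer]
            nearest[closer] = fid
        is_frac = best_d <= tol + 1e-9  # tolerance is inclusive of exact ties
        for run in _split_runs_by_nearest(_runs(is_frac, closed), nearest):
            if closed:
                run_pts = pts[np.mod(np.arange(run[0], run[0] + len(run) + 1),
                                     len(pts))]
            else:
                run_pts = pts[run[0]: run[-1] + 2]
            if len(run_pts) >= 2:
                line = FractureLine(patch.fragment_id, run_pts, index=idx)
                if line.length >= min_line:
                    lines.append(line)
                    idx += 1
    return lines


def _edge_outward_normals(tm, edge_vs, mids: np.ndarray,
                          edge_to_face: dict, sel_tris: np.ndarray,
                          sel_normals: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Outward in-face normal of each boundary edge, plus its face normal."""
    out = np.zeros((len(edge_vs), 3))
    fnorm = np.zeros((len(edge_vs), 3))
    fnorm[:, 2] = 1.0
    for i, (a, b) in enumerate(edge_vs):
        rows = edge_to_face.get((min(a, b), max(a, b)), [])
        if not rows:
            continue
        row = rows[0]
        tri = sel_tris[row]
        third = [v for v in tri if v != a and v != b]
        edge_vec = tm.vertices[b] - tm.vertices[a]
        n = np.cross(edge_vec, sel_normals[row])
        norm = np.linalg.norm(n)
        if norm == 0:
            continue
        n = n / norm
        if third and n @ (tm.vertices[third[0]] - mids[i]) > 0:
            n = -n
        out[i] = n
        fnorm[i] = sel_normals[row]
    return out, fnorm


def _split_runs_by_nearest(runs: list[list[int]],
                           nearest: np.ndarray) -> list[list[int]]:
    """Split each edge run into sub-runs of constant nearest fragment."""
    out = []
    n = len(nearest)
    for run in runs:
        cur = [run[0]]
        for e in run[1:]:
            if nearest[e % n] == nearest[cur[-1] % n]:
                cur.append(e)
            else:
                out.append(cur)
                cur = [e]
        out.append(cur)
    return out


def _runs(flags: np.ndarray, circular: bool) -> list[list[int]]:
    """Maximal runs of True indices, merging across the wrap if circular."""
    n = len(flags)
    if flags.all():
        return [list(range(n))]
    if not flags.any():
        return []
    runs = []
    cur: list[int] = []
    for i in range(n):
        if flags[i]:
            cur.append(i)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    if circular and len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == n - 1:
        runs[0] = runs.pop() + [i + n for i in runs[0]]
    return runs


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match_fracture_lines(lines: list[FractureLine],
                         match_limit: float = DEFAULT_MATCH_LIMIT_MM
                         ) -> tuple[list[CurvePair], list[FractureLine]]:
    """Greedy mutual-nearest pairing of fracture lines across fragments.

    Repeatedly pairs the two unmatched lines from distinct fragments with
    the smallest symmetric mean closest-point distance, while that distance
    is <= ``match_limit``. Ties break on lower (fragment_id, line index).
    Returns the pairs and the lines left unmatched.
    """
    lines = list(lines)
    if len(lines) < 2 or len({ln.fragment_id for ln in lines}) < 2:
        if lines:
            warnings.warn("no candidate fracture-line pairs", stacklevel=2)
        return [], lines
    order = sorted(range(len(lines)),
                   key=lambda i: (lines[i].fragment_id, lines[i].index))
    dist = {}
    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            i, j = order[ai], order[bi]
            if lines[i].fragment_id == lines[j].fragment_id:
                continue
            dist[(i, j)] = mean_closest_distance(lines[i], lines[j])
    matched: set[int] = set()
    pairs: list[CurvePair] = []
    for (i, j), d in sorted(dist.items(), key=lambda kv: (kv[1], kv[0])):
        if d > match_limit:
            break
        if i in matched or j in matched:
            continue
        pairs.append(CurvePair(lines[i], lines[j], mean_gap=float(d)))
        matched.update((i, j))
    unmatched = [lines[i] for i in order if i not in matched]
    if not pairs:
        warnings.warn("no fracture-line pair within match limit", stacklevel=2)
    if unmatched:
        logger.info("%d fracture line(s) left unmatched", len(unmatched))
    return pairs, unmatched


# ---------------------------------------------------------------------------
# minimal-area stitching
# ---------------------------------------------------------------------------

def _tri_area(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(q - p, r - p)))


def triangulate_gap(pair: CurvePair,
                    step: float | None = RESAMPLE_STEP_MM) -> GapSurface:
    """Minimal-area monotone triangulation between two fracture lines.

    Both polylines are resampled to a uniform <= ``step`` mm spacing and
    ``line_b`` is reversed if that lowers the summed endpoint distance.
    Dynamic programming over the (|a|-1) x (|b|-1) advance lattice finds
    the cheapest monotone stitching: every triangle uses one edge from one
    line and one vertex from the other, and the result is optimal among
    all monotone stitchings.
    """
    pa = (resample_polyline(pair.line_a.points, step) if step is not None
          else pair.line_a.points)
    pb = (resample_polyline(pair.line_b.points, step) if step is not None
          else pair.line_b.points)
    straight = (np.linalg.norm(pa[0] - pb[0]) + np.linalg.norm(pa[-1] - pb[-1]))
    crossed = (np.linalg.norm(pa[0] - pb[-1]) + np.linalg.norm(pa[-1] - pb[0]))
    if crossed < straight:
        pb = pb[::-1].copy()

    na, nb = len(pa), len(pb)
    dp = np.full((na, nb), np.inf)
    move = np.zeros((na, nb), dtype=np.int8)  # 1: advanced a, 2: advanced b
    dp[0, 0] = 0.0
    for i in range(na):
        for j in range(nb):
            if i == 0 and j == 0:
                continue
            best, mv = np.inf, 0
            if i > 0:
                c = dp[i - 1, j] + _tri_area(pa[i - 1], pa[i], pb[j])
                if c < best:
                    best, mv = c, 1
            if j > 0:
                c = dp[i, j - 1] + _tri_area(pb[j - 1], pb[j], pa[i])
                if c < best:
                    best, mv = c, 2
            dp[i, j], move[i, j] = best, mv

    tris = []
    i, j = na - 1, nb - 1
    while i > 0 or j > 0:
        if move[i, j] == 1:
            tris.append((pa[i - 1], pa[i], pb[j]))
            i -= 1
        else:
            tris.append((pb[j - 1], pb[j], pa[i]))
            j -= 1
    tris = np.asarray(tris[::-1]) if tris else np.zeros((0, 3, 3))
    return GapSurface(pair=pair, triangles=tris, area=float(dp[na - 1, nb - 1]))


def zigzag_area(pair: CurvePair,
                step: float | None = RESAMPLE_STEP_MM) -> float:
    """Area of the naive alternating stitching (upper bound for the DP)."""
    pa = (resample_polyline(pair.line_a.points, step) if step is not None
          else pair.line_a.points)
    pb = (resample_polyline(pair.line_b.points, step) if step is not None
          else pair.line_b.points)
    straight = (np.linalg.norm(pa[0] - pb[0]) + np.linalg.norm(pa[-1] - pb[-1]))
    crossed = (np.linalg.norm(pa[0] - pb[-1]) + np.linalg.norm(pa[-1] - pb[0]))
    if crossed < straight:
        pb = pb[::-1].copy()
    i = j = 0
    area = 0.0
    while i < len(pa) - 1 or j < len(pb) - 1:
        adv_a = (i < len(pa) - 1) and (i - j <= 0 or j == len(pb) - 1)
        if adv_a:
            area += _tri_area(pa[i], pa[i + 1], pb[j])
            i += 1
        else:
            area += _tri_area(pb[j], pb[j + 1], pa[i])
            j += 1
    return area


def total_gap_area(surfaces: list[GapSurface], case_id: str = "",
                   observer_id: str = "",
                   unmatched: list[FractureLine] | None = None
                   ) -> GapAreaResult:
    """Sum per-pair gap areas into the case-level 3D gap area."""
    result = GapAreaResult(case_id=case_id, observer_id=observer_id,
                           surfaces=list(surfaces),
                           unmatched=list(unmatched or []))
    if result.no_displacement:
        logger.info("case %s: no displacement detected", case_id or "<unnamed>")
    return result


def compute_gap_area(patches: list[ArticularPatch],
                     tol: float = DEFAULT_FRACTURE_TOL_MM,
                     match_limit: float = DEFAULT_MATCH_LIMIT_MM,
                     min_line: float = MIN_LINE_LENGTH_MM,
                     case_id: str = "", observer_id: str = "") -> GapAreaResult:
    """End-to-end gap area from marked patches (extraction → matching → DP)."""
    intra = [p for p in patches if p.is_intra]
    lines: list[FractureLine] = []
    for p in intra:
        lines.extend(extract_fracture_lines(p, intra, tol=tol,
                                            min_line=min_line))
    pairs, unmatched = ([], lines) if len(lines) < 2 else \
        match_fracture_lines(lines, match_limit=match_limit)
    surfaces = [triangulate_gap(p) for p in pairs]
    return total_gap_area(surfaces, case_id=case_id, observer_id=observer_id,
                          unmatched=unmatched)
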