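"""End-to-end per-case pipeline: inputs -> meshes -> gap area -> report.

A single YAML/dict config describes one case -- either a synthetic phantom
or real inputs (CT + labels or seeds) -- together with every tunable
parameter. ``run_case`` executes segmentation, articular marking, 3D gap
area and 2D slice measurements, and returns a ``CaseReport`` whose numeric
fields byte-reproduce across identical runs. The report optionally flags a
gap area of at least 150 mm^2 ("large gap area"): a speculative outcome
threshold that is reported but deliberately not acted upon.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from . import segmentation as seg
from . import articular as art
from . import gap_core
from . import planar
from . import phantom as phantom_mod

logger = logging.getLogger("gaparea3d")

#: Every pipeline default in one place (the config schema).
DEFAULT_PARAMS = {
    "hu_threshold": seg.DEFAULT_HU_THRESHOLD,          # HU, bone extraction
    "tol_mm": gap_core.DEFAULT_FRACTURE_TOL_MM,        # fracture vs rim edges
    "match_limit_mm": gap_core.DEFAULT_MATCH_LIMIT_MM, # line pairing limit
    "cutoff_mm": planar.DEFAULT_CUTOFF_MM,             # surgical 2 mm rule
    "min_area_mm2": art.DEFAULT_MIN_AREA_MM2,          # intra-articular floor
    "large_area_flag_mm2": 150.0,                      # report-only flag
}


@dataclass
class CaseReport:
    case_id: str
    observer_id: str
    total_gap_area_mm2: float
    per_pair_areas_mm2: list[float]
    pair_fragments: list[tuple[int, int]]
    max_gap_mm: float
    max_stepoff_mm: float
    above_cutoff: bool
    large_gap_area: bool
    n_fragments: int
    n_intra_articular: int
    n_unmatched_lines: int
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _stage(name: str, case_id: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(
                    f"stage {name!r} failed for case {case_id!r}: {exc}"
                ) from exc
            return False
    return _Ctx()


def run_case(config: dict, out_dir: str | Path | None = None) -> CaseReport:
    """Run the full measurement pipeline for one case.

    ``config`` keys: ``case_id``, ``observer_id``, ``seed``, ``params``
    (overrides of :data:`DEFAULT_PARAMS`) and exactly one input source:
    ``phantom`` (a PhantomSpec-shaped mapping) or ``inputs`` with ``ct``
    plus ``labels`` or ``seeds`` and optionally ``proxy``.
    """
    case_id = str(config.get("case_id", "case"))
    observer_id = str(config.get("observer_id", "auto"))
    params = {**DEFAULT_PARAMS, **(config.get("params") or {})}
    seed = int(config.get("seed", 0))
    provenance: dict = {
        "software": f"gaparea3d {__version__}",
        "parameters": dict(params),
        "seed": seed,
    }

    # ---- inputs ----------------------------------------------------------
    with _stage("inputs", case_id):
        if "phantom" in config:
            spec = build_phantom_spec(config["phantom"], seed=seed)
            volume, mask, truth = phantom_mod.make_fracture_phantom(spec)
            proxy = art.ArticularProxy(kind="roi_mask",
                                       roi=art.top_surface_roi(mask))
            provenance["inputs"] = {"phantom": config["phantom"]}
            provenance["ground_truth_total_gap_area_mm2"] = \
                truth.expected_gap_area_total
        elif "inputs" in config:
            inputs = config["inputs"]
            volume = seg.load_volume(inputs["ct"]) if "ct" in inputs else None
            if "labels" in inputs:
                mask = seg.load_label_mask(inputs["labels"])
            elif "seeds" in inputs and volume is not None:
                with open(inputs["seeds"]) as fh:
                    seed_groups = json.load(fh)
                binary = seg.threshold_bone(volume, params["hu_threshold"])
                flat = [s for grp in seed_groups for s in grp]
                grown = seg.region_grow(binary, flat)
                mask = seg.split_fragments(
                    seg.LabelMask((grown.labels > 0).astype(np.int32),
                                  grown.spacing, grown.origin),
                    seed_groups)
            else:
                raise ValueError("no fragment definition: supply labels or seeds")
            if "proxy" in inputs:
                proxy = art.load_proxy(inputs["proxy"], mask=mask)
            else:
                proxy = art.ArticularProxy(kind="roi_mask",
                                           roi=art.top_surface_roi(mask))
            provenance["inputs"] = dict(inputs)
        else:
            raise ValueError("no fragment definition: config needs "
                             "'phantom' or 'inputs'")

    # ---- segmentation / meshing -----------------------------------------
    with _stage("segmentation", case_id):
        meshes = seg.mesh_all_fragments(mask)

    # ---- articular marking ----------------------------------------------
    with _stage("articular_marking", case_id):
        patches = art.mark_all(meshes, proxy, min_area=params["min_area_mm2"])

    # ---- 3D gap area -----------------------------------------------------
    with _stage("gap_core", case_id):
        gap_result = gap_core.compute_gap_area(
            patches, tol=params["tol_mm"],
            match_limit=params["match_limit_mm"],
            case_id=case_id, observer_id=observer_id)

    # ---- 2D measurements -------------------------------------------------
    with _stage("planar_measures", case_id):
        slices = planar.scan_slices(mask)
        if slices:
            m2d = planar.max_per_case(slices, case_id, observer_id,
                                      cutoff=params["cutoff_mm"])
        else:
            m2d = planar.CaseMeasurement2D(case_id, observer_id, 0.0, 0.0,
                                           False, cutoff=params["cutoff_mm"])

    report = CaseReport(
        case_id=case_id,
        observer_id=observer_id,
        total_gap_area_mm2=round(gap_result.total_area, 6),
        per_pair_areas_mm2=[round(a, 6) for a in gap_result.per_pair_areas],
        pair_fragments=[(s.pair.line_a.fragment_id, s.pair.line_b.fragment_id)
                        for s in gap_result.surfaces],
        max_gap_mm=round(m2d.max_gap, 6),
        max_stepoff_mm=round(m2d.max_stepoff, 6),
        above_cutoff=m2d.above_cutoff,
        large_gap_area=gap_result.total_area >= params["large_area_flag_mm2"],
        n_fragments=len(meshes),
        n_intra_articular=sum(p.is_intra for p in patches),
        n_unmatched_lines=len(gap_result.unmatched),
        provenance=provenance,
    )

    if out_dir is not None:
        write_outputs(report, gap_result, slices, Path(out_dir))
    return report


def build_phantom_spec(cfg: dict, seed: int = 0) -> phantom_mod.PhantomSpec:
    """PhantomSpec from a config mapping (YAML-friendly field names)."""
    plate = cfg.get("plate")
    plate_dims = None
    if plate is not None:
        plate_dims = (float(plate["width"]), float(plate["depth"]),
                      float(plate["thickness"]))
    cuts = [phantom_mod.CutPlane(origin=tuple(c["origin"]),
                                 normal=tuple(c["normal"]))
            for c in cfg.get("cuts", [])]
    disps = [phantom_mod.RigidDisplacement(
                 translation=tuple(d.get("translation", (0, 0, 0))),
                 rotation_deg=float(d.get("rotation_deg", 0.0)),
                 rotation_axis=tuple(d.get("rotation_axis", (0, 0, 1))))
             for d in cfg.get("displacements", [])]
    return phantom_mod.PhantomSpec(
        plate_dims=plate_dims,
        cap_radius=cfg.get("cap_radius"),
        cap_height=cfg.get("cap_height"),
        cuts=cuts, displacements=disps,
        spacing=float(cfg.get("spacing", 0.5)),
        noise_sd=float(cfg.get("noise_sd", 0.0)),
        seed=int(cfg.get("seed", seed)))


def write_outputs(report: CaseReport, gap_result: gap_core.GapAreaResult,
                  slices: list[planar.SliceMeasurement], out_dir: Path) -> None:
    """Write report.json, gaparea.csv, measure2d.csv and STL QC surfaces."""
    import pandas as pd
    import trimesh

    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)

    rows = []
    for pid, s in enumerate(gap_result.surfaces):
        rows.append({
            "case_id": report.case_id, "observer_id": report.observer_id,
            "pair_id": pid,
            "frag_a": s.pair.line_a.fragment_id,
            "frag_b": s.pair.line_b.fragment_id,
            "area_mm2": s.area, "total_mm2": report.total_gap_area_mm2,
        })
    pd.DataFrame(rows, columns=["case_id", "observer_id", "pair_id", "frag_a",
                                "frag_b", "area_mm2", "total_mm2"]
                 ).to_csv(out_dir / "gaparea.csv", index=False)

    rows2 = [{
        "case_id": report.case_id, "observer_id": report.observer_id,
        "plane": m.plane, "slice": m.slice_index,
        "gap_mm": m.gap, "stepoff_mm": m.stepoff,
        "max_gap_mm": report.max_gap_mm,
        "max_stepoff_mm": report.max_stepoff_mm,
        "above_cutoff": report.above_cutoff,
    } for m in slices]
    pd.DataFrame(rows2, columns=["case_id", "observer_id", "plane", "slice",
                                 "gap_mm", "stepoff_mm", "max_gap_mm",
                                 "max_stepoff_mm", "above_cutoff"]
                 ).to_csv(out_dir / "measure2d.csv", index=False)

    for pid, s in enumerate(gap_result.surfaces):
        if len(s.triangles) == 0:
            continue
        verts = s.triangles.reshape(-1, 3)
        faces = np.arange(len(verts)).reshape(-1, 3)
        trimesh.Trimesh(verts, faces, process=False).export(
            out_dir / f"{report.case_id}_gap{pid}.stl")
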