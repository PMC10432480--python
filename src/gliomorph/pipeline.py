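"""End-to-end orchestration: segmentation -> graphs -> all metrics.

``analyze_images`` runs the full analysis on in-memory calibrated
images (any subset of channels) and returns a result bundle;
``run_pipeline`` wraps it with file I/O, logging and provenance for one
sample directory.  The pipeline is pure with respect to (inputs,
config, seed): identical inputs produce byte-identical CSV reports.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import gliovascular, morphometrics, neurons, segmentation, skeleton, vasculature
from .core import BinaryMask, CalibratedImage, LabelMask
from .io import RunConfig, load_image, load_surface, save_mask, write_provenance
from .morphometrics import CellRecord, SampleReport

__all__ = ["AnalysisResult", "analyze_images", "run_pipeline"]

log = logging.getLogger("gliomorph")


@dataclass
class AnalysisResult:
    """Everything one sample's analysis produced."""

    report: Optional[SampleReport] = None
    bodies: Optional[LabelMask] = None
    process_mask: Optional[BinaryMask] = None
    astro_skeleton: Optional[skeleton.Skeleton] = None
    cell_graphs: list = field(default_factory=list)
    cell_territories: Optional[LabelMask] = None
    vessel_mask: Optional[BinaryMask] = None
    vessel_map: Optional[vasculature.VesselMap] = None
    vessel_density: Optional[float] = None
    vessel_branch_density: Optional[float] = None
    puncta_mask: Optional[BinaryMask] = None
    coverage: Optional[gliovascular.CoverageReport] = None
    fraction_contacting: Optional[float] = None
    body_radial: Optional[gliovascular.RadialProfile] = None
    signal_radial: Optional[gliovascular.RadialProfile] = None
    detections: Optional[neurons.DetectionSet] = None
    depth_profile: Optional[neurons.DepthProfile] = None

    def summary_row(self) -> dict:
        row: dict = {}
        if self.report is not None:
            row.update(self.report.summary_row())
        if self.vessel_density is not None:
            row["vessel_density_um_per_um2"] = self.vessel_density
            row["vessel_branch_density_mm2"] = self.vessel_branch_density
        if self.fraction_contacting is not None:
            row["fraction_astro_contacting_vessels"] = self.fraction_contacting
        if self.coverage is not None:
            row["connexin_coverage_small"] = self.coverage.coverage_small
            row["connexin_coverage_large"] = self.coverage.coverage_large
        if self.detections is not None:
            row["n_neurons"] = len(self.detections)
        return row


def _cell_territories(
    process_mask: BinaryMask, bodies: LabelMask
) -> LabelMask:
    """Label every process/body pixel with its (nearest) cell id."""
    if bodies.n_objects == 0 or not process_mask.pixels.any():
        return LabelMask(np.zeros(process_mask.shape, dtype=np.int32),
                         process_mask.pixel_size)
    ind = ndi.distance_transform_edt(bodies.pixels == 0, return_indices=True)[1]
    nearest = bodies.pixels[ind[0], ind[1]]
    terr = np.where(process_mask.pixels, nearest, 0).astype(np.int32)
    return LabelMask(terr, process_mask.pixel_size)


def _analyze_astrocytes(
    image: CalibratedImage, cfg: RunConfig, vessel_mask: Optional[BinaryMask]
) -> tuple:
    body_cfg = segmentation.BodyDetectorConfig(
        smooth_sigma_um=cfg.smooth_sigma_um,
        window_um=cfg.window_um,
        opening_radius_um=cfg.body_opening_radius_um,
        min_area_um2=cfg.body_min_area_um2,
        peak_min_distance_um=cfg.body_peak_min_distance_um,
        max_hole_area_um2=cfg.body_max_hole_area_um2,
    )
    bodies = segmentation.detect_bodies(image, body_cfg)
    proc = segmentation.segment_processes(
        image, bodies, cfg.smooth_sigma_um, cfg.window_um, cfg.process_min_area_um2
    )
    skel = skeleton.thin(proc)
    body_bin = bodies.pixels > 0
    area = image.field_area_um2

    # Sample-level totals: extension length excludes intra-soma medial
    # lines.  The cut uses the body mask eroded by one pixel: the
    # thresholded soma mask carries a ~1 px blur/anti-aliasing halo, so
    # cutting at the raw mask would clip the proximal end of every
    # process by that halo.
    body_cut = ndi.binary_erosion(body_bin, structure=np.ones((3, 3), bool))
    ext_skel = skel.subset(~body_cut)
    ext_density = morphometrics.extension_length_density([ext_skel], area)

    parts = skeleton.split_skeleton_by_bodies(skel, bodies)
    graphs, cells = [], []
    contacts = _contact_labels(proc, bodies, vessel_mask)
    per_cell: dict[int, list] = {}
    for lab, pm in parts:
        sub = skel.subset(pm)
        body_mask = (
            BinaryMask(bodies.pixels == lab, bodies.pixel_size)
            if lab is not None
            else None
        )
        g = skeleton.build_graph(sub, body_mask, cfg.prune_um, cell_id=lab)
        graphs.append(g)
        if lab is not None:
            per_cell.setdefault(lab, []).append((g, pm))
        else:
            log.warning("rootless skeleton component (%d px) kept for totals",
                        int(pm.sum()))

    entropies = []
    for lab in sorted(per_cell):
        cell_graphs = [g for g, _ in per_cell[lab]]
        pm = np.zeros(skel.shape, dtype=bool)
        for _, m in per_cell[lab]:
            pm |= m
        cell_skel = skel.subset(pm & ~body_bin)
        angles = morphometrics.skeleton_orientations(cell_skel, cfg.orientation_radius_um)
        ent = morphometrics.angle_entropy(angles, cfg.n_orientation_bins)
        if ent is None:
            log.warning("cell %d: no defined orientation; excluded from entropy", lab)
        else:
            entropies.append(ent)
        cells.append(
            CellRecord(
                cell_id=lab,
                n_branch_points=sum(g.n_branch_points for g in cell_graphs),
                n_terminations=sum(g.n_terminations for g in cell_graphs),
                total_length_um=sum(g.total_length_um for g in cell_graphs),
                angle_entropy_bits=ent,
                contacts_vessel=(lab in contacts) if contacts is not None else None,
            )
        )

    report = SampleReport(
        sample_id=cfg.sample_id,
        area_um2=area,
        astrocyte_density_mm2=morphometrics.astrocyte_density(bodies, area),
        extension_length_density=ext_density,
        branching_density_mm2=morphometrics.branching_density(graphs, area),
        mean_angle_entropy_bits=(float(np.mean(entropies)) if entropies else None),
        n_cells_entropy_defined=len(entropies),
        cells=cells,
    )
    return bodies, proc, skel, graphs, report


def _contact_labels(proc, bodies, vessel_mask) -> Optional[set]:
    if vessel_mask is None or bodies.n_objects == 0:
        return None
    terr = _cell_territories(proc, bodies)
    labs = np.unique(terr.pixels[vessel_mask.pixels])
    return {int(v) for v in labs if v > 0}


def analyze_images(
    images: dict[str, CalibratedImage],
    cfg: Optional[RunConfig] = None,
    surface_um: Optional[np.ndarray] = None,
) -> AnalysisResult:
    """Run every stage for which an input channel exists.

    ``images`` maps channel names (``astrocyte``, ``vessel``,
    ``puncta``, ``neuron``) to calibrated images.
    """
    cfg = cfg or RunConfig()
    cfg.validate()
    res = AnalysisResult()

    if "vessel" in images:
        res.vessel_mask = segmentation.segment_vessels(
            images["vessel"],
            segmentation.VesselDetectorConfig(
                smooth_sigma_um=cfg.smooth_sigma_um,
                window_um=cfg.window_um,
                closing_radius_um=cfg.vessel_closing_radius_um,
                min_area_um2=cfg.vessel_min_area_um2,
            ),
        )
        area = images["vessel"].field_area_um2
        res.vessel_map = vasculature.build_vessel_map(res.vessel_mask, cfg.prune_um)
        res.vessel_density = vasculature.vessel_density(res.vessel_map, area)
        res.vessel_branch_density = vasculature.vessel_branch_density(
            res.vessel_map, area
        )

    if "astrocyte" in images:
        (res.bodies, res.process_mask, res.astro_skeleton, res.cell_graphs,
         res.report) = _analyze_astrocytes(images["astrocyte"], cfg, res.vessel_mask)
        res.cell_territories = _cell_territories(res.process_mask, res.bodies)
        if res.vessel_mask is not None:
            res.fraction_contacting = gliovascular.fraction_contacting(
                res.cell_territories, res.vessel_mask
            )
            if res.vessel_mask.pixels.any():
                if res.bodies.n_objects:
                    res.body_radial = gliovascular.radial_profile(
                        res.vessel_mask, bodies=res.bodies,
                        max_dist_um=cfg.radial_max_dist_um, step_um=cfg.radial_step_um,
                    )
                res.signal_radial = gliovascular.radial_profile(
                    res.vessel_mask, signal_mask=res.process_mask,
                    max_dist_um=cfg.radial_max_dist_um, step_um=cfg.radial_step_um,
                )

    if "puncta" in images:
        res.puncta_mask = segmentation.segment_puncta(
            images["puncta"], cfg.window_um, cfg.puncta_min_area_um2,
            cfg.smooth_sigma_um,
        )
        if res.vessel_map is not None and res.vessel_mask.pixels.any():
            res.coverage = gliovascular.connexin_coverage(
                res.puncta_mask, res.vessel_map,
                cfg.connexin_max_dist_um, cfg.diameter_split_um,
            )

    if "neuron" in images:
        eq = neurons.equalize(images["neuron"])
        res.detections = neurons.detect_neurons(
            eq, cfg.log_sigma_min_um, cfg.log_sigma_max_um,
            cfg.log_threshold, cfg.log_n_scales,
        )
        if surface_um is not None:
            res.depth_profile = neurons.depth_profile(
                res.detections, surface_um, images["neuron"].shape,
                images["neuron"].pixel_size, cfg.depth_bin_um,
            )
    return res


def run_pipeline(config: RunConfig) -> Path:
    """File-level entry point: load inputs, analyze, write a report dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    if not any(h for h in log.handlers if isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler)):
        log.addHandler(logging.StreamHandler(sys.stderr))

    stage = "load"
    try:
        images = {}
        for channel in ("astrocyte", "vessel", "puncta", "neuron"):
            path = getattr(config, f"{channel}_path")
            if path:
                images[channel] = load_image(path, config.pixel_size_um, channel)
        surface = load_surface(config.surface_path) if config.surface_path else None
        if not images:
            raise ValueError("no input channel configured")

        stage = "analyze"
        res = analyze_images(images, config, surface)

        stage = "write"
        _write_outputs(res, config, out)
    except Exception:
        log.error("pipeline failed at stage %r for sample %r", stage,
                  config.sample_id)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _write_outputs(res: AnalysisResult, config: RunConfig, out: Path) -> None:
    float_fmt = "%.10g"
    pd.DataFrame([res.summary_row()]).to_csv(
        out / "sample_summary.csv", index=False, float_format=float_fmt
    )
    if res.report is not None:
        res.report.cell_table().to_csv(
            out / "cells.csv", index=False, float_format=float_fmt
        )
        graphs = [g.to_dict() for g in res.cell_graphs]
        (out / "cell_graphs.json").write_text(json.dumps(graphs))
        save_mask(res.process_mask, out / "process_mask.tif")
        save_mask(BinaryMask(res.astro_skeleton.pixels,
                             res.astro_skeleton.pixel_size),
                  out / "astro_skeleton.tif")
    if res.bodies is not None:
        res.bodies.table.to_csv(out / "bodies.csv", index=False,
                                float_format=float_fmt)
    if res.vessel_mask is not None:
        save_mask(res.vessel_mask, out / "vessel_mask.tif")
    if res.vessel_map is not None:
        res.vessel_map.radius_table().to_csv(
            out / "vessel_radius.csv", index=False, float_format=float_fmt
        )
        (out / "vessel_graphs.json").write_text(
            json.dumps([g.to_dict() for g in res.vessel_map.graphs])
        )
    if res.puncta_mask is not None:
        save_mask(res.puncta_mask, out / "puncta_mask.tif")
    if res.coverage is not None:
        (out / "coverage.json").write_text(
            json.dumps(res.coverage.as_dict(), indent=1, sort_keys=True)
        )
    for name, prof in (("radial_bodies", res.body_radial),
                       ("radial_signal", res.signal_radial)):
        if prof is not None:
            prof.table().to_csv(out / f"{name}.csv", index=False,
                                float_format=float_fmt)
    if res.detections is not None:
        res.detections.points.to_csv(out / "neurons.csv", index=False,
                                     float_format=float_fmt)
    if res.depth_profile is not None:
        res.depth_profile.table().to_csv(out / "depth_profile.csv", index=False,
                                         float_format=float_fmt)
    write_provenance(config, out / "provenance.json")
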