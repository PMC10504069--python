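"""End-to-end orchestration: simulate → segment → quantify → summarise.

The pipeline has three entry modes:

* ``simulate`` — render one synthetic monolayer per condition, save the
  image stacks and ground truth, then run the full analysis on the
  rendered images;
* ``analyze`` — run the analysis on previously saved image stacks;
* ``flow-design`` — no images: compute the duct operating point
  (shear, velocity, pressure drop, Reynolds number) for a flow rate.

Every summary row in the report is traceable to a per-object CSV in the
output directory, every angular-histogram figure to a CSV of its bin
counts, and identical config + seed reproduce the report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ductflow, units
from .expression import QpcrPlate, livak_table, nuclear_marker_intensity, rank_sum_test
from .orientation import angular_histogram, axial_summary, fit_region_ellipse
from .polarity import polarity_summary, polarity_table
from .segment import (border_labels, label_centroids, segment_cells,
                      segment_golgi, segment_nuclei)
from .synth import ImageStack, MonolayerSpec, render_monolayer

__all__ = [
    "SegmentationParams",
    "AnalysisResult",
    "RunConfig",
    "run_pipeline",
    "analyze_stack",
    "region_shape_table",
    "flow_condition_spec",
    "static_condition_spec",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the classical segmentation stage."""

    min_nucleus_area: int = 30
    min_golgi_area: int = 5
    min_peak_distance: int = 10
    exclude_border_cells: bool = True
    eccentricity_threshold: float = 0.05
    max_pair_distance_factor: float = 1.5  # × median nucleus major axis


def flow_condition_spec(seed: int = 0, **overrides) -> MonolayerSpec:
    """A flow-stimulated monolayer: aligned, polarised, marker-high."""
    return MonolayerSpec(seed=seed, condition="flow", **overrides)


def static_condition_spec(seed: int = 0, **overrides) -> MonolayerSpec:
    """A static monolayer: isotropic orientation, random polarity,
    marker at half the flow level."""
    defaults = dict(kappa_axial=0.0, kappa_pol=0.0, marker_mean=100.0)
    defaults.update(overrides)
    return MonolayerSpec(seed=seed, condition="static", **defaults)


def region_shape_table(labels: np.ndarray,
                       eccentricity_threshold: float = 0.05) -> pd.DataFrame:
    """Ellipse fits for every labelled region.

    Columns: label, row, col, major_axis, minor_axis, orientation_deg,
    eccentricity, orientation_defined, border.
    """
    from scipy import ndimage as ndi

    rows = []
    border = border_labels(labels)
    for i, sl in enumerate(ndi.find_objects(labels)):
        if sl is None:
            continue
        lab = i + 1
        mask = labels[sl] == lab
        shape = fit_region_ellipse(mask, label=lab,
                                   eccentricity_threshold=eccentricity_threshold)
        rows.append({
            "label": lab,
            "row": shape.centroid_rc[0] + sl[0].start,
            "col": shape.centroid_rc[1] + sl[1].start,
            "major_axis": shape.major_axis_length,
            "minor_axis": shape.minor_axis_length,
            "orientation_deg": shape.orientation_deg,
            "eccentricity": shape.eccentricity,
            "orientation_defined": shape.orientation_defined,
            "border": lab in border,
        })
    return pd.DataFrame(rows, columns=[
        "label", "row", "col", "major_axis", "minor_axis", "orientation_deg",
        "eccentricity", "orientation_defined", "border"])


@dataclass
class AnalysisResult:
    """Per-object tables and population summaries for one field."""

    cells: pd.DataFrame
    nuclei: pd.DataFrame
    polarity: pd.DataFrame
    intensity: pd.DataFrame
    cell_summary: dict
    nucleus_summary: dict
    polarity_summary: dict
    counts: dict


def _summary_dict(sample_deg) -> dict:
    s = axial_summary(sample_deg)
    return {
        "mean_direction_deg": s.mean_direction_deg,
        "polarity_index": s.polarity_index,
        "n": s.n,
        "p_uniform": s.p_uniform,
    }


def analyze_stack(stack: ImageStack,
                  params: SegmentationParams = SegmentationParams()) -> AnalysisResult:
    """Full image analysis of one multi-channel field of view.

    Segments nuclei → cells → Golgi, fits ellipses, computes axial
    orientation summaries for cells and nuclei, nucleus→Golgi polarity
    relative to the stack's flow axis, and per-nucleus marker intensity.
    Border-touching cells are excluded from the orientation and polarity
    statistics (their truncated shapes bias the fits).
    """
    nuclei_labels = segment_nuclei(
        stack.channels["nuclei"], min_area=params.min_nucleus_area,
        min_peak_distance=params.min_peak_distance)
    cell_labels = segment_cells(stack.channels["junction"], nuclei_labels)

    cells = region_shape_table(cell_labels, params.eccentricity_threshold)
    nuclei = region_shape_table(nuclei_labels, params.eccentricity_threshold)
    # a nucleus inherits its cell's border status (cell labels = seed labels)
    cell_border = dict(zip(cells["label"], cells["border"]))
    if not nuclei.empty:
        nuclei["border"] = nuclei["label"].map(cell_border).fillna(True).astype(bool)

    def _axial_angles(df: pd.DataFrame) -> np.ndarray:
        keep = df["orientation_defined"] & ~df["border"] if params.exclude_border_cells \
            else df["orientation_defined"]
        return df.loc[keep, "orientation_deg"].to_numpy()

    cell_angles = _axial_angles(cells) if not cells.empty else np.array([])
    nuc_angles = _axial_angles(nuclei) if not nuclei.empty else np.array([])

    golgi_rc = segment_golgi(stack.channels["golgi"], min_area=params.min_golgi_area)
    nuc_centroids = label_centroids(nuclei_labels)
    nuc_ids = sorted(nuc_centroids)
    nuc_xy = [(nuc_centroids[i][1], -nuc_centroids[i][0]) for i in nuc_ids]
    golgi_xy = [(c, -r) for r, c in golgi_rc]
    if nuclei.empty:
        max_dist = np.inf
    else:
        max_dist = params.max_pair_distance_factor * float(nuclei["major_axis"].median())
    pol = polarity_table(nuc_xy, golgi_xy, flow_vector=stack.flow_axis,
                         max_distance=max_dist)
    if not pol.empty:
        pol["nucleus_id"] = [nuc_ids[i] for i in pol["nucleus_id"]]
        pol["border"] = pol["nucleus_id"].map(cell_border).fillna(True).astype(bool)
        pol_keep = pol.loc[~pol["border"], "polarity_deg"].to_numpy() \
            if params.exclude_border_cells else pol["polarity_deg"].to_numpy()
    else:
        pol_keep = np.array([])

    intensity = nuclear_marker_intensity(
        nuclei_labels, stack.channels["marker"], condition=stack.condition,
        min_area=params.min_nucleus_area)

    def _maybe(angles, summary_fn):
        if len(angles) == 0:
            return {"n": 0}
        return summary_fn(angles)

    def _pol_summary(angles) -> dict:
        s = polarity_summary(angles)
        return {"mean_direction_deg": s.mean_direction_deg,
                "resultant_length": s.resultant_length,
                "fpi": s.fpi, "n": s.n}

    return AnalysisResult(
        cells=cells, nuclei=nuclei, polarity=pol, intensity=intensity,
        cell_summary=_maybe(cell_angles, _summary_dict),
        nucleus_summary=_maybe(nuc_angles, _summary_dict),
        polarity_summary=_maybe(pol_keep, _pol_summary),
        counts={
            "nuclei_found": int(nuclei_labels.max()),
            "cells_found": int(len(cells)),
            "golgi_found": int(len(golgi_rc)),
            "pairs_retained": int(len(pol)),
            "cells_in_statistics": int(len(cell_angles)),
        },
    )


@dataclass
class RunConfig:
    """One pipeline invocation.

    Exactly one mode: "simulate" (render ``conditions`` then analyse),
    "analyze" (load ``image_paths``), "flow-design" (duct operating
    point for ``flow_ml_min``) or "qpcr" (Livak table from
    ``qpcr_table``).
    """

    mode: str
    out_dir: str | Path = "run"
    seed: int = 0
    conditions: dict[str, MonolayerSpec] = field(default_factory=dict)
    image_paths: list = field(default_factory=list)
    segmentation: SegmentationParams = SegmentationParams()
    histogram_bins: int = 18
    write_histogram_figures: bool = False
    # flow-design
    flow_ml_min: float = 14.0
    width_mm: float = 6.0
    height_um: float = 500.0
    length_mm: float = 125.77
    viscosity_mpas: float = 0.75
    density: float = 1000.0
    # qpcr
    qpcr_table: str | Path | None = None
    reference_gene: str = "GAPDH"
    control_sample: str = "static"

    def config_dict(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["image_paths"] = [str(p) for p in self.image_paths]
        d["qpcr_table"] = str(self.qpcr_table) if self.qpcr_table else None
        return d


def _write_histograms(out_dir: Path, name: str, angles, axial: bool,
                      n_bins: int, figures: bool) -> None:
    edges, counts = angular_histogram(angles, n_bins=n_bins, axial=axial)
    df = pd.DataFrame({"bin_left_deg": edges[:-1], "bin_right_deg": edges[1:],
                       "count": counts})
    hdir = out_dir / "histograms"
    hdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(hdir / f"{name}.csv", index=False)
    if figures:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        centers = np.radians((edges[:-1] + edges[1:]) / 2.0)
        fig = plt.figure(figsize=(4, 4))
        ax = fig.add_subplot(projection="polar")
        ax.bar(centers, counts, width=np.radians(np.diff(edges)), alpha=0.7)
        ax.set_title(name)
        fig.savefig(hdir / f"{name}.png", dpi=100)
        plt.close(fig)


def _analyze_and_write(stack: ImageStack, name: str, out_dir: Path,
                       config: RunConfig) -> dict:
    result = analyze_stack(stack, config.segmentation)
    tdir = out_dir / "tables"
    tdir.mkdir(parents=True, exist_ok=True)
    result.cells.to_csv(tdir / f"{name}_cells.csv", index=False)
    result.nuclei.to_csv(tdir / f"{name}_nuclei.csv", index=False)
    result.polarity.to_csv(tdir / f"{name}_polarity.csv", index=False)
    result.intensity.to_csv(tdir / f"{name}_intensity.csv", index=False)
    keep = result.cells["orientation_defined"] & ~result.cells["border"] \
        if not result.cells.empty else []
    if np.any(keep):
        _write_histograms(out_dir, f"{name}_cell_orientation",
                          result.cells.loc[keep, "orientation_deg"], True,
                          config.histogram_bins, config.write_histogram_figures)
    if not result.polarity.empty:
        _write_histograms(out_dir, f"{name}_polarity",
                          result.polarity["polarity_deg"], False,
                          config.histogram_bins, config.write_histogram_figures)
    return {
        "cells": result.cell_summary,
        "nuclei": result.nucleus_summary,
        "polarity": result.polarity_summary,
        "marker_intensity": {
            "mean": float(result.intensity["mean_intensity"].mean())
            if not result.intensity.empty else float("nan"),
            "n": int(len(result.intensity)),
        },
        "counts": result.counts,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute one configured run and return the (also serialised) report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.config_dict()
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    (out_dir / "config.json").write_text(cfg_json)
    report: dict = {
        "mode": config.mode,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }

    if config.mode == "simulate":
        report["conditions"] = {}
        img_dir = out_dir / "images"
        img_dir.mkdir(exist_ok=True)
        for name, spec in config.conditions.items():
            try:
                rendered = render_monolayer(spec)
            except Exception as exc:  # annotate with the failing stage
                raise RuntimeError(f"simulate stage failed for condition {name!r}: {exc}") from exc
            rendered.stack.save(img_dir / f"{name}.tif")
            (out_dir / "tables").mkdir(exist_ok=True)
            rendered.truth.to_csv(out_dir / "tables" / f"{name}_truth.csv", index=False)
            np.savetxt(out_dir / "tables" / f"{name}_cell_labels.csv",
                       rendered.cell_labels, fmt="%d", delimiter=",")
            report["conditions"][name] = _analyze_and_write(
                rendered.stack, name, out_dir, config)
        intensities = {}
        for name in config.conditions:
            df = pd.read_csv(out_dir / "tables" / f"{name}_intensity.csv")
            intensities[name] = df["mean_intensity"].to_numpy()
        if len(intensities) == 2:
            a, b = intensities.values()
            report["intensity_comparison"] = rank_sum_test(a, b)

    elif config.mode == "analyze":
        report["conditions"] = {}
        for path in config.image_paths:
            stack = ImageStack.load(path)
            name = Path(path).stem
            report["conditions"][name] = _analyze_and_write(stack, name, out_dir, config)

    elif config.mode == "flow-design":
        geom = ductflow.ChannelGeometry(
            width=config.width_mm * units.MM_TO_M,
            height=config.height_um * units.UM_TO_M,
            length=config.length_mm * units.MM_TO_M)
        fluid = ductflow.FluidProps(
            viscosity=config.viscosity_mpas * units.MPAS_TO_PAS,
            density=config.density)
        q = units.m3_per_s(config.flow_ml_min)
        report["flow_design"] = ductflow.operating_point_summary(q, geom, fluid)

    elif config.mode == "qpcr":
        table = pd.read_csv(config.qpcr_table)
        plate = QpcrPlate(table, reference_gene=config.reference_gene,
                          control_sample=config.control_sample)
        folds = livak_table(plate)
        (out_dir / "tables").mkdir(exist_ok=True)
        folds.to_csv(out_dir / "tables" / "fold_changes.csv", index=False)
        report["qpcr"] = folds.to_dict(orient="records")

    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
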