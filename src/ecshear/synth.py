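"""Synthetic confluent endothelial monolayers with known ground truth.

Real flow-response experiments produce multi-channel fluorescence
images of confluent monolayers: a junctional marker (VE-cadherin-like)
outlining each cell, a nuclear stain, a Golgi marker, and a nuclear
transcription-factor channel (KLF4-like).  None of that raw data ships
with this package, so the generator here fabricates images with the
same statistical structure *and* emits the per-cell truth needed to
validate every downstream stage:

* cell long-axis orientations follow an axial (180°-periodic) von Mises
  law — sampled by drawing θ from a von Mises with mean 2ᾱ₀ and
  concentration κ and returning α = θ/2, the inverse of the
  angle-doubling transform used in the analysis;
* cells tile the frame as an anisotropic Voronoi mosaic: seed points on
  a jittered lattice, with each seed's metric contracted along its
  sampled orientation axis by the elongation factor, so the fitted long
  axis of every region tracks its assigned true angle;
* nuclei are filled ellipses near each cell's centre whose orientation
  is the cell's angle plus wrapped-normal jitter (correlated but not
  identical alignment, as in real monolayers);
* the Golgi is a small Gaussian blob displaced from the nucleus along a
  polarity angle drawn from a (non-doubled) von Mises relative to the
  flow axis, clipped to the cell;
* the marker channel paints nuclear pixels at a condition-dependent
  level; Gaussian read noise and optional Poisson shot noise are
  applied last.

Fixing the seed makes the output byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from scipy.special import i0, i1
from skimage.segmentation import find_boundaries

from .orientation import fit_region_ellipse
from .polarity import polarity_angle

__all__ = [
    "MonolayerSpec",
    "ImageStack",
    "RenderResult",
    "GenerationError",
    "CHANNEL_NAMES",
    "vonmises_resultant_length",
    "sample_axial_angles",
    "sample_polarity_angles",
    "render_monolayer",
]

CHANNEL_NAMES = ("junction", "nuclei", "golgi", "marker")


class GenerationError(RuntimeError):
    """Raised when a spec cannot be rendered into distinct cells."""


def vonmises_resultant_length(kappa: float) -> float:
    """Population mean resultant length of a von Mises law: I₁(κ)/I₀(κ)."""
    if kappa < 0:
        raise ValueError("concentration must be non-negative")
    if kappa == 0:
        return 0.0
    return float(i1(kappa) / i0(kappa))


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_axial_angles(n: int, mean_deg: float = 0.0, kappa: float = 1.0,
                        seed=0) -> np.ndarray:
    """Draw axial orientation angles in [0°, 180°).

    Inverts the doubling construction: θ ~ vonMises(2·mean, κ) on the
    full circle, α = θ/2 mod 180.  The doubled-angle resultant length of
    the sample converges to I₁(κ)/I₀(κ), so κ directly sets the
    population polarity index.  κ = 0 gives a uniform axial law.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if kappa < 0:
        raise ValueError("concentration must be non-negative")
    rng = _as_rng(seed)
    if kappa == 0:
        theta = rng.uniform(-np.pi, np.pi, size=n)
    else:
        theta = rng.vonmises(np.radians(2.0 * mean_deg), kappa, size=n)
    return (np.degrees(theta) / 2.0) % 180.0


def sample_polarity_angles(n: int, mean_deg: float = 180.0, kappa: float = 1.0,
                           seed=0) -> np.ndarray:
    """Draw signed polarity angles in (−180°, 180°] (plain von Mises)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if kappa < 0:
        raise ValueError("concentration must be non-negative")
    rng = _as_rng(seed)
    if kappa == 0:
        theta = rng.uniform(-np.pi, np.pi, size=n)
    else:
        theta = rng.vonmises(np.radians(mean_deg), kappa, size=n)
    ang = np.degrees(theta)
    ang = ((ang + 180.0) % 360.0) - 180.0
    ang[ang == -180.0] = 180.0
    return ang


@dataclass(frozen=True)
class MonolayerSpec:
    """Everything needed to render one condition, reproducibly.

    The defaults describe a flow-stimulated monolayer: ~500 elongated
    cells aligned near the flow axis (κ_axial = 3), front–rear polarity
    concentrated against the flow (mean 180°, κ_pol = 2), and an
    elevated nuclear marker.  A static monolayer is the same spec with
    κ_axial = κ_pol = 0 and a lower marker mean.
    """

    shape: tuple[int, int] = (800, 800)       # (rows, cols) px
    pixel_size_um: float = 1.0
    n_cells: int = 500
    # axial orientation law of the cell long axes
    mean_axial_deg: float = 0.0
    kappa_axial: float = 3.0
    elongation: float = 2.5                   # major/minor contraction of the cell metric
    # nuclei: coupled to the cell axis with wrapped-normal jitter
    nucleus_semi_major_px: float = 8.0
    nucleus_semi_minor_px: float = 4.5
    nucleus_angle_jitter_sd_deg: float = 15.0
    nucleus_center_jitter_px: float = 1.5
    # Golgi offset along a von Mises polarity angle about the flow axis
    golgi_offset_um: float = 8.0
    polarity_mean_deg: float = 180.0
    kappa_pol: float = 2.0
    golgi_sigma_px: float = 1.8
    # nuclear marker (KLF4-like) intensity model
    marker_mean: float = 200.0
    marker_sd: float = 10.0
    marker_background: float = 20.0
    # mosaic construction
    lattice_jitter: float = 0.35       # seed jitter, fraction of lattice spacing
    alignment_stretch: float = 0.5     # weight of the population-level lattice stretch
    lloyd_iterations: int = 4          # centroidal relaxation passes of the mosaic
    # rendering levels (16-bit a.u.) and noise
    junction_level: float = 12000.0
    nucleus_level: float = 15000.0
    golgi_level: float = 12000.0
    cytoplasm_level: float = 300.0
    noise_gaussian_sd: float = 30.0
    shot_noise: bool = True
    flow_axis: tuple[float, float] = (-1.0, 0.0)
    condition: str = "flow"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("need at least one cell")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")
        if self.kappa_axial < 0 or self.kappa_pol < 0:
            raise ValueError("concentrations must be non-negative")
        if min(self.shape) < 16:
            raise ValueError("image too small")

    @property
    def golgi_offset_px(self) -> float:
        return self.golgi_offset_um / self.pixel_size_um


@dataclass
class ImageStack:
    """The four 16-bit channels of one field of view, plus metadata."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    flow_axis: tuple[float, float] = (-1.0, 0.0)
    seed: int | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def save(self, path) -> None:
        """Write a multi-channel TIFF (axes CYX, metadata in the description)."""
        path = Path(path)
        arr = np.stack([self.channels[name] for name in CHANNEL_NAMES])
        meta = {
            "channels": list(CHANNEL_NAMES),
            "pixel_size_um": self.pixel_size_um,
            "flow_axis": list(self.flow_axis),
            "seed": self.seed,
            "condition": self.condition,
        }
        tifffile.imwrite(path, arr, photometric="minisblack",
                         description=json.dumps(meta))

    @classmethod
    def load(cls, path) -> "ImageStack":
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].tags.get("ImageDescription")
            meta = json.loads(desc.value) if desc is not None else {}
        names = meta.get("channels", list(CHANNEL_NAMES))
        channels = {name: arr[i] for i, name in enumerate(names)}
        return cls(
            channels=channels,
            pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
            flow_axis=tuple(meta.get("flow_axis", (-1.0, 0.0))),
            seed=meta.get("seed"),
            condition=meta.get("condition", ""),
        )


@dataclass
class RenderResult:
    """A rendered field: images, per-cell truth, and the cell label map."""

    stack: ImageStack
    truth: pd.DataFrame
    cell_labels: np.ndarray  # int32, 0 = none (labels tile the full frame)


def _lattice_seeds(spec: MonolayerSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered-lattice seed points (row, col), exactly n_cells of them.

    The lattice is generated in a sheared frame stretched along the
    population mean axis by s = 1 + (e − 1)·ρ(κ)·alignment_stretch,
    where ρ(κ) = I₁(κ)/I₀(κ) is the population alignment strength.  In
    a collectively aligned monolayer cells are spaced further apart
    along their common axis; without this the per-seed anisotropic
    metric cancels between equally-oriented neighbours and aligned
    mosaics degenerate to near-isotropic cells.  The stretch is
    area-preserving (det = 1), so the seed density — and the cell count
    — is unchanged.
    """
    h, w = spec.shape
    n = spec.n_cells
    rho = vonmises_resultant_length(spec.kappa_axial)
    s = 1.0 + (spec.elongation - 1.0) * rho * spec.alignment_stretch
    am = np.radians(spec.mean_axial_deg)
    ca, sa = np.cos(am), np.sin(am)
    rot = np.array([[ca, -sa], [sa, ca]])
    stretch = rot @ np.diag([np.sqrt(s), 1.0 / np.sqrt(s)]) @ rot.T  # math xy
    inv = np.linalg.inv(stretch)
    corners = np.array([[0.0, 0.0], [w, 0.0], [0.0, -h], [w, -h]])  # x=col, y=-row
    pre = corners @ inv.T
    xlo, xhi = pre[:, 0].min(), pre[:, 0].max()
    ylo, yhi = pre[:, 1].min(), pre[:, 1].max()
    margin = 1.15
    for _ in range(6):
        target = int(np.ceil(margin * n * (xhi - xlo) * (yhi - ylo) / (w * h)))
        nrows = max(1, int(round(np.sqrt(target * (yhi - ylo) / (xhi - xlo)))))
        ncols = max(1, int(np.ceil(target / nrows)))
        sx, sy = (xhi - xlo) / ncols, (yhi - ylo) / nrows
        jj, ii = np.meshgrid(np.arange(ncols), np.arange(nrows))
        pts = np.column_stack([xlo + (jj.ravel() + 0.5) * sx,
                               ylo + (ii.ravel() + 0.5) * sy])
        pts += rng.uniform(-spec.lattice_jitter, spec.lattice_jitter,
                           size=pts.shape) * np.array([sx, sy])
        post = pts @ stretch.T
        inside = ((post[:, 0] >= 1.0) & (post[:, 0] <= w - 2.0)
                  & (post[:, 1] <= -1.0) & (post[:, 1] >= -(h - 2.0)))
        post = post[inside]
        if len(post) >= n:
            sel = np.sort(rng.choice(len(post), size=n, replace=False))
            post = post[sel]
            return np.column_stack([-post[:, 1], post[:, 0]])  # (row, col)
        margin *= 1.3
    raise GenerationError("could not place the requested number of seed points")


def _anisotropic_labels(spec: MonolayerSpec, seeds_rc: np.ndarray,
                        angles_deg: np.ndarray) -> np.ndarray:
    """Assign each pixel to the seed minimising the per-seed anisotropic
    metric (coordinates contracted by the elongation factor along the
    seed's orientation axis), searched over the nearest isotropic
    candidates."""
    h, w = spec.shape
    n = len(seeds_rc)
    k = min(n, 24)
    tree = cKDTree(seeds_rc)
    a = np.radians(angles_deg)
    ca, sa = np.cos(a), np.sin(a)
    inv_e = 1.0 / spec.elongation
    labels = np.empty(h * w, dtype=np.int32)
    rows, cols = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                             indexing="ij")
    coords = np.column_stack([rows.ravel(), cols.ravel()])
    chunk = 100_000
    for start in range(0, len(coords), chunk):
        pts = coords[start:start + chunk]
        _, idx = tree.query(pts, k=k)
        idx = np.atleast_2d(idx)
        dr = pts[:, 0:1] - seeds_rc[idx, 0]
        dc = pts[:, 1:2] - seeds_rc[idx, 1]
        # math coords: x = col, y = -row
        u = dc * ca[idx] - dr * sa[idx]
        v = -dc * sa[idx] - dr * ca[idx]
        d2 = (u * inv_e) ** 2 + v ** 2
        best = np.argmin(d2, axis=1)
        labels[start:start + chunk] = idx[np.arange(len(pts)), best] + 1
    return labels.reshape(h, w)


def _ellipse_mask_window(center_rc, semi_major, semi_minor, angle_deg, shape):
    """Boolean ellipse mask and its window slices, in math-angle convention."""
    r0, c0 = center_rc
    rad = int(np.ceil(semi_major)) + 2
    rlo, rhi = max(0, int(r0) - rad), min(shape[0], int(r0) + rad + 1)
    clo, chi = max(0, int(c0) - rad), min(shape[1], int(c0) + rad + 1)
    rr, cc = np.meshgrid(np.arange(rlo, rhi, dtype=float),
                         np.arange(clo, chi, dtype=float), indexing="ij")
    dx = cc - c0
    dy = -(rr - r0)
    a = np.radians(angle_deg)
    u = dx * np.cos(a) + dy * np.sin(a)
    v = -dx * np.sin(a) + dy * np.cos(a)
    mask = (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0
    return mask, (slice(rlo, rhi), slice(clo, chi))


def _wrap_axial(a: float) -> float:
    return a % 180.0


def render_monolayer(spec: MonolayerSpec) -> RenderResult:
    """Render one field of view and its ground truth.

    Returns the four-channel :class:`ImageStack`, a per-cell truth table
    (centroids in px, orientations and polarity in degrees, marker mean,
    border flag) and the noise-free cell label map the images were built
    from.  Identical specs produce identical bytes.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    n = spec.n_cells

    nucleus_area = np.pi * spec.nucleus_semi_major_px * spec.nucleus_semi_minor_px
    if h * w / n < 2.0 * nucleus_area:
        raise GenerationError(
            "cells too dense to render distinct nuclei: "
            f"{h * w / n:.0f} px²/cell vs nucleus area {nucleus_area:.0f} px²")

    seeds = _lattice_seeds(spec, rng)
    alpha_true = sample_axial_angles(n, spec.mean_axial_deg, spec.kappa_axial, rng)
    pol_true = sample_polarity_angles(n, spec.polarity_mean_deg, spec.kappa_pol, rng)
    marker_means = rng.normal(spec.marker_mean, spec.marker_sd, size=n)
    nuc_jitter = rng.normal(0.0, spec.nucleus_angle_jitter_sd_deg, size=n)
    nuc_center_jit = rng.normal(0.0, spec.nucleus_center_jitter_px, size=(n, 2))
    nuc_levels = rng.normal(spec.nucleus_level, 0.08 * spec.nucleus_level, size=n)

    labels = _anisotropic_labels(spec, seeds, alpha_true)
    # centroidal (Lloyd) relaxation in each cell's own metric: regularises
    # region shapes so the fitted long axis tracks the assigned angle.
    # Skipped for isotropic mosaics (elongation 1): there is no axis to
    # track, and relaxation would anneal the tessellation into
    # orientation-correlated crystalline grains.
    relax_passes = spec.lloyd_iterations if spec.elongation > 1.0 else 0
    for _ in range(relax_passes):
        cent = np.array(ndi.center_of_mass(np.ones_like(labels), labels,
                                           index=np.arange(1, n + 1)))
        if np.any(~np.isfinite(cent)):
            raise GenerationError("a cell vanished during mosaic relaxation")
        cent[:, 0] = np.clip(cent[:, 0], 1.0, h - 2.0)
        cent[:, 1] = np.clip(cent[:, 1], 1.0, w - 2.0)
        labels = _anisotropic_labels(spec, cent, alpha_true)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    if np.any(counts[1:] == 0):
        raise GenerationError(
            f"{int(np.sum(counts[1:] == 0))} cells rendered no pixels; "
            "reduce n_cells or elongation for this frame size")

    centroids = np.array(ndi.center_of_mass(np.ones_like(labels), labels,
                                            index=np.arange(1, n + 1)))
    border_ids = np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
    border = np.isin(np.arange(1, n + 1), border_ids)

    junction = np.full((h, w), spec.cytoplasm_level, dtype=float)
    junction[find_boundaries(labels, mode="thick")] = spec.junction_level
    junction = ndi.gaussian_filter(junction, 0.7)

    nuclei_img = np.zeros((h, w), dtype=float)
    golgi_img = np.zeros((h, w), dtype=float)
    marker_img = np.full((h, w), spec.marker_background, dtype=float)

    flow = np.asarray(spec.flow_axis, dtype=float)
    flow_angle = np.degrees(np.arctan2(flow[1], flow[0]))
    slices = ndi.find_objects(labels)

    records = []
    for i in range(n):
        cid = i + 1
        nuc_angle = _wrap_axial(alpha_true[i] + nuc_jitter[i])
        center = centroids[i] + nuc_center_jit[i]
        # keep the nucleus centred on a pixel of its own cell
        r0 = int(np.clip(round(center[0]), 0, h - 1))
        c0 = int(np.clip(round(center[1]), 0, w - 1))
        if labels[r0, c0] != cid:
            sl = slices[i]
            rr, cc = np.nonzero(labels[sl] == cid)
            rr = rr + sl[0].start
            cc = cc + sl[1].start
            j = np.argmin((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
            center = np.array([float(rr[j]), float(cc[j])])
        mask, win = _ellipse_mask_window(center, spec.nucleus_semi_major_px,
                                         spec.nucleus_semi_minor_px, nuc_angle,
                                         (h, w))
        mask &= labels[win] == cid
        if not mask.any():
            raise GenerationError(f"cell {cid} too small to hold a nucleus")
        nuclei_img[win][mask] = nuc_levels[i]
        marker_img[win][mask] = marker_means[i]
        rr, cc = np.nonzero(mask)
        nuc_rc = np.array([rr.mean() + win[0].start, cc.mean() + win[1].start])

        # walk the Golgi centre in from the sampled offset until it sits
        # inside the cell with room for the blob
        phi = np.radians(flow_angle + pol_true[i])
        step = np.array([-np.sin(phi), np.cos(phi)])  # (drow, dcol)
        dist = spec.golgi_offset_px
        g_rc = nuc_rc + dist * step
        for _ in range(30):
            gr = int(np.clip(round(g_rc[0]), 0, h - 1))
            gc = int(np.clip(round(g_rc[1]), 0, w - 1))
            if labels[gr, gc] == cid:
                break
            dist *= 0.85
            g_rc = nuc_rc + dist * step
        blob_mask, bwin = _ellipse_mask_window(
            g_rc, 3.0 * spec.golgi_sigma_px, 3.0 * spec.golgi_sigma_px, 0.0, (h, w))
        brr, bcc = np.meshgrid(np.arange(bwin[0].start, bwin[0].stop, dtype=float),
                               np.arange(bwin[1].start, bwin[1].stop, dtype=float),
                               indexing="ij")
        blob = spec.golgi_level * np.exp(
            -((brr - g_rc[0]) ** 2 + (bcc - g_rc[1]) ** 2)
            / (2.0 * spec.golgi_sigma_px ** 2))
        blob *= labels[bwin] == cid  # clip to the cell
        golgi_img[bwin] = np.maximum(golgi_img[bwin], blob)
        tot = blob.sum()
        if tot <= 0:
            raise GenerationError(f"cell {cid}: Golgi blob fell outside the cell")
        g_centroid = np.array([(blob * brr).sum() / tot, (blob * bcc).sum() / tot])
        pol_actual = polarity_angle(
            (nuc_rc[1], -nuc_rc[0]), (g_centroid[1], -g_centroid[0]), flow)

        records.append({
            "cell_id": cid,
            "cell_row": centroids[i][0], "cell_col": centroids[i][1],
            "orientation_deg": alpha_true[i],
            "nucleus_row": nuc_rc[0], "nucleus_col": nuc_rc[1],
            "nucleus_orientation_deg": nuc_angle,
            "golgi_row": g_centroid[0], "golgi_col": g_centroid[1],
            "polarity_deg": pol_actual,
            "marker_mean": marker_means[i],
            "border": bool(border[i]),
        })

    nuclei_img = ndi.gaussian_filter(nuclei_img, 0.8)
    golgi_img = ndi.gaussian_filter(golgi_img, 0.5)

    channels = {}
    for name, img in (("junction", junction), ("nuclei", nuclei_img),
                      ("golgi", golgi_img), ("marker", marker_img)):
        out = np.clip(img, 0, None)
        if spec.shot_noise:
            out = rng.poisson(out).astype(float)
        out = out + rng.normal(0.0, spec.noise_gaussian_sd, size=out.shape)
        channels[name] = np.clip(np.rint(out), 0, 65535).astype(np.uint16)

    stack = ImageStack(channels=channels, pixel_size_um=spec.pixel_size_um,
                       flow_axis=spec.flow_axis, seed=spec.seed,
                       condition=spec.condition)
    truth = pd.DataFrame.from_records(records)
    return RenderResult(stack=stack, truth=truth, cell_labels=labels)
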