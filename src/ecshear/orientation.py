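"""Axial orientation of cells and nuclei via circular statistics.

A cell's long axis is an *axial* quantity: an angle α is the same
orientation as α + 180°, so orientations live in [0°, 180°).  The
standard trick makes this unimodal: double every angle, θᵢ = 2αᵢ,
analyse θ on the full circle, and halve the results.  Two summaries
matter here:

* the mean direction ᾱ = θ̄ / 2, and
* the polarity index PI = R̄(θ), the length of the mean resultant
  vector of the doubled angles —

  PI = sqrt[(1/N Σ cos θᵢ)² + (1/N Σ sin θᵢ)²]

PI is 0 for a uniformly oriented monolayer and 1 when every cell points
the same way, so it quantifies the collective alignment of an
endothelial monolayer with the flow axis.

Per-object orientations come from an ellipse fit: the principal axes of
the second central moments of an object's pixels.  Angles are measured
counter-clockwise from the +x image axis in mathematical orientation
(the image row index increases *downward*, so y = −row), with the flow
axis along x.  Degrees at the API surface, radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegionShape",
    "AxialSample",
    "CircularSummary",
    "fit_region_ellipse",
    "double_angles",
    "circular_mean_resultant",
    "axial_summary",
    "rayleigh_test",
    "angular_histogram",
]


class EmptySampleError(ValueError):
    """Raised when a circular summary is requested for zero angles."""


@dataclass(frozen=True)
class RegionShape:
    """Ellipse fitted to one segmented object (moments of its pixels)."""

    label: int
    centroid_rc: tuple[float, float]     # (row, col), px
    major_axis_length: float             # px, full axis (4·sqrt(λ_max))
    minor_axis_length: float
    orientation_deg: float               # [0, 180), from +x, y flipped up
    eccentricity: float
    orientation_defined: bool = True


@dataclass(frozen=True)
class AxialSample:
    """Axial angles in degrees, each in [0, 180)."""

    angles_deg: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float) % 180.0
        object.__setattr__(self, "angles_deg", a)

    @property
    def n(self) -> int:
        return self.angles_deg.size


@dataclass(frozen=True)
class CircularSummary:
    """Axial summary: mean direction, polarity index, uniformity p."""

    mean_direction_deg: float      # [0, 180); NaN when PI ~ 0
    polarity_index: float          # R̄ of the doubled angles, in [0, 1]
    n: int
    p_uniform: float               # Rayleigh test on the doubled angles
    doubled_mean_deg: float        # θ̄ in [0, 360)


def fit_region_ellipse(mask: np.ndarray, label: int = 0,
                       eccentricity_threshold: float = 0.05) -> RegionShape:
    """Fit an ellipse to a binary object mask via second central moments.

    The orientation is α = ½·atan2(2 μ₁₁, μ₂₀ − μ₀₂) of the pixel
    distribution in mathematical coordinates (x = col, y = −row), mapped
    to [0°, 180°).  Axis lengths follow the 4·sqrt(eigenvalue) normal
    convention (exact for a filled ellipse).  Objects that are a single
    pixel or nearly circular (eccentricity below the threshold) have no
    meaningful axis and are flagged ``orientation_defined=False``.
    """
    mask = np.asarray(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    x = cols.astype(float)
    y = -rows.astype(float)
    cx, cy = x.mean(), y.mean()
    dx, dy = x - cx, y - cy
    # +1/12 per axis: variance of a unit pixel, matches moments of the
    # continuous shape the pixels sample
    mu20 = np.mean(dx * dx) + 1.0 / 12.0
    mu02 = np.mean(dy * dy) + 1.0 / 12.0
    mu11 = np.mean(dx * dy)
    common = np.sqrt(((mu20 - mu02) / 2.0) ** 2 + mu11 ** 2)
    lam1 = (mu20 + mu02) / 2.0 + common
    lam2 = (mu20 + mu02) / 2.0 - common
    major = 4.0 * np.sqrt(max(lam1, 0.0))
    minor = 4.0 * np.sqrt(max(lam2, 0.0))
    ecc = np.sqrt(1.0 - lam2 / lam1) if lam1 > 0 else 0.0
    alpha = np.degrees(0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)) % 180.0
    defined = rows.size > 1 and ecc >= eccentricity_threshold
    return RegionShape(
        label=label,
        centroid_rc=(float(rows.mean()), float(cols.mean())),
        major_axis_length=float(major),
        minor_axis_length=float(minor),
        orientation_deg=float(alpha),
        eccentricity=float(ecc),
        orientation_defined=bool(defined),
    )


def double_angles(angles_deg) -> np.ndarray:
    """Map axial angles αᵢ ∈ [0°, 180°) to unimodal θᵢ = 2αᵢ ∈ [0°, 360°).

    Out-of-range input is first normalised modulo 180°, which is exactly
    the axial identification of α with α + 180°.
    """
    a = np.asarray(angles_deg, dtype=float) % 180.0
    return (2.0 * a) % 360.0


def circular_mean_resultant(angles_deg) -> tuple[float, float]:
    """Mean direction θ̄ (deg, [0, 360)) and resultant length R̄ ∈ [0, 1].

    θ̄ is NaN when R̄ is numerically zero (the mean of a balanced sample
    is undefined).
    """
    theta = np.radians(np.asarray(angles_deg, dtype=float))
    if theta.size == 0:
        raise EmptySampleError("cannot summarise an empty angular sample")
    c = float(np.mean(np.cos(theta)))
    s = float(np.mean(np.sin(theta)))
    r = float(np.hypot(c, s))
    mean = float(np.degrees(np.arctan2(s, c)) % 360.0) if r > 1e-12 else float("nan")
    return mean, r


def rayleigh_test(angles_deg) -> float:
    """Rayleigh test of circular uniformity; small p ⇒ concentration.

    Uses Z = N R̄² with the standard finite-N correction
    p = exp( sqrt(1 + 4N + 4(N² − R²)) − (1 + 2N) ), R = N R̄.
    """
    theta = np.asarray(angles_deg, dtype=float)
    n = theta.size
    if n < 2:
        raise ValueError("Rayleigh test needs at least 2 angles")
    _, rbar = circular_mean_resultant(theta)
    rn = n * rbar
    p = float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - rn * rn)) - (1.0 + 2.0 * n)))
    return min(max(p, np.finfo(float).tiny), 1.0)


def axial_summary(sample) -> CircularSummary:
    """Summarise axial angles: double, take the circular mean, halve.

    Accepts an :class:`AxialSample` or a plain sequence of degrees.
    """
    angles = sample.angles_deg if isinstance(sample, AxialSample) else np.asarray(sample, dtype=float)
    if angles.size == 0:
        raise EmptySampleError("cannot summarise an empty angular sample")
    theta = double_angles(angles)
    theta_bar, r = circular_mean_resultant(theta)
    mean_axial = (theta_bar / 2.0) % 180.0 if np.isfinite(theta_bar) else float("nan")
    p = rayleigh_test(theta) if angles.size >= 2 else float("nan")
    return CircularSummary(
        mean_direction_deg=mean_axial,
        polarity_index=r,
        n=int(angles.size),
        p_uniform=p,
        doubled_mean_deg=theta_bar,
    )


def angular_histogram(angles_deg, n_bins: int = 36,
                      axial: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of circular data: (bin_edges_deg, counts).

    Axial histograms span [0°, 180°); vectorial ones span (−180°, 180°]
    (angles are wrapped into the range first).  Counts always sum to N.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    a = np.asarray(angles_deg, dtype=float)
    if axial:
        a = a % 180.0
        edges = np.linspace(0.0, 180.0, n_bins + 1)
    else:
        a = ((a + 180.0) % 360.0) - 180.0
        a[a == -180.0] = 180.0
        edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, edges = np.histogram(a, bins=edges)
    return edges, counts
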