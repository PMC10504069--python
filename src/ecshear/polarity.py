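"""Front–rear (axial) polarity from nucleus→Golgi vectors.

Endothelial cells position the Golgi apparatus on one side of the
nucleus; the nucleus→Golgi vector is the standard image-based proxy
for a cell's front–rear polarity axis, and under flow the population
typically polarises *against* the flow direction.

The analysis has three steps: (1) pair each nucleus with a Golgi by a
globally optimal minimum-total-distance assignment (pairs further apart
than a gate distance are discarded — they are almost surely cross-cell
mistakes); (2) express each nucleus→Golgi vector as a signed angle θ in
(−180°, 180°] relative to the flow vector, positive counter-clockwise
(to the left of the flow); (3) summarise with the circular mean
resultant length R̄ (no angle doubling — these are true vectors) and
the signed flow-polarity index FPI = mean cos θ, which is +1 when every
cell points with the flow, −1 against it, and ≈0 for random polarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .orientation import EmptySampleError, circular_mean_resultant

__all__ = [
    "Pairing",
    "PolaritySummary",
    "pair_organelles",
    "polarity_angle",
    "polarity_table",
    "polarity_summary",
]


@dataclass
class Pairing:
    """One-to-one nucleus↔Golgi assignment after distance gating."""

    pairs: list[tuple[int, int]]         # (nucleus index, golgi index)
    distances: list[float]               # px, same order as pairs
    unmatched_nuclei: list[int] = field(default_factory=list)
    unmatched_golgi: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.pairs)


def pair_organelles(nucleus_xy, golgi_xy, max_distance: float = np.inf,
                    method: str = "optimal") -> Pairing:
    """Assign at most one Golgi to each nucleus by centroid distance.

    ``method="optimal"`` (default) minimises the *total* Euclidean
    distance over all one-to-one matchings (Hungarian algorithm on the
    rectangular cost matrix); ``method="greedy"`` repeatedly takes the
    globally closest remaining pair, which is not guaranteed optimal and
    is provided only for comparison.  Pairs further apart than
    ``max_distance`` are dropped and both members reported unmatched.
    """
    nucleus_xy = np.atleast_2d(np.asarray(nucleus_xy, dtype=float)) if len(nucleus_xy) else np.empty((0, 2))
    golgi_xy = np.atleast_2d(np.asarray(golgi_xy, dtype=float)) if len(golgi_xy) else np.empty((0, 2))
    nn, ng = len(nucleus_xy), len(golgi_xy)
    if nn == 0 or ng == 0:
        return Pairing([], [], list(range(nn)), list(range(ng)))
    cost = cdist(nucleus_xy, golgi_xy)
    if method == "optimal":
        rows, cols = linear_sum_assignment(cost)
        candidate = list(zip(rows.tolist(), cols.tolist()))
    elif method == "greedy":
        candidate = []
        c = cost.copy()
        for _ in range(min(nn, ng)):
            i, j = np.unravel_index(np.argmin(c), c.shape)
            if not np.isfinite(c[i, j]):
                break
            candidate.append((int(i), int(j)))
            c[i, :] = np.inf
            c[:, j] = np.inf
    else:
        raise ValueError(f"unknown method {method!r}")
    pairs, dists = [], []
    for i, j in candidate:
        d = float(cost[i, j])
        if d <= max_distance:
            pairs.append((int(i), int(j)))
            dists.append(d)
    matched_n = {i for i, _ in pairs}
    matched_g = {j for _, j in pairs}
    return Pairing(
        pairs=pairs,
        distances=dists,
        unmatched_nuclei=[i for i in range(nn) if i not in matched_n],
        unmatched_golgi=[j for j in range(ng) if j not in matched_g],
    )


def polarity_angle(nucleus_xy, golgi_xy, flow_vector=(-1.0, 0.0)) -> float:
    """Signed angle (deg) of the nucleus→Golgi vector relative to flow.

    Coordinates are mathematical (x right, y up; convert image rows with
    y = −row).  Returns the counter-clockwise angle from the flow vector
    to the polarity vector in (−180°, 180°]: 0° = polarised with the
    flow, ±180° = against it, +90° = to the left of the flow.
    Coincident centroids have no direction → NaN.
    """
    n = np.asarray(nucleus_xy, dtype=float)
    g = np.asarray(golgi_xy, dtype=float)
    f = np.asarray(flow_vector, dtype=float)
    if np.allclose(f, 0):
        raise ValueError("flow vector must be nonzero")
    d = g - n
    if np.allclose(d, 0):
        return float("nan")
    ang = np.degrees(np.arctan2(f[0] * d[1] - f[1] * d[0], f[0] * d[0] + f[1] * d[1]))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def polarity_table(nucleus_xy, golgi_xy, flow_vector=(-1.0, 0.0),
                   max_distance: float = np.inf,
                   method: str = "optimal") -> pd.DataFrame:
    """Pair organelles and tabulate per-cell polarity angles.

    Columns: nucleus_id, golgi_id, nucleus_x/y, golgi_x/y, distance_px,
    polarity_deg.  Rows with undefined angles (coincident centroids) are
    excluded.
    """
    pairing = pair_organelles(nucleus_xy, golgi_xy, max_distance, method)
    rows = []
    for (i, j), d in zip(pairing.pairs, pairing.distances):
        ang = polarity_angle(nucleus_xy[i], golgi_xy[j], flow_vector)
        if np.isnan(ang):
            continue
        rows.append({
            "nucleus_id": i, "golgi_id": j,
            "nucleus_x": nucleus_xy[i][0], "nucleus_y": nucleus_xy[i][1],
            "golgi_x": golgi_xy[j][0], "golgi_y": golgi_xy[j][1],
            "distance_px": d, "polarity_deg": ang,
        })
    return pd.DataFrame(rows, columns=[
        "nucleus_id", "golgi_id", "nucleus_x", "nucleus_y",
        "golgi_x", "golgi_y", "distance_px", "polarity_deg"])


@dataclass(frozen=True)
class PolaritySummary:
    """Population polarity: circular mean, R̄, and signed FPI."""

    mean_direction_deg: float   # (−180, 180]; NaN if R̄ ≈ 0
    resultant_length: float     # R̄ ∈ [0, 1], unsigned concentration
    fpi: float                  # mean cos θ ∈ [−1, 1]; <0 = against flow
    n: int


def polarity_summary(angles_deg) -> PolaritySummary:
    """Summarise signed polarity angles (no doubling — vectorial data).

    |FPI| ≤ R̄ always; FPI = −R̄ when the population is concentrated at
    180° (polarised against the flow).
    """
    theta = np.asarray(angles_deg, dtype=float)
    theta = theta[np.isfinite(theta)]
    if theta.size == 0:
        raise EmptySampleError("no polarity angles to summarise")
    mean, r = circular_mean_resultant(theta)
    if np.isfinite(mean) and mean > 180.0:
        mean -= 360.0
    fpi = float(np.mean(np.cos(np.radians(theta))))
    return PolaritySummary(mean_direction_deg=mean, resultant_length=r,
                           fpi=fpi, n=int(theta.size))
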