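"""Classical segmentation of junction, nuclear and Golgi channels.

Nuclei are found by automatic (Otsu) thresholding of the nuclear stain,
hole filling, a minimum-area filter, and a distance-transform watershed
to split touching nuclei.  Cells are recovered by a seeded watershed on
the junction-marker intensity: junctional staining forms bright ridges
along cell–cell contacts, so flooding from the nucleus seeds partitions
the monolayer with one region per nucleus.  Golgi are thresholded
connected components reduced to intensity-weighted centroids.

Externally produced label maps (e.g. from a learned segmenter) can be
substituted anywhere a ``LabelMap`` array is accepted — downstream
statistics only see label maps and centroids.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.segmentation import relabel_sequential, watershed

__all__ = [
    "max_project",
    "segment_nuclei",
    "segment_cells",
    "segment_golgi",
    "border_labels",
    "label_centroids",
]


def max_project(stack) -> np.ndarray:
    """Maximum-intensity projection of a z-stack along its first axis."""
    arrs = [np.asarray(s) for s in stack]
    if len(arrs) == 0:
        raise ValueError("empty stack")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("slices must share one shape")
    return np.max(np.stack(arrs), axis=0)


def segment_nuclei(image: np.ndarray, threshold: float | None = None,
                   min_area: int = 30, split_touching: bool = True,
                   min_peak_distance: int = 10,
                   smoothing_sigma: float = 1.0) -> np.ndarray:
    """Label nuclei in a nuclear-stain image.

    Global threshold (Otsu unless given), hole filling, minimum-area
    filter, then an optional distance-transform watershed that splits
    touching nuclei.  A blank image yields an empty (all-zero) label
    map, not an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    smoothed = ndi.gaussian_filter(img, smoothing_sigma) if smoothing_sigma > 0 else img
    if threshold is None:
        if np.ptp(smoothed) == 0:
            return np.zeros(img.shape, dtype=np.int32)
        threshold = threshold_otsu(smoothed)
    mask = smoothed > threshold
    mask = ndi.binary_fill_holes(mask)
    mask = remove_small_objects(mask, max_size=min_area - 1)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    if not split_touching:
        labels, _ = ndi.label(mask)
        return labels.astype(np.int32)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(distance, min_distance=min_peak_distance,
                           labels=mask, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if markers.max() == 0:
        labels, _ = ndi.label(mask)
        return labels.astype(np.int32)
    labels = watershed(-distance, markers, mask=mask)
    labels = remove_small_objects(labels, max_size=min_area - 1)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_cells(junction: np.ndarray, seeds: np.ndarray,
                  smoothing_sigma: float = 1.0,
                  exclude_border: bool = False) -> np.ndarray:
    """Seeded watershed on the junction channel; one region per seed.

    Junctional staining marks cell outlines as bright ridges, so the
    watershed of the (lightly smoothed) intensity, flooded from the
    nucleus seed labels, partitions the frame into cells that keep their
    seed's label.  With ``exclude_border`` the regions touching the
    frame edge are zeroed (truncated shapes bias orientation fits).
    """
    junction = np.asarray(junction, dtype=float)
    seeds = np.asarray(seeds)
    if junction.shape != seeds.shape:
        raise ValueError("junction image and seed map shapes differ")
    if seeds.max() == 0:
        return np.zeros(junction.shape, dtype=np.int32)
    surface = ndi.gaussian_filter(junction, smoothing_sigma) if smoothing_sigma > 0 else junction
    labels = watershed(surface, markers=seeds.astype(np.int32)).astype(np.int32)
    if exclude_border:
        for lab in border_labels(labels):
            labels[labels == lab] = 0
    return labels


def border_labels(labels: np.ndarray) -> set[int]:
    """Labels of regions touching the image border (0 excluded)."""
    edge = np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    return set(int(v) for v in np.unique(edge) if v != 0)


def segment_golgi(image: np.ndarray, threshold: float | None = None,
                  min_area: int = 5,
                  smoothing_sigma: float = 1.0) -> np.ndarray:
    """Golgi centroids from threshold + connected components.

    Returns an (n, 2) array of intensity-weighted centroids in (row,
    col); empty for a blank image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    smoothed = ndi.gaussian_filter(img, smoothing_sigma) if smoothing_sigma > 0 else img
    if threshold is None:
        if np.ptp(smoothed) == 0:
            return np.empty((0, 2))
        threshold = threshold_otsu(smoothed)
    mask = smoothed > threshold
    mask = remove_small_objects(mask, max_size=min_area - 1)
    labels, nlab = ndi.label(mask)
    if nlab == 0:
        return np.empty((0, 2))
    weights = np.clip(img - threshold, 0, None) + 1e-9
    coms = ndi.center_of_mass(weights, labels, index=np.arange(1, nlab + 1))
    return np.asarray(coms, dtype=float)


def label_centroids(labels: np.ndarray) -> dict[int, tuple[float, float]]:
    """Centroid (row, col) of every nonzero label."""
    ids = np.unique(labels)
    ids = ids[ids != 0]
    if len(ids) == 0:
        return {}
    coms = ndi.center_of_mass(np.ones_like(labels), labels, index=ids)
    return {int(i): (float(r), float(c)) for i, (r, c) in zip(ids, coms)}
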