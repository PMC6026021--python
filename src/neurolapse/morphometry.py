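"""Per-frame segmentation and morphometric measurement.

Two morphologic filters are applied to each fluorescence frame:

* the **cell body filter** — smoothing, intensity threshold and a
  distance-transform watershed — yields a labeled soma mask with objects
  below a minimum size removed;
* the **neurite filter** — tubeness (ridge) enhancement combined with an
  intensity threshold — yields a binary mask of thin curvilinear structures
  disjoint from soma interiors.

A **node** is the location on the cell body from which a neurite projects;
operationally, a connected component of the overlap between a narrow band
around the soma boundary and the neurite mask.  The five measured features
per cell are: area (cell body size), compactness (isoperimetric ratio
4*pi*A/P^2), mean intensity, node count, and attached neurite length from
the skeleton of the neurite mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import gaussian, sato, threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import dilation, disk as disk_selem, skeletonize
from skimage.segmentation import expand_labels, watershed

__all__ = [
    "SegmentationParams",
    "CellObservation",
    "FrameSegmentation",
    "segment_somata",
    "segment_neurites",
    "detect_nodes",
    "measure_cells",
    "segment_frame",
    "process_stack",
    "observations_to_dataframe",
]

OBS_COLUMNS = [
    "frame",
    "label",
    "x",
    "y",
    "area_um2",
    "compactness",
    "intensity",
    "node_count",
    "neurite_um",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the cell-body and neurite filters.

    Thresholds are ``(method, level)`` pairs; method ``"absolute"`` uses the
    level directly, ``"otsu"`` ignores it.  ``min_object_size_px`` filters
    somata only, never neurites.  Defaults suit the default renderer
    intensities (soma 1000, neurite 400, background 100) at 1.25 um/px.
    """

    soma_threshold: tuple[str, float] = ("absolute", 700.0)
    neurite_threshold: tuple[str, float] = ("absolute", 250.0)
    min_object_size_px: int = 50
    soma_boundary_dilation_px: int = 3
    min_node_component_px: int = 3
    smoothing_sigma_px: float = 1.0
    watershed_min_distance_px: int = 10
    ridge_sigmas: tuple[float, ...] = (1.0, 2.0)
    use_ridge_enhancement: bool = True
    neurite_speckle_px: int = 4


@dataclass
class CellObservation:
    """One segmented cell at one frame."""

    frame: int
    label: int
    centroid_px: tuple[float, float]  # (x, y), pixel-center origin top-left
    area_px: float
    area_um2: float
    compactness: float
    mean_intensity: float
    node_count: int
    neurite_length_um: float
    node_positions_px: list[tuple[float, float]] = field(default_factory=list)
    mask_bbox: tuple[int, int, int, int] | None = None  # (rmin, cmin, rmax, cmax)
    mask: np.ndarray | None = None  # bool array of bbox shape

    def mask_pixels(self) -> np.ndarray | None:
        """Absolute (row, col) coordinates of mask pixels, or None."""
        if self.mask is None or self.mask_bbox is None:
            return None
        rr, cc = np.nonzero(self.mask)
        return np.column_stack([rr + self.mask_bbox[0], cc + self.mask_bbox[1]])


@dataclass
class FrameSegmentation:
    soma_label_image: np.ndarray
    neurite_mask: np.ndarray
    node_markers: dict[int, list[tuple[float, float]]]
    observations: list[CellObservation]


def _remove_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop connected components smaller than ``min_size`` pixels."""
    lab = cc_label(mask, connectivity=2)
    counts = np.bincount(lab.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[lab]


def _resolve_threshold(image: np.ndarray, spec: tuple[str, float]) -> float:
    method, level = spec
    if method == "absolute":
        return float(level)
    if method == "otsu":
        return float(threshold_otsu(image))
    raise ValueError(f"unknown threshold method {method!r}")


def segment_somata(image: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Cell body filter: labeled mask of bright compact regions.

    Touching somata are separated by marker-based watershed on the distance
    transform; objects smaller than ``min_object_size_px`` are removed.  An
    all-background image yields an empty labeling.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    smoothed = gaussian(img, sigma=params.smoothing_sigma_px, preserve_range=True)
    level = _resolve_threshold(smoothed, params.soma_threshold)
    mask = smoothed >= level
    mask = ndi.binary_fill_holes(mask)
    mask = _remove_small(mask, params.min_object_size_px)
    if not mask.any():
        return np.zeros_like(mask, dtype=np.int32)

    distance = ndi.distance_transform_edt(mask)
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        distance,
        min_distance=params.watershed_min_distance_px,
        labels=mask,
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return cc_label(mask, connectivity=2).astype(np.int32)
    labels = watershed(-distance, markers=markers, mask=mask)
    # watershed fragments below the size floor are dropped like any object
    labels = _filter_small_labels(labels, params.min_object_size_px)
    return _relabel_sequential(labels)


def _filter_small_labels(labels: np.ndarray, min_size: int) -> np.ndarray:
    counts = np.bincount(labels.ravel())
    kill = np.nonzero(counts < min_size)[0]
    if kill.size:
        labels = labels.copy()
        labels[np.isin(labels, kill)] = 0
    return labels


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def segment_neurites(
    image: np.ndarray, soma_label_image: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """Neurite filter: binary mask of thin elongated structures.

    Ridge (tubeness) enhancement provides support evidence which is combined
    with an intensity threshold; soma interiors are excluded by construction
    and small speckle removed without a minimum-object-size constraint.
    """
    img = np.asarray(image, dtype=np.float64)
    level = _resolve_threshold(img, params.neurite_threshold)
    mask = img >= level
    if params.use_ridge_enhancement and mask.any():
        ridge = sato(img, sigmas=params.ridge_sigmas, black_ridges=False)
        # dilate the ridge support so attachment pixels at the soma junction
        # (where tubeness dips) survive the conjunction
        support = dilation(ridge > 1e-3 * ridge.max(), disk_selem(2))
        mask &= support
    mask &= soma_label_image == 0
    if params.neurite_speckle_px > 1:
        mask = _remove_small(mask, params.neurite_speckle_px)
    return mask


def _boundary_bands(soma_label_image: np.ndarray, dilation_px: int) -> np.ndarray:
    """Label image of per-soma boundary bands (nearest-soma partition)."""
    expanded = expand_labels(soma_label_image, distance=dilation_px)
    bands = expanded.copy()
    bands[soma_label_image > 0] = 0
    return bands


def detect_nodes(
    soma_label_image: np.ndarray,
    neurite_mask: np.ndarray,
    params: SegmentationParams,
) -> dict[int, list[tuple[float, float]]]:
    """Nodes per soma: components of (boundary band ∩ neurite mask).

    Components smaller than ``min_node_component_px`` are discarded, as are
    components that never touch the soma boundary itself (a neurite merely
    passing through the band, e.g. from a neighboring cell, is not an
    attachment).  A component whose band pixels belong to two somata is
    assigned to the soma with the nearer centroid (ties to the lower label).
    """
    markers: dict[int, list[tuple[float, float]]] = {
        int(l): [] for l in np.unique(soma_label_image) if l > 0
    }
    bands = _boundary_bands(soma_label_image, params.soma_boundary_dilation_px)
    overlap = (bands > 0) & neurite_mask
    if not overlap.any():
        return markers

    soma_adjacent = dilation(soma_label_image > 0, disk_selem(1))
    centroids = {
        int(p.label): p.centroid for p in regionprops(soma_label_image)
    }
    comp = cc_label(overlap, connectivity=2)
    for p in regionprops(comp):
        if p.area < params.min_node_component_px:
            continue
        rr, cc = p.coords[:, 0], p.coords[:, 1]
        if not soma_adjacent[rr, cc].any():
            continue
        owners = np.unique(bands[rr, cc])
        owners = owners[owners > 0]
        if owners.size == 0:
            continue
        if owners.size == 1:
            owner = int(owners[0])
        else:
            cy, cx = p.centroid
            owner = min(
                (int(l) for l in owners),
                key=lambda l: (
                    (centroids[l][0] - cy) ** 2 + (centroids[l][1] - cx) ** 2,
                    l,
                ),
            )
        markers[owner].append((p.centroid[1], p.centroid[0]))  # (x, y)
    return markers


def _skeleton_length_px(coords: np.ndarray) -> float:
    """Length of a skeleton component: unit steps for 4-neighbors, sqrt(2)
    for diagonals, counting each adjacency once."""
    if len(coords) < 2:
        return 0.0
    occupied = {(int(r), int(c)) for r, c in coords}
    length = 0.0
    for r, c in occupied:
        for dr, dc, w in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, math.sqrt(2)),
                          (1, -1, math.sqrt(2))):
            if (r + dr, c + dc) in occupied:
                length += w
    return length


def measure_cells(
    image: np.ndarray,
    soma_label_image: np.ndarray,
    neurite_mask: np.ndarray,
    params: SegmentationParams,
    pixel_size_um: float,
    frame: int = 0,
) -> list[CellObservation]:
    """Measure every segmented soma; returns one observation per label.

    Neurite length is the skeleton length of neurite components attached to
    the soma's boundary band (in um; diagonal steps count sqrt(2)); a
    component attached to two or more somata contributes its length split
    equally among them.
    """
    img = np.asarray(image, dtype=np.float64)
    node_markers = detect_nodes(soma_label_image, neurite_mask, params)
    bands = _boundary_bands(soma_label_image, params.soma_boundary_dilation_px)

    # attribute skeleton length to somata via band contact
    neurite_len_um: dict[int, float] = {l: 0.0 for l in node_markers}
    skel = skeletonize(neurite_mask)
    if skel.any():
        skel_cc = cc_label(skel, connectivity=2)
        for p in regionprops(skel_cc):
            rr, cc = p.coords[:, 0], p.coords[:, 1]
            # contact within 1 px of the band (the skeleton is the medial
            # axis and can sit one pixel off the band)
            touch = set()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    r2 = np.clip(rr + dr, 0, bands.shape[0] - 1)
                    c2 = np.clip(cc + dc, 0, bands.shape[1] - 1)
                    touch.update(int(v) for v in np.unique(bands[r2, c2]) if v > 0)
            if not touch:
                continue
            length_um = _skeleton_length_px(p.coords) * pixel_size_um
            share = length_um / len(touch)
            for l in touch:
                if l in neurite_len_um:
                    neurite_len_um[l] += share

    px_area = pixel_size_um**2
    observations: list[CellObservation] = []
    for p in regionprops(soma_label_image, intensity_image=img):
        label = int(p.label)
        perim = p.perimeter
        compact = 4.0 * math.pi * p.area / perim**2 if perim > 0 else 1.0
        nodes = node_markers.get(label, [])
        rmin, cmin, rmax, cmax = p.bbox
        observations.append(
            CellObservation(
                frame=frame,
                label=label,
                centroid_px=(p.centroid[1], p.centroid[0]),
                area_px=float(p.area),
                area_um2=float(p.area) * px_area,
                compactness=min(1.0, float(compact)),
                mean_intensity=float(p.intensity_mean),
                node_count=len(nodes),
                neurite_length_um=float(neurite_len_um.get(label, 0.0))
                if nodes
                else 0.0,
                node_positions_px=list(nodes),
                mask_bbox=(rmin, cmin, rmax, cmax),
                mask=p.image.copy(),
            )
        )
    observations.sort(key=lambda o: o.label)
    return observations


def segment_frame(
    image: np.ndarray,
    params: SegmentationParams,
    pixel_size_um: float,
    frame: int = 0,
) -> FrameSegmentation:
    """Run the full per-frame pipeline: somata, neurites, nodes, measures."""
    soma = segment_somata(image, params)
    neurites = segment_neurites(image, soma, params)
    obs = measure_cells(image, soma, neurites, params, pixel_size_um, frame=frame)
    return FrameSegmentation(
        soma_label_image=soma,
        neurite_mask=neurites,
        node_markers={o.label: o.node_positions_px for o in obs},
        observations=obs,
    )


def process_stack(
    stack: np.ndarray,
    params: SegmentationParams,
    pixel_size_um: float,
) -> list[list[CellObservation]]:
    """Segment every frame of a (T, H, W) stack."""
    return [
        segment_frame(stack[f], params, pixel_size_um, frame=f).observations
        for f in range(stack.shape[0])
    ]


def observations_to_dataframe(
    per_frame: list[list[CellObservation]] | list[CellObservation],
) -> pd.DataFrame:
    """Flatten observations to the documented tidy CSV schema."""
    if per_frame and isinstance(per_frame[0], CellObservation):
        flat = per_frame  # type: ignore[assignment]
    else:
        flat = [o for frame in per_frame for o in frame]  # type: ignore[union-attr]
    rows = [
        {
            "frame": o.frame,
            "label": o.label,
            "x": o.centroid_px[0],
            "y": o.centroid_px[1],
            "area_um2": o.area_um2,
            "compactness": o.compactness,
            "intensity": o.mean_intensity,
            "node_count": o.node_count,
            "neurite_um": o.neurite_length_um,
        }
        for o in flat
    ]
    return pd.DataFrame(rows, columns=OBS_COLUMNS)
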