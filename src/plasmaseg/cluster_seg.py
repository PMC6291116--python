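"""Splitting touching plasma cells with watershed and a circularity gate.

The level set yields one connected blob per cluster of touching cells.
Because plasma cells are approximately circular at 1000x magnification,
clusters are split in two marker-controlled watershed passes — first the
nuclei (on the distance transform of a nuclei mask), then the full cells
(minima imposed at the nucleus centroids on the distance transform of the
stained mask) — keeping only watershed regions that contain a circular
Hough transform (CHT) center.  A final gate on the nucleus/cell area ratio
discards lymphocyte-like cells whose cytoplasm is scant.

Two nuclei-mask sources are supported: a 2-cluster k-means on the
nucleus-discriminative channels (B, H, V) of the stained pixels, or the
nucleus phase of the level set directly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw, morphology, segmentation, transform
from sklearn.cluster import KMeans

from .levelset import PHASE_NUCLEUS
from .preprocess import ChannelStack

#: Channels fed to the nuclei k-means: where nucleus and cytoplasm separate.
KMEANS_CHANNELS = ("B", "H", "V")


@dataclass(frozen=True)
class CellRecord:
    """Per-instance bookkeeping for one segmented plasma cell."""

    label: int
    area: int
    nucleus_area: int
    nucleus_ratio: float
    centroid: tuple[float, float]  # (row, col), 0-based
    circular: bool


@dataclass
class CellInstanceSet:
    """Labeled segmented cells with nucleus sub-masks.

    ``labels`` is an (H, W) integer map (0 = not a cell); ``nucleus_labels``
    carries the same labels restricted to nucleus pixels.  ``records`` holds
    one :class:`CellRecord` per retained instance.
    """

    labels: np.ndarray
    nucleus_labels: np.ndarray
    records: list[CellRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def instance_labels(self) -> list[int]:
        return [r.label for r in self.records]

    def instance_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def nucleus_mask(self, label: int) -> np.ndarray:
        return self.nucleus_labels == label

    def to_csv(self, path: str | Path) -> None:
        rows = ["label,area,nucleus_area,ratio,centroid_row,centroid_col,circular_flag"]
        for r in self.records:
            rows.append(
                f"{r.label},{r.area},{r.nucleus_area},{r.nucleus_ratio:.6f},"
                f"{r.centroid[0]:.2f},{r.centroid[1]:.2f},{int(r.circular)}"
            )
        Path(path).write_text("\n".join(rows) + "\n")


def nuclei_mask_kmeans(
    stack: ChannelStack, stained_mask: np.ndarray, k: int = 2, seed: int = 0
) -> np.ndarray:
    """Nuclei mask by k-means on the (B, H, V) features of stained pixels.

    The cluster with the lowest mean V (darkest) is taken as nuclei; the
    nucleus of a plasma cell is its darkest structure.  Deterministic for a
    fixed ``seed``.
    """
    stained_mask = np.asarray(stained_mask, dtype=bool)
    if stained_mask.shape != stack.shape:
        raise ValueError("mask and stack shapes disagree")
    n = int(stained_mask.sum())
    if n < k:
        warnings.warn("fewer stained pixels than clusters; returning an empty nuclei mask")
        return np.zeros_like(stained_mask)
    feats = np.stack([stack.plane(c)[stained_mask] for c in KMEANS_CHANNELS], axis=1)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(feats)
    v_col = KMEANS_CHANNELS.index("V")
    dark = int(np.argmin(km.cluster_centers_[:, v_col]))
    mask = np.zeros_like(stained_mask)
    mask[stained_mask] = km.labels_ == dark
    return mask


def nuclei_mask_levelset(phase_mask: np.ndarray) -> np.ndarray:
    """Nuclei mask straight from the nucleus phase of the level set."""
    return np.asarray(phase_mask) == PHASE_NUCLEUS


def equivalent_radius(mask: np.ndarray) -> float:
    """Area-weighted median equivalent-circle radius of mask components.

    Weighting by area keeps the estimate anchored to the real objects when
    the mask carries small speckle components.
    """
    labels, n = ndimage.label(np.asarray(mask, dtype=bool))
    if n == 0:
        return 0.0
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    radii = np.sqrt(areas / np.pi)
    order = np.argsort(radii)
    cum = np.cumsum(areas[order])
    return float(radii[order][np.searchsorted(cum, cum[-1] / 2.0)])


def clean_nuclei_mask(mask: np.ndarray, opening_radius: int = 2, min_px: int = 30) -> np.ndarray:
    """Denoise a nuclei mask: small-disk opening plus speckle removal.

    K-means (and the nucleus level-set phase) produce ragged masks whose
    specks and hairline protrusions over-seed the watershed; a light
    morphological cleanup stabilizes the marker extraction.
    """
    mask = np.asarray(mask, dtype=bool)
    if opening_radius > 0:
        mask = morphology.opening(mask, morphology.disk(opening_radius)).astype(bool)
    if min_px > 0:
        labels, n = ndimage.label(mask)
        if n:
            areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
            keep = np.concatenate(([False], areas >= min_px))
            mask = keep[labels]
    return mask


def estimate_radius_range(
    mask: np.ndarray, lo_frac: float = 0.25, hi_frac: float = 1.5, r_floor: int = 3
) -> tuple[int, int]:
    """CHT radius range from the typical equivalent-circle radius of components."""
    r_med = equivalent_radius(mask)
    if r_med == 0.0:
        return r_floor, r_floor + 1
    r_min = max(r_floor, int(round(lo_frac * r_med)))
    r_max = max(r_min + 1, int(round(hi_frac * r_med)))
    return r_min, r_max


def cht_centers(
    mask: np.ndarray,
    r_min: int,
    r_max: int,
    sensitivity: float = 0.3,
    max_circles: int = 200,
) -> list[tuple[tuple[int, int], int, float]]:
    """Circle centers on the mask's edge map by circular Hough accumulation.

    Returns ``((row, col), radius, score)`` tuples sorted by descending
    normalized accumulator score; only peaks scoring at least
    ``sensitivity`` (1.0 = a complete circle of edge pixels) are kept.
    """
    if r_min >= r_max:
        raise ValueError("r_min must be smaller than r_max")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    edges = segmentation.find_boundaries(mask, mode="inner")
    radii = np.arange(r_min, r_max + 1)
    accums = transform.hough_circle(edges, radii)
    peaks = transform.hough_circle_peaks(
        accums,
        radii,
        min_xdistance=max(1, r_min),
        min_ydistance=max(1, r_min),
        threshold=sensitivity,
        total_num_peaks=max_circles,
        normalize=False,
    )
    out = [
        ((int(cy), int(cx)), int(r), float(score))
        for score, cx, cy, r in zip(*peaks)
        if score >= sensitivity
    ]
    out.sort(key=lambda t: -t[2])
    return out


def _retain_regions_with_centers(
    ws_labels: np.ndarray, centers: list[tuple[tuple[int, int], int, float]]
) -> np.ndarray:
    """Keep watershed regions containing at least one CHT center, relabeled 1..n."""
    keep = set()
    for (r, c), _rad, _s in centers:
        if 0 <= r < ws_labels.shape[0] and 0 <= c < ws_labels.shape[1]:
            lab = int(ws_labels[r, c])
            if lab > 0:
                keep.add(lab)
    out = np.zeros_like(ws_labels)
    for new, lab in enumerate(sorted(keep), start=1):
        out[ws_labels == lab] = new
    return out


def split_nuclei(
    nuclei_mask: np.ndarray,
    r_min: int | None = None,
    r_max: int | None = None,
    sensitivity: float = 0.3,
    h_depth: float = 2.0,
    merge_factor: float = 1.4,
) -> np.ndarray:
    """Split touching nuclei by watershed, keeping only circular regions.

    Watershed floods the negated Euclidean distance transform of the mask
    from its regional maxima.  Maxima come from an h-maxima transform
    (saddles shallower than ``h_depth`` pixels do not seed a split), and
    resulting regions whose centroids sit closer than ``merge_factor``
    times the typical nucleus radius are merged back: two real nuclei are
    separated by at least a cell diameter minus the overlap, while an
    irregular single nucleus can fragment into nearby lobes.  Regions that
    do not contain a CHT center in the radius range are discarded as
    non-circular.
    """
    nuclei_mask = np.asarray(nuclei_mask, dtype=bool)
    if not nuclei_mask.any():
        return np.zeros(nuclei_mask.shape, dtype=np.int32)
    if r_min is None or r_max is None:
        r_min, r_max = estimate_radius_range(nuclei_mask)
    dist = ndimage.distance_transform_edt(nuclei_mask)
    peaks = morphology.h_maxima(dist, h_depth) & nuclei_mask
    markers, _ = ndimage.label(peaks)
    ws = segmentation.watershed(-dist, markers, mask=nuclei_mask)
    # typical single-nucleus radius from the watershed regions themselves
    # (connected components would conflate genuinely touching nuclei)
    ids = np.unique(ws)
    ids = ids[ids > 0]
    if len(ids):
        areas = ndimage.sum_labels(np.ones_like(ws), ws, index=ids)
        radii = np.sqrt(areas / np.pi)
        order = np.argsort(radii)
        cum = np.cumsum(areas[order])
        r_typ = float(radii[order][np.searchsorted(cum, cum[-1] / 2.0)])
        ws = _merge_close_regions(ws, merge_factor * r_typ)
    centers = cht_centers(nuclei_mask, r_min, r_max, sensitivity)
    return _retain_regions_with_centers(ws, centers).astype(np.int32)


def _merge_close_regions(labels: np.ndarray, min_separation: float) -> np.ndarray:
    """Union labels whose centroids lie closer than ``min_separation``."""
    ids = [int(v) for v in np.unique(labels) if v > 0]
    if len(ids) < 2 or min_separation <= 0:
        return labels
    cents = np.asarray(ndimage.center_of_mass(labels > 0, labels, ids))
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if np.hypot(*(cents[a] - cents[b])) < min_separation:
                parent[find(ids[a])] = find(ids[b])
    out = labels.copy()
    for i in ids:
        out[labels == i] = find(i)
    return out


def split_cells(
    stained_mask: np.ndarray,
    nuclei_labels: np.ndarray,
    r_min: int | None = None,
    r_max: int | None = None,
    sensitivity: float = 0.3,
    marker_radius: int = 3,
) -> CellInstanceSet:
    """Segment full cells by watershed seeded at nucleus centroids.

    Each nucleus centroid (dilated to a small disk) imposes a minimum on
    the negated distance transform of the stained mask; watershed regions
    without a CHT center are discarded, and each retained cell is paired
    with the nuclei it contains.
    """
    stained_mask = np.asarray(stained_mask, dtype=bool)
    nuclei_labels = np.asarray(nuclei_labels)
    if stained_mask.shape != nuclei_labels.shape:
        raise ValueError("masks must share a shape")

    empty = CellInstanceSet(
        labels=np.zeros(stained_mask.shape, dtype=np.int32),
        nucleus_labels=np.zeros(stained_mask.shape, dtype=np.int32),
    )
    nuc_ids = [int(v) for v in np.unique(nuclei_labels) if v > 0]
    if not stained_mask.any() or not nuc_ids:
        return empty

    if r_min is None or r_max is None:
        r_min, r_max = estimate_radius_range(stained_mask)

    markers = np.zeros(stained_mask.shape, dtype=np.int32)
    for lab in nuc_ids:
        nuc = nuclei_labels == lab
        if not (nuc & stained_mask).any():
            warnings.warn(f"nucleus {lab} lies outside the stained mask; skipped")
            continue
        r, c = (int(round(v)) for v in ndimage.center_of_mass(nuc))
        if not (0 <= r < markers.shape[0] and 0 <= c < markers.shape[1] and stained_mask[r, c]):
            # centroid fell off the stained mask (concave nucleus): snap to it
            rr, cc = np.nonzero(nuc & stained_mask)
            j = int(np.argmin((rr - r) ** 2 + (cc - c) ** 2))
            r, c = int(rr[j]), int(cc[j])
        dr, dc = draw.disk((r, c), marker_radius, shape=markers.shape)
        markers[dr, dc] = lab
    if not markers.any():
        return empty

    dist = ndimage.distance_transform_edt(stained_mask)
    ws = segmentation.watershed(-dist, markers, mask=stained_mask)
    centers = cht_centers(stained_mask, r_min, r_max, sensitivity)
    cells = _retain_regions_with_centers(ws, centers).astype(np.int32)

    nucleus_labels_out = np.zeros_like(cells)
    records: list[CellRecord] = []
    for lab in (int(v) for v in np.unique(cells) if v > 0):
        cell = cells == lab
        nuc = cell & (nuclei_labels > 0)
        nucleus_labels_out[nuc] = lab
        area = int(cell.sum())
        nuc_area = int(nuc.sum())
        cy, cx = ndimage.center_of_mass(cell)
        records.append(
            CellRecord(
                label=lab,
                area=area,
                nucleus_area=nuc_area,
                nucleus_ratio=nuc_area / area,
                centroid=(float(cy), float(cx)),
                circular=True,
            )
        )
    return CellInstanceSet(labels=cells, nucleus_labels=nucleus_labels_out, records=records)


def filter_by_nucleus_ratio(cells: CellInstanceSet, ratio_max: float = 0.85) -> CellInstanceSet:
    """Drop instances whose nucleus/cell area ratio exceeds ``ratio_max``.

    A plasma cell has abundant cytoplasm; a near-1 ratio indicates a
    lymphocyte-like cell that should not be counted.
    """
    if not 0.0 < ratio_max <= 1.0:
        raise ValueError("ratio_max must lie in (0, 1]")
    keep = [r for r in cells.records if r.nucleus_ratio <= ratio_max]
    keep_labels = {r.label for r in keep}
    labels = np.where(np.isin(cells.labels, list(keep_labels)), cells.labels, 0)
    nucleus = np.where(np.isin(cells.nucleus_labels, list(keep_labels)), cells.nucleus_labels, 0)
    return CellInstanceSet(labels=labels, nucleus_labels=nucleus, records=keep)
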