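"""Synthetic stained-smear scenes with instance-level ground truth.

The generator emulates the four-region structure of a Jenner-Giemsa
stained bone-marrow field: dark blue-violet plasma-cell nuclei inside
lighter violet cytoplasm, a pale mauve background, and pale tan unstained
cells.  Colors are sampled per pixel from per-region RGB Gaussians and the
derived channels (H, S, V, L, a, b) emerge through the forward color-space
conversions, so the nine channels stay mutually consistent.  The default
palette is tuned so that the fitted channel models show the qualitative
separability pattern seen on real smears: nucleus vs cytoplasm separable
(Bhattacharyya distance >= 1) only in B, H and V; unstained cells far from
the stained regions in hue, below the 8-bit hue cut of 120.

Cells are mildly perturbed circles (radial perturbation <= 10%) with an
eccentric inner nucleus; clusters place cell centers ``(2 - 2*overlap) r``
apart.  Ground truth (region map, instance map, nuclei, cluster manifest)
is recorded before color sampling.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .levelset import (
    PHASE_BACKGROUND,
    PHASE_CYTOPLASM,
    PHASE_NUCLEUS,
    PHASE_UNSTAINED,
)

_REGION_PHASE = {
    "nucleus": PHASE_NUCLEUS,
    "cytoplasm": PHASE_CYTOPLASM,
    "background": PHASE_BACKGROUND,
    "unstained": PHASE_UNSTAINED,
}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic stained-smear scene."""

    shape: tuple[int, int] = (256, 256)
    n_single: int = 14
    cluster_sizes: tuple[int, ...] = (2, 2, 2)
    n_unstained: int = 3
    cell_radius: tuple[float, float] = (11.0, 14.0)
    nucleus_frac: tuple[float, float] = (0.55, 0.75)
    overlap: float = 0.3
    boundary_perturb: float = 0.06
    rgb_means: dict = field(default_factory=lambda: {k: v.copy() for k, v in _DEFAULT_RGB_MEANS.items()})
    rgb_stds: dict = field(default_factory=lambda: {k: v.copy() for k, v in _DEFAULT_RGB_STDS.items()})
    noise_std: float = 2.0
    max_retries: int = 2000

    def __post_init__(self) -> None:
        if self.n_single < 0 or self.n_unstained < 0 or any(s < 1 for s in self.cluster_sizes):
            raise ValueError("counts must be nonnegative and cluster sizes >= 1")
        if self.cell_radius[0] <= 0 or self.cell_radius[1] < self.cell_radius[0]:
            raise ValueError("cell_radius must be a positive (min, max) range")
        if not 0.0 <= self.overlap <= 0.6:
            raise ValueError("overlap fraction must lie in [0, 0.6]")

    @property
    def n_cells(self) -> int:
        return self.n_single + sum(self.cluster_sizes)


@dataclass
class GroundTruth:
    """Region map, plasma-cell instance map and scene manifest."""

    region_map: np.ndarray     # phase codes: 3 nucleus, 2 cytoplasm, 1 bg, 0 unstained
    instances: np.ndarray      # per-cell labels, 0 elsewhere
    nucleus_instances: np.ndarray  # instance labels restricted to nuclei
    manifest: dict

    def region_mask(self, region: str) -> np.ndarray:
        return self.region_map == _REGION_PHASE[region]

    @property
    def stained_mask(self) -> np.ndarray:
        return self.region_map >= PHASE_CYTOPLASM

    def region_masks(self) -> dict[str, np.ndarray]:
        return {r: self.region_mask(r) for r in _REGION_PHASE}

    def cluster_instance_ids(self) -> list[list[int]]:
        """Instance labels grouped per multi-cell cluster."""
        return [c["instance_ids"] for c in self.manifest["clusters"]]


# Default palette (8-bit RGB means/stds per region).  The constants are
# chosen so the derived-channel separabilities reproduce the real-smear
# pattern documented in docs/methods.md.
_DEFAULT_RGB_MEANS = {
    "nucleus": np.array([105.0, 78.0, 140.0]),
    "cytoplasm": np.array([92.0, 92.0, 168.0]),
    "background": np.array([225.0, 200.0, 235.0]),
    "unstained": np.array([230.0, 215.0, 100.0]),
}
_DEFAULT_RGB_STDS = {
    "nucleus": np.array([6.0, 6.0, 6.0]),
    "cytoplasm": np.array([7.0, 7.0, 7.0]),
    "background": np.array([8.0, 8.0, 8.0]),
    "unstained": np.array([8.0, 8.0, 8.0]),
}


def default_scene_spec(**overrides) -> SceneSpec:
    """The study-condition scene: 20 plasma cells (three 2-cell clusters),
    three unstained cells, on a 256x256 canvas."""
    return replace(SceneSpec(), **overrides) if overrides else SceneSpec()


def _blob_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    rng: np.random.Generator,
    perturb: float,
) -> np.ndarray:
    """Mildly perturbed disk: r(theta) = r (1 + a1 sin(2t+p1) + a2 sin(3t+p2))."""
    h, w = shape
    a = rng.uniform(0, perturb, size=2)
    p = rng.uniform(0, 2 * np.pi, size=2)
    rows = np.arange(h)[:, None] - center[0]
    cols = np.arange(w)[None, :] - center[1]
    rr = np.hypot(rows, cols)
    theta = np.arctan2(rows, cols)
    r_theta = radius * (1.0 + a[0] * np.sin(2 * theta + p[0]) + a[1] * np.sin(3 * theta + p[1]))
    return rr <= r_theta


def _place_objects(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample object centers: clusters, singles, unstained cells."""
    h, w = spec.shape
    placed: list[tuple[float, float, float]] = []  # (row, col, radius) of every object

    def ok(r: float, c: float, rad: float, gap: float = 4.0) -> bool:
        if not (rad + 2 <= r <= h - rad - 2 and rad + 2 <= c <= w - rad - 2):
            return False
        return all(np.hypot(r - pr, c - pc) >= rad + prad + gap for pr, pc, prad in placed)

    def sample_center(rad: float) -> tuple[float, float]:
        for _ in range(spec.max_retries):
            r = rng.uniform(rad + 2, h - rad - 2)
            c = rng.uniform(rad + 2, w - rad - 2)
            if ok(r, c, rad):
                return r, c
        raise RuntimeError(
            "could not place all objects; use a larger image or fewer/smaller cells"
        )

    clusters = []
    for size in spec.cluster_sizes:
        rad = rng.uniform(*spec.cell_radius)
        # reserve room for the cluster to grow around its first cell
        r0, c0 = sample_center(rad * (1.0 + (size - 1) * (1.0 - spec.overlap)))
        members = [(r0, c0, rad)]
        sep = (2.0 - 2.0 * spec.overlap) * rad
        for _ in range(size - 1):
            for _ in range(spec.max_retries):
                base = members[rng.integers(len(members))]
                ang = rng.uniform(0, 2 * np.pi)
                r, c = base[0] + sep * np.sin(ang), base[1] + sep * np.cos(ang)
                rad_i = rng.uniform(*spec.cell_radius)
                near_member = any(np.hypot(r - mr, c - mc) < sep * 0.9 for mr, mc, _ in members)
                if ok(r, c, rad_i) and not near_member:
                    members.append((r, c, rad_i))
                    break
            else:
                raise RuntimeError("could not grow a cluster; reduce overlap or counts")
        placed.extend(members)
        clusters.append(members)

    singles = []
    for _ in range(spec.n_single):
        rad = rng.uniform(*spec.cell_radius)
        r, c = sample_center(rad)
        placed.append((r, c, rad))
        singles.append((r, c, rad))

    unstained = []
    for _ in range(spec.n_unstained):
        rad = rng.uniform(*spec.cell_radius)
        r, c = sample_center(rad)
        placed.append((r, c, rad))
        unstained.append((r, c, rad))

    return clusters, singles, unstained


def generate_scene(spec: SceneSpec, seed: int = 0) -> tuple[np.ndarray, GroundTruth]:
    """Draw one scene; returns the 8-bit RGB image and its ground truth."""
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    clusters, singles, unstained = _place_objects(spec, rng)

    region = np.full(spec.shape, PHASE_BACKGROUND, dtype=np.uint8)
    instances = np.zeros(spec.shape, dtype=np.int32)
    nucleus_instances = np.zeros(spec.shape, dtype=np.int32)

    for r, c, rad in unstained:
        region[_blob_mask(spec.shape, (r, c), rad, rng, spec.boundary_perturb)] = PHASE_UNSTAINED

    # cytoplasm disks first (later cells overwrite earlier within clusters) ...
    manifest = {"clusters": [], "cells": []}
    label = 0
    cells: list[tuple[int, float, float, float]] = []
    for group_idx, members in enumerate(clusters + [[s] for s in singles]):
        ids = []
        for r, c, rad in members:
            label += 1
            mask = _blob_mask(spec.shape, (r, c), rad, rng, spec.boundary_perturb)
            region[mask] = PHASE_CYTOPLASM
            instances[mask] = label
            cells.append((label, r, c, rad))
            ids.append(label)
            manifest["cells"].append(
                {"id": label, "center": [float(r), float(c)], "radius": float(rad)}
            )
        if len(members) > 1:
            manifest["clusters"].append({"id": group_idx, "instance_ids": ids})

    # ... then nuclei, restricted to the pixels their own cell retained
    for label, r, c, rad in cells:
        frac = rng.uniform(*spec.nucleus_frac)
        nrad = frac * rad
        shift = rng.uniform(0, 0.5 * (rad - nrad))
        ang = rng.uniform(0, 2 * np.pi)
        ncenter = (r + shift * np.sin(ang), c + shift * np.cos(ang))
        nmask = _blob_mask(spec.shape, ncenter, nrad, rng, spec.boundary_perturb)
        nmask &= instances == label
        region[nmask] = PHASE_NUCLEUS
        nucleus_instances[nmask] = label

    img = np.empty((h, w, 3), dtype=np.float64)
    for name, phase in _REGION_PHASE.items():
        sel = region == phase
        n = int(sel.sum())
        if n == 0:
            continue
        samples = rng.normal(spec.rgb_means[name], spec.rgb_stds[name], size=(n, 3))
        img[sel] = samples
    img += rng.normal(0.0, spec.noise_std, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    manifest["n_cells"] = spec.n_cells
    manifest["seed"] = int(seed)
    truth = GroundTruth(
        region_map=region,
        instances=instances,
        nucleus_instances=nucleus_instances,
        manifest=manifest,
    )
    return img, truth
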