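"""Gaussian region color models and Bhattacharyya channel weighting.

The image is modeled as four regions — plasma-cell nucleus, plasma-cell
cytoplasm, background, and unstained cells — each described per color
channel by a Gaussian fitted to the pixel intensities under a labeled mask.
Channel weights for the level-set energies come from the Bhattacharyya
distances between region pairs: a channel receives a (nonzero) weight for a
region only when that channel separates the region from both of its
competitors, in which case the weight is the larger of the two distances.
The weighted models then yield per-region probability maps (weighted
mixtures of per-channel Gaussian densities) and distance images (weighted
squared deviations from region means).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import CHANNEL_NAMES, ChannelStack

#: Region order: level-set phases (1,1), (1,0), (0,1), (0,0).
REGION_NAMES: tuple[str, ...] = ("nucleus", "cytoplasm", "background", "unstained")

#: Canonical order of the six unordered region pairs in a distance table.
PAIR_ORDER: tuple[tuple[str, str], ...] = (
    ("nucleus", "cytoplasm"),
    ("nucleus", "background"),
    ("nucleus", "unstained"),
    ("cytoplasm", "background"),
    ("cytoplasm", "unstained"),
    ("background", "unstained"),
)

#: Competitors each region must be separable from for a channel weight.
_COMPETITORS: dict[str, tuple[str, str]] = {
    "nucleus": ("cytoplasm", "background"),
    "cytoplasm": ("nucleus", "background"),
    "background": ("nucleus", "cytoplasm"),
    "unstained": ("nucleus", "cytoplasm"),
}

#: Density floor applied to probability maps before any logarithm.
P_FLOOR = 1e-12


def _region_index(region: str) -> int:
    try:
        return REGION_NAMES.index(region)
    except ValueError:
        raise KeyError(f"unknown region {region!r}; valid: {REGION_NAMES}") from None


def _channel_index(channel: str) -> int:
    try:
        return CHANNEL_NAMES.index(channel)
    except ValueError:
        raise KeyError(f"unknown channel {channel!r}; valid: {CHANNEL_NAMES}") from None


@dataclass(frozen=True)
class RegionColorModel:
    """Per-(region, channel) Gaussian parameters.

    ``means`` and ``stds`` are ``(4, 9)`` arrays indexed by
    ``REGION_NAMES`` x ``CHANNEL_NAMES``; every std is strictly positive.
    """

    means: np.ndarray
    stds: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(REGION_NAMES), len(CHANNEL_NAMES))
        if self.means.shape != shape or self.stds.shape != shape:
            raise ValueError(f"means/stds must have shape {shape}")
        if not np.all(self.stds > 0):
            raise ValueError("every fitted std must be strictly positive")

    def mean(self, region: str, channel: str) -> float:
        return float(self.means[_region_index(region), _channel_index(channel)])

    def std(self, region: str, channel: str) -> float:
        return float(self.stds[_region_index(region), _channel_index(channel)])

    def region_rgb_mean(self, region: str) -> np.ndarray:
        """Mean (R, G, B) color of a region — e.g. the background fill."""
        return self.means[_region_index(region), :3].copy()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regions": list(REGION_NAMES),
            "channels": list(CHANNEL_NAMES),
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionColorModel":
        payload = json.loads(Path(path).read_text())
        if tuple(payload["regions"]) != REGION_NAMES or tuple(payload["channels"]) != CHANNEL_NAMES:
            raise ValueError("region/channel layout in file does not match this model")
        return cls(np.asarray(payload["means"], float), np.asarray(payload["stds"], float))


@dataclass(frozen=True)
class DistanceTable:
    """Bhattacharyya distances for the six region pairs x nine channels.

    ``values`` has shape ``(9, 6)``: channel rows in ``CHANNEL_NAMES`` order,
    pair columns in ``PAIR_ORDER`` order.  Lookup is symmetric in the pair.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(CHANNEL_NAMES), len(PAIR_ORDER)):
            raise ValueError(f"values must have shape (9, 6), got {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("Bhattacharyya distances must be nonnegative")

    def get(self, region_a: str, region_b: str, channel: str) -> float:
        pair = (region_a, region_b)
        if pair not in PAIR_ORDER:
            pair = (region_b, region_a)
        if pair not in PAIR_ORDER:
            raise KeyError(f"no distance stored for pair ({region_a}, {region_b})")
        return float(self.values[_channel_index(channel), PAIR_ORDER.index(pair)])

    def to_csv(self, path: str | Path) -> None:
        header = "channel," + ",".join(f"{a}|{b}" for a, b in PAIR_ORDER)
        rows = [header]
        for ci, ch in enumerate(CHANNEL_NAMES):
            rows.append(ch + "," + ",".join(f"{v:.6g}" for v in self.values[ci]))
        Path(path).write_text("\n".join(rows) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceTable":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        header = lines[0].split(",")[1:]
        expected = [f"{a}|{b}" for a, b in PAIR_ORDER]
        if header != expected:
            raise ValueError(f"pair columns must be {expected}")
        vals = np.full((len(CHANNEL_NAMES), len(PAIR_ORDER)), np.nan)
        for ln in lines[1:]:
            parts = ln.split(",")
            vals[_channel_index(parts[0])] = [float(x) for x in parts[1:]]
        if np.isnan(vals).any():
            raise ValueError("distance table file is missing channel rows")
        return cls(vals)


@dataclass(frozen=True)
class WeightMatrix:
    """Channel weights per region: ``(9, 4)``, nonnegative."""

    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(CHANNEL_NAMES), len(REGION_NAMES)):
            raise ValueError(f"values must have shape (9, 4), got {self.values.shape}")
        if np.any(self.values < 0):
            raise ValueError("weights must be nonnegative")

    def weight(self, channel: str, region: str) -> float:
        return float(self.values[_channel_index(channel), _region_index(region)])

    def region_weights(self, region: str) -> np.ndarray:
        return self.values[:, _region_index(region)].copy()

    def to_csv(self, path: str | Path) -> None:
        rows = ["channel," + ",".join(REGION_NAMES)]
        for ci, ch in enumerate(CHANNEL_NAMES):
            rows.append(ch + "," + ",".join(f"{v:.6g}" for v in self.values[ci]))
        Path(path).write_text("\n".join(rows) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "WeightMatrix":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        if lines[0].split(",")[1:] != list(REGION_NAMES):
            raise ValueError(f"region columns must be {REGION_NAMES}")
        vals = np.full((len(CHANNEL_NAMES), len(REGION_NAMES)), np.nan)
        for ln in lines[1:]:
            parts = ln.split(",")
            vals[_channel_index(parts[0])] = [float(x) for x in parts[1:]]
        if np.isnan(vals).any():
            raise ValueError("weight matrix file is missing channel rows")
        return cls(vals)


def fit_region_model(stack: ChannelStack, region_masks: dict[str, np.ndarray]) -> RegionColorModel:
    """Fit the per-region, per-channel Gaussians by sample moments.

    Parameters
    ----------
    stack:
        9-channel stack of the image the masks refer to.
    region_masks:
        Mapping from region name (all four of ``REGION_NAMES``) to a boolean
        mask.  Masks must be pairwise disjoint and contain at least two
        pixels each; a region that is constant in some channel is rejected
        because its std would be zero.
    """
    missing = set(REGION_NAMES) - set(region_masks)
    if missing:
        raise ValueError(f"missing region masks: {sorted(missing)}")
    total = np.zeros(stack.shape, dtype=np.int64)
    means = np.empty((len(REGION_NAMES), len(CHANNEL_NAMES)))
    stds = np.empty_like(means)
    for ri, region in enumerate(REGION_NAMES):
        mask = np.asarray(region_masks[region], dtype=bool)
        if mask.shape != stack.shape:
            raise ValueError(f"mask for {region!r} has shape {mask.shape}, expected {stack.shape}")
        n = int(mask.sum())
        if n < 2:
            raise ValueError(f"region {region!r} has {n} pixels; need at least 2 to fit a std")
        total += mask
        vals = stack.planes[mask]  # (n, 9)
        means[ri] = vals.mean(axis=0)
        stds[ri] = vals.std(axis=0, ddof=1)
        if np.any(stds[ri] <= 0):
            bad = [CHANNEL_NAMES[ci] for ci in np.flatnonzero(stds[ri] <= 0)]
            raise ValueError(f"region {region!r} is constant in channel(s) {bad}; std would be 0")
    if np.any(total > 1):
        raise ValueError("region masks must be pairwise disjoint")
    return RegionColorModel(means, stds)


def bhattacharyya_gaussian(mu1, sigma1, mu2, sigma2):
    """Closed-form Bhattacharyya distance between two univariate Gaussians.

    ``D_B = (mu1-mu2)^2 / (4 (s1^2+s2^2)) + 0.5 ln((s1^2+s2^2)/(2 s1 s2))``,
    the exact value of ``-ln integral sqrt(p q)``.  Accepts scalars or
    broadcastable arrays; stds must be strictly positive.
    """
    mu1, sigma1, mu2, sigma2 = (np.asarray(a, dtype=np.float64) for a in (mu1, sigma1, mu2, sigma2))
    if np.any(sigma1 <= 0) or np.any(sigma2 <= 0):
        raise ValueError("standard deviations must be strictly positive")
    v = sigma1**2 + sigma2**2
    d = 0.25 * (mu1 - mu2) ** 2 / v + 0.5 * np.log(v / (2.0 * sigma1 * sigma2))
    return d if d.ndim else float(d)


def distance_table_from_model(model: RegionColorModel) -> DistanceTable:
    """Compute the six-pair distance table from a fitted color model."""
    vals = np.empty((len(CHANNEL_NAMES), len(PAIR_ORDER)))
    for pi, (ra, rb) in enumerate(PAIR_ORDER):
        ia, ib = _region_index(ra), _region_index(rb)
        vals[:, pi] = bhattacharyya_gaussian(
            model.means[ia], model.stds[ia], model.means[ib], model.stds[ib]
        )
    return DistanceTable(vals)


def assign_weights(table: DistanceTable, t_pc: float = 1.0, t_bg: float = 3.0) -> WeightMatrix:
    """Assign channel weights from pairwise separabilities.

    For nucleus and cytoplasm a channel is weighted when its distances to
    both competitors reach ``t_pc``; background and unstained cells must be
    delineated more sharply from the plasma cell, so their threshold is the
    stricter ``t_bg``.  Comparisons are non-strict (>=) and the weight is
    the larger of the two clearing distances.
    """
    vals = np.zeros((len(CHANNEL_NAMES), len(REGION_NAMES)))
    for ri, region in enumerate(REGION_NAMES):
        thresh = t_pc if region in ("nucleus", "cytoplasm") else t_bg
        other_a, other_b = _COMPETITORS[region]
        for ci, ch in enumerate(CHANNEL_NAMES):
            da = table.get(region, other_a, ch)
            db = table.get(region, other_b, ch)
            if da >= thresh and db >= thresh:
                vals[ci, ri] = max(da, db)
    return WeightMatrix(vals)


def _require_weighted(weights: WeightMatrix) -> None:
    sums = weights.values.sum(axis=0)
    for ri, region in enumerate(REGION_NAMES):
        if sums[ri] <= 0:
            raise ValueError(
                f"region {region!r} has an all-zero weight vector; "
                "no channel separates it from its competitors"
            )


def probability_maps(
    stack: ChannelStack,
    model: RegionColorModel,
    weights: WeightMatrix,
    p_floor: float = P_FLOOR,
) -> dict[str, np.ndarray]:
    """Per-region likelihood maps: weighted mixtures of channel Gaussians.

    Each map is ``sum_c w_c N(U_c(x); mu_c, sigma_c) / sum_c w_c``, floored
    at ``p_floor`` so logarithms taken by the level-set energy stay finite.
    """
    _require_weighted(weights)
    maps: dict[str, np.ndarray] = {}
    for ri, region in enumerate(REGION_NAMES):
        w = weights.values[:, ri]
        acc = np.zeros(stack.shape, dtype=np.float64)
        for ci in np.flatnonzero(w):
            mu = model.means[ri, ci]
            sd = model.stds[ri, ci]
            z = (stack.planes[..., ci] - mu) / sd
            acc += w[ci] * np.exp(-0.5 * z * z) / (sd * np.sqrt(2.0 * np.pi))
        maps[region] = np.maximum(acc / w.sum(), p_floor)
    return maps


def distance_images(
    stack: ChannelStack, model: RegionColorModel, weights: WeightMatrix
) -> dict[str, np.ndarray]:
    """Per-region weighted squared deviation from the region color means."""
    _require_weighted(weights)
    imgs: dict[str, np.ndarray] = {}
    for ri, region in enumerate(REGION_NAMES):
        w = weights.values[:, ri]
        acc = np.zeros(stack.shape, dtype=np.float64)
        for ci in np.flatnonzero(w):
            acc += w[ci] * (stack.planes[..., ci] - model.means[ri, ci]) ** 2
        imgs[region] = acc / w.sum()
    return imgs
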