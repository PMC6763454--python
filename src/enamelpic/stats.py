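"""Mis-orientation statistics on PIC maps.

The central measurement: for every valid pixel, the angular distance (in
3D, between c-axis directors) to its neighbors to the right and below, at
a given pixel stride; the distances are histogrammed in 0.5-degree bins.
Repeating with the stride doubling 1, 2, 4, ..., 256 probes how gradually
orientation changes with physical distance, and reading the angle at a
fixed frequency level off each histogram's descending tail condenses each
stride into one number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dichroism import PICMap
from .orientation import angles_to_director, hsb_to_angles, rgb_to_hsb

__all__ = [
    "AngularDistanceHistogram",
    "SpreadSummary",
    "neighbor_distances",
    "histogram",
    "multiscale_histograms",
    "angle_at_frequency",
    "region_spread",
    "map_from_rgb",
    "DEFAULT_STRIDES",
]

DEFAULT_STRIDES: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64, 128, 256)
BIN_WIDTH_DEG = 0.5


@dataclass
class AngularDistanceHistogram:
    """0.5-degree-binned counts of neighbor c-axis distances at one stride."""

    stride: int
    bin_edges: np.ndarray  # [0, 0.5, ..., 90]
    counts: np.ndarray
    n_pairs: int
    bin_width_deg: float = BIN_WIDTH_DEG

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if int(self.counts.sum()) != self.n_pairs:
            raise ValueError("counts must sum to n_pairs")


@dataclass
class SpreadSummary:
    """Orientation spread of a labeled region."""

    label: str
    max_pairwise_deg: float
    modal_neighbor_bin_deg: float | None
    fraction_below_30deg: float
    exact: bool  # False when the max was taken over a pair subsample


def _directors(pic_map: PICMap) -> np.ndarray:
    cp = np.where(pic_map.mask, pic_map.c_prime_deg, 0.0)
    g = np.where(pic_map.mask, pic_map.gamma_deg, 0.0)
    return angles_to_director(cp, g)


def _pair_distances(d: np.ndarray, valid: np.ndarray, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """Right- and below-neighbor distance planes (nan where a member is masked)."""
    h, w = valid.shape
    right = np.full((h, w), np.nan)
    below = np.full((h, w), np.nan)
    if stride < w:
        ok = valid[:, : w - stride] & valid[:, stride:]
        dots = np.abs(np.sum(d[:, : w - stride] * d[:, stride:], axis=-1))
        vals = np.degrees(np.arccos(np.clip(dots, 0.0, 1.0)))
        right[:, : w - stride] = np.where(ok, vals, np.nan)
    if stride < h:
        ok = valid[: h - stride, :] & valid[stride:, :]
        dots = np.abs(np.sum(d[: h - stride, :] * d[stride:, :], axis=-1))
        vals = np.degrees(np.arccos(np.clip(dots, 0.0, 1.0)))
        below[: h - stride, :] = np.where(ok, vals, np.nan)
    return right, below


def neighbor_distances(pic_map: PICMap, stride: int = 1, region: np.ndarray | None = None) -> np.ndarray:
    """Angular distances from each valid pixel to its right and below neighbor.

    For every unmasked pixel (i, j), emits the distance to (i, j+stride)
    and to (i+stride, j) when those pixels exist and are unmasked; pairs
    with any masked member are skipped.  Order is deterministic: row-major
    over pixels, right neighbor before below neighbor.  A stride at or
    beyond the image size yields an empty result.

    ``region`` optionally restricts pairs to those with both members inside
    a boolean region mask.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    valid = pic_map.mask
    if region is not None:
        valid = valid & np.asarray(region, dtype=bool)
    d = _directors(pic_map)
    right, below = _pair_distances(d, valid, stride)
    interleaved = np.stack([right, below], axis=-1).ravel()
    return interleaved[~np.isnan(interleaved)]


def histogram(distances: np.ndarray, stride: int = 1, bin_width_deg: float = BIN_WIDTH_DEG) -> AngularDistanceHistogram:
    """Bin distances into [0, 90] with left-closed bins of ``bin_width_deg``.

    The terminal edge is closed on the right so a distance of exactly 90
    lands in the last bin; counts always sum to the number of input pairs.
    """
    distances = np.asarray(distances, dtype=float)
    edges = np.arange(0.0, 90.0 + bin_width_deg / 2.0, bin_width_deg)
    counts, _ = np.histogram(distances, bins=edges)
    return AngularDistanceHistogram(stride, edges, counts, int(distances.size), bin_width_deg)


def multiscale_histograms(
    pic_map: PICMap,
    strides: tuple[int, ...] = DEFAULT_STRIDES,
    bin_width_deg: float = BIN_WIDTH_DEG,
) -> dict[int, AngularDistanceHistogram]:
    """One neighbor-distance histogram per stride (1, 2, 4, ... doubling).

    Strides exceeding the image size yield empty histograms.
    """
    out = {}
    for s in strides:
        dists = neighbor_distances(pic_map, s)
        out[s] = histogram(dists, s, bin_width_deg)
    return out


def angle_at_frequency(h: AngularDistanceHistogram, level: float) -> float | None:
    """Angle read off the histogram's descending tail at a count level.

    Returns the center of the largest-angle bin whose count still reaches
    ``level`` -- the last crossing of the level on the descending tail;
    None when no bin reaches the level.
    """
    if level <= 0:
        raise ValueError("level must be positive")
    counts = h.counts
    if counts.size == 0 or counts.max() < level:
        return None
    i = int(np.flatnonzero(counts >= level)[-1])
    return float(h.bin_centers[i])


def region_spread(
    pic_map: PICMap,
    region: np.ndarray,
    label: str = "region",
    *,
    exact_limit: int = 5000,
    n_subsample_pairs: int = 1_000_000,
    seed: int = 0,
) -> SpreadSummary:
    """Orientation spread of a region: max pairwise distance plus neighbor stats.

    The max pairwise distance is exact for regions of at most
    ``exact_limit`` valid pixels; larger regions are measured over a seeded
    random subsample of pairs (approximate, typically within a degree or
    two of exact on smooth fields).
    """
    region = np.asarray(region, dtype=bool)
    sel = region & pic_map.mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError("region is empty (no valid pixels)")
    d = angles_to_director(pic_map.c_prime_deg[sel], pic_map.gamma_deg[sel])
    exact = n <= exact_limit
    if exact:
        min_dot = 1.0
        for i0 in range(0, n, 512):
            blk = d[i0 : i0 + 512]
            min_dot = min(min_dot, float(np.abs(blk @ d.T).min()))
    else:
        rng = np.random.default_rng(seed)
        ii = rng.integers(0, n, size=n_subsample_pairs)
        jj = rng.integers(0, n, size=n_subsample_pairs)
        min_dot = float(np.abs(np.sum(d[ii] * d[jj], axis=-1)).min())
    spread = float(np.degrees(np.arccos(np.clip(min_dot, 0.0, 1.0))))

    neigh = neighbor_distances(pic_map, 1, region=region)
    if neigh.size:
        hist = histogram(neigh)
        modal = float(hist.bin_centers[int(np.argmax(hist.counts))])
        frac30 = float(np.mean(neigh < 30.0))
    else:
        modal, frac30 = None, 0.0
    return SpreadSummary(label, spread, modal, frac30, exact)


def map_from_rgb(rgb: np.ndarray, pixel_size_nm: float = 60.0) -> PICMap:
    """Recover a PIC map from an 8-bit RGB rendering (the legacy path).

    Reproduces the published workflow of reading orientations back from the
    map's colors; 8-bit channel quantization adds ~1 degree of orientation
    noise, which plausibly contributes to the 1-degree histogram peak.
    Black pixels (brightness 0) become masked.
    """
    hue, _sat, bri = rgb_to_hsb(rgb)
    mask = bri > 0
    bri_safe = np.where(mask, bri, 1.0)
    cp, g = hsb_to_angles(hue, bri_safe)
    cp = np.where(mask, cp, np.nan)
    g = np.where(mask, g, np.nan)
    return PICMap(cp, g, mask, pixel_size_nm)
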