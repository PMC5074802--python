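"""Projection-density maps, laminar density ratios, and hierarchy ordering.

A grayscale axon-projection image is smoothed with a circular averaging
filter and normalized to its peak; the mean optical density inside the
top-70% contour of each layer band yields the L2-4:L1 density ratio (DR)
of a pathway. DRs across source/target area combinations populate a
matrix from which per-source mean DRs and the hierarchical ordering of
areas are derived. DR > 1 marks feedforward-like termination, DR < 1
feedback-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.morphology import disk

from .exceptions import ConfigError, TooWeakSignalError, UndefinedResultError

__all__ = [
    "DensityImage",
    "LayerBands",
    "DRRecord",
    "DRMatrix",
    "HierarchyReport",
    "optical_density_map",
    "band_density",
    "density_ratio",
    "image_dr",
    "pathway_dr",
    "mean_dr",
    "hierarchy_order",
    "classify_pathway",
]

DEFAULT_FILTER_RADIUS = 10
DEFAULT_CONTOUR_FRACTION = 0.70


@dataclass
class DensityImage:
    """Grayscale projection image; intensity is the bouton-density proxy."""

    pixels: np.ndarray
    pixel_size: float  # um per pixel (rows map to depth from pia)
    slice_id: str = "slice0"
    source_area: str = "SRC"
    target_area: str = "TGT"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ConfigError("image must be a non-empty 2-D array")
        if np.any(self.pixels < 0):
            raise ConfigError("image intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")


@dataclass
class LayerBands:
    """Named depth bands in um from the pia: {name: (upper, lower)}."""

    bands: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if hi <= lo:
                raise ConfigError(f"band {name!r}: bounds must be increasing")
        for required in ("L1", "L2-4"):
            if required not in self.bands:
                raise ConfigError(f"band {required!r} is required")
        l1, l24 = self.bands["L1"], self.bands["L2-4"]
        if max(l1[0], l24[0]) < min(l1[1], l24[1]):
            raise ConfigError("L1 and L2-4 bands must be disjoint")

    def names(self) -> list[str]:
        return list(self.bands)

    def row_mask(self, name: str, n_rows: int, pixel_size: float) -> np.ndarray:
        """Boolean row mask for pixels whose centre depth lies in the band."""
        lo, hi = self.bands[name]
        depths = (np.arange(n_rows) + 0.5) * pixel_size
        return (depths >= lo) & (depths < hi)


@dataclass
class DRRecord:
    """Layer density ratio of one pathway (source -> target)."""

    source_area: str
    target_area: str
    dr: float
    n_slices: int = 1
    too_weak: bool = False


@dataclass
class DRMatrix:
    """Sources x targets matrix of density ratios; missing entries absent."""

    records: dict[tuple[str, str], DRRecord] = field(default_factory=dict)

    def add(self, record: DRRecord) -> None:
        if record.source_area == record.target_area:
            raise ConfigError("diagonal (source == target) entries are not allowed")
        self.records[(record.source_area, record.target_area)] = record

    def sources(self) -> list[str]:
        return sorted({s for s, _ in self.records})

    def entries_for(self, source: str) -> list[float]:
        """Usable DR values for one source (too-weak entries excluded)."""
        return [
            r.dr
            for (s, _), r in sorted(self.records.items())
            if s == source and not r.too_weak and np.isfinite(r.dr)
        ]


@dataclass
class HierarchyReport:
    """Sources ordered by descending mean DR, with pairwise tests."""

    order: list[str]
    means: dict[str, float]
    sems: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    pairwise_stat: dict[tuple[str, str], float]
    ties: list[tuple[str, str]]

    def to_dict(self) -> dict:
        return {
            "order": list(self.order),
            "means": dict(self.means),
            "sems": dict(self.sems),
            "pairwise": {
                f"{a}|{b}": {"statistic": self.pairwise_stat[(a, b)], "p_value": p}
                for (a, b), p in self.pairwise_p.items()
            },
            "ties": [list(t) for t in self.ties],
        }


# ---------------------------------------------------------------------------
# optical density


def optical_density_map(
    image: DensityImage | np.ndarray, filter_radius: int = DEFAULT_FILTER_RADIUS
) -> np.ndarray:
    """Circular-averaging-filtered image normalized to its peak.

    Uses a uniform disk kernel with reflective boundary handling so band
    means near the image edge are not darkened by padding.
    """
    pixels = image.pixels if isinstance(image, DensityImage) else np.asarray(image, float)
    if pixels.size == 0:
        raise ConfigError("empty image")
    if filter_radius < 1:
        raise ConfigError("filter_radius must be >= 1 pixel")
    kernel = disk(int(filter_radius)).astype(np.float64)
    kernel /= kernel.sum()
    smoothed = ndimage.convolve(pixels, kernel, mode="reflect")
    peak = smoothed.max()
    if peak <= 0:
        raise TooWeakSignalError("image has no signal to normalize")
    return smoothed / peak


def band_density(
    density_map: np.ndarray,
    band_mask: np.ndarray,
    fraction: float = DEFAULT_CONTOUR_FRACTION,
    method: str = "range",
) -> float:
    """Mean optical density inside the band's top-``fraction`` contour.

    ``method='range'`` (default) keeps band pixels with OD >=
    ``(1 - fraction) * band max`` — the contour bounding the top
    ``fraction`` of the intensity range. ``method='rank'`` keeps the top
    ``fraction`` of band pixels by value instead.
    """
    if not 0 < fraction <= 1:
        raise ConfigError("fraction must be in (0, 1]")
    band = np.asarray(density_map, dtype=float)[np.asarray(band_mask, dtype=bool)]
    if band.size == 0:
        raise ConfigError("band mask selects no pixels")
    peak = band.max()
    if peak <= 0:
        raise TooWeakSignalError("band has no signal")
    if method == "range":
        selected = band[band >= (1.0 - fraction) * peak]
    elif method == "rank":
        k = max(1, int(np.ceil(fraction * band.size)))
        selected = np.sort(band)[-k:]
    else:
        raise ConfigError(f"unknown contour method {method!r}")
    return float(selected.mean())


def density_ratio(
    density_map: np.ndarray,
    bands: LayerBands,
    pixel_size: float,
    fraction: float = DEFAULT_CONTOUR_FRACTION,
    method: str = "range",
    contour_scope: str = "band",
    source_area: str = "SRC",
    target_area: str = "TGT",
) -> DRRecord:
    """L2-4:L1 density ratio of a filtered, peak-normalized density map.

    ``contour_scope='band'`` thresholds each band against its own maximum
    (default); ``'map'`` thresholds against the whole-map maximum.
    """
    density_map = np.asarray(density_map, dtype=float)
    n_rows = density_map.shape[0]
    masks = {
        name: bands.row_mask(name, n_rows, pixel_size)[:, None]
        & np.ones(density_map.shape, dtype=bool)
        for name in ("L1", "L2-4")
    }
    try:
        if contour_scope == "map":
            thresh = (1.0 - fraction) * density_map.max()
            dens = {}
            for name, mask in masks.items():
                sel = density_map[mask & (density_map >= thresh)]
                if sel.size == 0:
                    raise TooWeakSignalError(f"band {name} empty above map contour")
                dens[name] = float(sel.mean())
        elif contour_scope == "band":
            dens = {
                name: band_density(density_map, mask, fraction, method)
                for name, mask in masks.items()
            }
        else:
            raise ConfigError(f"unknown contour_scope {contour_scope!r}")
        if dens["L1"] <= 0:
            raise TooWeakSignalError("L1 density is zero")
        dr = dens["L2-4"] / dens["L1"]
        return DRRecord(source_area, target_area, float(dr))
    except TooWeakSignalError:
        return DRRecord(source_area, target_area, float("nan"), too_weak=True)


def image_dr(
    image: DensityImage,
    bands: LayerBands,
    filter_radius: int = DEFAULT_FILTER_RADIUS,
    fraction: float = DEFAULT_CONTOUR_FRACTION,
    method: str = "range",
    contour_scope: str = "band",
) -> DRRecord:
    """End-to-end per-slice DR: filter, normalize, contour, ratio."""
    dmap = optical_density_map(image, filter_radius)
    return density_ratio(
        dmap,
        bands,
        image.pixel_size,
        fraction=fraction,
        method=method,
        contour_scope=contour_scope,
        source_area=image.source_area,
        target_area=image.target_area,
    )


def pathway_dr(slice_records: Sequence[DRRecord]) -> DRRecord:
    """Pathway-level DR: mean over usable slice DRs (typically 3 slices)."""
    if len(slice_records) == 0:
        raise ConfigError("no slice records")
    source = slice_records[0].source_area
    target = slice_records[0].target_area
    usable = [r.dr for r in slice_records if not r.too_weak and np.isfinite(r.dr)]
    if not usable:
        return DRRecord(source, target, float("nan"), n_slices=0, too_weak=True)
    return DRRecord(source, target, float(np.mean(usable)), n_slices=len(usable))


# ---------------------------------------------------------------------------
# matrix-level statistics


def mean_dr(matrix: DRMatrix, source: str) -> tuple[float, float]:
    """Arithmetic mean and SEM of a source's DRs over available targets.

    SEM is NaN for a single entry.
    """
    entries = np.asarray(matrix.entries_for(source), dtype=float)
    if entries.size == 0:
        raise UndefinedResultError(f"no usable DR entries for source {source!r}")
    mean = float(entries.mean())
    sem = float(entries.std(ddof=1) / np.sqrt(entries.size)) if entries.size > 1 else float("nan")
    return mean, sem


def hierarchy_order(matrix: DRMatrix) -> HierarchyReport:
    """Order sources by descending mean DR with pairwise Mann-Whitney tests."""
    sources = [s for s in matrix.sources() if len(matrix.entries_for(s)) >= 1]
    eligible = [s for s in sources if len(matrix.entries_for(s)) >= 2]
    if len(eligible) < 2:
        raise ConfigError("hierarchy ordering requires >= 2 sources with >= 2 entries")
    means = {s: mean_dr(matrix, s)[0] for s in sources}
    sems = {s: mean_dr(matrix, s)[1] for s in sources}
    order = sorted(sources, key=lambda s: (-means[s], s))
    ties = [
        (a, b)
        for i, a in enumerate(order)
        for b in order[i + 1 :]
        if means[a] == means[b]
    ]
    pairwise_p: dict[tuple[str, str], float] = {}
    pairwise_stat: dict[tuple[str, str], float] = {}
    for i, a in enumerate(eligible):
        for b in eligible[i + 1 :]:
            xa = np.asarray(matrix.entries_for(a))
            xb = np.asarray(matrix.entries_for(b))
            pooled = np.concatenate([xa, xb])
            if np.all(pooled == pooled[0]):
                stat, p = float(xa.size * xb.size / 2.0), 1.0
            else:
                stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            pairwise_p[(a, b)] = float(p)
            pairwise_stat[(a, b)] = float(stat)
    return HierarchyReport(
        order=order,
        means=means,
        sems=sems,
        pairwise_p=pairwise_p,
        pairwise_stat=pairwise_stat,
        ties=ties,
    )


def classify_pathway(dr: float, ff_threshold: float = 1.0) -> str:
    """Classify a pathway as feedforward ('FF') when DR strictly exceeds the
    threshold, else feedback ('FB')."""
    if not np.isfinite(dr) or dr <= 0:
        raise ConfigError("dr must be a positive finite number")
    return "FF" if dr > ff_threshold else "FB"
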