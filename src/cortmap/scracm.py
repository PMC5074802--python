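"""Gridded-photostimulation input maps and cell/pair/pathway statistics.

The pipeline converts per-site voltage-clamp sweeps (3-5 repetitions per
stimulation site on an 8x16 grid, 75 um pitch) into a per-cell input map:
repetitions are averaged, the pixel value is the baseline-subtracted mean
current over a 75 ms post-stimulus window, and pixels below 4x the baseline
standard deviation of the averaged trace are set to zero. Downstream
statistics (total input, input per pixel, responsive area, time to peak,
PV/Pyr fold ratios, laminar profiles, pathway comparisons) all operate on
these maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import interpolate, stats

from .exceptions import (
    ConfigError,
    ExcludedPairError,
    MissingSitesError,
    UndefinedResultError,
)
from .trace import (
    SweepTrace,
    baseline_bounds,
    rep_average,
    stack_reps,
    window_bounds,
)

__all__ = [
    "SCRACMMap",
    "CellRecording",
    "PairComparison",
    "LaminarProfile",
    "PathwayComparison",
    "baseline_sd",
    "compute_pixel_response",
    "signed_pixel_response",
    "build_map",
    "total_input",
    "mean_epsc_per_area",
    "responsive_area",
    "time_to_peak",
    "pair_ratio",
    "match_pairs",
    "cohort_slope",
    "laminar_profile",
    "average_map",
    "compare_pathways",
    "wilcoxon_signed_rank",
    "paired_ttest",
]

DEFAULT_WINDOW_MS = 75.0
DEFAULT_BASELINE_MS = 100.0
DEFAULT_THRESHOLD_MULT = 4.0
DEFAULT_PAIR_DIST_UM = 100.0


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SCRACMMap:
    """Per-cell input map: grid of response magnitudes in pA.

    ``values[r, c]`` is the significant response magnitude at grid site
    (r, c), 0 where the response did not pass the significance threshold.
    Row 0 is the row nearest the pia; the centre of row r lies at depth
    ``pia_offset + r * pixel_pitch`` um from the pia.
    """

    values: np.ndarray
    pixel_pitch: float = 75.0
    pia_offset: float = 37.5
    soma_position: tuple[float, float] | None = None
    polarity_flags: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ConfigError("map values must be a 2-D grid")
        if np.any(self.values < 0):
            raise ConfigError("map values must be non-negative magnitudes")
        if self.pixel_pitch <= 0:
            raise ConfigError("pixel_pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_pitch**2

    def row_depths(self) -> np.ndarray:
        """Depth of each row centre in um from the pia."""
        return self.pia_offset + np.arange(self.shape[0]) * self.pixel_pitch


@dataclass
class CellRecording:
    """One mapped neuron: per-site repetition sweeps plus metadata.

    ``sweeps`` maps (row, col) grid indices to the 3-5 repetition sweeps
    recorded at that site. ``soma_xy`` is (depth from pia, lateral position)
    in um and is used for pairing PV and Pyr neighbours.
    """

    cell_id: str
    cell_type: str
    layer: str
    conductance: float
    sweeps: dict[tuple[int, int], list[SweepTrace]]
    soma_xy: tuple[float, float] = (0.0, 0.0)
    slice_id: str = "slice0"
    pair_id: str | None = None
    grid_shape: tuple[int, int] = (16, 8)
    pixel_pitch: float = 75.0
    pia_offset: float = 37.5
    map: SCRACMMap | None = None

    def __post_init__(self) -> None:
        if self.cell_type not in ("PV", "Pyr"):
            raise ConfigError(f"cell_type must be 'PV' or 'Pyr', got {self.cell_type!r}")
        if self.conductance <= 0:
            raise ConfigError("conductance must be positive")
        for site, reps in self.sweeps.items():
            if not 3 <= len(reps) <= 5:
                raise ConfigError(
                    f"site {site}: expected 3-5 repetitions, got {len(reps)}"
                )

    def distance_to(self, other: "CellRecording") -> float:
        dx = self.soma_xy[0] - other.soma_xy[0]
        dy = self.soma_xy[1] - other.soma_xy[1]
        return math.hypot(dx, dy)


@dataclass
class PairComparison:
    """Matched PV/Pyr totals and their fold ratio."""

    pv_id: str
    pyr_id: str
    pv_total: float
    pyr_total: float
    fold: float
    fold_norm: float
    distance: float
    layer: str = "L2/3"


@dataclass
class LaminarProfile:
    """Row-wise input distribution as percentages of the cell total."""

    row_totals: np.ndarray  # % of total per row
    row_depths: np.ndarray  # um from pia
    layer_fractions: dict[str, float]  # mean row-total (%) per named band
    layer_sums: dict[str, float]  # summed row-total (%) per named band


@dataclass
class PathwayComparison:
    """Group-comparison report (Kruskal-Wallis plus pairwise Mann-Whitney)."""

    test: str
    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    pairwise: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_sizes": dict(self.group_sizes),
            "pairwise": {
                f"{a}|{b}": {"statistic": s, "p_value": p}
                for (a, b), (s, p) in self.pairwise.items()
            },
        }


# ---------------------------------------------------------------------------
# per-pixel statistics


def baseline_sd(
    sweeps: Sequence[SweepTrace], baseline_ms: float = DEFAULT_BASELINE_MS
) -> float:
    """Standard deviation of the repetition-averaged trace over the
    pre-stimulus baseline window."""
    avg = rep_average(sweeps)
    i0, i1 = baseline_bounds(avg.n_samples, avg.sampling_rate, avg.stim_onset, baseline_ms)
    return float(np.std(avg.samples[i0:i1]))


def signed_pixel_response(
    sweeps: Sequence[SweepTrace],
    window_ms: float = DEFAULT_WINDOW_MS,
    baseline_ms: float = DEFAULT_BASELINE_MS,
) -> float:
    """Baseline-subtracted mean of the repetition-averaged trace over the
    post-stimulus window, with physical sign retained."""
    avg = rep_average(sweeps)
    n, fs, onset = avg.n_samples, avg.sampling_rate, avg.stim_onset
    b0, b1 = baseline_bounds(n, fs, onset, baseline_ms)
    w0, w1 = window_bounds(n, fs, onset, window_ms)
    baseline = float(np.mean(avg.samples[b0:b1]))
    return float(np.mean(avg.samples[w0:w1])) - baseline


def compute_pixel_response(
    sweeps: Sequence[SweepTrace],
    window_ms: float = DEFAULT_WINDOW_MS,
    baseline_ms: float = DEFAULT_BASELINE_MS,
) -> float:
    """Response magnitude in pA: |windowed mean| of the repetition-averaged,
    baseline-subtracted trace."""
    return abs(signed_pixel_response(sweeps, window_ms, baseline_ms))


# ---------------------------------------------------------------------------
# map construction and per-cell statistics


def build_map(
    recording: CellRecording,
    threshold_mult: float = DEFAULT_THRESHOLD_MULT,
    window_ms: float = DEFAULT_WINDOW_MS,
    baseline_ms: float = DEFAULT_BASELINE_MS,
) -> SCRACMMap:
    """Build the significant-response map of one cell.

    A pixel is kept when its response magnitude exceeds ``threshold_mult``
    times the baseline SD of that site's averaged trace; other pixels are 0.
    Requires every grid site to be present. The built map is also attached
    to ``recording.map``.
    """
    rows, cols = recording.grid_shape
    expected = {(r, c) for r in range(rows) for c in range(cols)}
    missing = expected - set(recording.sweeps)
    if missing:
        raise MissingSitesError(missing)

    values = np.zeros((rows, cols))
    flags: list[tuple[int, int]] = []
    for (r, c), reps in recording.sweeps.items():
        if not (0 <= r < rows and 0 <= c < cols):
            raise ConfigError(f"site {(r, c)} outside grid {recording.grid_shape}")
        # single rep-average pass shared by the response and the SD estimate
        avg = stack_reps(reps).mean(axis=0)
        n, fs, onset = avg.shape[0], reps[0].sampling_rate, reps[0].stim_onset
        b0, b1 = baseline_bounds(n, fs, onset, baseline_ms)
        w0, w1 = window_bounds(n, fs, onset, window_ms)
        signed = float(avg[w0:w1].mean() - avg[b0:b1].mean())
        sd = float(np.std(avg[b0:b1]))
        if abs(signed) > threshold_mult * sd:
            values[r, c] = abs(signed)
            vhold = reps[0].holding_potential
            # inward (negative) current expected when clamped below ~-50 mV,
            # outward (positive) at 0 mV
            if vhold is not None:
                if (vhold < -50 and signed > 0) or (vhold > -10 and signed < 0):
                    flags.append((r, c))

    soma_frac = None
    if recording.soma_xy is not None:
        depth, lateral = recording.soma_xy
        soma_frac = (
            (depth - recording.pia_offset) / recording.pixel_pitch,
            lateral / recording.pixel_pitch,
        )
    built = SCRACMMap(
        values=values,
        pixel_pitch=recording.pixel_pitch,
        pia_offset=recording.pia_offset,
        soma_position=soma_frac,
        polarity_flags=flags,
    )
    recording.map = built
    return built


def total_input(scracm_map: SCRACMMap) -> float:
    """Total input in pA: sum of all pixel magnitudes."""
    return float(scracm_map.values.sum())


def mean_epsc_per_area(scracm_map: SCRACMMap) -> float:
    """Mean significant-pixel response divided by pixel area (pA/um^2)."""
    nonzero = scracm_map.values[scracm_map.values > 0]
    if nonzero.size == 0:
        raise UndefinedResultError("no significant pixels")
    return float(nonzero.mean() / scracm_map.pixel_area_um2)


def responsive_area(scracm_map: SCRACMMap) -> float:
    """Area with significant responses: nonzero-pixel count x pixel area (um^2)."""
    return float(np.count_nonzero(scracm_map.values) * scracm_map.pixel_area_um2)


def time_to_peak(
    recording: CellRecording,
    threshold_mult: float = DEFAULT_THRESHOLD_MULT,
    window_ms: float = DEFAULT_WINDOW_MS,
    baseline_ms: float = DEFAULT_BASELINE_MS,
    mode: str = "significant",
) -> float:
    """Mean latency (ms) from stimulus onset to the response extremum.

    ``mode='significant'`` averages over all significant pixels;
    ``mode='peak'`` uses only the strongest pixel.
    """
    scracm_map = recording.map
    if scracm_map is None:
        scracm_map = build_map(recording, threshold_mult, window_ms, baseline_ms)
    sig = np.argwhere(scracm_map.values > 0)
    if sig.size == 0:
        raise UndefinedResultError("no significant pixels")
    if mode == "peak":
        sig = [np.unravel_index(np.argmax(scracm_map.values), scracm_map.shape)]
    elif mode != "significant":
        raise ConfigError(f"unknown time-to-peak mode {mode!r}")

    latencies = []
    for r, c in map(tuple, sig):
        avg = rep_average(recording.sweeps[(r, c)])
        n, fs, onset = avg.n_samples, avg.sampling_rate, avg.stim_onset
        b0, b1 = baseline_bounds(n, fs, onset, baseline_ms)
        w0, w1 = window_bounds(n, fs, onset, window_ms)
        deviation = np.abs(avg.samples[w0:w1] - avg.samples[b0:b1].mean())
        i_ext = w0 + int(np.argmax(deviation))
        latencies.append(i_ext / fs * 1000.0 - onset)
    return float(np.mean(latencies))


# ---------------------------------------------------------------------------
# pairs and cohorts


def pair_ratio(
    pv: CellRecording,
    pyr: CellRecording,
    max_dist_um: float = DEFAULT_PAIR_DIST_UM,
    **map_kwargs,
) -> PairComparison:
    """Fold ratio of total input between a PV cell and its Pyr neighbour.

    ``fold_norm`` divides each cell's total by its own conductance before
    forming the ratio. Raises :class:`ExcludedPairError` when the Pyr total
    is zero.
    """
    if pv.cell_type != "PV" or pyr.cell_type != "Pyr":
        raise ConfigError("pair_ratio expects (PV, Pyr) recordings in that order")
    if pv.layer != pyr.layer:
        raise ConfigError("paired cells must be in the same layer")
    if pv.slice_id != pyr.slice_id:
        raise ConfigError("paired cells must be in the same slice")
    distance = pv.distance_to(pyr)
    if distance > max_dist_um:
        raise ConfigError(
            f"cells are {distance:.1f} um apart (> {max_dist_um} um pairing limit)"
        )
    pv_map = pv.map if pv.map is not None else build_map(pv, **map_kwargs)
    pyr_map = pyr.map if pyr.map is not None else build_map(pyr, **map_kwargs)
    pv_total = total_input(pv_map)
    pyr_total = total_input(pyr_map)
    if pyr_total == 0:
        raise ExcludedPairError(
            f"pair ({pv.cell_id}, {pyr.cell_id}): Pyr total is zero"
        )
    fold = pv_total / pyr_total
    fold_norm = (pv_total / pv.conductance) / (pyr_total / pyr.conductance)
    return PairComparison(
        pv_id=pv.cell_id,
        pyr_id=pyr.cell_id,
        pv_total=pv_total,
        pyr_total=pyr_total,
        fold=fold,
        fold_norm=fold_norm,
        distance=distance,
        layer=pv.layer,
    )


def match_pairs(
    recordings: Sequence[CellRecording],
    max_dist_um: float = DEFAULT_PAIR_DIST_UM,
) -> list[tuple[CellRecording, CellRecording]]:
    """Match PV cells to Pyr neighbours.

    Explicit ``pair_id`` labels take precedence; remaining cells are matched
    one-to-one to the nearest eligible neighbour (same layer and slice,
    within ``max_dist_um``), ties broken by distance then lowest cell_id.
    """
    by_pair: dict[str, dict[str, CellRecording]] = {}
    unlabelled: list[CellRecording] = []
    for rec in recordings:
        if rec.pair_id is not None:
            by_pair.setdefault(rec.pair_id, {})[rec.cell_type] = rec
        else:
            unlabelled.append(rec)

    pairs = [
        (cells["PV"], cells["Pyr"])
        for _, cells in sorted(by_pair.items())
        if "PV" in cells and "Pyr" in cells
    ]

    pvs = [r for r in unlabelled if r.cell_type == "PV"]
    pyrs = [r for r in unlabelled if r.cell_type == "Pyr"]
    candidates = []
    for pv in pvs:
        for pyr in pyrs:
            if pv.layer != pyr.layer or pv.slice_id != pyr.slice_id:
                continue
            d = pv.distance_to(pyr)
            if d <= max_dist_um:
                candidates.append((d, pv.cell_id, pyr.cell_id, pv, pyr))
    used_pv: set[str] = set()
    used_pyr: set[str] = set()
    for d, pv_id, pyr_id, pv, pyr in sorted(candidates, key=lambda t: (t[0], t[1], t[2])):
        if pv_id in used_pv or pyr_id in used_pyr:
            continue
        used_pv.add(pv_id)
        used_pyr.add(pyr_id)
        pairs.append((pv, pyr))
    return pairs


def cohort_slope(
    pairs: Sequence[PairComparison], use_normalized: bool = False
) -> float:
    """Geometric mean of the per-pair fold ratios (the slope of the line
    from the origin through the cohort in a PV-vs-Pyr total plot)."""
    if len(pairs) == 0:
        raise ConfigError("cohort_slope requires at least one pair")
    folds = np.array(
        [p.fold_norm if use_normalized else p.fold for p in pairs], dtype=float
    )
    if np.any(folds <= 0):
        raise ConfigError("all fold ratios must be positive")
    return float(np.exp(np.mean(np.log(folds))))


# ---------------------------------------------------------------------------
# laminar analysis


def laminar_profile(
    scracm_map: SCRACMMap, layer_bands: Mapping[str, tuple[float, float]]
) -> LaminarProfile:
    """Row totals as percent of the cell total, plus per-band fractions.

    ``layer_bands`` maps band names to (upper, lower) depth bounds in um
    from the pia. A row resides in a band when its centre depth lies in
    [upper, lower). The band fraction is the mean of its rows' percentages.
    """
    total = scracm_map.values.sum()
    if total == 0:
        raise UndefinedResultError("zero total input; laminar profile undefined")
    row_totals = scracm_map.values.sum(axis=1) / total * 100.0
    depths = scracm_map.row_depths()
    fractions: dict[str, float] = {}
    sums: dict[str, float] = {}
    for name, (lo, hi) in layer_bands.items():
        if hi <= lo:
            raise ConfigError(f"band {name!r}: bounds must be increasing")
        in_band = (depths >= lo) & (depths < hi)
        fractions[name] = float(row_totals[in_band].mean()) if in_band.any() else float("nan")
        sums[name] = float(row_totals[in_band].sum()) if in_band.any() else float("nan")
    return LaminarProfile(
        row_totals=row_totals,
        row_depths=depths,
        layer_fractions=fractions,
        layer_sums=sums,
    )


def average_map(
    maps: Sequence[SCRACMMap], mode: str = "panel_max", upsample: int = 4
) -> SCRACMMap:
    """Average maps after per-map normalization, then smooth to a finer raster.

    Modes: ``pair_max`` normalizes consecutive (PV, Pyr) map pairs to the
    larger peak of the pair; ``panel_max`` normalizes each map to its own
    peak; ``cell_total`` normalizes each map to its total. Under the two
    peak-normalizing modes the output peak is 1.
    """
    if len(maps) == 0:
        raise ConfigError("no maps to average")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ConfigError("maps must share a common grid shape")

    arrays = [m.values for m in maps]
    if mode == "cell_total":
        normed = []
        for v in arrays:
            if v.sum() == 0:
                raise UndefinedResultError("cell_total normalization with zero total")
            normed.append(v / v.sum())
    elif mode == "panel_max":
        normed = []
        for v in arrays:
            if v.max() == 0:
                raise UndefinedResultError("panel_max normalization with zero peak")
            normed.append(v / v.max())
    elif mode == "pair_max":
        if len(arrays) % 2 != 0:
            raise ConfigError("pair_max mode requires an even number of maps")
        normed = []
        for i in range(0, len(arrays), 2):
            peak = max(arrays[i].max(), arrays[i + 1].max())
            if peak == 0:
                raise UndefinedResultError("pair_max normalization with zero peak")
            normed.append(arrays[i] / peak)
            normed.append(arrays[i + 1] / peak)
    else:
        raise ConfigError(f"unknown averaging mode {mode!r}")

    avg = np.mean(normed, axis=0)
    rows, cols = shape
    if upsample > 1 and rows >= 4 and cols >= 4:
        spline = interpolate.RectBivariateSpline(
            np.arange(rows), np.arange(cols), avg, kx=3, ky=3, s=0
        )
        # exact 1/upsample index step so both axes share one physical pitch
        rf = np.arange((rows - 1) * upsample + 1) / upsample
        cf = np.arange((cols - 1) * upsample + 1) / upsample
        fine = np.clip(spline(rf, cf), 0, None)
        fine_pitch = maps[0].pixel_pitch / upsample
    else:
        fine = avg
        fine_pitch = maps[0].pixel_pitch
    if mode in ("panel_max", "pair_max") and fine.max() > 0:
        fine = fine / fine.max()
    return SCRACMMap(
        values=fine, pixel_pitch=fine_pitch, pia_offset=maps[0].pia_offset
    )


# ---------------------------------------------------------------------------
# statistics across pathways


def _all_identical(groups: Sequence[np.ndarray]) -> bool:
    pooled = np.concatenate(groups)
    return bool(np.all(pooled == pooled[0]))


def compare_pathways(groups: Mapping[str, Sequence[float]]) -> PathwayComparison:
    """Kruskal-Wallis test across pathway groups with pairwise two-sided
    Mann-Whitney U follow-ups."""
    names = list(groups)
    if len(names) < 2:
        raise ConfigError("compare_pathways requires at least two groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    for n, a in zip(names, arrays):
        if a.size == 0:
            raise ConfigError(f"group {n!r} is empty")
    if _all_identical(arrays):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*arrays)
    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if _all_identical([arrays[i], arrays[j]]):
                pairwise[(names[i], names[j])] = (
                    float(arrays[i].size * arrays[j].size / 2.0),
                    1.0,
                )
            else:
                u, pu = stats.mannwhitneyu(
                    arrays[i], arrays[j], alternative="two-sided"
                )
                pairwise[(names[i], names[j])] = (float(u), float(pu))
    return PathwayComparison(
        test="kruskal-wallis",
        statistic=float(stat),
        p_value=float(p),
        group_sizes={n: a.size for n, a in zip(names, arrays)},
        pairwise=pairwise,
    )


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples (e.g. PV vs
    Pyr totals within pairs). Zero differences are rank-split."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ConfigError("paired test requires matched samples of size >= 2")
    stat, p = stats.wilcoxon(x, y, zero_method="zsplit", alternative="two-sided")
    return float(stat), float(p)


def paired_ttest(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test (used for time-to-peak comparisons)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ConfigError("paired test requires matched samples of size >= 2")
    stat, p = stats.ttest_rel(x, y)
    return float(stat), float(p)
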