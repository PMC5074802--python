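"""Synthetic recordings and images with known ground truth.

Three generators emulate the experimental inputs the analysis pipelines
expect: gridded photostimulation sweeps with planted PV:Pyr amplitude
folds, laminar projection images with planted layer density ratios, and
PV/Pyr paired recordings with planted connectivity.

The synaptic-current kernel is a difference of exponentials
``A * (exp(-t/tau_decay) - exp(-t/tau_rise))`` scaled so that the mean of
its samples over the analysis window equals the target amplitude; the
windowed mean of a noiseless sweep therefore reproduces the planted
ground-truth amplitude exactly, and the kernel peak time has the closed
form ``ln(tau_d/tau_r) * tau_d*tau_r / (tau_d - tau_r)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .exceptions import ConfigError
from .hierarchy import DensityImage, LayerBands
from .paired import PairedRecording
from .scracm import CellRecording
from .trace import SweepTrace, window_bounds

__all__ = [
    "ScracmSimConfig",
    "GroundTruth",
    "epsc_kernel",
    "generate_scracm_dataset",
    "generate_projection_image",
    "generate_paired_recording",
    "generate_paired_cohort",
]


@dataclass
class ScracmSimConfig:
    """Parameters of the gridded-photostimulation simulation.

    Grid geometry and analysis windows default to the experimental
    protocol: an 8x16 stimulation grid at 75 um pitch and a 75 ms
    response window, with 3-5 repetitions per site.
    """

    n_pairs: int = 10
    grid_rows: int = 16
    grid_cols: int = 8
    pixel_pitch: float = 75.0
    reps_per_site: int = 3
    sampling_rate: float = 10_000.0
    baseline_duration: float = 100.0  # ms before stimulus onset
    window_duration: float = 75.0  # ms analysis window
    tail_duration: float = 25.0  # ms after window
    noise_sd: float = 2.0  # pA per sample
    pyr_peak_amplitude: float = 30.0  # pA windowed-mean at footprint centre
    pv_fold: float = 4.0  # planted geometric-mean PV:Pyr fold
    pv_fold_spread: float = 0.0  # log-normal sigma of per-pair folds
    input_center_row: float = 6.0  # grid rows (0-based)
    input_sigma_rows: float = 2.0
    tau_rise_pv: float = 1.0  # ms
    tau_rise_pyr: float = 3.0  # ms
    tau_decay: float = 20.0  # ms
    layer_boundaries: tuple[float, ...] = (100.0, 400.0, 600.0, 850.0)
    pia_offset: float = 37.5  # um from pia to row-0 centres
    layer: str = "L2/3"
    holding_potential: float = -70.0  # mV
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pixel_pitch",
            "sampling_rate",
            "baseline_duration",
            "window_duration",
            "noise_sd",
            "pyr_peak_amplitude",
            "pv_fold",
            "pv_fold_spread",
            "input_sigma_rows",
            "tau_rise_pv",
            "tau_rise_pyr",
            "tau_decay",
        ):
            value = getattr(self, name)
            if name in ("noise_sd", "pv_fold_spread", "pyr_peak_amplitude"):
                if value < 0:
                    raise ConfigError(f"{name} must be non-negative")
            elif value <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        if not 3 <= self.reps_per_site <= 5:
            raise ConfigError("reps_per_site must be in [3, 5]")
        bounds = self.layer_boundaries
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ConfigError("layer_boundaries must be strictly increasing")

    @property
    def trace_duration(self) -> float:
        return self.baseline_duration + self.window_duration + self.tail_duration

    @property
    def n_samples(self) -> int:
        return int(round(self.trace_duration * self.sampling_rate / 1000.0))

    def layer_bands(self) -> dict[str, tuple[float, float]]:
        names = ("L1", "L2-4", "L5", "L6")
        edges = (0.0,) + tuple(self.layer_boundaries)
        return {n: (edges[i], edges[i + 1]) for i, n in enumerate(names)}

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted quantities the recovery tests check against."""

    pair_folds: dict[str, float] = field(default_factory=dict)
    amplitudes: dict[str, np.ndarray] = field(default_factory=dict)
    connected: dict[str, bool] = field(default_factory=dict)
    planted_dr: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pair_folds": dict(self.pair_folds),
            "amplitudes": {k: v.tolist() for k, v in self.amplitudes.items()},
            "connected": dict(self.connected),
            "planted_dr": dict(self.planted_dr),
        }


def epsc_kernel(
    n_samples: int,
    sampling_rate: float,
    tau_rise: float,
    tau_decay: float,
    window_samples: int,
) -> np.ndarray:
    """Difference-of-exponentials kernel whose mean over the first
    ``window_samples`` samples is exactly 1."""
    if tau_decay <= tau_rise:
        raise ConfigError("tau_decay must exceed tau_rise")
    t = np.arange(n_samples) * 1000.0 / sampling_rate
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    m = k[:window_samples].mean()
    if m <= 0:
        raise ConfigError("degenerate kernel window")
    return k / m


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Closed-form peak latency (ms) of the difference-of-exponentials kernel."""
    return float(
        np.log(tau_decay / tau_rise) * tau_decay * tau_rise / (tau_decay - tau_rise)
    )


def _footprint(config: ScracmSimConfig) -> np.ndarray:
    """Noiseless Pyr amplitude per grid site (pA); zero outside 3 sigma."""
    rows = np.arange(config.grid_rows, dtype=float)
    z = (rows - config.input_center_row) / config.input_sigma_rows
    profile = np.where(np.abs(z) <= 3.0, np.exp(-0.5 * z**2), 0.0)
    amp = config.pyr_peak_amplitude * profile
    return np.repeat(amp[:, None], config.grid_cols, axis=1)


def generate_scracm_dataset(
    config: ScracmSimConfig,
) -> tuple[list[CellRecording], GroundTruth]:
    """Simulate PV/Pyr cell pairs under gridded photostimulation.

    Each pair shares a laminar input footprint; the PV cell's noiseless
    amplitudes are the Pyr cell's scaled by the pair's planted fold, drawn
    log-normally around ``pv_fold`` (geometric mean). Sweeps are the
    noiseless kernel plus white Gaussian noise. Deterministic under
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = config.n_samples
    onset_idx, onset_end = window_bounds(
        n, fs, config.baseline_duration, config.window_duration
    )
    window_samples = onset_end - onset_idx
    resp_len = n - onset_idx

    kernels = {
        "PV": epsc_kernel(resp_len, fs, config.tau_rise_pv, config.tau_decay, window_samples),
        "Pyr": epsc_kernel(resp_len, fs, config.tau_rise_pyr, config.tau_decay, window_samples),
    }
    pyr_amp = _footprint(config)

    truth = GroundTruth()
    recordings: list[CellRecording] = []
    n_sites = config.grid_rows * config.grid_cols
    mid_lateral = (config.grid_cols - 1) / 2.0 * config.pixel_pitch
    soma_depth = config.pia_offset + config.input_center_row * config.pixel_pitch

    for i in range(config.n_pairs):
        pair_id = f"pair{i:03d}"
        fold = config.pv_fold * float(np.exp(config.pv_fold_spread * rng.standard_normal()))
        truth.pair_folds[pair_id] = fold

        # soma geometry: Pyr near footprint centre, PV a nearby neighbour
        pyr_xy = (
            soma_depth + float(rng.uniform(-20, 20)),
            mid_lateral + float(rng.uniform(-20, 20)),
        )
        offset_angle = float(rng.uniform(0, 2 * np.pi))
        offset_r = float(rng.uniform(15, 80))
        pv_xy = (
            pyr_xy[0] + offset_r * np.cos(offset_angle),
            pyr_xy[1] + offset_r * np.sin(offset_angle),
        )

        for cell_type, amp_map, soma_xy, vhold_g in (
            ("PV", fold * pyr_amp, pv_xy, float(np.clip(rng.normal(10.0, 1.0), 1.0, None))),
            ("Pyr", pyr_amp, pyr_xy, float(np.clip(rng.normal(5.0, 0.5), 1.0, None))),
        ):
            cell_id = f"{pair_id}_{cell_type}"
            kernel = kernels[cell_type]
            noise = rng.normal(
                0.0, config.noise_sd, size=(n_sites, config.reps_per_site, n)
            )
            flat_amp = amp_map.ravel()
            hit = np.flatnonzero(flat_amp > 0)
            if hit.size:
                noise[hit, :, onset_idx:] += (
                    -flat_amp[hit, None, None] * kernel[None, None, :]
                )
            sweeps: dict[tuple[int, int], list[SweepTrace]] = {}
            site = 0
            for r in range(config.grid_rows):
                for c in range(config.grid_cols):
                    block = noise[site]
                    sweeps[(r, c)] = [
                        SweepTrace(
                            samples=block[k],
                            sampling_rate=fs,
                            stim_onset=config.baseline_duration,
                            holding_potential=config.holding_potential,
                        )
                        for k in range(config.reps_per_site)
                    ]
                    site += 1
            truth.amplitudes[cell_id] = amp_map.copy()
            recordings.append(
                CellRecording(
                    cell_id=cell_id,
                    cell_type=cell_type,
                    layer=config.layer,
                    conductance=vhold_g,
                    sweeps=sweeps,
                    soma_xy=soma_xy,
                    slice_id=f"slice{i:03d}",
                    pair_id=pair_id,
                    grid_shape=(config.grid_rows, config.grid_cols),
                    pixel_pitch=config.pixel_pitch,
                    pia_offset=config.pia_offset,
                )
            )
    return recordings, truth


# ---------------------------------------------------------------------------
# projection images


def generate_projection_image(
    planted_dr: float,
    layer_bands: Mapping[str, tuple[float, float]] | LayerBands,
    texture_scale: float = 4.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (300, 100),
    pixel_size: float = 2.0,
    base_intensity: float = 100.0,
    slice_id: str = "slice0",
    source_area: str = "SRC",
    target_area: str = "TGT",
) -> tuple[DensityImage, LayerBands, GroundTruth]:
    """Synthesize an axon-projection image with a planted L2-4:L1 ratio.

    The image is an axon-like multiplicative texture (smoothed Gaussian
    noise, bounded away from zero) rescaled within each layer band so that,
    before additive noise, ``mean(L2-4) / mean(L1) == planted_dr`` exactly.
    Rows map to depth: row i covers [i, i+1) * pixel_size um from the pia.
    """
    if planted_dr <= 0:
        raise ConfigError("planted_dr must be positive")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    bands = layer_bands if isinstance(layer_bands, LayerBands) else LayerBands(dict(layer_bands))

    rng = np.random.default_rng(seed)
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), texture_scale)
    sd = texture.std()
    if sd > 0:
        texture = texture / sd
    texture = np.clip(1.0 + 0.25 * texture, 0.6, 1.5)

    targets = {name: base_intensity for name in bands.names()}
    targets["L1"] = base_intensity
    targets["L2-4"] = base_intensity * planted_dr
    for name in bands.names():
        if name not in ("L1", "L2-4"):
            targets[name] = base_intensity * 0.5

    image = texture * (base_intensity * 0.2)  # background outside any band
    for name in bands.names():
        mask = bands.row_mask(name, shape[0], pixel_size)
        if not mask.any():
            continue
        block = texture[mask, :]
        image[mask, :] = block * (targets[name] / block.mean())

    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=shape)
    image = np.clip(image, 0.0, None)

    density = DensityImage(
        pixels=image,
        pixel_size=pixel_size,
        slice_id=slice_id,
        source_area=source_area,
        target_area=target_area,
    )
    truth = GroundTruth(planted_dr={slice_id: planted_dr})
    return density, bands, truth


# ---------------------------------------------------------------------------
# paired recordings


def ipsc_kernel(
    n_samples: int, sampling_rate: float, tau_rise: float = 1.0, tau_decay: float = 10.0
) -> np.ndarray:
    """Unit-peak outward synaptic-current kernel."""
    t = np.arange(n_samples) * 1000.0 / sampling_rate
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    peak = k.max()
    if peak <= 0:
        raise ConfigError("degenerate IPSC kernel")
    return k / peak


def generate_paired_recording(
    connected: bool,
    unitary_ipsc: float,
    spikes_per_step: Sequence[int],
    noise_sd: float,
    seed: int = 0,
    steps: tuple[int, ...] = (100, 200, 300, 400),
    n_reps: int = 5,
    sampling_rate: float = 10_000.0,
    step_onset: float = 100.0,
    step_duration: float = 50.0,
    tail: float = 100.0,
    synaptic_delay: float = 1.0,
    layer: str = "L2/3",
    distance: float = 50.0,
    pair_id: str = "pair000",
) -> PairedRecording:
    """Simulate one PV (current clamp) / Pyr (voltage clamp at 0 mV) pair.

    The PV membrane-potential trace contains exactly ``spikes_per_step[i]``
    spike waveforms during step i, evenly spaced within the step. If
    ``connected``, each spike evokes one outward IPSC of peak amplitude
    ``unitary_ipsc`` (plus noise) in the Pyr trace after ``synaptic_delay``.
    """
    if len(spikes_per_step) != len(steps):
        raise ConfigError("spikes_per_step must match the number of steps")
    if any(b < a for a, b in zip(spikes_per_step, spikes_per_step[1:])):
        raise ConfigError("spikes_per_step must be non-decreasing")
    if unitary_ipsc < 0 or noise_sd < 0:
        raise ConfigError("amplitudes and noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    fs = sampling_rate
    n = int(round((step_onset + step_duration + tail) * fs / 1000.0))
    onset_idx = int(round(step_onset * fs / 1000.0))
    dur_idx = int(round(step_duration * fs / 1000.0))
    spike_wave_n = int(round(1.0 * fs / 1000.0))  # 1 ms waveform
    spike_wave = 95.0 * np.exp(
        -0.5 * ((np.arange(spike_wave_n) - spike_wave_n / 2) / (spike_wave_n / 6)) ** 2
    )
    ipsc = ipsc_kernel(n, fs)
    delay_idx = int(round(synaptic_delay * fs / 1000.0))

    pv_traces: dict[int, np.ndarray] = {}
    pyr_traces: dict[int, np.ndarray] = {}
    for step, n_spikes in zip(steps, spikes_per_step):
        pv = rng.normal(0.0, 0.2, size=(n_reps, n)) - 65.0
        # subthreshold depolarization proportional to injected current
        pv[:, onset_idx : onset_idx + dur_idx] += step * 0.03
        pyr = rng.normal(0.0, noise_sd, size=(n_reps, n))
        if n_spikes > 0:
            spike_times = onset_idx + (
                (np.arange(n_spikes) + 0.5) / n_spikes * dur_idx
            ).astype(int)
            for t0 in spike_times:
                hi = min(n, t0 + spike_wave_n)
                pv[:, t0:hi] += spike_wave[: hi - t0]
                if connected and unitary_ipsc > 0:
                    s0 = t0 + delay_idx
                    if s0 < n:
                        pyr[:, s0:] += unitary_ipsc * ipsc[: n - s0]
        pv_traces[step] = pv
        pyr_traces[step] = pyr

    return PairedRecording(
        pair_id=pair_id,
        pv_traces=pv_traces,
        pyr_traces=pyr_traces,
        steps=tuple(steps),
        sampling_rate=fs,
        step_onset=step_onset,
        step_duration=step_duration,
        layer=layer,
        distance=distance,
    )


def generate_paired_cohort(
    connected_flags: Sequence[bool],
    unitary_ipsc: float = 20.0,
    spikes_per_step: Sequence[int] = (1, 2, 3, 4),
    noise_sd: float = 1.0,
    seed: int = 0,
    layer: str = "L2/3",
    **kwargs,
) -> tuple[list[PairedRecording], GroundTruth]:
    """Simulate a cohort of pairs with planted connectivity flags."""
    rng = np.random.default_rng(seed)
    pairs: list[PairedRecording] = []
    truth = GroundTruth()
    for i, flag in enumerate(connected_flags):
        pair_id = f"{layer.replace('/', '')}_pair{i:03d}"
        pairs.append(
            generate_paired_recording(
                connected=bool(flag),
                unitary_ipsc=unitary_ipsc,
                spikes_per_step=spikes_per_step,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
                layer=layer,
                pair_id=pair_id,
                **kwargs,
            )
        )
        truth.connected[pair_id] = bool(flag)
    return pairs, truth
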