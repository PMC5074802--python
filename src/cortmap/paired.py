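"""Paired-recording analysis of PV-mediated feedforward inhibition.

Current steps (100-400 pA, 50 ms) injected into a PV cell evoke spikes;
IPSCs are recorded in a neighbouring Pyr cell held at 0 mV. The pipeline
detects spikes, measures the mean IPSC over 75 ms from step onset,
classifies pairs as connected (largest-step IPSC above k x baseline SD),
and tests whether inhibition grows with PV excitation (one-way ANOVA
across steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ConfigError, IndeterminateConnectionError

__all__ = [
    "PairedRecording",
    "IECurve",
    "detect_spikes",
    "ipsc_response",
    "classify_connected",
    "connection_probability",
    "connection_probability_by_layer",
    "ie_curve",
]

DEFAULT_IPSC_WINDOW_MS = 75.0
DEFAULT_BASELINE_MS = 100.0
DEFAULT_SPIKE_THRESHOLD_MV = 0.0
DEFAULT_REFRACTORY_MS = 2.0
DEFAULT_K_SD = 4.0


@dataclass
class PairedRecording:
    """One PV/Pyr pair: per-step sweep blocks for both cells.

    ``pv_traces[step]`` is a (reps, n) membrane-potential block in mV;
    ``pyr_traces[step]`` a (reps, n) current block in pA (held at 0 mV).
    """

    pair_id: str
    pv_traces: dict[int, np.ndarray]
    pyr_traces: dict[int, np.ndarray]
    steps: tuple[int, ...]
    sampling_rate: float
    step_onset: float  # ms
    step_duration: float  # ms
    layer: str = "L2/3"
    distance: float = 50.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if self.distance >= 100.0:
            raise ConfigError("paired cells must be < 100 um apart")
        if set(self.pv_traces) != set(self.steps) or set(self.pyr_traces) != set(self.steps):
            raise ConfigError("pv/pyr traces must cover exactly the declared steps")
        for step in self.steps:
            pv = np.asarray(self.pv_traces[step], dtype=np.float64)
            pyr = np.asarray(self.pyr_traces[step], dtype=np.float64)
            if pv.ndim != 2 or pyr.ndim != 2:
                raise ConfigError("per-step traces must be (reps, samples) blocks")
            if pv.shape != pyr.shape:
                raise ConfigError(f"step {step}: PV and Pyr sweep counts/lengths differ")
            self.pv_traces[step] = pv
            self.pyr_traces[step] = pyr


@dataclass
class IECurve:
    """Per-step excitation/inhibition table with an across-step trend test."""

    steps: tuple[int, ...]
    spike_counts: list[int]
    mean_ipsc: list[float]
    per_rep_ipsc: dict[int, np.ndarray] = field(default_factory=dict)
    anova_f: float = float("nan")
    anova_p: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "steps": list(self.steps),
            "spike_counts": list(self.spike_counts),
            "mean_ipsc": list(self.mean_ipsc),
            "anova_f": self.anova_f,
            "anova_p": self.anova_p,
        }


def detect_spikes(
    vm: np.ndarray,
    sampling_rate: float,
    threshold: float = DEFAULT_SPIKE_THRESHOLD_MV,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
) -> np.ndarray:
    """Spike times (ms) from upward threshold crossings with a refractory guard."""
    vm = np.asarray(vm, dtype=float)
    if vm.ndim != 1 or vm.size == 0:
        raise ConfigError("vm must be a non-empty 1-D trace")
    above = vm >= threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if vm[0] >= threshold:
        crossings = np.concatenate([[0], crossings])
    refractory = refractory_ms * sampling_rate / 1000.0
    kept: list[int] = []
    last = -np.inf
    for idx in crossings:
        if idx - last >= refractory:
            kept.append(int(idx))
            last = idx
    return np.asarray(kept, dtype=float) * 1000.0 / sampling_rate


def ipsc_response(
    pyr_trace: np.ndarray,
    sampling_rate: float,
    step_onset: float,
    window_ms: float = DEFAULT_IPSC_WINDOW_MS,
    baseline_ms: float = DEFAULT_BASELINE_MS,
) -> float:
    """Magnitude (pA) of the baseline-subtracted mean current over
    ``window_ms`` from step onset; (reps, n) blocks are rep-averaged first."""
    trace = np.asarray(pyr_trace, dtype=float)
    if trace.ndim == 2:
        trace = trace.mean(axis=0)
    n = trace.size
    i_on = int(round(step_onset * sampling_rate / 1000.0))
    i_end = i_on + int(round(window_ms * sampling_rate / 1000.0))
    if i_end > n:
        raise ConfigError("IPSC window exceeds trace length")
    b0 = max(0, i_on - int(round(baseline_ms * sampling_rate / 1000.0)))
    if i_on <= b0:
        raise ConfigError("no pre-step samples for baseline")
    baseline = trace[b0:i_on].mean()
    return float(abs(trace[i_on:i_end].mean() - baseline))


def _baseline_sd(trace: np.ndarray, sampling_rate: float, step_onset: float,
                 baseline_ms: float = DEFAULT_BASELINE_MS) -> float:
    trace = np.asarray(trace, dtype=float)
    if trace.ndim == 2:
        trace = trace.mean(axis=0)
    i_on = int(round(step_onset * sampling_rate / 1000.0))
    b0 = max(0, i_on - int(round(baseline_ms * sampling_rate / 1000.0)))
    if i_on <= b0:
        raise ConfigError("no pre-step samples for baseline")
    return float(np.std(trace[b0:i_on]))


def _spike_count(pair: PairedRecording, step: int,
                 threshold: float = DEFAULT_SPIKE_THRESHOLD_MV,
                 refractory_ms: float = DEFAULT_REFRACTORY_MS) -> int:
    vm = pair.pv_traces[step].mean(axis=0)
    return int(detect_spikes(vm, pair.sampling_rate, threshold, refractory_ms).size)


def classify_connected(
    pair: PairedRecording,
    k: float = DEFAULT_K_SD,
    window_ms: float = DEFAULT_IPSC_WINDOW_MS,
    baseline_ms: float = DEFAULT_BASELINE_MS,
) -> bool:
    """Connected iff the largest-step IPSC exceeds ``k`` x the Pyr baseline SD.

    Raises :class:`IndeterminateConnectionError` when no step evokes a spike.
    """
    counts = {step: _spike_count(pair, step) for step in pair.steps}
    if all(c == 0 for c in counts.values()):
        raise IndeterminateConnectionError(
            f"pair {pair.pair_id}: no PV spikes at any step"
        )
    top = max(pair.steps)
    response = ipsc_response(
        pair.pyr_traces[top], pair.sampling_rate, pair.step_onset, window_ms, baseline_ms
    )
    sd = _baseline_sd(pair.pyr_traces[top], pair.sampling_rate, pair.step_onset, baseline_ms)
    return bool(response > k * sd)


def connection_probability(connected_flags: Sequence[bool]) -> float:
    """Percentage of tested pairs that are connected."""
    flags = [bool(f) for f in connected_flags]
    if len(flags) == 0:
        raise ConfigError("connection_probability requires >= 1 tested pair")
    return 100.0 * sum(flags) / len(flags)


def connection_probability_by_layer(
    pairs: Sequence[PairedRecording], k: float = DEFAULT_K_SD, **kwargs
) -> dict[str, dict]:
    """Classify each pair and summarize connection probability per layer.

    Pairs with no spikes at any step are counted as indeterminate and
    excluded from the tested denominator.
    """
    layers: dict[str, dict] = {}
    for pair in pairs:
        summary = layers.setdefault(
            pair.layer, {"n_connected": 0, "n_tested": 0, "n_indeterminate": 0}
        )
        try:
            connected = classify_connected(pair, k=k, **kwargs)
        except IndeterminateConnectionError:
            summary["n_indeterminate"] += 1
            continue
        summary["n_tested"] += 1
        summary["n_connected"] += int(connected)
    for summary in layers.values():
        summary["percent"] = (
            connection_probability([True] * summary["n_connected"]
                                   + [False] * (summary["n_tested"] - summary["n_connected"]))
            if summary["n_tested"]
            else float("nan")
        )
    return layers


def ie_curve(
    pair: PairedRecording,
    window_ms: float = DEFAULT_IPSC_WINDOW_MS,
    baseline_ms: float = DEFAULT_BASELINE_MS,
) -> IECurve:
    """Spike counts and mean IPSCs per current step, with a one-way ANOVA
    across steps over per-repetition IPSC responses."""
    if len(pair.steps) < 2:
        raise ConfigError("ie_curve requires >= 2 current steps")
    spike_counts: list[int] = []
    mean_ipsc: list[float] = []
    per_rep: dict[int, np.ndarray] = {}
    for step in pair.steps:
        spike_counts.append(_spike_count(pair, step))
        block = pair.pyr_traces[step]
        responses = np.array(
            [
                ipsc_response(block[r], pair.sampling_rate, pair.step_onset,
                              window_ms, baseline_ms)
                for r in range(block.shape[0])
            ]
        )
        per_rep[step] = responses
        mean_ipsc.append(float(responses.mean()))
    groups = [per_rep[s] for s in pair.steps]
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        f, p = 0.0, 1.0
    else:
        f, p = stats.f_oneway(*groups)
    return IECurve(
        steps=pair.steps,
        spike_counts=spike_counts,
        mean_ipsc=mean_ipsc,
        per_rep_ipsc=per_rep,
        anova_f=float(f),
        anova_p=float(p),
    )
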