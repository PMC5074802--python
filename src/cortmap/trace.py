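"""Digitized sweep type and window arithmetic shared by the analysis modules.

Sweeps carry physical sign conventions: inward EPSCs are negative at
hyperpolarized holding potentials, outward IPSCs positive at 0 mV. Analysis
functions convert to magnitudes at the last step only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigError

__all__ = [
    "SweepTrace",
    "stack_reps",
    "rep_average",
    "baseline_bounds",
    "window_bounds",
]


@dataclass(frozen=True)
class SweepTrace:
    """One digitized record.

    Parameters
    ----------
    samples : array-like
        Signal in pA (voltage clamp) or mV (current clamp).
    sampling_rate : float
        Samples per second (Hz).
    stim_onset : float
        Stimulus onset relative to trace start, in ms.
    holding_potential : float, optional
        Command potential in mV for voltage-clamp sweeps.
    """

    samples: np.ndarray
    sampling_rate: float
    stim_onset: float
    holding_potential: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ConfigError("samples must be one-dimensional")
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if not 0.0 <= self.stim_onset <= self.duration_ms:
            raise ConfigError(
                f"stim_onset {self.stim_onset} ms outside trace of "
                f"{self.duration_ms:.3f} ms"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.sampling_rate

    def index_at(self, t_ms: float) -> int:
        """Sample index of time ``t_ms`` from trace start."""
        return int(round(t_ms * self.sampling_rate / 1000.0))

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.sampling_rate


def stack_reps(sweeps: Sequence[SweepTrace]) -> np.ndarray:
    """Stack repetition sweeps into a (reps, n) array, checking consistency."""
    if len(sweeps) == 0:
        raise ConfigError("no sweeps given")
    first = sweeps[0]
    for s in sweeps[1:]:
        if s.n_samples != first.n_samples:
            raise ConfigError("repetition sweeps differ in length")
        if s.sampling_rate != first.sampling_rate:
            raise ConfigError("repetition sweeps differ in sampling rate")
        if s.stim_onset != first.stim_onset:
            raise ConfigError("repetition sweeps differ in stimulus onset")
    return np.stack([s.samples for s in sweeps])


def rep_average(sweeps: Sequence[SweepTrace]) -> SweepTrace:
    """Average repetitions into a single sweep."""
    stacked = stack_reps(sweeps)
    first = sweeps[0]
    return SweepTrace(
        samples=stacked.mean(axis=0),
        sampling_rate=first.sampling_rate,
        stim_onset=first.stim_onset,
        holding_potential=first.holding_potential,
    )


def window_bounds(
    n_samples: int, sampling_rate: float, onset_ms: float, window_ms: float
) -> tuple[int, int]:
    """Index bounds [i0, i1) of the response window starting at stimulus onset."""
    i0 = int(round(onset_ms * sampling_rate / 1000.0))
    i1 = i0 + int(round(window_ms * sampling_rate / 1000.0))
    if i1 > n_samples:
        raise ConfigError(
            f"response window [{onset_ms}, {onset_ms + window_ms}) ms exceeds trace"
        )
    if i1 <= i0:
        raise ConfigError("response window is empty")
    return i0, i1


def baseline_bounds(
    n_samples: int, sampling_rate: float, onset_ms: float, baseline_ms: float
) -> tuple[int, int]:
    """Index bounds of the pre-stimulus baseline window.

    Uses up to ``baseline_ms`` immediately preceding the stimulus onset.
    """
    i1 = int(round(onset_ms * sampling_rate / 1000.0))
    i0 = max(0, i1 - int(round(baseline_ms * sampling_rate / 1000.0)))
    if i1 <= i0:
        raise ConfigError("no pre-stimulus samples available for baseline")
    return i0, i1
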