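"""Data containers shared across the pipeline.

Conventions used throughout the package: time is measured in seconds from
the start of the recording, intervals are half-open ``[start, stop)``, and
rates are events per second (Hz).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

POPULATIONS = ("surface", "pachon", "tinaja", "molino")
TREATMENTS = ("control", "ablated")


class ValidationError(ValueError):
    """Raised when a container is constructed from inconsistent values."""


@dataclass(frozen=True)
class FishMetadata:
    """Identity and experimental condition of one larva.

    ``population`` is one of the Astyanax mexicanus morphs recorded from
    (eyed surface fish or one of the blind cave populations Pachon, Tinaja,
    Molino); ``treatment`` distinguishes intact fish from fish whose
    hindbrain efferent neurons were ablated.
    """

    fish_id: str
    population: str = "surface"
    treatment: str = "control"
    age_dpf: int | None = None
    amplifier_gain: float = 1000.0

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValidationError(
                f"unknown population {self.population!r}; "
                f"allowed values: {', '.join(POPULATIONS)}"
            )
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"unknown treatment {self.treatment!r}; "
                f"allowed values: {', '.join(TREATMENTS)}"
            )


@dataclass
class RecordingSession:
    """Paired raw voltage traces from one recording.

    ``afferent_trace`` holds the posterior lateral line ganglion signal and
    ``motor_trace`` the ventral-root signal, both uniformly sampled at
    ``sampling_rate`` (20 kHz in the recording protocol this package
    targets).
    """

    afferent_trace: np.ndarray
    motor_trace: np.ndarray
    sampling_rate: float
    metadata: FishMetadata

    def __post_init__(self) -> None:
        self.afferent_trace = np.asarray(self.afferent_trace, dtype=float)
        self.motor_trace = np.asarray(self.motor_trace, dtype=float)
        if self.afferent_trace.ndim != 1 or self.motor_trace.ndim != 1:
            raise ValidationError("traces must be one-dimensional")
        if self.afferent_trace.shape != self.motor_trace.shape:
            raise ValidationError("afferent and motor traces must have equal length")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.afferent_trace.size

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class SpikeTrain:
    """Sorted afferent event times, in seconds, for one fish."""

    times: np.ndarray
    fish_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class SwimBout:
    """One fictive swim bout recovered from the ventral root.

    ``burst_times`` are the motor bursts (tail-beat analogues) inside the
    bout; swim frequency is the number of bursts divided by the bout
    duration.
    """

    onset: float
    offset: float
    burst_times: np.ndarray | None = None
    n_bursts: int | None = None

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValidationError(
                f"bout offset ({self.offset}) must exceed onset ({self.onset})"
            )
        if self.burst_times is not None:
            self.burst_times = np.asarray(self.burst_times, dtype=float).ravel()
            if self.burst_times.size and (
                self.burst_times.min() < self.onset - 1e-9
                or self.burst_times.max() > self.offset + 1e-9
            ):
                raise ValidationError("burst times must lie within the bout")
            inferred = int(self.burst_times.size)
            if self.n_bursts is None:
                self.n_bursts = inferred
            elif self.n_bursts != inferred:
                raise ValidationError("n_bursts inconsistent with burst_times")
        elif self.n_bursts is None:
            self.n_bursts = 0

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def swim_frequency(self) -> float:
        """Bursts per second within the bout."""
        return self.n_bursts / self.duration

    @property
    def interval(self) -> tuple[float, float]:
        return (self.onset, self.offset)


@dataclass
class BoutRates:
    """Windowed spike rates for one bout.

    The pre-swim, swim and post-swim windows all share the bout's duration;
    the relative rate is swim over pre-swim and inhibition is one minus
    that ratio.  A bout is *retained* for downstream aggregation only when
    at least one afferent spike fell in the pre-swim window; non-retained
    bouts carry NaN for the relative rate and inhibition and ``None`` for
    the label.
    """

    bout: SwimBout
    pre_count: int
    swim_count: int
    post_count: int
    pre_rate: float
    swim_rate: float
    post_rate: float
    relative_rate: float
    inhibition: float
    label: str | None
    retained: bool


@dataclass
class FishSummary:
    """Per-fish averages over retained bouts.

    The regression weight is the square root of the number of retained
    swims, reflecting that per-fish estimate precision grows with the
    number of bouts observed.
    """

    fish_id: str
    population: str
    treatment: str
    n_swims: int
    mean_pre_rate: float
    mean_swim_rate: float
    mean_post_rate: float
    mean_spontaneous_rate: float
    mean_inhibition: float

    @property
    def weight(self) -> float:
        return math.sqrt(self.n_swims)


@dataclass
class StimulusSchedule:
    """Sweep structure of a sinusoidal neuromast stimulation session.

    Each sweep is ``stim_duration`` seconds of sinusoidal deflection at one
    frequency followed by ``rest_duration`` seconds of rest; frequencies
    are presented in blocks of ``n_sweeps`` sweeps.
    """

    sweep_onsets: np.ndarray
    sweep_frequencies: np.ndarray
    stim_duration: float = 1.0
    rest_duration: float = 4.0

    def __post_init__(self) -> None:
        self.sweep_onsets = np.asarray(self.sweep_onsets, dtype=float).ravel()
        self.sweep_frequencies = np.asarray(
            self.sweep_frequencies, dtype=float
        ).ravel()
        if self.sweep_onsets.size == 0:
            raise ValidationError("schedule must contain at least one sweep")
        if self.sweep_onsets.size != self.sweep_frequencies.size:
            raise ValidationError("one frequency per sweep onset is required")
        gaps = np.diff(self.sweep_onsets)
        period = self.stim_duration + self.rest_duration
        if gaps.size and gaps.min() < period - 1e-9:
            raise ValidationError(
                "sweep onsets must be spaced by at least stimulus plus rest"
            )

    @property
    def frequencies(self) -> np.ndarray:
        """Distinct stimulus frequencies, in presentation order."""
        _, idx = np.unique(self.sweep_frequencies, return_index=True)
        return self.sweep_frequencies[np.sort(idx)]

    @property
    def n_sweeps(self) -> int:
        return self.sweep_onsets.size

    def onsets_for(self, frequency: float) -> np.ndarray:
        return self.sweep_onsets[np.isclose(self.sweep_frequencies, frequency)]


@dataclass
class PSTH:
    """Peristimulus time histogram pooled over sweeps.

    ``counts`` are raw integer spike counts per bin so that spike-count
    conservation holds exactly: ``sum(counts)`` equals the number of spikes
    falling in the analysis windows.  ``mean_rate`` converts counts to a
    trial-averaged rate.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_sweeps: int
    mean_rate: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValidationError("counts must have one entry per bin")
        widths = np.diff(self.bin_edges)
        self.mean_rate = self.counts / (widths * self.n_sweeps)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class RegressionResult:
    """Weighted least-squares fit of swim rate on pre-swim rate.

    ``excludes_unity`` is True when the 95% confidence interval of the
    slope does not contain 1, the signature of swim-locked suppression of
    afferent activity.
    """

    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    excludes_unity: bool
    n: int
    slope_se: float
    p_unity: float
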