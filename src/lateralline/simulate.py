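"""Synthetic paired afferent/motor-root recordings with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* afferent spiking is a Poisson process at a configurable spontaneous rate
  with a 1-ms absolute refractory period,
* fictive swim bouts arrive as a renewal process; inside a bout the
  afferent rate is reduced multiplicatively by the corollary-discharge
  inhibition fraction (a step modulation — no onset/offset transients),
* motor bursts (tail-beat analogues) occur at a regular within-bout
  frequency with small timing jitter,
* raw traces are rendered by summing waveform templates on Gaussian noise.

Because the refractory deletion would otherwise bias realized rates below
their configured values, target rates are converted to dead-time-corrected
Poisson intensities (``r' = r / (1 - r * tau)`` for non-paralyzable dead
time ``tau``) before thinning, so the configured spontaneous rate is the
rate an observer actually measures.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize, stats

from .containers import (
    FishMetadata,
    RecordingSession,
    SpikeTrain,
    StimulusSchedule,
    SwimBout,
)

#: Shortest bout the generator will produce, in seconds.
MIN_BOUT_DURATION = 0.050


class InvalidConfigError(ValueError):
    """Raised for physically meaningless simulation parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic session.

    Defaults correspond to a control surface fish: spontaneous afferent
    rate 12.4 Hz, corollary-discharge inhibition of 68.5% during bouts,
    mean bout duration 357 ms.  ``spike_amplitude`` and ``burst_amplitude``
    are template peak amplitudes in the same (arbitrary volt) units as
    ``noise_sd``, so amplitude over noise_sd is the rendering SNR.
    """

    baseline_rate: float = 12.4
    inhibition_fraction: float = 0.685
    bout_rate: float = 0.5
    bout_duration_mean: float = 0.357
    bout_duration_sd: float = 0.28
    burst_frequency: float = 25.0
    session_duration: float = 60.0
    sampling_rate: float = 20_000.0
    spike_amplitude: float = 10.0
    burst_amplitude: float = 10.0
    noise_sd: float = 1.0
    refractory_s: float = 0.001
    burst_jitter_frac: float = 0.10
    min_inter_bout_gap: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.session_duration > 0:
            raise InvalidConfigError("session_duration must be positive")
        if not self.baseline_rate > 0:
            raise InvalidConfigError("baseline_rate must be positive")
        if not 0.0 <= self.inhibition_fraction <= 1.0:
            raise InvalidConfigError("inhibition_fraction must be in [0, 1]")
        if self.bout_rate < 0:
            raise InvalidConfigError("bout_rate must be nonnegative")
        if self.bout_rate > 0 and not self.bout_duration_mean >= MIN_BOUT_DURATION:
            raise InvalidConfigError(
                f"bout_duration_mean must be at least {MIN_BOUT_DURATION} s"
            )
        if self.bout_duration_sd < 0:
            raise InvalidConfigError("bout_duration_sd must be nonnegative")
        if not self.sampling_rate > 0:
            raise InvalidConfigError("sampling_rate must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be nonnegative")
        if self.refractory_s < 0:
            raise InvalidConfigError("refractory_s must be nonnegative")
        if self.min_inter_bout_gap < 0:
            raise InvalidConfigError("min_inter_bout_gap must be nonnegative")
        if self.baseline_rate * self.refractory_s >= 1:
            raise InvalidConfigError(
                "baseline_rate * refractory_s must be below 1"
            )


@dataclass
class GroundTruth:
    """Event-level truth of a synthetic session."""

    spike_times: np.ndarray
    bouts: np.ndarray  # shape (n_bouts, 2): onset, offset
    burst_times: np.ndarray
    inhibition_fraction: float
    config: SimulationConfig

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.bouts = np.asarray(self.bouts, dtype=float).reshape(-1, 2)
        self.burst_times = np.asarray(self.burst_times, dtype=float)


# --------------------------------------------------------------------------
# population presets (printed group means of the study conditions)
# --------------------------------------------------------------------------

#: Per-(population, treatment) generator parameters.  Spontaneous rates,
#: inhibition levels and mean bout durations are the group means reported
#: for each condition; the duration spread is the sample SD implied by the
#: reported standard errors and bout counts.
POPULATION_PRESETS: dict[tuple[str, str], dict[str, float]] = {
    ("surface", "control"): dict(
        baseline_rate=12.4, inhibition_fraction=0.685,
        bout_duration_mean=0.357, bout_duration_sd=0.28,
    ),
    ("pachon", "control"): dict(
        baseline_rate=18.6, inhibition_fraction=0.289,
        bout_duration_mean=0.264, bout_duration_sd=0.20,
    ),
    ("tinaja", "control"): dict(
        baseline_rate=18.6, inhibition_fraction=0.32,
        bout_duration_mean=0.35, bout_duration_sd=0.22,
    ),
    ("molino", "control"): dict(
        baseline_rate=18.6, inhibition_fraction=0.23,
        bout_duration_mean=0.42, bout_duration_sd=0.25,
    ),
    ("surface", "ablated"): dict(
        baseline_rate=20.7, inhibition_fraction=0.159,
        bout_duration_mean=0.357, bout_duration_sd=0.28,
    ),
    ("pachon", "ablated"): dict(
        baseline_rate=18.6, inhibition_fraction=0.210,
        bout_duration_mean=0.264, bout_duration_sd=0.20,
    ),
}

#: Number of fish recorded per condition in the study design.
COHORT_SIZES: dict[tuple[str, str], int] = {
    ("surface", "control"): 10,
    ("pachon", "control"): 5,
    ("tinaja", "control"): 5,
    ("molino", "control"): 8,
    ("surface", "ablated"): 4,
    ("pachon", "ablated"): 5,
}


def population_config(
    population: str, treatment: str = "control", **overrides
) -> SimulationConfig:
    """A :class:`SimulationConfig` parameterized at a condition's group means."""
    key = (population, treatment)
    if key not in POPULATION_PRESETS:
        raise InvalidConfigError(f"no preset for {key}")
    params = dict(POPULATION_PRESETS[key])
    params.update(overrides)
    return SimulationConfig(**params)


# --------------------------------------------------------------------------
# bout generation
# --------------------------------------------------------------------------

def _calibrated_duration_loc(mean: float, sd: float, floor: float) -> float:
    """Location of a floor-truncated normal whose truncated mean equals ``mean``.

    Truncation at the floor raises the mean of a normal draw, so sampling
    from N(mean, sd) truncated at the floor would bias durations upward;
    instead the location is solved so the configured value is the mean of
    what is actually generated.
    """
    if mean <= floor:
        raise InvalidConfigError("bout_duration_mean must exceed the 50-ms floor")

    def truncated_mean(loc: float) -> float:
        a = (floor - loc) / sd
        return float(stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd))

    lo = mean - 6.0 * sd
    while truncated_mean(lo) > mean:
        lo -= 6.0 * sd
    return float(optimize.brentq(lambda m: truncated_mean(m) - mean, lo, mean,
                                 xtol=1e-12))


def _draw_duration(rng: np.random.Generator, loc: float, sd: float,
                   floor: float) -> float:
    # rejection sampling; acceptance probability is high for calibrated loc
    while True:
        x = loc + sd * rng.standard_normal()
        if x >= floor:
            return x


def simulate_bouts(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Generate disjoint (onset, offset) swim-bout intervals.

    Candidate inter-onset gaps are exponential with rate ``bout_rate``;
    a candidate onset that would fall inside the previous bout or within
    ``min_inter_bout_gap`` of its offset is redrawn (by memorylessness this
    is equivalent to restarting the exponential clock at the end of that
    dead period), so bouts never overlap, durations are unbiased, and
    consecutive bouts stay far enough apart that a burst-grouping detector
    can resolve them.  The resulting bout count follows a renewal process
    with mean cycle ``mean_duration + min_inter_bout_gap + 1/bout_rate``.
    Bouts extending past the session end are clipped (and dropped if the
    remnant falls below the 50-ms floor).
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    T = config.session_duration
    if config.bout_rate == 0:
        return np.empty((0, 2))
    sd = config.bout_duration_sd
    if sd > 0:
        loc = _calibrated_duration_loc(
            config.bout_duration_mean, sd, MIN_BOUT_DURATION
        )
    bouts: list[tuple[float, float]] = []
    t = rng.exponential(1.0 / config.bout_rate)
    while t < T:
        if sd > 0:
            d = _draw_duration(rng, loc, sd, MIN_BOUT_DURATION)
        else:
            d = config.bout_duration_mean
        offset = min(t + d, T)
        if offset - t >= MIN_BOUT_DURATION - 1e-12:
            bouts.append((t, offset))
        t = (offset + config.min_inter_bout_gap
             + rng.exponential(1.0 / config.bout_rate))
    return np.asarray(bouts, dtype=float).reshape(-1, 2)


# --------------------------------------------------------------------------
# event trains
# --------------------------------------------------------------------------

def _dead_time_corrected(rate: float, tau: float) -> float:
    """Poisson intensity that yields ``rate`` after non-paralyzable dead time."""
    if tau <= 0 or rate == 0:
        return rate
    if rate * tau >= 1:
        raise InvalidConfigError("rate * refractory must be below 1")
    return rate / (1.0 - rate * tau)


def _enforce_refractory(times: np.ndarray, tau: float) -> np.ndarray:
    """Delete events closer than ``tau`` to the previous kept event."""
    if tau <= 0 or times.size < 2:
        return times
    kept = np.empty_like(times)
    n = 0
    last = -np.inf
    for t in times:
        if t - last >= tau:
            kept[n] = t
            n += 1
            last = t
    return kept[:n]


def in_bout_mask(times: np.ndarray, bouts: np.ndarray) -> np.ndarray:
    """Boolean mask of which times fall inside any half-open bout interval."""
    times = np.asarray(times, dtype=float)
    bouts = np.asarray(bouts, dtype=float).reshape(-1, 2)
    if bouts.size == 0:
        return np.zeros(times.shape, dtype=bool)
    edges = bouts.ravel()
    idx = np.searchsorted(edges, times, side="right")
    return idx % 2 == 1


def simulate_afferent_train(
    config: SimulationConfig,
    bouts: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Afferent spike times: Poisson at the spontaneous rate, multiplicatively
    suppressed inside bouts, with a refractory period enforced by deletion.

    Realized by thinning a homogeneous process at the (dead-time-corrected)
    out-of-bout intensity; spikes inside bouts survive with probability
    equal to the in/out intensity ratio, which is zero at full inhibition.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    bouts = np.asarray(bouts, dtype=float).reshape(-1, 2)
    T = config.session_duration
    tau = config.refractory_s
    lam_out = config.baseline_rate
    lam_in = lam_out * (1.0 - config.inhibition_fraction)
    r_out = _dead_time_corrected(lam_out, tau)
    r_in = _dead_time_corrected(lam_in, tau)

    n = rng.poisson(r_out * T)
    times = np.sort(rng.uniform(0.0, T, n))
    inside = in_bout_mask(times, bouts)
    accept = ~inside | (rng.random(n) < (r_in / r_out))
    times = times[accept]
    return _enforce_refractory(times, tau)


def simulate_motor_train(
    config: SimulationConfig,
    bouts: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Motor burst times: one regular burst train per bout with small jitter.

    Bursts are spaced ``1/burst_frequency`` apart starting at the bout
    onset; Gaussian jitter with SD equal to ``burst_jitter_frac`` of the
    inter-burst interval is added and bursts are clipped into the bout.
    No bursts occur outside bouts.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    if not config.burst_frequency > 0:
        raise InvalidConfigError("burst_frequency must be positive")
    bouts = np.asarray(bouts, dtype=float).reshape(-1, 2)
    f = config.burst_frequency
    jitter_sd = config.burst_jitter_frac / f
    out: list[np.ndarray] = []
    for onset, offset in bouts:
        d = offset - onset
        k = int(np.ceil(d * f - 1e-9))
        base = onset + np.arange(k) / f
        if jitter_sd > 0:
            base = base + rng.normal(0.0, jitter_sd, k)
        base = np.clip(base, onset, offset - 1e-9)
        out.append(np.sort(base))
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def true_swim_bouts(bouts: np.ndarray, burst_times: np.ndarray) -> list[SwimBout]:
    """Package ground-truth intervals and bursts as :class:`SwimBout` objects."""
    bouts = np.asarray(bouts, dtype=float).reshape(-1, 2)
    burst_times = np.asarray(burst_times, dtype=float)
    result = []
    for onset, offset in bouts:
        lo = np.searchsorted(burst_times, onset, side="left")
        hi = np.searchsorted(burst_times, offset, side="left")
        result.append(SwimBout(onset, offset, burst_times[lo:hi]))
    return result


# --------------------------------------------------------------------------
# waveform rendering
# --------------------------------------------------------------------------

def spike_template(
    sampling_rate: float, amplitude: float = 1.0, scale_s: float = 0.00015
) -> np.ndarray:
    """Biphasic extracellular spike waveform, about 1 ms wide.

    A Ricker (Mexican-hat) wavelet: a sharp positive peak at the spike time
    flanked by negative lobes, with spectral content near 1.5 kHz so it
    passes the 300-3000 Hz afferent band essentially unattenuated.
    """
    half = int(round(0.0005 * sampling_rate))
    t = np.arange(-half, half + 1) / sampling_rate
    u = t / scale_s
    x = (1.0 - u**2) * np.exp(-0.5 * u**2)
    return amplitude * x / np.abs(x).max()


def burst_template(
    sampling_rate: float,
    amplitude: float = 1.0,
    width_s: float = 0.010,
    carrier_hz: float = 150.0,
) -> np.ndarray:
    """Motor burst waveform: a 10-ms Hann-windowed oscillation.

    The 150-Hz carrier keeps the burst inside the 10-200 Hz motor band and
    outside the afferent spike band, so band-pass filtering separates the
    two channels' content.
    """
    n = int(round(width_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    env = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / width_s))
    x = np.sin(2.0 * np.pi * carrier_hz * t) * env
    return amplitude * x / np.abs(x).max()


def _add_events(
    trace: np.ndarray,
    template: np.ndarray,
    times: np.ndarray,
    sampling_rate: float,
    center: bool,
) -> None:
    """Sum ``template`` into ``trace`` at each event time (in place)."""
    n = trace.size
    m = template.size
    shift = m // 2 if center else 0
    for t in np.asarray(times, dtype=float):
        i0 = int(round(t * sampling_rate)) - shift
        i1 = i0 + m
        j0, j1 = max(i0, 0), min(i1, n)
        if j1 > j0:
            trace[j0:j1] += template[j0 - i0 : j1 - i0]


def render_session(
    config: SimulationConfig,
    spike_times: np.ndarray,
    burst_times: np.ndarray,
    metadata: FishMetadata | None = None,
    rng: np.random.Generator | None = None,
) -> RecordingSession:
    """Render event times into raw two-channel voltage traces.

    Channel 1 sums a biphasic spike template centred at each spike time,
    channel 2 a burst template starting at each burst time, both on i.i.d.
    Gaussian noise with SD ``config.noise_sd``.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    metadata = metadata or FishMetadata(fish_id="synthetic")
    fs = config.sampling_rate
    n = int(round(config.session_duration * fs))
    if config.noise_sd > 0:
        afferent = rng.normal(0.0, config.noise_sd, n)
        motor = rng.normal(0.0, config.noise_sd, n)
    else:
        afferent = np.zeros(n)
        motor = np.zeros(n)
    _add_events(
        afferent,
        spike_template(fs, config.spike_amplitude),
        spike_times, fs, center=True,
    )
    _add_events(
        motor,
        burst_template(fs, config.burst_amplitude),
        burst_times, fs, center=False,
    )
    return RecordingSession(afferent, motor, fs, metadata)


def simulate_session(
    config: SimulationConfig,
    metadata: FishMetadata | None = None,
    rng: np.random.Generator | None = None,
    render: bool = True,
) -> tuple[RecordingSession | None, GroundTruth]:
    """Full synthetic session: bouts, spikes, bursts, and (optionally) traces.

    With ``render=False`` only event-level ground truth is produced, which
    is orders of magnitude cheaper and sufficient for analyses that do not
    exercise the raw-trace detectors.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    bouts = simulate_bouts(config, rng)
    spikes = simulate_afferent_train(config, bouts, rng)
    bursts = simulate_motor_train(config, bouts, rng)
    truth = GroundTruth(spikes, bouts, bursts, config.inhibition_fraction, config)
    session = None
    if render:
        session = render_session(config, spikes, bursts, metadata, rng)
    return session, truth


# --------------------------------------------------------------------------
# evoked stimulation sessions
# --------------------------------------------------------------------------

@dataclass
class EvokedSimulation:
    """Bundle returned by :func:`simulate_evoked_session`."""

    spike_train: SpikeTrain
    schedule: StimulusSchedule
    ground_truth: GroundTruth
    session: RecordingSession | None = None


def simulate_evoked_session(
    config: SimulationConfig,
    stim_frequencies: tuple[float, ...] = (5.0, 10.0, 20.0, 30.0, 40.0),
    gain: float = 0.0,
    rng: np.random.Generator | None = None,
    n_sweeps: int = 60,
    stim_duration: float = 1.0,
    rest_duration: float = 4.0,
    metadata: FishMetadata | None = None,
    render: bool = False,
) -> EvokedSimulation:
    """Sinusoidal-stimulation session: blocks of sweeps at each frequency.

    During each 1-s stimulus the afferent intensity is
    ``baseline + gain * max(0, sin(2 pi f t))`` (half-wave phase-locked
    drive), so the sweep-averaged evoked rate is ``baseline + gain / pi``.
    Each sweep is followed by ``rest_duration`` seconds at the spontaneous
    rate.
    """
    if len(stim_frequencies) == 0:
        raise InvalidConfigError("stim_frequencies must be nonempty")
    if gain < 0:
        raise InvalidConfigError("gain must be nonnegative")
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng

    period = stim_duration + rest_duration
    freqs = np.asarray(stim_frequencies, dtype=float)
    n_blocks = freqs.size
    sweep_onsets = np.arange(n_blocks * n_sweeps) * period
    sweep_frequencies = np.repeat(freqs, n_sweeps)
    schedule = StimulusSchedule(
        sweep_onsets, sweep_frequencies, stim_duration, rest_duration
    )
    T = n_blocks * n_sweeps * period

    tau = config.refractory_s
    lam = config.baseline_rate
    r_max = _dead_time_corrected(lam + gain, tau)
    n = rng.poisson(r_max * T)
    cand = np.sort(rng.uniform(0.0, T, n))

    # target intensity at each candidate time
    block = np.minimum((cand // (n_sweeps * period)).astype(int), n_blocks - 1)
    phase_t = cand % period
    rate = np.full(n, lam)
    in_stim = phase_t < stim_duration
    drive = np.sin(2.0 * np.pi * freqs[block[in_stim]] * phase_t[in_stim])
    rate[in_stim] += gain * np.maximum(0.0, drive)
    if tau > 0:
        rate = rate / (1.0 - rate * tau)
    accept = rng.random(n) < rate / r_max
    times = _enforce_refractory(cand[accept], tau)

    cfg_echo = config
    truth = GroundTruth(times, np.empty((0, 2)), np.empty(0), 0.0, cfg_echo)
    session = None
    if render:
        render_cfg = SimulationConfig(
            **{**asdict(config), "session_duration": T}
        )
        session = render_session(render_cfg, times, np.empty(0), metadata, rng)
    fish_id = metadata.fish_id if metadata else "synthetic"
    return EvokedSimulation(SpikeTrain(times, fish_id), schedule, truth, session)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortFish:
    """Event-level synthetic recording of one fish in a cohort."""

    metadata: FishMetadata
    config: SimulationConfig
    spike_train: SpikeTrain
    bouts: list[SwimBout]
    session_duration: float
    true_inhibition: float


def simulate_cohort(
    population: str,
    treatment: str = "control",
    n_fish: int | None = None,
    session_duration: float = 300.0,
    rng: np.random.Generator | None = None,
    rate_cv: float = 0.15,
    inhibition_sd: float = 0.10,
    **overrides,
) -> list[CohortFish]:
    """Simulate a cohort of fish of one condition at event level.

    Between-fish variability is modelled as Gaussian jitter of the
    spontaneous rate (coefficient of variation ``rate_cv``) and of the
    inhibition fraction (SD ``inhibition_sd``, clipped to [0, 1]) around
    the condition's group means — individual fish differ both in baseline
    excitability and in the strength of their corollary discharge.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if n_fish is None:
        n_fish = COHORT_SIZES[(population, treatment)]
    base = population_config(
        population, treatment, session_duration=session_duration, **overrides
    )
    fish = []
    for i in range(n_fish):
        lam = max(2.0, rng.normal(base.baseline_rate, rate_cv * base.baseline_rate))
        inh = float(np.clip(
            rng.normal(base.inhibition_fraction, inhibition_sd), 0.0, 1.0
        ))
        cfg = SimulationConfig(**{
            **asdict(base), "baseline_rate": lam, "inhibition_fraction": inh,
        })
        meta = FishMetadata(
            fish_id=f"{population[:3]}_{treatment[:3]}_{i:02d}",
            population=population, treatment=treatment, age_dpf=6,
        )
        _, truth = simulate_session(cfg, meta, rng, render=False)
        fish.append(
            CohortFish(
                metadata=meta,
                config=cfg,
                spike_train=SpikeTrain(truth.spike_times, meta.fish_id),
                bouts=true_swim_bouts(truth.bouts, truth.burst_times),
                session_duration=session_duration,
                true_inhibition=inh,
            )
        )
    return fish
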