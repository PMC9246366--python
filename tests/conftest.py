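"""Shared fixtures: small rendered sessions reused across detection tests."""
from __future__ import annotations

import numpy as np
import pytest

import lateralline as ll


@pytest.fixture(scope="session")
def rendered_session():
    """A 60-s surface-like session rendered at SNR 8 with ground truth."""
    cfg = ll.SimulationConfig(
        baseline_rate=20.0, session_duration=60.0, rng_seed=3,
        spike_amplitude=8.0, burst_amplitude=8.0, noise_sd=1.0,
    )
    session, truth = ll.simulate_session(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def detected(rendered_session):
    cfg, session, truth = rendered_session
    spikes, bouts = ll.detect_session(session)
    return spikes, bouts


def match_events(true_times, detected_times, tol_s):
    """Greedy one-to-one matching of detected to true events within tol_s."""
    true_times = np.asarray(true_times)
    detected_times = np.asarray(detected_times)
    used: set[int] = set()
    tp = 0
    for t in true_times:
        i = np.searchsorted(detected_times, t)
        for j in (i - 1, i):
            if (
                0 <= j < detected_times.size
                and abs(detected_times[j] - t) <= tol_s
                and j not in used
            ):
                used.add(j)
                tp += 1
                break
    return tp
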