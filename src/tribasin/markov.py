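"""Continuous-time 3-state Markov fixtures with exact event logs.

These provide ground truth for the transition-counting and rate-estimation
machinery: a Gillespie simulation of a generator matrix over {O, A, H}
yields both a frame-sampled label series (what a trajectory analysis sees)
and the exact jump sequence with residence times (what the estimators should
recover).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import STATE_NAMES, StateSeries, TransitionStats, fractional_flux


@dataclass
class MarkovGroundTruth:
    """Exact event log of a Gillespie run."""

    states: list[str]                 # visit sequence
    durations: np.ndarray             # residence time of each visit
    counts: dict[str, int]            # direct transition counts
    n_oah: int
    residence_time: dict[str, float]
    total_time: float

    def rate(self, x: str, y: str) -> float | None:
        t = self.residence_time.get(x, 0.0)
        if t <= 0:
            return None
        return self.counts.get(x + y, 0) / t

    def stats(self, frame_time: float = 1.0) -> TransitionStats:
        """Ground truth packaged as TransitionStats (continuous-time version)."""
        probs = {s: self.residence_time[s] / self.total_time for s in STATE_NAMES}
        st = TransitionStats(
            counts=dict(self.counts), n_oah=self.n_oah,
            residence_frames={s: int(round(self.residence_time[s] / frame_time))
                              for s in STATE_NAMES},
            probabilities=probs,
            total_frames=int(round(self.total_time / frame_time)),
            frame_time=frame_time,
        )
        st.f_if, st.f_ps = fractional_flux(st)
        return st


def validate_generator(q: np.ndarray) -> np.ndarray:
    """Check a 3×3 generator matrix (rows sum to zero, off-diagonals ≥ 0)."""
    q = np.asarray(q, dtype=float)
    if q.shape != (3, 3):
        raise ValueError("generator must be 3x3 over (O, A, H)")
    off = q[~np.eye(3, dtype=bool)]
    if (off < 0).any():
        raise ValueError("off-diagonal rates must be non-negative")
    if not np.allclose(q.sum(axis=1), 0.0, atol=1e-10):
        raise ValueError("generator rows must sum to zero (non-conservative)")
    return q


def make_markov_series(
    generator: np.ndarray,
    duration: float,
    seed: int = 0,
    frame_time: float = 1.0,
    initial: str = "O",
) -> tuple[StateSeries, MarkovGroundTruth]:
    """Gillespie-simulate the chain and emit a frame-sampled StateSeries.

    ``generator[i, j]`` is the rate i→j over states (O, A, H); the exact
    jump log is retained as ground truth.  Frames are sampled every
    ``frame_time`` (label = state occupied at the sample instant).
    """
    q = validate_generator(generator)
    rng = np.random.default_rng(seed)
    idx = {s: k for k, s in enumerate(STATE_NAMES)}
    state = idx[initial]
    t = 0.0
    visit_states: list[str] = []
    visit_times: list[float] = []
    while t < duration:
        rates = q[state].copy()
        rates[state] = 0.0
        total = rates.sum()
        if total <= 0:
            # absorbing state: stays until the end
            visit_states.append(STATE_NAMES[state])
            visit_times.append(duration - t)
            t = duration
            break
        dt = rng.exponential(1.0 / total)
        stay = min(dt, duration - t)
        visit_states.append(STATE_NAMES[state])
        visit_times.append(stay)
        t += dt
        if t >= duration:
            break
        state = rng.choice(3, p=rates / total)

    # merge zero-probability artifacts: consecutive identical states cannot
    # occur in a Gillespie log by construction

    counts = {a + b: 0 for a in STATE_NAMES for b in STATE_NAMES if a != b}
    for a, b in zip(visit_states[:-1], visit_states[1:]):
        counts[a + b] += 1
    n_oah = sum(
        1 for i in range(len(visit_states) - 2)
        if visit_states[i:i + 3] == ["O", "A", "H"]
    )
    residence = {s: 0.0 for s in STATE_NAMES}
    for s, d in zip(visit_states, visit_times):
        residence[s] += d
    truth = MarkovGroundTruth(
        states=visit_states, durations=np.asarray(visit_times),
        counts=counts, n_oah=n_oah, residence_time=residence,
        total_time=duration,
    )

    # frame-sampled label series
    n_frames = int(duration / frame_time)
    bounds = np.cumsum(visit_times)
    sample_times = (np.arange(n_frames) + 0.5) * frame_time
    which = np.searchsorted(bounds, sample_times, side="right")
    which = np.minimum(which, len(visit_states) - 1)
    labels = np.array([visit_states[k] for k in which], dtype="U1")
    visits = []
    start = 0
    for i in range(1, n_frames + 1):
        if i == n_frames or labels[i] != labels[start]:
            visits.append((str(labels[start]), start, i - 1))
            start = i
    series = StateSeries(labels=labels, visits=visits, dwell_filter=0)
    return series, truth


def stationary_distribution(generator: np.ndarray) -> np.ndarray:
    """Stationary distribution of the generator (left null vector)."""
    q = validate_generator(generator)
    w, v = np.linalg.eig(q.T)
    k = np.argmin(np.abs(w))
    pi = np.real(v[:, k])
    pi = pi / pi.sum()
    return pi
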