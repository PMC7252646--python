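"""Scripted phase-oscillator networks with controllable cluster structure.

The simulator realizes networks of phase oscillators whose coupling acts on
the *angular speed* (the per-step phase increment) rather than on the phase
itself.  An uncoupled oscillator keeps its speed constant,

    phi_dot[m, t] = phi_dot[m, t-1],

and a pair coupled with strength ``a`` relaxes its speed difference
geometrically: with the attracting sign convention each partner moves toward
the other,

    phi_dot[m, t] = phi_dot[m, t-1] - a * (phi_dot[m, t-1] - phi_dot[n, t-1]),

so the pairwise speed gap decays with ratio ``1 - 2a`` per step.  Oscillators
sharing a common angular speed over an interval are *phase-locked*: their
phase difference is constant, which is exactly the synchrony notion the
connectivity pipeline detects.

Evolving cluster structure is described by a :class:`ScenarioScript`: a set
of piecewise-constant angular-speed targets (cluster membership = shared
target), an optional schedule of pairwise couplings for free-running
intervals, and ground-truth cluster labels.  Three built-in scripts
(:func:`build_scenario`) stage instantaneous cluster merges and splits used
to validate the eigenvector dynamics downstream.  Scripts also drive
:func:`synth_multichannel_signal`, which turns phase trajectories into
noisy, EEG-like multichannel signals for end-to-end testing.

Time is discrete with one step per sample; the default step duration of
1 ms mimics a 1 kHz recording, and oscillation frequencies in Hz convert to
angular speeds via ``2*pi*f/fs``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScenarioScript",
    "SpeedSegment",
    "CouplingWindow",
    "LabelInterval",
    "PhaseTrajectories",
    "ScenarioError",
    "hz_to_rad_per_step",
    "simulate_phase_network",
    "build_scenario",
    "synth_multichannel_signal",
    "SCENARIO_NAMES",
]

TWO_PI = 2.0 * np.pi


class ScenarioError(ValueError):
    """Invalid scenario configuration (overlapping segments, bad speeds...)."""


def hz_to_rad_per_step(freq_hz: float, fs: float = 1000.0) -> float:
    """Convert an oscillation frequency in Hz to rad/step at sampling rate fs."""
    return TWO_PI * freq_hz / fs


@dataclass(frozen=True)
class SpeedSegment:
    """Scripted angular-speed target on [start, end) for a set of oscillators."""

    start: int
    end: int
    oscillators: tuple[int, ...]
    speed: float  # rad/step


@dataclass(frozen=True)
class CouplingWindow:
    """Symmetric pairwise speed coupling of strength a_mn active on [start, end)."""

    start: int
    end: int
    pair: tuple[int, int]
    strength: float


@dataclass(frozen=True)
class LabelInterval:
    """Ground-truth cluster id per oscillator on [start, end)."""

    start: int
    end: int
    labels: tuple[int, ...]


@dataclass
class ScenarioScript:
    """Scripted angular-speed targets and coupling schedule for a simulation.

    Oscillator indices are 0-based.  Within a scripted segment the realized
    angular speed equals the target exactly; at steps not covered by any
    segment an oscillator free-runs under the coupling schedule (constant
    speed if uncoupled).  ``initial_speeds`` seeds free-running oscillators
    at step 0.
    """

    n_oscillators: int
    duration: int
    segments: list[SpeedSegment]
    coupling: list[CouplingWindow] = field(default_factory=list)
    label_intervals: list[LabelInterval] = field(default_factory=list)
    initial_speeds: np.ndarray | None = None
    step_duration: float = 1e-3  # seconds per step
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_oscillators < 1:
            raise ScenarioError("need at least one oscillator")
        if self.duration < 1:
            raise ScenarioError("duration must be positive")
        covered = [[] for _ in range(self.n_oscillators)]
        for seg in self.segments:
            if not (0 <= seg.start < seg.end <= self.duration):
                raise ScenarioError(f"segment [{seg.start}, {seg.end}) outside [0, {self.duration})")
            if not np.isfinite(seg.speed):
                raise ScenarioError("segment angular speed must be finite")
            for m in seg.oscillators:
                if not 0 <= m < self.n_oscillators:
                    raise ScenarioError(f"oscillator index {m} out of range")
                covered[m].append((seg.start, seg.end))
        for m, intervals in enumerate(covered):
            intervals.sort()
            for (s0, e0), (s1, _) in zip(intervals, intervals[1:]):
                if s1 < e0:
                    raise ScenarioError(f"overlapping scripted segments for oscillator {m}")
        for cw in self.coupling:
            m, n = cw.pair
            if m == n or not (0 <= m < self.n_oscillators and 0 <= n < self.n_oscillators):
                raise ScenarioError(f"bad coupling pair {cw.pair}")
        if self.initial_speeds is not None:
            self.initial_speeds = np.asarray(self.initial_speeds, dtype=float)
            if self.initial_speeds.shape != (self.n_oscillators,):
                raise ScenarioError("initial_speeds must have one entry per oscillator")

    @property
    def fs(self) -> float:
        return 1.0 / self.step_duration

    def cluster_labels(self, step: int) -> np.ndarray | None:
        """Ground-truth cluster id per oscillator at a time step, if recorded."""
        for iv in self.label_intervals:
            if iv.start <= step < iv.end:
                return np.asarray(iv.labels, dtype=int)
        return None

    def largest_cluster(self, step: int) -> frozenset[int] | None:
        """Member set of the largest scripted cluster at a time step."""
        labels = self.cluster_labels(step)
        if labels is None:
            return None
        ids, counts = np.unique(labels, return_counts=True)
        top = ids[np.argmax(counts)]
        return frozenset(np.flatnonzero(labels == top).tolist())

    def to_dict(self) -> dict:
        """Plain-python representation for YAML/JSON serialization."""
        return {
            "name": self.name,
            "n_oscillators": self.n_oscillators,
            "duration": self.duration,
            "step_duration": self.step_duration,
            "segments": [
                {"start": s.start, "end": s.end,
                 "oscillators": list(s.oscillators), "speed": float(s.speed)}
                for s in self.segments
            ],
            "coupling": [
                {"start": c.start, "end": c.end,
                 "pair": list(c.pair), "strength": float(c.strength)}
                for c in self.coupling
            ],
            "label_intervals": [
                {"start": iv.start, "end": iv.end, "labels": list(iv.labels)}
                for iv in self.label_intervals
            ],
            "initial_speeds": (None if self.initial_speeds is None
                               else [float(v) for v in self.initial_speeds]),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioScript":
        return cls(
            n_oscillators=int(d["n_oscillators"]),
            duration=int(d["duration"]),
            segments=[SpeedSegment(int(s["start"]), int(s["end"]),
                                   tuple(int(m) for m in s["oscillators"]),
                                   float(s["speed"]))
                      for s in d.get("segments", [])],
            coupling=[CouplingWindow(int(c["start"]), int(c["end"]),
                                     (int(c["pair"][0]), int(c["pair"][1])),
                                     float(c["strength"]))
                      for c in d.get("coupling", [])],
            label_intervals=[LabelInterval(int(iv["start"]), int(iv["end"]),
                                           tuple(int(v) for v in iv["labels"]))
                             for iv in d.get("label_intervals", [])],
            initial_speeds=d.get("initial_speeds"),
            step_duration=float(d.get("step_duration", 1e-3)),
            name=str(d.get("name", "")),
        )


@dataclass
class PhaseTrajectories:
    """Simulated phases and angular speeds, one row per step, one column per oscillator.

    ``speeds[t]`` is the phase increment applied at step t (``speeds[0]`` is
    the initial speed), so ``phases[t] - phases[t-1] == speeds[t]`` for t >= 1.
    """

    phases: np.ndarray  # (duration, n) rad
    speeds: np.ndarray  # (duration, n) rad/step
    step_duration: float = 1e-3

    @property
    def fs(self) -> float:
        return 1.0 / self.step_duration

    @property
    def n_oscillators(self) -> int:
        return self.phases.shape[1]

    @property
    def duration(self) -> int:
        return self.phases.shape[0]


def simulate_phase_network(
    script: ScenarioScript,
    seed: int = 0,
    coupling_sign: str = "attract",
) -> PhaseTrajectories:
    """Run the angular-speed autoregression defined by a scenario script.

    Initial phases are drawn uniformly on [0, 2*pi).  Scripted segments pin
    the realized speed to the target exactly; outside them oscillators
    follow the pairwise coupling recurrence.  ``coupling_sign="attract"``
    uses the stabilizing convention (speed differences decay with ratio
    ``1 - 2a`` under a symmetric pair coupling); ``"as_printed"`` flips the
    sign of the coupling term, which amplifies differences and is retained
    only for fidelity experiments.
    """
    if coupling_sign not in ("attract", "as_printed"):
        raise ValueError(f"unknown coupling_sign {coupling_sign!r}")
    sign = -1.0 if coupling_sign == "attract" else 1.0
    rng = np.random.default_rng(seed)
    n, duration = script.n_oscillators, script.duration

    speeds = np.full((duration, n), np.nan)
    for seg in script.segments:
        idx = list(seg.oscillators)
        speeds[seg.start:seg.end, idx] = seg.speed
    scripted = ~np.isnan(speeds)

    if script.initial_speeds is not None:
        free0 = ~scripted[0]
        speeds[0, free0] = script.initial_speeds[free0]
    if np.isnan(speeds[0]).any():
        missing = np.flatnonzero(np.isnan(speeds[0])).tolist()
        raise ScenarioError(
            f"oscillators {missing} have neither a scripted segment at step 0 "
            "nor an initial speed"
        )

    if not scripted[1:].all():
        for t in range(1, duration):
            free = ~scripted[t]
            if not free.any():
                continue
            prev = speeds[t - 1]
            nxt = prev.copy()
            for cw in script.coupling:
                if cw.start <= t < cw.end:
                    m, k = cw.pair
                    gap = prev[m] - prev[k]
                    nxt[m] += sign * cw.strength * gap
                    nxt[k] -= sign * cw.strength * gap
            speeds[t, free] = nxt[free]

    if not np.isfinite(speeds).all():
        raise FloatingPointError("angular speeds diverged (non-finite values)")

    phases = np.empty((duration, n))
    phases[0] = rng.uniform(0.0, TWO_PI, size=n)
    np.cumsum(speeds[1:], axis=0, out=phases[1:])
    phases[1:] += phases[0]
    return PhaseTrajectories(phases=phases, speeds=speeds,
                             step_duration=script.step_duration)


def _uniform_segments(schedule, duration):
    """Expand a [(start, end, {cluster: (members, hz)})] schedule into segments/labels."""
    segments, labels = [], []
    for start, end, clusters in schedule:
        lab = np.zeros(max(max(members) for members, _ in clusters.values()) + 1, int)
        for cid, (members, hz) in clusters.items():
            segments.append(SpeedSegment(start, end, tuple(members),
                                         hz_to_rad_per_step(hz)))
            lab[list(members)] = cid
        labels.append(LabelInterval(start, end, tuple(lab.tolist())))
    return segments, labels


SCENARIO_NAMES = ("scenario1", "scenario2", "benchmark")


def build_scenario(name: str) -> ScenarioScript:
    """Construct one of the built-in evolving-cluster scripts.

    All three run at 1 kHz (1 ms steps) with frequencies in Hz converted to
    rad/step, and all cluster rearrangements are instantaneous step changes
    of the target speed:

    ``scenario1``
        8 oscillators: a 3-oscillator cluster at 3 Hz and a 5-oscillator
        cluster at 5 Hz merge into a single cluster (4 Hz) at step 500 and
        separate again at step 1500; duration 2000.
    ``scenario2``
        15 oscillators: cluster 1 (3 osc, 3 Hz) runs alone while clusters 2
        (5 osc) and 3 (7 osc) share 5 Hz; at step 1000 cluster 2 leaves
        cluster 3 and joins cluster 1 at 3 Hz; duration 2000.
    ``benchmark``
        27 oscillators in four indivisible clusters of 3/5/9/10 at
        3/4/5/7 Hz; merges and splits at steps 500 (1+2 and 3+4 pair up),
        1000 (3 leaves 4, joins 1+2), 1500 (1 leaves, 2+3 merge with 4);
        duration 2500 so the final arrangement is well represented.
    """
    c = {
        "scenario1": {
            "n": 8,
            "schedule": [
                (0, 500, {1: (range(0, 3), 3.0), 2: (range(3, 8), 5.0)}),
                (500, 1500, {1: (range(0, 8), 4.0)}),
                (1500, 2000, {1: (range(0, 3), 3.0), 2: (range(3, 8), 5.0)}),
            ],
            "duration": 2000,
        },
        "scenario2": {
            "n": 15,
            "schedule": [
                (0, 1000, {1: (range(0, 3), 3.0), 2: (range(3, 15), 5.0)}),
                (1000, 2000, {1: (range(0, 8), 3.0), 2: (range(8, 15), 5.0)}),
            ],
            "duration": 2000,
        },
        "benchmark": {
            "n": 27,
            "schedule": [
                (0, 500, {1: (range(0, 3), 3.0), 2: (range(3, 8), 4.0),
                          3: (range(8, 17), 5.0), 4: (range(17, 27), 7.0)}),
                (500, 1000, {1: (range(0, 8), 3.5), 2: (range(8, 27), 6.0)}),
                (1000, 1500, {1: (range(0, 17), 3.5), 2: (range(17, 27), 7.0)}),
                (1500, 2500, {1: (range(0, 3), 3.0), 2: (range(3, 27), 6.0)}),
            ],
            "duration": 2500,
        },
    }.get(name)
    if c is None:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    segments, labels = _uniform_segments(c["schedule"], c["duration"])
    return ScenarioScript(
        n_oscillators=c["n"], duration=c["duration"], segments=segments,
        label_intervals=labels, name=name,
    )


def synth_multichannel_signal(
    script: ScenarioScript,
    carrier_band: tuple[float, float] | None = None,
    noise_sd: float = 0.0,
    fs: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """EEG-like multichannel fixture: ``cos(phase) + white Gaussian noise``.

    Returns a (channels, samples) array plus channel labels.  Each channel
    is the cosine of a simulated oscillator's phase, so channels sharing a
    scripted angular speed are genuinely phase-locked and, with
    ``noise_sd=0``, the connectivity pipeline recovers the scripted cluster
    structure exactly.  ``carrier_band`` declares the band the scripted
    frequencies live in and is validated against Nyquist.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    fs = script.fs if fs is None else float(fs)
    if carrier_band is not None and carrier_band[1] * 2.0 > fs:
        raise ScenarioError(
            f"carrier band {carrier_band} violates Nyquist at fs={fs}"
        )
    traj = simulate_phase_network(script, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5169]))
    x = np.cos(traj.phases.T)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    labels = [f"ch{m:02d}" for m in range(script.n_oscillators)]
    return x, labels
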