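"""Phase-locking connectivity from multichannel signals.

The pipeline goes: narrow band-pass filter -> analytic-signal phase
(Hilbert transform) -> angular speed (first phase difference) -> sliding
windows of unit phasors ``exp(i*phi_dot)`` -> pairwise Euclidean distance
between phasor rows -> threshold into a binary adjacency series.

The distance between channels m and n over a window of width W is

    d_mn = || v_m - v_n ||_2,   v_m = (exp(i*phi_dot[m, t]))_{t in window},

which equals ``sqrt(sum_t 4*sin^2((phi_dot[m,t] - phi_dot[n,t]) / 2))``.
Small d means the two channels kept nearly equal angular speeds across the
window, i.e. a constant phase difference: phase-locking.  Because the
distance is accumulated sample by sample, a window split into disjoint
sub-windows satisfies ``d^2 = d_a^2 + d_b^2`` exactly, which is what makes
windows that straddle an instantaneous network change resolve a merge and
a split as two separate events downstream.

The classical phase-coherence PLV (modulus of the mean phase-difference
phasor) is provided for comparison; it measures mean phase difference
rather than speed difference and can miss crossings of phase trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "WindowSpec",
    "DistanceMatrixSeries",
    "BinaryNetworkSeries",
    "DEFAULT_THRESHOLD",
    "DEFAULT_BANDS",
    "design_bandpass",
    "edge_margin",
    "bandpass_filter",
    "instantaneous_phase",
    "angular_speed",
    "windowed_plv_distance",
    "phase_coherence",
    "binarize",
    "suggest_threshold",
]

#: Distance threshold below which a channel pair counts as phase-locked.
DEFAULT_THRESHOLD = 4e-4

#: Narrow frequency bands (Hz) used for the band-limited analysis.
DEFAULT_BANDS = ((8.0, 12.0), (18.0, 22.0), (26.0, 30.0), (38.0, 42.0))


@dataclass(frozen=True)
class WindowSpec:
    """Sliding window in samples: width, hop, and the sampling rate behind them."""

    width: int
    step: int
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ValueError("window width must be at least 2 samples")
        if not 1 <= self.step <= self.width:
            raise ValueError("window step must satisfy 1 <= step <= width")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @classmethod
    def from_ms(cls, width_ms: float = 40.0, step_ms: float = 5.0,
                fs: float = 1000.0) -> "WindowSpec":
        return cls(width=int(round(width_ms * fs / 1000.0)),
                   step=int(round(step_ms * fs / 1000.0)), fs=fs)

    def starts(self, n_samples: int, margin: int = 0) -> np.ndarray:
        """Window start indices fitting in a series, optionally inset by a margin."""
        last = n_samples - margin - self.width
        if last < margin:
            raise ValueError(
                f"series of length {n_samples} fits no window of width "
                f"{self.width} with margin {margin}"
            )
        return np.arange(margin, last + 1, self.step)


@dataclass
class DistanceMatrixSeries:
    """Per-window symmetric distance matrices with window metadata."""

    distances: np.ndarray  # (n_windows, C, C), nonnegative, zero diagonal
    window_starts: np.ndarray  # (n_windows,) sample index of each window start
    window: WindowSpec
    channel_names: list[str]

    @property
    def n_windows(self) -> int:
        return self.distances.shape[0]

    @property
    def n_channels(self) -> int:
        return self.distances.shape[1]


@dataclass
class BinaryNetworkSeries:
    """Per-window symmetric binary adjacency matrices (the dynamical network)."""

    adjacency: np.ndarray  # (n_windows, C, C) bool, zero diagonal
    threshold: float
    window_starts: np.ndarray
    window: WindowSpec
    channel_names: list[str]

    @property
    def n_windows(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_channels(self) -> int:
        return self.adjacency.shape[1]


def design_bandpass(band: tuple[float, float], fs: float,
                    transition_hz: float = 4.0) -> np.ndarray:
    """Linear-phase FIR band-pass taps (Hamming window design).

    The number of taps follows the Hamming transition-width rule
    ``N >= 3.3 / (transition_hz / fs)``, rounded up to odd so the filter
    has an integer group delay and can be applied with exactly zero phase
    by centered convolution.
    """
    lo, hi = band
    if not 0.0 < lo < hi < fs / 2.0:
        raise ValueError(f"band {band} must lie strictly inside (0, fs/2)")
    numtaps = int(np.ceil(3.3 * fs / transition_hz))
    numtaps += 1 - numtaps % 2
    return sps.firwin(numtaps, [lo, hi], pass_zero=False, window="hamming", fs=fs)


def edge_margin(band: tuple[float, float], fs: float,
                transition_hz: float = 4.0) -> int:
    """Samples at each end contaminated by filter transients and phase startup.

    Half the filter length (the group delay) plus one period of the lowest
    band frequency; windows overlapping this margin are excluded by default.
    """
    taps = int(np.ceil(3.3 * fs / transition_hz))
    taps += 1 - taps % 2
    return taps // 2 + int(np.ceil(fs / band[0]))


def bandpass_filter(x: np.ndarray, band: tuple[float, float], fs: float,
                    transition_hz: float = 4.0) -> np.ndarray:
    """Zero-phase FIR band-pass of a (channels, samples) array.

    The symmetric taps are applied by centered convolution, so the output
    has exactly zero phase distortion and the Hamming design's stopband
    attenuation (~53 dB).  The first and last :func:`edge_margin` samples
    carry startup transients and should not enter sliding windows.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    taps = design_bandpass(band, fs, transition_hz)
    if x.shape[-1] < 3 * len(taps) // 2:
        raise ValueError(
            f"signal length {x.shape[-1]} too short for filter of "
            f"{len(taps)} taps; need at least {3 * len(taps) // 2} samples"
        )
    return sps.fftconvolve(x, taps[np.newaxis, :], mode="same", axes=-1)


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Unwrapped analytic-signal phase of each channel of a narrow-band signal."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    sd = x.std(axis=-1)
    if np.any(sd < 1e-12 * max(1.0, float(np.abs(x).max(initial=0.0)))):
        warnings.warn(
            "near-constant channel(s): analytic-signal phase is degenerate",
            RuntimeWarning, stacklevel=2,
        )
    return np.unwrap(np.angle(sps.hilbert(x, axis=-1)), axis=-1)


def angular_speed(phase: np.ndarray) -> np.ndarray:
    """First time-difference of the unwrapped phase (rad/sample).

    Output is one sample shorter than the input.  A magnitude above pi is
    physically impossible for a properly unwrapped narrow-band phase and
    flags an unwrap failure.
    """
    phase = np.atleast_2d(np.asarray(phase, dtype=float))
    if phase.shape[-1] < 2:
        raise ValueError("need at least two phase samples to differentiate")
    speed = np.diff(phase, axis=-1)
    if np.abs(speed).max(initial=0.0) > np.pi:
        warnings.warn(
            "angular speed exceeds pi rad/sample; phase may not be unwrapped",
            RuntimeWarning, stacklevel=2,
        )
    return speed


def _pairwise_window_norms(rows: np.ndarray, width: int) -> np.ndarray:
    """Squared pairwise distances between complex or real rows of one window."""
    if np.iscomplexobj(rows):
        gram = rows @ rows.conj().T
        sq = gram.real
        diag = np.diag(sq)
    else:
        sq = rows @ rows.T
        diag = np.diag(sq)
    d2 = diag[:, None] + diag[None, :] - 2.0 * sq
    d2 = 0.5 * (d2 + d2.T)  # exact symmetry despite summation-order round-off
    np.maximum(d2, 0.0, out=d2)
    return d2


def windowed_plv_distance(
    speeds: np.ndarray,
    window: WindowSpec,
    mode: str = "phasor",
    margin: int = 0,
    channel_names: list[str] | None = None,
) -> DistanceMatrixSeries:
    """Sliding-window pairwise phase-locking distances of an angular-speed series.

    ``speeds`` is (channels, samples) in rad/sample.  In the canonical
    ``"phasor"`` mode each window row is the unit-phasor vector
    ``exp(i*phi_dot)`` and the distance is the Euclidean norm of row
    differences; ``"speed"`` skips the phasor map and measures the raw
    speed rows, which agrees to first order for small speed gaps.
    """
    if mode not in ("phasor", "speed"):
        raise ValueError(f"unknown mode {mode!r}")
    speeds = np.atleast_2d(np.asarray(speeds, dtype=float))
    if not np.isfinite(speeds).all():
        raise ValueError("angular speeds must be finite")
    n_channels, n_samples = speeds.shape
    starts = window.starts(n_samples, margin=margin)
    rows_all = np.exp(1j * speeds) if mode == "phasor" else speeds
    out = np.empty((len(starts), n_channels, n_channels))
    for k, s in enumerate(starts):
        d2 = _pairwise_window_norms(rows_all[:, s:s + window.width], window.width)
        out[k] = np.sqrt(d2)
        np.fill_diagonal(out[k], 0.0)
    names = channel_names or [f"ch{m:02d}" for m in range(n_channels)]
    return DistanceMatrixSeries(distances=out, window_starts=starts,
                                window=window, channel_names=list(names))


def phase_coherence(
    phases: np.ndarray,
    window: WindowSpec,
    margin: int = 0,
) -> np.ndarray:
    """Classical phase-coherence PLV per sliding window.

    Returns (n_windows, C, C) values in [0, 1]: the modulus of the
    window-averaged phasor of the phase difference,
    ``|mean_t exp(i*(phi_m - phi_n))|``.
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    starts = window.starts(phases.shape[-1], margin=margin)
    z = np.exp(1j * phases)
    out = np.empty((len(starts), phases.shape[0], phases.shape[0]))
    for k, s in enumerate(starts):
        seg = z[:, s:s + window.width]
        out[k] = np.abs(seg @ seg.conj().T) / window.width
    return np.clip(out, 0.0, 1.0)


def binarize(distances: DistanceMatrixSeries,
             threshold: float = DEFAULT_THRESHOLD) -> BinaryNetworkSeries:
    """Threshold a distance series into binary phase-locking networks.

    An edge (m, n) is present iff ``d_mn < threshold`` (strict: a tie at
    the threshold is a non-edge).  The diagonal is always zero.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    adj = distances.distances < threshold
    for a in adj:
        np.fill_diagonal(a, False)
    return BinaryNetworkSeries(
        adjacency=adj, threshold=float(threshold),
        window_starts=distances.window_starts, window=distances.window,
        channel_names=distances.channel_names,
    )


def suggest_threshold(distances: DistanceMatrixSeries,
                      max_samples: int = 200_000,
                      seed: int = 0) -> float:
    """Data-driven locking threshold from the bimodal distance distribution.

    Automates the reviewer's procedure of inspecting distances of known
    locked and unlocked pairs: pools the off-diagonal distances, and splits
    their log-scale distribution at the Otsu point between the locked
    (small-distance) and unlocked modes.  Only meaningful when both modes
    are present in the data.
    """
    from skimage.filters import threshold_otsu

    iu = np.triu_indices(distances.n_channels, k=1)
    vals = distances.distances[:, iu[0], iu[1]].ravel()
    vals = vals[vals > 0]
    if vals.size < 2:
        raise ValueError("not enough nonzero distances to estimate a threshold")
    if vals.size > max_samples:
        rng = np.random.default_rng(seed)
        vals = rng.choice(vals, size=max_samples, replace=False)
    return float(10.0 ** threshold_otsu(np.log10(vals)))
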