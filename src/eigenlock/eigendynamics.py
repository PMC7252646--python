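"""Prime-eigenvector dynamics of binary network series.

The *prime eigenvector* of a symmetric binary adjacency matrix is the
eigenvector of its largest eigenvalue.  By Perron-Frobenius it can be
oriented entrywise nonnegative, and its support identifies the most
strongly connected cluster: for a disjoint union of cliques it is exactly
the uniform unit vector on the largest clique, with entries
``1/sqrt(|clique|)``.

Tracking the prime eigenvector ``Phi(t)`` across sliding windows turns a
time-varying network into a trajectory in eigenvector space.  When the
dominant cluster is stable, successive inner products
``<Phi(t), Phi(t+1)>`` sit on a plateau near 1; when it changes members or
identity, the inner product dips to the analytic overlap of uniform
vectors, ``|A ∩ B| / sqrt(|A| |B|)`` for consecutive dominant cliques A
and B — all the way to 0 when the supports are disjoint.  The trajectory
therefore resolves into meta-stable states separated by quick transitions,
quantified here by event counts (inner product < 0.01: transition;
> 0.99: persistence), spike detection, all-pairs recurrence matrices, and
a greedy state segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectivity import BinaryNetworkSeries, WindowSpec

__all__ = [
    "PrimeEigenvector",
    "EigenvectorSeries",
    "InnerProductSeries",
    "EventSummary",
    "Spike",
    "StateSegment",
    "StateSegmentation",
    "prime_eigenvector",
    "prime_eigenvector_series",
    "successive_inner_products",
    "count_events",
    "detect_spikes",
    "recurrence_matrix",
    "segment_states",
    "accumulated_event_frequency",
]

#: Relative eigenvalue gap below which the top eigenvalue counts as degenerate.
DEGENERACY_TOL = 1e-8

#: Successive-inner-product bounds defining transition / persistence events.
EVENT0_LEVEL = 0.01
EVENT1_LEVEL = 0.99

#: Plateau level and dip level for spike detection (see ``detect_spikes``).
PLATEAU_LEVEL = 0.99
SPIKE_LEVEL = 0.95


@dataclass(frozen=True)
class PrimeEigenvector:
    """Unit-norm nonnegative leading eigenvector of one window's adjacency."""

    vector: np.ndarray
    eigenvalue: float
    valid: bool


def _validate_adjacency(adjacency: np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    return a.astype(float)


def _component_perron(sub: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest eigenvalue and nonnegative unit eigenvector of a connected graph."""
    w, v = np.linalg.eigh(sub)
    lam = float(w[-1])
    vec = v[:, -1]
    # Perron vector of a connected nonnegative matrix is strictly positive
    # after orientation; tiny negative round-off is clipped away.
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    return lam, vec / np.linalg.norm(vec)


def prime_eigenvector(
    adjacency: np.ndarray,
    previous: np.ndarray | None = None,
    degeneracy_tol: float = DEGENERACY_TOL,
) -> PrimeEigenvector:
    """Leading eigenvector of a symmetric binary adjacency matrix.

    Works per connected component: each component contributes its Perron
    eigenvalue, and the prime eigenvector is the Perron vector of the
    component with the largest one, embedded in the full node set.  If two
    or more components tie within ``degeneracy_tol`` (equal-size cliques,
    typically), the tie is resolved toward maximal overlap with
    ``previous``, or, lacking one, toward the component containing the
    lowest node index — a deterministic, continuous rule where a raw
    eigensolver would return an arbitrary mixture.  An edgeless matrix has
    no meaningful dominant cluster and is flagged invalid.
    """
    a = _validate_adjacency(adjacency)
    n = a.shape[0]
    if not a.any():
        return PrimeEigenvector(np.zeros(n), 0.0, False)

    n_comp, labels = connected_components(csr_matrix(a), directed=False)
    candidates: list[tuple[float, np.ndarray]] = []
    for comp in range(n_comp):
        nodes = np.flatnonzero(labels == comp)
        if nodes.size < 2:
            continue
        lam, vec = _component_perron(a[np.ix_(nodes, nodes)])
        full = np.zeros(n)
        full[nodes] = vec
        candidates.append((lam, full))

    lam_max = max(lam for lam, _ in candidates)
    tol = degeneracy_tol * max(1.0, abs(lam_max))
    tied = [(lam, v) for lam, v in candidates if lam_max - lam <= tol]
    if len(tied) == 1:
        lam, vec = tied[0]
    elif previous is not None:
        lam, vec = max(tied, key=lambda c: float(c[1] @ previous))
    else:
        lam, vec = min(tied, key=lambda c: int(np.flatnonzero(c[1])[0]))
    return PrimeEigenvector(vec, lam, True)


@dataclass
class EigenvectorSeries:
    """Prime eigenvector per window: unit-norm, entrywise nonnegative when valid."""

    vectors: np.ndarray  # (n_windows, C)
    eigenvalues: np.ndarray  # (n_windows,)
    valid: np.ndarray  # (n_windows,) bool
    window_starts: np.ndarray
    window: WindowSpec | None = None
    channel_names: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]


def prime_eigenvector_series(
    networks: BinaryNetworkSeries,
    degeneracy_tol: float = DEGENERACY_TOL,
) -> EigenvectorSeries:
    """Prime eigenvector of every window, chained for degeneracy continuity.

    Each window's degenerate ties are broken against the most recent valid
    eigenvector, so identical consecutive adjacencies always yield
    identical vectors (inner product exactly 1) even under eigenvalue
    multiplicity.
    """
    n_w, n_c = networks.n_windows, networks.n_channels
    vectors = np.zeros((n_w, n_c))
    eigenvalues = np.zeros(n_w)
    valid = np.zeros(n_w, dtype=bool)
    previous: np.ndarray | None = None
    for k in range(n_w):
        pe = prime_eigenvector(networks.adjacency[k], previous=previous,
                               degeneracy_tol=degeneracy_tol)
        vectors[k] = pe.vector
        eigenvalues[k] = pe.eigenvalue
        valid[k] = pe.valid
        if pe.valid:
            previous = pe.vector
    return EigenvectorSeries(
        vectors=vectors, eigenvalues=eigenvalues, valid=valid,
        window_starts=networks.window_starts, window=networks.window,
        channel_names=networks.channel_names,
    )


@dataclass
class InnerProductSeries:
    """Inner products of consecutive prime eigenvectors, in [0, 1] when valid.

    ``values[p]`` pairs windows p and p+1; a pair is valid only if both
    windows carry a valid eigenvector.  ``window_starts`` holds the start
    sample of the *later* window of each pair, which is the natural time
    stamp of a change between the two windows.
    """

    values: np.ndarray  # (n_windows - 1,)
    valid: np.ndarray  # (n_windows - 1,) bool
    window_starts: np.ndarray  # (n_windows - 1,) start of window p+1
    window: WindowSpec | None = None

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


def successive_inner_products(series: EigenvectorSeries) -> InnerProductSeries:
    """Dot products of consecutive prime eigenvectors."""
    if series.n_windows < 2:
        raise ValueError("need at least two windows for successive inner products")
    if int(series.valid.sum()) < 2:
        raise ValueError("need at least two valid windows")
    values = np.einsum("ij,ij->i", series.vectors[:-1], series.vectors[1:])
    values = np.clip(values, 0.0, 1.0)
    valid = series.valid[:-1] & series.valid[1:]
    values[~valid] = np.nan
    return InnerProductSeries(
        values=values, valid=valid, window_starts=series.window_starts[1:],
        window=series.window,
    )


@dataclass(frozen=True)
class EventSummary:
    """Counts and normalized frequencies of transition and persistence events."""

    n_event0: int
    n_event1: int
    n_valid: int
    freq_event0: float
    freq_event1: float


def count_events(series: InnerProductSeries, lo: float = EVENT0_LEVEL,
                 hi: float = EVENT1_LEVEL) -> EventSummary:
    """Count Event 0 (< lo: state transition) and Event 1 (> hi: persistence).

    Frequencies are normalized by the number of valid pairs only.
    """
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("need 0 <= lo < hi <= 1")
    vals = series.valid_values()
    n_valid = vals.size
    if n_valid == 0:
        raise ValueError("no valid inner-product pairs")
    n0 = int((vals < lo).sum())
    n1 = int((vals > hi).sum())
    return EventSummary(n0, n1, n_valid, n0 / n_valid, n1 / n_valid)


@dataclass(frozen=True)
class Spike:
    """One transition spike in a successive-inner-product series."""

    pair_index: int  # index of the minimum pair within the series
    window_start: int  # start sample of the later window at the minimum
    minimum: float
    depth: float  # 1 - minimum


def detect_spikes(
    series: InnerProductSeries,
    plateau_level: float = PLATEAU_LEVEL,
    spike_level: float = SPIKE_LEVEL,
) -> list[Spike]:
    """Locate transition spikes as excursions below the plateau.

    A spike is a maximal run of consecutive valid values below
    ``plateau_level`` that reaches ``spike_level`` or lower at least once;
    it is reported at its minimum.  Two spikes are distinct only if
    separated by at least one value back at plateau level, so the double
    dips produced by a window straddling simultaneous cluster events are
    counted as two spikes, while noise wiggles inside one excursion are
    not.
    """
    if not plateau_level > spike_level >= 0.0:
        raise ValueError("need plateau_level > spike_level >= 0")
    spikes: list[Spike] = []
    run: list[int] = []

    def close_run() -> None:
        if not run:
            return
        vals = series.values[run]
        k = int(np.argmin(vals))
        if vals[k] <= spike_level:
            p = run[k]
            spikes.append(Spike(
                pair_index=p, window_start=int(series.window_starts[p]),
                minimum=float(vals[k]), depth=float(1.0 - vals[k]),
            ))
        run.clear()

    for p in range(series.n_pairs):
        if not series.valid[p]:
            continue
        if series.values[p] < plateau_level:
            run.append(p)
        else:
            close_run()
    close_run()
    return spikes


def recurrence_matrix(
    series: EigenvectorSeries,
    window_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """All-pairs inner products of prime eigenvectors over a window range.

    Entry (i, j) is ``<Phi(i), Phi(j)>``; rows/columns of invalid windows
    are NaN.  Blocks of high values are temporal clusters — residences
    near one attractor — and the diagonal is 1 for valid windows.
    """
    lo, hi = window_range if window_range is not None else (0, series.n_windows)
    if not 0 <= lo < hi <= series.n_windows:
        raise ValueError(f"window range [{lo}, {hi}) is empty or out of bounds")
    v = series.vectors[lo:hi]
    r = np.clip(v @ v.T, 0.0, 1.0)
    invalid = ~series.valid[lo:hi]
    r[invalid, :] = np.nan
    r[:, invalid] = np.nan
    return r


@dataclass(frozen=True)
class StateSegment:
    """One meta-stable state: a run of windows with a common centroid vector."""

    start: int  # first window index (inclusive)
    end: int  # last window index (exclusive)
    centroid: np.ndarray  # unit-norm mean eigenvector of the run

    @property
    def n_windows(self) -> int:
        return self.end - self.start


@dataclass
class StateSegmentation:
    """Ordered, disjoint meta-stable states covering all valid windows."""

    segments: list[StateSegment]
    window: WindowSpec | None = None

    @property
    def attractors(self) -> np.ndarray:
        return np.stack([s.centroid for s in self.segments])

    def durations(self) -> np.ndarray:
        """State durations in windows."""
        return np.array([s.n_windows for s in self.segments])

    def durations_seconds(self) -> np.ndarray | None:
        if self.window is None:
            return None
        return self.durations() * self.window.step / self.window.fs


def segment_states(series: EigenvectorSeries,
                   similarity: float = 0.99) -> StateSegmentation:
    """Greedy segmentation of the eigenvector trajectory into meta-stable states.

    Scans valid windows in order, extending the current state while the
    next eigenvector's inner product with the running centroid (the
    renormalized mean of the state's vectors so far) stays at or above
    ``similarity``; otherwise a new state begins.  Invalid windows are
    skipped and belong to no state, so state durations sum to the number
    of valid windows.
    """
    if not 0.0 < similarity <= 1.0:
        raise ValueError("similarity must be in (0, 1]")
    segments: list[StateSegment] = []
    start: int | None = None
    acc = np.zeros(series.vectors.shape[1])
    count = 0
    last = 0

    def close(end: int) -> None:
        nonlocal start, count
        if start is None:
            return
        centroid = acc / np.linalg.norm(acc)
        segments.append(StateSegment(start=start, end=end, centroid=centroid))
        start, count = None, 0
        acc[:] = 0.0

    for k in range(series.n_windows):
        if not series.valid[k]:
            continue
        v = series.vectors[k]
        if count:
            centroid = acc / np.linalg.norm(acc)
            if float(v @ centroid) < similarity:
                close(last + 1)
        if not count:
            start = k
        acc += v
        count += 1
        last = k
    close(last + 1)
    return StateSegmentation(segments=segments, window=series.window)


def accumulated_event_frequency(
    series: InnerProductSeries,
    lo: float = EVENT0_LEVEL,
    hi: float = EVENT1_LEVEL,
) -> tuple[np.ndarray, np.ndarray]:
    """Running Event 0 and Event 1 frequencies over the valid pairs seen so far.

    Suitable for online monitoring: entry p is the event count among valid
    pairs up to and including p, divided by the number of valid pairs so
    far (NaN while that number is zero).  The final entries equal the
    :func:`count_events` frequencies.
    """
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("need 0 <= lo < hi <= 1")
    valid = series.valid.astype(float)
    n_seen = np.cumsum(valid)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc0 = np.cumsum(valid * (series.values < lo)) / n_seen
        acc1 = np.cumsum(valid * (series.values > hi)) / n_seen
    acc0[n_seen == 0] = np.nan
    acc1[n_seen == 0] = np.nan
    return acc0, acc1
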