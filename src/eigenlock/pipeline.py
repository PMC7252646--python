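"""End-to-end orchestration: transformers, config-driven runs, manifests.

Two scikit-learn-style transformers expose the pipeline stages:

* :class:`PhaseLockingConnectivity` — (channels, samples) signals ->
  :class:`~eigenlock.connectivity.BinaryNetworkSeries` via band-pass,
  Hilbert phase, angular speed, windowed phasor distance, threshold;
* :class:`LeadingEigenvectorDynamics` — network series ->
  :class:`~eigenlock.eigendynamics.InnerProductSeries`, with helpers for
  eigenvectors, events, spikes, recurrence and state segmentation.

Both are stateless in the statistical sense (``fit`` only validates and
records shapes) but follow the estimator contract — ``get_params`` /
``set_params``, fitted attributes with trailing underscores — so they
compose with sklearn pipelines and model selection.  :func:`run_pipeline`
drives them from a config mapping and writes a text artifact bundle plus a
machine-readable run manifest.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import __version__, connectivity as conn, eigendynamics as eig, io as eio
from . import topology as topo
from .connectivity import BinaryNetworkSeries, DistanceMatrixSeries, WindowSpec
from .scenarios import SCENARIO_NAMES, build_scenario, simulate_phase_network

__all__ = [
    "PhaseLockingConnectivity",
    "LeadingEigenvectorDynamics",
    "run_pipeline",
]


class PhaseLockingConnectivity(BaseEstimator, TransformerMixin):
    """Multichannel signals to binary phase-locking network series.

    Parameters
    ----------
    fs : sampling rate in Hz.
    band : (lo, hi) band-pass edges in Hz, or None to accept signals that
        are already narrow-band (no filtering, no edge exclusion).
    window_ms, step_ms : sliding-window width and hop in milliseconds;
        converted to samples at ``fs``.
    threshold : phasor-distance level below which a pair counts as locked.
    distance : "phasor" (canonical) or "speed" (raw-speed Euclidean).
    input_kind : "signal" (filter + Hilbert phase), "phase" (unwrapped
        phase, skips filter/Hilbert) or "speed" (rad/sample angular
        speeds, used directly).
    exclude_edges : drop windows overlapping the filter's startup
        transients (only meaningful when a band is set).
    transition_hz : FIR transition width driving the filter order.
    """

    def __init__(self, fs: float = 1000.0, band: tuple[float, float] | None = None,
                 window_ms: float = 40.0, step_ms: float = 5.0,
                 threshold: float = conn.DEFAULT_THRESHOLD,
                 distance: str = "phasor", input_kind: str = "signal",
                 exclude_edges: bool = True, transition_hz: float = 4.0):
        self.fs = fs
        self.band = band
        self.window_ms = window_ms
        self.step_ms = step_ms
        self.threshold = threshold
        self.distance = distance
        self.input_kind = input_kind
        self.exclude_edges = exclude_edges
        self.transition_hz = transition_hz

    def _window(self) -> WindowSpec:
        return WindowSpec.from_ms(self.window_ms, self.step_ms, self.fs)

    def fit(self, X: np.ndarray, y=None) -> "PhaseLockingConnectivity":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.input_kind not in ("signal", "phase", "speed"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        if self.band is None and self.input_kind == "signal":
            raise ValueError("input_kind='signal' requires a band to filter to")
        self.window_ = self._window()
        self.n_channels_ = X.shape[0]
        self.margin_ = (conn.edge_margin(self.band, self.fs, self.transition_hz)
                        if (self.band is not None and self.exclude_edges
                            and self.input_kind == "signal") else 0)
        return self

    def distance_series(self, X: np.ndarray,
                        channel_names: list[str] | None = None) -> DistanceMatrixSeries:
        """Windowed pairwise distances without thresholding."""
        if not hasattr(self, "window_"):
            self.fit(X)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.input_kind == "signal":
            X = conn.bandpass_filter(X, self.band, self.fs, self.transition_hz)
            phase = conn.instantaneous_phase(X)
            speeds = conn.angular_speed(phase)
        elif self.input_kind == "phase":
            speeds = conn.angular_speed(X)
        else:
            speeds = X
        return conn.windowed_plv_distance(
            speeds, self.window_, mode=self.distance, margin=self.margin_,
            channel_names=channel_names,
        )

    def transform(self, X: np.ndarray,
                  channel_names: list[str] | None = None) -> BinaryNetworkSeries:
        return conn.binarize(self.distance_series(X, channel_names),
                             self.threshold)


class LeadingEigenvectorDynamics(BaseEstimator, TransformerMixin):
    """Binary network series to successive prime-eigenvector inner products.

    ``transform`` returns the :class:`InnerProductSeries`; the companion
    methods expose the other views of the same trajectory (events, spikes,
    recurrence matrix, meta-stable-state segmentation).
    """

    def __init__(self, lo: float = eig.EVENT0_LEVEL, hi: float = eig.EVENT1_LEVEL,
                 plateau_level: float = eig.PLATEAU_LEVEL,
                 spike_level: float = eig.SPIKE_LEVEL,
                 similarity: float = 0.99,
                 degeneracy_tol: float = eig.DEGENERACY_TOL):
        self.lo = lo
        self.hi = hi
        self.plateau_level = plateau_level
        self.spike_level = spike_level
        self.similarity = similarity
        self.degeneracy_tol = degeneracy_tol

    def fit(self, X: BinaryNetworkSeries, y=None) -> "LeadingEigenvectorDynamics":
        self.n_channels_ = X.n_channels
        return self

    def eigenvectors(self, X: BinaryNetworkSeries) -> eig.EigenvectorSeries:
        return eig.prime_eigenvector_series(X, degeneracy_tol=self.degeneracy_tol)

    def transform(self, X: BinaryNetworkSeries) -> eig.InnerProductSeries:
        return eig.successive_inner_products(self.eigenvectors(X))

    def events(self, X: BinaryNetworkSeries) -> eig.EventSummary:
        return eig.count_events(self.transform(X), self.lo, self.hi)

    def spikes(self, X: BinaryNetworkSeries) -> list[eig.Spike]:
        return eig.detect_spikes(self.transform(X), self.plateau_level,
                                 self.spike_level)

    def recurrence(self, X: BinaryNetworkSeries,
                   window_range: tuple[int, int] | None = None) -> np.ndarray:
        return eig.recurrence_matrix(self.eigenvectors(X), window_range)

    def segmentation(self, X: BinaryNetworkSeries) -> eig.StateSegmentation:
        return eig.segment_states(self.eigenvectors(X), self.similarity)


REQUIRED_CONFIG_KEYS = ("input", "window_ms", "step_ms", "threshold", "outdir")


def run_pipeline(config: dict) -> dict:
    """Run the full analysis described by a config mapping and write a bundle.

    Required keys: ``input`` (a built-in scenario name, or a path to a
    delimited signal file), ``window_ms``, ``step_ms``, ``threshold``,
    ``outdir``.  Optional: ``fs`` (default 1000), ``band`` ([lo, hi] Hz;
    required for signal files), ``seed`` (default 0), ``distance``,
    ``spike_level``.  Scenario inputs are analyzed on their exact scripted
    angular speeds; signal files run through filter -> phase -> speed.

    Writes delimited-text tables (distances are omitted: they are large
    and recomputable) plus ``manifest.json`` recording every parameter,
    and returns the in-memory artifact bundle.
    """
    missing = [k for k in REQUIRED_CONFIG_KEYS if k not in config]
    if missing:
        raise KeyError(f"config missing required key(s): {missing}")
    fs = float(config.get("fs", 1000.0))
    seed = int(config.get("seed", 0))
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    source = str(config["input"])
    if source in SCENARIO_NAMES:
        script = build_scenario(source)
        traj = simulate_phase_network(script, seed=seed)
        X = traj.speeds.T
        names = [f"osc{m:02d}" for m in range(script.n_oscillators)]
        input_kind, band, fs = "speed", None, script.fs
    else:
        X, names = eio.read_signals_text(source)
        band = config.get("band")
        if band is None:
            raise ValueError("signal-file input requires a 'band' entry")
        band = (float(band[0]), float(band[1]))
        input_kind = "signal"

    plc = PhaseLockingConnectivity(
        fs=fs, band=band, window_ms=float(config["window_ms"]),
        step_ms=float(config["step_ms"]), threshold=float(config["threshold"]),
        distance=str(config.get("distance", "phasor")), input_kind=input_kind,
    ).fit(X)
    networks = plc.transform(X, channel_names=names)

    led = LeadingEigenvectorDynamics(
        spike_level=float(config.get("spike_level", eig.SPIKE_LEVEL)))
    vectors = led.eigenvectors(networks)
    inner = eig.successive_inner_products(vectors)
    events = eig.count_events(inner, led.lo, led.hi)
    spikes = eig.detect_spikes(inner, led.plateau_level, led.spike_level)
    segmentation = eig.segment_states(vectors, led.similarity)
    table = topo.topology_table(networks)
    averages = topo.time_average(table)

    eio.write_binary_networks(outdir / "networks.tsv", networks)
    eio.write_eigenvectors(outdir / "eigenvectors.tsv", vectors)
    eio.write_inner_products(outdir / "inner_products.tsv", inner)
    eio.write_segmentation(outdir / "states.tsv", segmentation)
    eio.write_topology(outdir / "topology.tsv", table, averages)

    manifest = {
        "package": "eigenlock",
        "version": __version__,
        "python": platform.python_version(),
        "input": source,
        "fs": fs,
        "band": list(band) if band else None,
        "window_ms": float(config["window_ms"]),
        "step_ms": float(config["step_ms"]),
        "threshold": float(config["threshold"]),
        "distance": plc.distance,
        "spike_level": led.spike_level,
        "event_levels": [led.lo, led.hi],
        "seed": seed,
        "n_channels": int(networks.n_channels),
        "n_windows": int(networks.n_windows),
        "n_spikes": len(spikes),
        "event0_frequency": events.freq_event0,
        "event1_frequency": events.freq_event1,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "networks": networks,
        "eigenvectors": vectors,
        "inner_products": inner,
        "events": events,
        "spikes": spikes,
        "segmentation": segmentation,
        "topology": table,
        "topology_average": averages,
        "manifest": manifest,
    }
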