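"""Delimited-text readers and writers for every pipeline artifact.

All interchange formats are plain text.  Signals travel as tab-separated
tables with a header row of channel labels and one row per sample;
network series as long-form edge lists; eigenvector and inner-product
series as per-window tables.  EDF recordings are read through mne when
the optional dependency is installed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import BinaryNetworkSeries, DistanceMatrixSeries, WindowSpec
from .eigendynamics import EigenvectorSeries, InnerProductSeries, StateSegmentation
from .scenarios import PhaseTrajectories, ScenarioScript
from .topology import EdgeProbabilityNetwork, TopologyRecord

__all__ = [
    "read_signals_text",
    "write_signals_text",
    "read_signals_edf",
    "read_scenario_yaml",
    "write_scenario_yaml",
    "write_trajectories",
    "write_distances",
    "write_binary_networks",
    "read_binary_networks",
    "write_eigenvectors",
    "write_inner_products",
    "write_recurrence",
    "write_segmentation",
    "write_topology",
    "write_edge_probabilities",
]


def read_signals_text(path: str | Path, sep: str = "\t") -> tuple[np.ndarray, list[str]]:
    """Read a (channels, samples) array from a delimited table.

    The file has a header row of channel labels and one row per sample
    (samples run down the file); the array is returned channels-first.
    """
    df = pd.read_csv(path, sep=sep)
    return df.to_numpy(dtype=float).T, [str(c) for c in df.columns]


def write_signals_text(path: str | Path, x: np.ndarray,
                       channel_names: list[str] | None = None,
                       sep: str = "\t") -> None:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    names = channel_names or [f"ch{m:02d}" for m in range(x.shape[0])]
    pd.DataFrame(x.T, columns=names).to_csv(path, sep=sep, index=False)


def read_signals_edf(path: str | Path) -> tuple[np.ndarray, list[str], float]:
    """Read an EDF recording; returns (channels, samples), labels, fs."""
    try:
        from mne.io import read_raw_edf
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF input requires mne; install the 'edf' extra"
        ) from exc
    raw = read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data(), list(raw.ch_names), float(raw.info["sfreq"])


def read_scenario_yaml(path: str | Path) -> ScenarioScript:
    with open(path) as fh:
        return ScenarioScript.from_dict(yaml.safe_load(fh))


def write_scenario_yaml(path: str | Path, script: ScenarioScript) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(script.to_dict(), fh, sort_keys=False)


def write_trajectories(outdir: str | Path, traj: PhaseTrajectories,
                       stem: str = "trajectories") -> None:
    """Write phases and speeds: one row per step, one column per oscillator."""
    outdir = Path(outdir)
    names = [f"osc{m:02d}" for m in range(traj.n_oscillators)]
    pd.DataFrame(traj.phases, columns=names).to_csv(
        outdir / f"{stem}_phases.tsv", sep="\t", index=False)
    pd.DataFrame(traj.speeds, columns=names).to_csv(
        outdir / f"{stem}_speeds.tsv", sep="\t", index=False)


def _pair_frame(series, values_name: str, values) -> pd.DataFrame:
    n = series.distances.shape[1] if hasattr(series, "distances") else series.adjacency.shape[1]
    iu = np.triu_indices(n, k=1)
    rows = []
    for k in range(values.shape[0]):
        block = values[k][iu]
        keep = np.flatnonzero(block) if values.dtype == bool else np.arange(block.size)
        for idx in keep:
            rows.append((k, int(series.window_starts[k]),
                         series.channel_names[iu[0][idx]],
                         series.channel_names[iu[1][idx]],
                         block[idx]))
    return pd.DataFrame(rows, columns=[
        "window", "window_start", "channel_i", "channel_j", values_name])


def write_distances(path: str | Path, series: DistanceMatrixSeries) -> None:
    """Long-form distance table: window, start, channel pair, distance."""
    df = _pair_frame(series, "distance", series.distances)
    df.to_csv(path, sep="\t", index=False)


def write_binary_networks(path: str | Path, series: BinaryNetworkSeries) -> None:
    """Long-form edge list of present edges only, with a threshold header."""
    df = _pair_frame(series, "edge", series.adjacency).drop(columns="edge")
    with open(path, "w") as fh:
        fh.write(f"# threshold={series.threshold!r} width={series.window.width} "
                 f"step={series.window.step} fs={series.window.fs} "
                 f"n_windows={series.n_windows} "
                 f"channels={','.join(series.channel_names)} "
                 f"starts={','.join(str(int(s)) for s in series.window_starts)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_binary_networks(path: str | Path) -> BinaryNetworkSeries:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# "):
            raise ValueError("missing metadata header line")
        meta = dict(item.split("=", 1) for item in header[2:].split())
        df = pd.read_csv(fh, sep="\t")
    names = meta["channels"].split(",")
    starts = np.array([int(s) for s in meta["starts"].split(",")])
    window = WindowSpec(width=int(meta["width"]), step=int(meta["step"]),
                        fs=float(meta["fs"]))
    n, n_windows = len(names), int(meta["n_windows"])
    adj = np.zeros((n_windows, n, n), dtype=bool)
    index = {c: i for i, c in enumerate(names)}
    for w, ci, cj in zip(df["window"], df["channel_i"], df["channel_j"]):
        i, j = index[str(ci)], index[str(cj)]
        adj[int(w), i, j] = adj[int(w), j, i] = True
    return BinaryNetworkSeries(adjacency=adj, threshold=float(meta["threshold"]),
                               window_starts=starts, window=window,
                               channel_names=names)


def write_eigenvectors(path: str | Path, series: EigenvectorSeries) -> None:
    names = series.channel_names or [f"ch{m:02d}" for m in range(series.vectors.shape[1])]
    df = pd.DataFrame(series.vectors, columns=names)
    df.insert(0, "window", np.arange(series.n_windows))
    df.insert(1, "window_start", series.window_starts.astype(int))
    df.insert(2, "eigenvalue", series.eigenvalues)
    df.insert(3, "valid", series.valid.astype(int))
    df.to_csv(path, sep="\t", index=False)


def write_inner_products(path: str | Path, series: InnerProductSeries) -> None:
    pd.DataFrame({
        "pair": np.arange(series.n_pairs),
        "window_start": series.window_starts.astype(int),
        "inner_product": series.values,
        "valid": series.valid.astype(int),
    }).to_csv(path, sep="\t", index=False)


def write_recurrence(path: str | Path, matrix: np.ndarray) -> None:
    pd.DataFrame(matrix).to_csv(path, sep="\t", index=False, header=False,
                                float_format="%.6f")


def write_segmentation(path: str | Path, seg: StateSegmentation) -> None:
    secs = seg.durations_seconds()
    pd.DataFrame({
        "state": np.arange(len(seg.segments)),
        "start_window": [s.start for s in seg.segments],
        "end_window": [s.end for s in seg.segments],
        "n_windows": seg.durations(),
        "duration_s": secs if secs is not None else np.nan,
    }).to_csv(path, sep="\t", index=False)


def write_topology(path: str | Path, table: pd.DataFrame,
                   averages: TopologyRecord | None = None) -> None:
    """Per-window metric table plus one trailing time-average summary row."""
    out = table.copy()
    if averages is not None:
        out = pd.concat([out, pd.DataFrame([{
            "window": -1, "window_start": -1,
            "density": averages.density,
            "mean_efficiency": averages.mean_efficiency,
            "global_clustering": averages.global_clustering,
        }])], ignore_index=True)
    out.to_csv(path, sep="\t", index=False)


def write_edge_probabilities(path: str | Path, net: EdgeProbabilityNetwork) -> None:
    net.to_edge_list().to_csv(path, sep="\t", index=False)
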