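"""Readers and writers for the pipeline's artifacts.

Spike tables and trained models go to HDF5; pulse programs, configs and
reports to JSON; pulse matrices and metric tables to CSV; connectivity
graphs to GraphML. Every writer embeds a format version and the hash of
the configuration that produced the artifact, and readers fail loudly
on version mismatches or truncated files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import networkx as nx
import numpy as np

from .decoding import PcaBasis, TrainedDecoder
from .encoding import PulseMatrix, PulseProgram
from .imaging import ExtractorConfig, ExtractorParams
from .simulator import SpikeEventTable

FORMAT_VERSION = "1"

__all__ = [
    "config_hash",
    "write_spike_table", "read_spike_table", "spike_table_to_csv",
    "write_pulse_program", "read_pulse_program",
    "write_pulse_matrix", "read_pulse_matrix",
    "write_extractor", "read_extractor",
    "write_decoder", "read_decoder",
    "write_graphml",
]


def config_hash(cfg) -> str:
    """Stable short hash of a (dataclass or dict) configuration."""
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        cfg = dataclasses.asdict(cfg)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    blob = json.dumps(cfg, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _check_version(found) -> None:
    if str(found) != FORMAT_VERSION:
        raise ValueError(
            f"unsupported format version {found!r} (expected {FORMAT_VERSION})"
        )


# -- spike tables (HDF5) ----------------------------------------------------

def write_spike_table(st: SpikeEventTable, path, cfg_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("channel", data=st.channels)
        f.create_dataset("time", data=st.times)
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["config_hash"] = cfg_hash
        f.attrs["n_channels"] = st.n_channels
        f.attrs["duration"] = st.duration
        f.attrs["metadata_json"] = json.dumps(st.metadata, default=str)


def read_spike_table(path) -> SpikeEventTable:
    with h5py.File(path, "r") as f:
        _check_version(f.attrs.get("format_version"))
        return SpikeEventTable(
            channels=f["channel"][:], times=f["time"][:],
            n_channels=int(f.attrs["n_channels"]),
            duration=float(f.attrs["duration"]),
            metadata=json.loads(f.attrs.get("metadata_json", "{}")),
        )


def spike_table_to_csv(st: SpikeEventTable, path) -> None:
    arr = np.column_stack([st.channels, st.times])
    np.savetxt(path, arr, fmt=["%d", "%.9f"], delimiter=",",
               header="channel,time_s", comments="")


# -- pulse programs / matrices ----------------------------------------------

def write_pulse_program(pp: PulseProgram, path, cfg_hash: str = "") -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "config_hash": cfg_hash,
        "slot_period": pp.slot_period,
        "window": pp.window,
        "pulse_amplitude_mv": pp.pulse_amplitude_mv,
        "phase_duration_us": pp.phase_duration_us,
        "provenance": {k: str(v) for k, v in pp.provenance.items()},
        "channels": [list(map(float, t)) for t in pp.channels],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_pulse_program(path) -> PulseProgram:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"malformed pulse program file {path}: {e}") from e
    _check_version(doc.get("format_version"))
    return PulseProgram(
        channels=[np.asarray(t, float) for t in doc["channels"]],
        slot_period=doc["slot_period"], window=doc["window"],
        pulse_amplitude_mv=doc["pulse_amplitude_mv"],
        phase_duration_us=doc["phase_duration_us"],
        provenance=doc.get("provenance", {}),
    )


def write_pulse_matrix(pm: PulseMatrix, path, cfg_hash: str = "") -> None:
    header = f"format_version={FORMAT_VERSION};config_hash={cfg_hash};slot_period={pm.slot_period}"
    np.savetxt(path, pm.bits, fmt="%d", delimiter=",", header=header)


def read_pulse_matrix(path) -> PulseMatrix:
    lines = Path(path).read_text().strip().splitlines()
    if not lines or "format_version=" not in lines[0]:
        raise ValueError(f"malformed pulse matrix file {path}")
    meta = dict(kv.split("=") for kv in lines[0].lstrip("# ").split(";"))
    _check_version(meta.get("format_version"))
    bits = np.loadtxt(lines[1:], delimiter=",", dtype=int, ndmin=2)
    return PulseMatrix(bits=bits, slot_period=float(meta["slot_period"]))


# -- models (HDF5) ----------------------------------------------------------

def write_extractor(params: ExtractorParams, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["config_json"] = json.dumps(dataclasses.asdict(params.config))
        f.attrs["config_hash"] = config_hash(params.config)
        f.attrs["val_loss"] = params.val_loss
        f.attrs["val_accuracy"] = params.val_accuracy
        f.attrs["epochs_run"] = params.epochs_run
        for i, (w, b) in enumerate(zip(params.weights, params.biases)):
            f.create_dataset(f"conv{i}/w", data=w)
            f.create_dataset(f"conv{i}/b", data=b)
        f.create_dataset("head/w", data=params.head_w)
        f.create_dataset("head/b", data=params.head_b)


def read_extractor(path) -> ExtractorParams:
    with h5py.File(path, "r") as f:
        _check_version(f.attrs.get("format_version"))
        cfg_dict = json.loads(f.attrs["config_json"])
        cfg_dict["filters_per_layer"] = tuple(cfg_dict["filters_per_layer"])
        cfg = ExtractorConfig(**cfg_dict)
        weights = [f[f"conv{i}/w"][:] for i in range(3)]
        biases = [f[f"conv{i}/b"][:] for i in range(3)]
        return ExtractorParams(
            weights=weights, biases=biases,
            head_w=f["head/w"][:], head_b=f["head/b"][:], config=cfg,
            val_loss=float(f.attrs["val_loss"]),
            val_accuracy=float(f.attrs["val_accuracy"]),
            epochs_run=int(f.attrs["epochs_run"]),
        )


def write_decoder(dec: TrainedDecoder, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["converged"] = dec.converged
        f.create_dataset("coef", data=dec.coef)
        f.create_dataset("classes", data=dec.classes)
        f.create_dataset("loss_trace", data=np.asarray(dec.loss_trace))
        f.create_dataset("pca/mean", data=dec.pca.mean)
        f.create_dataset("pca/components", data=dec.pca.components)
        f.create_dataset("pca/evr", data=dec.pca.explained_variance_ratio)
        f.attrs["pca_bypass"] = dec.pca.bypass


def read_decoder(path) -> TrainedDecoder:
    with h5py.File(path, "r") as f:
        _check_version(f.attrs.get("format_version"))
        pca = PcaBasis(
            mean=f["pca/mean"][:], components=f["pca/components"][:],
            explained_variance_ratio=f["pca/evr"][:],
            bypass=bool(f.attrs["pca_bypass"]),
        )
        return TrainedDecoder(
            pca=pca, coef=f["coef"][:], classes=f["classes"][:],
            loss_trace=list(f["loss_trace"][:]),
            converged=bool(f.attrs["converged"]),
        )


# -- graphs -----------------------------------------------------------------

def write_graphml(cg, path) -> None:
    g = cg.graph.copy()
    if cg.partition:
        nx.set_node_attributes(g, {int(k): int(v) for k, v in cg.partition.items()}, "module")
    g.graph["format_version"] = FORMAT_VERSION
    nx.write_graphml(g, path)


def write_edge_list_csv(cg, path) -> None:
    rows = [
        (u, v, d["weight"]) for u, v, d in cg.graph.edges(data=True)
    ]
    arr = np.array(rows, dtype=float).reshape(-1, 3)
    np.savetxt(path, arr, fmt=["%d", "%d", "%.9f"], delimiter=",",
               header="i,j,sttc", comments="")
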