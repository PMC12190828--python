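"""End-to-end orchestration: images -> pulses -> activity -> decoding -> graphs.

A single :class:`RunConfig` carries the configuration of every stage and
one global seed, fanned out to each stochastic component through stable
tags so the whole run is reproducible from one integer.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import connectivity as conn
from .decoding import DecodingConfig, evaluate_protocol
from .encoding import EncodingConfig, encode, to_binary_matrix
from .imaging import (
    ExtractorConfig,
    extract_features,
    generate_synthetic_images,
    train_feature_extractor,
)
from .io import config_hash
from .simulator import (
    SimulatorConfig,
    inject_correlated_pairs,
    make_gain,
    simulate_session,
    simulate_spontaneous,
)

log = logging.getLogger("bnnvision")

__all__ = ["RunConfig", "ConnectivityConfig", "child_seed", "run_pipeline"]


def child_seed(global_seed: int, tag: str) -> int:
    """Derive a component seed from the global seed and a stable tag."""
    return (int(global_seed) * 1000003 + zlib.crc32(tag.encode())) % (2**31)


@dataclass(frozen=True)
class ConnectivityConfig:
    dt: float = 0.010
    k_representative: int = 40
    n_surrogates: int = 50
    alpha: float = 0.05
    jitter: float = 0.050
    consensus_runs: int = 50
    recording_duration: float = 120.0
    n_correlated_pairs: int = 12
    shared_rate: float = 1.0


@dataclass
class RunConfig:
    """Nested configuration of the full pipeline."""

    seed: int = 0
    n_per_class: int = 20
    image_side: int = 40
    n_channels: int = 64
    blank: bool = False
    extractor: ExtractorConfig = field(default_factory=ExtractorConfig)
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        if doc["simulator"]["gain"] is not None:
            doc["simulator"]["gain"] = np.asarray(doc["simulator"]["gain"]).tolist()
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        ex = doc.pop("extractor", {})
        ex["filters_per_layer"] = tuple(ex.get("filters_per_layer", (12, 14, 8)))
        sim = doc.pop("simulator", {})
        if sim.get("gain") is not None:
            sim["gain"] = np.asarray(sim["gain"], dtype=float)
        return cls(
            extractor=ExtractorConfig(**ex),
            encoding=EncodingConfig(**doc.pop("encoding", {})),
            simulator=SimulatorConfig(**sim),
            decoding=DecodingConfig(**doc.pop("decoding", {})),
            connectivity=ConnectivityConfig(**doc.pop("connectivity", {})),
            **doc,
        )


def _grid_positions(n_channels: int) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n_channels)))
    yy, xx = np.divmod(np.arange(n_channels), side)
    return np.column_stack([xx, yy]).astype(float)


def run_pipeline(cfg: RunConfig, outdir=None) -> dict:
    """Run the full encode -> stimulate -> record -> decode -> connectivity loop.

    Returns (and optionally writes) a JSON-serializable report with
    per-stage decoding accuracy and confusion matrices, network-metric
    summaries before/after training, and full seed/config provenance.
    """
    chash = config_hash(cfg)
    report: dict = {"config_hash": chash, "seed": cfg.seed, "stages": {}}

    log.info("generating synthetic images")
    images = generate_synthetic_images(
        cfg.n_per_class, side=cfg.image_side, seed=child_seed(cfg.seed, "images")
    )
    rng = np.random.default_rng(child_seed(cfg.seed, "split"))
    by_class = {}
    for im in images:
        by_class.setdefault(im.label, []).append(im)
    train, val, encode_set = [], [], []
    for label, group in sorted(by_class.items()):
        order = rng.permutation(len(group))
        n_val = max(1, len(group) // 10)
        val += [group[i] for i in order[:n_val]]
        train += [group[i] for i in order[n_val:]]
        encode_set += [group[i] for i in order[:3]]  # 3 per class -> 9 stimuli

    log.info("training feature extractor")
    ex_cfg = dataclasses.replace(cfg.extractor, seed=child_seed(cfg.seed, "extractor"))
    params = train_feature_extractor(train, val, ex_cfg)
    report["extractor"] = {
        "val_loss": params.val_loss, "val_accuracy": params.val_accuracy,
        "epochs_run": params.epochs_run,
    }

    log.info("encoding 9 images into pulse programs")
    programs = [
        encode(extract_features(im, params), cfg.encoding) for im in encode_set
    ]
    report["programs"] = {
        "n_pulses": [pp.n_pulses for pp in programs],
        "binary_shapes": [list(to_binary_matrix(pp).shape) for pp in programs],
    }

    log.info("simulating stimulation session")
    sim_cfg = cfg.simulator
    if sim_cfg.gain is None or sim_cfg.n_channels != cfg.n_channels:
        sim_cfg = dataclasses.replace(
            sim_cfg, n_channels=cfg.n_channels,
            gain=make_gain(cfg.n_channels, len(programs[0].channels),
                           seed=child_seed(cfg.seed, "gain")),
        )
    session = simulate_session(
        programs, sim_cfg, seed=child_seed(cfg.seed, "session"), blank=cfg.blank
    )

    log.info("staged decoding")
    results = evaluate_protocol(session, cfg.decoding)
    for r in results:
        report["stages"][str(r.stage)] = {
            "accuracy": r.accuracy,
            "n_test": r.n_test,
            "confusion": r.confusion.tolist(),
        }

    log.info("connectivity before/after")
    ccfg = cfg.connectivity
    positions = _grid_positions(cfg.n_channels)
    k = min(ccfg.k_representative, cfg.n_channels)
    rep = conn.select_representative_channels(
        positions, k=k, seed=child_seed(cfg.seed, "kmeans")
    )
    spont_cfg = dataclasses.replace(sim_cfg, gain=None)
    before = simulate_spontaneous(
        ccfg.recording_duration, spont_cfg, child_seed(cfg.seed, "spont-before")
    )
    after = simulate_spontaneous(
        ccfg.recording_duration, spont_cfg, child_seed(cfg.seed, "spont-after")
    )
    prng = np.random.default_rng(child_seed(cfg.seed, "pairs"))
    pairs = [tuple(prng.choice(rep, 2, replace=False)) for _ in range(ccfg.n_correlated_pairs)]
    after = inject_correlated_pairs(
        after, pairs, ccfg.shared_rate, seed=child_seed(cfg.seed, "inject")
    )
    summaries = {}
    metrics = {}
    for tag, rec in (("before", before), ("after", after)):
        trains = [conn.SpikeTrain(rec.train(c), rec.duration) for c in rep]
        graph = conn.build_graph(
            trains, channel_ids=rep, positions=positions[rep],
            dt=ccfg.dt, n_surrogates=ccfg.n_surrogates, alpha=ccfg.alpha,
            jitter=ccfg.jitter, seed=child_seed(cfg.seed, f"graph-{tag}"),
        )
        part = conn.consensus_modules(
            graph, n_runs=ccfg.consensus_runs, seed=child_seed(cfg.seed, f"modules-{tag}")
        )
        nm = conn.node_metrics(graph, part)
        metrics[tag] = (nm, [d["weight"] for _, _, d in graph.graph.edges(data=True)])
        summaries[tag] = {
            "n_edges": graph.graph.number_of_edges(),
            "n_modules": len(set(part.values())),
            "mean_degree": float(nm["degree"].mean()),
            "mean_strength": float(nm["strength"].mean()),
            "mean_participation": float(nm["participation"].mean()),
        }
    comparison = conn.compare_conditions(
        metrics["before"][0], metrics["after"][0],
        metrics["before"][1], metrics["after"][1],
    )
    report["connectivity"] = {
        "summaries": summaries,
        "tests": {
            m: {"t": row["t"], "p": row["p"]}
            for m, row in comparison.iterrows()
        },
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        cfg.to_yaml(outdir / "config.yaml")
    return report
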