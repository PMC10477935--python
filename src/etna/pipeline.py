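"""Run configuration and end-to-end pipelines.

A :class:`RunConfig` captures everything a run needs — input paths, loss
weights per species, architecture, NetMF parameters, block count, optimizer
settings, ablation flags and the master seed — and is serialized to YAML in
the run directory together with a content hash, so runs are reproducible and
re-runs with identical config and inputs are detected.

This package is used from Python; :func:`run_pipeline` and
:func:`simulate_to_dir` are the entry points the examples drive.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .align import FitConfig, JointEmbedding, LossWeights, fit_joint, score_matrix
from .graph_io import (
    Network,
    preprocess_network,
    read_anchor_pairs,
    read_edge_list,
    write_anchor_pairs,
    write_edge_list,
    write_gaf,
)
from .seeds import derive_seed
from .synthetic import (
    TWIN_PRESETS,
    generate_module_annotations,
    generate_network_pair,
    generate_sl_pairs,
)

__all__ = ["RunConfig", "run_pipeline", "simulate_to_dir", "load_config"]


@dataclass
class RunConfig:
    """Fully serializable description of one alignment run."""

    net_a: str = ""
    net_b: str = ""
    anchors: str = ""
    seed: int = 0
    blocks: int = 10
    weights_a: LossWeights = field(default_factory=LossWeights)
    weights_b: LossWeights = field(default_factory=LossWeights)
    fit: FitConfig = field(default_factory=FitConfig)

    def to_dict(self) -> dict:
        return {
            "net_a": self.net_a,
            "net_b": self.net_b,
            "anchors": self.anchors,
            "seed": self.seed,
            "blocks": self.blocks,
            "weights_a": asdict(self.weights_a),
            "weights_b": asdict(self.weights_b),
            "fit": asdict(self.fit),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("weights_a", LossWeights), ("weights_b", LossWeights),
                         ("fit", FitConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def _inputs_hash(cfg: RunConfig) -> str:
    h = hashlib.sha256()
    for p in (cfg.net_a, cfg.net_b, cfg.anchors):
        with open(p, "rb") as fh:
            h.update(fh.read())
        h.update(b"\x00")
    return h.hexdigest()[:16]


def run_pipeline(cfg: RunConfig, out_dir: str, force: bool = False) -> JointEmbedding:
    """Read -> preprocess -> NetMF -> joint fit -> score, into ``out_dir``.

    Writes the config, a run manifest (config + input hashes, per-block
    losses), preprocessing reports, the score matrix and parameter
    checkpoints. If a completed run with the same config and inputs already
    exists, it is detected via the manifest hashes and the fit is re-executed
    only with ``force=True``.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.json")
    chash, ihash = cfg.config_hash(), _inputs_hash(cfg)
    if not force and os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        if (manifest.get("config_hash") == chash
                and manifest.get("inputs_hash") == ihash
                and manifest.get("complete")):
            raise FileExistsError(
                f"{out_dir}: identical completed run found (pass force=True to redo)"
            )

    netA_raw = read_edge_list(cfg.net_a)
    netB_raw = read_edge_list(cfg.net_b)
    netA, repA = preprocess_network(netA_raw, seed=derive_seed(cfg.seed, "prep-a"))
    netB, repB = preprocess_network(netB_raw, seed=derive_seed(cfg.seed, "prep-b"))
    repA.to_tsv(os.path.join(out_dir, "preprocess_a.tsv"))
    repB.to_tsv(os.path.join(out_dir, "preprocess_b.tsv"))
    anchors = read_anchor_pairs(cfg.anchors, netA, netB)

    joint = fit_joint(
        netA, netB, anchors,
        weights=(cfg.weights_a, cfg.weights_b),
        blocks=cfg.blocks, config=cfg.fit, seed=cfg.seed,
    )
    S = score_matrix(joint)
    S.to_tsv(os.path.join(out_dir, "scores.tsv"))
    np.savez_compressed(
        os.path.join(out_dir, "checkpoint.npz"),
        config_hash=np.array([chash]),
        **{f"A_{k}": v for k, v in joint.params_A.tensors.items()},
        **{f"B_{k}": v for k, v in joint.params_B.tensors.items()},
    )
    save_config(cfg, os.path.join(out_dir, "config.yaml"))
    with open(manifest_path, "w") as fh:
        json.dump(
            {
                "config_hash": chash,
                "inputs_hash": ihash,
                "complete": True,
                "n_a": netA.n,
                "n_b": netB.n,
                "n_anchors": len(anchors),
                "log": joint.log,
            },
            fh,
            indent=1,
        )
    return joint


def simulate_to_dir(out_dir: str, preset: str = "twin", seed: int = 0,
                    **overrides) -> dict[str, str]:
    """Write a full synthetic twin-pair dataset as plain-text files.

    Produces edge lists, anchors, GAF annotations for both species, the
    ontology relation table, SL pair labels and a truth table; returns the
    path map. Presets: twin, twin-noisy, twin-small.
    """
    os.makedirs(out_dir, exist_ok=True)
    params = dict(TWIN_PRESETS[preset])
    params.update(overrides)
    netA, netB, truth = generate_network_pair(seed=seed, **params)
    annA, annB, ontology = generate_module_annotations(
        truth, seed=derive_seed(seed, "annotations")
    )
    sl = generate_sl_pairs(truth, seed=derive_seed(seed, "sl"))

    paths = {k: os.path.join(out_dir, v) for k, v in {
        "net_a": "net_a.tsv", "net_b": "net_b.tsv", "anchors": "anchors.tsv",
        "gaf_a": "ann_a.gaf", "gaf_b": "ann_b.gaf",
        "ontology": "ontology.tsv", "sl": "sl_pairs.tsv", "truth": "truth.tsv",
    }.items()}
    write_edge_list(netA, paths["net_a"])
    write_edge_list(netB, paths["net_b"])
    with open(paths["anchors"], "w") as fh:
        for a, b in truth.anchors:
            fh.write(f"{a}\t{b}\n")
    write_gaf(annA, paths["gaf_a"])
    write_gaf(annB, paths["gaf_b"])
    with open(paths["ontology"], "w") as fh:
        for c, p, r in ontology:
            fh.write(f"{c}\t{p}\t{r}\n")
    with open(paths["sl"], "w") as fh:
        for species, (pos, neg) in sorted(sl.items()):
            for a, b in pos:
                fh.write(f"{species}\t{a}\t{b}\t1\n")
            for a, b in neg:
                fh.write(f"{species}\t{a}\t{b}\t0\n")
    with open(paths["truth"], "w") as fh:
        fh.write("# gene_a\tgene_b\tmodule\tis_anchor\n")
        anchored = set(truth.anchors)
        for a, b in sorted(truth.true_map.items()):
            fh.write(
                f"{a}\t{b}\t{truth.module_of[a]}\t{int((a, b) in anchored)}\n"
            )
    return paths
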