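"""End-to-end pipeline driver: config in, artifacts and report out.

A single structured config (YAML/JSON, or an equivalent dict) declares
either a synthetic scenario or input files, the split specification, the
mapping family and training protocol, and the evaluation settings.  The
run executes split → embed (with automatic dimension selection unless
fixed) → fit mappings → predict probability blocks → evaluate, writing
the embedding, fitted models, per-block predictions, the evaluation
report and a manifest recording the resolved config and all seeds.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import yaml

from . import __version__
from .graph import NodeMetadataTable, read_adjacency, read_edge_list
from .mapping import TrainingConfig
from .model import RdpgLinkPredictor
from .split import BLOCKS, SplitSpec
from .synthetic import SyntheticScenario, make_benchmark

__all__ = ["run_pipeline", "load_config"]

log = logging.getLogger("rdpglink")


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _build_model(config: dict, seed: int | None) -> RdpgLinkPredictor:
    if "scenario" in config:
        sc = dict(config["scenario"])
        if seed is not None:
            sc["seed"] = seed
        truth = make_benchmark(SyntheticScenario(**sc))
        graph, row_md, col_md = truth.graph, truth.row_metadata, truth.col_metadata
        _build_model.last_truth = truth
    else:
        inputs = config["inputs"]
        if "edge_list" in inputs:
            graph = read_edge_list(
                inputs["edge_list"], header=inputs.get("header", False)
            )
        else:
            graph = read_adjacency(inputs["adjacency"])
        row_md = NodeMetadataTable.from_csv(
            inputs["row_metadata"], inputs["row_schema"]
        )
        col_md = NodeMetadataTable.from_csv(
            inputs["col_metadata"], inputs["col_schema"]
        )
    split_kw = dict(config.get("split", {}))
    if seed is not None:
        split_kw.setdefault("seed", seed)
    training = None
    if config.get("training"):
        tkw = dict(config["training"])
        if seed is not None:
            tkw.setdefault("seed", seed)
        training = TrainingConfig(**tkw)
    return RdpgLinkPredictor(
        graph,
        row_md,
        col_md,
        split_spec=SplitSpec(**split_kw),
        d=config.get("d"),
        family=config.get("family", "linear"),
        training_config=training,
    )


def run_pipeline(config: dict | str, seed: int | None = None, out_dir=None):
    """Run the whole procedure; returns ``(report, results)``.

    ``config`` may be a dict or a path to a YAML file.  ``seed`` overrides
    every stage seed not pinned explicitly in the config.  With
    ``out_dir``, artifacts (embedding, models, predictions, report,
    manifest) are written there; any stage failure leaves the artifacts
    produced so far plus a manifest marking the run incomplete.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
    manifest = {
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "complete": False,
        "stages": [],
    }
    stage = "setup"
    try:
        t0 = time.perf_counter()
        model = _build_model(config, seed)
        manifest["stages"].append({"stage": stage, "seconds": time.perf_counter() - t0})

        stage = "fit (split + embed + mappings)"
        t0 = time.perf_counter()
        results = model.fit()
        log.info("fitted: d=%d, %s", results.d, "selected" if results.d_was_selected else "fixed")
        manifest["stages"].append({"stage": stage, "seconds": time.perf_counter() - t0})

        stage = "evaluate"
        t0 = time.perf_counter()
        ev = dict(config.get("evaluation", {}))
        if seed is not None:
            ev.setdefault("seed", seed)
        report = results.evaluate(**ev)
        manifest["stages"].append({"stage": stage, "seconds": time.perf_counter() - t0})

        if out is not None:
            stage = "artifacts"
            results.embedding.save(out / "embedding")
            results.row_mapping.save(out / "row_mapping.json")
            results.col_mapping.save(out / "col_mapping.json")
            block_metrics = {}
            for block in BLOCKS:
                sc = results.score_block(block)
                probs = results.block_probabilities(block)
                probs.write_tsv(out / f"predictions_{block}.tsv", top_k=20)
                block_metrics[block] = {
                    "pairs_scored": len(sc),
                    "links_held_out": int(sc.labels.sum()),
                    "auc": results.block_auc(block)
                    if sc.labels.min() != sc.labels.max() else None,
                }
            (out / "block_metrics.json").write_text(json.dumps(block_metrics, indent=1))
            report.to_json(out / "report.json")
            (out / "summary.txt").write_text(results.summary() + "\n")
            manifest["complete"] = True
        return report, results
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        manifest["error"] = f"{stage}: {exc}"
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc
    finally:
        if out is not None:
            if manifest.get("error") is None and "stages" in manifest:
                manifest["complete"] = True
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
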