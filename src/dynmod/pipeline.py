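"""End-to-end orchestration: simulate/load, select, network, modules, events,
strength — with a run manifest for reproducibility.

The per-stage sample grouping is declarative: a :class:`StageDesign` lists
ordered (label, metadata-predicate) pairs, covering both the time-based
layout (one stage per timestamp, optionally restricted to a disease state)
and strategy-based layouts where stages are response-path groups.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .datasets import ExpressionDataset
from .events import classify_events, sweep_alpha, tally_events, write_events_jsonl, write_tallies_tsv
from .modules import ModuleCatalog, catalog_stages, deduplicate_catalog, write_gmt
from .network import build_network
from .selection import rank_genes, select_top_genes, write_gene_list, write_ranking_tsv
from .strength import StrengthConfig, build_trajectories, write_trajectories_tsv
from .synthetic import script_standard_scenario, simulate_dataset
from .topology import topology_trajectory, write_topology_json, write_topology_tsv

log = logging.getLogger("dynmod")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": True,
    "scenario": {},  # overrides for script_standard_scenario()
    "input": {},     # expression/metadata paths when simulate is false
    "selection": {"top_genes": 2000},
    "network": {"edge_fraction": 0.10, "signed": False},
    "modules": {"k": 50, "n_restarts": 5, "membership_ratio": 0.8, "max_iter": 200},
    "events": {"alphas": [0.12, 0.16, 0.20]},
    "strength": {
        "smoothing_weight": 0.3,
        "flat_range_cutoff": 0.05,
        "pattern_delta": 0.2,
        "dedup_jaccard": 0.9,
    },
    "stages": None,  # default: time mode over patient samples per timestamp
    "output_dir": "dynmod_run",
}


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class StageDesign:
    """Ordered stages, each selecting samples by metadata equality filters."""

    mode: str  # "time" or "strategy"
    stages: tuple[tuple[str, Mapping[str, str]], ...]

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("a stage design needs at least 2 stages")

    @classmethod
    def time_based(
        cls, timestamp_labels: list[str], group: str = "patient", disease_state: str | None = None
    ) -> "StageDesign":
        stages = []
        for lab in timestamp_labels:
            where = {"timestamp": lab, "group": group}
            if disease_state is not None:
                where["disease_state"] = disease_state
            stages.append((lab, where))
        return cls(mode="time", stages=tuple(stages))

    @classmethod
    def from_config(cls, cfg: Mapping[str, Any]) -> "StageDesign":
        stages = tuple((s["label"], dict(s["where"])) for s in cfg["list"])
        return cls(mode=cfg.get("mode", "time"), stages=stages)


def assemble_stage_datasets(
    dataset: ExpressionDataset, design: StageDesign
) -> list[ExpressionDataset]:
    """One expression subset per stage, in stage order.

    A stage selecting fewer than 3 samples is an error (correlation needs at
    least 3 observations).
    """
    out = []
    for label, where in design.stages:
        sub = dataset.where(**where)
        if sub.n_samples < 3:
            raise ValueError(
                f"stage {label!r} selects {sub.n_samples} sample(s); "
                "at least 3 are required"
            )
        log.info("stage %s: %d samples", label, sub.n_samples)
        out.append(sub)
    return out


# ---------------------------------------------------------------------------
@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    input_hashes: dict[str, str]
    artifacts: dict[str, str]
    stage_stats: dict[str, Any] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "config": self.config,
                    "input_hashes": self.input_hashes,
                    "artifacts": self.artifacts,
                    "stage_stats": self.stage_stats,
                    "timings": self.timings,
                },
                sort_keys=True,
                indent=1,
            )
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ValueError("config file must contain a YAML mapping")
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


# ---------------------------------------------------------------------------
def run_pipeline(
    config: str | Path | Mapping[str, Any] | None = None,
    output_dir: str | Path | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Execute the full analysis and write all artifacts under a run directory.

    ``config`` may be a YAML path or an (already merged) mapping; ``seed`` and
    ``output_dir`` override the config.  Returns the manifest, which is also
    written as ``manifest.json``.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = _merge(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    if output_dir is not None:
        cfg["output_dir"] = str(output_dir)

    run_dir = Path(cfg["output_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest = RunManifest(
        version=__version__, seed=cfg["seed"], config=cfg, input_hashes={}, artifacts={}
    )
    t_start = time.perf_counter()
    try:
        # -- input ---------------------------------------------------------
        t0 = time.perf_counter()
        if cfg["simulate"]:
            scen = dict(cfg["scenario"])
            scen.setdefault("seed", cfg["seed"])
            sim_config = script_standard_scenario(**scen)
            per_ts, truth = simulate_dataset(sim_config)
            combined = ExpressionDataset.combine(per_ts)
            expr_path = run_dir / "expression.tsv"
            meta_path = run_dir / "metadata.tsv"
            combined.to_tsv(expr_path, meta_path)
            truth.to_json(run_dir / "truth.json")
            manifest.artifacts["truth"] = "truth.json"
            labels = list(truth.timestamp_labels)
        else:
            expr_path = Path(cfg["input"]["expression"])
            meta_path = Path(cfg["input"]["metadata"])
            combined = ExpressionDataset.from_tsv(expr_path, meta_path)
            labels = list(dict.fromkeys(combined.metadata["timestamp"]))
        manifest.input_hashes = {
            "expression": _sha256(expr_path),
            "metadata": _sha256(meta_path),
        }
        manifest.artifacts["expression"] = str(expr_path)
        manifest.artifacts["metadata"] = str(meta_path)
        manifest.timings["input"] = time.perf_counter() - t0

        # -- stage design ----------------------------------------------------
        if cfg["stages"] is not None:
            design = StageDesign.from_config(cfg["stages"])
        else:
            design = StageDesign.time_based(labels)
        stage_data = assemble_stage_datasets(combined, design)
        manifest.stage_stats["stages"] = {
            label: ds.n_samples for (label, _), ds in zip(design.stages, stage_data)
        }

        # -- gene selection (baseline patients vs controls) ------------------
        t0 = time.perf_counter()
        baseline_patients = stage_data[0]
        controls = combined.controls()
        if controls.n_samples == 0:
            raise ValueError("no control samples found; gene selection needs controls")
        ranking = rank_genes(baseline_patients, controls)
        top_k = cfg["selection"]["top_genes"]
        genes = select_top_genes(ranking, k=min(top_k, len(ranking)))
        write_ranking_tsv(ranking, run_dir / "ranking.tsv")
        write_gene_list(genes, run_dir / "selected_genes.txt")
        manifest.artifacts["ranking"] = "ranking.tsv"
        manifest.artifacts["selected_genes"] = "selected_genes.txt"
        manifest.stage_stats["genes_selected"] = len(genes)
        manifest.timings["gene_selection"] = time.perf_counter() - t0
        log.info("selected %d genes", len(genes))

        # -- per-stage networks ----------------------------------------------
        t0 = time.perf_counter()
        nets = []
        for i, ds in enumerate(stage_data):
            net = build_network(
                ds,
                genes,
                q=cfg["network"]["edge_fraction"],
                timestamp=i,
                signed=cfg["network"]["signed"],
            )
            net.to_tsv(run_dir / f"network_t{i}.tsv")
            manifest.artifacts[f"network_t{i}"] = f"network_t{i}.tsv"
            nets.append(net)
            log.info(
                "network t%d: %d nodes, %d edges (%d augmented)",
                i, net.n_nodes, net.n_edges, len(net.augmented_edges),
            )
        manifest.stage_stats["edges_per_stage"] = [n.n_edges for n in nets]
        manifest.timings["networks"] = time.perf_counter() - t0

        # -- topology ---------------------------------------------------------
        t0 = time.perf_counter()
        summaries = topology_trajectory(nets)
        write_topology_tsv(summaries, run_dir / "topology.tsv")
        write_topology_json(summaries, run_dir / "topology.json")
        manifest.artifacts["topology"] = "topology.tsv"
        manifest.timings["topology"] = time.perf_counter() - t0

        # -- module detection -------------------------------------------------
        t0 = time.perf_counter()
        mcfg = cfg["modules"]
        catalog = catalog_stages(
            nets,
            k=mcfg["k"],
            seed=cfg["seed"],
            n_restarts=mcfg["n_restarts"],
            membership_ratio=mcfg["membership_ratio"],
            max_iter=mcfg["max_iter"],
        )
        write_gmt(catalog.all_modules(), run_dir / "modules.gmt")
        manifest.artifacts["modules"] = "modules.gmt"
        manifest.stage_stats["modules_per_stage"] = {
            t: len(catalog.modules_at(t)) for t in catalog.timestamps
        }
        manifest.timings["module_detection"] = time.perf_counter() - t0
        log.info("modules per stage: %s", manifest.stage_stats["modules_per_stage"])

        # -- event tracking with alpha sweep ----------------------------------
        t0 = time.perf_counter()
        alphas = tuple(cfg["events"]["alphas"])
        tallies = sweep_alpha(catalog, alphas)
        write_tallies_tsv(tallies, run_dir / "event_tallies.tsv")
        manifest.artifacts["event_tallies"] = "event_tallies.tsv"
        ts = catalog.timestamps
        for alpha in alphas:
            events = []
            for a, b in zip(ts, ts[1:]):
                events.extend(
                    classify_events(
                        catalog.modules_at(a), catalog.modules_at(b), alpha, transition=(a, b)
                    )
                )
            name = f"events_alpha{alpha:g}.jsonl"
            write_events_jsonl(events, run_dir / name)
            manifest.artifacts[f"events_alpha{alpha:g}"] = name
            manifest.stage_stats[f"event_counts_alpha{alpha:g}"] = tally_events(events).counts
        manifest.timings["event_tracking"] = time.perf_counter() - t0

        # -- strength progression ---------------------------------------------
        t0 = time.perf_counter()
        scfg = cfg["strength"]
        candidates = deduplicate_catalog(catalog, jaccard_cutoff=scfg["dedup_jaccard"])
        manifest.stage_stats["candidate_modules"] = len(candidates)
        strength_config = StrengthConfig(
            smoothing_weight=scfg["smoothing_weight"],
            flat_range_cutoff=scfg["flat_range_cutoff"],
            pattern_delta=scfg["pattern_delta"],
        )
        trajectories = build_trajectories(candidates, nets, strength_config)
        write_trajectories_tsv(trajectories, run_dir / "strength.tsv")
        manifest.artifacts["strength"] = "strength.tsv"
        pattern_counts: dict[str, int] = {}
        for t in trajectories:
            pattern_counts[t.pattern or "unclassified"] = (
                pattern_counts.get(t.pattern or "unclassified", 0) + 1
            )
        manifest.stage_stats["pattern_counts"] = pattern_counts
        manifest.timings["strength"] = time.perf_counter() - t0

        manifest.timings["total"] = time.perf_counter() - t_start
        manifest.to_json(run_dir / "manifest.json")
        manifest.artifacts["manifest"] = "manifest.json"
        log.info("run complete in %.1f s", manifest.timings["total"])
        return manifest
    except Exception:
        log.exception("pipeline aborted")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
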