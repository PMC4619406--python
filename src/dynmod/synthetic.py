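"""Synthetic multi-timestamp expression data with planted, evolving modules.

The generator emulates a longitudinal treatment-response cohort: patients are
sampled at each timestamp, healthy controls once (attached to the baseline
timestamp), and sets of genes are planted as co-expressed modules whose
membership changes between timestamps according to a scripted list of
evolutionary events (form, dissolve, continue, split, merge).

Expression model
----------------
For gene ``g`` in sample ``s``::

    x_gs = mu_g(group) + noise_sd * ( sqrt(rho) * f_{m,s} + sqrt(1-rho) * eps_gs )

where ``f_{m,s}`` is a per-module, per-sample standard-normal latent factor
shared by all genes of module ``m`` at that timestamp, and ``eps_gs`` is
i.i.d. standard normal.  Two genes in the same module therefore have
population Pearson correlation exactly ``rho`` — an analytic oracle for the
tests.  Genes in no module are independent noise.  Module genes carry a
patient-vs-control mean shift of ``de_effect_size`` (log units) so that a
two-sample t-test separates them from null genes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datasets import ExpressionDataset

EVENT_TYPES = ("form", "dissolve", "continue", "split", "merge")

#: default admissible planted-module size range
DEFAULT_SIZE_RANGE = (30, 180)


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PlantedModule:
    """A ground-truth module: gene membership per timestamp (empty = absent).

    ``corr_per_timestamp`` optionally overrides the configuration-wide
    within-module correlation at specific timestamps, which allows planting
    trajectories such as a module whose cohesion rises only late.
    """

    module_id: str
    gene_ids_per_timestamp: Mapping[int, frozenset]
    corr_per_timestamp: Mapping[int, float] | None = None

    def genes_at(self, t: int) -> frozenset:
        return frozenset(self.gene_ids_per_timestamp.get(t, frozenset()))

    def corr_at(self, t: int, default: float) -> float:
        if self.corr_per_timestamp is None:
            return default
        return float(self.corr_per_timestamp.get(t, default))


@dataclass(frozen=True)
class PlantedEvent:
    """A scripted evolutionary event at transition i -> i+1."""

    transition: int  # the index i of the transition i -> i+1
    type: str
    source_ids: tuple[str, ...]
    target_ids: tuple[str, ...]

    def validate(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type: {self.type}")
        ns, nt = len(self.source_ids), len(self.target_ids)
        ok = {
            "form": ns == 0 and nt == 1,
            "dissolve": ns == 1 and nt == 0,
            "continue": ns == 1 and nt == 1,
            "split": ns == 1 and nt >= 2,
            "merge": ns >= 2 and nt == 1,
        }[self.type]
        if not ok:
            raise ValueError(
                f"event arity inconsistent for {self.type}: "
                f"{ns} source(s), {nt} target(s)"
            )


@dataclass
class SimulationConfig:
    """Everything needed to generate a multi-timestamp synthetic cohort."""

    n_genes: int = 2500
    n_patient_samples_per_timestamp: int = 30
    n_control_samples: int = 20
    n_timestamps: int = 4
    planted_modules: list[PlantedModule] = field(default_factory=list)
    event_script: list[PlantedEvent] = field(default_factory=list)
    noise_sd: float = 0.2
    within_module_corr: float = 0.8
    de_effect_size: float = 1.0
    seed: int = 0
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE
    overlap_cap: float = 0.2
    timestamp_labels: tuple[str, ...] | None = None

    def labels(self) -> tuple[str, ...]:
        if self.timestamp_labels is not None:
            return self.timestamp_labels
        if self.n_timestamps == 4:
            return ("m0", "m4", "m6", "m12")
        return tuple(f"t{i}" for i in range(self.n_timestamps))

    def validate(self) -> None:
        if self.n_timestamps < 2:
            raise ValueError("n_timestamps must be >= 2")
        if not (0.0 <= self.within_module_corr < 1.0):
            raise ValueError("within_module_corr must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_patient_samples_per_timestamp < 3:
            raise ValueError("need at least 3 patient samples per timestamp")
        if self.n_control_samples < 2:
            raise ValueError("need at least 2 control samples")
        universe = {f"g{i:04d}" for i in range(self.n_genes)}
        lo, hi = self.size_range
        for mod in self.planted_modules:
            sizes = [len(mod.genes_at(t)) for t in range(self.n_timestamps)]
            if all(s == 0 for s in sizes):
                raise ValueError(f"module {mod.module_id} is empty at every timestamp")
            for t, s in enumerate(sizes):
                if s and not (lo <= s <= hi):
                    raise ValueError(
                        f"module {mod.module_id} has {s} genes at timestamp {t}; "
                        f"admissible size range is [{lo}, {hi}]"
                    )
                extra = mod.genes_at(t) - universe
                if extra:
                    raise ValueError(
                        f"gene universe too small: module {mod.module_id} "
                        f"references unknown genes (e.g. {sorted(extra)[:3]})"
                    )
        # overlap cap between distinct modules at any one timestamp
        for t in range(self.n_timestamps):
            present = [(m.module_id, m.genes_at(t)) for m in self.planted_modules if m.genes_at(t)]
            for i in range(len(present)):
                for j in range(i + 1, len(present)):
                    a, b = present[i][1], present[j][1]
                    cap = self.overlap_cap * min(len(a), len(b))
                    if len(a & b) > cap:
                        raise ValueError(
                            f"modules {present[i][0]} and {present[j][0]} overlap by "
                            f"{len(a & b)} genes at timestamp {t}, exceeding the cap "
                            f"of {cap:.1f} ({self.overlap_cap:.0%} of the smaller module)"
                        )
        for ev in self.event_script:
            ev.validate()
            if not (0 <= ev.transition < self.n_timestamps - 1):
                raise ValueError(f"event transition {ev.transition} out of range")


@dataclass
class SimulationTruth:
    """Ground truth record of a simulation run: modules, events, group means."""

    planted_modules: list[PlantedModule]
    planted_events: list[PlantedEvent]
    gene_means: dict[str, tuple[float, float]]  # gene -> (patient mean, control mean)
    timestamp_labels: tuple[str, ...]

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "planted_modules": [
                {
                    "module_id": m.module_id,
                    "gene_ids_per_timestamp": {
                        str(t): sorted(g) for t, g in m.gene_ids_per_timestamp.items()
                    },
                    "corr_per_timestamp": (
                        None
                        if m.corr_per_timestamp is None
                        else {str(t): float(c) for t, c in m.corr_per_timestamp.items()}
                    ),
                }
                for m in self.planted_modules
            ],
            "planted_events": [
                {
                    "transition": e.transition,
                    "type": e.type,
                    "source_ids": list(e.source_ids),
                    "target_ids": list(e.target_ids),
                }
                for e in self.planted_events
            ],
            "gene_means": {g: [float(p), float(c)] for g, (p, c) in self.gene_means.items()},
            "timestamp_labels": list(self.timestamp_labels),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        modules = [
            PlantedModule(
                module_id=m["module_id"],
                gene_ids_per_timestamp={
                    int(t): frozenset(g) for t, g in m["gene_ids_per_timestamp"].items()
                },
                corr_per_timestamp=(
                    None
                    if m.get("corr_per_timestamp") is None
                    else {int(t): float(c) for t, c in m["corr_per_timestamp"].items()}
                ),
            )
            for m in d["planted_modules"]
        ]
        events = [
            PlantedEvent(
                transition=e["transition"],
                type=e["type"],
                source_ids=tuple(e["source_ids"]),
                target_ids=tuple(e["target_ids"]),
            )
            for e in d["planted_events"]
        ]
        means = {g: (float(v[0]), float(v[1])) for g, v in d["gene_means"].items()}
        return cls(modules, events, means, tuple(d["timestamp_labels"]))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
def simulate_dataset(config: SimulationConfig) -> tuple[list[ExpressionDataset], SimulationTruth]:
    """Generate one :class:`ExpressionDataset` per timestamp plus ground truth.

    Healthy-control samples are attached to the first (baseline) timestamp,
    matching a design where controls are profiled once.  Controls share the
    module correlation structure but not the patient mean shift, so the
    patient-vs-control contrast is purely a difference in means.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    genes = [f"g{i:04d}" for i in range(n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    labels = config.labels()

    base_mean = rng.normal(8.0, 1.0, n_genes)  # typical log2 microarray scale
    de_mask = np.zeros(n_genes, dtype=bool)
    for mod in config.planted_modules:
        for t in range(config.n_timestamps):
            for g in mod.genes_at(t):
                de_mask[gene_index[g]] = True
    patient_mean = base_mean + config.de_effect_size * de_mask

    datasets: list[ExpressionDataset] = []
    for t in range(config.n_timestamps):
        sample_ids = [f"p{t}s{j:02d}" for j in range(config.n_patient_samples_per_timestamp)]
        groups = ["patient"] * len(sample_ids)
        if t == 0:
            sample_ids += [f"hc{j:02d}" for j in range(config.n_control_samples)]
            groups += ["control"] * config.n_control_samples
        n_s = len(sample_ids)

        eps = rng.standard_normal((n_genes, n_s))
        factor_sum = np.zeros((n_genes, n_s))
        n_memberships = np.zeros(n_genes)
        rho_sum = np.zeros(n_genes)
        for mod in config.planted_modules:
            members = mod.genes_at(t)
            if not members:
                continue
            rho = mod.corr_at(t, config.within_module_corr)
            f = rng.standard_normal(n_s)
            idx = [gene_index[g] for g in sorted(members)]
            factor_sum[idx] += math.sqrt(rho) * f
            n_memberships[idx] += 1
            rho_sum[idx] += rho
        latent = eps.copy()
        in_mod = n_memberships > 0
        if in_mod.any():
            mean_rho = rho_sum[in_mod] / n_memberships[in_mod]
            latent[in_mod] = (
                factor_sum[in_mod] / np.sqrt(n_memberships[in_mod])[:, None]
                + np.sqrt(1.0 - mean_rho)[:, None] * eps[in_mod]
            )

        mu = np.where(
            np.array([g == "patient" for g in groups])[None, :],
            patient_mean[:, None],
            base_mean[:, None],
        )
        values = pd.DataFrame(
            mu + config.noise_sd * latent, index=genes, columns=sample_ids
        )
        metadata = pd.DataFrame(
            {
                "group": groups,
                "timestamp": labels[t],
                "disease_state": ["AD" if g == "patient" else "HC" for g in groups],
                "response_path": "NA",
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        datasets.append(ExpressionDataset(values, metadata))

    truth = SimulationTruth(
        planted_modules=list(config.planted_modules),
        planted_events=list(config.event_script),
        gene_means={
            g: (float(patient_mean[i]), float(base_mean[i])) for i, g in enumerate(genes)
        },
        timestamp_labels=labels,
    )
    return datasets, truth


# ---------------------------------------------------------------------------
def script_standard_scenario(
    n_genes: int = 2500,
    n_patient_samples_per_timestamp: int = 30,
    n_control_samples: int = 20,
    noise_sd: float = 0.2,
    within_module_corr: float = 0.8,
    de_effect_size: float = 1.0,
    module_size: int = 40,
    seed: int = 20150,
) -> SimulationConfig:
    """A canned four-timestamp scenario exercising all five event types.

    Seven planted modules evolve over four timestamps:

    * ``A`` continues from t0 to t1, then splits into ``A1``/``A2`` which
      persist to t3;
    * ``B`` dissolves after t0; ``C`` forms at t1, continues, then dissolves;
    * ``D`` and ``E`` continue from t0 to t1 and merge into ``F`` at t2,
      which persists; ``G`` forms at t3.

    ``module_size`` controls the base module size (``A`` is built from two
    halves of 0.75x that size so the split parts stay in the admissible
    range).  The defaults are sized like a realistic cohort — a few
    thousand genes and a few tens of samples per timestamp — but every size
    can be scaled down for quick runs.
    """
    half = max(30, int(round(0.75 * module_size)))
    size = max(30, module_size)

    def block(start: int, n: int) -> frozenset:
        return frozenset(f"g{i:04d}" for i in range(start, start + n))

    a1 = block(0, half)
    a2 = block(half, half)
    a = a1 | a2
    pos = 2 * half
    b = block(pos, size); pos += size
    c = block(pos, size); pos += size
    d = block(pos, size); pos += size
    e = block(pos, size); pos += size
    f_mod = d | e
    g_mod = block(pos, size); pos += size
    if pos > n_genes:
        raise ValueError(f"standard scenario needs at least {pos} genes, got {n_genes}")

    modules = [
        PlantedModule("A", {0: a, 1: a}),
        PlantedModule("A1", {2: a1, 3: a1}),
        PlantedModule("A2", {2: a2, 3: a2}),
        PlantedModule("B", {0: b}),
        PlantedModule("C", {1: c, 2: c}),
        PlantedModule("D", {0: d, 1: d}),
        PlantedModule("E", {0: e, 1: e}),
        PlantedModule("F", {2: f_mod, 3: f_mod}),
        PlantedModule("G", {3: g_mod}),
    ]
    events = [
        PlantedEvent(0, "continue", ("A",), ("A",)),
        PlantedEvent(0, "dissolve", ("B",), ()),
        PlantedEvent(0, "form", (), ("C",)),
        PlantedEvent(0, "continue", ("D",), ("D",)),
        PlantedEvent(0, "continue", ("E",), ("E",)),
        PlantedEvent(1, "split", ("A",), ("A1", "A2")),
        PlantedEvent(1, "merge", ("D", "E"), ("F",)),
        PlantedEvent(1, "continue", ("C",), ("C",)),
        PlantedEvent(2, "continue", ("A1",), ("A1",)),
        PlantedEvent(2, "continue", ("A2",), ("A2",)),
        PlantedEvent(2, "continue", ("F",), ("F",)),
        PlantedEvent(2, "dissolve", ("C",), ()),
        PlantedEvent(2, "form", (), ("G",)),
    ]
    # F (2x size) can exceed the default cap of 180 only for module_size > 90
    size_range = (min(30, half), max(DEFAULT_SIZE_RANGE[1], 2 * size))
    return SimulationConfig(
        n_genes=n_genes,
        n_patient_samples_per_timestamp=n_patient_samples_per_timestamp,
        n_control_samples=n_control_samples,
        n_timestamps=4,
        planted_modules=modules,
        event_script=events,
        noise_sd=noise_sd,
        within_module_corr=within_module_corr,
        de_effect_size=de_effect_size,
        seed=seed,
        size_range=size_range,
    )


def script_late_rise_scenario(
    n_genes: int = 400,
    n_patient_samples_per_timestamp: int = 40,
    n_control_samples: int = 10,
    module_size: int = 40,
    late_corr: float = 0.8,
    seed: int = 0,
) -> SimulationConfig:
    """A four-timestamp scenario with one late-strengthening module.

    The ``late`` module's genes are uncorrelated background at the first
    three timestamps and become a dense co-expression block (correlation
    ``late_corr``) only at the last — the planted analogue of a strength
    trajectory that is low and flat, then rises sharply.  Three constant
    reference modules provide cross-module context for normalization.
    """
    size = max(30, module_size)

    def block(start: int, n: int) -> frozenset:
        return frozenset(f"g{i:04d}" for i in range(start, start + n))

    if 4 * size > n_genes:
        raise ValueError(f"late-rise scenario needs at least {4 * size} genes")
    mods = [
        PlantedModule(
            "late",
            {t: block(0, size) for t in range(4)},
            corr_per_timestamp={0: 0.0, 1: 0.0, 2: 0.0, 3: late_corr},
        ),
        PlantedModule("ref1", {t: block(size, size) for t in range(4)}),
        PlantedModule("ref2", {t: block(2 * size, size) for t in range(4)}),
        PlantedModule("ref3", {t: block(3 * size, size) for t in range(4)}),
    ]
    return SimulationConfig(
        n_genes=n_genes,
        n_patient_samples_per_timestamp=n_patient_samples_per_timestamp,
        n_control_samples=n_control_samples,
        n_timestamps=4,
        planted_modules=mods,
        within_module_corr=0.7,
        noise_sd=0.2,
        de_effect_size=1.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# YAML round trip for configs (documented schema: scalar fields by name;
# planted modules as {module_id, genes: {timestamp: [gene ids]}, corr:
# {timestamp: rho}}; events as {transition, type, sources, targets}).
def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "n_genes": config.n_genes,
        "n_patient_samples_per_timestamp": config.n_patient_samples_per_timestamp,
        "n_control_samples": config.n_control_samples,
        "n_timestamps": config.n_timestamps,
        "noise_sd": config.noise_sd,
        "within_module_corr": config.within_module_corr,
        "de_effect_size": config.de_effect_size,
        "seed": config.seed,
        "size_range": list(config.size_range),
        "overlap_cap": config.overlap_cap,
        "timestamp_labels": (
            None if config.timestamp_labels is None else list(config.timestamp_labels)
        ),
        "planted_modules": [
            {
                "module_id": m.module_id,
                "genes": {int(t): sorted(g) for t, g in m.gene_ids_per_timestamp.items()},
                "corr": (
                    None
                    if m.corr_per_timestamp is None
                    else {int(t): float(c) for t, c in m.corr_per_timestamp.items()}
                ),
            }
            for m in config.planted_modules
        ],
        "event_script": [
            {
                "transition": e.transition,
                "type": e.type,
                "sources": list(e.source_ids),
                "targets": list(e.target_ids),
            }
            for e in config.event_script
        ],
    }


def config_from_dict(d: dict) -> SimulationConfig:
    modules = [
        PlantedModule(
            module_id=m["module_id"],
            gene_ids_per_timestamp={int(t): frozenset(g) for t, g in m["genes"].items()},
            corr_per_timestamp=(
                None
                if m.get("corr") is None
                else {int(t): float(c) for t, c in m["corr"].items()}
            ),
        )
        for m in d.get("planted_modules", [])
    ]
    events = [
        PlantedEvent(e["transition"], e["type"], tuple(e["sources"]), tuple(e["targets"]))
        for e in d.get("event_script", [])
    ]
    return SimulationConfig(
        n_genes=d.get("n_genes", 2500),
        n_patient_samples_per_timestamp=d.get("n_patient_samples_per_timestamp", 30),
        n_control_samples=d.get("n_control_samples", 20),
        n_timestamps=d.get("n_timestamps", 4),
        planted_modules=modules,
        event_script=events,
        noise_sd=d.get("noise_sd", 0.2),
        within_module_corr=d.get("within_module_corr", 0.8),
        de_effect_size=d.get("de_effect_size", 1.0),
        seed=d.get("seed", 0),
        size_range=tuple(d.get("size_range", DEFAULT_SIZE_RANGE)),
        overlap_cap=d.get("overlap_cap", 0.2),
        timestamp_labels=(
            None if d.get("timestamp_labels") is None else tuple(d["timestamp_labels"])
        ),
    )


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))


def config_from_yaml(path: str | Path) -> SimulationConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
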