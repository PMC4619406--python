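"""Temporal module-strength progression: smoothing, normalization, patterns.

A module's raw strength in one network is the conductance-style ratio
W_in / (W_in + W_out) of internal to total incident edge weight: a cohesive,
insulated module scores near 1.  Each candidate module (the deduplicated
union over all timestamps) is scored against every timestamp's network, the
resulting trajectory is smoothed with a quadratic successive-difference
penalty (treatment response changes gradually, and single-timestamp networks
are noisy), strengths are min-max normalized across modules per timestamp,
flat trajectories are discarded, and the remainder is classified into three
progression shapes: a late rise, a hill, or an early drop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .modules import GeneModule
from .network import CoexpressionNetwork

PATTERNS = ("flat", "pattern1_late_rise", "pattern2_hill", "pattern3_early_drop", "other")


@dataclass(frozen=True)
class StrengthConfig:
    smoothing_weight: float = 0.3   # lambda of the successive-difference penalty
    flat_range_cutoff: float = 0.05  # normalized range below which a module is flat
    pattern_delta: float = 0.2       # minimum normalized change to call a rise/drop

    def __post_init__(self) -> None:
        if not (0.0 <= self.smoothing_weight < 1.0):
            raise ValueError("smoothing_weight must be in [0, 1)")
        if self.flat_range_cutoff < 0 or self.pattern_delta <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass(frozen=True)
class StrengthTrajectory:
    module_id: str
    raw_strengths: tuple[float, ...]
    smoothed_strengths: tuple[float, ...]
    normalized_strengths: tuple[float, ...] | None = None
    pattern: str | None = None


# ---------------------------------------------------------------------------
def raw_strength(module: frozenset, net: CoexpressionNetwork) -> float:
    """W_in / (W_in + W_out) of the module inside one network.

    W_in sums edge weights with both endpoints in the module, W_out those
    with exactly one.  A module with no incident edges scores 0.
    """
    nodes = set(net.gene_ids)
    if not module <= nodes:
        raise ValueError("module genes must be a subset of the network nodes")
    w_in = w_out = 0.0
    for a, b, w in net.all_edges():
        ina, inb = a in module, b in module
        if ina and inb:
            w_in += abs(w)
        elif ina or inb:
            w_out += abs(w)
    total = w_in + w_out
    return w_in / total if total > 0 else 0.0


def smooth_trajectory(raw: np.ndarray, lam: float) -> np.ndarray:
    """Exact minimizer of sum (x_t - raw_t)^2 + lam * sum (x_t - x_{t-1})^2.

    The normal equations (I + lam * L) x = raw, with L the path-graph
    Laplacian, are tridiagonal and solved directly.  lam = 0 returns the
    input unchanged.
    """
    raw = np.asarray(raw, float)
    if raw.ndim != 1 or len(raw) < 1:
        raise ValueError("raw must be a non-empty vector")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    T = len(raw)
    if lam == 0 or T == 1:
        return raw.copy()
    diag = np.ones(T) + 2.0 * lam
    diag[0] -= lam
    diag[-1] -= lam
    off = np.full(T - 1, -lam)
    ab = np.zeros((3, T))
    ab[0, 1:] = off
    ab[1] = diag
    ab[2, :-1] = off
    return solve_banded((1, 1), ab, raw)


def normalize_catalog(trajectories: list[StrengthTrajectory]) -> list[StrengthTrajectory]:
    """Per-timestamp min-max scaling of smoothed strengths across modules.

    A timestamp where all modules agree maps everyone to 0.5.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories to normalize")
    mat = np.array([t.smoothed_strengths for t in trajectories], float)
    lo = mat.min(axis=0)
    hi = mat.max(axis=0)
    span = hi - lo
    out = np.where(span > 0, (mat - lo) / np.where(span > 0, span, 1.0), 0.5)
    return [
        replace(t, normalized_strengths=tuple(float(v) for v in out[i]))
        for i, t in enumerate(trajectories)
    ]


def classify_pattern(traj: StrengthTrajectory, config: StrengthConfig) -> str:
    """Assign one of the five labels to a four-timestamp trajectory.

    Precedence: flat first, then late rise, hill, early drop; ``other``
    otherwise.  Exactly one label is always produced.
    """
    x = traj.normalized_strengths
    if x is None:
        raise ValueError("trajectory must be normalized before classification")
    if len(x) != 4:
        raise ValueError("pattern classification is defined for 4 timestamps")
    x = np.asarray(x, float)
    delta = config.pattern_delta
    if x.max() - x.min() < config.flat_range_cutoff:
        return "flat"
    if x[3] - x[:3].mean() >= delta and (x[:3].max() - x[:3].min()) < delta:
        return "pattern1_late_rise"
    peak = int(np.argmax(x))
    if peak in (1, 2) and (x[peak] - x[0]) >= delta and (x[peak] - x[3]) >= delta:
        return "pattern2_hill"
    if x[0] - x[1:].mean() >= delta:
        return "pattern3_early_drop"
    return "other"


# ---------------------------------------------------------------------------
def build_trajectories(
    candidates: list[GeneModule],
    nets: list[CoexpressionNetwork],
    config: StrengthConfig | None = None,
) -> list[StrengthTrajectory]:
    """Score every candidate module against every network, smooth, normalize,
    and (for four timestamps) classify the progression pattern."""
    config = config or StrengthConfig()
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate modules")
    nets = sorted(nets, key=lambda n: n.timestamp)
    trajs = []
    for mod in candidates:
        raw = np.array([raw_strength(mod.gene_ids, net) for net in nets])
        smoothed = smooth_trajectory(raw, config.smoothing_weight)
        trajs.append(
            StrengthTrajectory(
                module_id=mod.module_id,
                raw_strengths=tuple(float(v) for v in raw),
                smoothed_strengths=tuple(float(v) for v in smoothed),
            )
        )
    trajs = normalize_catalog(trajs)
    if len(nets) == 4:
        trajs = [replace(t, pattern=classify_pattern(t, config)) for t in trajs]
    return trajs


def filter_flat(trajectories: list[StrengthTrajectory]) -> list[StrengthTrajectory]:
    """Drop modules whose strength never moves (pattern == flat)."""
    return [t for t in trajectories if t.pattern != "flat"]


def compare_groups(
    traj_a: list[StrengthTrajectory],
    traj_b: list[StrengthTrajectory],
    delta: float = 0.2,
) -> dict:
    """Divergence of two groups' normalized trajectories over shared modules.

    Per module: the mean absolute difference of normalized strengths.  Per
    pattern (labels from group A): the fraction of its modules whose
    difference exceeds ``delta``; a pattern is ``divergent`` if more than half
    of its modules exceed the threshold, else ``shared``.
    """
    by_a = {t.module_id: t for t in traj_a}
    by_b = {t.module_id: t for t in traj_b}
    shared = sorted(set(by_a) & set(by_b))
    if not shared:
        raise ValueError("the two groups share no modules")
    per_module = {}
    for mid in shared:
        xa = np.asarray(by_a[mid].normalized_strengths, float)
        xb = np.asarray(by_b[mid].normalized_strengths, float)
        per_module[mid] = float(np.abs(xa - xb).mean())
    patterns: dict[str, dict] = {}
    for mid in shared:
        label = by_a[mid].pattern or "other"
        patterns.setdefault(label, {"module_ids": [], "n_divergent": 0})
        patterns[label]["module_ids"].append(mid)
        if per_module[mid] > delta:
            patterns[label]["n_divergent"] += 1
    for label, info in patterns.items():
        n = len(info["module_ids"])
        frac = info["n_divergent"] / n
        info["fraction_divergent"] = frac
        info["status"] = "divergent" if frac > 0.5 else "shared"
    return {"delta": delta, "per_module": per_module, "per_pattern": patterns}


# ---------------------------------------------------------------------------
def write_trajectories_tsv(trajectories: list[StrengthTrajectory], path: str | Path) -> None:
    rows = []
    for t in trajectories:
        row = {"module_id": t.module_id, "pattern": t.pattern}
        for i, v in enumerate(t.raw_strengths):
            row[f"raw_t{i}"] = v
        for i, v in enumerate(t.smoothed_strengths):
            row[f"smoothed_t{i}"] = v
        if t.normalized_strengths is not None:
            for i, v in enumerate(t.normalized_strengths):
                row[f"normalized_t{i}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_divergence_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=1))
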