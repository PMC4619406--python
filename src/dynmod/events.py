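"""Tracking module evolution between consecutive timestamps.

Five event types describe how a module changes from timestamp i to i+1:

* **continue** — a module's best match in the next catalog overlaps enough;
* **split** — one module's genes are spread over >=2 next-stage modules,
  each of which it covers by at least the overlap threshold alpha;
* **merge** — >=2 modules each pour at least an alpha fraction of their genes
  into one next-stage module;
* **dissolve** — a module with no sufficiently similar successor;
* **form** — a next-stage module with no sufficiently similar predecessor.

The matching metric between gene sets a and b is |a & b| / max(|a|, |b|); a
match requires it to reach alpha.  Split and merge use directed containments
(|a & b| / |b| and |a & b| / |a| respectively).  Categories are resolved with
the precedence split/merge > continue > form/dissolve, and every module is
covered by at least one record per adjacent transition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .modules import GeneModule, ModuleCatalog

EVENT_TYPES = ("form", "dissolve", "continue", "split", "merge")


# ---------------------------------------------------------------------------
def module_similarity(a: frozenset, b: frozenset) -> float:
    """|a & b| / max(|a|, |b|), symmetric, in [0, 1]."""
    if not a or not b:
        raise ValueError("module gene sets must be non-empty")
    return len(a & b) / max(len(a), len(b))


def _containment(a: frozenset, b: frozenset) -> float:
    """Fraction of b covered by a: |a & b| / |b|."""
    return len(a & b) / len(b)


@dataclass(frozen=True)
class TrackResult:
    source_module: str
    matched_module: str | None
    similarity: float
    alpha: float


def track(module: GeneModule, catalog_next: list[GeneModule], alpha: float) -> TrackResult:
    """Best-overlap match of ``module`` in the next catalog, or none.

    Returns the argmax of :func:`module_similarity`; no match if the best
    similarity is below ``alpha``.  Ties break on the smallest module id.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    best_id, best_sim = None, -1.0
    for cand in sorted(catalog_next, key=lambda m: m.module_id):
        sim = module_similarity(module.gene_ids, cand.gene_ids)
        if sim > best_sim:
            best_id, best_sim = cand.module_id, sim
    if best_id is None or best_sim < alpha:
        return TrackResult(module.module_id, None, max(best_sim, 0.0), alpha)
    return TrackResult(module.module_id, best_id, best_sim, alpha)


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class EventRecord:
    transition: tuple[int, int]
    type: str
    source_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    similarities: tuple[float, ...] = ()

    def to_json_line(self) -> str:
        return json.dumps(
            {
                "transition": list(self.transition),
                "type": self.type,
                "source_ids": list(self.source_ids),
                "target_ids": list(self.target_ids),
                "similarities": [round(s, 10) for s in self.similarities],
            },
            sort_keys=True,
        )


def classify_events(
    catalog_i: list[GeneModule],
    catalog_next: list[GeneModule],
    alpha: float,
    transition: tuple[int, int] | None = None,
    strict: bool = False,
) -> list[EventRecord]:
    """Classify all events on the transition between two module catalogs.

    ``strict`` switches overlap comparisons from >= alpha to > alpha.
    Precedence: split/merge first; continue for unclaimed tracked modules;
    form/dissolve as the fallback so that every module on both sides appears
    in at least one record.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    if transition is None:
        ti = catalog_i[0].timestamp if catalog_i else 0
        transition = (ti, ti + 1)
    meets = (lambda v: v > alpha) if strict else (lambda v: v >= alpha)

    sources = sorted(catalog_i, key=lambda m: m.module_id)
    targets = sorted(catalog_next, key=lambda m: m.module_id)
    records: list[EventRecord] = []
    covered_src: set[str] = set()
    covered_tgt: set[str] = set()
    in_split_or_merge: set[str] = set()

    # splits: the source covers each target part by >= alpha of the part
    for x in sources:
        parts = [
            (y.module_id, _containment(x.gene_ids, y.gene_ids))
            for y in targets
            if meets(_containment(x.gene_ids, y.gene_ids))
        ]
        if len(parts) >= 2:
            records.append(
                EventRecord(
                    transition,
                    "split",
                    (x.module_id,),
                    tuple(p for p, _ in parts),
                    tuple(s for _, s in parts),
                )
            )
            covered_src.add(x.module_id)
            covered_tgt.update(p for p, _ in parts)
            in_split_or_merge.add(x.module_id)

    # merges: each source pours >= alpha of itself into the target
    for y in targets:
        feeders = [
            (x.module_id, _containment(y.gene_ids, x.gene_ids))
            for x in sources
            if meets(_containment(y.gene_ids, x.gene_ids))
        ]
        if len(feeders) >= 2:
            records.append(
                EventRecord(
                    transition,
                    "merge",
                    tuple(f for f, _ in feeders),
                    (y.module_id,),
                    tuple(s for _, s in feeders),
                )
            )
            covered_tgt.add(y.module_id)
            covered_src.update(f for f, _ in feeders)
            in_split_or_merge.update(f for f, _ in feeders)

    # continues: best-match tracking for modules not claimed by split/merge
    for x in sources:
        if x.module_id in in_split_or_merge:
            continue
        tr = track(x, targets, alpha)
        if tr.matched_module is not None:
            records.append(
                EventRecord(
                    transition,
                    "continue",
                    (x.module_id,),
                    (tr.matched_module,),
                    (tr.similarity,),
                )
            )
            covered_src.add(x.module_id)
            covered_tgt.add(tr.matched_module)

    # dissolve: sources covered by nothing
    for x in sources:
        if x.module_id not in covered_src:
            records.append(EventRecord(transition, "dissolve", (x.module_id,), ()))

    # form / backward continue: targets covered by nothing
    src_by_id = {m.module_id: m for m in sources}
    for y in targets:
        if y.module_id in covered_tgt:
            continue
        back = track(y, sources, alpha)
        if back.matched_module is None:
            records.append(EventRecord(transition, "form", (), (y.module_id,)))
        else:
            # a similar predecessor exists but tracked elsewhere; the module
            # did not newly form — record its continuation for coverage
            records.append(
                EventRecord(
                    transition,
                    "continue",
                    (back.matched_module,),
                    (y.module_id,),
                    (back.similarity,),
                )
            )
    return records


# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class EventTally:
    transition: tuple[int, int] | None
    counts: dict
    fractions: dict
    alpha: float | None = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def tally_events(events: list[EventRecord], alpha: float | None = None) -> EventTally:
    """Counts and normalized fractions per event type.

    An empty event list yields an all-zero tally (guarded denominators).
    """
    counts = {t: 0 for t in EVENT_TYPES}
    for ev in events:
        counts[ev.type] += 1
    total = sum(counts.values())
    fractions = {t: (counts[t] / total if total else 0.0) for t in EVENT_TYPES}
    transitions = {ev.transition for ev in events}
    transition = transitions.pop() if len(transitions) == 1 else None
    return EventTally(transition=transition, counts=counts, fractions=fractions, alpha=alpha)


def sweep_alpha(
    catalog: ModuleCatalog,
    alphas: tuple[float, ...] = (0.12, 0.16, 0.20),
    strict: bool = False,
) -> list[EventTally]:
    """One aggregated tally per overlap threshold.

    Thresholds must be strictly increasing in (0, 1].  Form+dissolve counts
    are checked to be non-decreasing in alpha (they are, by construction:
    raising the threshold can only break matches).
    """
    if any(not (0.0 < a <= 1.0) for a in alphas):
        raise ValueError("alphas must lie in (0, 1]")
    if any(b <= a for a, b in zip(alphas, alphas[1:])):
        raise ValueError("alphas must be strictly increasing")
    ts = catalog.timestamps
    tallies = []
    for alpha in alphas:
        events: list[EventRecord] = []
        for a, b in zip(ts, ts[1:]):
            events.extend(
                classify_events(
                    catalog.modules_at(a),
                    catalog.modules_at(b),
                    alpha,
                    transition=(a, b),
                    strict=strict,
                )
            )
        tallies.append(tally_events(events, alpha=alpha))
    fd = [t.counts["form"] + t.counts["dissolve"] for t in tallies]
    if any(b < a for a, b in zip(fd, fd[1:])):
        raise AssertionError("form+dissolve counts must be non-decreasing in alpha")
    return tallies


# ---------------------------------------------------------------------------
def write_events_jsonl(events: list[EventRecord], path: str | Path) -> None:
    Path(path).write_text("\n".join(ev.to_json_line() for ev in events) + "\n")


def read_events_jsonl(path: str | Path) -> list[EventRecord]:
    events = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        events.append(
            EventRecord(
                tuple(d["transition"]),
                d["type"],
                tuple(d["source_ids"]),
                tuple(d["target_ids"]),
                tuple(d["similarities"]),
            )
        )
    return events


def write_tallies_tsv(tallies: list[EventTally], path: str | Path) -> None:
    rows = []
    for t in tallies:
        row = {"alpha": t.alpha, "transition": str(t.transition), "total": t.total}
        for typ in EVENT_TYPES:
            row[f"n_{typ}"] = t.counts[typ]
            row[f"frac_{typ}"] = t.fractions[typ]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
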