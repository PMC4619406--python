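"""Event tracking: similarity metric, best-match tracking, five-way classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import dynmod as dm
from dynmod.events import EVENT_TYPES, module_similarity, tally_events
from dynmod.modules import ModuleCatalog

from conftest import random_catalog_pair


def gm(mid, t, genes):
    return dm.GeneModule(mid, t, frozenset(genes))


# -- similarity -------------------------------------------------------------
def test_similarity_hand_arithmetic():
    """|a|=6, |b|=10, |a&b|=3 -> 3/10."""
    a = frozenset(f"g{i}" for i in range(1, 7))
    b = frozenset(f"g{i}" for i in range(4, 14))
    assert module_similarity(a, b) == pytest.approx(0.3)


def test_similarity_trivial_cases():
    a = frozenset("abc")
    assert module_similarity(a, a) == 1.0
    assert module_similarity(a, frozenset("xyz")) == 0.0
    with pytest.raises(ValueError):
        module_similarity(a, frozenset())


@given(st.sets(st.integers(0, 30), min_size=1), st.sets(st.integers(0, 30), min_size=1))
def test_similarity_symmetric_and_bounded(a, b):
    a, b = frozenset(a), frozenset(b)
    s = module_similarity(a, b)
    assert s == module_similarity(b, a)
    assert 0.0 <= s <= 1.0
    # independent brute-force set arithmetic
    assert s == len(a & b) / max(len(a), len(b))


# -- track ------------------------------------------------------------------
def test_track_identical_module_matches_with_similarity_one():
    m = gm("x", 0, "abcdef")
    nxt = [gm("y1", 1, "abcdef"), gm("y2", 1, "abq")]
    r = dm.track(m, nxt, alpha=0.5)
    assert r.matched_module == "y1" and r.similarity == 1.0


def test_track_below_alpha_returns_none():
    m = gm("x", 0, "abcdef")
    r = dm.track(m, [gm("y", 1, "az")], alpha=0.5)
    assert r.matched_module is None
    assert dm.track(m, [], alpha=0.5).matched_module is None


@pytest.mark.parametrize("seed", range(10))
def test_track_equals_exhaustive_argmax(seed):
    rng = np.random.default_rng(seed)
    src, tgt = random_catalog_pair(rng, n_modules=20)
    for m in src:
        r = dm.track(m, tgt, alpha=0.12)
        sims = {c.module_id: module_similarity(m.gene_ids, c.gene_ids) for c in tgt}
        best = max(sims.values())
        if best < 0.12:
            assert r.matched_module is None
        else:
            winners = sorted(mid for mid, s in sims.items() if s == best)
            assert r.matched_module == winners[0]
            assert r.similarity == best


# -- classify ---------------------------------------------------------------
def test_scripted_catalog_reproduces_all_five_events():
    """On the standard scenario's true catalogs, classification returns
    exactly the scripted events (form, dissolve, continue, split, merge)."""
    cfg = dm.script_standard_scenario(n_genes=300, module_size=30, seed=0)
    per_t = {t: [] for t in range(4)}
    for m in cfg.planted_modules:
        for t, genes in m.gene_ids_per_timestamp.items():
            if genes:
                per_t[t].append(gm(m.module_id, t, genes))
    events = []
    for a, b in zip(range(4), range(1, 4)):
        events.extend(dm.classify_events(per_t[a], per_t[b], alpha=0.16, transition=(a, b)))
    got = {(e.transition[0], e.type, e.source_ids, e.target_ids) for e in events}
    expected = {
        (e.transition, e.type, e.source_ids, e.target_ids) for e in cfg.event_script
    }
    assert got == expected
    assert {e.type for e in events} == set(EVENT_TYPES)


def test_split_and_merge_shapes():
    src = [gm("s", 0, range(20))]
    tgt = [gm("p1", 1, range(10)), gm("p2", 1, range(10, 20))]
    (ev,) = dm.classify_events(src, tgt, alpha=0.5)
    assert ev.type == "split" and ev.target_ids == ("p1", "p2")
    evs = dm.classify_events(tgt, src, alpha=0.5, transition=(0, 1))
    (ev,) = [e for e in evs if e.type == "merge"]
    assert set(ev.source_ids) == {"p1", "p2"} and ev.target_ids == ("s",)


def test_zero_overlap_gives_form_and_dissolve():
    src = [gm("old", 0, "abc")]
    tgt = [gm("new", 1, "xyz")]
    events = dm.classify_events(src, tgt, alpha=0.2)
    assert {(e.type, e.source_ids, e.target_ids) for e in events} == {
        ("dissolve", ("old",), ()),
        ("form", (), ("new",)),
    }


def test_alpha_one_without_identical_modules_dissolves_everything():
    rng = np.random.default_rng(0)
    src, tgt = random_catalog_pair(rng, n_modules=8)
    events = dm.classify_events(src, tgt, alpha=1.0)
    types = {e.type for e in events}
    assert types <= {"form", "dissolve"}
    assert sum(e.type == "dissolve" for e in events) == len(src)
    assert sum(e.type == "form" for e in events) == len(tgt)


@pytest.mark.parametrize("seed", range(15))
def test_every_module_covered_by_some_record(seed):
    """Exhaustiveness: each module on both sides appears in >= 1 record."""
    rng = np.random.default_rng(100 + seed)
    src, tgt = random_catalog_pair(rng)
    events = dm.classify_events(src, tgt, alpha=0.16)
    seen_src = set().union(*(e.source_ids for e in events)) if events else set()
    seen_tgt = set().union(*(e.target_ids for e in events)) if events else set()
    assert {m.module_id for m in src} <= seen_src
    assert {m.module_id for m in tgt} <= seen_tgt


# -- tally / sweep ----------------------------------------------------------
def test_tally_fractions():
    events = [
        dm.EventRecord((0, 1), t, ("s",) if t != "form" else (), ("t",) if t != "dissolve" else ())
        for t in EVENT_TYPES
    ]
    tally = tally_events(events)
    assert all(f == pytest.approx(0.2) for f in tally.fractions.values())
    assert sum(tally.fractions.values()) == pytest.approx(1.0, abs=1e-9)
    empty = tally_events([])
    assert empty.total == 0 and all(f == 0.0 for f in empty.fractions.values())


def test_sweep_alpha_three_thresholds():
    rng = np.random.default_rng(3)
    src, tgt = random_catalog_pair(rng)
    cat = ModuleCatalog(k=15, per_timestamp={0: src, 1: tgt})
    tallies = dm.sweep_alpha(cat, (0.12, 0.16, 0.20))
    assert len(tallies) == 3
    fd = [t.counts["form"] + t.counts["dissolve"] for t in tallies]
    assert fd == sorted(fd)
    with pytest.raises(ValueError):
        dm.sweep_alpha(cat, (0.2, 0.12))


@pytest.mark.parametrize("seed", range(25))
def test_form_dissolve_monotone_in_alpha(seed):
    rng = np.random.default_rng(500 + seed)
    src, tgt = random_catalog_pair(rng)
    counts = []
    for alpha in (0.12, 0.16, 0.20):
        t = tally_events(dm.classify_events(src, tgt, alpha))
        counts.append(t.counts["form"] + t.counts["dissolve"])
    assert counts == sorted(counts)


def test_events_jsonl_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    src, tgt = random_catalog_pair(rng, n_modules=6)
    events = dm.classify_events(src, tgt, alpha=0.16)
    p = tmp_path / "ev.jsonl"
    from dynmod.events import read_events_jsonl, write_events_jsonl

    write_events_jsonl(events, p)
    back = read_events_jsonl(p)
    assert [(e.type, e.source_ids, e.target_ids) for e in back] == [
        (e.type, e.source_ids, e.target_ids) for e in events
    ]
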