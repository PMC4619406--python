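# dynmod

Dynamic gene co-expression network analysis of treatment response:
per-stage network construction, overlapping module detection, evolutionary
event tracking, and temporal module-strength progression.

## The problem

In longitudinal transcriptomic cohorts — the motivating case is whole-blood
expression from children with juvenile idiopathic arthritis sampled at 0, 4,
6 and 12 months of therapy — the interesting signal is often not which genes
change, but how the *co-expression network* reorganizes: which functional
modules form, dissolve, persist, split or merge as treatment takes hold, and
which modules gain or lose cohesion over time.  `dynmod` provides that
analysis as a tested, reusable pipeline for anyone with per-stage expression
matrices and sample metadata, plus a synthetic-data generator with planted
ground truth so every stage is verifiable without cohort data.

## The method

For stages *i* = 1…T (calendar timestamps or response-path groups):

1. **Gene selection** — keep the 2,000 genes best separating baseline
   patients from healthy controls (Welch t-test, smallest p-values).
2. **Network** *Wⁱ* — Pearson-correlate all selected gene pairs over stage
   *i*'s samples; keep exactly the top 10% of pairs by |r|; greedily add the
   strongest inter-component correlations until the graph is connected.
3. **Modules** *Cⁱ* = {C₁ⁱ…C₅₀ⁱ} — factorize the weighted adjacency with
   NMF (k = 50, best of seeded restarts); gene g joins module j whenever
   H[j,g] ≥ 0.8·maxⱼ′ H[j′,g], so modules overlap.
4. **Events** — between consecutive stages, modules are matched by the
   overlap ratio |Vₓⁱ ∩ V_z^{i+1}| / max(|Vₓⁱ|, |V_z^{i+1}|) against a
   threshold α (swept over 0.12/0.16/0.20) and classified into five events:
   *form, dissolve, continue, split, merge*.
5. **Strength** — each candidate module (deduplicated union over stages)
   gets a strength trajectory W_in/(W_in+W_out) per stage, smoothed by a
   quadratic successive-difference penalty, min–max normalized across
   modules per stage, and classified as flat / late rise / hill / early
   drop / other; groups (e.g. active vs inactive disease) are compared per
   pattern.

Per-stage topology summaries (average betweenness, closeness, clustering
coefficient, mean edge |r|) are reported alongside.  See `docs/methods.md`
for assumptions, parameter defaults and numerical choices.

## Worked example

```python
import dynmod as dm

# simulate a 4-stage cohort with planted, evolving modules
cfg = dm.script_standard_scenario(n_genes=500, module_size=40, seed=7)
datasets, truth = dm.simulate_dataset(cfg)

ranking = dm.rank_genes(datasets[0].patients(), datasets[0].controls())
genes = dm.select_top_genes(ranking, k=400)
nets = [dm.build_network(datasets[t].patients(), genes, timestamp=t)
        for t in range(4)]
print(nets[0].n_nodes, nets[0].n_edges)      # 400 7980  (top 10% of 79,800 pairs)

catalog = dm.catalog_stages(nets, k=10, seed=1, n_restarts=3)
events = []
for a, b in ((0, 1), (1, 2), (2, 3)):
    events += dm.classify_events(catalog.modules_at(a), catalog.modules_at(b),
                                 alpha=0.16, transition=(a, b))
print(dm.tally_events(events).counts)
# {'form': 0, 'dissolve': 0, 'continue': 4, 'split': 15, 'merge': 14}

candidates = dm.deduplicate_catalog(catalog)
trajectories = dm.build_trajectories(candidates, nets)
print({t.pattern for t in trajectories})
# {'flat', 'other', 'pattern1_late_rise', 'pattern2_hill', 'pattern3_early_drop'}
```

The edge count is exact by construction (`ceil(0.10 · 79,800) = 7,980`).
The tallies show few continue events — module membership reorganizes
extensively between stages, and at this small demo scale the dense noise
background links modules mostly through split/merge records — and every
strength trajectory receives exactly one pattern label.

The same pipeline runs from the shell:

```bash
dynmod run-all --seed 1 --out-dir runs/demo          # simulated standard scenario
dynmod run-all --config my_cohort.yaml --seed 1 --out-dir runs/cohort
```

`run-all` writes per-stage edge lists, a GMT module catalog, JSON-lines
event records, tally and strength tables, and a `manifest.json` with config,
seeds and input hashes; re-running with the same seed reproduces the module
and event files byte for byte.  Individual steps are available as
`dynmod simulate / select-genes / build-network / topology / detect-modules /
track-events / strength`.

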