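# engramkit

Analysis toolkit for deconstructing a dorsal-CA1 fear-memory engram from
miniscope calcium imaging and pose-tracked behavior.

In closed-loop tagging experiments, mice undergo contextual fear
conditioning (FC: four 2-s foot shocks at minutes 2–5 of a 7-minute
session) while light delivery — gated on behavior — marks the cells active
during a chosen condition: the **pre-shock** baseline, the **shock**
responses, **freezing** bouts, or **no-freezing** movement. `engramkit`
re-expresses that experiment as a reproducible analysis pipeline for the
scientist who has trace matrices, pose tracks and cross-session
registration maps (or wants ground-truthed synthetic versions of them):

- **behavior** — body-part speeds from pose tracks; freezing by the online
  closed-loop rule (≥ *k* of 10 body parts slower than 0.5 cm/s, with
  *k* = 7 for freezing-tags and *k* = 6 for no-freezing-tags) and by a
  windowed post-hoc classifier (velocity 0.3 cm/s, angle 12°, window 32,
  count 10, min duration 0.5 s); per-epoch freezing percentages and
  Δfreezing = %freezing(ON) − %freezing(OFF).
- **tagging_scheduler** — session timelines for the published protocols and
  the light-delivery epochs each condition would have produced, with exact
  40-s budgets.
- **event_extraction** — 1-s binning, per-cell z-scoring with a 2-SD cut,
  strict-local-maximum peak detection → binary event rasters and
  events/s.
- **ensemble_detection** — group membership by *activity ranking* (cells
  whose condition-epoch mean exceeds the across-cell mean + 1 SD) and by a
  *statistical* criterion (in/out activity ratio above the 95th percentile
  of 1000 random circular shifts); group topography via asymmetric
  nearest-neighbor distances.
- **overlap_stats** — Jaccard overlap of group pairs against a bootstrapped
  chance distribution with 95th/5th-percentile verdicts.
- **cross_session** — reactivation metrics through a registration map, in
  particular the **relative reactivation**

  R(g) = (tracked members of g / |g|) ÷ (tracked cells / all FC cells),

  with chance = 1 (e.g. 100 FC cells, 70 tracked, a 10-cell group with 5
  tracked: R = 50%/70% = 0.71); recall event rates inside/outside freezing
  bouts; recall-ensemble composition of FC groups.
- **correlations** — pairwise Pearson correlations of event rasters,
  intra-/inter-group slices, and a circular-shift null that conserves each
  cell's event count exactly.
- **synthetic_data** — seeded sessions (pose, traces, positions,
  registration) with planted period-tuned ensembles and Markovian freezing
  bouts, so every stage is testable with known ground truth.

## Worked example

```python
import engramkit as ek

bundle = ek.run_pipeline(ek.PipelineConfig(seed=1, out_dir="engram_out"))
print(bundle.reactivation[["group", "group_size", "tracked",
                           "relative", "in_out_ratio"]].round(3))
```

On the seeded synthetic experiment (90 FC cells, 16-cell planted groups,
55 cells tracked into recall) this prints:

```
      group  group_size  tracked  relative  in_out_ratio
  pre-shock          16        8     0.818         0.716
      shock          16       10     1.023         0.636
   freezing          16        7     0.716         6.793
no-freezing          14       10     1.169         0.174
     others          23       23     1.636         0.631
```

`relative` is the chance-normalized tracked fraction per FC group
(`others` = tracked cells outside every group, hence fully tracked by
construction). `in_out_ratio` is each group's recall event rate inside
freezing bouts divided by its rate outside: the planted freezing ensemble
is ~6.8× more active during recall freezing while the no-freezing ensemble
drops to 0.17×, and the six pairwise overlap verdicts mark the planted
groups significantly non-overlapped. The same run writes every stage's
table (memberships for both detection methods, overlap verdicts,
correlation slices vs. their circular-shift null) under `engram_out/` with
provenance headers.

The same stages are scriptable from the shell:

```bash
engram synth --preset fc --seed 1 --out-dir session/
engram freeze --pose session/pose.tsv --mode online --min-parts 7 --out frz.tsv
engram tag --condition freezing --timeline FC --labels frz.tsv --out light.tsv
engram run --seed 1 --out-dir engram_out/
```

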