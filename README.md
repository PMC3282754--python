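# placeburst

Analysis toolkit for hippocampal **place cells** recorded while a rodent
forages in a cylindrical arena, with a focus on the **temporal structure of
complex-spike bursts** and on **place-field stability under cue rotation**.
It is written for electrophysiologists comparing groups of cells (e.g. a
mutant line against wild-type littermates) on per-cell spatial and temporal
statistics, and it includes a synthetic-recording generator so every stage of
the battery can be exercised, tested, and power-checked without any recorded
data.

## What it computes

For each cell-session (spike times + amplitudes, 60-Hz position track,
session descriptor):

* **Rate map** on a 1x1-cm grid: per-pixel rate = spikes / dwell time, with
  an occupancy-validity mask; place fields as *above-mean* pixels (also the
  field-size measure) or the *top-quartile* pixels.
* **Spatial statistics**: selectivity log10(in-field/out-field rate),
  coherence (correlation of each pixel with its 8-neighbor mean, Fisher-Z),
  and information rate I = Σ_x p(x) λ(x) log2(λ(x)/λ̄) in bits/s.
* **Stability**: pixel-by-pixel cross-session correlation, a 1°-step rotation
  search for the field displacement, classification of each session pair as
  **DistalCue / LocalCue / Remap** (±45° windows about the unmoved distal
  reference and the card rotation), and a random-pair baseline.
* **Bursts**: a burst is ≥2 spikes, each within 15 ms of its predecessor,
  with strictly decreasing amplitudes. The battery reports burst frequency,
  intra-burst spike rate, spikes/burst, intra-burst ratio, inter-burst
  intervals, per-ordinal intra-burst ISIs (ISI-1, ISI-2, ISI-3) with
  histogram peak / CV / SD / Shannon entropy, burst-in-field reliability,
  and the coherence of the burst place-map.
* **Models**: a loess-style locally weighted regression of pixel rate on
  position (tri-cube weights, degree-1, span chosen by 10-fold CV) summarized
  as percent variance explained, PVE = 100(1 − σ²_resid/σ²_total); and a
  logistic regression of remapping on ISI peak time, group, and session,
  fitted by IRLS with a monotone deviance guarantee.
* **Pipeline**: the place-cell inclusion rule (mean rate > 0.2 Hz and
  selectivity > 0.5), per-cell orchestration over three-session cue-rotation
  protocols, pooled all-session statistics, and per-metric Welch t-tests
  with means ± SEM (plus a Benjamini–Hochberg column for transparency).

See `docs/methods.md` for every definition, default, and numerical choice.

## Worked example

Simulate two 6-cell groups that differ only in their intra-burst ISI mean
(2.5 vs 3.9 ms), run the full battery, and compare groups:

```python
from placeburst import (
    AnalysisConfig, CohortParams, SyntheticCellParams, TrajectoryParams,
    analyze_cohort, compare_groups, default_protocol, generate_cohort,
)

protocol = default_protocol(duration=300.0)   # 3 sessions, card +90 deg CCW in session 2
cohorts = {}
for label, isi in [("control", 2.5), ("mutant", 3.9)]:
    params = CohortParams(
        cell=SyntheticCellParams(intra_isi_mean=isi, p_single=0.6),
        trajectory=TrajectoryParams(duration=300.0),
    )
    cohorts[label] = generate_cohort(6, params, protocol,
                                     master_seed=1 if label == "control" else 2)

metrics, pairs = analyze_cohort(cohorts, AnalysisConfig(fit_regression=False))
per_cell = (metrics[metrics.session_id > 0]
            .groupby(["group", "cell_id"]).mean(numeric_only=True).reset_index())
comp = compare_groups(per_cell[per_cell.group == "control"],
                      per_cell[per_cell.group == "mutant"],
                      metrics=("isi1_mean_ms", "mean_spikes_per_burst", "coherence_z"))
print(comp[["metric", "mean_a", "mean_b", "t", "df", "p"]].round(3).to_string(index=False))
```

prints

```
               metric  mean_a  mean_b      t    df     p
         isi1_mean_ms   2.586   3.881 -9.765 7.976 0.000
mean_spikes_per_burst   2.227   2.199  2.101 9.684 0.063
          coherence_z   0.529   0.541 -0.292 6.164 0.780
```

The detector recovers the generated ISI-1 contrast (2.59 vs 3.88 ms,
Welch p < 0.001) while the groups are indistinguishable on map smoothness
(coherence Z, p = 0.78) — the two generators share identical spatial tuning.
The stability table classifies each session pair; for these stable cells the
1-vs-2 pair follows the unmoved distal cue:

```
    cell_id  best_angle    max_r cue_class
control-000       353.0 0.428549 DistalCue
control-001        33.0 0.399028 DistalCue
control-002        12.0 0.505249 DistalCue
```

## Command line

```
placeburst synthgen --config cohort.yaml --out data/ --seed 3   # write a synthetic cohort
placeburst analyze  --data data/ --out results/                 # metrics, stability, group tables
```

The cohort YAML format and on-disk layout are documented in
`placeburst/cli.py`; every analysis default (bin widths, occupancy threshold,
burst amplitude toggle, span grid, seeds) is overridable through the analyze
config.

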