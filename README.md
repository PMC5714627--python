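# surro4d

Dual external-surrogate respiratory waveform comparison and retrospective
4D CT phase sorting, exercised end to end on a digital moving phantom.

## The problem

Respiratory-correlated CT (4D CT) oversamples each couch position over a
breathing cycle and retrospectively sorts the slices into respiratory
phases using an *external surrogate* of breathing — typically an infrared
camera tracking a reflective marker block on the abdomen (displacement in
mm at 30 Hz, "rpm" channel here) or a pneumatic bellows belt whose pressure
tracks abdominal expansion (arbitrary units at ~38 Hz). The two systems
differ in units, gain, sampling rate and small latencies, so a natural
clinical question is whether the choice of surrogate changes the sorted
images and, downstream, the delineated internal target volume (ITV) used
for treatment planning.

`surro4d` implements the complete analysis chain needed to answer that
question quantitatively, and a synthetic-data generator (programmable
breathing curves, dual surrogate channels, a lung-mimicking digital phantom
under low-pitch helical acquisition) so the whole pipeline can be validated
without scanner hardware:

* **waveform_io** — the two trace-file dialects (a minimal VXP text format
  and a bellows CSV export) mapped onto one in-memory representation with
  times in seconds and the per-sample X-RAY ON (beam active) flag.
* **waveform_analysis** — synchronisation at the X-RAY ON rising edge,
  downsampling of the bellows onto the rpm timestamps, end-inhale peak
  detection (prominence/separation search with a plateau-midpoint rule for
  truncated tops), normalisation to the tallest peak, greedy peak pairing,
  and statistics: latency Δt = t_bellows − t_rpm (positive ⇔ rpm leads),
  amplitude mean ± SD, %CV = SD/mean × 100, breathing rate (BPM), Pearson
  r, and a Mann–Whitney U test (exact for small untied samples).
* **phase_sorting** — end-inhale tags (automatic from detected peaks, with
  audited manual add/remove edits), linear-in-time phase between
  consecutive tags (0% = end-inhale, 50% ≈ end-exhale), circular binning
  into 10 phases, and per-couch-position slice selection by closest phase.
* **phantom_sim** — the synthetic study: irregular breathing programs
  (lognormal per-cycle period/amplitude jitter, baseline drift, 7–22
  breaths/min envelope), dual surrogate synthesis with configurable gain,
  lag, noise and a low-amplitude plateau floor, a −800 HU slab phantom with
  high-contrast inserts, helical oversampled acquisition, and the
  ground-truth ITV (union of the object at end-inhale, end-exhale and mid
  displacement).
* **image_metrics** — MIP (voxelwise maximum over phases), threshold and
  simplified enclosed-air lung segmentation, and the similarity metrics

      DSC = 2|A ∩ B| / (|A| + |B|)
      OI  = |A ∩ B| / |A|            (A = accepted volume)
      percent volume change = (V_A − V_B)/V_A × 100
      percent difference from truth = (V_true − V)/V_true × 100

  plus centroid differences (lateral, A–P, S–I in mm) and difference maps.
* **cli_report** — pipeline drivers, bundled published summary tables with
  their derivable statistics, and the `surro4d` command-line interface
  (`simulate`, `compare-waveforms`, `sort`, `mip`, `metrics`,
  `phantom-study`, `paper-tables`).

## Worked example

```python
from surro4d import (make_breathing_curve, synthesize_surrogates,
                     SurrogateModel, compare_waveforms)
from surro4d.cli_report import run_phantom_batch

# one irregular breathing program, bellows delayed by 80 ms
program = make_breathing_curve(kind="irregular", mean_period_s=4.0,
                               seed=11, duration_s=90.0)
bellows_model = SurrogateModel(label="bellows", gain=1.0, lag_ms=80.0,
                               sampling_rate=38.0)
rpm, bellows = synthesize_surrogates(program, bellows_model=bellows_model,
                                     beam_window=(5.0, 80.0), seed=11)
result = compare_waveforms(rpm, bellows)
print(f"Pearson r          : {result.pearson_r:.4f}")
print(f"latency (mean+/-sd): {result.latency.mean_ms:+.1f} +/- {result.latency.sd_ms:.1f} ms")
print(f"rpm %CV / BPM      : {result.stats_rpm.cv_percent:.1f} / {result.stats_rpm.bpm:.1f}")

# end-to-end phantom study for three simulated cases
table, cases = run_phantom_batch(seeds=range(3))
cols = ["seed", "dsc", "percent_volume_change",
        "itv_true_diff_rpm_pct", "cv_percent_rpm", "bpm"]
print(table[cols].round(3).to_string(index=False))
```

prints

```
Pearson r          : 0.9914
latency (mean+/-sd): +81.5 +/- 13.9 ms
rpm %CV / BPM      : 99.7 / 14.4

seed  dsc  percent_volume_change  itv_true_diff_rpm_pct  cv_percent_rpm   bpm
   0  1.0                    0.0                 14.191         106.003 9.231
   1  1.0                    0.0                 10.700         101.741 6.923
   2  1.0                    0.0                 13.306         114.941 6.923
mean  1.0                    0.0                 12.732         107.562 7.692
  sd  0.0                    0.0                  1.815           6.737 1.332
```

Reading the output: the two channels record the same motion, so their
normalised waveforms correlate near-perfectly (r = 0.991) and the latency
pipeline recovers the injected 80 ms bellows delay (+81.5 ms, positive
because the rpm end-inhale peaks come first). In the phantom study the two
sortings of the *same* acquisition agree exactly (DSC = 1, volume change
0%) because the surrogates are noise-free here, while the MIP-derived ITV
underestimates the ground-truth ITV by 11–14% — the sorting never captures
the deepest inhale at every couch position when breathing is irregular.
Each batch row is a distinct simulated case whose breathing rate and
irregularity are drawn from a clinical envelope.

The same chains are available from the shell:

```sh
surro4d simulate --seed 11 --out sim/
surro4d compare-waveforms --rpm sim/rpm.vxp --bellows sim/bellows.csv --out report/
surro4d phantom-study --seeds 0,1,2,3,4,5,6,7 --out study/
surro4d paper-tables
```

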