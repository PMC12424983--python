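# isletca

Analysis of beta-cell cytosolic Ca²⁺ dynamics in pancreatic tissue-slice
imaging, and of mitochondria–ER contacts in beta-cell electron microscopy.

Islets in acute pancreatic slices are imaged as XYT fluorescence stacks
(nominally 20 Hz, 256×256 px) while the perfusion switches glucose and
pharmacological conditions (epinephrine, acetylcholine).  `isletca` takes
such recordings — or pre-extracted ROI traces — through the full
quantification chain:

* **Segmentation** — a *statistical image* (per-pixel temporal mean + 99th
  temporal percentile) is thresholded and watershed-split into ROIs; each
  ROI yields one trace.
* **Event kinetics** — traces are normalized to F/F₀ with a robust
  exponential baseline, and oscillatory Ca²⁺ events are detected across
  dyadic timescales of 1–256 s by band-pass filtering and a z > 4
  threshold.  Each event is described by its full width at half maximum
  (halfwidth) and its midtime; inter-event intervals (IEI) are differences
  of consecutive midtimes.  ROIs with fewer than 5 oscillations are
  discarded and analysis focuses on the dominant 1–10 s component.
* **Summaries** — per-condition medians, Gaussian KDEs (bandwidth factor
  0.2), KDE differences, Mann–Whitney U (exact for small samples),
  Student's t, and Kolmogorov–Smirnov tests.
* **Dose–response** — the four-parameter logistic
  `bottom + (top − bottom)/(1 + (EC50/c)^h)` fitted in log-concentration
  space, for agonist ramps such as 0.1–100 nM epinephrine.
* **Functional networks** — ROI pairs whose de-bleached traces correlate
  at ≥ 0.7 (zero-lag Pearson) are joined into an unweighted, undirected
  graph per condition; mean node degree, average clustering and global
  efficiency summarize islet connectivity.
* **Organelle contacts** — from 2D mitochondria/ER segmentation masks
  (5 nm/px SEM), contact sites are boundary stretches ≥ 10 nm long with
  organelle perimeters within 10 nm; a mitochondrion is ER-coupled when
  > 5% of its perimeter is in contact.  3D ER masks yield per-object
  surface-area-to-volume ratios.
* **Synthetic data** — ground-truthed generators for traces, movies,
  dose–response tables and organelle mask layouts, so the whole chain is
  testable without any raw recordings.

See `docs/methods.md` for the estimators, parameter defaults and their
rationale.

## Worked example

```python
import numpy as np
from isletca import synthetic as syn, segmentation as seg, events as ev, summaries as summ

# a two-condition recording: sparse slow activity, then dense fast activity
spec_slow = syn.TracePopulationSpec(
    n_cells=6, duration_s=300, halfwidth_dist=(4.0, 0.3), iei_dist=(30.0, 0.3),
    noise_sd=2.0, amplitude_snr=8.0, bleach_tau_s=600.0, seed=42,
)
spec_fast = syn.TracePopulationSpec(
    n_cells=6, duration_s=300, halfwidth_dist=(2.8, 0.3), iei_dist=(12.0, 0.3),
    noise_sd=2.0, amplitude_snr=8.0, bleach_tau_s=600.0, seed=43,
)
layout = syn.disk_layout(6, (64, 64), radius=6.0, seed=42)
movie_a, _, _ = syn.simulate_movie(spec_slow, layout)
movie_b, _, _ = syn.simulate_movie(spec_fast, layout)
movie = seg.Movie(np.concatenate([movie_a.stack, movie_b.stack]), 20.0)

rois = seg.segment_rois(seg.statistical_image(movie))
print(f"{rois.n_rois} ROIs segmented")
traces = seg.extract_traces(movie, rois)
events = ev.detect_events_traceset(traces)
events = ev.band_filter_events(ev.filter_rois(events, 5), 1.0, 10.0)
print(f"{len(events)} events after filtering")

timeline = summ.ProtocolTimeline([(0, 300, "6 mM glucose"), (300, 600, "8 mM glucose")])
labeled = summ.assign_condition(events, timeline)
print(summ.condition_medians(labeled).round(2).to_string(index=False))

hw6 = labeled.loc[labeled.condition == "6 mM glucose", "halfwidth_s"]
hw8 = labeled.loc[labeled.condition == "8 mM glucose", "halfwidth_s"]
res = summ.compare_groups(hw6, hw8, "ks")
print(f"KS D = {res.statistic:.3f}, p = {res.p_value:.2e}")
```

Output:

```
6 ROIs segmented
200 events after filtering
   condition  median_halfwidth_s  median_iei_s  n_events  n_iei
6 mM glucose                4.73         29.87        58     52
8 mM glucose                3.08         11.93       142    136
KS D = 0.566, p = 9.03e-13
```

All six planted cells are recovered as ROIs.  The medians reproduce the
planted contrast between the two epochs — events roughly 1.7 s shorter and
intervals ~18 s shorter in the fast condition — and the KS test rejects
equality of the halfwidth distributions decisively.

A command-line interface mirrors the library
(`islet-ca simulate|segment|extract|detect|summarize|doseresponse|network|contacts|er-sav|run`);
`islet-ca run --config run.yaml` executes the whole chain from one config
and writes a provenance manifest alongside the outputs.

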