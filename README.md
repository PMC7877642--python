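# gutmotion

Spatiotemporal-map analysis of in-vitro intestinal motility, built around
the recordings used to study bolus handling in the agastric ballan wrasse
(*Labrus bergylta*). From a calibrated position x time diameter matrix of
an isolated intestine, the package

* computes the **bulbous emptying time** (BET): with AW1(t) the mean
  diameter over Segment 1 (the dilated anterior 39 % of the gut) and
  `alpha` the type-7 5th percentile of the 14-h AW1 series, BET is the
  first time with `AW1(t) <= alpha`;
* selects the six 30-min **analysis sub-periods** t1–t6 around BET
  (periods I/II = bolus in/out of the bulbous);
* **detects, measures and classifies contractions** on the thresholded
  relative-constriction field `(baseline − D)/baseline >= 7 %`
  (watershed-split connected regions): events propagating <= 1.0 mm are
  *standing* contractions; otherwise the OLS fit of path position on time
  decides between *ripples* (R² >= 0.8) and *slow propulsive*
  contractions (R² < 0.8), with velocity = |slope| and the slope sign
  giving the anterograde/retrograde direction;
* **summarizes** frequency (contractions min⁻¹ mm⁻¹), amplitude (%),
  duration (s), distance (% of gut length), velocity (mm s⁻¹) and
  direction proportions per segment x period x kind;
* **simulates** ground-truthed preparations whose event statistics,
  evacuation times and rates are calibrated to the published group
  values, so every stage is testable although the original videos are
  not deposited.

Intended for researchers quantifying gut motility from organ-bath video
recordings (fish or other small-animal preparations) and for anyone who
needs a ground-truthed testbed for kymograph event detection.

## Worked example

```python
import numpy as np
from gutmotion import (default_params, draw_scenario, render_preparation,
                       partition_segments, bet_from_matrix)
from gutmotion.synthetic_data import analyze_preparation
from gutmotion.summary import summarize

params = default_params("cellulose")          # published-statistics calibration
scenario = draw_scenario(params, n_preparations=1, seed=0)
truth = scenario.preparations[0]
res = analyze_preparation(truth)              # BET -> windows -> detection

print(f"BET = {res['bet'].bet_h:.2f} h (alpha = {res['bet'].alpha:.2f} mm)")
df = summarize([res])
cell = df[(df.segment == 1) & (df.period == "I") & (df.kind == "standing")]
print(cell[["n_events", "frequency_cpm_mm_mean", "amplitude_pct_median"]])
```

prints (seed 0):

```
BET = 0.92 h (alpha = 4.59 mm)
   n_events  frequency_cpm_mm_mean  amplitude_pct_median
0      2630               1.399697             47.644275
```

i.e. this simulated cellulose-fed bulbous emptied after 0.92 h, and while
the bolus was present the pipeline recovered ~1.40 standing contractions
per minute per mm of Segment 1 (nominal 1.5) with a median amplitude near
the calibrated 47.4 % diameter reduction.

A thin CLI wraps the same functions:

```sh
gutmotion simulate --treatment cellulose --n 6 --seed 42 --out sim/
gutmotion bet sim/cellulose-01.tsv
gutmotion detect sim/cellulose-01.tsv --out events.tsv
gutmotion stmap sim/cellulose-01.tsv map.png
```

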