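# feedkit

Quantitative eating-behavior analysis for freely moving nonhuman
primates.  Feeding behavior splits into an **appetitive** phase
(searching for and approaching the food) and a **consummatory** phase
(actually eating it), and the motivational state of an animal — how
hungry it is, how palatable it finds the food — shows up in simple
indices of each phase.  `feedkit` computes those indices from two
independent measurement routes and compares them:

* the **manual route** (`M-` indices), from timestamped ethogram logs
  produced by human coders: approach frequency *M-AF*, appetitive
  (food-zone) duration *M-AD*, approach latency *M-AL* (censored at
  900 s when the food is never touched), the composite score
  *M-AC = AF/AL*, cheek-push frequency *M-CF* and consummatory
  (chewing) duration *M-CD*;
* the **pose route** (`D-` indices), from markerless pose-estimation
  coordinate exports (per frame and body part: `x`, `y`, `likelihood`
  at 30 frames/s): tray-approach frequency *D-AF*, food-zone duration
  *D-AD* and feeding-bout frequency *D-CF*.

The pose route works on cleaned trajectories — keypoints with
likelihood < 0.7 are dropped and linearly interpolated — and on simple,
explicit operational definitions: a tray approach is a hand entering a
circle around the tray (same-hand entries closer than 0.5 s collapse to
the first); the food-zone duration is the time the body center sits
right of the food zone's left edge; a bout is a hand entering a circle
around the (moving) mouth after that same hand visited the tray within
the preceding 3 s.

On top of the indices the package provides the temporal and spatial
summaries used to characterise sessions (5-min bins with a qualitative
pattern classifier, forward-window temporal event density, occupancy
heatmaps, 1-s averaged posture trajectories), the statistics used to
rank indices and compare routes (paired t-tests, the
direction+significance performance score, Bland–Altman limits of
agreement, normalized 2D hunger/palatability plots), and a synthetic
session generator that plants ground-truth events so the whole pipeline
is testable without any video data.

## Worked example

```python
from feedkit import (
    filter_interpolate, tray_approaches, detect_bouts, food_zone_occupancy,
    deep_indices, manual_indices, simulate_pose, simulate_ethogram,
    SessionDesign, bin_index, classify_pattern,
)
from feedkit.synthetic import random_session_spec

# a 20-min synthetic session with 5 % keypoint dropout
spec = random_session_spec(seed=7, dropout_prob=0.05)
track, truth = simulate_pose(spec)

clean = filter_interpolate(track, spec.zone.likelihood_threshold)
tray  = tray_approaches(clean, spec.zone)
bouts = detect_bouts(clean, spec.zone)
occ   = food_zone_occupancy(clean, spec.zone)

design = SessionDesign(subject_id="A", internal_state="hunger",
                       food="palatable", condition="artificial-1",
                       test_type="one-food")
deep = deep_indices(tray, bouts, occ, design)
print("pose route   :", {k: round(v, 1) for k, v in deep.values.items()})

log, _ = simulate_ethogram(spec)
print("manual route :", manual_indices(log, design).values)

binned = bin_index(tray)
print("5-min bins   :", binned.values.tolist(), "->", classify_pattern(binned.values))
```

prints

```
pose route   : {'D_AF': 24.0, 'D_AD': 154.9, 'D_CF': 10.0}
manual route : {'M_AF': 24.0, 'M_AD': 154.9, 'M_AL': 36.38, 'M_AC': 0.66, ...}
5-min bins   : [5.0, 7.0, 4.0, 8.0] -> unclassified
```

Despite 5 % simulated tracking dropout, the pose route recovers the
planted session exactly: 24 tray entries, 154.9 s in the food zone and
10 bouts, matching both the generator's ground truth and the manual
route.  *M-AL* = 36.38 s is the first-approach latency, and
*M-AC* ≈ 0.66 approaches/s-of-latency is the composite appetitive
score.  The per-bin tray-entry counts fluctuate without a dominant
early peak, so the pattern classifier declines to assign one of the
four canonical session shapes.

A command-line interface wraps the same pipeline
(`feedkit synth | preprocess | events | indices | dynamics | score |
agree | run`); every output directory carries a JSON manifest with
config and input digests for reproducibility.

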