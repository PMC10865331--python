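# Methods

## Scope and data model

`feedkit` analyses single feeding sessions of a freely moving primate
in a test cage with a food tray.  Two test designs are supported: a
one-food test (one palatable or unpalatable stimulus, 1200 s) and a
pairwise-food test (both stimuli side by side, 900 s).  Sessions are
identified by subject, internal state (hunger / neutral / satiety),
food stimulus and replicate condition (two artificial-food runs, one
natural-food run).

Inputs are (a) pose coordinate tables in the standard markerless
pose-estimation CSV dialect — a three-row header (scorer / body part /
coordinate) over `x`, `y`, `likelihood` triplets, one row per frame at
30 frames/s, with keypoints head-top, mouth, body center, both hands,
both feet and tail; an HDF5 variant is read the same way — and (b)
ethogram CSV exports of manual coding: point events and state
intervals with behavior codes drawn from a user-extensible codebook.
Image coordinates have their origin at the top-left with y increasing
downward; time is `frame_index / fps`; state intervals are half-open
`[onset, offset)`.  Frame indices must be gap-free: exports with
dropped rows are rejected, and `repair_frame_index` reindexes them
explicitly, filling missing frames with likelihood 0 so the filtering
stage treats them as unobserved.

## Trajectory cleaning

Keypoint samples with likelihood strictly below the threshold (default
0.7; a sample at exactly 0.7 is kept) are treated as missing and
replaced by linear interpolation between the nearest flanking
confident samples, independently per body part and coordinate.
Leading/trailing low-confidence runs have no flanking sample on one
side and are filled by holding the nearest confident value — holding
avoids extrapolation artifacts at session edges.  Replaced samples
keep their original likelihood and receive a provenance flag
(`observed` / `interpolated` / `boundary-filled`), which makes the
filter idempotent and the cleaning auditable.  Likelihood values are
never themselves interpolated.  No smoothing beyond this linear
interpolation is applied.

The pixel scale defaults to 5.77 px/cm (the study's camera geometry);
`to_cm` divides pixel distances by it.

## Event detection

**Tray approaches (D-AF).**  A hand enters the tray zone — a circle
around the tray center, boundary inclusive — when its per-frame inside
mask transitions false→true (a first frame already inside counts at
t = 0).  Same-hand entries closer together than the minimum event
interval (0.5 s) are implausible at 30 frames/s and collapse to the
first: the de-duplication is greedy and sequential — after a kept
event, subsequent same-hand entries are suppressed until the interval
has elapsed, and the next surviving event restarts the clock.  The
constraint is applied per hand, so left- and right-hand entries 0.2 s
apart both count.  With two trays (pairwise sessions) the inside mask
is the union over trays and each surviving entry is attributed to the
nearest tray center at its entry frame.

**Food-zone occupancy (D-AD).**  Intervals at frame resolution where
the body center's x exceeds the food zone's left edge; a run of frames
`f0..f1` maps to `[f0/fps, (f1+1)/fps)`.

**Bouts (D-CF).**  Per hand, entries into the mouth zone — a circle
centered on the per-frame mouth keypoint, i.e. a zone that moves with
the animal; its radius is a calibration input since no canonical value
exists — are detected and de-duplicated exactly like tray entries.  An
entry at time t is a bout iff the same hand was inside the tray zone
at least once during the closed window `[t − 3 s, t]`, evaluated on
the per-frame inside mask (presence-based, not on de-duplicated
events).  Consummatory behaviors finer than bouts (chewing, cheek
pushing) are not derivable from pose coordinates at this spatial
resolution and remain manual-route-only.

## Indices

Manual indices count/accumulate codebook records: *M-AF* approach
points; *M-AD* food-zone state time; *M-AL* onset of the first
approach, stored as the 900 s censoring bound plus a censored flag
when no approach occurs; *M-AC = M-AF / M-AL*, reported missing when
*M-AL* is censored (dividing by a censoring bound would fabricate
precision); *M-CF* cheek-push points; *M-CD* chewing state time.
Pairwise sessions yield per-food *M-AF*, *M-AL*, drop counts and
latencies (*M-AF-d*, *M-AL-d*) and the consummatory amount *CA*
(grams when an intake `value` column is present, items otherwise; the
unit travels with the value).  The approach-per-intake ratio
*M-AF / CA* checks whether the amount taken per approach varies with
internal state.  Pose indices aggregate the detectors: *D-AF* total
de-duplicated tray entries (both hands), *D-AD* summed occupancy,
*D-CF* total bouts; the three inputs must agree on session duration.

## Temporal and spatial summaries

Indices are re-computed per 5-min bin of the 20-min session (counts by
timestamp, durations split at bin boundaries, so bin sums always equal
session totals; a trailing partial bin warns).  The four qualitative
session shapes are assigned by fixed rules over the 4-bin profile —
*early decline*: bin 1 maximal and bin 2 ≤ half of it; *mid-peak with
early incline*: maximum at bin 2/3 with bin 1 strictly below it; *late
decline*: bins 1–3 within 20 % of their mean and bin 4 below half that
mean; *steady decline*: monotone non-increasing without the sharp early
drop; precedence early > mid-peak > late > steady, anything else (and
all-zero profiles) unclassified.  The original classification was
qualitative; these rules are one deterministic, testable realisation of
the four described shapes.

The temporal density of an event series at time t is the number of
events in the forward window `[t, t + 5 s)` divided by the window
length, evaluated at every frame time; windows reaching past the
session end are truncated and divided by their actual length.  The
whole-session evaluation grid is a choice of this implementation —
only "at a specific moment" is prescribed.  Partitioning the session
into consecutive window-length pieces and summing `density × effective
length` at the piece starts recovers the exact event count
(`DensityTrace.integrate`), which the tests assert to 1e-9.

Occupancy heatmaps histogram a keypoint's per-frame position on a grid
(default 50×50 over the cage extent) and divide by the frame count, so
in-frame proportions sum to 1 and coarse cells equal the sum of their
refined sub-cells.  Posture trajectories average head-top, mouth and
body center per 1-s step over the first minute, with the connecting
head–mouth and mouth–body segments; an optional trailing-trace export
keeps the raw previous 0.3 s per frame for animation.

## Statistics and scoring

Within-subject state/food contrasts use two-sided paired t-tests
(`scipy.stats.ttest_rel`); a Wilcoxon signed-rank alternative and an
optional Bonferroni adjustment are provided but off by default.  The
*altogether* flag is true iff every per-subject difference is nonzero
and shares one sign — a zero difference conservatively breaks it.
Zero-variance differences leave the p-value missing.  The performance
score per comparison is 1 point for altogether plus 2 points if
p < 0.01, else 1 if p < 0.05, else 0 (strict inequalities); direction
and significance points can both accrue from the same comparison, and
totals accumulate across the replicate conditions.

Route agreement uses Pearson correlation (r, R², two-tailed p; missing
below n = 3 or for constant vectors) and Bland–Altman statistics: bias
= mean(manual − deep), SD of bias with ddof = 1, limits of agreement
bias ± 1.96·SD.  2D plots place each (subject, state, food) cell by a
palatability-specific index (x) and a hunger-specific index (y); the
normalized variant divides each subject's values by that subject's
hunger-palatable cell, which therefore maps to exactly (1, 1).

## Synthetic sessions

Because the study's videos are not deposited, the generator emulates
the *structure* of the data, not its appearance.  A planted schedule —
tray entries per hand, bout lags, occupancy segments, plus the
manual-coding side (approaches, food-zone states, chewing, cheek
pushes, intake) — is realised as an 8-keypoint pose track: hands rest
away from all zones and make cosine-eased excursions to the tray or
mouth, holding an 8 px guard margin outside the zone boundary until
the planted entry frame, so the inside mask transitions exactly there
even under Gaussian jitter (default SD 1 px, several times smaller
than the margin).  Event times come from hard-core renewal processes
(exponential gaps plus a 2 s minimum spacing, alternated between
hands) so planted counts are unambiguous under de-duplication.  Bout
lags are drawn in [1.0, 2.8] s — inside the 3 s look-back; lags in the
ambiguity band (look-back, look-back + dwell] are rejected by the spec
validator because the dwell would leave tray presence inside the
look-back window, making the planted negative undetectable as such.

Tracking failure is emulated as likelihood dropout: geometric runs
(mean 2 frames) whose overall frequency matches the requested dropout
fraction, with likelihood pushed below threshold and coordinates
scrambled uniformly over the image.  The cleaning stage must repair
these; with 10 % dropout, recovered counts stay within 5 % of truth on
the standard session.

Default rates describe a motivated animal in a 20-min test: ~20–30
tray approaches, ~40 % followed by a bout, a few hundred seconds of
food-zone occupancy, sparser consummatory records.  A full experiment
(3 subjects × 3 conditions × {hunger, satiety} × {palatable,
unpalatable}) scales each cell's rates by `1 + hunger_effect` and
`1 + palatability_effect` on top of a per-subject baseline drawn once,
so with zero effects the per-subject state difference is continuous
and symmetric around zero and the all-same-direction probability is
the 2·(1/2)³ = 25 % sign-agreement null.

What the generator does **not** emulate: real pose-estimator error
structure (correlated drift, identity swaps, occlusion geometry),
inter-coder disagreement on the manual side, or any visual content.
Both routes see the same planted schedule, so near-perfect
manual-vs-pose agreement on synthetic experiments demonstrates
pipeline consistency, not real-world inter-method agreement — the
generator cannot stand in for animal data on that question.

## Numerical choices and limitations

* Zone boundaries are inclusive (distance ≤ radius counts as inside).
* Likelihood threshold comparison is strict (`< 0.7` removed).
* Acceptance-style checks run at session scale (1200 s, 36,000 frames)
  with a handful of seeds, and 200-seed batches for the
  directional-consistency rates; these sizes keep the full suite under
  a minute while leaving the binomial null check a ±4σ band.
* With three subjects the paired t-test has 2 degrees of freedom;
  p-values are reported as computed and should be read alongside the
  altogether flag, as in the scoring rule.
* Manual and pose food-zone definitions are treated as independently
  calibrated; the tool does not force M-AD and D-AD onto the same
  geometry.
* Latency censoring uses the 900 s bound for both test designs;
  censored values are excluded from means downstream and make the
  composite score missing.
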