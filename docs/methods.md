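# Methods

## The measurement model

Swung eighth notes phrase each quarter note as an eighth-note triplet of
which only the first and third members are played.  On a canonical grid of
960 ticks per quarter note, the triplet anchors sit at 0 ("base" notes,
nominally on the metronome click), 320 (the rarely played middle-triplet
position) and 640 ("swing" notes, the offbeat).  All timing in the package
is carried in ticks as real numbers; 1 tick = 60000 / (960 · BPM) ms.

**Classification.**  Every note is assigned to the nearest anchor with a
half-open window of ±160 ticks (half a triplet).  A residue exactly 160
ticks past an anchor belongs to the *next* anchor with signed offset −160,
so offsets always lie in [−160, 160).  Residues in [800, 960) wrap to the
next quarter's base anchor with a negative offset: a base note struck
slightly early still counts against its own click, and class means are
computed on these wrap-aware signed offsets (which is why a recording can
have a negative mean base position).  The window half-width is a design
choice: the triplet sketch fixes the bin structure, but no exact boundary
is published, so the natural "half a triplet, half-open" rule is used and
exposed in one place (`grid.HALF_WINDOW`).

**Temporal bins and chords.**  All notes sharing one (quarter, anchor)
slot form a temporal bin; a chord contributes one timing value, that of
its earliest onset.  The earliest-onset rule is applied uniformly — to
class means, deviation statistics and manipulation — not only to the
serial correlations where it is strictly required; `sigma_mode="all"`
switches the spread and swing-ratio statistics to per-note accounting for
comparison.

**Deviations.**  The microtiming deviation (MTD) of a bin is its signed
offset minus the mean offset of its class in that recording.  Defining
deviations about the per-recording class means absorbs both an
intentional ahead/behind-the-beat feel (mean base offset b̄) and the
recording's average swing ratio into the reference grid, and makes the
deviations mean-zero per class by construction.

**Summary statistics.**  σ_b and σ_s are standard deviations of the class
deviations (n−1 divisor — a sample-statistics convention; the choice is
invisible at realistic n) converted to milliseconds.  The average swing
ratio is the mean of per-note ratios r_i = (p mod 960)/(960 − (p mod 960))
over swing notes (2 = exact triplets, 1 = straight eighths), with δ_r its
standard deviation.  Because r_i is convex in the position, the mean of
per-note ratios exceeds the ratio at the mean position whenever there is
jitter; the package computes the former.  Serial structure is measured by
Spearman rank correlations over pairs (base bin, next swing bin) and
(swing bin, next base bin) no more than one quarter note apart; the
distance is measured between bin anchor times, so a badly dragged note
still pairs with its own beat's partner (raw-onset distance is available
behind a flag).  Ties — common after integer-tick rounding — get average
ranks.  Directions with fewer than 3 pairs are reported missing.

## Manipulation

Each deviation is multiplied by a constant m and the note re-placed at
`quarter_start + anchor + class_mean_offset + m·d`.  Presets: quantized
(m = 0), exaggerated (m = 2), inverted (m = −1), original (m = 1).
Because deviations are mean-zero, the class means — and hence the average
swing ratio and any laid-back feel — are preserved for every m.  Nothing
but onsets changes: velocities, durations, channels, sustain-pedal and
all other non-note MIDI events pass through byte-identical.  Chord bins
move rigidly by default (`chord_mode="rigid_bin"`), preserving the strum
spread inside the chord; `per_note` scales each chord tone by its own
deviation instead.  Results stay fractional in memory; rounding
half-away-from-zero to integer ticks happens only at MIDI write time.

Two degenerate regimes are handled explicitly: onsets that would become
negative are clamped to zero with a warning, and note-order crossings
introduced by a large |m| are permitted but reported.  One limitation is
worth stating plainly: the identity "re-analysis of the m-scaled piece
yields exactly m-scaled statistics" holds only while every |m·d| (plus
chord strum spread) stays inside the ±160-tick window.  A deviation
scaled past the window boundary is re-classified to a different grid slot
on re-analysis, which is a property of the measurement, not a bug of the
manipulation; the exact-algebra tests therefore use a low-noise fixture
(σ = 6 ms) where the m = 2 boundary lies more than five standard
deviations out, while statistical tests run at the realistic σ ≈ 18.5 ms.

`verify_manipulation` re-analyzes both versions and checks mean
preservation, d′ = m·d per bin, and content equality, with a half-tick
tolerance that covers file round trips.

## Synthetic performances

The generator emulates a metronomic solo recording of swung eighths: one
base and one swing bin per quarter, optional chords (2–4 tones with a
1–12-tick strum after the earliest onset), and a small fraction of
middle-triplet notes.  Defaults are the aggregate conditions observed in
real recordings: 150 BPM, σ = 18.5 ms per note, lag-1 rank correlation
0.5, average swing ratio 1.9, middle-note fraction 0.7%.  The deviation
sequence interleaves base and swing notes, so the requested lag-1
dependence is exactly what the base→swing / swing→base correlations
estimate.  Noise models: white Gaussian, AR(1), and 1/f^β noise by
spectral synthesis (β free, default 0.8) for long-range correlated
series.

Two calibrations align generator targets with analyzer definitions:

* **Swing anchor.**  Solving E[r(anchor + noise)] = target_r numerically
  (expectation over the window-truncated Gaussian) rather than placing
  the anchor at 960·r/(1+r); the convexity of r(p) would otherwise
  inflate the analyzed mean ratio by ≈ 0.05 at the default noise scale.
  With σ = 0 the solution reduces to the exact inverse, so a noiseless
  target of 2 puts swing notes exactly at 640 ticks.
* **Serial correlation.**  `serial_rho` is a *Spearman* target; the
  underlying Gaussian lag-1 Pearson coefficient is set to
  2·sin(π·ρ/6).  The distinction is small (≈ 0.017 at ρ = 0.5) but
  systematic, and would otherwise eat most of a 3-standard-error
  recovery budget.

Deviations that would leave their class window are redrawn from the
marginal (i.i.d.) distribution, with a counter reporting how often; at
default scale this is a > 3.5σ event.  Redrawing preserves the Gaussian
shape inside the window but mildly weakens the serial dependence at the
redrawn positions — invisible at the tested tolerances.  What the
generator does **not** emulate: melody/harmony (pitches are random
diatonic notes), tempo drift, phrase structure, a backing rhythm
section, or the power-law *magnitude* profile of any specific performer.
Passing recovery tests therefore validates the measurement pipeline, not
any musical claim about real recordings.

## Rating statistics

Ordinal ratings (1–4) of two conditions of a piece are compared by the
Mann–Whitney AUC, A = P(X > Y) + ½P(X = Y), with X the manipulated and Y
the original condition, so A < 0.5 means the original is preferred.  The
variance uses DeLong structural components with the tie-adjusted ½
kernel — on a 4-point scale ties dominate and the unadjusted kernel
would be badly miscalibrated — and the design is between-subjects, so
the unpaired form applies.  The 95% interval is the normal approximation
clipped to [0, 1]; the interval containing 0.5 is the "no detectable
difference" criterion.  The ROC curve is the polygon of cumulative
proportions from category 4 down to 1; its trapezoidal area equals the
Mann–Whitney AUC identically, which the tests exploit as an invariant.
Interval calibration is checked empirically: on a latent-binormal
ordinal model (n = 100 per condition, a size chosen for the asymptotic
regime, comparable to pooled per-condition survey counts) 1000 replicate
intervals cover the true discretized-scale AUC at 95% ± 2 points.  No
multiple-testing correction is applied across pieces, matching how
per-piece intervals are conventionally reported in this design.

`export_long_table` emits the long-format participant × piece ×
condition × rating table that ordinal mixed-model software consumes and
enforces the between-subjects constraint (one condition per participant
per piece).  Fitting the proportional-odds mixed model itself is out of
scope by design — it is a standard fit for existing statistics packages.

## Problem sizes and numerical choices

Statistical tests run at 5000 bins (3-standard-error bands), the
interval-coverage check at 1000 replicates, and oracle-equivalence
checks on dozens of small random vectors with exact (1e-12 … 1e-14)
tolerances; the whole suite completes in seconds.  MIDI round trips are
exact for source resolutions dividing 960 and bounded by half a tick
otherwise.  Overlapping same-pitch notes are matched first-in-first-out;
note-on with velocity 0 counts as note-off; a dangling note-on is closed
at end of track with a warning.  Tempo is modelled as a single constant
BPM (the recordings are metronomic); additional tempo events are
preserved verbatim but ignored for unit conversion, with a warning.

## Reproducing published per-piece values

The per-piece reproduction tests (`TestDepositedRecordings`) compare
against the published statistics of the twelve studio recordings and the
survey's per-piece AUCs.  The raw MIDI files and survey data are
distributed as the original study's supporting information and are not
bundled; place the MIDI files under `data/deposited/` and a long-format
survey CSV at `data/deposited/survey.csv` to run them.  Without the
archive these tests fail with a pointer to this section rather than
silently skipping.
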