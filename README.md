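# swingtiming

Tools for quantifying and manipulating the **microtiming deviations
(MTDs)** of swung-eighth-note MIDI performances, and for evaluating how
listeners rate the results.

When a jazz soloist plays swung eighths over a metronomic rhythm
section, each note lands near — but not on — a triplet grid: "base"
notes near the quarter-note click, "swing" notes near the third triplet
position.  Whether the few-tens-of-milliseconds deviations from that
grid help create the *swing feel* is a long-standing debate in music
psychology (the "participatory discrepancies" hypothesis).  Testing it
requires exactly the machinery this package provides: measuring a
recording's MTDs against its own average grid, rescaling them
systematically without touching anything else in the performance, and
comparing listener ratings of the versions.  It is aimed at researchers
in music cognition and rhythm production who work with solo MIDI
recordings at constant nominal tempo.

## The model

All timing lives on a canonical grid of 960 ticks per quarter note.
Each note is classified by its position p mod 960 to the nearest triplet
anchor {0, 320, 640} (window ±160 ticks, half-open); middle-triplet
notes (anchor 320) are counted but never analyzed or moved.  For one
recording with mean base position b̄ and mean swing position s̄, the MTD
of a note is its deviation from its class mean,

    d_i = (p_i mod 960) − b̄        (base notes)
    d_i = (p_i mod 960) − s̄        (swing notes),

one value per temporal bin (chords count once, via their earliest
onset).  The average swing ratio is the mean of per-note ratios

    r_i = (p_i mod 960) / (960 − (p_i mod 960)),   i ∈ swing notes,

with r = 2 for exact triplets and r = 1 for straight eighths.  Serial
structure is measured by Spearman's ρ between deviations of neighbouring
base→swing and swing→base bins at most one quarter note apart.

Manipulation multiplies every deviation by a constant m and re-places
the note at its class mean plus m·d_i: **quantized** (m = 0),
**exaggerated** (m = 2), **inverted** (m = −1).  Because deviations are
mean-zero, b̄ and s̄ — and with them the average swing ratio and any
intentional laid-back feel — are preserved for every m, and velocities,
durations and sustain-pedal data pass through untouched.

Rating samples (4-point ordinal scale) are compared by the Mann–Whitney
AUC, `A = P(X > Y) + ½P(X = Y)`, with DeLong structural-component
variance (tie-adjusted, unpaired) for 95% confidence intervals; an
interval containing 0.5 means the two versions are not distinguishable.

## Worked example

Generate a synthetic performance with realistic statistics, analyze it,
quantize it, and compare two rating samples:

```python
from swingtiming import (
    DeviationScaler, MicrotimingAnalyzer, RatingSample, SynthSpec,
    generate_performance, roc_auc,
)

res = generate_performance(SynthSpec(n_quarters=400, seed=1))
an = MicrotimingAnalyzer().fit(res.performance)
print(f"b_bar={an.b_bar_:.2f} ticks  s_bar={an.s_bar_:.2f} ticks")
print(f"sigma_b={an.sigma_b_ms_:.2f} ms  sigma_s={an.sigma_s_ms_:.2f} ms")
print(f"r={an.r_:.3f}  delta_r={an.delta_r_:.3f}")
print(f"rho_b_to_s={an.rho_b_to_s_:.3f}  rho_s_to_b={an.rho_s_to_b_:.3f}")

quantized = DeviationScaler(preset="quantized").fit_transform(res.performance)
qa = MicrotimingAnalyzer().fit(quantized)
print(f"after quantization: sigma_b={qa.sigma_b_ms_:.2e} ms  b_bar={qa.b_bar_:.2f}")

inverted = RatingSample("Jordu", "inverted", (1,)*5 + (2,)*16 + (3,)*14 + (4,)*5)
original = RatingSample("Jordu", "original", (1,)*2 + (2,)*8 + (3,)*17 + (4,)*13)
roc = roc_auc(inverted, original)
print(f"AUC={roc.auc:.2f}  95% CI=({roc.ci_low:.2f}, {roc.ci_high:.2f})")
```

prints

```
b_bar=-6.23 ticks  s_bar=619.26 ticks
sigma_b=17.77 ms  sigma_s=17.63 ms
r=1.862  delta_r=0.366
rho_b_to_s=0.442  rho_s_to_b=0.478
after quantization: sigma_b=5.59e-12 ms  b_bar=-6.23
AUC=0.33  95% CI=(0.22, 0.44)
```

The analyzer recovers the generator's conditions (σ = 18.5 ms per note,
rank correlation 0.5, average ratio 1.9) up to sampling noise at 400
quarters; quantization drives the deviation spread to numerical zero
while b̄ is untouched.  The AUC of 0.33 with an interval excluding 0.5
says the "inverted" sample was rated reliably below the "original" one.

The same operations are available from a shell:

```sh
swingtiming synth piece.mid --n-quarters 200 --seed 1 --truth truth.csv
swingtiming analyze piece.mid --csv report.csv --deviations devs.csv
swingtiming manipulate piece.mid quantized.mid --preset quantized --report check.json
swingtiming roc ratings.csv --piece Jordu --condition-a inverted
```

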