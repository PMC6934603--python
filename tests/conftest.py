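"""Shared fixtures: small deterministic performances built in memory."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from swingtiming import NoteEvent, Performance, SynthSpec, generate_performance
from swingtiming.midi_io import PassthroughEvent


def make_performance(onsets, bpm=120.0, pitch=60, velocity=80, duration=200.0):
    """Performance from bare onsets; distinct pitches keep sorting stable."""
    notes = [
        NoteEvent(onset=float(t), pitch=pitch + (i % 12), velocity=velocity, duration=duration)
        for i, t in enumerate(onsets)
    ]
    return Performance(notes=notes, bpm=bpm)


@pytest.fixture
def quantized_perf():
    """Eight quarters of perfectly placed base (0) and swing (640) notes."""
    onsets = []
    for q in range(8):
        onsets += [q * 960, q * 960 + 640]
    return make_performance(onsets)


@pytest.fixture
def jittered_perf():
    """Base/swing notes with fixed, hand-written deviations (mean zero)."""
    base_dev = [10, -10, 20, -20, 5, -5, 15, -15]
    swing_dev = [-8, 8, -16, 16, -4, 4, -12, 12]
    onsets = []
    for q, (db, ds) in enumerate(zip(base_dev, swing_dev)):
        onsets += [q * 960 + 960 + db, q * 960 + 960 + 627 + ds]  # s_bar = 627
    return make_performance(onsets)


@pytest.fixture
def pedalled_perf(quantized_perf):
    """Quantized fixture plus CC64 sustain events and a tempo event."""
    pedal = [
        PassthroughEvent(tick=0.0, kind="channel", status=0xB0, data=bytes([64, 127])),
        PassthroughEvent(tick=1920.0, kind="channel", status=0xB0, data=bytes([64, 0])),
    ]
    perf = quantized_perf.with_notes(quantized_perf.notes)
    perf.passthrough_events = pedal
    return perf


@pytest.fixture
def synthetic_result():
    """Moderate synthetic performance with chords and middle notes."""
    return generate_performance(
        SynthSpec(n_quarters=300, seed=42, chord_prob=0.2, middle_note_frac=0.02)
    )


@pytest.fixture
def mild_synth_perf():
    """Low-noise synthetic performance for exact scaling-algebra checks.

    Multiplicative deviation scaling is an exact re-analyzable identity
    only while |m*d| (plus chord strum spread) stays inside the
    half-triplet window, so no note changes grid class; 6 ms of noise
    puts the m=2 boundary more than five sigma away.
    """
    return generate_performance(
        SynthSpec(n_quarters=240, sigma_ms=6.0, seed=17, chord_prob=0.2, middle_note_frac=0.01)
    ).performance


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
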