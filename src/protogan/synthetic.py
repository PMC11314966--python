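"""Labeled synthetic EEG-like signals for download-free end-to-end runs.

Each class archetype produces band-limited noise plus a sparse sinusoid
mixture inside a dominant frequency band, affinely scaled into an
amplitude range, optionally decorated with periodic epileptiform-style
transients (sharp waves of 70-200 ms, or spike-and-slow-wave complexes
whose slow component lasts 200-500 ms).  The three default archetypes
emulate, in caricature, healthy scalp EEG (fast, moderate amplitude),
inter-ictal iEEG (slow, low amplitude), and ictal iEEG (transient-rich,
high amplitude).  Spectral structure, amplitude and imbalance are the
only realism targets; morphology, nonstationarity and artifacts of real
recordings are not modelled.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import filtfilt, firwin

from .io import SignalRecord

__all__ = [
    "ClassArchetype",
    "DEFAULT_ARCHETYPES",
    "generate_class_signal",
    "generate_dataset",
    "proportional_counts",
    "write_bonn_ascii",
    "write_edf",
]


@dataclass(frozen=True)
class ClassArchetype:
    """A synthetic signal class: amplitude range, dominant band, transients."""

    name: str
    amp_range: tuple  # (lo, hi) in microvolts
    band: tuple  # dominant band (lo, hi) in Hz
    transient: str | None = None  # None | 'sharp' | 'spike_slow'
    noise_sd: float = 0.15  # relative white-noise level

    def __post_init__(self):
        if not self.amp_range[0] < self.amp_range[1]:
            raise ValueError(f"{self.name}: degenerate amplitude range")
        if not 0.5 <= self.band[0] < self.band[1] <= 40.0:
            raise ValueError(f"{self.name}: band must lie inside [0.5, 40] Hz")
        if self.transient not in (None, "sharp", "spike_slow"):
            raise ValueError(f"{self.name}: unknown transient {self.transient!r}")


DEFAULT_ARCHETYPES = (
    # healthy-like: fast activity, moderate-to-high amplitude
    ClassArchetype("healthy", (-180.0, 100.0), (18.0, 30.0)),
    # inter-ictal-like: slow activity, low amplitude
    ClassArchetype("interictal", (-70.0, 70.0), (1.0, 4.0)),
    # ictal-like: spike-and-slow-wave bursts over 2-12 Hz rhythmic activity
    ClassArchetype("ictal", (-300.0, 300.0), (2.0, 12.0), transient="spike_slow"),
)


def _bandlimited_noise(n, fs, band, rng):
    white = rng.standard_normal(n + 400)
    numtaps = 201 if n + 400 > 603 else max(31, (n + 400) // 4 * 2 + 1)
    taps = firwin(numtaps, list(band), pass_zero="bandpass", fs=fs)
    x = filtfilt(taps, [1.0], white, padlen=min(3 * numtaps, n + 399))
    x = x[200 : 200 + n]
    return x / max(x.std(), 1e-12)


def _sharp_wave(fs, width_s=0.12):
    """Monophasic (negative) deflection; 70-200 ms in real recordings."""
    n = max(int(round(width_s * fs)), 3)
    t = np.linspace(-1.0, 1.0, n)
    return -np.exp(-0.5 * (t / 0.35) ** 2)


def _spike_slow_complex(fs):
    """Spike (~70 ms) followed by a dominant ~350 ms slow wave."""
    spike = 0.8 * _sharp_wave(fs, width_s=0.07)
    slow = np.sin(np.linspace(0, np.pi, max(int(round(0.35 * fs)), 4)))
    return np.concatenate([spike, 1.2 * slow])


#: burst cadence of transient-rich archetypes (seconds)
_TRANSIENT_PERIOD_S = 1.5


def generate_class_signal(
    a: ClassArchetype, fs: float, duration: float, seed=None
) -> SignalRecord:
    """Deterministically synthesize one signal of archetype ``a``.

    Class members are time-shifted copies of a fixed template - a
    three-tone mixture at fixed in-band frequencies plus (optionally) a
    periodic transient train - corrupted by band-limited and white noise,
    then scaled into the amplitude range.  Only the time shift and the
    noise vary between members, which keeps each class's time-frequency
    signature highly stereotyped.
    """
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration * fs must be at least 2 samples")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = 2.0 * a.noise_sd * _bandlimited_noise(n, fs, a.band, rng)
    lo, hi = a.band
    t0 = rng.uniform(0.0, 1.0)  # global time shift of the template
    t = np.arange(n) / fs - t0
    for pos, amp, phase in ((0.2, 1.0, 0.0), (0.5, 0.7, 0.9), (0.8, 0.5, 1.7)):
        f = lo + pos * (hi - lo)
        x = x + amp * np.sin(2 * np.pi * f * t + phase)
    x = x / np.abs(x).max()
    if a.transient is not None:
        shape = _sharp_wave(fs) if a.transient == "sharp" else _spike_slow_complex(fs)
        pos = t0 % _TRANSIENT_PERIOD_S
        while True:
            start = int(round(pos * fs))
            if start >= n:
                break
            end = min(start + shape.size, n)
            x[start:end] += 1.5 * shape[: end - start]
            pos += _TRANSIENT_PERIOD_S
    x = x + a.noise_sd * rng.standard_normal(n)
    lo, hi = a.amp_range
    xmin, xmax = x.min(), x.max()
    x = (x - xmin) / (xmax - xmin) * (hi - lo) + lo
    return SignalRecord(x, fs=fs, source_id=a.name, label=a.name)


def proportional_counts(ratios, n_total: int) -> list[int]:
    """Largest-remainder apportionment of ``n_total`` by integer ratios."""
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("ratios must be positive")
    quota = ratios / ratios.sum() * n_total
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for i in np.argsort(-remainder)[: n_total - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def generate_dataset(
    archetypes=DEFAULT_ARCHETYPES,
    ratios=(2, 2, 1),
    n_total: int = 300,
    fs: float = 173.61,
    duration: float = 23.6,
    seed: int = 0,
) -> list[SignalRecord]:
    """Labeled synthetic collection with exact proportional class counts.

    Per-class counts follow largest-remainder rounding of ``ratios``; the
    returned order is a seeded shuffle so classes are interleaved.
    """
    if len(ratios) != len(archetypes):
        raise ValueError("one ratio per archetype required")
    if n_total < sum(int(r) for r in ratios):
        raise ValueError("n_total smaller than the ratio total")
    counts = proportional_counts(ratios, n_total)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(sum(counts) + 1)
    records, i = [], 0
    for arch, count in zip(archetypes, counts):
        for j in range(count):
            rec = generate_class_signal(
                arch, fs, duration, np.random.default_rng(child_seeds[i])
            )
            rec.source_id = f"{arch.name}_{j:04d}"
            records.append(rec)
            i += 1
    order = np.random.default_rng(child_seeds[-1]).permutation(len(records))
    return [records[k] for k in order]


# ---------------------------------------------------------------------------
# fixture writers


def write_bonn_ascii(records, out_dir, labels_csv: str = "labels.csv"):
    """Write one-column ASCII files plus a labels CSV; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        name = f"{rec.source_id or f'record_{i:04d}'}.txt"
        np.savetxt(out_dir / name, rec.samples, fmt="%.6f")
        rows.append((name, rec.fs, rec.label or ""))
    with open(out_dir / labels_csv, "w") as fh:
        fh.write("file,fs,label\n")
        for name, fs, label in rows:
            fh.write(f"{name},{fs},{label}\n")
    return out_dir


def _edf_field(value, width: int) -> bytes:
    text = str(value)[:width]
    return text.ljust(width).encode("ascii")


def write_edf(path, records: dict):
    """Write a minimal 16-bit EDF file with one data record per channel set.

    ``records`` maps channel label -> :class:`SignalRecord`; all channels
    must share length and sampling rate.  The writer covers only what the
    round-trip tests of the EDF reader need (single data record, linear
    16-bit scaling) - it is a synthetic-fixture utility, not a general
    EDF exporter.
    """
    labels = list(records)
    recs = [records[ch] for ch in labels]
    n = recs[0].samples.size
    fs = recs[0].fs
    if any(r.samples.size != n or r.fs != fs for r in recs):
        raise ValueError("all channels must share length and sampling rate")
    ns = len(labels)
    duration = n / fs
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("synthetic fixture", 80),
            _edf_field("protogan test data", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (ns + 1), 8),
            _edf_field("", 44),
            _edf_field(1, 8),  # one data record
            _edf_field(f"{duration:.6g}", 8),
            _edf_field(ns, 4),
        ]
    )
    phys = []
    for r in recs:
        lo, hi = float(r.samples.min()), float(r.samples.max())
        if hi == lo:
            hi = lo + 1.0
        phys.append((lo, hi))
    per_signal = b"".join(
        [
            b"".join(_edf_field(ch, 16) for ch in labels),
            b"".join(_edf_field("synthetic", 80) for _ in labels),
            b"".join(_edf_field("uV", 8) for _ in labels),
            b"".join(_edf_field(f"{lo:.6g}"[:8], 8) for lo, _ in phys),
            b"".join(_edf_field(f"{hi:.6g}"[:8], 8) for _, hi in phys),
            b"".join(_edf_field(-32768, 8) for _ in labels),
            b"".join(_edf_field(32767, 8) for _ in labels),
            b"".join(_edf_field("", 80) for _ in labels),
            b"".join(_edf_field(n, 8) for _ in labels),
            b"".join(_edf_field("", 32) for _ in labels),
        ]
    )
    body = bytearray()
    for r, (lo, hi) in zip(recs, phys):
        digital = np.round(
            (r.samples - lo) / (hi - lo) * 65535.0 - 32768.0
        ).astype("<i2")
        body += struct.pack(f"<{n}h", *digital.tolist())
    Path(path).write_bytes(header + per_signal + bytes(body))
    return Path(path)
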