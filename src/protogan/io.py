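"""Reading raw EEG/iEEG signals.

Two on-disk forms are supported: Bonn-style one-column ASCII files (one
amplitude sample per line, sampling rate supplied by the caller) and EDF
recordings with channel selection by label (read through :mod:`mne`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["SignalRecord", "read_signal_ascii", "read_signal_edf"]


@dataclass
class SignalRecord:
    """A single-channel amplitude series in microvolts.

    Attributes
    ----------
    samples : ndarray
        Finite amplitude values.
    fs : float
        Sampling rate in Hz, strictly positive.
    source_id : str
        Provenance tag (file name, channel, segment index...).
    label : str or None
        Optional class tag, carried through preprocessing.
    """

    samples: np.ndarray
    fs: float
    source_id: str = ""
    label: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("signal has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite values")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


def read_signal_ascii(path, fs: float, label: str | None = None) -> SignalRecord:
    """Read a one-column numeric text file (Bonn record layout).

    Parameters
    ----------
    path : path-like
        File with one amplitude value per line; blank lines are ignored.
    fs : float
        Sampling rate in Hz (the format itself carries no timing metadata).
    """
    path = Path(path)
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno} is not numeric: {text!r}"
                ) from None
    if not values:
        raise ValueError(f"{path}: file contains no samples")
    return SignalRecord(np.array(values), fs=fs, source_id=path.name, label=label)


def read_signal_edf(path, channel: str, label: str | None = None) -> SignalRecord:
    """Read one channel of an EDF recording.

    Raises
    ------
    KeyError
        If ``channel`` is absent; the message lists the available channels.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    if channel not in raw.ch_names:
        raise KeyError(
            f"channel {channel!r} not in {Path(path).name}; "
            f"available: {', '.join(raw.ch_names)}"
        )
    raw = raw.pick([channel])
    raw.load_data(verbose="error")
    # mne scales EEG-typed channels to volts internally; undo to microvolts
    data = raw.get_data(units="uV")[0] if _has_unit_support(raw) else raw.get_data()[0]
    return SignalRecord(
        np.asarray(data, dtype=float),
        fs=float(raw.info["sfreq"]),
        source_id=f"{Path(path).name}:{channel}",
        label=label,
    )


def _has_unit_support(raw) -> bool:
    try:
        raw.get_data(units="uV", start=0, stop=1)
        return True
    except Exception:
        return False
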