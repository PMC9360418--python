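"""In-memory containers for continuous EEG and epoched data, with disk I/O.

Recordings are stored on disk as a compressed NPZ array (``signal`` in μV,
float32, channels x samples) next to a JSON sidecar carrying the sampling
rate, channel order and reference state.  EDF files can be read through
:mod:`mne` when available; all writers use the array container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .montage import Montage


@dataclass
class ContinuousRecording:
    """Continuous multichannel signal in μV tied to a montage.

    ``reference_state`` is ``"recording-reference"`` until average
    re-referencing, then ``"average"``.
    """

    signal: np.ndarray  # (n_channels, n_samples), μV
    rate: float  # samples / s
    montage: Montage
    reference_state: str = "recording-reference"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"signal has {self.signal.shape[0]} channels but montage has "
                f"{self.montage.n_channels}"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.rate * 1000.0

    def copy_with(self, signal: np.ndarray | None = None, **kw) -> "ContinuousRecording":
        return ContinuousRecording(
            signal=self.signal.copy() if signal is None else signal,
            rate=kw.get("rate", self.rate),
            montage=kw.get("montage", self.montage),
            reference_state=kw.get("reference_state", self.reference_state),
        )

    def save(self, path) -> None:
        """Write signal as compressed NPZ plus a ``.json`` metadata sidecar."""
        path = Path(path)
        np.savez_compressed(path, signal=self.signal.astype(np.float32))
        meta = {
            "rate": self.rate,
            "channels": list(self.montage.channels),
            "reference_state": self.reference_state,
            "units": "uV",
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path, montage: Montage) -> "ContinuousRecording":
        path = Path(path)
        if path.suffix.lower() == ".edf":
            return read_edf(path, montage)
        meta = json.loads(path.with_suffix(".json").read_text())
        if list(meta["channels"]) != list(montage.channels):
            raise ValueError("channel order in sidecar does not match montage")
        with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
            signal = data["signal"].astype(float)
        return cls(
            signal=signal,
            rate=float(meta["rate"]),
            montage=montage,
            reference_state=meta.get("reference_state", "recording-reference"),
        )


def read_edf(path, montage: Montage) -> ContinuousRecording:
    """Read an EDF recording (requires :mod:`mne`), mapped onto ``montage``."""
    import mne  # local import: optional dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    picks = [raw.ch_names.index(ch) for ch in montage.channels]
    signal = raw.get_data()[picks] * 1e6  # volts -> μV
    return ContinuousRecording(signal=signal, rate=float(raw.info["sfreq"]), montage=montage)


@dataclass
class EpochSet:
    """Per-condition stacks of stimulus-locked epochs for one subject visit.

    ``epochs`` maps condition -> array (n_trials, n_channels, n_samples);
    ``times_ms`` is the shared peristimulus time axis.  ``rejection_log``
    records every dropped epoch as ``(condition, trial index, reason)``.
    """

    subject: str
    timepoint: str
    epochs: dict[str, np.ndarray]
    times_ms: np.ndarray
    montage: Montage
    rejection_log: list[tuple[str, int, str]] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        return {c: arr.shape[0] for c, arr in self.epochs.items()}

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"epochs_{c}": arr.astype(np.float32) for c, arr in self.epochs.items()}
        np.savez_compressed(path, times_ms=self.times_ms, **arrays)
        meta = {
            "subject": self.subject,
            "timepoint": self.timepoint,
            "conditions": sorted(self.epochs),
            "rejection_log": [list(r) for r in self.rejection_log],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path, montage: Montage) -> "EpochSet":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
            times = data["times_ms"]
            epochs = {c: data[f"epochs_{c}"].astype(float) for c in meta["conditions"]}
        return cls(
            subject=meta["subject"],
            timepoint=meta["timepoint"],
            epochs=epochs,
            times_ms=times,
            montage=montage,
            rejection_log=[tuple(r) for r in meta["rejection_log"]],
        )
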