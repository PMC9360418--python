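"""Deterministic signal conditioning and epoch-level quality control.

Stages mirror a standard developmental-ERP pipeline: zero-phase band-pass
(0.1-30 Hz) plus 50 Hz notch filtering and downsampling to 500 Hz, spherical
interpolation of bad channels, common average reference, stimulus-locked
epoching (-100..613 ms), +/-200 μV amplitude-based epoch rejection, and the
"at least 20 epochs per condition" subject-inclusion rule.

Epoch sample convention: half-open window [start, end) on the sampling grid
after downsampling; the onset sample is the first sample at or after the
event time.  Both choices are asserted by the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import ContinuousRecording, EpochSet


def bandpass_notch_downsample(
    rec: ContinuousRecording,
    low_hz: float = 0.1,
    high_hz: float = 30.0,
    notch_hz: float | None = 50.0,
    target_rate: float = 500.0,
) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass + narrow band-stop notch, then resample.

    The band-pass is a 4th-order Butterworth (two second-order sections per
    edge), the notch a 2nd-order band-stop spanning ``notch_hz`` +/- 2 Hz; both
    are applied forward-backward (``sosfiltfilt``) so no phase delay is
    introduced.  Resampling is polyphase (``resample_poly``).
    """
    nyq = min(rec.rate, target_rate) / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"invalid band edges ({low_hz}, {high_hz}) for Nyquist {nyq} Hz"
        )
    x = rec.signal
    sos = sps.butter(2, [low_hz, high_hz], btype="bandpass", fs=rec.rate, output="sos")
    x = sps.sosfiltfilt(sos, x, axis=1)
    if notch_hz is not None:
        if not (high_hz < notch_hz < rec.rate / 2.0 - 2.0):
            # notch inside the pass band would be redundant but is allowed;
            # outside Nyquist it is an error
            if notch_hz >= rec.rate / 2.0:
                raise ValueError(f"notch {notch_hz} Hz above Nyquist of {rec.rate} Hz")
        sos_n = sps.butter(
            1, [notch_hz - 2.0, notch_hz + 2.0], btype="bandstop", fs=rec.rate, output="sos"
        )
        x = sps.sosfiltfilt(sos_n, x, axis=1)
    if target_rate != rec.rate:
        up, down = (np.array([target_rate, rec.rate]) / np.gcd(int(target_rate), int(rec.rate))).astype(int)
        x = sps.resample_poly(x, up, down, axis=1)
    return rec.copy_with(signal=x, rate=target_rate)


def interpolate_channels(
    rec: ContinuousRecording, bad: list[str], k: int = 4, max_bad: int = 5
) -> ContinuousRecording:
    """Replace bad channels by an inverse-distance mean of nearest good ones.

    ``k`` nearest good neighbours (3-D Euclidean distance between unit-sphere
    positions) are combined with weights 1/d.  At most ``max_bad`` channels may
    be interpolated per recording.
    """
    if not bad:
        return rec.copy_with()
    if len(bad) > max_bad:
        raise ValueError(f"{len(bad)} bad channels exceeds the cap of {max_bad}")
    bad_idx = rec.montage.index(bad)
    good_idx = np.setdiff1d(np.arange(rec.montage.n_channels), bad_idx)
    if good_idx.size == 0:
        raise ValueError("cannot interpolate: no good channels remain")
    x = rec.signal.copy()
    pos = rec.montage.positions
    for bi in bad_idx:
        d = np.linalg.norm(pos[good_idx] - pos[bi], axis=1)
        order = np.argsort(d)[: min(k, good_idx.size)]
        w = 1.0 / np.maximum(d[order], 1e-12)
        w /= w.sum()
        x[bi] = w @ rec.signal[good_idx[order]]
    return rec.copy_with(signal=x)


def rereference_average(rec: ContinuousRecording) -> ContinuousRecording:
    """Common average reference: subtract the cross-channel mean per sample."""
    if rec.montage.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    x = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return rec.copy_with(signal=x, reference_state="average")


def epoch(
    rec: ContinuousRecording,
    events: pd.DataFrame,
    window_ms: tuple[float, float] = (-100.0, 613.0),
    baseline: tuple[float, float] | None = (-100.0, 0.0),
    subject: str = "",
    timepoint: str = "",
) -> EpochSet:
    """Cut stimulus-locked epochs around every non-target event.

    Target events never enter the ERP epochs.  Events whose window would run
    past the recording edge are skipped and logged.  When ``baseline`` is
    given, the mean over that interval (endpoints inclusive) is subtracted
    per channel and epoch.
    """
    start_ms, end_ms = window_ms
    rate = rec.rate
    off0 = int(np.ceil(start_ms * rate / 1000.0 - 1e-9))
    off1 = int(np.ceil(end_ms * rate / 1000.0 - 1e-9))  # exclusive
    offsets = np.arange(off0, off1)
    times_ms = offsets * 1000.0 / rate

    epochs: dict[str, list[np.ndarray]] = {}
    log: list[tuple[str, int, str]] = []
    nontarget = events.loc[~events["is_target"].astype(bool)]
    for cond, grp in nontarget.groupby("condition", sort=False):
        stack: list[np.ndarray] = []
        for trial, (_, ev) in enumerate(grp.iterrows()):
            i0 = int(np.ceil(ev["onset_ms"] * rate / 1000.0 - 1e-9))
            lo, hi = i0 + off0, i0 + off1
            if lo < 0 or hi > rec.n_samples:
                log.append((str(cond), trial, "event too close to recording edge"))
                continue
            ep = rec.signal[:, lo:hi].copy()
            if baseline is not None:
                sel = (times_ms >= baseline[0] - 1e-9) & (times_ms <= baseline[1] + 1e-9)
                ep -= ep[:, sel].mean(axis=1, keepdims=True)
            stack.append(ep)
        epochs[str(cond)] = np.array(stack) if stack else np.empty((0, rec.montage.n_channels, offsets.size))
    return EpochSet(
        subject=subject,
        timepoint=timepoint,
        epochs=epochs,
        times_ms=times_ms,
        montage=rec.montage,
        rejection_log=log,
    )


def reject_epochs(es: EpochSet, threshold_uv: float = 200.0) -> EpochSet:
    """Drop epochs whose absolute amplitude exceeds ``threshold_uv`` anywhere."""
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    kept: dict[str, np.ndarray] = {}
    log = list(es.rejection_log)
    for cond, arr in es.epochs.items():
        if arr.shape[0] == 0:
            kept[cond] = arr
            continue
        peak = np.abs(arr).max(axis=(1, 2))
        mask = peak <= threshold_uv
        for i in np.nonzero(~mask)[0]:
            log.append((cond, int(i), f"amplitude {peak[i]:.1f} μV exceeds ±{threshold_uv:g} μV"))
        kept[cond] = arr[mask]
    return EpochSet(
        subject=es.subject,
        timepoint=es.timepoint,
        epochs=kept,
        times_ms=es.times_ms,
        montage=es.montage,
        rejection_log=log,
    )


@dataclass
class InclusionDecision:
    """Outcome of the minimum-epochs rule for one subject visit."""

    subject: str
    timepoint: str
    counts: dict[str, int]
    included: bool
    reason: str = ""


def apply_inclusion_rule(
    es: EpochSet,
    min_epochs: int = 20,
    conditions: tuple[str, ...] = ("DIG", "LET", "FF"),
) -> InclusionDecision:
    """Include a subject visit only if every condition kept >= ``min_epochs``."""
    counts = es.counts()
    missing = [c for c in conditions if c not in counts]
    if missing:
        return InclusionDecision(
            es.subject, es.timepoint, counts, False, f"missing condition(s) {missing}"
        )
    low = {c: counts[c] for c in conditions if counts[c] < min_epochs}
    if low:
        return InclusionDecision(
            es.subject, es.timepoint, counts, False,
            f"fewer than {min_epochs} epochs in {sorted(low)}",
        )
    return InclusionDecision(es.subject, es.timepoint, counts, True)


def rejection_log_table(es: EpochSet) -> pd.DataFrame:
    """Rejection log as a tidy table (condition, trial, reason)."""
    return pd.DataFrame(es.rejection_log, columns=["condition", "trial", "reason"])
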