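"""Condition averaging, global field power, and data-driven N1 measures.

The N1 analysis window is found from the global field power (GFP) of the
grand-average ERP pooled over subjects and conditions at each wave: the
second post-stimulus local maximum of the GFP marks the N1 peak (the first
belongs to the P1), and the window is the +/-30 ms interval around it.  Mean
amplitudes are then taken over the left and right occipito-temporal clusters
within that window, producing the long-format amplitude table analysed by
the mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import Montage
from .recording import EpochSet


@dataclass
class ErpAverage:
    """Condition-mean waveform (channels x samples, μV) for one subject visit."""

    subject: str
    timepoint: str
    condition: str
    data: np.ndarray
    times_ms: np.ndarray
    n_epochs: int


def average_condition(es: EpochSet) -> dict[str, ErpAverage]:
    """Pointwise mean over retained epochs, per condition."""
    out: dict[str, ErpAverage] = {}
    for cond, arr in es.epochs.items():
        if arr.shape[0] == 0:
            raise ValueError(
                f"no epochs for condition {cond!r} (subject {es.subject}, {es.timepoint}); "
                "the inclusion rule should have excluded this visit"
            )
        out[cond] = ErpAverage(
            subject=es.subject,
            timepoint=es.timepoint,
            condition=cond,
            data=arr.mean(axis=0),
            times_ms=es.times_ms,
            n_epochs=arr.shape[0],
        )
    return out


def gfp(x: np.ndarray) -> np.ndarray:
    """Global field power: population SD across channels.

    ``x`` is ``(n_channels,)`` for a single map or ``(n_channels, n_samples)``
    for a waveform; channels are always the first axis.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return x.std(axis=0, ddof=0)


@dataclass
class GfpTrace:
    """Per-sample GFP of a pooled grand-average ERP at one wave."""

    timepoint: str
    values: np.ndarray
    times_ms: np.ndarray
    provenance: list[str] = field(default_factory=list)


def grand_gfp(erps: list[ErpAverage], timepoint: str = "") -> GfpTrace:
    """GFP of the unweighted mean ERP across subjects and conditions."""
    if not erps:
        raise ValueError("no ERPs to pool")
    times = erps[0].times_ms
    grand = np.mean([e.data for e in erps], axis=0)
    return GfpTrace(
        timepoint=timepoint or erps[0].timepoint,
        values=gfp(grand),
        times_ms=times,
        provenance=[f"{e.subject}:{e.timepoint}:{e.condition}" for e in erps],
    )


@dataclass
class N1Window:
    """+/-30 ms window around the GFP-defined N1 peak."""

    timepoint: str
    start_ms: float
    end_ms: float
    peak_ms: float
    candidates_ms: list[float] = field(default_factory=list)


def _local_maxima(values: np.ndarray) -> list[int]:
    """Indices of strict local maxima; plateaus resolve to their centre."""
    idx: list[int] = []
    n = values.size
    i = 1
    while i < n - 1:
        if values[i] > values[i - 1]:
            j = i
            while j + 1 < n and values[j + 1] == values[j]:
                j += 1
            if j < n - 1 and values[j + 1] < values[j]:
                idx.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return idx


def find_n1_window(
    g: GfpTrace,
    search_ms: tuple[float, float] = (80.0, 350.0),
    half_width_ms: float = 30.0,
    smooth_ms: float = 0.0,
    which: int = 2,
    topography_check=None,
) -> N1Window:
    """Select the N1 window as +/-``half_width_ms`` around a GFP local maximum.

    Local maxima of the (optionally moving-average smoothed) GFP inside the
    post-stimulus search range are listed in order of latency; the
    ``which``-th one (default: second, the N1 following the P1) defines the
    peak.  ``topography_check(peak_ms) -> bool``, when given, can veto a
    candidate and advance to the next.  Window endpoints are snapped to the
    nearest samples on the time grid.
    """
    values = np.asarray(g.values, dtype=float)
    times = np.asarray(g.times_ms, dtype=float)
    if times[0] > search_ms[0] or times[-1] < search_ms[1]:
        raise ValueError(f"GFP trace does not cover the search range {search_ms}")
    if smooth_ms > 0:
        dt = np.median(np.diff(times))
        w = max(int(round(smooth_ms / dt)), 1)
        kernel = np.ones(w) / w
        values = np.convolve(values, kernel, mode="same")
    sel = (times >= search_ms[0]) & (times <= search_ms[1])
    sub_idx = np.nonzero(sel)[0]
    maxima = [sub_idx[i] for i in _local_maxima(values[sub_idx])]
    candidates = [float(times[i]) for i in maxima]
    eligible = list(candidates)
    if topography_check is not None:
        eligible = [t for t in eligible if topography_check(t)]
    if len(eligible) < which:
        raise ValueError(
            f"only {len(eligible)} GFP local maxima in {search_ms}; "
            "cannot select the second one — enter the window manually"
        )
    peak = eligible[which - 1]
    # snap endpoints to the sampling grid
    start = float(times[np.argmin(np.abs(times - (peak - half_width_ms)))])
    end = float(times[np.argmin(np.abs(times - (peak + half_width_ms)))])
    return N1Window(
        timepoint=g.timepoint, start_ms=start, end_ms=end, peak_ms=float(peak),
        candidates_ms=candidates,
    )


def cluster_mean_amplitude(
    erp: ErpAverage, window: N1Window, montage: Montage, cluster: str
) -> float:
    """Mean μV over cluster channels and window samples (endpoints included)."""
    idx = montage.cluster_index(cluster)
    if idx.size == 0:
        raise ValueError(f"cluster {cluster!r} is empty")
    t = erp.times_ms
    sel = (t >= window.start_ms - 1e-9) & (t <= window.end_ms + 1e-9)
    if not sel.any():
        raise ValueError("window lies outside the epoch span")
    return float(erp.data[np.ix_(idx, np.nonzero(sel)[0])].mean())


def amplitude_table(
    erps_by_visit: dict[tuple[str, str], dict[str, ErpAverage]],
    windows: dict[str, N1Window],
    montage: Montage,
    clusters: tuple[str, ...] = ("LOT", "ROT"),
) -> pd.DataFrame:
    """Long-format N1 mean-amplitude table over subject x timepoint x condition x hemisphere."""
    rows = []
    for (subject, tp), erps in erps_by_visit.items():
        for cond, erp in erps.items():
            for cl in clusters:
                rows.append(
                    {
                        "subject": subject,
                        "timepoint": tp,
                        "condition": cond,
                        "hemisphere": cl,
                        "n1_mean_amplitude": cluster_mean_amplitude(
                            erp, windows[tp], montage, cl
                        ),
                        "n_epochs": erp.n_epochs,
                    }
                )
    return pd.DataFrame(rows)


def sensitivity_differences(amplitudes: pd.DataFrame) -> pd.DataFrame:
    """Coarse (DIG-FF) and fine (DIG-LET) differences per subject x timepoint x hemisphere.

    Negative values mean a stronger (more negative) N1 to digits.  Rows with
    a missing condition are skipped and reported in the ``skipped`` attribute
    of the returned frame (``df.attrs['skipped']``).
    """
    wide = amplitudes.pivot_table(
        index=["subject", "timepoint", "hemisphere"],
        columns="condition",
        values="n1_mean_amplitude",
    )
    needed = {"DIG", "LET", "FF"}
    have = needed.issubset(wide.columns)
    skipped: list[tuple] = []
    if have:
        complete = wide.dropna(subset=list(needed))
        skipped = [tuple(i) for i in wide.index.difference(complete.index)]
        wide = complete
    else:
        raise ValueError(f"missing condition column(s) {needed - set(wide.columns)}")
    out = pd.DataFrame(
        {
            "coarse": wide["DIG"] - wide["FF"],
            "fine": wide["DIG"] - wide["LET"],
        }
    ).reset_index()
    out.attrs["skipped"] = skipped
    return out
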