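"""Synthetic longitudinal EEG cohort with ground-truth N1 condition effects.

The generator emulates the data structure of a five-wave developmental study
of visual digit processing: 124-channel average-reference-consistent EEG, a
three-condition (digits / letters / false fonts) target-detection task, an
occipito-temporal N1 whose amplitude differs by condition, 1/f background
noise, occasional high-amplitude artifact and blink epochs, longitudinal
missingness (1-5 visits per child), and behavioral scores rank-coupled to the
neural digit-sensitivity effect through a Gaussian copula.

Two levels of fidelity are provided:

* :func:`simulate_subject` builds a continuous recording from a forward model
  (temporal kernel x zero-mean scalp topography x condition amplitude, plus
  noise) that is pushed through the full preprocessing / ERP pipeline.
* :func:`simulate_amplitude_table` draws N1 cluster mean amplitudes directly
  from the mixed-effects data-generating model (condition means + subject
  random intercept + residual noise), which is the natural scale for
  statistical calibration and power studies.

Every function is deterministic given its seed; cohort-level seeds fan out to
per-subject streams via a documented counter scheme (:func:`child_seed`).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .design import CONDITIONS, DesignSpec, make_design
from .montage import Montage, _LOT_CENTER, _ROT_CENTER, make_montage
from .recording import ContinuousRecording

TIMEPOINTS = ("T1", "T2", "T3", "T4", "T5")

#: Subjects available per wave in the emulated study.
DEFAULT_GROUP_SIZES = {"T1": 23, "T2": 22, "T3": 27, "T4": 27, "T5": 42}

#: N1 peak latency per wave (ms); the +/-30 ms analysis windows around these
#: peaks are 198-258, 188-248, 190-250, 180-240 and 178-238 ms.
DEFAULT_N1_LATENCY_MS = {"T1": 228.0, "T2": 218.0, "T3": 220.0, "T4": 210.0, "T5": 208.0}


def child_seed(master_seed: int, *labels) -> int:
    """Derive a deterministic 31-bit child seed from a master seed and labels.

    The counter scheme is a CRC-32 of the colon-joined labels mixed with the
    master seed, reduced mod 2**31, so the same (seed, labels) pair always
    yields the same stream and distinct labels yield distinct streams.
    """
    tag = ":".join(str(x) for x in labels).encode()
    return (int(master_seed) * 2654435761 + zlib.crc32(tag)) % (2**31)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Forward-model parameters with known condition effects.

    Amplitudes are the N1 peak values (μV, negative) measured as the mean
    over the occipito-temporal cluster channels; the spatial pattern is scaled
    so the LOT/ROT cluster mean equals 1, hence ``condition_amplitude_uv``
    is directly the injected cluster amplitude at the peak sample.
    """

    n1_latency_ms: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_N1_LATENCY_MS)
    )
    n1_width_ms: float = 90.0  # FWHM of the Gaussian temporal kernel
    condition_amplitude_uv: dict[str, float] = field(
        default_factory=lambda: {"DIG": -8.0, "LET": -7.0, "FF": -6.0}
    )
    #: per-(condition, timepoint) overrides, e.g. an enhanced letter response
    #: in the wave that follows intensive grapheme training
    amplitude_overrides: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("LET", "T2"): -8.0}
    )
    #: optional condition-specific azimuthal rotation (radians) of the N1
    #: topography; empty = all conditions share one map configuration
    topo_shift_rad: dict[str, float] = field(default_factory=dict)
    p1_latency_ms: float = 120.0
    p1_amplitude_uv: float = 5.0
    p1_width_ms: float = 70.0
    noise_spectrum_exponent: float = 1.0
    background_noise_sd_uv: float = 6.0
    sensor_noise_sd_uv: float = 2.0
    artifact_epoch_rate: float = 0.05
    blink_rate: float = 0.05
    subject_intercept_sd_uv: float = 1.5
    coarse_effect_subject_sd_uv: float = 1.0
    amplitude_noise_sd_uv: float = 2.0  # residual SD of cluster mean amplitudes

    def __post_init__(self) -> None:
        for r in (self.artifact_epoch_rate, self.blink_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not all(np.isfinite(list(self.condition_amplitude_uv.values()))):
            raise ValueError("amplitudes must be finite")

    def amplitude(self, condition: str, timepoint: str) -> float:
        return self.amplitude_overrides.get(
            (condition, timepoint), self.condition_amplitude_uv[condition]
        )

    def expected_window_mean(self, condition: str, timepoint: str, half_width_ms: float = 30.0) -> float:
        """Cluster mean amplitude expected over a +/-``half_width_ms`` window.

        The temporal kernel has peak 1, so the window mean is the kernel's
        average over the window times the injected peak amplitude.
        """
        sigma = self.n1_width_ms / 2.354820045
        t = np.linspace(-half_width_ms, half_width_ms, 2001)
        return float(self.amplitude(condition, timepoint) * np.exp(-0.5 * (t / sigma) ** 2).mean())


def n1_topography(montage: Montage, shift_rad: float = 0.0) -> np.ndarray:
    """Zero-mean scalp pattern of the N1: bilateral occipito-temporal focus.

    Two Gaussian-on-sphere patches centred on the cluster centroids, with a
    broad anterior counter-patch of opposite sign; the pattern is exactly
    demeaned (average-reference consistent) and scaled so that its mean over
    the LOT+ROT channels equals 1.  ``shift_rad`` rotates the patch centres
    about the vertical axis, yielding a genuinely different map
    configuration (used to inject condition-specific topographies).
    """
    centers = [_rotate_z(_LOT_CENTER, shift_rad), _rotate_z(_ROT_CENTER, shift_rad)]
    return _blob_topography(montage, centers, width_rad=0.45)


def _rotate_z(v: np.ndarray, angle_rad: float) -> np.ndarray:
    if angle_rad == 0.0:
        return v
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])


def p1_topography(montage: Montage) -> np.ndarray:
    """Zero-mean midline-occipital pattern used for the earlier P1 component."""
    center = np.array([0.0, -0.85, 0.35])
    center /= np.linalg.norm(center)
    return _blob_topography(montage, [center], width_rad=0.55)


def _blob_topography(montage: Montage, centers, width_rad: float) -> np.ndarray:
    pos = montage.positions
    topo = np.zeros(montage.n_channels)
    for c in centers:
        ang = np.arccos(np.clip(pos @ c, -1.0, 1.0))
        topo += np.exp(-0.5 * (ang / width_rad) ** 2)
    anterior = np.array([0.0, 0.9, 0.44])
    anterior /= np.linalg.norm(anterior)
    ang = np.arccos(np.clip(pos @ anterior, -1.0, 1.0))
    counter = np.exp(-0.5 * (ang / 0.8) ** 2)
    counter *= topo.sum() / counter.sum()  # exact cancellation
    topo -= counter
    topo -= topo.mean()
    cl = np.concatenate([montage.cluster_index("LOT"), montage.cluster_index("ROT")])
    scale = topo[cl].mean()
    if abs(scale) < 1e-12:  # pragma: no cover - degenerate montage
        raise ValueError("topography vanishes over the clusters")
    return topo / scale


def one_over_f_noise(
    n_channels: int, n_samples: int, rate: float, exponent: float, sd_uv: float, rng
) -> np.ndarray:
    """Spatially independent 1/f^exponent noise, scaled to ``sd_uv`` per channel."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * sd_uv


def _gauss_kernel(times_ms: np.ndarray, latency_ms: float, fwhm_ms: float) -> np.ndarray:
    sigma = fwhm_ms / 2.354820045
    return np.exp(-0.5 * ((times_ms - latency_ms) / sigma) ** 2)


def simulate_subject(
    montage: Montage,
    events: pd.DataFrame,
    truth: GroundTruth,
    timepoint: str = "T1",
    seed: int = 0,
    rate: float = 1000.0,
    epoch_span_ms: tuple[float, float] = (-100.0, 613.0),
) -> ContinuousRecording:
    """Forward-simulate one continuous recording for a subject visit.

    Each non-target event contributes a P1 and an N1 deflection (temporal
    Gaussian kernel at the timepoint's latency x fixed zero-mean topography x
    condition amplitude).  1/f background noise and white sensor noise are
    added, and with the configured rates an epoch receives a high-amplitude
    boxcar artifact on a random channel subset or a frontal blink transient;
    both exceed the +/-200 μV rejection criterion by construction.
    """
    rng = np.random.default_rng(seed)
    tail_ms = epoch_span_ms[1] + 400.0
    n_samples = int(np.ceil((events["onset_ms"].max() + tail_ms) * rate / 1000.0))
    if events["onset_ms"].min() + epoch_span_ms[0] < 0:
        raise ValueError("first event does not fit inside the recording")

    n1_topo_by_cond = {
        c: n1_topography(montage, truth.topo_shift_rad.get(c, 0.0))
        for c in events["condition"].unique()
    }
    p1_topo = p1_topography(montage)
    sig = np.zeros((montage.n_channels, n_samples))
    t_axis = np.arange(n_samples) / rate * 1000.0

    kern_t = np.arange(0.0, epoch_span_ms[1] + 200.0, 1000.0 / rate)
    for _, ev in events.iterrows():
        i0 = int(np.ceil(ev["onset_ms"] * rate / 1000.0 - 1e-9))
        sl = slice(i0, min(i0 + kern_t.size, n_samples))
        kt = kern_t[: sl.stop - sl.start]
        if ev["is_target"]:
            continue  # target trials carry task responses, not analysed ERPs
        amp = truth.amplitude(str(ev["condition"]), timepoint)
        n1_topo = n1_topo_by_cond[ev["condition"]]
        n1 = _gauss_kernel(kt, truth.n1_latency_ms[timepoint], truth.n1_width_ms)
        p1 = _gauss_kernel(kt, truth.p1_latency_ms, truth.p1_width_ms)
        sig[:, sl] += np.outer(n1_topo, n1) * amp + np.outer(p1_topo, p1) * truth.p1_amplitude_uv

    if truth.background_noise_sd_uv > 0:
        sig += one_over_f_noise(
            montage.n_channels, n_samples, rate,
            truth.noise_spectrum_exponent, truth.background_noise_sd_uv, rng,
        )
    if truth.sensor_noise_sd_uv > 0:
        sig += rng.normal(scale=truth.sensor_noise_sd_uv, size=sig.shape)

    # artifact / blink epochs (detectable only via the amplitude criterion)
    frontal = np.nonzero(montage.positions[:, 1] > 0.55)[0]
    if frontal.size == 0:
        frontal = np.arange(min(4, montage.n_channels))
    for _, ev in events.iterrows():
        i0 = int(np.ceil(ev["onset_ms"] * rate / 1000.0 - 1e-9))
        span = slice(max(i0 + int(epoch_span_ms[0] * rate / 1000.0), 0),
                     min(i0 + int(epoch_span_ms[1] * rate / 1000.0), n_samples))
        if rng.random() < truth.artifact_epoch_rate:
            n_ch = max(1, montage.n_channels // 10)
            chans = rng.choice(montage.n_channels, size=n_ch, replace=False)
            width = int(rng.uniform(0.1, 0.3) * rate)
            start = span.start + int(rng.random() * max((span.stop - span.start) - width, 1))
            amp = rng.uniform(260.0, 420.0) * rng.choice([-1.0, 1.0])
            sig[np.ix_(chans, np.arange(start, min(start + width, n_samples)))] += amp
        if rng.random() < truth.blink_rate:
            blink_t = t_axis[span] - t_axis[span.start]
            blink = np.sin(np.pi * blink_t / max(blink_t[-1], 1.0)) ** 2
            sig[np.ix_(frontal, np.arange(span.start, span.stop))] += (
                rng.uniform(260.0, 380.0) * blink
            )
    return ContinuousRecording(signal=sig, rate=rate, montage=montage)


# ---------------------------------------------------------------------------
# cohort structure


@dataclass
class CohortSpec:
    """Longitudinal cohort layout: waves, per-wave group sizes, missingness."""

    timepoints: tuple[str, ...] = TIMEPOINTS
    group_size: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_subjects: int = 62
    visit_pattern: dict[str, list[str]] | None = None  # subject -> timepoints
    seed: int = 0

    def __post_init__(self) -> None:
        for tp in self.timepoints:
            if self.group_size.get(tp, 0) <= 0:
                raise ValueError(f"group size for {tp} must be positive")
        if max(self.group_size[tp] for tp in self.timepoints) > self.n_subjects:
            raise ValueError("a wave cannot have more participants than subjects")


def draw_visit_pattern(cohort: CohortSpec, seed: int | None = None) -> dict[str, list[str]]:
    """Draw a subject -> visited-timepoints mapping matching the group sizes.

    Each wave's participants are sampled uniformly from the subject pool;
    subjects left with no visit steal one from a multiply-visiting subject,
    preserving the per-wave counts exactly.  Deterministic given the seed.
    """
    if cohort.visit_pattern is not None:
        return {s: list(tps) for s, tps in cohort.visit_pattern.items()}
    rng = np.random.default_rng(cohort.seed if seed is None else seed)
    subjects = [f"S{i + 1:03d}" for i in range(cohort.n_subjects)]
    visits = {s: [] for s in subjects}
    for tp in cohort.timepoints:
        for s in rng.choice(subjects, size=cohort.group_size[tp], replace=False):
            visits[str(s)].append(tp)
    for s in subjects:
        if not visits[s]:
            donors = [d for d in subjects if len(visits[d]) > 1]
            donor = str(rng.choice(donors))
            tp = str(rng.choice(visits[donor]))
            visits[donor].remove(tp)
            visits[s].append(tp)
    return visits


@dataclass
class BehaviorTruth:
    """Latent-skill model for the behavioral batteries.

    A standard-normal latent skill per subject drives all observed scores by
    deterministic monotone transforms; the subject-level coarse N1 effect is
    coupled to the skill through a Gaussian copula whose correlation is set so
    the rank (Spearman) association equals ``brain_behavior_rho``.
    """

    brain_behavior_rho: float = 0.6

    def __post_init__(self) -> None:
        if not -1.0 <= self.brain_behavior_rho <= 1.0:
            raise ValueError("brain_behavior_rho must be in [-1, 1]")

    @property
    def copula_r(self) -> float:
        # invert rho_S = (6/pi) asin(r/2) for the bivariate normal copula
        return float(2.0 * np.sin(np.pi * self.brain_behavior_rho / 6.0))


#: behavioral measures and the timepoints at which they are administered
BEHAVIOR_SCHEDULE = {
    "number_knowledge": ("T1", "T2", "T3", "T4"),
    "arithmetic_pr": ("T4", "T5"),
    "reading_word_pr": ("T3", "T4", "T5"),
    "reading_pseudoword_pr": ("T3", "T4", "T5"),
    "reading_average_pr": ("T3", "T4", "T5"),
}


def simulate_behavior(
    visits: dict[str, list[str]],
    behavior: BehaviorTruth,
    truth: GroundTruth,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw latent skills, subject effects, and observed behavioral scores.

    Returns ``(behavior_table, subject_truth)``.  ``subject_truth`` carries
    the latent skill, the subject random intercept and the subject-specific
    coarse-effect deviation (μV) whose rank coupling with skill is the
    configured ``brain_behavior_rho``.
    """
    rng = np.random.default_rng(seed)
    subjects = sorted(visits)
    n = len(subjects)
    r = behavior.copula_r
    z_skill = rng.standard_normal(n)
    w = r * z_skill + np.sqrt(max(1.0 - r * r, 0.0)) * rng.standard_normal(n)
    intercept = rng.normal(scale=truth.subject_intercept_sd_uv, size=n)
    # higher skill -> less negative (weaker) digit sensitivity by default,
    # matching a positive rank correlation between scores and the signed
    # DIG-FF difference
    coarse_dev = truth.coarse_effect_subject_sd_uv * w

    subject_truth = pd.DataFrame(
        {
            "subject": subjects,
            "latent_skill": z_skill,
            "subject_intercept_uv": intercept,
            "coarse_effect_dev_uv": coarse_dev,
        }
    )

    u = sstats.norm.cdf(z_skill)  # uniform ranks of the latent skill
    rows = []
    for i, s in enumerate(subjects):
        for tp in visits[s]:
            for measure, schedule in BEHAVIOR_SCHEDULE.items():
                if tp not in schedule:
                    continue
                if measure == "number_knowledge":
                    # count correct of 21 items; ceiling grows with grade
                    ceiling = {"T1": 0.70, "T2": 0.87, "T3": 0.90, "T4": 0.985}[tp]
                    score = np.clip(np.round(21 * ceiling * (0.55 + 0.45 * u[i])), 0, 21)
                else:
                    score = np.round(100.0 * u[i], 1)  # percentile scale
                rows.append(
                    {"subject": s, "timepoint": tp, "measure": measure, "score": float(score)}
                )
    return pd.DataFrame(rows), subject_truth


def subject_truth_for(
    truth: GroundTruth, subject_row: pd.Series
) -> GroundTruth:
    """Ground truth specialised to one subject (intercept + coarse deviation)."""
    amps = {
        c: truth.condition_amplitude_uv[c] + subject_row["subject_intercept_uv"]
        for c in truth.condition_amplitude_uv
    }
    amps["DIG"] = amps["DIG"] + subject_row["coarse_effect_dev_uv"]
    overrides = {
        k: v + subject_row["subject_intercept_uv"] for k, v in truth.amplitude_overrides.items()
    }
    return replace(truth, condition_amplitude_uv=amps, amplitude_overrides=overrides)


def simulate_amplitude_table(
    cohort: CohortSpec,
    truth: GroundTruth,
    behavior: BehaviorTruth | None = None,
    seed: int = 0,
) -> dict:
    """Draw N1 cluster mean amplitudes directly from the mixed-effects model.

    amplitude(subject, timepoint, condition, hemisphere) =
    condition amplitude + subject intercept
    + (coarse-effect deviation, digits only) + N(0, amplitude_noise_sd).

    Unlike the EEG forward model, no temporal-kernel attenuation applies:
    ``condition_amplitude_uv`` is interpreted directly on the measured
    window-mean scale, so injected condition differences are recovered
    without a scale factor.

    Returns a bundle dict with keys ``amplitudes`` (long table),
    ``behavior``, ``subject_truth`` and ``manifest`` (per subject x timepoint
    injected condition amplitudes and true coarse/fine effects).
    """
    behavior = behavior or BehaviorTruth()
    visits = draw_visit_pattern(cohort, seed=child_seed(seed, "visits"))
    behav, subj_truth = simulate_behavior(
        visits, behavior, truth, seed=child_seed(seed, "behavior")
    )
    rng = np.random.default_rng(child_seed(seed, "amplitudes"))

    amp_rows, man_rows = [], []
    for _, row in subj_truth.iterrows():
        s = row["subject"]
        for tp in visits[s]:
            for cond in CONDITIONS:
                mu = truth.amplitude(cond, tp) + row["subject_intercept_uv"]
                if cond == "DIG":
                    mu += row["coarse_effect_dev_uv"]
                for hemi in ("LOT", "ROT"):
                    amp_rows.append(
                        {
                            "subject": s,
                            "timepoint": tp,
                            "condition": cond,
                            "hemisphere": hemi,
                            "n1_mean_amplitude": mu
                            + rng.normal(scale=truth.amplitude_noise_sd_uv),
                        }
                    )
                man_rows.append(
                    {"subject": s, "timepoint": tp, "condition": cond, "true_amplitude_uv": mu}
                )
    amplitudes = pd.DataFrame(amp_rows)
    manifest = pd.DataFrame(man_rows)
    wide = manifest.pivot_table(
        index=["subject", "timepoint"], columns="condition", values="true_amplitude_uv"
    ).reset_index()
    wide["true_coarse_uv"] = wide["DIG"] - wide["FF"]
    wide["true_fine_uv"] = wide["DIG"] - wide["LET"]
    return {
        "amplitudes": amplitudes,
        "behavior": behav,
        "subject_truth": subj_truth,
        "manifest": wide,
        "visits": visits,
    }


def iter_cohort_recordings(
    cohort: CohortSpec,
    truth: GroundTruth,
    behavior: BehaviorTruth | None = None,
    design: DesignSpec | None = None,
    montage: Montage | None = None,
    seed: int = 0,
    rate: float = 1000.0,
):
    """Yield ``(subject, timepoint, events, recording)`` for every visit.

    Recordings are generated lazily (one visit at a time) because a full
    cohort does not fit comfortably in memory.  The behavioral tables and the
    ground-truth manifest for the same seed are available from
    :func:`simulate_cohort_tables`.
    """
    behavior = behavior or BehaviorTruth()
    design = design or DesignSpec()
    montage = montage or make_montage(124, seed=child_seed(seed, "montage"))
    visits = draw_visit_pattern(cohort, seed=child_seed(seed, "visits"))
    _, subj_truth = simulate_behavior(
        visits, behavior, truth, seed=child_seed(seed, "behavior")
    )
    for _, row in subj_truth.iterrows():
        s = row["subject"]
        s_truth = subject_truth_for(truth, row)
        for tp in visits[s]:
            events = make_design(design, seed=child_seed(seed, "design", s, tp))
            rec = simulate_subject(
                montage, events, s_truth, timepoint=tp,
                seed=child_seed(seed, "eeg", s, tp), rate=rate,
            )
            yield s, tp, events, rec


def simulate_cohort_tables(
    cohort: CohortSpec,
    truth: GroundTruth,
    behavior: BehaviorTruth | None = None,
    seed: int = 0,
) -> dict:
    """Cohort-level tables (visits, behavior, subject truth) without EEG."""
    behavior = behavior or BehaviorTruth()
    visits = draw_visit_pattern(cohort, seed=child_seed(seed, "visits"))
    behav, subj_truth = simulate_behavior(
        visits, behavior, truth, seed=child_seed(seed, "behavior")
    )
    return {"visits": visits, "behavior": behav, "subject_truth": subj_truth}
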