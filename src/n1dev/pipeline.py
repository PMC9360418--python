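"""End-to-end orchestration: simulate a cohort, run the full ERP analysis.

A single :class:`RunConfig` carries every stage parameter with the study's
defaults (0.1-30 Hz band-pass, 50 Hz notch, 500 Hz, +/-200 μV rejection,
>=20 epochs per condition, +/-30 ms N1 windows, 5000 permutations, +/-3
normalized-residual exclusion, 36-test correlation grid) and serializes
to/from YAML.  A master seed fans out deterministically to every stage and
subject via :func:`n1dev.simulate.child_seed`, so two runs with the same
config produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import DesignSpec, make_design, read_events, write_events
from .erp import (
    amplitude_table,
    average_condition,
    find_n1_window,
    grand_gfp,
    sensitivity_differences,
)
from .montage import Montage, make_montage
from .preprocess import (
    apply_inclusion_rule,
    bandpass_notch_downsample,
    epoch,
    reject_epochs,
    rereference_average,
)
from .recording import ContinuousRecording
from .simulate import (
    BehaviorTruth,
    CohortSpec,
    GroundTruth,
    child_seed,
    simulate_amplitude_table,
    simulate_cohort_tables,
    simulate_subject,
    subject_truth_for,
)
from .stats import (
    GridSpec,
    LmmSpec,
    correlation_grid,
    fit_lmm,
    posthoc_contrasts,
    report_lines,
    spearman,
)
from .tanova import electrode_t_map, tanova_permutation_test


@dataclass
class RunConfig:
    """All stage parameters of a synthetic-study run."""

    seed: int = 0
    # --- cohort / simulation
    n_channels: int = 124
    native_rate_hz: float = 1000.0
    timepoints: tuple[str, ...] = ("T1", "T2", "T3", "T4", "T5")
    group_size: dict = field(
        default_factory=lambda: {"T1": 23, "T2": 22, "T3": 27, "T4": 27, "T5": 42}
    )
    n_subjects: int = 62
    design: dict = field(default_factory=dict)  # DesignSpec overrides
    truth: dict = field(default_factory=dict)  # GroundTruth overrides
    behavior_rho: float = 0.6
    # --- preprocessing
    band_low_hz: float = 0.1
    band_high_hz: float = 30.0
    notch_hz: float = 50.0
    target_rate_hz: float = 500.0
    reject_threshold_uv: float = 200.0
    min_epochs: int = 20
    baseline: bool = True
    # --- ERP / window
    window_search_ms: tuple[float, float] = (80.0, 350.0)
    window_half_width_ms: float = 30.0
    # --- statistics
    n_permutations: int = 5000
    outlier_threshold: float = 3.0
    lmm_reml: bool = True

    # ----- constructors ---------------------------------------------------
    def make_design_spec(self) -> DesignSpec:
        return DesignSpec(**self.design)

    def make_truth(self) -> GroundTruth:
        kw = dict(self.truth)
        for key in ("condition_amplitude_uv", "n1_latency_ms"):
            if key in kw:
                kw[key] = dict(kw[key])
        if "amplitude_overrides" in kw:
            kw["amplitude_overrides"] = {
                tuple(k.split("@")) if isinstance(k, str) else tuple(k): v
                for k, v in kw["amplitude_overrides"].items()
            }
        return GroundTruth(**kw)

    def make_cohort(self) -> CohortSpec:
        return CohortSpec(
            timepoints=tuple(self.timepoints),
            group_size=dict(self.group_size),
            n_subjects=self.n_subjects,
            seed=self.seed,
        )

    def make_behavior(self) -> BehaviorTruth:
        return BehaviorTruth(brain_behavior_rho=self.behavior_rho)

    # ----- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        truth = d.get("truth", {})
        if "amplitude_overrides" in truth:
            truth["amplitude_overrides"] = {
                "@".join(k) if isinstance(k, tuple) else k: v
                for k, v in truth["amplitude_overrides"].items()
            }
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        kw = dict(raw)
        for key in ("timepoints", "window_search_ms"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------


def run_simulate(config: RunConfig, outdir) -> Path:
    """Write a full synthetic dataset bundle (recordings, events, tables).

    Layout: ``montage.csv``, ``visits.json``, ``behavior.csv``,
    ``subject_truth.csv`` (the ground-truth manifest),
    ``recordings/<subject>_<tp>.npz(.json)`` and
    ``events/<subject>_<tp>.tsv``.
    """
    outdir = Path(outdir)
    (outdir / "recordings").mkdir(parents=True, exist_ok=True)
    (outdir / "events").mkdir(exist_ok=True)

    montage = make_montage(config.n_channels, seed=child_seed(config.seed, "montage"))
    montage.to_csv(outdir / "montage.csv")
    cohort = config.make_cohort()
    truth = config.make_truth()
    tables = simulate_cohort_tables(cohort, truth, config.make_behavior(), seed=config.seed)
    (outdir / "visits.json").write_text(json.dumps(tables["visits"], indent=1))
    tables["behavior"].to_csv(outdir / "behavior.csv", index=False)
    tables["subject_truth"].to_csv(outdir / "subject_truth.csv", index=False)

    design = config.make_design_spec()
    for _, row in tables["subject_truth"].iterrows():
        s = row["subject"]
        s_truth = subject_truth_for(truth, row)
        for tp in tables["visits"][s]:
            events = make_design(design, seed=child_seed(config.seed, "design", s, tp))
            rec = simulate_subject(
                montage, events, s_truth, timepoint=tp,
                seed=child_seed(config.seed, "eeg", s, tp), rate=config.native_rate_hz,
            )
            write_events(events, outdir / "events" / f"{s}_{tp}.tsv")
            rec.save(outdir / "recordings" / f"{s}_{tp}.npz")
    config.to_yaml(outdir / "config.yaml")
    return outdir


def preprocess_visit(
    rec: ContinuousRecording, events: pd.DataFrame, config: RunConfig,
    subject: str = "", timepoint: str = "",
):
    """Filter/downsample, average-reference, epoch and reject for one visit."""
    if rec.rate != config.target_rate_hz or config.band_low_hz > 0:
        rec = bandpass_notch_downsample(
            rec, config.band_low_hz, config.band_high_hz,
            config.notch_hz, config.target_rate_hz,
        )
    rec = rereference_average(rec)
    es = epoch(
        rec, events,
        baseline=(-100.0, 0.0) if config.baseline else None,
        subject=subject, timepoint=timepoint,
    )
    es = reject_epochs(es, config.reject_threshold_uv)
    decision = apply_inclusion_rule(es, config.min_epochs)
    return es, decision


def run_analysis(config: RunConfig, bundle_dir, outdir) -> dict:
    """Run the full analysis on a simulated bundle; write result tables.

    Outputs: per-wave N1 windows and GFP traces, the long amplitude table,
    sensitivity differences, TANOVA tables, electrode t-maps, LMM report and
    the brain-behavior correlation grid, plus a provenance log.
    """
    bundle_dir, outdir = Path(bundle_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    montage = Montage.from_csv(bundle_dir / "montage.csv")
    visits = json.loads((bundle_dir / "visits.json").read_text())
    behavior = pd.read_csv(bundle_dir / "behavior.csv")

    erps_by_visit: dict[tuple[str, str], dict] = {}
    inclusion_rows = []
    for s, tps in visits.items():
        for tp in tps:
            rec = ContinuousRecording.load(bundle_dir / "recordings" / f"{s}_{tp}.npz", montage)
            events = read_events(bundle_dir / "events" / f"{s}_{tp}.tsv")
            es, decision = preprocess_visit(rec, events, config, subject=s, timepoint=tp)
            inclusion_rows.append(
                {"subject": s, "timepoint": tp, "included": decision.included,
                 "reason": decision.reason, **{f"n_{c}": n for c, n in decision.counts.items()}}
            )
            if decision.included:
                erps_by_visit[(s, tp)] = average_condition(es)
    inclusion = pd.DataFrame(inclusion_rows)
    inclusion.to_csv(outdir / "inclusion.csv", index=False)
    if not erps_by_visit:
        raise ValueError("no subject visit passed the inclusion rule")

    # per-wave grand GFP -> N1 window
    windows = {}
    window_rows = []
    timepoints = sorted({tp for _, tp in erps_by_visit})
    for tp in timepoints:
        pool = [e for (s, t), erps in erps_by_visit.items() if t == tp for e in erps.values()]
        trace = grand_gfp(pool, timepoint=tp)
        w = find_n1_window(
            trace, search_ms=config.window_search_ms,
            half_width_ms=config.window_half_width_ms,
        )
        windows[tp] = w
        window_rows.append(
            {"timepoint": tp, "start_ms": w.start_ms, "end_ms": w.end_ms,
             "peak_ms": w.peak_ms, "candidates_ms": ";".join(f"{c:g}" for c in w.candidates_ms)}
        )
        pd.DataFrame({"time_ms": trace.times_ms, "gfp_uv": trace.values}).to_csv(
            outdir / f"gfp_{tp}.csv", index=False
        )
    pd.DataFrame(window_rows).to_csv(outdir / "n1_windows.csv", index=False)

    amplitudes = amplitude_table(erps_by_visit, windows, montage)
    amplitudes.to_csv(outdir / "amplitudes.csv", index=False)
    differences = sensitivity_differences(amplitudes)
    differences.to_csv(outdir / "differences.csv", index=False)

    # TANOVA per wave on window-restricted maps
    tanova_frames = []
    tmap_rows = []
    for tp in timepoints:
        subs = sorted({s for (s, t) in erps_by_visit if t == tp})
        if len(subs) < 2:
            continue  # permutation and t statistics need >= 2 subjects
        conds = sorted(next(iter(erps_by_visit.values())).keys())
        first = erps_by_visit[(subs[0], tp)][conds[0]]
        sel = (first.times_ms >= windows[tp].start_ms - 1e-9) & (
            first.times_ms <= windows[tp].end_ms + 1e-9
        )
        t_sel = first.times_ms[sel]
        maps = np.stack(
            [[erps_by_visit[(s, tp)][c].data[:, sel] for c in conds] for s in subs]
        )
        res = tanova_permutation_test(
            maps, n_permutations=config.n_permutations,
            seed=child_seed(config.seed, "tanova", tp),
        )
        frame = res.to_frame()
        frame["sample_ms"] = t_sel
        frame.insert(0, "timepoint", tp)
        tanova_frames.append(frame)
        # electrode-wise t maps of window-averaged condition differences
        for a, b in (("DIG", "FF"), ("DIG", "LET")):
            if a in conds and b in conds:
                diffs = np.stack(
                    [
                        (erps_by_visit[(s, tp)][a].data[:, sel]
                         - erps_by_visit[(s, tp)][b].data[:, sel]).mean(axis=1)
                        for s in subs
                    ]
                )
                t_vals, p_vals = electrode_t_map(diffs)
                tmap_rows.extend(
                    {"timepoint": tp, "contrast": f"{a}-{b}", "channel": ch,
                     "t": tv, "p": pv}
                    for ch, tv, pv in zip(montage.channels, t_vals, p_vals)
                )
    tanova_all = (
        pd.concat(tanova_frames)
        if tanova_frames
        else pd.DataFrame(columns=["timepoint", "sample_ms", "statistic", "p"])
    )
    tanova_all.to_csv(outdir / "tanova.csv", index=False)
    pd.DataFrame(tmap_rows).to_csv(outdir / "electrode_t_maps.csv", index=False)

    # LMM + contrasts + correlation grid
    spec = LmmSpec(outlier_threshold=config.outlier_threshold, reml=config.lmm_reml)
    lmm = fit_lmm(amplitudes, spec)
    lmm.anova.to_csv(outdir / "lmm_anova.csv", index=False)
    lmm.excluded.to_csv(outdir / "lmm_excluded.csv", index=False)
    contrasts = posthoc_contrasts(lmm)
    contrasts.to_csv(outdir / "contrasts.csv", index=False)
    grid_spec = _grid_for(config, behavior)
    grid = correlation_grid(differences, behavior, grid_spec)
    grid.to_csv(outdir / "correlation_grid.csv", index=False)

    (outdir / "report.txt").write_text("\n".join(report_lines(lmm, contrasts, grid)) + "\n")
    provenance = {
        "n1dev_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config_hash": config.hash(),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1))
    try:
        from .plots import plot_gfp_tanova

        for tp in timepoints:
            g = pd.read_csv(outdir / f"gfp_{tp}.csv")
            tv = tanova_all.query("timepoint == @tp")
            plot_gfp_tanova(g, tv, windows[tp], outdir / f"figure_{tp}.png")
    except Exception:  # plotting must never sink an analysis run
        pass
    return {
        "windows": windows,
        "amplitudes": amplitudes,
        "differences": differences,
        "tanova": tanova_all,
        "lmm": lmm,
        "contrasts": contrasts,
        "grid": grid,
        "inclusion": inclusion,
    }


def _grid_for(config: RunConfig, behavior: pd.DataFrame) -> GridSpec:
    """Restrict the default 36-cell grid to waves present in this run."""
    present = set(zip(behavior["measure"], behavior["timepoint"]))
    spec = GridSpec()
    behaviors = tuple(b for b in spec.behaviors if b in present)
    return GridSpec(behaviors=behaviors or spec.behaviors)


# ---------------------------------------------------------------------------
# recovery / calibration suite


def run_recovery_suite(
    config: RunConfig,
    n_null_cohorts: int = 500,
    null_permutations: int = 500,
    n_power_cohorts: int = 100,
    n_rho_replicates: int = 200,
    outdir=None,
) -> dict:
    """Parameter-recovery and calibration metrics under the study conditions.

    Runs (1) the TANOVA type-I calibration over exchangeable-null cohorts,
    (2) LMM coarse-contrast power and bias over simulated cohorts with the
    configured group sizes, and (3) Spearman recovery of the configured
    brain-behavior rank coupling at n=27.  Returns a metrics dict and, when
    ``outdir`` is given, writes ``recovery.json`` with pass/fail flags.
    """
    rng = np.random.default_rng(child_seed(config.seed, "recovery"))
    truth = config.make_truth()

    # (1) TANOVA null calibration: iid maps => labels exchangeable
    rejections = 0
    tests = 0
    for i in range(n_null_cohorts):
        maps = rng.standard_normal((12, 3, 19, 3))
        res = tanova_permutation_test(
            maps, n_permutations=null_permutations,
            seed=child_seed(config.seed, "null", i),
        )
        rejections += int((res.p < 0.05).sum())
        tests += res.p.size
    tanova_alpha = rejections / tests

    # (2) LMM coarse-effect recovery at the study's group sizes
    cohort = config.make_cohort()
    true_coarse = {
        tp: truth.amplitude("DIG", tp) - truth.amplitude("FF", tp)
        for tp in cohort.timepoints
    }
    sig_neg = 0
    n_contrasts = 0
    bias_acc = []
    for i in range(n_power_cohorts):
        bundle = simulate_amplitude_table(
            cohort, truth, config.make_behavior(), seed=child_seed(config.seed, "power", i)
        )
        lmm = fit_lmm(bundle["amplitudes"], LmmSpec(reml=config.lmm_reml))
        con = posthoc_contrasts(lmm, pairs=(("DIG", "FF"),))
        for _, r in con.iterrows():
            n_contrasts += 1
            if r["t"] < 0 and r["p"] < 0.05:
                sig_neg += 1
            bias_acc.append(r["estimate"] - true_coarse[r["timepoint"]])
    power = sig_neg / n_contrasts
    bias = float(np.mean(bias_acc))

    # (3) Spearman recovery of the injected rank coupling at n=27
    r = config.make_behavior().copula_r
    inside = 0
    rhos = []
    for i in range(n_rho_replicates):
        rr = np.random.default_rng(child_seed(config.seed, "rho", i))
        z = rr.standard_normal(27)
        w = r * z + np.sqrt(1 - r * r) * rr.standard_normal(27)
        rho, _ = spearman(z, w)
        rhos.append(rho)
        if 0.3 <= rho <= 0.85:
            inside += 1
    coverage = inside / n_rho_replicates

    metrics = {
        "tanova_type1_alpha05": tanova_alpha,
        "tanova_pass": bool(0.03 <= tanova_alpha <= 0.07),
        "coarse_contrast_power": power,
        "power_pass": bool(power >= 0.95),
        "coarse_contrast_bias_uv": bias,
        "bias_pass": bool(abs(bias) < 0.1),
        "spearman_coverage": coverage,
        "spearman_mean_rho": float(np.mean(rhos)),
        "coverage_pass": bool(coverage >= 0.90),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "recovery.json").write_text(json.dumps(metrics, indent=1))
    return metrics
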