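"""End-to-end analysis: clean -> spectra -> indices -> spans -> cosinor -> stats.

Two analysis streams per record, mirroring the two time scales of interest:

* short stream — 2-Hz spline tachogram, consecutive 5-min windows, MEM
  spectra with AIC-selected order (max 30), HF/LF/VLF band powers;
* long stream — 0.1-Hz (10-s bin mean) tachogram, 180-min windows stepped by
  5 min, fixed-order MEM spectra, ULF band powers (total and bands 1-3) and
  the power-law slope beta over 1e-4 to 1e-2 Hz.

Window values are averaged over the 24-h, awake and asleep spans (window
midpoint decides the span).  The per-record beta window series feeds single
cosinor fits (time referenced to arising), summarized per condition by the
population-mean cosinor; per-subject session means feed the group
statistics.  A replication mode runs the identical group-statistics code
path directly on a table of per-subject session values, so published group
statistics can be reproduced without raw recordings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cosinor as cs
from . import group_stats as gs
from .mem_spectrum import EvenSeries, fit_auto, resample_even
from .nn_io import (
    NNSeries,
    SpanLabels,
    filter_normal_beats,
    label_sleep_wake,
    read_diary,
    read_rr,
    write_results,
)
from .spectral_indices import (
    BANDS,
    BETA_FIT_RANGE,
    band_power,
    beta_slope,
    log_grid,
    span_summary,
    window_schedule,
)
from .synthetic_data import Cohort


@dataclass
class RunConfig:
    """All analysis knobs, persisted (with hash) alongside outputs."""

    # windows
    short_window_s: float = 300.0
    short_step_s: float = 300.0
    long_window_s: float = 10800.0
    long_step_s: float = 300.0
    # resampling
    resample_rate_short_hz: float = 2.0
    resample_rate_long_hz: float = 0.1
    # AR order policy
    short_order_criterion: str = "aic"
    short_max_order: int = 30
    long_order_criterion: str = "fixed"
    long_fixed_order: int = 30
    long_max_order: int = 120
    # detrend per window: "mean" or "linear"
    short_detrend: str = "linear"
    long_detrend: str = "mean"
    # slope fit
    beta_fit_lo_hz: float = BETA_FIT_RANGE[0]
    beta_fit_hi_hz: float = BETA_FIT_RANGE[1]
    # cleaning
    max_rel_change: float = 0.2
    bounds_ms: tuple[float, float] = (300.0, 2000.0)
    # spans / cosinor
    auto_detect_sleep: bool = False
    cosinor_reference: str = "wake"  # or "midnight"
    # stats
    bonferroni_m: int = 5
    # misc
    seed: int = 0
    compute_short_bands: bool = True

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bounds_ms" in data:
            data["bounds_ms"] = tuple(data["bounds_ms"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["bounds_ms"] = list(d["bounds_ms"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# Per-record analysis
# ---------------------------------------------------------------------------

def analyze_record(
    series: NNSeries,
    spans: SpanLabels,
    config: RunConfig | None = None,
) -> dict:
    """Window-level indices and span summary for one cleaned record.

    Returns a dict with ``windows_long`` (beta, ULF bands per 180-min
    window), ``windows_short`` (HF/LF/VLF per 5-min window, if enabled),
    ``summary`` (span means) and ``cosinor`` (single cosinor fit of the
    beta window series against hours since arising).
    """
    cfg = config or RunConfig()
    long_even = resample_even(series, cfg.resample_rate_long_hz, method="binned")
    dur = long_even.n * long_even.dt
    sched = window_schedule(dur, cfg.long_window_s, cfg.long_step_s)
    nwin = int(round(cfg.long_window_s * cfg.resample_rate_long_hz))
    step = int(round(cfg.long_step_s * cfg.resample_rate_long_hz))

    rows = []
    for wi, (start, mid, end) in enumerate(sched):
        w = long_even.values[wi * step : wi * step + nwin]
        w = _detrend(w, cfg.long_detrend)
        model = fit_auto(
            EvenSeries(w, long_even.dt),
            criterion=cfg.long_order_criterion,
            max_order=cfg.long_max_order,
            fixed_order=cfg.long_fixed_order,
        )
        est = beta_slope(model, (cfg.beta_fit_lo_hz, cfg.beta_fit_hi_hz), window_mid_time=mid)
        row = {
            "window_mid_time": long_even.start_time + mid,
            "beta": est.beta,
            "alpha": est.alpha,
            "r_squared": est.r_squared,
            "ar_order": model.order,
        }
        for name in ("ulf", "ulf_band1", "ulf_band2", "ulf_band3"):
            row[name] = band_power(model, *BANDS[name])
        rows.append(row)
    windows_long = pd.DataFrame(rows)
    windows_long["span_label"] = spans.label_times(windows_long["window_mid_time"].to_numpy())

    windows_short = None
    if cfg.compute_short_bands:
        short_even = resample_even(series, cfg.resample_rate_short_hz, method="spline")
        sdur = short_even.n * short_even.dt
        ssched = window_schedule(sdur, cfg.short_window_s, cfg.short_step_s)
        snwin = int(round(cfg.short_window_s * cfg.resample_rate_short_hz))
        sstep = int(round(cfg.short_step_s * cfg.resample_rate_short_hz))
        srows = []
        for wi, (start, mid, end) in enumerate(ssched):
            w = short_even.values[wi * sstep : wi * sstep + snwin]
            w = _detrend(w, cfg.short_detrend)
            model = fit_auto(
                EvenSeries(w, short_even.dt), criterion=cfg.short_order_criterion, max_order=cfg.short_max_order
            )
            srow = {"window_mid_time": short_even.start_time + mid}
            for name in ("vlf", "lf", "hf"):
                srow[name] = band_power(model, *BANDS[name])
            srows.append(srow)
        windows_short = pd.DataFrame(srows)
        windows_short["span_label"] = spans.label_times(windows_short["window_mid_time"].to_numpy())

    values = {c: windows_long[c].to_numpy() for c in ("beta", "alpha", "ulf", "ulf_band1", "ulf_band2", "ulf_band3")}
    summary = span_summary(windows_long["window_mid_time"].to_numpy(), values, spans)
    if windows_short is not None:
        svalues = {c: windows_short[c].to_numpy() for c in ("vlf", "lf", "hf")}
        ssummary = span_summary(windows_short["window_mid_time"].to_numpy(), svalues, spans)
        summary.update({k: v for k, v in ssummary.items() if not k.startswith("n_windows")})
        summary["n_windows_short"] = int(len(windows_short))

    # cosinor of the beta window series, hours after arising (or midnight)
    ref_s = spans.wake_reference_s if cfg.cosinor_reference == "wake" else 0.0
    t_h = (windows_long["window_mid_time"].to_numpy() - ref_s) / 3600.0
    fit = cs.single_cosinor(t_h, windows_long["beta"].to_numpy(), subject_id=series.subject_id)
    return {
        "windows_long": windows_long,
        "windows_short": windows_short,
        "summary": summary,
        "cosinor": fit,
    }


def _detrend(w: np.ndarray, mode: str) -> np.ndarray:
    if mode == "mean":
        return w - w.mean()
    if mode == "linear":
        t = np.arange(w.size, dtype=float)
        return w - np.polyval(np.polyfit(t, w, 1), t)
    raise ValueError(f"unknown detrend mode {mode!r}")


# ---------------------------------------------------------------------------
# Cohort analysis
# ---------------------------------------------------------------------------

def analyze_cohort(cohort: Cohort, config: RunConfig | None = None) -> dict:
    """Full pipeline over a cohort of records plus its diary.

    Returns session summaries (one row per subject x session), the
    statistics table over the space-vs-Earth and in-flight contrasts, and
    population-mean cosinor summaries for the Earth and space conditions.
    """
    cfg = config or RunConfig()
    diary = cohort.diary
    summaries = []
    fits: dict[tuple[str, str], cs.CosinorFit] = {}
    run_log = {"config_hash": cfg.hash(), "records": {}}
    for (subj, session), series in sorted(cohort.records.items()):
        cleaned, report = filter_normal_beats(
            series, max_rel_change=cfg.max_rel_change, bounds_ms=cfg.bounds_ms
        )
        drows = diary[(diary.subject_id == subj) & (diary.session_id == session)]
        iv = [
            (_clock_h(r.sleep_onset), _clock_h(r.sleep_offset))
            for r in drows.itertuples()
        ]
        spans = label_sleep_wake(cleaned, iv, auto_detect=cfg.auto_detect_sleep)
        res = analyze_record(cleaned, spans, cfg)
        row = {"subject_id": subj, "session_id": session, **res["summary"]}
        summaries.append(row)
        fits[(subj, session)] = res["cosinor"]
        run_log["records"][f"{subj}/{session}"] = {
            "beats_read": series.n_beats,
            "beats_excluded": report.n_excluded,
            "windows_long": int(len(res["windows_long"])),
            "sleep_h": spans.total_sleep_h,
        }

    summary_df = pd.DataFrame(summaries)
    sessions = [s for s in gs.STAGES if s in set(summary_df.session_id)]

    # group statistics on per-subject session means (24-h values)
    indices = {}
    for col, name in (("beta_24h", "beta"), ("ulf_24h", "ulf"), ("vlf_24h", "vlf"), ("lf_24h", "lf"), ("hf_24h", "hf")):
        if col in summary_df.columns and summary_df[col].notna().all():
            wide = summary_df.pivot(index="subject_id", columns="session_id", values=col)
            if set(gs.STAGES) <= set(wide.columns):
                indices[name] = wide
    stats_df = gs.statistics_table(indices, m_bonferroni=cfg.bonferroni_m) if indices else pd.DataFrame()

    # population-mean cosinor per condition: average per-subject rhythm
    # vectors over the condition's sessions, then summarize across subjects
    pop = {}
    for cond, cond_sessions in (("earth", ("Pre", "Post")), ("space", ("F01", "F02", "F03"))):
        cond_fits = []
        for subj in sorted({s for s, _ in fits}):
            sub = [fits[(subj, ses)] for ses in cond_sessions if (subj, ses) in fits]
            if sub:
                cond_fits.append(_average_fits(sub, subj))
        if len(cond_fits) >= 3:
            pop[cond] = cs.population_mean_cosinor(cond_fits)

    return {
        "session_summary": summary_df,
        "statistics": stats_df,
        "cosinor_fits": fits,
        "population_cosinor": pop,
        "run_log": run_log,
    }


def _average_fits(fits: list[cs.CosinorFit], subject_id: str) -> cs.CosinorFit:
    """Per-subject condition average of cosinor fits (mean rhythm vector)."""
    bc = float(np.mean([f.beta_c for f in fits]))
    bs = float(np.mean([f.beta_s for f in fits]))
    mesor = float(np.mean([f.mesor for f in fits]))
    amp = float(np.hypot(bc, bs))
    return cs.CosinorFit(
        mesor=mesor,
        amplitude=amp,
        acrophase_deg=cs._acrophase_deg(bc, bs),
        period_h=fits[0].period_h,
        beta_c=bc,
        beta_s=bs,
        residual_var=float(np.mean([f.residual_var for f in fits])),
        n=sum(f.n for f in fits),
        ci_mesor=(mesor, mesor),
        ci_amplitude=(amp, amp),
        subject_id=subject_id,
    )


def _clock_h(s: str) -> float:
    from .nn_io import _parse_clock

    return _parse_clock(s)


# ---------------------------------------------------------------------------
# Replication mode
# ---------------------------------------------------------------------------

def replication_analysis(
    indices: dict[str, pd.DataFrame] | None = None,
    m_bonferroni: int = gs.DEFAULT_BONFERRONI_M,
) -> pd.DataFrame:
    """Group statistics directly from per-subject session values.

    Defaults to the bundled reference cohort (the published per-astronaut
    24-h values), exercising the identical group-statistics code path used
    by the full pipeline.
    """
    if indices is None:
        from .datasets import load_reference_cohort

        indices = load_reference_cohort()
    return gs.statistics_table(indices, m_bonferroni=m_bonferroni)


# ---------------------------------------------------------------------------
# Disk-facing entry points
# ---------------------------------------------------------------------------

def analyze_directory(indir: str | Path, outdir: str | Path, config: RunConfig | None = None) -> dict:
    """Analyze a directory of RR files + diary.csv written by ``simulate``."""
    indir = Path(indir)
    cfg = config or RunConfig()
    diary = read_diary(indir / "diary.csv")
    records = {}
    for p in sorted(indir.glob("*.rr.csv")):
        subj, session = p.name.replace(".rr.csv", "").split("_", 1)
        records[(subj, session)] = read_rr(p, subject_id=subj, session_id=session)
    cohort = Cohort(records=records, diary=diary, ground_truth={})
    results = analyze_cohort(cohort, cfg)
    save_results(results, outdir, cfg)
    return results


def save_results(results: dict, outdir: str | Path, cfg: RunConfig) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {"session_summary": results["session_summary"]}
    if len(results["statistics"]):
        tables["statistics"] = results["statistics"]
    pop_rows = []
    for cond, p in results.get("population_cosinor", {}).items():
        pop_rows.append(
            {
                "condition": cond,
                "mesor": p.mesor,
                "amplitude": p.amplitude,
                "acrophase_deg": p.acrophase_deg,
                "acrophase_h_after_wake": cs.acrophase_to_hours(p.acrophase_deg),
                "p_zero_amplitude": p.p_zero_amplitude,
                "k": p.k,
            }
        )
    if pop_rows:
        tables["population_cosinor"] = pd.DataFrame(pop_rows)
    write_results(tables, outdir)
    cfg.to_yaml(outdir / "config.yaml")
    with (outdir / "run_log.json").open("w") as fh:
        json.dump(results.get("run_log", {}), fh, indent=1)


def report(results_dir: str | Path) -> str:
    """Human-readable markdown summary of a results directory."""
    results_dir = Path(results_dir)
    parts: list[str] = ["# fractalhrv analysis report", ""]
    found = False
    for name, title in (
        ("statistics", "Group statistics (space vs Earth, in-flight ANOVA)"),
        ("population_cosinor", "Population-mean cosinor of the power-law slope"),
        ("session_summary", "Session summaries (per subject x session)"),
    ):
        p = results_dir / f"{name}.csv"
        if p.exists():
            found = True
            df = pd.read_csv(p)
            parts += [f"## {title}", "", "```", df.to_string(index=False), "```", ""]
    if not found:
        raise FileNotFoundError(f"no result tables found in {results_dir}")
    return "\n".join(parts)
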