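"""Synthetic NN-interval cohorts with known ground truth.

The generator emulates the statistical structure that the analysis pipeline
assumes of a 24-h ambulatory NN record:

* a 1/f^beta colored background whose exponent follows a 24-h cosine (MESOR,
  amplitude, acrophase) plus a sleep/wake step, with a session effect
  shifting the MESOR in "space" sessions;
* narrow-band LF (~0.1 Hz) and HF (~0.25 Hz) oscillations;
* integrate-and-fire beat generation with 8-ms Holter quantization;
* sleep spans of 6.17 +/- 1.38 h recorded in a diary;
* occasional ectopic beats for the cleaning step to find.

Colored noise is built by Fourier synthesis over the whole record: a single
set of random spectral phases is shared across a grid of candidate
exponents, and the time-varying exponent is realized by interpolating
pointwise between the coherent fixed-exponent realizations.  This keeps the
full frequency support of the record (down to 1/86400 Hz, well below the
1e-4 Hz lower edge of the power-law fit) while making the local spectral
slope track the target; per-segment synthesis cannot do this, because a
short segment carries no power below the inverse of its own length.  The
background is normalized so the ULF-band (1e-4 to 3e-3 Hz) power matches a
configured target at every exponent, and tapered steeply above a 0.04-Hz
knee so that power beyond the beat-sampling Nyquist does not alias into the
LF/HF bands on the way through beat generation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .mem_spectrum import EvenSeries
from .nn_io import NNSeries, write_rr

SESSIONS = ("Pre", "F01", "F02", "F03", "Post")
SPACE_SESSIONS = ("F01", "F02", "F03")

ULF_EDGES = (1e-4, 3e-3)
F_REF = 1e-3  # Hz, reference frequency for the power-law scale constant


@dataclass
class SubjectModel:
    """Ground-truth parameters for one synthetic subject."""

    subject_id: str = "S01"
    mean_nn: float = 950.0  # ms
    beta_mesor_earth: float = -1.163
    beta_mesor_space: float = -0.949
    beta_circadian_amplitude: float = 0.15  # free parameter, not a published value
    beta_acrophase_earth: float = -308.0  # degrees, phase zero = arising
    beta_acrophase_space: float = -317.0
    delta_beta: float = 0.43  # asleep minus awake target
    sleep_onset_h: float = 16.5  # hours after record start (start = arising)
    sleep_duration_h: float = 6.17
    ulf_ms2: float = 3000.0
    lf_ms2: float = 650.0
    hf_ms2: float = 120.0
    ectopic_rate_per_h: float = 3.0
    quantization_ms: float = 8.0

    def __post_init__(self) -> None:
        if not (600.0 <= self.mean_nn <= 1200.0):
            raise ValueError("mean_nn outside [600, 1200] ms")
        for b in (self.beta_mesor_earth, self.beta_mesor_space):
            if not (-2.0 < b < 0.0):
                raise ValueError("beta MESOR outside (-2, 0)")
        if not (3.0 < self.sleep_duration_h < 10.0):
            raise ValueError("sleep duration outside (3, 10) h")

    def mesor(self, session: str) -> float:
        return self.beta_mesor_space if session in SPACE_SESSIONS else self.beta_mesor_earth

    def acrophase(self, session: str) -> float:
        return self.beta_acrophase_space if session in SPACE_SESSIONS else self.beta_acrophase_earth


# ---------------------------------------------------------------------------
# Instantaneous exponent profile
# ---------------------------------------------------------------------------

def sleep_step_for_delta(
    amplitude: float,
    acrophase_deg: float,
    sleep_interval_s: tuple[float, float],
    delta_beta: float,
    duration_s: float = 86400.0,
) -> float:
    """Step size so that asleep-minus-awake of the full profile equals delta_beta.

    The circadian cosine itself contributes to the sleep/wake contrast
    (sleep sits near the acrophase); the step makes up the remainder.
    """
    a, b = sleep_interval_s
    tt = np.linspace(0.0, duration_s, 8641)
    cosv = np.cos(2 * np.pi * (tt - b) / 86400.0 + np.deg2rad(acrophase_deg))
    asleep = (tt >= a) & (tt < b)
    if not asleep.any() or asleep.all():
        return delta_beta
    cos_contrast = amplitude * (cosv[asleep].mean() - cosv[~asleep].mean())
    return float(delta_beta - cos_contrast)


def synth_beta_profile(
    model: SubjectModel,
    t_s: np.ndarray,
    session: str,
    sleep_interval_s: tuple[float, float],
    duration_s: float = 86400.0,
) -> np.ndarray:
    """Target exponent beta(t): MESOR + circadian cosine + sleep step.

    The cosine's phase zero is the time of arising (the sleep offset), the
    same circadian reference the analysis uses, so the injected acrophase is
    recovered in the same convention.
    """
    t = np.asarray(t_s, dtype=float)
    phi = np.deg2rad(model.acrophase(session))
    step = sleep_step_for_delta(
        model.beta_circadian_amplitude, model.acrophase(session), sleep_interval_s, model.delta_beta, duration_s
    )
    a, b = sleep_interval_s
    prof = (
        model.mesor(session)
        + model.beta_circadian_amplitude * np.cos(2 * np.pi * (t - b) / 86400.0 + phi)
        + step * ((t >= a) & (t < b))
    )
    return prof


# ---------------------------------------------------------------------------
# Colored noise synthesis
# ---------------------------------------------------------------------------

def _ulf_scale(beta: float, ulf_ms2: float) -> float:
    """Constant c with S(f) = c (f/F_REF)^beta integrating to ulf_ms2 over the ULF band."""
    lo, hi = ULF_EDGES
    if abs(beta + 1.0) < 1e-9:
        integral = F_REF * np.log(hi / lo)
    else:
        integral = F_REF ** (-beta) * (hi ** (beta + 1.0) - lo ** (beta + 1.0)) / (beta + 1.0)
    return ulf_ms2 / integral


def synth_colored_series(
    beta_target: float | Callable[[np.ndarray], np.ndarray],
    duration_s: float,
    rate_hz: float,
    rng: np.random.Generator,
    ulf_ms2: float = 3000.0,
    f_knee: float | None = 0.04,
    beta_grid_step: float = 0.1,
) -> EvenSeries:
    """Gaussian series whose local one-sided spectrum follows f^beta(t).

    ``beta_target`` is a scalar or a callable of time (seconds).  The series
    is synthesized over the full duration; for a time-varying target, a grid
    of coherent fixed-exponent realizations (shared spectral phases) is
    interpolated pointwise.  ``f_knee`` tapers the spectrum as f^-4 above
    the knee; None disables the taper.
    """
    if rate_hz < 0.1:
        raise ValueError("rate_hz must be >= 0.1")
    n = int(round(duration_s * rate_hz))
    if n < 32:
        raise ValueError("duration too short to synthesize")
    dt = 1.0 / rate_hz
    t = np.arange(n) * dt
    bt = np.asarray(beta_target(t) if callable(beta_target) else beta_target, dtype=float)
    scalar = bt.ndim == 0
    if scalar:
        bt = np.full(n, float(bt))
    if np.any(bt <= -2.0) or np.any(bt >= 0.0):
        raise ValueError("beta target outside (-2, 0) unsupported" if not scalar else "beta target outside (-2, 0)")

    freqs = np.fft.rfftfreq(n, dt)
    Z = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) / np.sqrt(2.0)
    Z[0] = 0.0
    scale = np.sqrt(n / (2.0 * dt))

    def realization(beta: float) -> np.ndarray:
        S = np.zeros_like(freqs)
        nz = freqs > 0
        S[nz] = _ulf_scale(beta, ulf_ms2) * (freqs[nz] / F_REF) ** beta
        if f_knee is not None:
            hi = freqs > f_knee
            S[hi] *= (freqs[hi] / f_knee) ** -4.0
        return np.fft.irfft(np.sqrt(S) * scale * Z, n)

    if scalar or np.ptp(bt) < 1e-12:
        return EvenSeries(values=realization(float(bt[0])), dt=dt)

    b_lo = np.floor(bt.min() / beta_grid_step) * beta_grid_step
    b_hi = np.ceil(bt.max() / beta_grid_step) * beta_grid_step
    grid = np.arange(b_lo, b_hi + beta_grid_step / 2, beta_grid_step)
    X = np.stack([realization(float(b)) for b in grid])
    idx = np.clip(((bt - grid[0]) / beta_grid_step).astype(int), 0, grid.size - 2)
    w = (bt - grid[idx]) / beta_grid_step
    vals = (1.0 - w) * X[idx, np.arange(n)] + w * X[idx + 1, np.arange(n)]
    return EvenSeries(values=vals, dt=dt)


def narrowband_series(
    duration_s: float,
    rate_hz: float,
    f0: float,
    bandwidth_hz: float,
    power_ms2: float,
    rng: np.random.Generator,
) -> EvenSeries:
    """Narrow-band Gaussian process: Gaussian spectral bump at f0, integral = power."""
    n = int(round(duration_s * rate_hz))
    dt = 1.0 / rate_hz
    freqs = np.fft.rfftfreq(n, dt)
    S = np.exp(-0.5 * ((freqs - f0) / bandwidth_hz) ** 2)
    S *= power_ms2 / np.trapezoid(S, freqs)
    Z = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) / np.sqrt(2.0)
    Z[0] = 0.0
    vals = np.fft.irfft(np.sqrt(S * n / (2.0 * dt)) * Z, n)
    return EvenSeries(values=vals, dt=dt)


# ---------------------------------------------------------------------------
# Beat generation
# ---------------------------------------------------------------------------

def tachogram_to_beats(
    even: EvenSeries,
    quantization_ms: float = 8.0,
    subject_id: str = "synthetic",
    session_id: str = "synthetic",
    start_clock_h: float = 7.0,
) -> NNSeries:
    """Integrate-and-fire: beats spaced by the instantaneous NN of the tachogram.

    The next beat falls one current-NN after the previous one; beat times
    are quantized to the Holter resolution, so every emitted nn_ms is an
    integer multiple of ``quantization_ms``.
    """
    vals = even.values
    if vals.min() < 300.0 or vals.max() > 2000.0:
        raise ValueError("tachogram NN outside [300, 2000] ms")
    v = vals.tolist()
    dt = even.dt
    tmax = (len(v) - 1) * dt
    q = quantization_ms / 1000.0
    beats: list[float] = []
    t = 0.0
    n_grid = len(v)
    while True:
        x = t / dt
        i = int(x)
        if i >= n_grid - 1:
            nn = v[-1]
        else:
            frac = x - i
            nn = v[i] * (1.0 - frac) + v[i + 1] * frac
        t2 = t + nn / 1000.0
        if t2 > tmax:
            break
        beats.append(t2)
        t = t2
    bq = np.round(np.asarray(beats) / q) * q
    nn_ms = np.diff(np.concatenate([[0.0], bq])) * 1000.0
    return NNSeries(
        subject_id=subject_id,
        session_id=session_id,
        beat_times=even.start_time + bq,
        nn_ms=np.round(nn_ms / quantization_ms) * quantization_ms,
        quantization_ms=quantization_ms,
        start_clock_h=start_clock_h,
    )


def inject_ectopics(series: NNSeries, rate_per_h: float, rng: np.random.Generator) -> NNSeries:
    """Insert premature beats (shortened NN + compensatory pause), keeping total time.

    The affected beat is moved earlier so its interval drops to ~45% of
    normal; the following interval lengthens by the complement.  Labels stay
    ``normal`` — finding these is the beat-cleaning step's job.
    """
    n_ect = rng.poisson(rate_per_h * series.duration_s / 3600.0)
    if n_ect == 0:
        return series
    times = series.beat_times.copy()
    q = series.quantization_ms / 1000.0
    idx = rng.choice(np.arange(2, series.n_beats - 2), size=min(n_ect, series.n_beats // 10), replace=False)
    for i in np.sort(idx):
        nn_i = times[i] - times[i - 1]
        times[i] = round((times[i - 1] + 0.45 * nn_i) / q) * q
    nn_ms = np.diff(np.concatenate([[0.0], times])) * 1000.0
    out = NNSeries(
        subject_id=series.subject_id,
        session_id=series.session_id,
        beat_times=times,
        nn_ms=np.round(nn_ms / series.quantization_ms) * series.quantization_ms,
        quantization_ms=series.quantization_ms,
        start_clock_h=series.start_clock_h,
    )
    return out


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    records: dict[tuple[str, str], NNSeries]
    diary: pd.DataFrame
    ground_truth: dict

    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.records})


def generate_cohort(
    n_subjects: int = 7,
    sessions: tuple[str, ...] = SESSIONS,
    space_effect: float = 0.214,
    seed: int = 0,
    duration_s: float = 86400.0,
    tachogram_rate_hz: float = 2.0,
    base_model: SubjectModel | None = None,
    include_short_bands: bool = True,
    ectopic_rate_per_h: float | None = None,
) -> Cohort:
    """Simulate a subjects x sessions cohort of 24-h NN records.

    Each subject draws an Earth MESOR around the group default; the space
    MESOR is that value plus ``space_effect``, so the injected contrast is
    exact per subject.  Sleep onset/duration vary per record (duration
    6.17 +/- 1.38 h).  ``include_short_bands=False`` omits the LF/HF
    narrow-band components for faster slope-only studies.  Deterministic
    under a fixed seed.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    base = base_model or SubjectModel()
    if ectopic_rate_per_h is None:
        ectopic_rate_per_h = base.ectopic_rate_per_h
    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.spawn(n_subjects)
    records: dict[tuple[str, str], NNSeries] = {}
    diary_rows = []
    truth: dict = {
        "seed": seed,
        "space_effect": space_effect,
        "n_subjects": n_subjects,
        "sessions": list(sessions),
        "records": {},
    }
    for si in range(n_subjects):
        subj = f"S{si + 1:02d}"
        s_rng = np.random.default_rng(subj_seeds[si])
        mesor_earth = float(s_rng.normal(base.beta_mesor_earth, 0.10))
        mesor_earth = float(np.clip(mesor_earth, -1.8, -0.4))
        mean_nn = float(s_rng.uniform(860.0, 1040.0))
        rec_seeds = subj_seeds[si].spawn(len(sessions))
        for ti, session in enumerate(sessions):
            rng = np.random.default_rng(rec_seeds[ti])
            model = SubjectModel(
                subject_id=subj,
                mean_nn=mean_nn,
                beta_mesor_earth=mesor_earth,
                beta_mesor_space=float(np.clip(mesor_earth + space_effect, -1.8, -0.3)),
                beta_circadian_amplitude=base.beta_circadian_amplitude,
                beta_acrophase_earth=base.beta_acrophase_earth,
                beta_acrophase_space=base.beta_acrophase_space,
                delta_beta=base.delta_beta,
                sleep_onset_h=float(np.clip(rng.normal(base.sleep_onset_h, 0.5), 14.5, 18.5)),
                sleep_duration_h=float(np.clip(rng.normal(6.17, 1.38), 3.2, 9.8)),
                ulf_ms2=base.ulf_ms2,
                lf_ms2=base.lf_ms2,
                hf_ms2=base.hf_ms2,
                ectopic_rate_per_h=ectopic_rate_per_h,
                quantization_ms=base.quantization_ms,
            )
            sleep_iv = (model.sleep_onset_h * 3600.0, (model.sleep_onset_h + model.sleep_duration_h) * 3600.0)
            series = _simulate_record(
                model, session, sleep_iv, duration_s, tachogram_rate_hz, rng, include_short_bands
            )
            if ectopic_rate_per_h > 0:
                series = inject_ectopics(series, ectopic_rate_per_h, rng)
            records[(subj, session)] = series
            onset_clock = (series.start_clock_h + model.sleep_onset_h) % 24.0
            offset_clock = (onset_clock + model.sleep_duration_h) % 24.0
            diary_rows.append(
                {
                    "subject_id": subj,
                    "session_id": session,
                    "sleep_onset": _fmt_clock(onset_clock),
                    "sleep_offset": _fmt_clock(offset_clock),
                }
            )
            step = sleep_step_for_delta(
                model.beta_circadian_amplitude, model.acrophase(session), sleep_iv, model.delta_beta, duration_s
            )
            truth["records"][f"{subj}/{session}"] = {
                "mesor": model.mesor(session),
                "amplitude": model.beta_circadian_amplitude,
                "acrophase_deg": model.acrophase(session),
                "delta_beta": model.delta_beta,
                "sleep_step": step,
                "sleep_interval_s": list(sleep_iv),
                "mean_nn": mean_nn,
                "ulf_ms2": model.ulf_ms2,
                "lf_ms2": model.lf_ms2,
                "hf_ms2": model.hf_ms2,
                "is_space": session in SPACE_SESSIONS,
            }
    return Cohort(records=records, diary=pd.DataFrame(diary_rows), ground_truth=truth)


def _simulate_record(
    model: SubjectModel,
    session: str,
    sleep_iv: tuple[float, float],
    duration_s: float,
    rate_hz: float,
    rng: np.random.Generator,
    include_short_bands: bool,
) -> NNSeries:
    prof = lambda t: synth_beta_profile(model, t, session, sleep_iv, duration_s)
    colored = synth_colored_series(prof, duration_s, rate_hz, rng, ulf_ms2=model.ulf_ms2)
    nn = model.mean_nn + colored.values
    if include_short_bands:
        nn = nn + narrowband_series(duration_s, rate_hz, 0.10, 0.02, model.lf_ms2, rng).values
        nn = nn + narrowband_series(duration_s, rate_hz, 0.25, 0.04, model.hf_ms2, rng).values
    # physiological clamp before firing; out-of-range tails are vanishingly rare
    nn = np.clip(nn, 320.0, 1980.0)
    tach = EvenSeries(values=nn, dt=1.0 / rate_hz)
    return tachogram_to_beats(
        tach, quantization_ms=model.quantization_ms, subject_id=model.subject_id, session_id=session
    )


def _fmt_clock(h: float) -> str:
    hh = int(h) % 24
    mm = int(round((h - int(h)) * 60.0))
    if mm == 60:
        hh, mm = (hh + 1) % 24, 0
    return f"{hh:02d}:{mm:02d}"


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """RR files (t_nn dialect), diary CSV and ground-truth JSON ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (subj, session), series in cohort.records.items():
        write_rr(series, outdir / f"{subj}_{session}.rr.csv", dialect="t_nn")
    cohort.diary.to_csv(outdir / "diary.csv", index=False)
    with (outdir / "ground_truth.json").open("w") as fh:
        json.dump(cohort.ground_truth, fh, indent=1)
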