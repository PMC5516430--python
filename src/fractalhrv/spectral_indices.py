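"""Window scheduling, HRV band powers, and the 1/f^beta power-law slope.

Frequency bands (Hz), following the long-term HRV conventions:

====================  ===================
HF                    0.15 - 0.40
LF                    0.04 - 0.15
VLF                   0.003 - 0.04
ULF (total)           0.0001 - 0.003
ULF band-1            0.0001 - 0.0003
ULF band-2            0.0003 - 0.001
ULF band-3            0.001 - 0.005
====================  ===================

Band powers are trapezoidal integrals of the MEM density over a log-spaced
grid, in ms^2.  Note ULF band-3 extends past the ULF total upper edge and
overlaps the bottom of VLF; the bands are integrated independently, so
band-1 + band-2 <= ULF total while band-3 deliberately is not nested.

The power-law slope beta is the OLS slope of log10(density) against
log10(frequency) over 0.0001-0.01 Hz on a grid with equal weight per decade;
the derived scaling exponent is alpha = (beta + 1) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mem_spectrum import ARModel, PowerSpectrum, psd
from .nn_io import SpanLabels

#: (f_lo, f_hi) in Hz
BANDS: dict[str, tuple[float, float]] = {
    "hf": (0.15, 0.40),
    "lf": (0.04, 0.15),
    "vlf": (0.003, 0.04),
    "ulf": (1e-4, 0.003),
    "ulf_band1": (1e-4, 3e-4),
    "ulf_band2": (3e-4, 1e-3),
    "ulf_band3": (1e-3, 5e-3),
}

BETA_FIT_RANGE = (1e-4, 1e-2)
GRID_POINTS_PER_DECADE = 100


@dataclass
class BetaEstimate:
    """Power-law fit of a single window's MEM spectrum."""

    beta: float
    intercept: float
    r_squared: float
    window_mid_time: float | None = None
    span_label: str | None = None

    @property
    def alpha(self) -> float:
        return alpha_from_beta(self.beta)


def window_schedule(duration_s: float, window_s: float, step_s: float) -> list[tuple[float, float, float]]:
    """(start, mid, end) for every window fully inside [0, duration].

    Consecutive 5-min windows use step == window; the 180-min power-law
    windows use a 5-min stride.  Exactly 24 h yields 288 five-minute and 253
    sliding 180-min windows.
    """
    if window_s > duration_s:
        raise ValueError("window longer than record")
    if step_s <= 0:
        raise ValueError("step must be positive")
    starts = np.arange(0.0, duration_s - window_s + 1e-9, step_s)
    return [(float(s), float(s + window_s / 2), float(s + window_s)) for s in starts]


def log_grid(f_lo: float, f_hi: float, per_decade: int = GRID_POINTS_PER_DECADE) -> np.ndarray:
    npts = max(int(round(np.log10(f_hi / f_lo) * per_decade)) + 1, 10)
    return np.logspace(np.log10(f_lo), np.log10(f_hi), npts)


def band_power(spec: PowerSpectrum | ARModel, f_lo: float, f_hi: float) -> float:
    """Integrated power (ms^2) over [f_lo, f_hi) on a dense log-spaced grid.

    Accepts either a fitted AR model (evaluated exactly on the grid) or a
    PowerSpectrum (log-log interpolated onto the grid, which must be covered
    by the spectrum's support).
    """
    if not (0.0 < f_lo < f_hi):
        raise ValueError("need 0 < f_lo < f_hi")
    grid = log_grid(f_lo, f_hi)
    if isinstance(spec, ARModel):
        grid = _pole_refined_grid(spec, grid, f_lo, f_hi)
        dens = psd(spec, grid).density
    else:
        if f_lo < spec.freqs[0] * (1 - 1e-9) or f_hi > spec.freqs[-1] * (1 + 1e-9):
            raise ValueError("band outside spectrum support")
        dens = _loglog_interp(spec, grid)
    return float(np.trapezoid(dens, grid))


def _pole_refined_grid(model: ARModel, grid: np.ndarray, f_lo: float, f_hi: float) -> np.ndarray:
    """Add integration points around each AR pole inside the band.

    A pole close to the unit circle makes the MEM density a near-Lorentzian
    peak whose half-width (-ln|r| / (2 pi dt)) can be far narrower than any
    fixed grid spacing; without refinement a narrow oscillation's power is
    silently missed.  Points are placed on an arctangent scale around each
    pole frequency so the Lorentzian is sampled evenly in its own metric.
    """
    if model.order == 0:
        return grid
    roots = model.characteristic_roots()
    extra = []
    tan_grid = np.tan(np.linspace(-1.55, 1.55, 81))
    for r in roots:
        if np.imag(r) < 0 or np.abs(r) < 0.5:
            continue
        f0 = np.abs(np.angle(r)) / (2 * np.pi * model.dt)
        hw = max(-np.log(np.abs(r)) / (2 * np.pi * model.dt), 1e-12)
        pts = f0 + hw * tan_grid
        pts = pts[(pts > f_lo) & (pts < f_hi)]
        if pts.size:
            extra.append(pts)
    if not extra:
        return grid
    return np.unique(np.concatenate([grid, *extra]))


def beta_slope(
    spec: PowerSpectrum | ARModel,
    f_range: tuple[float, float] = BETA_FIT_RANGE,
    window_mid_time: float | None = None,
    span_label: str | None = None,
) -> BetaEstimate:
    """OLS slope of log10(density) vs log10(f) over the power-law range."""
    f_lo, f_hi = f_range
    grid = log_grid(f_lo, f_hi)
    if grid.size < 10:
        raise ValueError("need at least 10 grid points in the fit range")
    if isinstance(spec, ARModel):
        dens = psd(spec, grid).density
    else:
        if f_lo < spec.freqs[0] * (1 - 1e-9) or f_hi > spec.freqs[-1] * (1 + 1e-9):
            raise ValueError("spectrum does not cover the fit range")
        dens = _loglog_interp(spec, grid)
    if np.any(dens <= 0):
        raise ValueError("non-positive density in fit range (log undefined)")
    lx = np.log10(grid)
    ly = np.log10(dens)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return BetaEstimate(
        beta=float(slope),
        intercept=float(intercept),
        r_squared=max(0.0, min(1.0, r2)),
        window_mid_time=window_mid_time,
        span_label=span_label,
    )


def alpha_from_beta(beta: float) -> float:
    """Scaling exponent alpha = (beta + 1) / 2 (DFA-equivalent mapping)."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return (beta + 1.0) / 2.0


def _loglog_interp(spec: PowerSpectrum, grid: np.ndarray) -> np.ndarray:
    if np.any(spec.density <= 0):
        raise ValueError("non-positive density in spectrum")
    ld = np.interp(np.log10(grid), np.log10(spec.freqs), np.log10(spec.density))
    return 10.0**ld


# ---------------------------------------------------------------------------
# Span summaries
# ---------------------------------------------------------------------------

def span_summary(
    window_mid_times: np.ndarray,
    values: dict[str, np.ndarray],
    spans: SpanLabels,
) -> dict[str, float | int | None]:
    """Arithmetic means over the 24-h, awake and asleep spans.

    Each window contributes to exactly one span, decided by its midpoint
    label (the rule that reproduces ~70 asleep windows out of ~250 for a
    6.17-h sleep span with 180-min windows stepped 5 min).  Empty spans are
    reported as None, never as zero.  For beta, the sleep/wake difference is
    reported as delta_beta = asleep mean - awake mean (positive: the slope
    is less negative during sleep), together with two alpha versions:
    ``delta_alpha_of_delta_beta`` = (delta_beta + 1) / 2 (the published
    convention) and ``delta_alpha_halved`` = delta_beta / 2 (the algebraic
    difference of span alphas).
    """
    mids = np.asarray(window_mid_times, dtype=float)
    labels = spans.label_times(mids)
    out: dict[str, float | int | None] = {
        "n_windows_24h": int(mids.size),
        "n_windows_awake": int(np.sum(labels == "awake")),
        "n_windows_asleep": int(np.sum(labels == "asleep")),
    }
    for name, vals in values.items():
        v = np.asarray(vals, dtype=float)
        out[f"{name}_24h"] = float(np.mean(v)) if v.size else None
        for span in ("awake", "asleep"):
            sel = v[labels == span]
            out[f"{name}_{span}"] = float(np.mean(sel)) if sel.size else None
    if "beta" in values:
        aw, asl = out.get("beta_awake"), out.get("beta_asleep")
        if aw is not None and asl is not None:
            db = asl - aw
            out["delta_beta"] = db
            out["delta_alpha_of_delta_beta"] = (db + 1.0) / 2.0
            out["delta_alpha_halved"] = db / 2.0
        else:
            out["delta_beta"] = None
            out["delta_alpha_of_delta_beta"] = None
            out["delta_alpha_halved"] = None
    return out
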