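"""Maximum-entropy (Burg autoregressive) spectral estimation of NN tachograms.

The maximum entropy method models a mean-centered, evenly sampled series as
an autoregressive process

    x_t = a_1 x_{t-1} + ... + a_p x_{t-p} + e_t,   e_t ~ (0, sigma^2)

fitted by the Burg recursion, which minimizes the sum of forward and backward
prediction errors and keeps every reflection coefficient in (-1, 1), so the
fitted model is always stationary.  Its one-sided power spectral density is

    S(f) = 2 sigma^2 dt / |1 - sum_k a_k exp(-i 2 pi f k dt)|^2

in ms^2/Hz, scaled so that the integral over (0, Nyquist] approximates the
series variance.  MEM gives smooth spectra from short windows, which is what
makes a power-law fit over two decades of frequency possible from a 180-min
window.

Two resampling regimes serve the analysis: a cubic-spline tachogram at 2 Hz
for 5-min windows (HF/LF/VLF; Nyquist 1 Hz), and 10-s bin means (0.1 Hz) for
180-min windows (ULF and the power-law slope; Nyquist 0.05 Hz).  Bin
averaging doubles as a crude anti-alias filter with spectral nulls at
multiples of 0.1 Hz, suppressing LF/HF leakage into the slow stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .nn_io import NNSeries


class DegenerateInputError(ValueError):
    """Zero-variance or otherwise unusable input series."""


class ConfigurationError(ValueError):
    pass


@dataclass
class EvenSeries:
    """Evenly resampled tachogram: NN in ms on a uniform grid."""

    values: np.ndarray
    dt: float
    start_time: float = 0.0
    detrended: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 16:
            raise ValueError("EvenSeries needs at least 16 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in EvenSeries")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def nyquist(self) -> float:
        return 0.5 / self.dt

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) * self.dt


@dataclass
class ARModel:
    """Autoregressive model in predictor convention x_t = sum a_k x_{t-k} + e_t."""

    order: int
    coefficients: np.ndarray
    noise_variance: float
    dt: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != self.order:
            raise ValueError("order must equal number of coefficients")
        if self.noise_variance <= 0:
            raise ValueError("noise variance must be positive")
        self._roots: np.ndarray | None = None

    def characteristic_roots(self) -> np.ndarray:
        """Roots of 1 - a_1 z^-1 - ... - a_p z^-p (cached; all inside the unit circle)."""
        if self._roots is None:
            self._roots = (
                np.roots(np.concatenate([[1.0], -self.coefficients])) if self.order else np.zeros(0)
            )
        return self._roots


@dataclass
class PowerSpectrum:
    """One-sided PSD on a strictly increasing frequency grid (ms^2/Hz)."""

    freqs: np.ndarray
    density: np.ndarray
    window_mid_time: float | None = None
    window_length: float | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("negative power density")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_even(
    series: NNSeries,
    rate_hz: float,
    method: str = "spline",
    min_nyquist_hz: float | None = None,
    fine_rate_hz: float = 2.0,
) -> EvenSeries:
    """Resample a (cleaned) NN series onto a uniform grid.

    ``spline``: cubic-spline interpolation of nn_ms against beat time,
    evaluated at ``rate_hz``.  ``binned``: spline at ``fine_rate_hz`` then
    averaged into 1/rate_hz bins — preferred for slow streams, where the bin
    mean suppresses aliasing of LF/HF power.  The mean is left in place;
    detrending is the spectral step's decision.
    """
    if rate_hz <= 0:
        raise ConfigurationError("rate_hz must be positive")
    if min_nyquist_hz is not None and rate_hz < 2.0 * min_nyquist_hz:
        raise ConfigurationError(
            f"resample rate {rate_hz} Hz below 2x the highest analysis frequency {min_nyquist_hz} Hz"
        )
    mask = series.normal_mask()
    t = series.beat_times[mask]
    y = series.nn_ms[mask]
    if t.size < 2:
        raise DegenerateInputError("need at least 2 normal beats to resample")
    cs = CubicSpline(t, y)
    if method == "spline":
        grid = np.arange(t[0], t[-1], 1.0 / rate_hz)
        return EvenSeries(values=cs(grid), dt=1.0 / rate_hz, start_time=float(t[0]))
    if method == "binned":
        if fine_rate_hz < rate_hz:
            raise ConfigurationError("fine_rate_hz must be >= rate_hz")
        per_bin = int(round(fine_rate_hz / rate_hz))
        fine = np.arange(t[0], t[-1], 1.0 / fine_rate_hz)
        vals = cs(fine)
        nbins = vals.size // per_bin
        binned = vals[: nbins * per_bin].reshape(nbins, per_bin).mean(axis=1)
        return EvenSeries(values=binned, dt=1.0 / rate_hz, start_time=float(t[0]))
    raise ConfigurationError(f"unknown resampling method {method!r}")


# ---------------------------------------------------------------------------
# Burg recursion
# ---------------------------------------------------------------------------

def _burg_recursion(x: np.ndarray, max_order: int):
    """Run the Burg lattice recursion up to ``max_order``.

    Returns (orders_reached, coeffs_by_order, sigma2_by_order) where
    ``coeffs_by_order[m]`` are the predictor coefficients of the order-m
    model and ``sigma2_by_order[m]`` the residual variance (index 0 = the
    zero-order model).  The recursion stops early if the prediction error
    energy vanishes (e.g. for a noise-free deterministic signal).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_order >= n:
        raise ValueError("order must be smaller than the series length")
    sigma2 = float(np.mean(x * x))
    if sigma2 <= 0.0:
        raise DegenerateInputError("zero-variance input")
    f = x.copy()
    b = x.copy()
    coeffs: list[np.ndarray] = [np.zeros(0)]
    sigmas: list[float] = [sigma2]
    a = np.zeros(0)
    for m in range(1, max_order + 1):
        ff = f[1:]
        bb = b[:-1]
        denom = ff @ ff + bb @ bb
        if denom <= 1e-30 * n * sigmas[0]:
            break
        k = 2.0 * (ff @ bb) / denom  # reflection coefficient, |k| < 1
        a_new = np.empty(m)
        if m > 1:
            a_new[: m - 1] = a - k * a[::-1]
        a_new[m - 1] = k
        sigma2 = sigma2 * (1.0 - k * k)
        if sigma2 <= 0.0:
            coeffs.append(a_new)
            sigmas.append(max(sigma2, 1e-300))
            break
        f, b = ff - k * bb, bb - k * ff
        a = a_new
        coeffs.append(a_new)
        sigmas.append(sigma2)
    return len(coeffs) - 1, coeffs, sigmas


def burg_fit(x: EvenSeries | np.ndarray, order: int) -> ARModel:
    """Fit an AR model of the given order by the Burg recursion.

    The input should be mean-centered (the pipeline removes the window mean
    or a linear trend first).  If the recursion terminates early on a
    degenerate signal, the model at the highest reachable order is returned.
    """
    vals, dt = _unpack(x)
    reached, coeffs, sigmas = _burg_recursion(vals, order)
    m = min(order, reached)
    return ARModel(order=m, coefficients=coeffs[m], noise_variance=sigmas[m], dt=dt)


def select_order(
    x: EvenSeries | np.ndarray,
    criterion: str = "aic",
    max_order: int = 30,
    fixed_order: int | None = None,
) -> int:
    """Choose an AR order by AIC or FPE over 1..max_order, or return a fixed one.

    AIC: n log sigma_p^2 + 2p.  FPE: sigma_p^2 (n+p+1)/(n-p-1).
    """
    if criterion == "fixed":
        if fixed_order is None:
            raise ConfigurationError("fixed criterion needs fixed_order")
        return int(fixed_order)
    vals, _ = _unpack(x)
    n = vals.size
    if max_order >= n / 2:
        raise ValueError("max_order must be < length/2")
    reached, _, sigmas = _burg_recursion(vals, max_order)
    orders = np.arange(reached + 1)
    s = np.asarray(sigmas)
    if criterion == "aic":
        crit = n * np.log(s) + 2.0 * orders
    elif criterion == "fpe":
        crit = s * (n + orders + 1) / (n - orders - 1)
    else:
        raise ConfigurationError(f"unknown criterion {criterion!r}")
    best = int(np.argmin(crit[1:])) + 1 if reached >= 1 else 0
    return best


def fit_auto(
    x: EvenSeries | np.ndarray,
    criterion: str = "aic",
    max_order: int = 30,
    fixed_order: int | None = None,
) -> ARModel:
    """Order selection + fit in a single recursion pass."""
    vals, dt = _unpack(x)
    if criterion == "fixed":
        return burg_fit(x, int(fixed_order if fixed_order is not None else max_order))
    n = vals.size
    reached, coeffs, sigmas = _burg_recursion(vals, max_order)
    orders = np.arange(reached + 1)
    s = np.asarray(sigmas)
    crit = n * np.log(s) + 2.0 * orders if criterion == "aic" else s * (n + orders + 1) / (n - orders - 1)
    m = int(np.argmin(crit[1:])) + 1 if reached >= 1 else 0
    return ARModel(order=m, coefficients=coeffs[m], noise_variance=sigmas[m], dt=dt)


def psd(model: ARModel, freqs: np.ndarray) -> PowerSpectrum:
    """One-sided MEM power spectral density at the given frequencies.

    S(f) = 2 sigma^2 dt / |1 - sum_k a_k e^{-i 2 pi f k dt}|^2; the factor 2
    folds negative frequencies so the integral over (0, Nyquist] matches the
    series variance.
    """
    f = np.asarray(freqs, dtype=float)
    if f.size == 0:
        raise ValueError("empty frequency list")
    if np.any(f <= 0) or np.any(f > 0.5 / model.dt + 1e-12):
        raise ValueError("frequencies must lie in (0, Nyquist]")
    k = np.arange(1, model.order + 1)
    E = np.exp(-2j * np.pi * np.outer(f, k) * model.dt)
    denom = np.abs(1.0 - E @ model.coefficients) ** 2
    dens = 2.0 * model.noise_variance * model.dt / denom
    return PowerSpectrum(freqs=f, density=dens)


def _unpack(x: EvenSeries | np.ndarray) -> tuple[np.ndarray, float]:
    if isinstance(x, EvenSeries):
        return x.values, x.dt
    return np.asarray(x, dtype=float), 1.0
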