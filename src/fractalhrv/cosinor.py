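"""Cosinor rhythmometry: single-subject fits, population-mean summary, tests.

A 24-h rhythm in a variable y sampled at times t (hours) is modelled as

    y = M + beta_c cos(2 pi t / tau) + beta_s sin(2 pi t / tau) + e

fitted by ordinary least squares.  The rhythm parameters are the MESOR M
(Midline-Estimating Statistic Of Rhythm, the rhythm-adjusted mean), the
amplitude A = sqrt(beta_c^2 + beta_s^2) (half the predictable within-day
change) and the acrophase phi (timing of the fitted maximum), reported here
in negative degrees with 360 deg = 24 h, measured clockwise from phase zero
(by convention the time of arising).

A group of k subjects is summarized by the population-mean cosinor: the
per-subject (beta_c, beta_s) vectors are averaged, and the null hypothesis
of no rhythm (A = 0) is tested by Hotelling's T^2 on the mean vector, with
an F(2, k-2) reference distribution.  The 95% confidence region of the mean
vector is an ellipse in the (beta_c, beta_s) plane; it excludes the origin
exactly when p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class SingularDesignError(ValueError):
    """All samples at one phase: the cosinor design matrix is rank-deficient."""


class InsufficientSubjectsError(ValueError):
    pass


@dataclass
class CosinorFit:
    mesor: float
    amplitude: float
    acrophase_deg: float
    period_h: float
    beta_c: float
    beta_s: float
    residual_var: float
    n: int
    ci_mesor: tuple[float, float]
    ci_amplitude: tuple[float, float]
    subject_id: str | None = None

    def predict(self, times_h: np.ndarray) -> np.ndarray:
        w = 2.0 * np.pi / self.period_h
        return self.mesor + self.beta_c * np.cos(w * times_h) + self.beta_s * np.sin(w * times_h)


@dataclass
class PopulationCosinor:
    mesor: float
    amplitude: float
    acrophase_deg: float
    period_h: float
    mean_beta_c: float
    mean_beta_s: float
    covariance: np.ndarray
    p_zero_amplitude: float
    k: int
    ci_mesor: tuple[float, float]
    ci_amplitude: tuple[float, float] | None
    ci_acrophase_deg: tuple[float, float] | None

    def ellipse_excludes_origin(self, alpha: float = 0.05) -> bool:
        return self.p_zero_amplitude < alpha

    def ellipse_points(self, n_points: int = 100, alpha: float = 0.05) -> np.ndarray:
        """Sampled boundary of the confidence region for the mean (beta_c, beta_s)."""
        return _ellipse_boundary(
            np.array([self.mean_beta_c, self.mean_beta_s]), self.covariance, self.k, alpha, n_points
        )


# ---------------------------------------------------------------------------
# Single cosinor
# ---------------------------------------------------------------------------

def single_cosinor(
    times_h: np.ndarray,
    values: np.ndarray,
    period_h: float = 24.0,
    subject_id: str | None = None,
) -> CosinorFit:
    """Least-squares 24-h cosine fit of one subject's series."""
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("times and values length mismatch")
    if np.unique(t).size < 4:
        raise ValueError("need at least 4 distinct sample times")
    if t.max() - t.min() < period_h / 2:
        raise ValueError("samples must span at least half a period")
    w = 2.0 * np.pi / period_h
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    gram = X.T @ X
    if np.linalg.cond(gram) > 1e10:
        raise SingularDesignError("samples concentrated at a single phase")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mesor, bc, bs = (float(c) for c in coef)
    resid = y - X @ coef
    dof = max(t.size - 3, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(gram)
    amp = float(np.hypot(bc, bs))
    tcrit = stats.t.ppf(0.975, dof)
    se_m = float(np.sqrt(cov[0, 0]))
    # delta-method SE of the amplitude along the mean vector direction
    if amp > 0:
        g = np.array([bc / amp, bs / amp])
        se_a = float(np.sqrt(g @ cov[1:, 1:] @ g))
    else:
        se_a = float(np.sqrt(max(cov[1, 1], cov[2, 2])))
    return CosinorFit(
        mesor=mesor,
        amplitude=amp,
        acrophase_deg=_acrophase_deg(bc, bs),
        period_h=period_h,
        beta_c=bc,
        beta_s=bs,
        residual_var=s2,
        n=int(t.size),
        ci_mesor=(mesor - tcrit * se_m, mesor + tcrit * se_m),
        ci_amplitude=(max(0.0, amp - tcrit * se_a), amp + tcrit * se_a),
        subject_id=subject_id,
    )


def _acrophase_deg(beta_c: float, beta_s: float) -> float:
    """Acrophase in (-360, 0]: bc cos(wt) + bs sin(wt) = A cos(wt + phi_rad)."""
    phi = -np.degrees(np.arctan2(beta_s, beta_c))
    if phi > 0:
        phi -= 360.0
    if phi <= -360.0:
        phi += 360.0
    return float(phi)


def acrophase_to_hours(phi_deg: float) -> float:
    """Hours after phase zero at which the fitted maximum occurs (360 deg = 24 h)."""
    if not (-360.0 < phi_deg <= 0.0):
        raise ValueError("acrophase must lie in (-360, 0] degrees")
    return -phi_deg / 360.0 * 24.0


def hours_to_acrophase(hours: float) -> float:
    phi = -(hours % 24.0) / 24.0 * 360.0
    return float(phi if phi > -360.0 else phi + 360.0)


# ---------------------------------------------------------------------------
# Population-mean cosinor
# ---------------------------------------------------------------------------

def population_mean_cosinor(fits: list[CosinorFit], alpha: float = 0.05) -> PopulationCosinor:
    """Group summary of per-subject fits with the zero-amplitude test.

    The per-subject rhythm vectors (beta_c, beta_s) are averaged; their
    between-subject scatter provides the bivariate confidence region
    (Hotelling T^2, F with (2, k-2) degrees of freedom).  Serial correlation
    within each subject's series does not enter: inference rests on the
    k independent subjects.
    """
    k = len(fits)
    if k < 3:
        raise InsufficientSubjectsError("population-mean cosinor needs >= 3 subjects")
    taus = {f.period_h for f in fits}
    if len(taus) != 1:
        raise ValueError("all fits must share the same period")
    B = np.array([[f.beta_c, f.beta_s] for f in fits])
    M = np.array([f.mesor for f in fits])
    mean_vec = B.mean(axis=0)
    S = np.cov(B, rowvar=False)
    amp = float(np.hypot(*mean_vec))
    # Hotelling T^2 for H0: population mean rhythm vector = 0
    det = float(np.linalg.det(S))
    if det <= 1e-30 * (np.trace(S) ** 2 + 1e-300):
        # degenerate scatter (e.g. identical subjects): zero-area ellipse
        p_zero = 0.0 if amp > 0 else 1.0
    else:
        t2 = k * float(mean_vec @ np.linalg.solve(S, mean_vec))
        F = (k - 2) / (2.0 * (k - 1)) * t2
        p_zero = float(stats.f.sf(F, 2, k - 2))
    tcrit = stats.t.ppf(1 - alpha / 2, k - 1)
    se_m = float(M.std(ddof=1) / np.sqrt(k))
    ci_m = (float(M.mean() - tcrit * se_m), float(M.mean() + tcrit * se_m))
    ci_a = ci_phi = None
    if det > 0 and p_zero < alpha:
        pts = _ellipse_boundary(mean_vec, S, k, alpha, 360)
        radii = np.hypot(pts[:, 0], pts[:, 1])
        ci_a = (float(radii.min()), float(radii.max()))
        phis = np.array([_acrophase_deg(x, y) for x, y in pts])
        ci_phi = _angular_range(phis)
    return PopulationCosinor(
        mesor=float(M.mean()),
        amplitude=amp,
        acrophase_deg=_acrophase_deg(*mean_vec),
        period_h=fits[0].period_h,
        mean_beta_c=float(mean_vec[0]),
        mean_beta_s=float(mean_vec[1]),
        covariance=S,
        p_zero_amplitude=p_zero,
        k=k,
        ci_mesor=ci_m,
        ci_amplitude=ci_a,
        ci_acrophase_deg=ci_phi,
    )


def _ellipse_boundary(mean_vec: np.ndarray, S: np.ndarray, k: int, alpha: float, n_points: int) -> np.ndarray:
    """Boundary of the (1-alpha) confidence region for the mean rhythm vector."""
    fcrit = stats.f.ppf(1 - alpha, 2, k - 2)
    c2 = 2.0 * (k - 1) / (k * (k - 2)) * fcrit
    vals, vecs = np.linalg.eigh(S)
    vals = np.maximum(vals, 0.0)
    theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    return mean_vec + np.sqrt(c2) * circle * np.sqrt(vals) @ vecs.T


def _angular_range(phis_deg: np.ndarray) -> tuple[float, float]:
    """Smallest arc (in the (-360, 0] convention) containing all angles."""
    a = np.sort(np.mod(phis_deg, 360.0))
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    i = int(np.argmax(gaps))
    lo, hi = a[(i + 1) % a.size], a[i]
    to_neg = lambda x: x - 360.0 if x > 0 else x
    return (to_neg(float(lo)), to_neg(float(hi)))


# ---------------------------------------------------------------------------
# Parameter tests between groups
# ---------------------------------------------------------------------------

def parameter_tests(
    group_a: list[CosinorFit],
    group_b: list[CosinorFit],
    paired: bool | None = None,
) -> dict[str, dict]:
    """Compare MESOR, amplitude and acrophase between two groups of fits.

    MESOR and amplitude by t tests (paired when subject identities match);
    the joint amplitude-acrophase comparison by Hotelling's T^2 on the
    (beta_c, beta_s) vectors; the separate acrophase test on the wrapped
    per-subject phase differences (paired) or a two-sample test on phases.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise InsufficientSubjectsError("each group needs >= 3 fits")
    ids_a = [f.subject_id for f in group_a]
    ids_b = [f.subject_id for f in group_b]
    if paired is None:
        paired = None not in ids_a and set(ids_a) == set(ids_b) and len(set(ids_a)) == len(ids_a)
    if paired:
        if None in ids_a or set(ids_a) != set(ids_b):
            raise ValueError("paired comparison requires matching subject sets")
        order = {s: i for i, s in enumerate(ids_a)}
        group_b = sorted(group_b, key=lambda f: order[f.subject_id])

    Ma = np.array([f.mesor for f in group_a])
    Mb = np.array([f.mesor for f in group_b])
    Aa = np.array([f.amplitude for f in group_a])
    Ab = np.array([f.amplitude for f in group_b])
    Ba = np.array([[f.beta_c, f.beta_s] for f in group_a])
    Bb = np.array([[f.beta_c, f.beta_s] for f in group_b])

    out: dict[str, dict] = {}
    if paired:
        k = len(group_a)
        t_m, p_m = _paired_t_guarded(Ma, Mb)
        t_a, p_a = _paired_t_guarded(Aa, Ab)
        D = Ba - Bb
        Sd = np.cov(D, rowvar=False)
        dbar = D.mean(axis=0)
        if np.linalg.det(Sd) <= 0:
            F_j, p_j = (0.0, 1.0) if np.allclose(dbar, 0) else (np.inf, 0.0)
        else:
            t2 = k * float(dbar @ np.linalg.solve(Sd, dbar))
            F_j = (k - 2) / (2.0 * (k - 1)) * t2
            p_j = float(stats.f.sf(F_j, 2, k - 2))
        dphi = np.array([
            _wrap_deg(fa.acrophase_deg - fb.acrophase_deg) for fa, fb in zip(group_a, group_b)
        ])
        t_p, p_p = _paired_t_guarded(dphi, np.zeros_like(dphi))
        out["mesor"] = dict(statistic=float(t_m), df=k - 1, p=float(p_m), method="paired t")
        out["amplitude"] = dict(statistic=float(t_a), df=k - 1, p=float(p_a), method="paired t")
        out["acrophase"] = dict(statistic=float(t_p), df=k - 1, p=float(p_p), method="paired t on wrapped phase differences")
        out["joint_amplitude_acrophase"] = dict(statistic=float(F_j), df=(2, k - 2), p=float(p_j), method="paired Hotelling T^2")
    else:
        ka, kb = len(group_a), len(group_b)
        t_m, p_m = stats.ttest_ind(Ma, Mb)
        t_a, p_a = stats.ttest_ind(Aa, Ab)
        diff = Ba.mean(axis=0) - Bb.mean(axis=0)
        Sp = ((ka - 1) * np.cov(Ba, rowvar=False) + (kb - 1) * np.cov(Bb, rowvar=False)) / (ka + kb - 2)
        t2 = (ka * kb) / (ka + kb) * float(diff @ np.linalg.solve(Sp, diff))
        F_j = (ka + kb - 3) / (2.0 * (ka + kb - 2)) * t2
        p_j = float(stats.f.sf(F_j, 2, ka + kb - 3))
        pa = np.array([f.acrophase_deg for f in group_a])
        pb = np.array([f.acrophase_deg for f in group_b])
        t_p, p_p = stats.ttest_ind(pa, pb)
        out["mesor"] = dict(statistic=float(t_m), df=ka + kb - 2, p=float(p_m), method="two-sample t")
        out["amplitude"] = dict(statistic=float(t_a), df=ka + kb - 2, p=float(p_a), method="two-sample t")
        out["acrophase"] = dict(statistic=float(t_p), df=ka + kb - 2, p=float(p_p), method="two-sample t on phases")
        out["joint_amplitude_acrophase"] = dict(statistic=float(F_j), df=(2, ka + kb - 3), p=float(p_j), method="two-sample Hotelling T^2")
    return out


def _paired_t_guarded(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired t that treats identically-zero differences as 'no evidence' (p=1)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    scale = max(np.abs(a).max(), np.abs(b).max(), 1.0)
    if np.allclose(d, 0.0, atol=1e-12 * scale) or np.allclose(d.std(ddof=1), 0.0, atol=1e-12 * scale):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def _wrap_deg(d: float) -> float:
    return float((d + 180.0) % 360.0 - 180.0)
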