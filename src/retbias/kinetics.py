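"""Exponential decay fitting for normalized offset traces.

One-phase model:  Y = (Y0 - Plateau) * exp(-K*x) + Plateau
Two-phase model:  Y = Plateau + SpanFast * exp(-KFast*x) + SpanSlow * exp(-KSlow*x)
with SpanFast = (Y0 - Plateau) * %Fast * 0.01 and
SpanSlow = (Y0 - Plateau) * (100 - %Fast) * 0.01.

Under the constrained convention Y0 is fixed to 1 and Plateau to 0 (traces
are normalized to the maximum response before fitting).  Rate positivity is
enforced by fitting log rates; KFast >= KSlow is enforced by relabeling after
the fit (with %Fast complemented), removing label-switching ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .errors import FitError

__all__ = [
    "DecayFit",
    "ModelComparison",
    "one_phase_model",
    "two_phase_model",
    "fit_one_phase_decay",
    "fit_two_phase_decay",
    "compare_decay_models",
]

_K_FLOOR = 1e-8  # rates at/below this are treated as "no decay"
_RATE_RATIO_MIN = 3.0  # KFast/KSlow below this is practically one-phase


@dataclass
class DecayFit:
    model: str  # "one_phase" | "two_phase"
    y0: float
    plateau: float
    k: float | None = None
    k_fast: float | None = None
    k_slow: float | None = None
    percent_fast: float | None = None
    sse: float = np.nan
    n_points: int = 0
    n_params: int = 0
    constrained: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def span_fast(self) -> float | None:
        if self.percent_fast is None:
            return None
        return (self.y0 - self.plateau) * self.percent_fast * 0.01

    @property
    def span_slow(self) -> float | None:
        if self.percent_fast is None:
            return None
        return (self.y0 - self.plateau) * (100.0 - self.percent_fast) * 0.01

    @property
    def half_life(self) -> float | None:
        """Time at which the one-phase curve reaches (Y0+Plateau)/2."""
        if self.k is None or self.k <= 0:
            return None
        return float(np.log(2.0) / self.k)

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        if self.model == "one_phase":
            return one_phase_model(t, self.y0, self.plateau, self.k)
        return two_phase_model(
            t, self.y0, self.plateau, self.k_fast, self.k_slow, self.percent_fast
        )


@dataclass
class ModelComparison:
    f_statistic: float
    p_value: float
    df_extra: int
    df_denominator: int
    preferred: str
    alpha: float = 0.05


def one_phase_model(t, y0, plateau, k):
    return (y0 - plateau) * np.exp(-k * np.asarray(t, dtype=float)) + plateau


def two_phase_model(t, y0, plateau, k_fast, k_slow, percent_fast):
    t = np.asarray(t, dtype=float)
    span = y0 - plateau
    span_fast = span * percent_fast * 0.01
    span_slow = span * (100.0 - percent_fast) * 0.01
    return plateau + span_fast * np.exp(-k_fast * t) + span_slow * np.exp(-k_slow * t)


def _validate(t, y, min_points: int):
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size:
        raise FitError("t and y must have equal length")
    if t.size < min_points:
        raise FitError(f"need >= {min_points} points, got {t.size}")
    if np.any(t < 0):
        raise FitError("time values must be >= 0")
    return t, y


def _initial_rate(t, y, y0, plateau):
    """Log-linear regression estimate of the decay rate."""
    z = (y - plateau) / (y0 - plateau) if y0 != plateau else y
    ok = z > 1e-12
    if ok.sum() >= 2 and np.ptp(t[ok]) > 0:
        slope = np.polyfit(t[ok], np.log(z[ok]), 1)[0]
        if slope < 0:
            return -slope
    span = np.ptp(t)
    return 1.0 / span if span > 0 else 1.0


def fit_one_phase_decay(t, y, constrain: bool = True) -> DecayFit:
    """Least-squares one-phase decay; K > 0 via log-parameterization.

    With ``constrain`` (default) Y0 is fixed at 1 and Plateau at 0.  Data
    that do not decay (best K stuck at the floor) are flagged
    ``non_convergent``.
    """
    t, y = _validate(t, y, 4)
    flags: list[str] = []
    if constrain:
        y0_init, plateau_init = 1.0, 0.0
    else:
        y0_init, plateau_init = float(y[np.argmin(t)]), float(np.min(y))
        if y0_init == plateau_init:
            y0_init = plateau_init + 1.0
    k0 = _initial_rate(t, y, y0_init, plateau_init)

    if constrain:
        def resid(p):
            return one_phase_model(t, 1.0, 0.0, np.exp(p[0])) - y

        best = None
        for start in (np.log(k0), np.log(k0) + 1.5, np.log(k0) - 1.5):
            sol = least_squares(resid, x0=[start], method="lm")
            if best is None or sol.cost < best.cost:
                best = sol
        k = float(np.exp(best.x[0]))
        fit = DecayFit(
            model="one_phase",
            y0=1.0,
            plateau=0.0,
            k=k,
            sse=float(2 * best.cost),
            n_points=t.size,
            n_params=1,
            constrained=True,
            flags=flags,
        )
    else:
        def resid(p):
            return one_phase_model(t, p[1], p[2], np.exp(p[0])) - y

        best = None
        for start in (np.log(k0), np.log(k0) + 1.5, np.log(k0) - 1.5):
            sol = least_squares(
                resid, x0=[start, y0_init, plateau_init], method="lm"
            )
            if best is None or sol.cost < best.cost:
                best = sol
        k = float(np.exp(best.x[0]))
        fit = DecayFit(
            model="one_phase",
            y0=float(best.x[1]),
            plateau=float(best.x[2]),
            k=k,
            sse=float(2 * best.cost),
            n_points=t.size,
            n_params=3,
            constrained=False,
            flags=flags,
        )
    if fit.k <= _K_FLOOR:
        flags.append("non_convergent")
    return fit


def fit_two_phase_decay(t, y, constrain: bool = True) -> DecayFit:
    """Least-squares two-phase decay (KFast, KSlow, %Fast).

    Rates fitted in log space, %Fast through a logistic transform.  After
    fitting, phases are ordered so KFast >= KSlow.  Flags:
    ``practically_one_phase`` when KFast/KSlow < 3, ``degenerate`` when
    %Fast is pinned at 0 or 100 or the data do not decay.
    """
    t, y = _validate(t, y, 6)
    flags: list[str] = []
    if constrain:
        y0_fix, plateau_fix = 1.0, 0.0
    else:
        y0_fix, plateau_fix = float(y[np.argmin(t)]), float(np.min(y))
        if y0_fix == plateau_fix:
            y0_fix = plateau_fix + 1.0
    k0 = _initial_rate(t, y, y0_fix, plateau_fix)
    k0 = max(k0, 10 * _K_FLOOR)

    def unpack(p):
        kf, ks = np.exp(p[0]), np.exp(p[1])
        pf = 100.0 / (1.0 + np.exp(-p[2]))
        return kf, ks, pf

    if constrain:
        def resid(p):
            kf, ks, pf = unpack(p)
            return two_phase_model(t, 1.0, 0.0, kf, ks, pf) - y

        n_params = 3
    else:
        def resid(p):
            kf, ks, pf = unpack(p)
            return two_phase_model(t, p[3], p[4], kf, ks, pf) - y

        n_params = 5

    starts = [
        [np.log(5 * k0), np.log(k0 / 5), 0.0],
        [np.log(20 * k0), np.log(k0), 1.0],
        [np.log(k0), np.log(k0 / 20), -1.0],
    ]
    best = None
    for s in starts:
        x0 = list(s) if constrain else list(s) + [y0_fix, plateau_fix]
        try:
            sol = least_squares(resid, x0=x0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("two-phase fit failed for all starts")
    kf, ks, pf = unpack(best.x)
    if kf < ks:  # relabel so fast really is fast
        kf, ks = ks, kf
        pf = 100.0 - pf
    if constrain:
        y0_out, plateau_out = 1.0, 0.0
    else:
        y0_out, plateau_out = float(best.x[3]), float(best.x[4])
    if pf < 1e-3 or pf > 100.0 - 1e-3:
        flags.append("degenerate")
    if kf <= _K_FLOOR:
        flags.append("degenerate")
    elif ks > 0 and kf / ks < _RATE_RATIO_MIN:
        flags.append("practically_one_phase")
    return DecayFit(
        model="two_phase",
        y0=y0_out,
        plateau=plateau_out,
        k_fast=float(kf),
        k_slow=float(ks),
        percent_fast=float(pf),
        sse=float(2 * best.cost),
        n_points=t.size,
        n_params=n_params,
        constrained=constrain,
        flags=flags,
    )


def compare_decay_models(
    fit_simple: DecayFit, fit_complex: DecayFit, n_points: int | None = None,
    alpha: float = 0.05,
) -> ModelComparison:
    """Extra-sum-of-squares F test between nested fits on identical data."""
    if fit_simple.n_params >= fit_complex.n_params:
        raise FitError("fits are not nested (simple must have fewer parameters)")
    n = n_points if n_points is not None else fit_complex.n_points
    if n != fit_simple.n_points or n != fit_complex.n_points:
        raise FitError("fits must be on identical data (same n_points)")
    df_extra = fit_complex.n_params - fit_simple.n_params
    df_den = n - fit_complex.n_params
    if df_den <= 0:
        raise FitError("not enough points for model comparison")
    sse1, sse2 = fit_simple.sse, fit_complex.sse
    if sse2 <= 0.0:
        if sse1 <= 0.0:
            f_stat, p = 0.0, 1.0  # both fits perfect: keep the simpler model
        else:
            f_stat, p = np.inf, 0.0
    else:
        f_stat = max(0.0, (sse1 - sse2) / df_extra / (sse2 / df_den))
        p = float(stats.f.sf(f_stat, df_extra, df_den))
    preferred = fit_complex.model if p < alpha else fit_simple.model
    return ModelComparison(
        f_statistic=float(f_stat),
        p_value=float(p),
        df_extra=df_extra,
        df_denominator=df_den,
        preferred=preferred,
        alpha=alpha,
    )
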