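"""Hill concentration-response fits, competition binding and Cheng-Prusoff.

All curve fitting is done in log10-concentration space with untransformed
responses.  The Hill fit fixes the bottom at zero (four-parameter logistic
with variable slope, bottom = 0); the competition fit works on the
percent-of-control scale with top/bottom fixed at 100/0 unless overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError

__all__ = [
    "HillFit",
    "CompetitionFit",
    "hill_model",
    "competition_model",
    "fit_hill",
    "fit_competition",
    "cheng_prusoff",
]

#: fitted curves flatter than this displacement fraction get the
#: no-displacement flag
_MIN_DISPLACEMENT = 0.2


@dataclass
class HillFit:
    ec50: float
    top: float
    hill_slope: float
    bottom: float = 0.0
    sse: float = np.nan
    converged: bool = True
    covariance: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def predict(self, conc):
        return hill_model(conc, self.top, self.ec50, self.hill_slope, self.bottom)


@dataclass
class CompetitionFit:
    ic50: float
    hill_slope: float
    top: float = 100.0
    bottom: float = 0.0
    sse: float = np.nan
    no_displacement: bool = False
    ic50_lower_bound: float | None = None  # set when censored (> max tested)
    radioligand_conc: float | None = None
    radioligand_kd: float | None = None
    ki: float | None = None
    flags: list[str] = field(default_factory=list)

    def predict(self, conc):
        return competition_model(
            conc, self.ic50, self.hill_slope, self.top, self.bottom
        )

    def with_ki(self, radioligand_conc: float, radioligand_kd: float
                ) -> "CompetitionFit":
        """Attach a Cheng-Prusoff Ki given radioligand concentration and Kd."""
        ki = (
            None
            if self.no_displacement
            else cheng_prusoff(self.ic50, radioligand_conc, radioligand_kd)
        )
        import dataclasses

        return dataclasses.replace(
            self,
            radioligand_conc=radioligand_conc,
            radioligand_kd=radioligand_kd,
            ki=ki,
        )


def hill_model(conc, top, ec50, hill_slope, bottom=0.0):
    """Y = bottom + (top - bottom) * [A]^h / ([A]^h + EC50^h); Y(0) = bottom."""
    a = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = a**hill_slope / (a**hill_slope + ec50**hill_slope)
    frac = np.where(a <= 0, 0.0, frac)
    return bottom + (top - bottom) * frac


def competition_model(conc, ic50, hill_slope, top=100.0, bottom=0.0):
    """Descending curve: Y = bottom + (top - bottom) / (1 + ([I]/IC50)^h)."""
    a = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = bottom + (top - bottom) / (1.0 + (a / ic50) ** hill_slope)
    return np.where(a <= 0, top, y)


def _check_conc(conc, response, min_distinct):
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if conc.size != response.size:
        raise FitError("conc and response must have equal length")
    pos = conc > 0
    if np.unique(conc[pos]).size < min_distinct:
        raise FitError(f"need >= {min_distinct} distinct positive concentrations")
    return conc[pos], response[pos]


def fit_hill(conc, response, top: float | None = None) -> HillFit:
    """Variable-slope Hill fit with the bottom fixed at zero.

    ``top`` may be fixed; by default it floats.  Fitting is over
    (log10 EC50, log top, log hill slope) so all three stay positive.
    Non-monotone data trigger a warning; data with no transition in range
    are returned with ``converged=False``.
    """
    c, y = _check_conc(conc, response, 4)
    order = np.argsort(c)
    c, y = c[order], y[order]
    # warn when responses decrease by more than noise-scale along the curve
    ymax = float(np.max(np.abs(y))) or 1.0
    drops = np.diff([np.mean(y[c == u]) for u in np.unique(c)])
    if np.any(drops < -0.25 * ymax):
        warnings.warn("responses are non-monotone in concentration", stacklevel=2)

    top_fixed = top is not None
    top0 = top if top_fixed else max(float(np.max(y)), 1e-12)
    logec50_0 = float(np.log10(np.median(c)))

    if top_fixed:
        def resid(p):
            return hill_model(c, top0, 10.0 ** p[0], np.exp(p[1])) - y

        x0 = [logec50_0, 0.0]
    else:
        def resid(p):
            return hill_model(c, np.exp(p[2]), 10.0 ** p[0], np.exp(p[1])) - y

        x0 = [logec50_0, 0.0, np.log(top0)]

    best = None
    for shift in (0.0, 1.5, -1.5):
        start = list(x0)
        start[0] += shift
        sol = least_squares(resid, x0=start, method="lm", max_nfev=10000)
        if best is None or sol.cost < best.cost:
            best = sol
    ec50 = float(10.0 ** best.x[0])
    hill = float(np.exp(best.x[1]))
    top_out = top0 if top_fixed else float(np.exp(best.x[2]))
    flags: list[str] = []
    converged = True
    if ec50 < c.min() / 1e3 or ec50 > c.max() * 1e3:
        converged = False
        flags.append("no_transition_in_range")
    cov = None
    try:
        jtj = best.jac.T @ best.jac
        dof = max(c.size - best.x.size, 1)
        cov = np.linalg.inv(jtj) * (2 * best.cost / dof)
    except np.linalg.LinAlgError:
        pass
    return HillFit(
        ec50=ec50,
        top=float(top_out),
        hill_slope=hill,
        bottom=0.0,
        sse=float(2 * best.cost),
        converged=converged,
        covariance=cov,
        flags=flags,
    )


def fit_competition(
    conc, percent_specific, top: float = 100.0, bottom: float = 0.0
) -> CompetitionFit:
    """IC50 and slope of a descending percent-of-control displacement curve.

    A curve that stays flat near the top (no displacement at any tested
    concentration) is returned with ``no_displacement=True`` and the IC50
    right-censored at the highest tested concentration
    (``ic50_lower_bound``).
    """
    c, y = _check_conc(conc, percent_specific, 4)
    span = top - bottom
    min_y = float(np.min(y))
    if min_y > top - _MIN_DISPLACEMENT * span:
        return CompetitionFit(
            ic50=np.inf,
            hill_slope=np.nan,
            top=top,
            bottom=bottom,
            no_displacement=True,
            ic50_lower_bound=float(np.max(c)),
            flags=["no_displacement"],
        )

    def resid(p):
        return competition_model(c, 10.0 ** p[0], np.exp(p[1]), top, bottom) - y

    best = None
    for shift in (0.0, 1.5, -1.5):
        x0 = [float(np.log10(np.median(c))) + shift, 0.0]
        sol = least_squares(resid, x0=x0, method="lm", max_nfev=10000)
        if best is None or sol.cost < best.cost:
            best = sol
    return CompetitionFit(
        ic50=float(10.0 ** best.x[0]),
        hill_slope=float(np.exp(best.x[1])),
        top=top,
        bottom=bottom,
        sse=float(2 * best.cost),
    )


def cheng_prusoff(ic50: float, radioligand_conc: float, radioligand_kd: float
                  ) -> float:
    """Ki = IC50 / (1 + [L]/Kd).

    ``radioligand_conc`` may be 0 (the limit Ki = IC50); IC50 and Kd must be
    positive.
    """
    if ic50 <= 0 or radioligand_kd <= 0 or radioligand_conc < 0:
        raise ValueError(
            "IC50 and Kd must be > 0 and radioligand concentration >= 0"
        )
    return ic50 / (1.0 + radioligand_conc / radioligand_kd)
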