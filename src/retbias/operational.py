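"""Global operational-model fitting and ligand-bias comparison.

The operational model of agonism relates agonist concentration to response
through an efficacy parameter tau and a binding constant Ki::

    Y = [A]^n * tau^n * Emax / ([A]^n * tau^n + ([A] + Ki)^n)

All agonists of one pathway are fitted simultaneously with one shared slope
n, per-agonist tau, Ki fixed per agonist to the competition-binding value,
and Emax fixed by the pathway's normalization convention (or left free).
Positivity of tau and n is enforced by fitting their log10.  From the fit,
log10(tau/Ki) is computed per agonist and expressed relative to a reference
agonist as delta log10(tau/Ki); differences of this quantity across pathways
indicate ligand bias.

Rank ordering of agonist efficacies uses tie groups: adjacent agonists whose
underlying per-cell values are not separated by a Tukey-adjusted pairwise
test (or by a numeric tolerance, as fallback) are reported as equivalent.
Two pathways are compared by listing discordant agonist pairs: pairs whose
order is reversed between the pathways with both agonists outside tie groups
in both pathways.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError
from .fret import EfficacyTable
from .statcomp import anova_tukey
from .synthetic import operational_response

__all__ = [
    "OperationalDataset",
    "OperationalFitResult",
    "BiasFactors",
    "RankOrder",
    "PathwayComparison",
    "BiasReport",
    "fit_operational_global",
    "compute_bias_factors",
    "rank_order",
    "compare_pathways",
]

#: responses below this fraction of Emax across the whole curve mark an
#: agonist as non-responding (tau right-censored)
_RESPONSE_FLOOR_FRAC = 0.02


# --------------------------------------------------------------------- types


@dataclass
class OperationalDataset:
    """Concentration-response curves for one pathway.

    ``data`` maps agonist -> (concentrations mol/L, normalized responses);
    ``ki`` maps agonist -> fixed Ki (mol/L).  ``emax`` is the fixed system
    maximum per the pathway's normalization convention, or None to float it.
    """

    pathway_id: str
    data: dict[str, tuple[np.ndarray, np.ndarray]]
    ki: dict[str, float]
    emax: float | None = 1.0

    def __post_init__(self) -> None:
        clean = {}
        for agonist, (c, y) in self.data.items():
            c = np.asarray(c, dtype=float)
            y = np.asarray(y, dtype=float)
            if c.size != y.size:
                raise FitError(f"{agonist}: conc and response length mismatch")
            if np.unique(c[c > 0]).size < 4:
                raise FitError(
                    f"{agonist}: need >= 4 distinct positive concentrations"
                )
            if agonist not in self.ki or self.ki[agonist] <= 0:
                raise FitError(f"{agonist}: missing or non-positive Ki")
            clean[agonist] = (c, y)
        self.data = clean

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        ki: dict[str, float],
        pathway_id: str = "pathway",
        emax: float | None = 1.0,
    ) -> "OperationalDataset":
        """Build from a long-format frame with agonist, conc_M, response."""
        data = {}
        for agonist, df in frame.groupby("agonist"):
            data[agonist] = (
                df["conc_M"].to_numpy(dtype=float),
                df["response"].to_numpy(dtype=float),
            )
        return cls(pathway_id=pathway_id, data=data, ki=ki, emax=emax)


@dataclass
class OperationalFitResult:
    pathway_id: str
    tau: dict[str, float]
    log10_tau_se: dict[str, float]
    n: float
    n_se: float
    emax: float
    emax_fixed: bool
    ki: dict[str, float]
    sse: float
    converged: bool
    censored: list[str] = field(default_factory=list)  # no-response agonists

    def log_tau_over_ki(self, agonist: str) -> float:
        return float(np.log10(self.tau[agonist]) - np.log10(self.ki[agonist]))


@dataclass
class BiasFactors:
    """log10(tau/Ki) per agonist and its difference from a reference."""

    pathway_id: str
    reference: str
    log_tau_over_ki: dict[str, float]
    delta_log_tau_over_ki: dict[str, float]
    delta_se: dict[str, float]
    censored: list[str] = field(default_factory=list)


@dataclass
class RankOrder:
    """Agonists sorted by mean efficacy, merged into tie groups."""

    groups: list[list[str]]
    means: dict[str, float]
    tie_rule: str

    def position(self, agonist: str) -> int:
        for i, g in enumerate(self.groups):
            if agonist in g:
                return i
        raise KeyError(agonist)

    def tied(self, a: str, b: str) -> bool:
        return self.position(a) == self.position(b)

    def __contains__(self, agonist: str) -> bool:
        return any(agonist in g for g in self.groups)

    def __str__(self) -> str:
        return " > ".join(" ≈ ".join(g) for g in self.groups)


@dataclass
class PathwayComparison:
    pathway_a: str
    pathway_b: str
    discordant_pairs: list[tuple[str, str]]
    concordance: float | None  # Kendall-style over pairs untied in both
    table: pd.DataFrame  # agonist, efficacy_a, efficacy_b


@dataclass
class BiasReport:
    """Full cross-pathway bias summary.

    Every bias call references the discordant pair that backs it.
    """

    efficacy_tables: dict[str, pd.DataFrame]
    rank_orders: dict[str, RankOrder]
    pairwise_stats: dict[str, pd.DataFrame]
    comparisons: list[PathwayComparison]
    bias_calls: list[dict]

    def to_dict(self) -> dict:
        return {
            "efficacy_tables": {
                p: df.to_dict(orient="records")
                for p, df in sorted(self.efficacy_tables.items())
            },
            "rank_orders": {
                p: {"groups": r.groups, "display": str(r), "tie_rule": r.tie_rule}
                for p, r in sorted(self.rank_orders.items())
            },
            "pairwise_stats": {
                p: df.to_dict(orient="records")
                for p, df in sorted(self.pairwise_stats.items())
            },
            "comparisons": [
                {
                    "pathway_a": c.pathway_a,
                    "pathway_b": c.pathway_b,
                    "discordant_pairs": [list(p) for p in c.discordant_pairs],
                    "concordance": c.concordance,
                    "table": c.table.to_dict(orient="records"),
                }
                for c in self.comparisons
            ],
            "bias_calls": self.bias_calls,
        }


# ------------------------------------------------------------------ fitting


def fit_operational_global(ds: OperationalDataset) -> OperationalFitResult:
    """Simultaneous least-squares operational fit across agonists.

    One shared n, per-agonist tau, Ki fixed.  Agonists whose responses never
    exceed 2% of Emax carry no information about tau or n; they are excluded
    from the global fit and reported as right-censored.
    """
    emax_fixed = ds.emax is not None
    scale = ds.emax if emax_fixed else max(
        float(np.max(y)) for _, y in ds.data.values()
    )
    active, censored = [], []
    for agonist, (c, y) in ds.data.items():
        if float(np.max(y)) < _RESPONSE_FLOOR_FRAC * scale:
            censored.append(agonist)
        else:
            active.append(agonist)
    if not active:
        raise FitError(f"{ds.pathway_id}: no agonist shows a measurable response")

    m = len(active)
    conc = [ds.data[a][0] for a in active]
    resp = [ds.data[a][1] for a in active]
    kis = [ds.ki[a] for a in active]

    # params: log10 tau per active agonist, log10 n, [log10 emax if free]
    def unpack(p):
        taus = 10.0 ** p[:m]
        n = 10.0 ** p[m]
        emax = ds.emax if emax_fixed else 10.0 ** p[m + 1]
        return taus, n, emax

    def resid(p):
        taus, n, emax = unpack(p)
        parts = [
            operational_response(c_i, t_i, k_i, n, emax) - y_i
            for c_i, y_i, t_i, k_i in zip(conc, resp, taus, kis)
        ]
        return np.concatenate(parts)

    # initial taus from the half-max heuristic EC50 ~ Ki/tau
    x0 = []
    for c_i, y_i, k_i in zip(conc, resp, kis):
        top = max(float(np.max(y_i)), 1e-9)
        half = top / 2.0
        above = c_i[y_i >= half]
        ec50_guess = float(np.min(above)) if above.size else float(np.median(c_i))
        x0.append(np.log10(max(k_i / ec50_guess, 1e-6)))
    x0.append(0.0)  # n = 1
    if not emax_fixed:
        x0.append(np.log10(scale))

    best = None
    for n_shift in (0.0, 0.3, -0.3):
        start = list(x0)
        start[m] += n_shift
        sol = least_squares(resid, x0=start, method="lm", max_nfev=20000)
        if best is None or sol.cost < best.cost:
            best = sol

    taus, n, emax = unpack(best.x)
    dof = max(sum(c_i.size for c_i in conc) - best.x.size, 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * s2
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        ses = np.full(best.x.size, np.nan)
    return OperationalFitResult(
        pathway_id=ds.pathway_id,
        tau={a: float(t) for a, t in zip(active, taus)},
        log10_tau_se={a: float(s) for a, s in zip(active, ses[:m])},
        n=float(n),
        n_se=float(ses[m]),
        emax=float(emax),
        emax_fixed=emax_fixed,
        ki={a: ds.ki[a] for a in active},
        sse=float(2.0 * best.cost),
        converged=bool(best.success),
        censored=censored,
    )


def compute_bias_factors(
    fit: OperationalFitResult, reference: str = "ACh"
) -> BiasFactors:
    """Per-agonist delta log10(tau/Ki) relative to the reference agonist.

    Ki values are treated as fixed constants (as in the fit), so the
    uncertainty on each delta is the quadrature sum of the two log10-tau
    standard errors.  Censored agonists get no point value.
    """
    if reference not in fit.tau:
        raise FitError(f"reference agonist {reference!r} not in fit")
    ref_val = fit.log_tau_over_ki(reference)
    ref_se = fit.log10_tau_se[reference]
    log_vals, deltas, ses = {}, {}, {}
    for agonist in fit.tau:
        log_vals[agonist] = fit.log_tau_over_ki(agonist)
        deltas[agonist] = log_vals[agonist] - ref_val
        if agonist == reference:
            deltas[agonist] = 0.0
            ses[agonist] = 0.0
        else:
            ses[agonist] = float(
                np.sqrt(fit.log10_tau_se[agonist] ** 2 + ref_se**2)
            )
    return BiasFactors(
        pathway_id=fit.pathway_id,
        reference=reference,
        log_tau_over_ki=log_vals,
        delta_log_tau_over_ki=deltas,
        delta_se=ses,
        censored=list(fit.censored),
    )


# ------------------------------------------------------------- rank & bias


def rank_order(
    efficacies: EfficacyTable,
    tie_rule: str = "tukey",
    tie_tol: float = 0.05,
    alpha: float = 0.05,
) -> RankOrder:
    """Sort agonists by mean efficacy and merge statistical ties.

    With ``tie_rule="tukey"`` two adjacent agonists belong to the same tie
    group when their Tukey-adjusted pairwise p (over the per-cell values) is
    >= alpha; a new group starts when the candidate is separated from every
    member of the current group.  ``tie_rule="tolerance"`` merges when the
    mean difference is below ``tie_tol`` — also the fallback when dispersion
    information is unavailable.
    """
    means = efficacies.means
    if len(means) < 2:
        raise FitError("need >= 2 agonists to rank")
    ordered = sorted(means, key=lambda a: -means[a])

    separated = None
    if tie_rule == "tukey":
        sizes_ok = all(np.asarray(v).size >= 2 for v in efficacies.values.values())
        if sizes_ok:
            res = anova_tukey(efficacies.values)
            padj = {}
            for row in res.pairwise.itertuples():
                padj[frozenset((row.group_a, row.group_b))] = row.p_adjusted

            def separated(a, b):
                return padj[frozenset((a, b))] < alpha

        else:
            warnings.warn(
                "tukey tie rule needs >= 2 values per agonist; "
                "falling back to tolerance rule",
                stacklevel=2,
            )
            tie_rule = "tolerance"
    if separated is None:
        if tie_rule != "tolerance":
            raise ValueError(f"unknown tie_rule {tie_rule!r}")

        def separated(a, b):
            return abs(means[a] - means[b]) >= tie_tol

    groups: list[list[str]] = [[ordered[0]]]
    for agonist in ordered[1:]:
        if all(separated(agonist, member) for member in groups[-1]):
            groups.append([agonist])
        else:
            groups[-1].append(agonist)
    return RankOrder(groups=groups, means=means, tie_rule=tie_rule)


def compare_pathways(
    rank_a: RankOrder,
    rank_b: RankOrder,
    table_a: EfficacyTable,
    table_b: EfficacyTable,
) -> PathwayComparison:
    """Cross-pathway rank comparison over the common agonist set.

    A pair is discordant when its order is reversed between pathways and
    neither agonist is tied with the other in either pathway.  Concordance
    is (concordant - discordant) / evaluated over pairs untied in both
    pathways (None when fewer than 3 common agonists).
    """
    common = [a for a in table_a.values if a in table_b.values
              and a in rank_a and a in rank_b]
    n_conc = n_disc = 0
    discordant: list[tuple[str, str]] = []
    for a, b in itertools.combinations(common, 2):
        if rank_a.tied(a, b) or rank_b.tied(a, b):
            continue
        sign_a = np.sign(rank_a.position(a) - rank_a.position(b))
        sign_b = np.sign(rank_b.position(a) - rank_b.position(b))
        if sign_a == sign_b:
            n_conc += 1
        else:
            n_disc += 1
            discordant.append(tuple(sorted((a, b))))
    concordance = None
    if len(common) >= 3 and (n_conc + n_disc) > 0:
        concordance = (n_conc - n_disc) / (n_conc + n_disc)
    mean_a, mean_b = table_a.means, table_b.means
    table = pd.DataFrame(
        [
            {
                "agonist": a,
                f"efficacy_{table_a.pathway_id}": mean_a[a],
                f"efficacy_{table_b.pathway_id}": mean_b[a],
            }
            for a in common
        ]
    )
    return PathwayComparison(
        pathway_a=table_a.pathway_id,
        pathway_b=table_b.pathway_id,
        discordant_pairs=sorted(discordant),
        concordance=concordance,
        table=table,
    )
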