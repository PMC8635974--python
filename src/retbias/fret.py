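"""Single-cell FRET trace processing.

Turns raw two-channel recordings (donor emission and acceptor emission under
donor excitation, optionally acceptor emission under direct acceptor
excitation) into corrected ratio traces and per-application normalized
amplitudes:

1. :func:`correct_channels` removes background, bleed-through and false
   excitation.
2. :func:`compute_ratio` forms the acceptor/donor emission ratio.
3. :func:`baseline_correct` divides out a mono-exponential-plus-constant
   photobleaching drift fitted to buffer-only samples.
4. :func:`extract_amplitude` applies the 5-second window rule: mean ratio in
   the 5 s before agonist withdrawal minus mean ratio in the 5 s before
   agonist application.
5. :func:`normalize_to_reference` scales each cell's amplitudes to its own
   reference-agonist (default ACh) amplitude.
6. :func:`aggregate_efficacies` summarises normalized amplitudes per agonist
   into an :class:`EfficacyTable` for one pathway.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import CorrectionError, TraceError, WindowError
from .protocol import ApplicationEvent, ApplicationProtocol

__all__ = [
    "RawRecording",
    "CorrectionCoefficients",
    "RatioTrace",
    "AmplitudeRecord",
    "EfficacyTable",
    "correct_channels",
    "compute_ratio",
    "baseline_correct",
    "extract_amplitude",
    "extract_amplitudes",
    "normalize_to_reference",
    "aggregate_efficacies",
    "estimate_correction_coefficients",
]

logger = logging.getLogger(__name__)

#: length of the pre-application / pre-withdrawal averaging windows (s)
AMPLITUDE_WINDOW_S = 5.0

#: fraction of masked (non-positive donor) samples tolerated before erroring
MASK_FRACTION_LIMIT = 0.10


# --------------------------------------------------------------------- types


@dataclass
class RawRecording:
    """Multi-channel fluorescence time series for one cell.

    ``donor_em`` and ``acceptor_em`` are emissions under donor excitation;
    ``acceptor_direct`` is the acceptor emission under direct acceptor
    excitation (needed for false-excitation correction).
    """

    cell_id: str
    time: np.ndarray
    donor_em: np.ndarray
    acceptor_em: np.ndarray
    protocol: ApplicationProtocol
    acceptor_direct: np.ndarray | None = None
    channels_corrected: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.donor_em = np.asarray(self.donor_em, dtype=float)
        self.acceptor_em = np.asarray(self.acceptor_em, dtype=float)
        if self.acceptor_direct is not None:
            self.acceptor_direct = np.asarray(self.acceptor_direct, dtype=float)
        n = self.time.size
        for name in ("donor_em", "acceptor_em", "acceptor_direct"):
            v = getattr(self, name)
            if v is not None and v.size != n:
                raise TraceError(
                    f"cell {self.cell_id!r}: channel {name} has {v.size} "
                    f"samples, expected {n}"
                )
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise TraceError(f"cell {self.cell_id!r}: time not strictly increasing")


@dataclass(frozen=True)
class CorrectionCoefficients:
    """Spectral correction coefficients.

    ``bleedthrough_frac`` is the fraction of donor emission leaking into the
    acceptor channel; ``false_excitation_frac`` the fraction of directly
    excited acceptor emission appearing under donor excitation.
    """

    background_donor: float = 0.0
    background_acceptor: float = 0.0
    bleedthrough_frac: float = 0.0
    false_excitation_frac: float = 0.0

    def __post_init__(self) -> None:
        for name in ("bleedthrough_frac", "false_excitation_frac"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise CorrectionError(f"{name} must be in [0, 1), got {v}")
        for name in ("background_donor", "background_acceptor"):
            if getattr(self, name) < 0:
                raise CorrectionError(f"{name} must be >= 0")


@dataclass
class RatioTrace:
    """Corrected acceptor/donor emission ratio over time for one cell.

    Samples where the corrected donor was non-positive are NaN.
    """

    cell_id: str
    time: np.ndarray
    ratio: np.ndarray
    protocol: ApplicationProtocol
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)

    @property
    def n_masked(self) -> int:
        return int(np.isnan(self.ratio).sum())


@dataclass
class AmplitudeRecord:
    """Raw and reference-normalized FRET amplitude for one application."""

    cell_id: str
    agonist_id: str
    concentration: float
    raw_amplitude: float
    window_pre: tuple[float, float]
    window_post: tuple[float, float]
    application_index: int = 0
    normalized_amplitude: float | None = None


@dataclass
class EfficacyTable:
    """Per-agonist normalized amplitudes for one pathway.

    ``values`` keeps the underlying per-cell normalized amplitudes so that
    downstream rank ordering can use statistical tie rules.
    """

    pathway_id: str
    values: dict[str, np.ndarray]

    @property
    def summary(self) -> pd.DataFrame:
        rows = []
        for agonist, v in self.values.items():
            v = np.asarray(v, dtype=float)
            rows.append(
                {
                    "pathway": self.pathway_id,
                    "agonist": agonist,
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                    "n": int(v.size),
                }
            )
        return pd.DataFrame(rows)

    @property
    def means(self) -> dict[str, float]:
        return {a: float(np.mean(v)) for a, v in self.values.items()}


# ---------------------------------------------------------------- operations


def correct_channels(
    rec: RawRecording, coeff: CorrectionCoefficients
) -> RawRecording:
    """Remove background, bleed-through and false excitation.

    donor' = donor_em - background_donor
    acceptor' = (acceptor_em - background_acceptor)
                - bleedthrough_frac * donor'
                - false_excitation_frac * (acceptor_direct - background_acceptor)

    Raises
    ------
    CorrectionError
        If the corrected donor is negative for more than 10% of samples, or
        false-excitation correction is requested without a direct-excitation
        channel.
    """
    donor = rec.donor_em - coeff.background_donor
    acceptor = rec.acceptor_em - coeff.background_acceptor
    acceptor = acceptor - coeff.bleedthrough_frac * donor
    if coeff.false_excitation_frac > 0:
        if rec.acceptor_direct is None:
            raise CorrectionError(
                f"cell {rec.cell_id!r}: false_excitation_frac > 0 requires "
                "the acceptor_direct channel"
            )
        acceptor = acceptor - coeff.false_excitation_frac * (
            rec.acceptor_direct - coeff.background_acceptor
        )
    frac_neg = float(np.mean(donor < 0))
    if frac_neg > MASK_FRACTION_LIMIT:
        raise CorrectionError(
            f"cell {rec.cell_id!r}: corrected donor negative for "
            f"{frac_neg:.0%} of samples; check background_donor"
        )
    direct = None
    if rec.acceptor_direct is not None:
        direct = rec.acceptor_direct - coeff.background_acceptor
    return replace(
        rec,
        donor_em=donor,
        acceptor_em=acceptor,
        acceptor_direct=direct,
        channels_corrected=True,
    )


def compute_ratio(rec: RawRecording) -> RatioTrace:
    """Acceptor/donor emission ratio; non-positive-donor samples are masked.

    Raises :class:`TraceError` when more than 10% of samples are masked.
    """
    if not rec.channels_corrected:
        warnings.warn(
            f"cell {rec.cell_id!r}: computing ratio on uncorrected channels",
            stacklevel=2,
        )
    donor = rec.donor_em
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(donor > 0, rec.acceptor_em / donor, np.nan)
    n_masked = int(np.isnan(ratio).sum())
    if n_masked:
        frac = n_masked / ratio.size
        if frac > MASK_FRACTION_LIMIT:
            raise TraceError(
                f"cell {rec.cell_id!r}: {frac:.0%} of samples have "
                "non-positive donor after correction"
            )
        warnings.warn(
            f"cell {rec.cell_id!r}: masked {n_masked} samples with "
            "non-positive donor",
            stacklevel=2,
        )
    return RatioTrace(
        cell_id=rec.cell_id, time=rec.time, ratio=ratio, protocol=rec.protocol
    )


def _buffer_mask(
    trace: RatioTrace, protocol: ApplicationProtocol, washout_settle: float
) -> np.ndarray:
    """Samples that see buffer only, excluding a post-washout settling margin."""
    t = trace.time
    mask = ~protocol.in_any_event(t)
    for ev in protocol.events:
        mask &= ~((t >= ev.t_end) & (t < ev.t_end + washout_settle))
    mask &= ~np.isnan(trace.ratio)
    return mask


def _count_segments(mask: np.ndarray) -> int:
    m = mask.astype(int)
    return int(np.sum(np.diff(np.concatenate(([0], m))) == 1))


def _drift_model(t, a, b, c):
    return a + b * np.exp(-c * t)


def baseline_correct(
    trace: RatioTrace,
    protocol: ApplicationProtocol | None = None,
    washout_settle: float = 30.0,
) -> RatioTrace:
    """Divide a slow photobleaching drift out of the ratio trace.

    A mono-exponential-plus-constant model ``a + b*exp(-c*t)`` is fitted by
    least squares to buffer-only samples (application windows and a
    ``washout_settle`` margin after each washout are excluded) and the trace
    is divided by the fitted drift normalized to its value at t = 0, so a
    drift-free trace is returned unchanged.  With fewer than two buffer-only
    segments the model falls back to a straight line, with a warning.
    """
    protocol = protocol or trace.protocol
    t = trace.time
    mask = _buffer_mask(trace, protocol, washout_settle)
    if mask.sum() < 3:
        raise TraceError(
            f"cell {trace.cell_id!r}: not enough buffer-only samples "
            "for baseline correction"
        )
    tb, yb = t[mask], trace.ratio[mask]
    use_linear = _count_segments(mask) < 2
    if use_linear:
        warnings.warn(
            f"cell {trace.cell_id!r}: fewer than 2 buffer segments; "
            "using linear drift model",
            stacklevel=2,
        )
    drift = None
    if not use_linear:
        span = yb[-1] - yb[0]
        t_scale = max(tb[-1] - tb[0], 1.0)
        p0 = (yb[-1], span if abs(span) > 1e-12 else 1e-3, 1.0 / t_scale)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _drift_model, tb, yb, p0=p0, maxfev=10000,
                    bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                )
            drift = _drift_model(t, *popt)
        except (RuntimeError, ValueError):
            logger.info(
                "cell %s: exponential drift fit failed, linear fallback",
                trace.cell_id,
            )
    if drift is None:
        coefs = np.polyfit(tb, yb, 1)
        drift = np.polyval(coefs, t)
    d0 = drift[0]
    if d0 <= 0 or np.any(drift <= 0):
        raise TraceError(
            f"cell {trace.cell_id!r}: fitted drift model not positive; "
            "cannot divide out"
        )
    corrected = trace.ratio / (drift / d0)
    return RatioTrace(
        cell_id=trace.cell_id,
        time=t,
        ratio=corrected,
        protocol=protocol,
        baseline_corrected=True,
    )


def _window_mean(trace: RatioTrace, lo: float, hi: float, label: str) -> float:
    sel = (trace.time >= lo) & (trace.time < hi)
    vals = trace.ratio[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise WindowError(
            f"cell {trace.cell_id!r}: empty {label} window [{lo}, {hi}) s"
        )
    return float(np.mean(vals))


def extract_amplitude(
    trace: RatioTrace,
    event: ApplicationEvent,
    application_index: int = 0,
    window: float = AMPLITUDE_WINDOW_S,
) -> AmplitudeRecord:
    """Amplitude of one application by the 5-second window rule.

    amplitude = mean(ratio over [t_end-5, t_end)) - mean(ratio over
    [t_start-5, t_start)); both windows half-open.  At 2 Hz each window
    holds 10 samples.  Masked samples are excluded from the means.
    """
    pre = (event.t_start - window, event.t_start)
    post = (event.t_end - window, event.t_end)
    pre_mean = _window_mean(trace, *pre, label=f"pre-{event.agonist_id}")
    post_mean = _window_mean(trace, *post, label=f"post-{event.agonist_id}")
    return AmplitudeRecord(
        cell_id=trace.cell_id,
        agonist_id=event.agonist_id,
        concentration=event.concentration,
        raw_amplitude=post_mean - pre_mean,
        window_pre=pre,
        window_post=post,
        application_index=application_index,
    )


def extract_amplitudes(
    trace: RatioTrace, protocol: ApplicationProtocol | None = None
) -> list[AmplitudeRecord]:
    """Amplitudes for every event in the protocol, in order."""
    protocol = protocol or trace.protocol
    counters: dict[str, int] = {}
    out = []
    for ev in protocol.events:
        idx = counters.get(ev.agonist_id, 0)
        counters[ev.agonist_id] = idx + 1
        out.append(extract_amplitude(trace, ev, application_index=idx))
    return out


def normalize_to_reference(
    records: list[AmplitudeRecord],
    reference_agonist: str = "ACh",
    reference_policy: str = "first",
) -> list[AmplitudeRecord]:
    """Normalize each cell's amplitudes to its own reference-agonist amplitude.

    ``reference_policy`` selects which reference application defines the
    denominator when the reference agonist was applied more than once:
    ``"first"`` (default) or ``"max"``.  Cells whose reference amplitude is
    non-positive are excluded entirely, with a logged reason.
    """
    if reference_policy not in ("first", "max"):
        raise ValueError(f"unknown reference_policy {reference_policy!r}")
    by_cell: dict[str, list[AmplitudeRecord]] = {}
    for r in records:
        by_cell.setdefault(r.cell_id, []).append(r)
    out: list[AmplitudeRecord] = []
    for cell_id, recs in by_cell.items():
        refs = [r for r in recs if r.agonist_id == reference_agonist]
        if not refs:
            logger.warning(
                "cell %s excluded: no %s application", cell_id, reference_agonist
            )
            continue
        if reference_policy == "first":
            ref_amp = min(refs, key=lambda r: r.application_index).raw_amplitude
        else:
            ref_amp = max(r.raw_amplitude for r in refs)
        if ref_amp <= 0:
            logger.warning(
                "cell %s excluded: reference amplitude %.4g <= 0",
                cell_id,
                ref_amp,
            )
            continue
        for r in recs:
            out.append(replace(r, normalized_amplitude=r.raw_amplitude / ref_amp))
    return out


def aggregate_efficacies(
    records: list[AmplitudeRecord], pathway_id: str
) -> EfficacyTable:
    """Collect normalized amplitudes per agonist into an efficacy table.

    For agonists applied more than once per cell, only the first application
    enters the table (repeats probe signal stability, not efficacy).
    """
    values: dict[str, list[float]] = {}
    for r in records:
        if r.normalized_amplitude is None or r.application_index != 0:
            continue
        values.setdefault(r.agonist_id, []).append(r.normalized_amplitude)
    return EfficacyTable(
        pathway_id=pathway_id,
        values={a: np.asarray(v, dtype=float) for a, v in values.items()},
    )


def estimate_correction_coefficients(
    donor_only: RawRecording,
    acceptor_only: RawRecording,
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
) -> CorrectionCoefficients:
    """Estimate cross-talk fractions from single-fluorophore calibration cells.

    Bleed-through is the mean acceptor/donor emission ratio of a donor-only
    cell; false excitation is the mean ratio of acceptor emission under donor
    excitation to acceptor emission under direct excitation in an
    acceptor-only cell.
    """
    d = donor_only.donor_em - background_donor
    a = donor_only.acceptor_em - background_acceptor
    ok = d > 0
    if not ok.any():
        raise CorrectionError("donor-only recording has no positive donor samples")
    bleedthrough = float(np.mean(a[ok] / d[ok]))
    if acceptor_only.acceptor_direct is None:
        raise CorrectionError(
            "acceptor-only recording needs the direct-excitation channel"
        )
    direct = acceptor_only.acceptor_direct - background_acceptor
    under_donor = acceptor_only.acceptor_em - background_acceptor
    ok = direct > 0
    if not ok.any():
        raise CorrectionError("acceptor-only recording has no positive samples")
    false_exc = float(np.mean(under_donor[ok] / direct[ok]))
    return CorrectionCoefficients(
        background_donor=background_donor,
        background_acceptor=background_acceptor,
        bleedthrough_frac=min(max(bleedthrough, 0.0), 0.999),
        false_excitation_frac=min(max(false_exc, 0.0), 0.999),
    )
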