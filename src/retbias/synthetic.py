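"""Synthetic data generation with known ground truth.

Every input the pipeline consumes can be generated here: single-cell
two-channel FRET recordings with cross-talk and photobleaching, three-phase
BRET plates, operational-model concentration-response tables, and sigmoidal
competition-binding tables.  Ground truth is always carried alongside the
generated data (and serialized as a sidecar JSON by the workflow module) so
tests never re-derive it.

Generator model for FRET recordings
-----------------------------------
A latent occupancy signal ``f(t)`` per cell rises toward the agonist's
relative efficacy with ``on_rate`` during an application and relaxes to zero
with ``off_rate`` after washout.  With per-channel mono-exponential bleaching
``B_d(t)``, ``B_a(t)``, per-cell scale ``s``, donor-quench fraction
``fret_scale`` and sensitized-emission gain ``acceptor_gain``::

    donor_latent(t)    = s * donor_scale * B_d(t) * (1 - fret_scale * f(t))
    acceptor_latent(t) = s * donor_scale * B_a(t) * (r0 + acceptor_gain * f(t))

where ``r0`` is the baseline acceptor/donor ratio.  The recorded channels add
background, bleed-through and false excitation exactly as the correction
in :mod:`retbias.fret` inverts them, plus Gaussian noise::

    donor_em    = bg_d + donor_latent + noise
    acc_direct  = bg_a + s * direct_scale * B_a(t) + noise
    acceptor_em = bg_a + acceptor_latent
                  + bleedthrough * donor_latent
                  + false_excitation * (acc_direct - bg_a) + noise
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ProtocolError
from .fret import RawRecording
from .protocol import ApplicationEvent, ApplicationProtocol

__all__ = [
    "FretGroundTruth",
    "OperationalGroundTruth",
    "BretPlateTruth",
    "BretPlateRecording",
    "generate_fret_recording",
    "generate_fret_cohort",
    "generate_bret_plate",
    "generate_concentration_response",
    "generate_competition_binding",
    "operational_response",
    "standard_protocol",
]


# --------------------------------------------------------------------- truth


@dataclass(frozen=True)
class FretGroundTruth:
    """Generator-side truth for single-cell FRET recordings."""

    efficacies: dict  # agonist_id -> relative efficacy in [0, 1]
    on_rate: float = 2.0  # 1/s
    off_rate: float = 1.0  # 1/s
    donor_bleach_rate: float = 0.0  # 1/s
    acceptor_bleach_rate: float = 0.0  # 1/s
    bleedthrough_frac: float = 0.0
    false_excitation_frac: float = 0.0
    background_donor: float = 0.0
    background_acceptor: float = 0.0
    noise_sd: float = 0.0
    donor_scale: float = 100.0
    direct_scale: float = 100.0
    baseline_ratio: float = 1.0  # r0
    fret_scale: float = 0.05  # donor fraction quenched at full occupancy
    acceptor_gain: float = 0.25  # sensitized acceptor emission at full occupancy
    cell_scale_sd: float = 0.0  # lognormal sigma of the per-cell scale
    seed: int = 0

    def __post_init__(self) -> None:
        for a, e in self.efficacies.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"efficacy for {a!r} must be in [0,1], got {e}")
        for name in ("bleedthrough_frac", "false_excitation_frac"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0,1), got {v}")
        for name in (
            "on_rate",
            "off_rate",
            "donor_bleach_rate",
            "acceptor_bleach_rate",
            "noise_sd",
            "cell_scale_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.fret_scale < 1.0:
            raise ValueError("fret_scale must be in (0,1)")
        if self.acceptor_gain <= 0:
            raise ValueError("acceptor_gain must be > 0")

    def expected_amplitude(self, efficacy: float) -> float:
        """Exact noiseless amplitude of the baseline-corrected ratio for a
        fully developed response of the given efficacy."""
        k, g, r0 = self.fret_scale, self.acceptor_gain, self.baseline_ratio
        return (r0 + g * efficacy) / (1.0 - k * efficacy) - r0

    def expected_normalized(self, efficacy: float) -> float:
        """Exact noiseless amplitude normalized to an efficacy-1 reference."""
        return self.expected_amplitude(efficacy) / self.expected_amplitude(1.0)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class OperationalGroundTruth:
    """Truth for operational-model concentration-response generation."""

    tau: dict  # agonist_id -> tau > 0
    ki: dict  # agonist_id -> Ki in mol/L
    n: float = 1.0
    emax: float = 1.0
    concentration_grid: tuple = ()
    noise_sd: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0 or self.emax <= 0:
            raise ValueError("n and Emax must be > 0")
        for a, t in self.tau.items():
            if t <= 0:
                raise ValueError(f"tau for {a!r} must be > 0")
            if self.ki.get(a, 0) <= 0:
                raise ValueError(f"Ki for {a!r} must be > 0")
        grid = np.asarray(self.concentration_grid, dtype=float)
        if grid.size and not np.all(np.diff(grid) > 0):
            raise ValueError("concentration_grid must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def log_tau_over_ki(self, agonist: str) -> float:
        return float(np.log10(self.tau[agonist]) - np.log10(self.ki[agonist]))

    def delta_log_tau_over_ki(self, agonist: str, reference: str) -> float:
        return self.log_tau_over_ki(agonist) - self.log_tau_over_ki(reference)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["concentration_grid"] = list(self.concentration_grid)
        return d


@dataclass(frozen=True)
class BretPlateTruth:
    """Per-phase line parameters (intercept, slope) used to build a plate."""

    phase_lines: tuple  # ((b0, m0), (b1, m1), (b2, m2))
    cycles_per_phase: int = 10
    cycle_time: float = 44.0
    noise_sd: float = 0.0
    nluc_level: float = 1.0e6
    seed: int = 0


@dataclass
class BretPlateRecording:
    """A generated BRET plate: long-format frame plus its ground truth."""

    data: pd.DataFrame
    truth: BretPlateTruth


# --------------------------------------------------------------- FRET traces


def _latent_signal(
    time: np.ndarray, protocol: ApplicationProtocol, truth: FretGroundTruth
) -> np.ndarray:
    """Piecewise-exponential occupancy: rise toward efficacy during an
    application, decay toward zero after washout.  Exact per-step updates,
    so the result is independent of sampling rate."""
    f = np.empty_like(time)
    f[0] = 0.0
    events = list(protocol.events)
    for i in range(1, time.size):
        dt = time[i] - time[i - 1]
        t = time[i]
        active = None
        for ev in events:
            if ev.t_start <= t < ev.t_end:
                active = ev
                break
        if active is not None:
            target = truth.efficacies.get(active.agonist_id, 0.0)
            f[i] = target + (f[i - 1] - target) * np.exp(-truth.on_rate * dt)
        else:
            f[i] = f[i - 1] * np.exp(-truth.off_rate * dt)
    return f


def generate_fret_recording(
    protocol: ApplicationProtocol,
    truth: FretGroundTruth,
    cell_id: str = "cell_000",
    rng: np.random.Generator | None = None,
) -> RawRecording:
    """Simulate one cell's raw recording under the stated generator model.

    Unknown agonists in the protocol get efficacy 0.  When ``rng`` is not
    supplied a fresh generator seeded from ``truth.seed`` is used, so
    identical inputs give bit-identical recordings.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    t = protocol.time_vector()
    f = _latent_signal(t, protocol, truth)
    scale = 1.0
    if truth.cell_scale_sd > 0:
        scale = float(np.exp(rng.normal(0.0, truth.cell_scale_sd)))
    bleach_d = np.exp(-truth.donor_bleach_rate * t)
    bleach_a = np.exp(-truth.acceptor_bleach_rate * t)
    donor_latent = scale * truth.donor_scale * bleach_d * (1.0 - truth.fret_scale * f)
    acceptor_latent = (
        scale
        * truth.donor_scale
        * bleach_a
        * (truth.baseline_ratio + truth.acceptor_gain * f)
    )
    direct_latent = scale * truth.direct_scale * bleach_a

    donor_em = truth.background_donor + donor_latent
    acceptor_direct = truth.background_acceptor + direct_latent
    acceptor_em = (
        truth.background_acceptor
        + acceptor_latent
        + truth.bleedthrough_frac * donor_latent
        + truth.false_excitation_frac * direct_latent
    )
    if truth.noise_sd > 0:
        donor_em = donor_em + rng.normal(0.0, truth.noise_sd, t.size)
        acceptor_em = acceptor_em + rng.normal(0.0, truth.noise_sd, t.size)
        acceptor_direct = acceptor_direct + rng.normal(0.0, truth.noise_sd, t.size)
    return RawRecording(
        cell_id=cell_id,
        time=t,
        donor_em=donor_em,
        acceptor_em=acceptor_em,
        acceptor_direct=acceptor_direct,
        protocol=protocol,
    )


def generate_fret_cohort(
    protocol: ApplicationProtocol,
    truth: FretGroundTruth,
    n_cells: int,
    cell_prefix: str = "cell",
) -> list[RawRecording]:
    """Simulate ``n_cells`` independent cells from one seeded stream."""
    rng = np.random.default_rng(truth.seed)
    return [
        generate_fret_recording(protocol, truth, f"{cell_prefix}_{i:03d}", rng)
        for i in range(n_cells)
    ]


def standard_protocol(
    agonists: list[str],
    reference_agonist: str = "ACh",
    pulse: float = 30.0,
    gap: float = 60.0,
    concentration: float = 3.0e-5,
    sampling_rate: float = 2.0,
    repeat_reference: bool = True,
) -> ApplicationProtocol:
    """Sequential saturating applications: reference first, then each test
    agonist, optionally the reference again at the end (signal-stability
    check)."""
    order = [reference_agonist] + [a for a in agonists if a != reference_agonist]
    if repeat_reference:
        order.append(reference_agonist)
    events = []
    t = gap
    for a in order:
        events.append(ApplicationEvent(a, concentration, t, t + pulse))
        t += pulse + gap
    return ApplicationProtocol(
        events=tuple(events), total_duration=t, sampling_rate=sampling_rate
    )


# --------------------------------------------------------------- BRET plates

PHASES = ("baseline", "agonist", "saturation")


def generate_bret_plate(
    n_wells: int,
    phase_lines,
    noise_sd: float = 0.0,
    seed: int = 0,
    cycles_per_phase: int = 10,
    cycle_time: float = 44.0,
    nluc_level: float = 1.0e6,
    agonist_id: str = "ACh",
    concentration: float = 3.0e-5,
) -> BretPlateRecording:
    """Simulate a three-phase BRET plate from piecewise-linear truth.

    ``phase_lines`` is a sequence of three ``(intercept, slope)`` pairs (in
    ratio units and ratio units per second) or three scalars (flat phases).
    Cycle times run continuously across phases.  The YFP channel is
    ``ratio * nluc`` with noise added to the ratio.
    """
    if cycles_per_phase < 1:
        raise ValueError("cycles_per_phase must be >= 1")
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    lines = []
    for pl in phase_lines:
        if np.isscalar(pl):
            lines.append((float(pl), 0.0))
        else:
            b, m = pl
            lines.append((float(b), float(m)))
    if len(lines) != 3:
        raise ValueError("phase_lines must describe exactly 3 phases")
    truth = BretPlateTruth(
        phase_lines=tuple(lines),
        cycles_per_phase=cycles_per_phase,
        cycle_time=cycle_time,
        noise_sd=noise_sd,
        nluc_level=nluc_level,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    rows = []
    for w in range(n_wells):
        for p, (phase, (b, m)) in enumerate(zip(PHASES, lines)):
            for c in range(cycles_per_phase):
                cycle = p * cycles_per_phase + c
                t = cycle * cycle_time
                ratio = b + m * t
                if noise_sd > 0:
                    ratio += rng.normal(0.0, noise_sd)
                rows.append(
                    {
                        "well_id": f"W{w:02d}",
                        "cycle_index": cycle,
                        "cycle_time_s": t,
                        "phase": phase,
                        "yfp": ratio * nluc_level,
                        "nluc": nluc_level,
                        "agonist": agonist_id,
                        "conc_M": concentration,
                    }
                )
    return BretPlateRecording(data=pd.DataFrame(rows), truth=truth)


# ------------------------------------------------- operational / binding


def operational_response(conc, tau: float, ki: float, n: float, emax: float):
    """Operational-model response Y = [A]^n τ^n Emax / ([A]^n τ^n + ([A]+Ki)^n)."""
    a = np.asarray(conc, dtype=float)
    num = a**n * tau**n * emax
    den = a**n * tau**n + (a + ki) ** n
    return num / den


def generate_concentration_response(
    truth: OperationalGroundTruth,
) -> pd.DataFrame:
    """Evaluate the operational model on the truth's grid, add noise, repeat.

    Returns a long-format frame with columns ``agonist, conc_M, response,
    replicate``.
    """
    grid = np.asarray(truth.concentration_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("concentration_grid is empty")
    rng = np.random.default_rng(truth.seed)
    rows = []
    for agonist, tau in truth.tau.items():
        y0 = operational_response(grid, tau, truth.ki[agonist], truth.n, truth.emax)
        for rep in range(truth.replicates):
            y = y0.copy()
            if truth.noise_sd > 0:
                y = y + rng.normal(0.0, truth.noise_sd, grid.size)
            for c, v in zip(grid, y):
                rows.append(
                    {
                        "agonist": agonist,
                        "conc_M": float(c),
                        "response": float(v),
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def generate_competition_binding(
    ic50: float,
    hill: float = 1.0,
    noise_sd: float = 0.0,
    grid=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Percent-of-control specific binding on a concentration grid.

    %binding = 100 / (1 + ([I]/IC50)^hill) + noise; [I] = 0 gives 100%.
    """
    if ic50 <= 0:
        raise ValueError("IC50 must be > 0")
    if grid is None:
        grid = np.logspace(np.log10(ic50) - 3, np.log10(ic50) + 3, 13)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore"):
        y = 100.0 / (1.0 + (grid / ic50) ** hill)
    y = np.where(grid == 0, 100.0, y)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, grid.size)
    return pd.DataFrame(
        {"conc_M": grid, "response": y, "replicate": np.zeros(grid.size, dtype=int)}
    )
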