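"""Configuration, file formats and the end-to-end pipeline.

File formats (all plain text):

* trace CSV (long): cell_id, time_s, channel in {donor_em, acceptor_em,
  acceptor_direct}, intensity
* protocol JSON: events with agonist_id / concentration_M / t_start_s /
  t_end_s, plus total_duration_s and sampling_rate_hz
* plate CSV: well_id, cycle_index, cycle_time_s, phase, yfp, nluc, agonist,
  conc_M
* binding CSV: conc_M, response, replicate
* concentration-response CSV: agonist, conc_M, response, replicate
* report: JSON with provenance metadata (input hashes, config snapshot,
  package version) plus rendered CSV tables

The pipeline chains: channel correction -> ratio -> baseline correction ->
amplitude extraction -> reference normalization -> per-pathway efficacy
aggregation -> rank orders -> cross-pathway comparison -> bias calls, and is
deterministic given the configuration and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, ScenarioError
from .fret import (
    AmplitudeRecord,
    CorrectionCoefficients,
    EfficacyTable,
    RawRecording,
    aggregate_efficacies,
    baseline_correct,
    compute_ratio,
    correct_channels,
    extract_amplitudes,
    normalize_to_reference,
)
from .operational import BiasReport, compare_pathways, rank_order
from .protocol import ApplicationProtocol
from .statcomp import anova_tukey
from .synthetic import FretGroundTruth, generate_fret_cohort, standard_protocol

__all__ = [
    "PipelineConfig",
    "PathwayInput",
    "write_traces_csv",
    "read_traces_csv",
    "run_pipeline",
    "simulate_scenario",
    "SCENARIOS",
]

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ["cell_id", "time_s", "channel", "intensity"]
CHANNELS = ("donor_em", "acceptor_em", "acceptor_direct")


# ----------------------------------------------------------------- trace I/O


def write_traces_csv(recordings: list[RawRecording], path: str | Path) -> None:
    """Write recordings to the long-format trace CSV."""
    frames = []
    for rec in recordings:
        for channel in CHANNELS:
            values = getattr(rec, channel)
            if values is None:
                continue
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": rec.cell_id,
                        "time_s": rec.time,
                        "channel": channel,
                        "intensity": values,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(
    path: str | Path, protocol: ApplicationProtocol
) -> list[RawRecording]:
    """Read the long-format trace CSV back into per-cell recordings."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: trace CSV missing columns {missing}")
    bad = set(df["channel"].unique()) - set(CHANNELS)
    if bad:
        raise ConfigError(f"{path}: unknown channels {sorted(bad)}")
    recordings = []
    for cell_id, cell_df in df.groupby("cell_id", sort=True):
        channels = {}
        time = None
        for channel, ch_df in cell_df.groupby("channel"):
            ch_df = ch_df.sort_values("time_s")
            channels[channel] = ch_df["intensity"].to_numpy(dtype=float)
            t = ch_df["time_s"].to_numpy(dtype=float)
            if time is not None and (t.size != time.size or not np.allclose(t, time)):
                raise ConfigError(
                    f"{path}: cell {cell_id!r} channels sampled on different grids"
                )
            time = t
        for required in ("donor_em", "acceptor_em"):
            if required not in channels:
                raise ConfigError(f"{path}: cell {cell_id!r} missing {required}")
        recordings.append(
            RawRecording(
                cell_id=str(cell_id),
                time=time,
                donor_em=channels["donor_em"],
                acceptor_em=channels["acceptor_em"],
                acceptor_direct=channels.get("acceptor_direct"),
                protocol=protocol,
            )
        )
    return recordings


# ------------------------------------------------------------------- config


@dataclass
class PathwayInput:
    """One pathway's FRET input files."""

    pathway_id: str
    traces_csv: str
    protocol_json: str


@dataclass
class PipelineConfig:
    pathways: list[PathwayInput]
    correction: CorrectionCoefficients = field(
        default_factory=CorrectionCoefficients
    )
    reference_agonist: str = "ACh"
    reference_policy: str = "first"
    tie_rule: str = "tukey"
    tie_tol: float = 0.05
    alpha: float = 0.05
    output_dir: str = "retbias_out"
    seed: int = 0

    def validate(self) -> dict[str, ApplicationProtocol]:
        """Check files exist and the reference agonist is applied everywhere.

        Returns the loaded protocols keyed by pathway, so validation happens
        before any computation.
        """
        if not self.pathways:
            raise ConfigError("no pathways configured")
        protocols = {}
        for pw in self.pathways:
            for attr in ("traces_csv", "protocol_json"):
                p = Path(getattr(pw, attr))
                if not p.exists():
                    raise ConfigError(f"pathway {pw.pathway_id!r}: {p} not found")
            proto = ApplicationProtocol.from_json(pw.protocol_json)
            if self.reference_agonist not in proto.agonists:
                raise ConfigError(
                    f"pathway {pw.pathway_id!r}: reference agonist "
                    f"{self.reference_agonist!r} not in protocol"
                )
            protocols[pw.pathway_id] = proto
        return protocols

    def to_dict(self) -> dict:
        return {
            "pathways": [
                {
                    "pathway_id": p.pathway_id,
                    "traces_csv": p.traces_csv,
                    "protocol_json": p.protocol_json,
                }
                for p in self.pathways
            ],
            "correction": {
                "background_donor": self.correction.background_donor,
                "background_acceptor": self.correction.background_acceptor,
                "bleedthrough_frac": self.correction.bleedthrough_frac,
                "false_excitation_frac": self.correction.false_excitation_frac,
            },
            "reference_agonist": self.reference_agonist,
            "reference_policy": self.reference_policy,
            "tie_rule": self.tie_rule,
            "tie_tol": self.tie_tol,
            "alpha": self.alpha,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        corr = d.get("correction", {})
        return cls(
            pathways=[PathwayInput(**p) for p in d["pathways"]],
            correction=CorrectionCoefficients(
                background_donor=corr.get("background_donor", 0.0),
                background_acceptor=corr.get("background_acceptor", 0.0),
                bleedthrough_frac=corr.get("bleedthrough_frac", 0.0),
                false_excitation_frac=corr.get("false_excitation_frac", 0.0),
            ),
            reference_agonist=d.get("reference_agonist", "ACh"),
            reference_policy=d.get("reference_policy", "first"),
            tie_rule=d.get("tie_rule", "tukey"),
            tie_tol=d.get("tie_tol", 0.05),
            alpha=d.get("alpha", 0.05),
            output_dir=d.get("output_dir", "retbias_out"),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ----------------------------------------------------------------- pipeline


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def process_fret_pathway(
    recordings: list[RawRecording],
    correction: CorrectionCoefficients,
    pathway_id: str,
    reference_agonist: str = "ACh",
    reference_policy: str = "first",
) -> tuple[list[AmplitudeRecord], EfficacyTable]:
    """FRET stage for one pathway: correct, ratio, baseline, amplitudes,
    normalization and aggregation."""
    records: list[AmplitudeRecord] = []
    for rec in recordings:
        corrected = correct_channels(rec, correction)
        trace = compute_ratio(corrected)
        trace = baseline_correct(trace)
        records.extend(extract_amplitudes(trace))
    normalized = normalize_to_reference(
        records, reference_agonist=reference_agonist,
        reference_policy=reference_policy,
    )
    table = aggregate_efficacies(normalized, pathway_id)
    return normalized, table


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> BiasReport:
    """Run the full analysis chain and (optionally) write all outputs.

    Deterministic given the configuration; intermediate tables and the final
    JSON report carry provenance metadata.
    """
    protocols = config.validate()
    out_dir = Path(config.output_dir)

    tables: dict[str, EfficacyTable] = {}
    amplitude_frames = {}
    for pw in config.pathways:
        recordings = read_traces_csv(pw.traces_csv, protocols[pw.pathway_id])
        logger.info(
            "pathway %s: %d cells loaded", pw.pathway_id, len(recordings)
        )
        normalized, table = process_fret_pathway(
            recordings,
            config.correction,
            pw.pathway_id,
            reference_agonist=config.reference_agonist,
            reference_policy=config.reference_policy,
        )
        logger.info(
            "pathway %s: %d amplitude records from %d agonists",
            pw.pathway_id,
            len(normalized),
            len(table.values),
        )
        tables[pw.pathway_id] = table
        amplitude_frames[pw.pathway_id] = pd.DataFrame(
            [
                {
                    "cell_id": r.cell_id,
                    "agonist": r.agonist_id,
                    "conc_M": r.concentration,
                    "application_index": r.application_index,
                    "raw_amplitude": r.raw_amplitude,
                    "normalized_amplitude": r.normalized_amplitude,
                }
                for r in normalized
            ]
        )

    rank_orders = {
        p: rank_order(t, tie_rule=config.tie_rule, tie_tol=config.tie_tol,
                      alpha=config.alpha)
        for p, t in tables.items()
    }
    pairwise_stats = {}
    for p, t in tables.items():
        if all(v.size >= 2 for v in t.values.values()) and len(t.values) >= 2:
            pairwise_stats[p] = anova_tukey(t.values).pairwise

    comparisons = []
    bias_calls = []
    pathway_ids = sorted(tables)
    for a, b in ((x, y) for i, x in enumerate(pathway_ids)
                 for y in pathway_ids[i + 1:]):
        comp = compare_pathways(rank_orders[a], rank_orders[b], tables[a], tables[b])
        comparisons.append(comp)
        for pair in comp.discordant_pairs:
            hi_in_b = (
                tables[b].means[pair[0]] > tables[b].means[pair[1]]
            )
            favored = pair[0] if hi_in_b else pair[1]
            bias_calls.append(
                {
                    "agonist_pair": list(pair),
                    "pathway_a": a,
                    "pathway_b": b,
                    "direction": f"{favored} relatively favored in {b}",
                    "evidence": "discordant rank-order pair",
                }
            )

    report = BiasReport(
        efficacy_tables={p: t.summary for p, t in tables.items()},
        rank_orders=rank_orders,
        pairwise_stats=pairwise_stats,
        comparisons=comparisons,
        bias_calls=bias_calls,
    )

    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
        for p, frame in amplitude_frames.items():
            frame.to_csv(out_dir / f"amplitudes_{p}.csv", index=False)
        for p, t in tables.items():
            t.summary.to_csv(out_dir / f"efficacies_{p}.csv", index=False)
        provenance = {
            "package_version": __version__,
            "config": config.to_dict(),
            "input_hashes": {
                pw.pathway_id: {
                    "traces_csv": _sha256(pw.traces_csv),
                    "protocol_json": _sha256(pw.protocol_json),
                }
                for pw in config.pathways
            },
        }
        payload = {"provenance": provenance, "report": report.to_dict()}
        (out_dir / "bias_report.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
    return report


# ---------------------------------------------------------------- scenarios

_AGONISTS = ("ACh", "Metha", "Fur", "Are", "Guva", "Pilo", "Mda")

#: per-scenario relative efficacies for the two simulated pathways
SCENARIOS: dict[str, dict[str, dict[str, float]]] = {
    "concordant": {
        "Gq_activation": {
            "ACh": 1.0, "Metha": 0.6, "Fur": 0.6, "Are": 0.3, "Guva": 0.3,
            "Pilo": 0.1, "Mda": 0.03,
        },
        "arrestin3_recruitment": {
            "ACh": 1.0, "Metha": 0.6, "Fur": 0.6, "Are": 0.3, "Guva": 0.3,
            "Pilo": 0.1, "Mda": 0.03,
        },
    },
    # one built-in reversal: Pilo and Are swap between pathways while Pilo
    # stays tied with Guva in the second pathway
    "arrestin_reversal": {
        "Gq_activation": {
            "ACh": 1.0, "Metha": 0.6, "Fur": 0.6, "Are": 0.3, "Guva": 0.3,
            "Pilo": 0.1, "Mda": 0.03,
        },
        "arrestin3_recruitment": {
            "ACh": 1.0, "Metha": 0.6, "Fur": 0.6, "Guva": 0.3, "Pilo": 0.3,
            "Are": 0.1, "Mda": 0.03,
        },
    },
    "null": {
        "Gq_activation": {a: 1.0 for a in _AGONISTS},
        "arrestin3_recruitment": {a: 1.0 for a in _AGONISTS},
    },
}


def simulate_scenario(
    scenario_name: str,
    seed: int = 0,
    out_dir: str | Path = "scenario_out",
    n_cells: int = 12,
    noise_sd: float = 0.5,
) -> PipelineConfig:
    """Generate a complete input set (traces, protocols, sidecar truth and a
    ready-to-run config) for a named scenario.

    Scenarios: ``concordant`` (identical rank orders in both pathways),
    ``arrestin_reversal`` (exactly one discordant agonist pair) and ``null``
    (all agonists equivalent).  Returns the pipeline configuration pointing
    at the generated files.
    """
    if scenario_name not in SCENARIOS:
        raise ScenarioError(
            f"unknown scenario {scenario_name!r}; "
            f"choose from {sorted(SCENARIOS)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coeff = CorrectionCoefficients(
        background_donor=10.0,
        background_acceptor=8.0,
        bleedthrough_frac=0.15,
        false_excitation_frac=0.05,
    )
    pathway_inputs = []
    truth_payload = {}
    for i, (pathway_id, efficacies) in enumerate(
        sorted(SCENARIOS[scenario_name].items())
    ):
        protocol = standard_protocol(list(efficacies))
        truth = FretGroundTruth(
            efficacies=dict(efficacies),
            donor_bleach_rate=2e-4,
            acceptor_bleach_rate=4e-4,
            bleedthrough_frac=coeff.bleedthrough_frac,
            false_excitation_frac=coeff.false_excitation_frac,
            background_donor=coeff.background_donor,
            background_acceptor=coeff.background_acceptor,
            noise_sd=noise_sd,
            cell_scale_sd=0.1,
            seed=seed + 1000 * i,
        )
        recordings = generate_fret_cohort(
            protocol, truth, n_cells, cell_prefix=f"{pathway_id}_cell"
        )
        traces_csv = out_dir / f"traces_{pathway_id}.csv"
        protocol_json = out_dir / f"protocol_{pathway_id}.json"
        write_traces_csv(recordings, traces_csv)
        protocol.to_json(protocol_json)
        truth_payload[pathway_id] = truth.to_dict()
        pathway_inputs.append(
            PathwayInput(
                pathway_id=pathway_id,
                traces_csv=str(traces_csv),
                protocol_json=str(protocol_json),
            )
        )
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truth_payload, indent=2, sort_keys=True) + "\n"
    )
    config = PipelineConfig(
        pathways=pathway_inputs,
        correction=coeff,
        output_dir=str(out_dir / "results"),
        seed=seed,
    )
    (out_dir / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return config
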