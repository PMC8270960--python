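"""Tabular and JSON result I/O.

All TSVs are UTF-8, tab-separated, decimal-point floats printed with %.6g.
A run-metadata JSON (config, seed, package version, timestamp) is written
alongside every CLI output so any run is reproducible from it alone.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from ringsym.config import AnalysisConfig
from ringsym.polarize import RadialBand
from ringsym.population import SymmetryDistribution
from ringsym.ringforge import GroundTruthRecord
from ringsym.symscan import RotationalSpectrum, SymmetryCall

_FLOAT_FMT = "%.6g"

CALL_COLUMNS = ["particle_id", "order", "confidence", "status", "peak_power"]
TRUTH_COLUMNS = [
    "particle_id", "true_order", "rotation_rad", "center_x_px", "center_y_px",
    "snr", "seed",
]


def calls_to_frame(calls: list[SymmetryCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "particle_id": [c.particle_id for c in calls],
            "order": [c.order if c.order is not None else -1 for c in calls],
            "confidence": [c.confidence for c in calls],
            "status": [c.status for c in calls],
            "peak_power": [c.peak_power for c in calls],
        }
    )


def write_calls_tsv(calls: list[SymmetryCall], path: str | Path) -> None:
    """One row per input particle; unassigned orders are written as -1."""
    if not calls:
        raise ValueError("nothing to write: no calls")
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_calls_tsv(path: str | Path) -> list[SymmetryCall]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        order = None if row.order < 0 else int(row.order)
        out.append(
            SymmetryCall(
                order=order, peak_power=float(row.peak_power),
                confidence=float(row.confidence), status=str(row.status),
                candidate_range=(2, 2), particle_id=str(row.particle_id),
            )
        )
    return out


def write_truth_tsv(records: list[GroundTruthRecord], path: str | Path) -> None:
    if not records:
        raise ValueError("nothing to write: no truth records")
    pd.DataFrame(
        {
            "particle_id": [r.particle_id for r in records],
            "true_order": [r.true_order for r in records],
            "rotation_rad": [r.rotation_rad for r in records],
            "center_x_px": [r.center_xy_px[0] for r in records],
            "center_y_px": [r.center_xy_px[1] for r in records],
            "snr": [r.snr for r in records],
            "seed": [r.seed for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_truth_tsv(path: str | Path) -> list[GroundTruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        GroundTruthRecord(
            particle_id=str(r.particle_id), true_order=int(r.true_order),
            rotation_rad=float(r.rotation_rad),
            center_xy_px=(float(r.center_x_px), float(r.center_y_px)),
            snr=float(r.snr), seed=int(r.seed),
        )
        for r in df.itertuples(index=False)
    ]


def write_spectra_tsv(
    spectra: dict[str, RotationalSpectrum] | list[tuple[str, RotationalSpectrum]],
    path: str | Path,
) -> None:
    """Long-format TSV with columns (id, k, power)."""
    items = spectra.items() if isinstance(spectra, dict) else spectra
    rows = []
    for name, spec in items:
        for k, p in enumerate(spec.power):
            rows.append((name, k, p))
    if not rows:
        raise ValueError("nothing to write: no spectra")
    pd.DataFrame(rows, columns=["id", "k", "power"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def distribution_to_dict(dist: SymmetryDistribution) -> dict:
    return {
        "orders": {
            str(k): {"count": int(dist.counts[k]), "pct": float(dist.percentages[k])}
            for k in sorted(dist.counts)
        },
        "total_input": dist.total_input,
        "total_assigned": dist.total_assigned,
    }


def distribution_from_dict(d: dict) -> SymmetryDistribution:
    counts = {int(k): int(v["count"]) for k, v in d["orders"].items()}
    pcts = {int(k): float(v["pct"]) for k, v in d["orders"].items()}
    return SymmetryDistribution(
        counts=counts, total_assigned=int(d["total_assigned"]),
        total_input=int(d["total_input"]), percentages=pcts,
    )


def write_distribution_json(dist: SymmetryDistribution, path: str | Path) -> None:
    Path(path).write_text(json.dumps(distribution_to_dict(dist), indent=2) + "\n")


def read_distribution_json(path: str | Path) -> SymmetryDistribution:
    return distribution_from_dict(json.loads(Path(path).read_text()))


def write_run_metadata(
    path: str | Path, command: str, config: AnalysisConfig | None = None,
    seed: int | None = None, extra: dict | None = None,
) -> None:
    from ringsym import __version__

    meta = {
        "command": command,
        "config": config.to_dict() if config is not None else None,
        "seed": seed,
        "versions": {
            "ringsym": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")


def write_calls_star(calls: list[SymmetryCall], path: str | Path) -> None:
    """Optional STAR-format export of the calls table for interoperability
    with particle-processing suites."""
    if not calls:
        raise ValueError("nothing to write: no calls")
    lines = [
        "data_calls", "", "loop_",
        "_ringParticleId #1", "_ringSymmetryOrder #2", "_ringConfidence #3",
        "_ringStatus #4", "_ringPeakPower #5",
    ]
    for c in calls:
        order = c.order if c.order is not None else -1
        lines.append(
            f"{c.particle_id}\t{order}\t{_FLOAT_FMT % c.confidence}\t"
            f"{c.status}\t{_FLOAT_FMT % c.peak_power}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
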