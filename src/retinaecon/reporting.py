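"""Publication-shaped result tables and run manifests.

All outputs are plain delimited text ('.' decimal, no thousands
separators) so runs can be diffed; every output directory receives a
single ``manifest.json`` recording the command, inputs, seed and package
version, which together determine the outputs bit for bit.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .bia import BIAResult
from .cea import IncrementalResult
from .outcomes import EconResult

__all__ = [
    "RunManifest",
    "write_manifest",
    "incremental_table",
    "components_table",
    "bia_table",
    "write_table",
]


@dataclass
class RunManifest:
    """What produced an output directory: command, inputs, seed, version."""

    command: str
    config_paths: list[str]
    seed: int | None
    package_version: str
    output_dir: str
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())
    extra: dict = field(default_factory=dict)


def write_manifest(outdir: str | Path, command: str, config_paths: list[str],
                   seed: int | None = None, **extra) -> Path:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        command=command,
        config_paths=[str(p) for p in config_paths],
        seed=seed,
        package_version=__version__,
        output_dir=str(outdir),
        extra={**extra, "python": platform.python_version()},
    )
    path = outdir / "manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return path


def incremental_table(results: list[EconResult],
                      incrementals: list[IncrementalResult]) -> pd.DataFrame:
    """Cost-effectiveness table: one row per treatment, intervention first.

    Incremental columns follow the cost-saving sign convention: positive
    incremental cost means the comparator costs more than the intervention.
    """
    rows = [{
        "treatment": results[0].treatment,
        "cost": results[0].total_cost,
        "incremental_cost": None,
        "qalys": results[0].qalys,
        "incremental_qalys": None,
        "icer": None,
        "label": "",
        "nmb": None,
    }]
    for res, inc in zip(results[1:], incrementals):
        rows.append({
            "treatment": res.treatment,
            "cost": res.total_cost,
            "incremental_cost": inc.delta_cost,
            "qalys": res.qalys,
            # printed from the comparator's row: comparator − intervention
            "incremental_qalys": -inc.delta_qaly,
            "icer": inc.icer,
            "label": inc.label,
            "nmb": inc.nmb,
        })
    return pd.DataFrame(rows)


def components_table(results: list[EconResult]) -> pd.DataFrame:
    """Cost components and injection totals, one row per treatment."""
    return pd.DataFrame([r.components_row() for r in results])


def bia_table(res: BIAResult) -> pd.DataFrame:
    """Scenario × year budget table with the cumulative 3-year column."""
    out = res.table.copy()
    out["cumulative_3yr"] = [res.cumulative_without, res.cumulative_with, res.cumulative_impact]
    out.index.name = "scenario"
    return out.reset_index()


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path
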