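"""Result formatting, run manifests, and output writing.

Formatted tables mirror the publication conventions — hospitalization counts
rounded to the nearest 1,000, dollar amounts to the nearest $0.1 billion,
uncertainty intervals rendered "(low to high)" — for eyeball comparison.
Rounding is presentation-only: raw full-precision values are always written
alongside the formatted table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .engine import QUANTITIES, SimulationResult
from .projection import MultiYearResult

_DOLLARS = ("averted_expenditures", "program_cost", "net_savings")


def round_to_nearest(x: float, base: float) -> float:
    """Round to the nearest multiple of ``base`` (half away from handled by numpy)."""
    return base * round(x / base)


def format_count(x: float) -> str:
    """Nearest-1000 rendering with space-grouped thousands: 1601374 -> '1 601 000'."""
    return f"{int(round_to_nearest(x, 1000)):,}".replace(",", " ")


def format_billions(x: float) -> str:
    """Nearest-$0.1B rendering: 13856000000 -> '13.9'."""
    return f"{x / 1e9:.1f}"


def _cell(summary: pd.DataFrame, stratum: str, quantity: str) -> str:
    fmt = format_billions if quantity in _DOLLARS else format_count
    mean = fmt(summary.loc[stratum, f"{quantity}_mean"])
    lo = fmt(summary.loc[stratum, f"{quantity}_ui_low"])
    hi = fmt(summary.loc[stratum, f"{quantity}_ui_high"])
    return f"{mean} ({lo} to {hi})"


def format_result_table(
    result: SimulationResult | MultiYearResult | pd.DataFrame,
    population: str = "primary",
) -> pd.DataFrame:
    """Publication-style string table from a simulation summary.

    Accepts a :class:`SimulationResult`, :class:`MultiYearResult`, or a bare
    summary frame.  Columns: averted hospitalizations, averted expenditures
    ($B), program cost ($B), net savings ($B), each "mean (low to high)".
    """
    if isinstance(result, SimulationResult):
        summary = result.summary
    elif isinstance(result, MultiYearResult):
        summary = result.cumulative_summary
    else:
        summary = result
    strata = [s for s in summary.index if s != "total"] + ["total"]
    rows = {}
    for stratum in strata:
        rows[(population, stratum)] = {
            "averted_hospitalizations": _cell(summary, stratum, "averted_hospitalizations"),
            "averted_expenditures_billion": _cell(summary, stratum, "averted_expenditures"),
            "program_cost_billion": _cell(summary, stratum, "program_cost"),
            "net_savings_billion": _cell(summary, stratum, "net_savings"),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.names = ("population", "stratum")
    return table


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    config_hash: str
    seed: int | None
    package_version: str
    created_utc: str
    config: dict[str, Any] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256_of(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def build_manifest(
    raw_config: Mapping[str, Any],
    seed: int | None,
    input_paths: Mapping[str, str | Path] | None = None,
) -> RunManifest:
    from . import __version__

    canonical = json.dumps(dict(raw_config), sort_keys=True).encode()
    digests = {}
    for label, p in (input_paths or {}).items():
        digests[label] = _sha256_of(Path(p).read_bytes())
    return RunManifest(
        config_hash=_sha256_of(canonical),
        seed=seed,
        package_version=__version__,
        created_utc=datetime.now(timezone.utc).isoformat(),
        config=dict(raw_config),
        input_digests=digests,
    )


def save_result(
    result: SimulationResult | MultiYearResult,
    outdir: str | Path,
    prefix: str = "result",
    manifest: RunManifest | None = None,
) -> dict[str, Path]:
    """Write summary CSV/JSON, replicate CSV, formatted table, and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(result, MultiYearResult):
        summary, reps = result.cumulative_summary, result.cumulative_replicates
        extra = {
            "horizon_years": result.horizon_years,
            "discount_rate": result.discount_rate,
            "carryover_fraction": result.carryover_fraction,
            "seed": result.seed,
        }
    else:
        summary, reps = result.summary, result.replicates
        extra = {
            "n_replicates": result.n_replicates,
            "seed": result.seed,
            "fraction_cost_saving": result.fraction_cost_saving,
            "coverage_fraction": result.coverage_fraction,
        }
    paths = {
        "summary_csv": outdir / f"{prefix}_summary.csv",
        "replicates_csv": outdir / f"{prefix}_replicates.csv",
        "summary_json": outdir / f"{prefix}_summary.json",
        "formatted_txt": outdir / f"{prefix}_table.txt",
    }
    summary.to_csv(paths["summary_csv"])
    reps.to_csv(paths["replicates_csv"], index=False)
    payload = {"meta": extra, "summary": summary.to_dict(orient="index")}
    paths["summary_json"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    paths["formatted_txt"].write_text(format_result_table(result).to_string())
    if manifest is not None:
        paths["manifest_json"] = outdir / f"{prefix}_manifest.json"
        paths["manifest_json"].write_text(manifest.to_json())
    return paths


def plot_replicate_scatter(result: SimulationResult, path: str | Path) -> Path:
    """Scatter of (program cost, averted expenditures) replicate pairs by stratum,
    with the cost-neutrality diagonal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reps = result.replicates
    fig, ax = plt.subplots(figsize=(7, 6))
    for stratum, grp in reps[reps["stratum"] != "total"].groupby("stratum"):
        ax.scatter(
            grp["program_cost"] / 1e9,
            grp["averted_expenditures"] / 1e9,
            s=6,
            alpha=0.4,
            label=stratum,
        )
    lim = max(ax.get_xlim()[1], ax.get_ylim()[1])
    ax.plot([0, lim], [0, lim], color="black", lw=1, label="cost neutrality")
    ax.set_xlabel("MTM program cost ($B/year)")
    ax.set_ylabel("Averted health care expenditures ($B/year)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
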