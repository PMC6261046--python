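"""Run orchestration: many seeded instances per layout, aggregated tables.

A campaign simulates ``n_instances`` instances per growth layout (instance
i always receives seed ``base_seed + i``, so results are independent of
execution order and resumable), runs the per-instance analysis battery on
each, and writes per-layout instance tables plus one aggregate row per
layout, together with a checksummed manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .calibration import params_for_layout
from .connectome import aggregate_connectome, structural_measures
from .layouts import GrowthLayoutConfig
from .simulation import SimulationParams, run_instance
from .stats import AnalysisConfig, InstanceReport, aggregate_instances, analyze_instance
from . import io as cio


@dataclass
class LayoutResult:
    layout: GrowthLayoutConfig
    reports: list[InstanceReport]
    aggregate: dict


def analyze_layout(
    layout: GrowthLayoutConfig,
    n_instances: int,
    base_seed: int,
    params: SimulationParams | None = None,
    min_axons: int = 1,
    config: AnalysisConfig = AnalysisConfig(),
) -> LayoutResult:
    """Simulate and analyze ``n_instances`` seeded instances of one layout."""
    params = params if params is not None else params_for_layout(layout)
    reports = []
    for i in range(n_instances):
        res = run_instance(layout, params, base_seed + i)
        con = aggregate_connectome(
            res.synapses, res.neuron_area, res.sheet.n_areas, min_axons
        )
        reports.append(analyze_instance(con, structural_measures(res.sheet), config))
    return LayoutResult(layout, reports, aggregate_instances(reports, config))


def run_campaign(
    layouts: list[GrowthLayoutConfig],
    n_instances: int = 100,
    base_seed: int = 0,
    out_dir: Path | str = "campaign",
    params_by_mode: dict[str, SimulationParams] | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Run the analysis battery for several layouts and write result tables.

    Completed layouts (instance table already present with the expected row
    count) are skipped, making reruns resumable; partial failures are
    recorded in the manifest and do not abort the campaign.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, written, failures = [], [], {}
    for layout in layouts:
        sub = out_dir / layout.abbreviation
        sub.mkdir(exist_ok=True)
        inst_path = sub / "instances.csv"
        try:
            if inst_path.exists() and len(pd.read_csv(inst_path)) == n_instances:
                frame = pd.read_csv(inst_path)
                agg = _aggregate_frame(frame, config)
            else:
                params = None
                if params_by_mode is not None:
                    mode = "2D" if layout.growth_mode == "2D" else "1D"
                    params = params_by_mode[mode]
                result = analyze_layout(
                    layout, n_instances, base_seed, params, config=config
                )
                frame = pd.DataFrame([r.to_row() for r in result.reports])
                frame.to_csv(inst_path, index=False)
                agg = result.aggregate
            written.append(inst_path)
        except Exception as exc:  # keep going; manifest records the gap
            failures[layout.abbreviation] = repr(exc)
            continue
        rows.append({"layout": layout.abbreviation, **agg})
    aggregate = pd.DataFrame(rows)
    agg_path = out_dir / "aggregate.csv"
    aggregate.to_csv(agg_path, index=False)
    written.append(agg_path)
    cio.write_manifest(
        out_dir,
        {
            "base_seed": base_seed,
            "n_instances": n_instances,
            "layouts": [l.abbreviation for l in layouts],
            "failures": failures,
        },
        written,
    )
    return aggregate


def _aggregate_frame(frame: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Re-aggregate a stored instance table (resume path)."""
    from .stats import sign_test_left

    out = {
        "n_instances": len(frame),
        "median_fraction_connected": float(frame["fraction_connected"].median()),
        "median_n_connections": float(frame["n_connections"].median()),
    }
    for key in ("freq_distance", "freq_absdens", "degree_density"):
        out[f"median_rho_{key}"] = float(frame[f"rho_{key}"].median())
        p = frame[f"p_{key}"].dropna()
        out[f"median_p_{key}"] = float(p.median()) if len(p) else float("nan")
        if len(p):
            st = sign_test_left(p.to_numpy(), config.alpha_spearman)
            out[f"sign_z_{key}"], out[f"sign_p_{key}"] = st["z"], st["p"]
    for key in ("r2_distance", "r2_abs_density_diff", "r2_both"):
        out[f"median_{key}"] = float(frame[key].median())
    return out
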