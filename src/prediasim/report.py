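"""Report writers: CSV/JSON emission of the headline outcome tables."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .parameters import ModelParameters

MONEY_DP = 2
YEARS_DP = 2


def parameter_hash(params: ModelParameters) -> str:
    """Content hash of the full parameter set (identifies a run)."""
    blob = json.dumps(_params_dict(params), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _params_dict(params: ModelParameters) -> dict:
    def _clean(obj):
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        return obj
    return _clean({
        "strategies": {sid: asdict(s) for sid, s in params.strategies.items()},
        "screening": asdict(params.screening),
        "shared": asdict(params.shared),
        "costs": asdict(params.costs),
        "utilities": asdict(params.utilities),
        "settings": asdict(params.settings),
        "conventions": asdict(params.conventions),
    })


def write_manifest(out_dir: Path, params: ModelParameters, seed: int,
                   n: int, ages, arms) -> Path:
    manifest = {
        "seed": int(seed),
        "n": int(n),
        "ages": list(ages),
        "arms": list(arms),
        "parameter_hash": parameter_hash(params),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def extra_time_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Extra time before onset/complications, strategies x ages (wide)."""
    rows = summary[summary["strategy"] != "control"]
    onset = rows.pivot(index="strategy", columns="initiation_age",
                       values="extra_time_onset")
    comp = rows.pivot(index="strategy", columns="initiation_age",
                      values="extra_time_complication")
    onset.columns = [f"onset_age_{a}" for a in onset.columns]
    comp.columns = [f"complication_age_{a}" for a in comp.columns]
    return pd.concat([onset, comp], axis=1).round(YEARS_DP).reset_index()


def outcomes_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Clinical/economic outcomes per arm x age (long layout)."""
    cols = ["strategy", "initiation_age", "n_subjects", "n_eligible",
            "remaining_years_dm_igt", "remaining_years_lo", "remaining_years_hi",
            "qalys_dm_igt", "qalys_lo", "qalys_hi",
            "cost_per_subject", "cost_lo", "cost_hi", "cost_all_subjects",
            "saving_vs_control", "increment_qalys_vs_control"]
    out = summary[cols].copy()
    money = ["cost_per_subject", "cost_lo", "cost_hi", "cost_all_subjects",
             "saving_vs_control"]
    out[money] = out[money].round(MONEY_DP)
    years = ["remaining_years_dm_igt", "remaining_years_lo", "remaining_years_hi",
             "qalys_dm_igt", "qalys_lo", "qalys_hi", "increment_qalys_vs_control"]
    out[years] = out[years].round(YEARS_DP)
    return out


def compliance_pivot(sensitivity: pd.DataFrame) -> pd.DataFrame:
    """Savings by compliance level: strategies x (age x {baseline, 80%, 60%})."""
    keep = sensitivity[sensitivity["parameter_path"].isin(
        ["baseline", "screening.compliance"])].copy()
    level = keep["scenario"].map(
        lambda s: "reference" if s == "baseline" else s.rsplit("=", 1)[1])
    keep["level"] = level
    pivot = keep.pivot_table(index="strategy", columns=["initiation_age", "level"],
                             values="saving_vs_control")
    pivot.columns = [f"age{a}_{lvl}" for a, lvl in pivot.columns]
    return pivot.round(MONEY_DP).reset_index()


def write_run_outputs(out_dir: str | Path, summary: pd.DataFrame,
                      params: ModelParameters, seed: int, n: int,
                      ages, arms) -> dict[str, Path]:
    """Emit table3.csv / table4.csv / summary.json / manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    t3 = extra_time_table(summary)
    t4 = outcomes_table(summary)
    paths["table3"] = out_dir / "table3.csv"
    t3.to_csv(paths["table3"], index=False)
    paths["table4"] = out_dir / "table4.csv"
    t4.to_csv(paths["table4"], index=False)
    paths["summary_json"] = out_dir / "summary.json"
    paths["summary_json"].write_text(
        json.dumps(json.loads(t4.to_json(orient="records")), indent=2) + "\n")
    paths["manifest"] = write_manifest(out_dir, params, seed, n, ages, arms)
    return paths
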