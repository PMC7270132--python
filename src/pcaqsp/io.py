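"""CSV/JSON readers and writers for trajectories, screens, trees, datasets."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .calibration import (CalibrationDataset, Observation, ScenarioSeries)
from .model import STATE_NAMES
from .screening import ScreenResult
from .simulate import Trajectory
from .treatments import DoseEvent, TreatmentSchedule

__all__ = ["write_trajectory", "read_trajectory", "write_screen",
           "read_screen", "write_tree", "write_schedule", "read_schedule",
           "write_dataset", "read_dataset"]


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Full-precision CSV: time_days, the 19 states, total_tumor."""
    frame = traj.to_frame()
    np.savetxt(path, frame.to_numpy(), fmt="%.17g", delimiter=",",
               comments="", header=",".join(frame.columns))


def read_trajectory(path: str | Path) -> Trajectory:
    frame = pd.read_csv(path, float_precision="round_trip")
    return Trajectory(frame["time_days"].to_numpy(),
                      frame[list(STATE_NAMES)].to_numpy())


def write_screen(results: Sequence[ScreenResult], path: str | Path) -> None:
    """Screen CSV: combo, percent inhibition, percent change vs baseline."""
    rows = [{
        "combo": "+".join(r.combo),
        "n_treatments": len(r.combo),
        "tumor_inhibition_pct": 100.0 * r.tumor_inhibition,
        "tumor_change_vs_baseline_pct": 100.0 * r.tumor_fold_change_vs_baseline,
        "eval_time_days": r.eval_time,
    } for r in results]
    columns = ["combo", "n_treatments", "tumor_inhibition_pct",
               "tumor_change_vs_baseline_pct", "eval_time_days"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False,
                                               float_format="%.17g")


def read_screen(path: str | Path) -> list[ScreenResult]:
    frame = pd.read_csv(path, float_precision="round_trip")
    return [ScreenResult(tuple(row.combo.split("+")),
                         row.tumor_inhibition_pct / 100.0,
                         row.tumor_change_vs_baseline_pct / 100.0,
                         row.eval_time_days)
            for row in frame.itertuples()]


def write_tree(tree: nx.DiGraph, path: str | Path, fmt: str = "json") -> None:
    """Decision-tree export: JSON node/edge lists or a DOT digraph."""
    path = Path(path)
    if fmt == "json":
        payload = {
            "nodes": [{"combo": "+".join(node),
                       "tumor_inhibition": data["tumor_inhibition"],
                       "fold_change_vs_baseline": data["fold_change"]}
                      for node, data in tree.nodes(data=True)],
            "edges": [{"parent": "+".join(u), "child": "+".join(v),
                       "added": data["added"], "bci": data["bci"]}
                      for u, v, data in tree.edges(data=True)],
        }
        path.write_text(json.dumps(payload, indent=1))
    elif fmt == "dot":
        lines = ["digraph synergy {"]
        for node, data in tree.nodes(data=True):
            lines.append(f'  "{"+".join(node)}" '
                         f'[fold_change="{data["fold_change"]:.4f}"];')
        for u, v, data in tree.edges(data=True):
            lines.append(f'  "{"+".join(u)}" -> "{"+".join(v)}" '
                         f'[label="BCI={data["bci"]:.2f}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown tree format {fmt!r}; use 'json' or 'dot'")


def write_schedule(schedule: TreatmentSchedule, path: str | Path) -> None:
    payload = {
        "horizon": schedule.horizon,
        "cx_interval": list(schedule.cx_interval)
        if schedule.cx_interval else None,
        "events": [{"therapy": e.therapy, "time_days": e.time,
                    "amount": e.amount} for e in schedule.events],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_schedule(path: str | Path) -> TreatmentSchedule:
    payload = json.loads(Path(path).read_text())
    events = tuple(DoseEvent(e["therapy"], e["time_days"], e["amount"])
                   for e in payload.get("events", ()))
    cx = payload.get("cx_interval")
    return TreatmentSchedule(events=events,
                             cx_interval=tuple(cx) if cx else None,
                             horizon=payload["horizon"])


def write_dataset(dataset: CalibrationDataset, path: str | Path) -> None:
    payload = dataclasses.asdict(dataset)
    payload["scenarios"] = [
        {"combo": list(s.combo),
         "observations": [[o.variable, o.time, o.value]
                          for o in s.observations]}
        for s in dataset.scenarios]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_dataset(path: str | Path) -> CalibrationDataset:
    payload = json.loads(Path(path).read_text())
    scenarios = tuple(
        ScenarioSeries(tuple(s["combo"]),
                       tuple(Observation(v, t, x)
                             for v, t, x in s["observations"]))
        for s in payload.pop("scenarios"))
    payload["treatment_ratio_targets"] = tuple(
        tuple(pair) for pair in payload["treatment_ratio_targets"])
    for key in ("w_hat", "w_tilde"):
        payload[key] = tuple(payload[key])
    return CalibrationDataset(scenarios=scenarios, **payload)
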