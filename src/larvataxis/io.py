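"""File formats: trajectory tables, event tables, truth logs and configs.

Trajectory dialect: tab-separated text with ``#key<TAB>value`` header lines
(version, fps, midline point count, units) followed by one row per
(frame, track) with columns ``t_s``, ``track_id`` and x/y pairs for the
midline points tail→head, in cm.  Round-trips losslessly.
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from .segmentation import HeadSweep, Reorientation, Run, Track
from .simulator import AgentParams, GroundTruthLog, SimConfig, TruthEvent
from .stimulus import DirectionalField, TemporalRamp

__all__ = [
    "TrackParseError",
    "read_tracks",
    "write_tracks",
    "write_events",
    "read_events",
    "write_truth_log",
    "read_truth_log",
    "load_stimulus_config",
    "dump_stimulus_config",
    "load_sim_config",
    "dump_sim_config",
]

_DIALECT_VERSION = "1"


class TrackParseError(ValueError):
    pass


def write_tracks(tracks: List[Track], path, fps: Optional[float] = None,
                 experiment_id: Optional[str] = None) -> None:
    path = Path(path)
    if tracks:
        m = tracks[0].midline.shape[1]
        fps = fps if fps is not None else (1.0 / tracks[0].dt if len(tracks[0]) > 1 else 13.0)
        experiment_id = experiment_id if experiment_id is not None else tracks[0].experiment_id
    else:
        m = 5
        fps = fps or 13.0
        experiment_id = experiment_id or ""
    with open(path, "w") as fh:
        fh.write(f"#larvatrack\t{_DIALECT_VERSION}\n")
        fh.write(f"#fps\t{fps:g}\n")
        fh.write(f"#midline_points\t{m}\n")
        fh.write("#units\tcm\n")
        fh.write(f"#experiment_id\t{experiment_id}\n")
        cols = ["t_s", "track_id"] + [f"{a}{i}" for i in range(m) for a in ("x", "y")]
        fh.write("\t".join(cols) + "\n")
        for tr in tracks:
            flat = tr.midline.reshape(len(tr), -1)
            block = pd.DataFrame(flat, columns=cols[2:])
            block.insert(0, "track_id", tr.id)
            block.insert(0, "t_s", tr.t)
            block.to_csv(fh, sep="\t", header=False, index=False,
                         float_format="%.6f")


def read_tracks(path, expected_fps: Optional[float] = None) -> List[Track]:
    """Parse a trajectory file; malformed rows are reported with line numbers."""
    path = Path(path)
    header = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            parts = line[1:].rstrip("\n").split("\t")
            header[parts[0]] = parts[1] if len(parts) > 1 else ""
    for key in ("larvatrack", "fps", "midline_points", "units"):
        if key not in header:
            raise TrackParseError(f"{path}: missing header line '#{key}'")
    if header["units"] != "cm":
        raise TrackParseError(f"{path}: units must be cm, got {header['units']!r}")
    fps = float(header["fps"])
    if expected_fps is not None and not math.isclose(fps, expected_fps, rel_tol=1e-6):
        raise TrackParseError(f"{path}: fps {fps} does not match expected {expected_fps}")
    m = int(header["midline_points"])
    experiment_id = header.get("experiment_id", "")

    df = pd.read_csv(path, sep="\t", skiprows=n_header)
    expected_cols = ["t_s", "track_id"] + [f"{a}{i}" for i in range(m) for a in ("x", "y")]
    if list(df.columns) != expected_cols:
        raise TrackParseError(f"{path}: bad column header, expected {expected_cols}")
    if len(df) == 0:
        return []
    coords = df[expected_cols[2:]].to_numpy(dtype=float)
    bad = ~np.all(np.isfinite(coords), axis=1) | ~np.isfinite(df["t_s"].to_numpy(dtype=float))
    if bad.any():
        lineno = int(np.flatnonzero(bad)[0]) + n_header + 2
        raise TrackParseError(f"{path}: non-finite coordinate at line {lineno}")

    tracks = []
    for tid, sub in df.groupby("track_id", sort=False):
        t = sub["t_s"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            i = int(np.flatnonzero(np.diff(t) <= 0)[0])
            lineno = int(sub.index[i + 1]) + n_header + 2
            raise TrackParseError(
                f"{path}: non-monotone time for track {tid!r} at line {lineno}")
        midline = sub[expected_cols[2:]].to_numpy(dtype=float).reshape(len(sub), m, 2)
        tracks.append(Track(str(tid), t, midline, experiment_id))
    return tracks


_EVENT_COLS = ["track_id", "event", "kind", "t_start", "t_end", "side", "outcome",
               "ordinal", "heading_start", "heading_end", "mean_heading",
               "max_bend_deg", "max_heading", "path_length_cm", "mean_speed",
               "n_sweeps"]


def write_events(events_per_track: dict, path) -> None:
    """Write segmented events (and their sweeps) as a delimited event table."""
    rows = []
    for tid, events in events_per_track.items():
        for ev in events:
            if isinstance(ev, Run):
                rows.append(dict(track_id=tid, event="run", kind="run",
                                 t_start=ev.t_start, t_end=ev.t_end,
                                 heading_start=ev.start_heading,
                                 heading_end=ev.end_heading,
                                 mean_heading=ev.mean_heading,
                                 path_length_cm=ev.path_length_cm,
                                 mean_speed=ev.mean_speed))
            else:
                rows.append(dict(track_id=tid, event="reorientation", kind=ev.kind,
                                 t_start=ev.t_start, t_end=ev.t_end,
                                 heading_start=ev.prior_heading,
                                 heading_end=ev.new_heading,
                                 n_sweeps=len(ev.sweeps)))
                for sw in ev.sweeps:
                    rows.append(dict(track_id=tid, event="sweep", kind="sweep",
                                     t_start=sw.t_start, t_end=sw.t_end,
                                     side=sw.side, outcome=sw.outcome,
                                     ordinal=sw.ordinal,
                                     heading_start=sw.heading_before,
                                     max_bend_deg=sw.max_bend_deg,
                                     max_heading=sw.max_heading))
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(path, sep="\t", index=False)


def read_events(path) -> dict:
    """Read an event table back into per-track Run/Reorientation lists."""
    df = pd.read_csv(path, sep="\t")
    out: dict = {}
    current = None
    for _, r in df.iterrows():
        tid = str(r["track_id"])
        out.setdefault(tid, [])
        if r["event"] == "run":
            out[tid].append(Run(
                t_start=r["t_start"], t_end=r["t_end"], i_start=-1, i_end=-1,
                start_heading=r["heading_start"], end_heading=r["heading_end"],
                mean_heading=r["mean_heading"], path_length_cm=r["path_length_cm"],
                mean_speed=r["mean_speed"], mean_velocity=(float("nan"),) * 2,
                n_frames=0))
            current = None
        elif r["event"] == "reorientation":
            current = Reorientation(t_start=r["t_start"], t_end=r["t_end"],
                                    i_start=-1, i_end=-1,
                                    prior_heading=r["heading_start"],
                                    new_heading=r["heading_end"])
            out[tid].append(current)
        else:
            sw = HeadSweep(t_start=r["t_start"], t_end=r["t_end"], side=r["side"],
                           max_bend_deg=r["max_bend_deg"], outcome=r["outcome"],
                           ordinal=int(r["ordinal"]),
                           heading_before=r["heading_start"],
                           max_heading=r["max_heading"])
            if current is not None:
                current.sweeps.append(sw)
    return out


def write_truth_log(log: GroundTruthLog, path) -> None:
    rows = [dataclasses.asdict(e) for e in log.events]
    cols = [f.name for f in dataclasses.fields(TruthEvent)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_truth_log(path) -> GroundTruthLog:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["nan", ""])
    events = []
    for _, r in df.iterrows():
        events.append(TruthEvent(
            kind=str(r["kind"]), agent=str(r["agent"]),
            t_start=float(r["t_start"]), t_end=float(r["t_end"]),
            side=str(r["side"]) if pd.notna(r["side"]) else "",
            outcome=str(r["outcome"]) if pd.notna(r["outcome"]) else "",
            ordinal=int(r["ordinal"]),
            heading_start=float(r["heading_start"]) if pd.notna(r["heading_start"]) else float("nan"),
            heading_end=float(r["heading_end"]) if pd.notna(r["heading_end"]) else float("nan"),
            d_sign=int(r["d_sign"])))
    return GroundTruthLog(events=events)


def dump_stimulus_config(stimulus, path=None):
    if isinstance(stimulus, DirectionalField):
        doc = dict(type="directional", edge_intensity=stimulus.edge_intensity,
                   gradient_per_cm=stimulus.gradient,
                   light_angle_deg=stimulus.light_angle_deg,
                   arena_cm=list(stimulus.arena_cm))
    elif isinstance(stimulus, TemporalRamp):
        doc = dict(type="temporal", i_max=stimulus.i_max, t_ramp_s=stimulus.t_ramp_s,
                   t_hold_s=stimulus.t_hold_s, n_cycles=stimulus.n_cycles,
                   exclusion_margin_s=stimulus.exclusion_margin_s,
                   phase_order=stimulus.phase_order)
    elif stimulus is None:
        doc = dict(type="none")
    else:
        raise TrackParseError(f"unknown stimulus {stimulus!r}")
    if path is not None:
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
    return doc


def load_stimulus_config(source):
    """Load a stimulus from a YAML path or an already-parsed mapping."""
    doc = source if isinstance(source, dict) else yaml.safe_load(Path(source).read_text())
    kind = doc.get("type")
    if kind == "directional":
        return DirectionalField(
            edge_intensity=float(doc.get("edge_intensity", 4331.0)),
            gradient=float(doc.get("gradient_per_cm", 103.0)),
            light_angle_deg=float(doc.get("light_angle_deg", 180.0)),
            arena_cm=tuple(doc.get("arena_cm", (24.5, 24.5))))
    if kind == "temporal":
        return TemporalRamp(
            i_max=float(doc.get("i_max", 380.0)),
            t_ramp_s=float(doc.get("t_ramp_s", 25.5)),
            t_hold_s=float(doc.get("t_hold_s", 4.5)),
            n_cycles=int(doc.get("n_cycles", 11)),
            exclusion_margin_s=float(doc.get("exclusion_margin_s", 1.0)),
            phase_order=str(doc.get("phase_order", "up_first")))
    if kind in ("none", None):
        return None
    raise TrackParseError(f"unknown stimulus type {kind!r}")


def dump_sim_config(config: SimConfig, params: AgentParams, path=None):
    doc = dict(
        arena_cm=list(config.arena_cm), n_agents=config.n_agents,
        duration_s=config.duration_s, fps=config.fps,
        n_experiments=config.n_experiments, seed=config.seed,
        midline_points=config.midline_points,
        body_length_cm=config.body_length_cm,
        stimulus=dump_stimulus_config(config.stimulus),
        agent=dataclasses.asdict(params))
    if path is not None:
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
    return doc


def load_sim_config(source):
    doc = source if isinstance(source, dict) else yaml.safe_load(Path(source).read_text())
    stimulus = load_stimulus_config(doc.get("stimulus", {"type": "none"}))
    config = SimConfig(
        arena_cm=tuple(doc.get("arena_cm", (24.5, 24.5))),
        n_agents=int(doc.get("n_agents", 30)),
        duration_s=float(doc.get("duration_s", 660.0)),
        fps=float(doc.get("fps", 13.0)),
        n_experiments=int(doc.get("n_experiments", 1)),
        seed=int(doc.get("seed", 0)),
        stimulus=stimulus,
        midline_points=int(doc.get("midline_points", 5)),
        body_length_cm=float(doc.get("body_length_cm", 0.4)))
    params = AgentParams(**doc.get("agent", {}))
    return config, params
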