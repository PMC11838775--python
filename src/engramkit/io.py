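"""Delimited-text readers and writers with provenance headers.

All tables are TSV with ``#``-prefixed ``key=value`` provenance lines
(stage, seed, config hash, package version) before the column header.
Matrices are written cells-as-rows with cell ids as the first column.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .behavior import FreezingLabels, PoseTrack
from .cross_session import RegistrationMap
from .ensembles import CellPositions
from .epochs import EpochSet
from .events import EventRaster, TraceMatrix


def config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _provenance_lines(meta: Dict[str, object]) -> List[str]:
    from . import __version__
    base = {"engramkit_version": __version__}
    base.update(meta)
    return [f"# {k}={v}" for k, v in base.items()]


def write_table(path, df: pd.DataFrame, meta: Dict[str, object] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance_lines(meta or {}):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- epochs -------------------------------------------------------------------

def write_epochs(path, epochs: EpochSet, meta: Dict[str, object] | None = None) -> None:
    df = pd.DataFrame([(l, s, e) for l, s, e in epochs],
                      columns=["label", "start_s", "end_s"])
    write_table(path, df, meta)


def read_epochs(path) -> EpochSet:
    df = read_table(path)
    return EpochSet(zip(df.label.astype(str), df.start_s, df.end_s))


# -- traces and rasters -------------------------------------------------------

def write_traces(path, trace: TraceMatrix, meta: Dict[str, object] | None = None) -> None:
    meta = dict(meta or {})
    meta["sample_rate_hz"] = trace.sample_rate
    df = pd.DataFrame(trace.values)
    df.insert(0, "cell", trace.cell_ids)
    write_table(path, df, meta)


def read_traces(path) -> TraceMatrix:
    sample_rate = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line[1:].strip().startswith("sample_rate_hz="):
                sample_rate = float(line.split("=", 1)[1])
    if sample_rate is None:
        raise ValueError(f"{path}: missing '# sample_rate_hz=' header")
    df = read_table(path)
    cells = df["cell"].astype(int).tolist()
    return TraceMatrix(df.drop(columns="cell").to_numpy(float), sample_rate, cells)


def write_raster(path, raster: EventRaster, meta: Dict[str, object] | None = None) -> None:
    df = pd.DataFrame(raster.events.astype(int))
    df.insert(0, "cell", raster.cell_ids)
    write_table(path, df, meta)


def read_raster(path) -> EventRaster:
    df = read_table(path)
    cells = df["cell"].astype(int).tolist()
    return EventRaster(df.drop(columns="cell").to_numpy(int), cells)


# -- pose ---------------------------------------------------------------------

def write_pose(path, track: PoseTrack, meta: Dict[str, object] | None = None) -> None:
    """Wide layout: frame, then <part>_x / <part>_y per named body part."""
    meta = dict(meta or {})
    meta["frame_rate_hz"] = track.frame_rate
    cols = {"frame": np.arange(track.n_frames)}
    for i, part in enumerate(track.body_parts):
        cols[f"{part}_x"] = track.positions[:, i, 0]
        cols[f"{part}_y"] = track.positions[:, i, 1]
    write_table(path, pd.DataFrame(cols), meta)


def read_pose(path, frame_rate: float | None = None, px_to_cm: float = 1.0) -> PoseTrack:
    """Read a wide pose table; ``px_to_cm`` rescales pixel coordinates to cm."""
    if frame_rate is None:
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if line[1:].strip().startswith("frame_rate_hz="):
                    frame_rate = float(line.split("=", 1)[1])
    if frame_rate is None:
        raise ValueError(f"{path}: frame rate neither given nor in header")
    df = read_table(path)
    parts = [c[:-2] for c in df.columns if c.endswith("_x")]
    pos = np.stack([df[[f"{p}_x", f"{p}_y"]].to_numpy(float) for p in parts], axis=1)
    return PoseTrack(pos * px_to_cm, frame_rate, parts)


# -- labels, membership, registration, positions ------------------------------

def write_labels(path, labels: FreezingLabels, meta: Dict[str, object] | None = None) -> None:
    write_epochs(path, labels.bouts, {**(meta or {}), "frame_rate_hz": labels.frame_rate})


def write_membership(path, membership: Dict[str, Iterable[int]], method: str,
                     meta: Dict[str, object] | None = None) -> None:
    rows = [(int(c), g, method) for g, cells in membership.items() for c in sorted(cells)]
    write_table(path, pd.DataFrame(rows, columns=["cell", "group", "method"]), meta)


def read_membership(path) -> Dict[str, set]:
    df = read_table(path)
    out: Dict[str, set] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row.group), set()).add(int(row.cell))
    return out


def write_registration(path, reg: RegistrationMap, meta: Dict[str, object] | None = None) -> None:
    write_table(path, pd.DataFrame(reg.pairs, columns=["cell_A", "cell_B"]), meta)


def read_registration(path) -> RegistrationMap:
    df = read_table(path)
    return RegistrationMap(list(zip(df.cell_A.astype(int), df.cell_B.astype(int))))


def write_positions(path, pos: CellPositions, meta: Dict[str, object] | None = None) -> None:
    df = pd.DataFrame({"cell": pos.cell_ids, "x_um": pos.xy[:, 0], "y_um": pos.xy[:, 1]})
    write_table(path, df, meta)


def read_positions(path) -> CellPositions:
    df = read_table(path)
    return CellPositions(df.cell.astype(int).tolist(), df[["x_um", "y_um"]].to_numpy(float))
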