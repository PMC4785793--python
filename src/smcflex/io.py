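"""Readers and writers for the package's plain-text interchange formats.

* landmark tables: TSV, one row per frame, empty cells for missing landmarks;
* arm/chain traces: JSON-lines, one object per polyline (ragged arrays);
* end-to-end distances: single-column CSV with header ``distance_nm``;
* labels and ground truth: TSV;
* reports: JSON with schema version, seed and config echo, sorted keys.

Floats are serialised with ``repr`` so every format round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .conformations import ConformationLabel, DimerFrame, MovieAnnotation
from .errors import FormatError
from .synthetic import GroundTruth, GroundTruthEntry
from .wlc import ChainTrace, EndToEndSample

__all__ = [
    "LANDMARK_COLUMNS",
    "read_landmarks",
    "write_landmarks",
    "read_distances",
    "write_distances",
    "read_arm_traces",
    "write_arm_traces",
    "write_chain_traces",
    "read_movie",
    "write_labels",
    "read_labels",
    "write_truth",
    "read_truth",
    "write_report",
    "read_report",
]

LANDMARK_COLUMNS = [
    "frame_id",
    "time_s",
    "head1_x_nm",
    "head1_y_nm",
    "head2_x_nm",
    "head2_y_nm",
    "hinge_x_nm",
    "hinge_y_nm",
]

SCHEMA_VERSION = 1


def _fmt(x: Optional[float]) -> str:
    return "" if x is None else repr(float(x))


def _parse_cell(raw, column: str, line_no: int) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise FormatError(f"line {line_no}: malformed numeric in column '{column}': {raw!r}")


def read_landmarks(path: Union[str, Path]) -> List[DimerFrame]:
    """Parse a landmark TSV into frames, preserving row order.

    A landmark is treated as missing when either of its coordinate cells is
    empty.  Malformed numerics raise a row-level error with the line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {', '.join(missing)}")
    frames: List[DimerFrame] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after the header
        rec = dict(zip(df.columns, row))
        fid = _parse_cell(rec["frame_id"], "frame_id", line_no)
        tim = _parse_cell(rec["time_s"], "time_s", line_no)
        if fid is None or tim is None:
            raise FormatError(f"line {line_no}: frame_id and time_s are required")
        pts = {}
        for name in ("head1", "head2", "hinge"):
            x = _parse_cell(rec[f"{name}_x_nm"], f"{name}_x_nm", line_no)
            y = _parse_cell(rec[f"{name}_y_nm"], f"{name}_y_nm", line_no)
            pts[name] = None if (x is None or y is None) else (x, y)
        frames.append(DimerFrame(frame_id=int(fid), time=tim, **pts))
    return frames


def write_landmarks(frames: Sequence[DimerFrame], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(LANDMARK_COLUMNS) + "\n")
        for f in frames:
            cells = [str(f.frame_id), repr(float(f.time))]
            for name in ("head1", "head2", "hinge"):
                p = getattr(f, name)
                cells += ["", ""] if p is None else [_fmt(p[0]), _fmt(p[1])]
            fh.write("\t".join(cells) + "\n")


def read_distances(path: Union[str, Path]) -> EndToEndSample:
    df = pd.read_csv(path)
    if "distance_nm" not in df.columns:
        raise FormatError(f"{path}: missing required column 'distance_nm'")
    return EndToEndSample(distances=df["distance_nm"].to_numpy(dtype=float))


def write_distances(sample: Union[EndToEndSample, np.ndarray], path: Union[str, Path]) -> None:
    d = sample.distances if isinstance(sample, EndToEndSample) else np.asarray(sample)
    with open(path, "w") as fh:
        fh.write("distance_nm\n")
        for x in d:
            fh.write(repr(float(x)) + "\n")


def write_arm_traces(frames: Sequence[DimerFrame], path: Union[str, Path]) -> None:
    """JSON-lines: {"frame_id", "arm": 1|2, "x_nm": [...], "y_nm": [...]}."""
    with open(path, "w") as fh:
        for f in frames:
            for arm, tr in ((1, f.arm1_trace), (2, f.arm2_trace)):
                if tr is None:
                    continue
                obj = {
                    "frame_id": f.frame_id,
                    "arm": arm,
                    "x_nm": [float(v) for v in tr[:, 0]],
                    "y_nm": [float(v) for v in tr[:, 1]],
                }
                fh.write(json.dumps(obj) + "\n")


def read_arm_traces(path: Union[str, Path]) -> Dict[Tuple[int, int], np.ndarray]:
    traces: Dict[Tuple[int, int], np.ndarray] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                key = (int(obj["frame_id"]), int(obj["arm"]))
                traces[key] = np.column_stack(
                    [np.asarray(obj["x_nm"], dtype=float), np.asarray(obj["y_nm"], dtype=float)]
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise FormatError(f"{path} line {line_no}: bad trace record ({exc})")
    return traces


def write_chain_traces(traces: Sequence[ChainTrace], path: Union[str, Path]) -> None:
    """JSON-lines for simulated chains: {"chain_id", "x_nm", "y_nm"}."""
    with open(path, "w") as fh:
        for i, tr in enumerate(traces):
            obj = {
                "chain_id": i,
                "x_nm": [float(v) for v in tr.vertices[:, 0]],
                "y_nm": [float(v) for v in tr.vertices[:, 1]],
            }
            fh.write(json.dumps(obj) + "\n")


def read_movie(
    landmarks_path: Union[str, Path],
    traces_path: Optional[Union[str, Path]] = None,
) -> List[DimerFrame]:
    """Read landmarks and, if given, attach arm traces by frame id."""
    frames = read_landmarks(landmarks_path)
    if traces_path is not None:
        traces = read_arm_traces(traces_path)
        for f in frames:
            f.arm1_trace = traces.get((f.frame_id, 1))
            f.arm2_trace = traces.get((f.frame_id, 2))
    return frames


def write_labels(
    annotation: MovieAnnotation,
    frames: Sequence[DimerFrame],
    path: Union[str, Path],
) -> None:
    times = {f.frame_id: f.time for f in frames}
    with open(path, "w") as fh:
        fh.write("frame_id\ttime_s\tlabel\n")
        for fid, lab in annotation.labels:
            fh.write(f"{fid}\t{repr(float(times.get(fid, float('nan'))))}\t{lab.value}\n")


def read_labels(path: Union[str, Path]) -> List[Tuple[int, float, ConformationLabel]]:
    df = pd.read_csv(path, sep="\t")
    for col in ("frame_id", "time_s", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return [
        (int(r.frame_id), float(r.time_s), ConformationLabel(r.label))
        for r in df.itertuples(index=False)
    ]


def write_truth(truth: GroundTruth, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("frame_id\ttrue_state\n")
        for i, e in enumerate(truth.entries):
            fh.write(f"{i}\t{e.state.value}\n")


def read_truth(path: Union[str, Path]) -> List[ConformationLabel]:
    df = pd.read_csv(path, sep="\t")
    for col in ("frame_id", "true_state"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return [ConformationLabel(s) for s in df["true_state"]]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, ConformationLabel):
        return obj.value
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


def write_report(
    results: dict,
    path: Union[str, Path],
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> None:
    """JSON report with schema version, seed and config echo; deterministic layout."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config": _jsonable(config) if config is not None else None,
        "results": _jsonable(results),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        return json.load(fh)
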