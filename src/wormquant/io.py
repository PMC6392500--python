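"""Readers and writers for the pipeline's file formats.

Delimited text is comma-separated UTF-8 with a header row; the missing-value
token is the empty field.  Two-channel stacks are stored as multi-page TIFF,
frame-major with the CFP page before the YFP page for each time point; the
channel order and frame rate are recorded in the TIFF ImageDescription as
JSON.  Ground truth travels as a JSON sidecar next to the data file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .behavior import PostureTrace
from .calcium import TwoChannelStack
from .errors import ParameterError

__all__ = [
    "write_event_table",
    "read_event_table",
    "write_posture_trace",
    "read_posture_trace",
    "write_stack",
    "read_stack",
    "write_json",
    "read_json",
]

_FLOAT_FMT = "%.10g"


def write_event_table(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_event_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"strain": str, "plate_id": str, "worm_id": str})
    for col in ("tracked",):
        if col in df:
            df[col] = df[col].astype(bool)
    if "reversed" in df:
        df["reversed"] = df["reversed"].astype("boolean")
    return df


def write_posture_trace(trace: PostureTrace, path: str | Path) -> None:
    pd.DataFrame({"time": trace.time, "bend_angle": trace.bend_angle}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_posture_trace(path: str | Path) -> PostureTrace:
    df = pd.read_csv(path)
    if not {"time", "bend_angle"} <= set(df.columns):
        raise ParameterError(f"{path}: posture trace needs 'time' and 'bend_angle' columns")
    return PostureTrace(time=df["time"].to_numpy(), bend_angle=df["bend_angle"].to_numpy())


def write_stack(stack: TwoChannelStack, path: str | Path) -> None:
    """Multi-page TIFF, pages ordered (frame 0 CFP, frame 0 YFP, frame 1 CFP, ...)."""
    n = stack.n_frames
    pages = np.empty((2 * n,) + stack.shape, dtype=np.float32)
    pages[0::2] = stack.cyan
    pages[1::2] = stack.yellow
    meta = {"channel_order": ["cyan", "yellow"], "frame_rate_hz": stack.frame_rate,
            "layout": "frame-major, CFP page then YFP page per time point"}
    tifffile.imwrite(path, pages, description=json.dumps(meta))


def read_stack(path: str | Path, frame_rate: float | None = None) -> TwoChannelStack:
    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if frame_rate is None:
        frame_rate = meta.get("frame_rate_hz")
    if frame_rate is None:
        raise ParameterError(f"{path}: frame rate neither in metadata nor supplied")
    if pages.shape[0] % 2:
        raise ParameterError(f"{path}: odd page count, expected CFP/YFP pairs")
    return TwoChannelStack(
        cyan=pages[0::2].astype(float),
        yellow=pages[1::2].astype(float),
        frame_rate=float(frame_rate),
    )


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
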