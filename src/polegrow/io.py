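"""File-format plumbing: multi-page TIFF stacks, truth tables, CSV/JSON.

TIFF layout is time-major: one page per channel per time point, pages
ordered (t0·ch0, t0·ch1, …, t1·ch0, …).  CSV floats are written at six
significant digits so re-runs with identical inputs and seeds reproduce
byte-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .segmentation import CellMesh
from .synthetic import SceneTruth, TimeLapse

__all__ = [
    "write_stack",
    "read_stack",
    "write_truth",
    "write_csv",
    "write_meshes",
    "profiles_to_frame",
]

FLOAT_FMT = "%.6g"


def write_stack(
    path: str | Path,
    frames: Sequence[Mapping[str, np.ndarray]],
    channel_order: Sequence[str],
) -> None:
    """Write frames (list over time of {channel: 2D array}) time-major."""
    pages = [np.asarray(f[ch], dtype=np.float32) for f in frames for ch in channel_order]
    tifffile.imwrite(str(path), np.stack(pages), photometric="minisblack")


def write_timelapse(path: str | Path, tl: TimeLapse) -> None:
    channel_order = [ch for ch in ("phase", "label", "cap") if ch in tl.frames[0]]
    write_stack(path, tl.frames, channel_order)


def read_stack(
    path: str | Path, channels: Mapping[str, int]
) -> list[dict[str, np.ndarray]]:
    """Read a time-major multi-page TIFF into [{channel: image}, ...].

    ``channels`` maps names to page indices within one time point; the
    number of channels per time point is ``max(index) + 1``.
    """
    pages = tifffile.imread(str(path))
    if pages.ndim == 2:
        pages = pages[None]
    n_ch = max(channels.values()) + 1
    if len(pages) % n_ch:
        raise ValueError(
            f"{path}: {len(pages)} pages not divisible by {n_ch} channels"
        )
    frames = []
    for t in range(len(pages) // n_ch):
        frames.append(
            {name: pages[t * n_ch + idx] for name, idx in channels.items()}
        )
    return frames


def write_truth(out_dir: str | Path, truth: SceneTruth) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "truth.json").write_text(truth.to_json())
    write_csv(out / "truth_cells.csv", truth.to_table())


def write_csv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_meshes(path: str | Path, meshes: Sequence[CellMesh]) -> None:
    payload = [
        dict(
            cell_id=m.cell_id,
            degenerate=m.degenerate,
            length_um=round(m.length, 6),
            outline=np.round(m.outline, 6).tolist(),
            centerline=np.round(m.centerline, 6).tolist(),
            arc_length=np.round(m.arc_length, 6).tolist(),
            local_width=np.round(m.local_width, 6).tolist(),
        )
        for m in meshes
    ]
    Path(path).write_text(json.dumps(payload))


def profiles_to_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for pos, val in zip(p.positions, p.values):
            rows.append(
                dict(cell_id=p.cell_id, channel=p.channel, position_um=pos, value=val)
            )
    return pd.DataFrame(rows, columns=["cell_id", "channel", "position_um", "value"])
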