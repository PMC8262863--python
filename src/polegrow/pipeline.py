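"""High-level measurement workflows over whole frames and time lapses.

These functions chain segmentation, mesh extraction and the per-cell
measurements so that the command-line interface, validation scripts and
tests all exercise the identical code path: segment the phase channel,
build a mesh per cell, read intensity profiles from the fluorescence
channel(s), then compute morphometrics, unlabeled-wall statistics,
septum counts or pole profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import poleprofile as pp
from . import pulsechase as pc
from .segmentation import (
    AxialProfile,
    CellMask,
    CellMesh,
    axial_profile,
    extract_mesh,
    mesh_width,
    segment_frame,
)

__all__ = [
    "SegmentedCell",
    "segment_and_mesh",
    "morphometry_frame",
    "unlabeled_measures_frame",
    "estimate_rate_from_timelapse",
    "septa_survey",
    "pole_profile_survey",
]


@dataclass
class SegmentedCell:
    mask: CellMask
    mesh: CellMesh


def segment_and_mesh(
    phase: np.ndarray,
    pixel_size: float,
    *,
    min_area: int = 80,
    max_area: int | None = None,
    polarity: str = "auto",
    drop_degenerate: bool = False,
) -> list[SegmentedCell]:
    """Segment a phase-contrast frame and mesh every detected cell."""
    cells = []
    for mask in segment_frame(phase, min_area=min_area, max_area=max_area, polarity=polarity):
        mesh = extract_mesh(mask, pixel_size)
        if drop_degenerate and mesh.degenerate:
            continue
        cells.append(SegmentedCell(mask=mask, mesh=mesh))
    return cells


def morphometry_frame(
    phase: np.ndarray,
    pixel_size: float,
    *,
    strain: str = "",
    replicate: str = "",
    **seg_kw,
) -> pd.DataFrame:
    """Per-cell length and width table from one phase frame."""
    rows = []
    for cell in segment_and_mesh(phase, pixel_size, **seg_kw):
        rows.append(
            dict(
                strain=strain,
                replicate=replicate,
                cell_id=cell.mesh.cell_id,
                length_um=cell.mesh.length,
                width_um=mesh_width(cell.mesh),
                degenerate=cell.mesh.degenerate,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["strain", "replicate", "cell_id", "length_um", "width_um", "degenerate"],
    )


def _profiles(
    cells: list[SegmentedCell],
    channel_frame: np.ndarray,
    channel_name: str,
    band_halfwidth: float,
) -> list[AxialProfile]:
    out = []
    for cell in cells:
        if cell.mesh.degenerate:
            continue
        out.append(
            axial_profile(
                cell.mesh,
                channel_frame,
                mask=cell.mask,
                band_halfwidth=band_halfwidth,
                channel=channel_name,
            )
        )
    return out


def unlabeled_measures_frame(
    phase: np.ndarray,
    label: np.ndarray,
    pixel_size: float,
    *,
    time: float = 0.0,
    frac: float = 0.2,
    band_halfwidth: float = 0.65,
    background_subtract: bool = True,
    **seg_kw,
) -> list[pc.UnlabeledMeasure]:
    """Unlabeled-wall length of every non-degenerate cell in one frame.

    The camera background (median outside the dilated masks) is removed
    from the label profiles before thresholding by default; the 20%-of-
    max rule assumes signal, not signal + offset.
    """
    cells = segment_and_mesh(phase, pixel_size, **seg_kw)
    bg = pp.estimate_background(label, [c.mask for c in cells]) if background_subtract else 0.0
    measures = []
    for prof in _profiles(cells, label, "label", band_halfwidth):
        prof.values = np.maximum(prof.values - bg, 0.0)
        measures.append(pc.unlabeled_length(prof, frac=frac, time=time))
    return measures


def estimate_rate_from_timelapse(
    frames: dict[float, dict[str, np.ndarray]],
    pixel_size: float,
    t_initial: float,
    t_final: float,
    *,
    frac: float = 0.2,
    **kw,
) -> pc.ElongationEstimate:
    """Population elongation rate from two time points of a pulse-chase
    stack (``frames`` maps time → {channel: image})."""
    m0 = unlabeled_measures_frame(
        frames[t_initial]["phase"],
        frames[t_initial]["label"],
        pixel_size,
        time=t_initial,
        frac=frac,
        **kw,
    )
    m1 = unlabeled_measures_frame(
        frames[t_final]["phase"],
        frames[t_final]["label"],
        pixel_size,
        time=t_final,
        frac=frac,
        **kw,
    )
    return pc.polar_elongation_rate(m0, m1)


def septa_survey(
    phase: np.ndarray,
    label: np.ndarray,
    pixel_size: float,
    *,
    prominence_frac: float = 0.3,
    pole_exclusion: float = 0.4,
    band_halfwidth: float = 0.65,
    background_subtract: bool = True,
    **seg_kw,
) -> tuple[list[pc.SeptaRecord], dict]:
    """Count septa in every cell of a frame and classify the population."""
    cells = segment_and_mesh(phase, pixel_size, **seg_kw)
    bg = pp.estimate_background(label, [c.mask for c in cells]) if background_subtract else 0.0
    records = []
    for prof in _profiles(cells, label, "label", band_halfwidth):
        prof.values = np.maximum(prof.values - bg, 0.0)
        if prof.length < 2 * pole_exclusion + 2 * prof.step:
            records.append(pc.SeptaRecord(prof.cell_id, 0))
            continue
        records.append(
            pc.count_septa(
                prof, prominence_frac=prominence_frac, pole_exclusion=pole_exclusion
            )
        )
    fractions = pc.septa_fractions(records) if records else {}
    return records, fractions


def pole_profile_survey(
    phase: np.ndarray,
    fluor: np.ndarray,
    pixel_size: float,
    *,
    window: float = 0.5,
    grid_step: float = 0.065,
    max_distance: float = 2.0,
    band_halfwidth: float = 0.65,
    **seg_kw,
) -> pp.MeanPoleProfile:
    """Brightest-pole-aligned mean fluorescence profile of a population."""
    cells = segment_and_mesh(phase, pixel_size, **seg_kw)
    background = pp.estimate_background(fluor, [c.mask for c in cells])
    aligned = []
    for prof in _profiles(cells, fluor, "fluor", band_halfwidth):
        w = min(window, prof.length / 2)
        pole = pp.brightest_pole(prof, window=w)
        aligned.append(pp.align_to_pole(prof, pole))
    if not aligned:
        raise ValueError("no usable cells in frame")
    return pp.mean_pole_profile(
        aligned,
        grid_step=grid_step,
        max_distance=max_distance,
        background=background,
    )
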