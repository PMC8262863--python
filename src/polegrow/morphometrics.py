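"""Replicate-aware morphometrics and strain comparisons.

Length and width are recorded per cell but inference runs on biological-
replicate means (the SuperPlot convention): each replicate population
contributes one mean to a one-way ANOVA, which avoids treating hundreds
of cells from the same culture as independent observations.

Also provides the beta-galactosidase (Miller-unit) activity computation
used for promoter-reporter assays:

    activity = (OD420 − 1.75·OD550) / (t_min · V_ml · OD600 · 1000)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MorphoRecord",
    "BetaGalInput",
    "AnovaResult",
    "MillerResult",
    "records_to_frame",
    "summarize_replicates",
    "anova_replicate_means",
    "anova_vs_reference",
    "miller_units",
    "significance_label",
]


@dataclass(frozen=True)
class MorphoRecord:
    """Length and width of one cell, keyed by strain and replicate."""

    strain: str
    replicate: str
    cell_id: int
    length: float
    width: float

    def __post_init__(self):
        if not (self.length >= self.width > 0):
            raise ValueError(
                f"need length >= width > 0, got L={self.length}, W={self.width}"
            )


@dataclass(frozen=True)
class BetaGalInput:
    """Raw optical densities and assay conditions for one Miller-unit
    measurement (time in minutes, volume in ml)."""

    od420: float
    od550: float
    od600: float
    time: float
    volume: float = 1.0

    def __post_init__(self):
        if min(self.od420, self.od550) < 0:
            raise ValueError("optical densities must be >= 0")
        if self.time <= 0 or self.od600 <= 0 or self.volume <= 0:
            raise ValueError("time, od600 and volume must be > 0")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int


@dataclass(frozen=True)
class MillerResult:
    activity: float
    negative: bool


def records_to_frame(records: Sequence[MorphoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                strain=r.strain,
                replicate=r.replicate,
                cell_id=r.cell_id,
                length_um=r.length,
                width_um=r.width,
            )
            for r in records
        ]
    )


def summarize_replicates(
    records: Sequence[MorphoRecord] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One summary row per (strain, replicate) plus the pooled per-cell
    table in SuperPlot-ready long format.

    Replicates with no cells never appear; a replicate label present in
    the input but carrying no rows is logged and dropped.
    """
    df = (
        records.copy()
        if isinstance(records, pd.DataFrame)
        else records_to_frame(records)
    )
    required = {"strain", "replicate", "length_um", "width_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("no records")
    empty = df.groupby(["strain", "replicate"], sort=True).size() == 0
    for key in empty[empty].index:
        logger.warning("replicate %s dropped: no cells", key)
    summary = (
        df.groupby(["strain", "replicate"], sort=True)
        .agg(
            n_cells=("length_um", "size"),
            mean_length_um=("length_um", "mean"),
            mean_width_um=("width_um", "mean"),
        )
        .reset_index()
    )
    pooled = df.melt(
        id_vars=[c for c in ("strain", "replicate", "cell_id") if c in df.columns],
        value_vars=["length_um", "width_um"],
        var_name="metric",
        value_name="value",
    )
    return summary, pooled


def anova_replicate_means(*groups: Sequence[float]) -> AnovaResult:
    """One-way ANOVA whose observations are replicate means.

    Every group needs at least two replicates, otherwise the within-
    group variance is undefined.  Groups with zero variance and equal
    means give F = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, a in enumerate(arrays):
        if len(a) < 2:
            raise ValueError(f"group {i} has fewer than 2 replicates")
    grand = np.concatenate(arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ssb = sum(len(a) * (a.mean() - grand.mean()) ** 2 for a in arrays)
    df_b = len(arrays) - 1
    df_w = len(grand) - len(arrays)
    if ssw == 0 and ssb == 0:
        return AnovaResult(0.0, 1.0, df_b, df_w)
    F, p = stats.f_oneway(*arrays)
    if not np.isfinite(F):  # zero within-group variance, nonzero between
        F, p = np.inf, 0.0
    return AnovaResult(float(F), float(p), df_b, df_w)


def anova_vs_reference(
    summary: pd.DataFrame,
    reference_strain: str,
    metric: str = "mean_length_um",
) -> pd.DataFrame:
    """Pairwise replicate-mean ANOVA of each strain against a reference.

    Returns one row per non-reference strain with F, p, degrees of
    freedom, and a significance label (* for p < 0.05, ** for
    p < 0.0001).
    """
    if reference_strain not in set(summary["strain"]):
        raise ValueError(f"reference strain {reference_strain!r} not in summary")
    ref = summary.loc[summary["strain"] == reference_strain, metric].to_numpy()
    rows = []
    for strain, grp in summary.groupby("strain", sort=True):
        if strain == reference_strain:
            continue
        res = anova_replicate_means(grp[metric].to_numpy(), ref)
        rows.append(
            dict(
                strain=strain,
                reference=reference_strain,
                metric=metric,
                F=res.F,
                p=res.p,
                df_between=res.df_between,
                df_within=res.df_within,
                significance=significance_label(res.p),
            )
        )
    return pd.DataFrame(rows)


def significance_label(p: float) -> str:
    if p < 0.0001:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def miller_units(b: BetaGalInput) -> MillerResult:
    """Beta-galactosidase activity in Miller-style units.

    Negative activities (OD420 < 1.75·OD550) are possible with noisy
    blanks; they are returned as-is with ``negative=True`` rather than
    clamped, so downstream QC can decide.
    """
    activity = (b.od420 - 1.75 * b.od550) / (b.time * b.volume * b.od600 * 1000.0)
    return MillerResult(activity=float(activity), negative=activity < 0)
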