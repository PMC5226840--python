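"""Normalization of bead-plex (QuantiGene-style) transcript readings.

Raw bead intensities arrive as technical replicates per (gene, timepoint,
biological replicate).  The normalization order is fixed: technical
replicates are averaged first, the background intensity is subtracted,
and the result is divided by the same-sample value of a designated
reference gene (one with flat diurnal expression, e.g. *timeless*).
Biological replicates are then summarised as mean and SD per timepoint,
and trough-vs-acrophase differences are tested with Welch's two-sample
t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import TimeCourse

logger = logging.getLogger("dielkit")

__all__ = [
    "PlexReadings",
    "NormalizedPlex",
    "normalize_plex",
    "trough_acrophase_test",
    "read_plex_long",
]


@dataclass(frozen=True)
class PlexReadings:
    """Long-format plex intensities.

    `table` columns: gene, zt, bio_rep, tech_rep, intensity.  `background`
    is a per-plate scalar unless a per-gene mapping is supplied.
    """

    table: pd.DataFrame
    reference_gene: str
    background: float | Mapping[str, float] = 0.0

    REQUIRED = ("gene", "zt", "bio_rep", "tech_rep", "intensity")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"plex table missing columns {sorted(missing)}")
        if self.reference_gene not in set(self.table["gene"]):
            raise ValueError(f"reference gene {self.reference_gene!r} absent")
        if (self.table["intensity"] < 0).any():
            raise ValueError("negative raw intensity")

    def background_of(self, gene: str) -> float:
        if isinstance(self.background, Mapping):
            return float(self.background[gene])
        return float(self.background)


@dataclass(frozen=True)
class NormalizedPlex:
    """Per-bio-rep normalized time courses plus mean/SD summaries."""

    per_replicate: dict[int, TimeCourse]
    mean: pd.DataFrame  # gene x ZT
    sd: pd.DataFrame  # gene x ZT
    n_floored: int  # negative post-subtraction values clamped to 0


def normalize_plex(readings: PlexReadings) -> NormalizedPlex:
    """Average technical replicates, subtract background, normalize to the
    reference gene, then summarise biological replicates.

    The reference division uses the same (timepoint, bio-rep) sample's
    background-subtracted reference value; a non-positive reference value
    is an error naming the sample.  Negative post-subtraction values for
    non-reference genes are floored at 0 and counted.
    """
    df = readings.table
    # step 1: average technical replicates
    tech_avg = (
        df.groupby(["gene", "zt", "bio_rep"], sort=True)["intensity"]
        .mean()
        .reset_index()
    )
    # step 2: subtract background
    tech_avg["corrected"] = [
        v - readings.background_of(g)
        for g, v in zip(tech_avg["gene"], tech_avg["intensity"])
    ]
    n_floored = int((tech_avg["corrected"] < 0).sum())
    if n_floored:
        logger.info("normalize_plex: floored %d negative values at 0", n_floored)
    tech_avg["corrected"] = tech_avg["corrected"].clip(lower=0.0)

    # step 3: divide by the same-sample reference value
    ref = tech_avg[tech_avg["gene"] == readings.reference_gene].set_index(
        ["zt", "bio_rep"]
    )["corrected"]
    norm_rows = []
    for _, row in tech_avg.iterrows():
        key = (row["zt"], row["bio_rep"])
        if key not in ref.index:
            raise ValueError(f"no reference reading for sample ZT{key[0]} rep{key[1]}")
        ref_val = ref.loc[key]
        if ref_val <= 0:
            raise ValueError(
                f"reference gene non-positive after background subtraction "
                f"in sample ZT{key[0]} rep{key[1]}"
            )
        norm_rows.append(row["corrected"] / ref_val)
    tech_avg["normalized"] = norm_rows

    wide = tech_avg.pivot_table(
        index=["gene", "bio_rep"], columns="zt", values="normalized", sort=True
    )
    timepoints = tuple(float(z) for z in wide.columns)
    interval = timepoints[1] - timepoints[0] if len(timepoints) > 1 else 0.0
    per_rep: dict[int, TimeCourse] = {}
    for rep in sorted(set(df["bio_rep"])):
        sub = wide.xs(rep, level="bio_rep")
        per_rep[int(rep)] = TimeCourse(
            tuple(sub.index), timepoints, sub.to_numpy(), interval
        )
    mean = wide.groupby(level="gene").mean()
    sd = wide.groupby(level="gene").std(ddof=1)
    return NormalizedPlex(per_rep, mean, sd, n_floored)


def trough_acrophase_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> float:
    """Welch's two-sample t-test p-value between trough and acrophase
    measurement groups.  Identical degenerate groups (zero variance, equal
    means) yield p = 1 by convention."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(p)


def read_plex_long(source, reference_gene: str, background: float = 0.0) -> PlexReadings:
    """Read a long-format TSV (gene, zt, bio_rep, tech_rep, intensity)."""
    df = pd.read_csv(source, sep="\t")
    return PlexReadings(df, reference_gene, background)
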