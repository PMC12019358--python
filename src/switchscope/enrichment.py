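"""Topic-by-subgroup enrichment scores.

The statistic compares how much of a topic's total weight falls inside a
patient subgroup with how much would fall there if topic and subgroup were
independent:

    theta(k, j) = N * sum_n q(n,k) y(n,j) / (sum_n q(n,k) * sum_n y(n,j))

where q(n,k) is the topic-k weight of note n (rows sum to 1), y(n,j) is the
binary subgroup indicator, and N is the note count. The N factor makes the
score dimensionless — under independence theta = 1 — so the reported
natural-log score is centred at 0. Cells whose topic weight or subgroup
size is zero are undefined and reported as missing, never silently zeroed.
An un-scaled variant (without the N factor, matching a raw ratio-of-sums
reading of the formula) is available via ``scale_by_n=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AGE_BINS",
    "RACE_CATEGORIES",
    "age_bin",
    "SubgroupIndicator",
    "EnrichmentMatrix",
    "stratify",
    "enrichment_scores",
    "recover_planted_enrichment",
]

AGE_BINS = ("<21", "21-30", "31-40", "40+")
RACE_CATEGORIES = (
    "White",
    "Latinx",
    "Black or African American",
    "Asian",
    "Other",
    "Multi-Race/Ethnicity",
)


def age_bin(age: float) -> str:
    """Assign an age to its analysis bin.

    The boundary age 40 goes to "31-40": the published bin labels overlap
    at 40, so closed upper bounds are used throughout (21-30 means
    21 <= a <= 30).
    """
    if age < 21:
        return AGE_BINS[0]
    if age <= 30:
        return AGE_BINS[1]
    if age <= 40:
        return AGE_BINS[2]
    return AGE_BINS[3]


@dataclass
class SubgroupIndicator:
    """Notes x subgroups binary membership matrix for one stratification axis."""

    y: pd.DataFrame  # index = note ids, columns = subgroup labels, values 0/1
    axis: str

    def validate(self) -> None:
        vals = self.y.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("subgroup indicator entries must be 0/1")
        if (vals.sum(axis=1) > 1).any():
            raise ValueError("a note may belong to at most one subgroup per axis")


@dataclass
class EnrichmentMatrix:
    """Log-transformed theta over topics x subgroups; NaN marks undefined cells."""

    theta_log: pd.DataFrame
    n_notes: int
    meta: dict

    def to_long(self) -> pd.DataFrame:
        long = self.theta_log.stack(future_stack=True).rename("log_theta").reset_index()
        long.columns = ["topic", "subgroup", "log_theta"]
        return long


def stratify(
    demographics: pd.DataFrame,
    axis: str,
    note_patients: pd.Series,
) -> SubgroupIndicator:
    """Build the notes x subgroups indicator for one axis.

    ``note_patients`` maps note id (index) -> patient id. Race categories
    are used verbatim; unknown categories are logged and binned as
    "Other". Notes whose patient has no demographic record are excluded
    (all-zero row) from the axis.
    """
    demo = demographics.set_index("patient_id")
    if axis == "race":
        labels = list(RACE_CATEGORIES)
        raw = note_patients.map(demo["race_ethnicity"])
        unknown = raw.dropna()[~raw.dropna().isin(labels)]
        if len(unknown):
            warnings.warn(
                f"{len(unknown)} notes with unknown race/ethnicity categories "
                f"{sorted(unknown.unique())}; binned as 'Other'"
            )
            raw = raw.where(raw.isin(labels) | raw.isna(), "Other")
    elif axis == "age":
        labels = list(AGE_BINS)
        ages = note_patients.map(demo["age_first_rx"])
        raw = ages.map(lambda a: age_bin(a) if pd.notna(a) else np.nan)
    else:
        raise ValueError(f"unknown stratification axis: {axis!r}")
    y = pd.DataFrame(0, index=note_patients.index, columns=labels, dtype=int)
    for lab in labels:
        y.loc[(raw == lab).to_numpy(), lab] = 1
    return SubgroupIndicator(y=y, axis=axis)


def enrichment_scores(
    q: pd.DataFrame | np.ndarray,
    y: SubgroupIndicator | pd.DataFrame,
    *,
    scale_by_n: bool = True,
) -> EnrichmentMatrix:
    """Compute log theta(k, j) for every topic k and subgroup j.

    ``q`` rows must sum to 1 (soft topic assignments per note); ``y`` is a
    notes x subgroups 0/1 indicator aligned row-for-row with ``q``.
    """
    yf = y.y if isinstance(y, SubgroupIndicator) else y
    axis = y.axis if isinstance(y, SubgroupIndicator) else "custom"
    qf = pd.DataFrame(q) if not isinstance(q, pd.DataFrame) else q
    if len(qf) != len(yf):
        raise ValueError(f"q has {len(qf)} notes but y has {len(yf)}")
    n = len(qf)
    qm = qf.to_numpy(dtype=float)
    ym = yf.to_numpy(dtype=float)
    joint = qm.T @ ym  # topics x subgroups
    topic_tot = qm.sum(axis=0)  # sum_n q(n,k)
    group_tot = ym.sum(axis=0)  # sum_n y(n,j)
    denom = np.outer(topic_tot, group_tot)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = joint / denom
        if scale_by_n:
            theta = theta * n
        log_theta = np.log(theta)
    log_theta[denom == 0] = np.nan
    out = pd.DataFrame(log_theta, index=qf.columns, columns=yf.columns)
    return EnrichmentMatrix(
        theta_log=out,
        n_notes=n,
        meta={
            "axis": axis,
            "log_base": "e",
            "scaled_by_n": scale_by_n,
            "undefined_cells": int(np.isnan(log_theta).sum()),
        },
    )


def recover_planted_enrichment(
    matrix: EnrichmentMatrix,
    *,
    threshold: float = 0.3,
    min_expected_count: float = 5.0,
    q: pd.DataFrame | np.ndarray | None = None,
    y: SubgroupIndicator | pd.DataFrame | None = None,
) -> list[tuple[str, str, float]]:
    """Rank (topic, subgroup) cells by log theta and return those above threshold.

    When ``q`` and ``y`` are supplied, cells whose expected joint support
    under independence (topic weight x subgroup share) is below
    ``min_expected_count`` notes are suppressed — their log theta is
    dominated by sampling noise rather than signal.
    """
    tl = matrix.theta_log.copy()
    if q is not None and y is not None:
        yf = y.y if isinstance(y, SubgroupIndicator) else y
        qf = pd.DataFrame(q)
        expected = np.outer(qf.sum(axis=0), yf.sum(axis=0)) / max(len(qf), 1)
        tl = tl.mask(pd.DataFrame(expected < min_expected_count, index=tl.index, columns=tl.columns))
    cells = [
        (str(k), str(j), float(tl.loc[k, j]))
        for k in tl.index
        for j in tl.columns
        if np.isfinite(tl.loc[k, j]) and tl.loc[k, j] >= threshold
    ]
    return sorted(cells, key=lambda c: -c[2])
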